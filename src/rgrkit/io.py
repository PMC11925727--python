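"""File formats, fixture generation and the illumination-dose helper.

FASTA and GenBank go through Biopython; internal coordinates are 0-based
half-open and converted to GenBank's 1-based inclusive locations only at
the file boundary. The fixture generator builds everything the test and
demo pipelines need — random spacers, a synthetic circular destination
vector with a type IIS dropout, and a promoter with planted PAMs — from a
single seed, with rejection sampling wherever a sequence must be free of
enzyme sites.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .cloning import DsFragment
from .design import Spacer, domesticate_check
from .errors import DesignError, RgrKitError
from .registry import PartRegistry
from .seqcore import NucSeq, revcomp_str

logger = logging.getLogger("rgrkit")

FEATURE_TYPES = ("ribozyme", "spacer", "scaffold", "direct_repeat",
                 "enzyme_site", "arm", "orf")


@dataclass(frozen=True)
class Feature:
    """One annotation: 0-based half-open interval on the record."""

    label: str
    start: int
    end: int
    strand: str = "plus"
    type: str = "misc_feature"


@dataclass
class AnnotatedRecord:
    """A named DNA sequence with interval annotations."""

    id: str
    sequence: str
    features: list[Feature] = field(default_factory=list)
    description: str = ""

    def __post_init__(self) -> None:
        self.sequence = str(NucSeq(self.sequence))
        for f in self.features:
            if not (0 <= f.start < f.end <= len(self.sequence)):
                raise RgrKitError(
                    f"feature {f.label!r} [{f.start}, {f.end}) outside "
                    f"record of length {len(self.sequence)}"
                )


# -- FASTA -----------------------------------------------------------------

def read_fasta(path: str | Path) -> list[AnnotatedRecord]:
    """Read a multi-record FASTA; sequences are uppercased on read."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        if raw != raw.upper():
            logger.info("record %s: lowercase bases uppercased on read", rec.id)
        records.append(AnnotatedRecord(id=rec.id, sequence=raw.upper(),
                                       description=rec.description))
    return records


def write_fasta(records: Sequence[AnnotatedRecord], path: str | Path) -> None:
    seqio_records = [
        SeqRecord(Seq(r.sequence), id=r.id,
                  description=r.description or "")
        for r in records
    ]
    SeqIO.write(seqio_records, str(path), "fasta")


# -- GenBank ---------------------------------------------------------------

def write_genbank(record: AnnotatedRecord, path: str | Path,
                  topology: str = "linear") -> None:
    """Write a record as a GenBank flat file.

    Internal 0-based half-open intervals map directly onto Biopython's
    ``FeatureLocation`` (which emits 1-based inclusive text); minus-strand
    features come out as ``complement(..)`` locations.
    """
    rec = SeqRecord(Seq(record.sequence), id=record.id, name=record.id[:16],
                    description=record.description or "")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = topology
    for f in record.features:
        loc = FeatureLocation(f.start, f.end, strand=1 if f.strand == "plus" else -1)
        rec.features.append(SeqFeature(loc, type=_genbank_type(f.type),
                                       qualifiers={"label": [f.label],
                                                   "rgrkit_type": [f.type]}))
    SeqIO.write([rec], str(path), "genbank")


def _genbank_type(t: str) -> str:
    return {"orf": "CDS"}.get(t, "misc_feature")


def read_genbank(path: str | Path) -> AnnotatedRecord:
    rec = SeqIO.read(str(path), "genbank")
    features = []
    for f in rec.features:
        if f.type == "source":
            continue
        label = (f.qualifiers.get("label") or [f.type])[0]
        ftype = (f.qualifiers.get("rgrkit_type") or [f.type])[0]
        features.append(Feature(
            label=label, start=int(f.location.start), end=int(f.location.end),
            strand="minus" if f.location.strand == -1 else "plus", type=ftype,
        ))
    return AnnotatedRecord(id=rec.id, sequence=str(rec.seq).upper(),
                           features=features, description=rec.description)


# -- spacer tables ---------------------------------------------------------

def read_spacer_table(path: str | Path) -> list[Spacer]:
    """Plain-text spacer input: one per line, ``label<TAB>sequence<TAB>cas``.

    Lines starting with ``#`` and blank lines are skipped; whitespace of
    any kind separates the three fields.
    """
    spacers = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 3:
            raise DesignError(
                f"{path}:{ln}: expected 'label sequence cas', got {len(fields)} fields"
            )
        label, seq, cas = fields
        spacers.append(Spacer(sequence=seq, cas=cas.lower(), label=label))
    return spacers


# -- illumination dose -----------------------------------------------------

@dataclass(frozen=True)
class IlluminationRegime:
    """A pulsed blue-light regime (e.g. 1 mW/cm², 20 s ON, 40 s OFF, 470 nm)."""

    intensity_mw_cm2: float
    on_s: float
    off_s: float
    duration_h: float
    wavelength_nm: float = 470.0

    def __post_init__(self) -> None:
        if self.intensity_mw_cm2 <= 0 or self.duration_h <= 0:
            raise DesignError("intensity and duration must be positive")
        if self.on_s < 0 or self.off_s < 0 or self.on_s + self.off_s <= 0:
            raise DesignError("need on_s >= 0, off_s >= 0, on_s + off_s > 0")


def illumination_dose(r: IlluminationRegime) -> tuple[float, float, float]:
    """(duty cycle, total ON seconds, fluence in J/cm²) for a regime.

    duty = on / (on + off); total_on = duty × duration;
    fluence = intensity [mW/cm²] × total_on [s] / 1000.
    """
    duty = r.on_s / (r.on_s + r.off_s)
    total_on_s = duty * r.duration_h * 3600.0
    fluence_j_cm2 = r.intensity_mw_cm2 * total_on_s / 1000.0
    return duty, total_on_s, fluence_j_cm2


# -- fixture generation ----------------------------------------------------

@dataclass
class FixtureBundle:
    """Synthetic inputs for a full design→cleavage→assembly run."""

    spacers: list[Spacer]
    vector_sapi: DsFragment
    vector_bbsi: DsFragment
    promoter: str
    promoter_tss: int
    planted_pams: list[dict]


def _random_clean_seq(rng: random.Random, length: int,
                      registry: PartRegistry) -> str:
    """Random sequence free of every registered enzyme's sites (both strands)."""
    enzymes = list(registry.enzymes.values())
    for _ in range(10_000):
        seq = "".join(rng.choice("ACGT") for _ in range(length))
        if not domesticate_check(seq, enzymes):
            return seq
    raise DesignError(f"could not sample an enzyme-site-free {length}-mer")


def _dropout_vector(rng: random.Random, registry: PartRegistry,
                    enzyme_name: str, overhangs: tuple[str, str],
                    vector_len: int) -> DsFragment:
    """Circular destination vector with an inward dropout for one enzyme.

    Layout (plus strand): backbone + o5 + filler + RC(rec) + dropout core
    + rec + filler + o3 + (backbone continues around the circle). Digestion
    releases a backbone whose right end presents o5 and whose left end
    presents o3 (plus-strand images) — exactly the ends of a designed
    insert — plus a site-carrying dropout that is discarded.
    """
    enz = registry.get_enzyme(enzyme_name)
    o5, o3 = overhangs
    rec = enz.recognition.pattern
    filler = "A" * enz.cut_offset_top
    cassette = (o5 + filler + revcomp_str(rec)
                + _random_clean_seq(rng, 60, registry)
                + rec + filler + o3)
    backbone_len = vector_len - len(cassette)
    if backbone_len < 40:
        raise DesignError(
            f"vector_len {vector_len} too short for a dropout cassette"
        )
    for _ in range(10_000):
        backbone = _random_clean_seq(rng, backbone_len, registry)
        span = backbone + cassette
        # the full circle must contain exactly the two designed sites
        from .seqcore import find_sites
        pad = span + span[: len(rec) - 1]
        if len(find_sites(NucSeq(pad), enz.recognition, "both")) == 2:
            return DsFragment(span, topology="circular",
                              name=f"dest_vector_{enzyme_name.lower()}")
    raise DesignError("could not sample a clean vector backbone")


def _promoter_with_pams(rng: random.Random, length: int, tss: int,
                        registry: PartRegistry) -> tuple[str, list[dict]]:
    """Promoter with one clean SpCas9 and one clean LbCas12a protospacer
    planted wholly inside the default 75–300 bp upstream window."""
    from .design import DEFAULT_SPACER_LEN, TargetWindow, find_candidate_spacers

    window = TargetWindow()
    planted: list[dict] = []
    for _ in range(10_000):
        seq = list("".join(rng.choice("ACTG") for _ in range(length)))
        # wipe PAM-like context by rebuilding below, then plant:
        # SpCas9: protospacer + AGG starting 200 bp upstream of the TSS
        sp_len = DEFAULT_SPACER_LEN["spcas9"]
        sp_start = tss - 200
        for i, ch in enumerate("AGG"):
            seq[sp_start + sp_len + i] = ch
        # LbCas12a: TTTA PAM then protospacer, protospacer starting 150 bp
        # upstream of the TSS
        lb_len = DEFAULT_SPACER_LEN["lbcas12a"]
        lb_start = tss - 150
        for i, ch in enumerate("TTTA"):
            seq[lb_start - 4 + i] = ch
        s = "".join(seq)
        if domesticate_check(s, list(registry.enzymes.values())):
            continue
        sp_hits = find_candidate_spacers(s, tss, "spcas9", window)
        lb_hits = find_candidate_spacers(s, tss, "lbcas12a", window)
        if not any(h.start == sp_start and h.strand == "plus" for h in sp_hits):
            continue
        if not any(h.start == lb_start and h.strand == "plus" for h in lb_hits):
            continue
        planted = [
            {"cas": "spcas9", "start": sp_start, "end": sp_start + sp_len,
             "strand": "plus", "pam": s[sp_start + sp_len : sp_start + sp_len + 3]},
            {"cas": "lbcas12a", "start": lb_start, "end": lb_start + lb_len,
             "strand": "plus", "pam": s[lb_start - 4 : lb_start]},
        ]
        return s, planted
    raise DesignError("could not construct a promoter fixture")


def generate_fixtures(seed: int, n_spacers: int = 4,
                      vector_len: int = 400,
                      registry: PartRegistry | None = None) -> FixtureBundle:
    """Deterministic synthetic fixture bundle (same seed → identical bundle).

    Produces ``n_spacers`` random enzyme-site-free spacers alternating
    between Cas systems, one SapI and one BbsI circular destination
    vector (each with an inward dropout wired to the default overhang
    set), and a 1 kb promoter with planted PAMs recoverable by
    :func:`rgrkit.design.find_candidate_spacers`.
    """
    if registry is None:
        from .registry import load_registry
        registry = load_registry()
    rng = random.Random(seed)

    from .design import DEFAULT_SPACER_LEN

    spacers = []
    for i in range(n_spacers):
        cas = "spcas9" if i % 2 == 0 else "lbcas12a"
        seq = _random_clean_seq(rng, DEFAULT_SPACER_LEN[cas], registry)
        spacers.append(Spacer(sequence=seq, cas=cas, label=f"sp{i:02d}_{cas}"))

    vector_sapi = _dropout_vector(rng, registry, "SapI",
                                  tuple(registry.get_overhang_set("sapi_default")[:2]),
                                  vector_len)
    vector_bbsi = _dropout_vector(rng, registry, "BbsI",
                                  tuple(registry.get_overhang_set("bbsi_default")[:2]),
                                  vector_len)
    tss = 900
    promoter, planted = _promoter_with_pams(rng, 1000, tss, registry)
    return FixtureBundle(spacers=spacers, vector_sapi=vector_sapi,
                         vector_bbsi=vector_bbsi, promoter=promoter,
                         promoter_tss=tss, planted_pams=planted)
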