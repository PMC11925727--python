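"""Part registry: sequence parts and type IIS enzyme definitions.

Everything biologically fixed-but-configurable lives here: ribozyme
templates, guide scaffolds, enzyme cut geometries and the overhang sets
used for directional Golden Gate insertion. The bundled defaults
(``data/default_registry.yaml``) are the minimal hammerhead / genomic HDV
ribozymes of the RGR literature plus the canonical SpCas9 scaffold and
LbCas12a direct repeat; users supply their own YAML to override or extend
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO

import yaml

from .errors import PartLookupError, RegistryError
from .seqcore import MotifPattern, NucSeq, find_sites, revcomp_str

PLACEHOLDER = "NNNNNN"
PART_ROLES = ("hh_template", "hdv", "cas9_scaffold", "cas12a_direct_repeat",
              "vector_arm")
_REQUIRED_ROLES = ("hh_template", "hdv", "cas9_scaffold", "cas12a_direct_repeat")


@dataclass(frozen=True)
class Part:
    """A named sequence part.

    The ``hh_template`` role is special: its sequence starts with the
    literal six-character placeholder ``NNNNNN``, replaced at design time
    by the guide-specific stem.
    """

    name: str
    role: str
    sequence: str

    def __post_init__(self) -> None:
        if self.role not in PART_ROLES:
            raise RegistryError(f"part {self.name!r}: unknown role {self.role!r}")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if self.role == "hh_template":
            if not seq.startswith(PLACEHOLDER):
                raise RegistryError(
                    f"part {self.name!r}: hh_template placeholder missing "
                    f"(sequence must start with {PLACEHOLDER})"
                )
            body = seq[len(PLACEHOLDER):]
            if "N" in body:
                raise RegistryError(
                    f"part {self.name!r}: hh_template contains placeholder "
                    "characters outside the 6-nt prefix"
                )
            NucSeq(body)  # alphabet check
        else:
            if "N" in seq:
                raise RegistryError(
                    f"part {self.name!r}: placeholder characters are only "
                    "allowed in hh_template"
                )
            NucSeq(seq)

    @property
    def body(self) -> str:
        """Sequence with the placeholder prefix stripped (hh_template only)."""
        return self.sequence[len(PLACEHOLDER):] if self.role == "hh_template" else self.sequence


@dataclass(frozen=True)
class TypeIISEnzyme:
    """A type IIS restriction enzyme cutting downstream of its site.

    ``cut_offset_top``/``cut_offset_bottom`` are measured in nt downstream
    of the recognition site's 3' end, on the recognition strand and its
    complement respectively; bottom > top yields 5' overhangs of length
    ``overhang_len``.
    """

    name: str
    recognition: MotifPattern
    cut_offset_top: int
    cut_offset_bottom: int
    aliases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not isinstance(self.recognition, MotifPattern):
            object.__setattr__(self, "recognition", MotifPattern(self.recognition))
        rec = self.recognition.pattern
        if set(rec) <= set("ACGT") and rec == revcomp_str(rec):
            raise RegistryError(
                f"enzyme {self.name!r}: recognition site is palindromic; "
                "a type IIS enzyme must be strand-asymmetric"
            )
        if self.cut_offset_top < 0 or self.cut_offset_bottom < 0:
            raise RegistryError(f"enzyme {self.name!r}: negative cut offset")
        if self.overhang_len <= 0:
            raise RegistryError(
                f"enzyme {self.name!r}: cut_offset_bottom must exceed "
                "cut_offset_top (only 5' overhang enzymes are supported)"
            )

    @property
    def overhang_len(self) -> int:
        return self.cut_offset_bottom - self.cut_offset_top


@dataclass
class PartRegistry:
    """Validated collection of parts, enzymes and overhang sets."""

    parts: dict[str, Part] = field(default_factory=dict)
    enzymes: dict[str, TypeIISEnzyme] = field(default_factory=dict)
    overhang_sets: dict[str, list[str]] = field(default_factory=dict)

    def parts_by_role(self, role: str) -> list[Part]:
        return [p for p in self.parts.values() if p.role == role]

    def get_part(self, role: str, name: str | None = None) -> Part:
        """The named part, or the unique default for a role.

        Raises :class:`PartLookupError` on a missing role/name, or when a
        role has several parts and no name disambiguates.
        """
        if role not in PART_ROLES:
            raise PartLookupError(f"unknown part role {role!r}")
        candidates = self.parts_by_role(role)
        if name is not None:
            for p in candidates:
                if p.name == name:
                    return p
            raise PartLookupError(f"no part named {name!r} with role {role!r}")
        if not candidates:
            raise PartLookupError(f"no part registered for role {role!r}")
        if len(candidates) > 1:
            raise PartLookupError(
                f"role {role!r} is ambiguous ({len(candidates)} parts: "
                f"{sorted(p.name for p in candidates)}); pass a name"
            )
        return candidates[0]

    def get_enzyme(self, name: str) -> TypeIISEnzyme:
        for enz in self.enzymes.values():
            if enz.name == name or name in enz.aliases:
                return enz
        raise PartLookupError(f"no enzyme named {name!r}")

    def get_overhang_set(self, name: str) -> list[str]:
        try:
            return list(self.overhang_sets[name])
        except KeyError:
            raise PartLookupError(f"no overhang set named {name!r}") from None


def default_registry_text() -> str:
    """The bundled default registry config, as YAML text."""
    return (resources.files("rgrkit") / "data" / "default_registry.yaml").read_text()


def load_registry(source: str | Path | IO[str] | None = None,
                  merge_defaults: bool = True) -> PartRegistry:
    """Load and validate a registry config.

    Parameters
    ----------
    source:
        Path to a YAML file (or an open text handle). ``None`` loads the
        bundled defaults only.
    merge_defaults:
        When true (default) the bundled defaults are loaded first and the
        user config is merged on top (same-name entries override).

    Raises
    ------
    RegistryError
        On schema violations, unknown roles, or any invariant failure;
        the message names the offending part/enzyme and rule. An empty
        config file is an error, not an empty registry.
    """
    docs: list[dict] = []
    if merge_defaults or source is None:
        docs.append(yaml.safe_load(default_registry_text()))
    if source is not None:
        if hasattr(source, "read"):
            text = source.read()  # type: ignore[union-attr]
        else:
            text = Path(source).read_text()
        data = yaml.safe_load(text)
        if data is None:
            raise RegistryError("registry config is empty")
        if not isinstance(data, dict):
            raise RegistryError("registry config must be a YAML mapping")
        docs.append(data)

    reg = PartRegistry()
    for doc in docs:
        _merge_doc(reg, doc)

    violations = [v for v in validate_registry(reg) if v.fatal]
    if violations:
        raise RegistryError("; ".join(v.message for v in violations))
    return reg


def _merge_doc(reg: PartRegistry, doc: dict) -> None:
    known = {"parts", "enzymes", "overhang_sets"}
    extra = set(doc) - known
    if extra:
        raise RegistryError(f"unknown registry sections: {sorted(extra)}")
    for entry in doc.get("parts", []) or []:
        try:
            part = Part(name=entry["name"], role=entry["role"],
                        sequence=entry["sequence"])
        except KeyError as exc:
            raise RegistryError(f"part entry missing field {exc}") from None
        reg.parts[part.name] = part
    for entry in doc.get("enzymes", []) or []:
        try:
            enz = TypeIISEnzyme(
                name=entry["name"],
                recognition=MotifPattern(entry["recognition"]),
                cut_offset_top=int(entry["cut_offset_top"]),
                cut_offset_bottom=int(entry["cut_offset_bottom"]),
                aliases=tuple(entry.get("aliases", ()) or ()),
            )
        except KeyError as exc:
            raise RegistryError(f"enzyme entry missing field {exc}") from None
        reg.enzymes[enz.name] = enz
    for name, overhangs in (doc.get("overhang_sets", {}) or {}).items():
        reg.overhang_sets[name] = [str(o).upper() for o in overhangs]


@dataclass(frozen=True)
class Violation:
    """A single registry-validation finding."""

    message: str
    fatal: bool = True


def validate_registry(reg: PartRegistry) -> list[Violation]:
    """Cross-check a registry; empty list means valid.

    Checks required roles, overhang-set directionality (pairwise distinct,
    none self-complementary) and part domestication: no part other than a
    vector arm may contain any registered enzyme's recognition site on
    either strand.
    """
    out: list[Violation] = []
    for role in _REQUIRED_ROLES:
        if not reg.parts_by_role(role):
            out.append(Violation(f"no part registered for required role {role!r}"))
    for sname, overhangs in reg.overhang_sets.items():
        if len(set(overhangs)) != len(overhangs):
            out.append(Violation(f"overhang set {sname!r}: overhangs not distinct"))
        for o in overhangs:
            try:
                NucSeq(o)
            except Exception:
                out.append(Violation(f"overhang set {sname!r}: invalid overhang {o!r}"))
                continue
            if o == revcomp_str(o):
                out.append(Violation(
                    f"overhang set {sname!r}: overhang {o!r} is "
                    "self-complementary (breaks directionality)"
                ))
    for part in reg.parts.values():
        if part.role == "vector_arm":
            continue
        scan = part.body  # placeholder prefix cannot be scanned literally
        for enz in reg.enzymes.values():
            for hit in find_sites(NucSeq(scan), enz.recognition, "both"):
                out.append(Violation(
                    f"part {part.name!r} contains a {enz.name} site at "
                    f"[{hit.start}, {hit.end}) ({hit.strand} strand)"
                ))
    return out


def registry_to_fasta(reg: PartRegistry) -> str:
    """Export all parts as FASTA text (one record per part)."""
    lines: list[str] = []
    for part in reg.parts.values():
        lines.append(f">{part.name} role={part.role}")
        lines.append(part.sequence)
    return "\n".join(lines) + ("\n" if lines else "")


def save_registry(reg: PartRegistry, path: str | Path) -> None:
    """Serialize a registry back to the YAML schema (round-trips)."""
    doc = {
        "parts": [
            {"name": p.name, "role": p.role, "sequence": p.sequence}
            for p in reg.parts.values()
        ],
        "enzymes": [
            {
                "name": e.name,
                "recognition": e.recognition.pattern,
                "cut_offset_top": e.cut_offset_top,
                "cut_offset_bottom": e.cut_offset_bottom,
                **({"aliases": list(e.aliases)} if e.aliases else {}),
            }
            for e in reg.enzymes.values()
        ],
        "overhang_sets": {k: list(v) for k, v in reg.overhang_sets.items()},
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
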