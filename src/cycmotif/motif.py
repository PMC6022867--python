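"""Bracket-syntax motif model for nucleotide-cyclase catalytic centres.

A motif is an ordered list of elements, each either a residue class
(``[RKS]``-style alternation over the 20 standard amino acids) or a bounded
wildcard gap (``X``, ``X{9}``, ``X{1,3}``).  Elements carry a functional-role
annotation (purine binding, substrate specificity, transition-state
stabilisation, metal binding, ...) so that derived motifs keep track of which
position does what.

Motifs are immutable and always stored in canonical form: residue classes
are alphabetically sorted and adjacent wildcard gaps are merged, so parsing
a motif's serialisation reproduces an identical object.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "STANDARD_RESIDUES",
    "Role",
    "ResidueClass",
    "MotifElement",
    "Motif",
    "MotifParseError",
    "parse_motif",
    "motif_to_string",
    "substitute_position",
    "constrain_wildcard",
    "add_upstream_anchor",
    "preset",
    "preset_names",
    "preset_catalogue",
]

#: The 20 standard one-letter amino-acid codes.
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


class Role(enum.Enum):
    """Functional role of a motif element within the catalytic centre."""

    PURINE_BINDING = "purine_binding"
    SUBSTRATE_SPECIFICITY = "substrate_specificity"
    HYDROPHOBIC_POCKET = "hydrophobic_pocket"
    TRANSITION_STATE = "transition_state"
    METAL_BINDING = "metal_binding"
    ANCHOR = "anchor"
    NONE = "none"


class MotifParseError(ValueError):
    """Raised for malformed motif pattern strings.

    Carries the offending token and its 0-based character offset.
    """

    def __init__(self, message: str, token: str, offset: int):
        super().__init__(f"{message} (token {token!r} at offset {offset})")
        self.token = token
        self.offset = offset


@dataclass(frozen=True)
class ResidueClass:
    """A set of allowed residues, or a wildcard matching any residue."""

    allowed: frozenset = frozenset()
    is_wildcard: bool = False

    def __post_init__(self):
        object.__setattr__(self, "allowed", frozenset(self.allowed))
        if self.is_wildcard:
            if self.allowed:
                raise ValueError("wildcard classes must have an empty allowed set")
        else:
            if not self.allowed:
                raise ValueError("non-wildcard residue class must be non-empty")
            bad = self.allowed - STANDARD_RESIDUES
            if bad:
                raise ValueError(
                    f"non-standard residues in class: {''.join(sorted(bad))}"
                )

    @classmethod
    def wildcard(cls) -> "ResidueClass":
        return cls(frozenset(), True)

    @classmethod
    def of(cls, residues: Iterable[str]) -> "ResidueClass":
        return cls(frozenset(residues), False)

    def matches(self, residue: str) -> bool:
        if self.is_wildcard:
            return residue.isalpha()
        return residue in self.allowed

    def __str__(self) -> str:
        if self.is_wildcard:
            return "X"
        return "[" + "".join(sorted(self.allowed)) + "]"


@dataclass(frozen=True)
class MotifElement:
    """One motif element: a residue class with a repeat range and a role."""

    residue_class: ResidueClass
    min_repeat: int = 1
    max_repeat: int = 1
    role: Role = Role.NONE

    def __post_init__(self):
        if self.min_repeat < 0:
            raise ValueError("min_repeat must be non-negative")
        if self.max_repeat < 1:
            raise ValueError("max_repeat must be positive")
        if self.min_repeat > self.max_repeat:
            raise ValueError("min_repeat must not exceed max_repeat")
        if not self.residue_class.is_wildcard and not (
            self.min_repeat == self.max_repeat == 1
        ):
            raise ValueError("non-wildcard elements must have repeat exactly 1")

    @property
    def is_gap(self) -> bool:
        return self.residue_class.is_wildcard

    @property
    def fixed_length(self) -> bool:
        return self.min_repeat == self.max_repeat


def _canonicalize(elements: Sequence[MotifElement]) -> tuple:
    """Merge adjacent wildcard gaps and drop zero-width gaps."""
    out: list[MotifElement] = []
    for el in elements:
        if el.is_gap and el.min_repeat == 0 and el.max_repeat == 0:
            continue  # cannot occur via the constructor, but guard anyway
        if el.is_gap and out and out[-1].is_gap:
            prev = out.pop()
            if prev.role is not Role.NONE or el.role is not Role.NONE:
                raise ValueError("wildcard gaps cannot carry a role")
            el = MotifElement(
                ResidueClass.wildcard(),
                prev.min_repeat + el.min_repeat,
                prev.max_repeat + el.max_repeat,
            )
        out.append(el)
    return tuple(out)


@dataclass(frozen=True)
class Motif:
    """A named, ordered list of motif elements in canonical form."""

    name: str
    elements: tuple = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(self, "elements", _canonicalize(self.elements))
        if not self.elements:
            raise ValueError("motif must contain at least one element")
        seen_roles = set()
        for el in self.elements:
            if el.role is Role.NONE:
                continue
            if el.role in seen_roles:
                raise ValueError(f"duplicate role {el.role.value} in motif")
            seen_roles.add(el.role)

    @property
    def min_span(self) -> int:
        return sum(el.min_repeat for el in self.elements)

    @property
    def max_span(self) -> int:
        return sum(el.max_repeat for el in self.elements)

    @property
    def pattern(self) -> str:
        return motif_to_string(self)

    def expanded_extents(self) -> list:
        """(element_index, first_position, last_position) over the minimal
        instantiation, positions 1-based.  Zero-width optional gaps get
        last_position = first_position - 1."""
        out = []
        pos = 1
        for i, el in enumerate(self.elements):
            out.append((i, pos, pos + el.min_repeat - 1))
            pos += el.min_repeat
        return out

    def role_position(self, role: Role) -> int:
        """1-based expanded position (minimal instantiation) of the element
        carrying *role*.  For multi-residue elements the first position is
        returned."""
        for i, start, _end in self.expanded_extents():
            if self.elements[i].role is role:
                return start
        raise KeyError(f"motif {self.name!r} has no element with role {role.value}")

    def with_name(self, name: str) -> "Motif":
        return replace(self, name=name)

    def to_dict(self) -> dict:
        """Full-fidelity serialization: pattern plus role annotations.

        The bracket pattern alone cannot carry roles or the name, so this
        is the canonical lossless form; ``Motif.from_dict`` round-trips it.
        """
        roles = {i: el.role.value for i, el in enumerate(self.elements)
                 if el.role is not Role.NONE}
        return {"name": self.name, "pattern": motif_to_string(self),
                "roles": roles}

    @classmethod
    def from_dict(cls, d: dict) -> "Motif":
        roles = {int(i): Role(v) for i, v in d.get("roles", {}).items()}
        return parse_motif(d["pattern"], d["name"], roles)

    def __str__(self) -> str:
        return motif_to_string(self)


# ---------------------------------------------------------------------------
# parsing / serialisation


def parse_motif(pattern: str, name: str = "motif",
                roles: Mapping[int, Role] | None = None) -> Motif:
    """Parse a bracket-syntax pattern into a :class:`Motif`.

    Parameters
    ----------
    pattern:
        Concatenation of bracket groups ``[...]``, bare residue letters,
        and wildcard terms ``X``, ``X{n}`` or ``X{m,n}``.
    name:
        Name recorded on the returned motif.
    roles:
        Optional mapping of element index (0-based, in pattern order, before
        canonical gap merging) to :class:`Role`.
    """
    elements: list[MotifElement] = []
    i = 0
    n = len(pattern)
    while i < n:
        c = pattern[i]
        if c == "[":
            j = pattern.find("]", i)
            if j < 0:
                raise MotifParseError("unterminated bracket group", pattern[i:], i)
            body = pattern[i + 1:j]
            if not body:
                raise MotifParseError("empty residue class", pattern[i:j + 1], i)
            for k, r in enumerate(body):
                if r == "X":
                    raise MotifParseError(
                        "wildcard X not allowed inside brackets", r, i + 1 + k)
                if r not in STANDARD_RESIDUES:
                    raise MotifParseError(
                        "not a standard amino-acid code", r, i + 1 + k)
            elements.append(MotifElement(ResidueClass.of(body)))
            i = j + 1
        elif c == "X":
            min_rep = max_rep = 1
            i += 1
            if i < n and pattern[i] == "{":
                j = pattern.find("}", i)
                if j < 0:
                    raise MotifParseError("unterminated repeat braces", pattern[i:], i)
                body = pattern[i + 1:j]
                parts = body.split(",")
                try:
                    if len(parts) == 1:
                        min_rep = max_rep = int(parts[0])
                    elif len(parts) == 2:
                        min_rep, max_rep = int(parts[0]), int(parts[1])
                    else:
                        raise ValueError
                except ValueError:
                    raise MotifParseError(
                        "malformed repeat range", pattern[i:j + 1], i) from None
                if min_rep > max_rep:
                    raise MotifParseError(
                        f"lower repeat bound {min_rep} exceeds upper bound {max_rep}",
                        pattern[i:j + 1], i)
                if max_rep < 1 or min_rep < 0:
                    raise MotifParseError(
                        "repeat bounds out of range", pattern[i:j + 1], i)
                i = j + 1
            elements.append(MotifElement(ResidueClass.wildcard(), min_rep, max_rep))
        elif c in STANDARD_RESIDUES:
            elements.append(MotifElement(ResidueClass.of(c)))
            i += 1
        elif c == "{":
            raise MotifParseError("repeat braces may only follow X", c, i)
        else:
            raise MotifParseError("unexpected character", c, i)
    if roles:
        for idx, role in roles.items():
            if not 0 <= idx < len(elements):
                raise IndexError(f"role index {idx} out of range")
            elements[idx] = replace(elements[idx], role=role)
    return Motif(name, tuple(elements))


def motif_to_string(m: Motif) -> str:
    """Serialise a motif to canonical bracket syntax.

    Residue classes are emitted in alphabetical order inside brackets;
    wildcards as ``X`` (single), ``X{n}`` (fixed, n > 1) or ``X{m,n}``.
    ``parse_motif(motif_to_string(m))`` reproduces ``m``.
    """
    parts = []
    for el in m.elements:
        if el.is_gap:
            if el.min_repeat == el.max_repeat:
                parts.append("X" if el.min_repeat == 1 else "X{%d}" % el.min_repeat)
            else:
                parts.append("X{%d,%d}" % (el.min_repeat, el.max_repeat))
        else:
            parts.append(str(el.residue_class))
    return "".join(parts)


# ---------------------------------------------------------------------------
# derivation operators


def substitute_position(m: Motif, element_index: int,
                        new_class: ResidueClass) -> Motif:
    """Return a motif with the residue class at *element_index* replaced.

    The index addresses the element list (0-based) and must name a
    non-wildcard element.  The role annotation is preserved unless the new
    class is a wildcard (gaps cannot carry roles).
    """
    if not 0 <= element_index < len(m.elements):
        raise IndexError(f"element index {element_index} out of range")
    el = m.elements[element_index]
    if el.is_gap:
        raise ValueError("cannot substitute into a wildcard gap element")
    role = Role.NONE if new_class.is_wildcard else el.role
    new_el = MotifElement(new_class, 1, 1, role)
    elements = list(m.elements)
    elements[element_index] = new_el
    return Motif(m.name, tuple(elements))


def constrain_wildcard(m: Motif, motif_position: int, new_class: ResidueClass,
                       role: Role = Role.NONE) -> Motif:
    """Pin one position of a fixed-length gap to a residue class.

    *motif_position* is 1-based over the expanded minimal instantiation of
    the motif.  The gap is split so that the named position becomes a
    one-residue class element and the gap shrinks by one; total spans are
    unchanged.  Positions inside variable-length gaps are rejected as
    ambiguous.
    """
    for i, start, end in m.expanded_extents():
        el = m.elements[i]
        if start <= motif_position <= end:
            if not el.is_gap:
                raise ValueError(
                    f"position {motif_position} is not inside a gap element")
            if not el.fixed_length:
                raise ValueError(
                    f"position {motif_position} lies in a variable-length gap; "
                    "the split would be ambiguous")
            offset = motif_position - start
            tail = el.min_repeat - offset - 1
            pieces: list[MotifElement] = []
            if offset:
                pieces.append(MotifElement(ResidueClass.wildcard(), offset, offset))
            if new_class.is_wildcard:
                pieces.append(MotifElement(ResidueClass.wildcard(), 1, 1))
            else:
                pieces.append(MotifElement(new_class, 1, 1, role))
            if tail:
                pieces.append(MotifElement(ResidueClass.wildcard(), tail, tail))
            elements = list(m.elements[:i]) + pieces + list(m.elements[i + 1:])
            return Motif(m.name, tuple(elements))
    raise ValueError(
        f"position {motif_position} is outside the motif "
        f"(1..{m.min_span} over the minimal instantiation)")


def add_upstream_anchor(m: Motif, anchor_class: ResidueClass,
                        min_gap: int, max_gap: int) -> Motif:
    """Prepend an anchor residue class and a wildcard gap to the motif."""
    if min_gap < 0 or max_gap < 0:
        raise ValueError("gap bounds must be non-negative")
    if min_gap > max_gap:
        raise ValueError("min_gap must not exceed max_gap")
    if anchor_class.is_wildcard:
        raise ValueError("anchor must be a concrete residue class")
    prefix = [MotifElement(anchor_class, 1, 1, Role.ANCHOR)]
    if max_gap > 0:
        prefix.append(MotifElement(ResidueClass.wildcard(), min_gap, max_gap))
    return Motif(m.name, tuple(prefix) + m.elements)


# ---------------------------------------------------------------------------
# preset catalogue

_GC_PATTERN = "[RKS][YFW][CTGH][VIL]X{9}[KR]X{1,3}[DE]"
_GC_ROLES = {
    0: Role.PURINE_BINDING,
    2: Role.SUBSTRATE_SPECIFICITY,
    5: Role.TRANSITION_STATE,
    7: Role.METAL_BINDING,
}
# Printed literal; not derivable from ac_core by a single operator because
# the gap after [VIL] shrinks to X{8} while a second [KR] is appended.
_KR15_PATTERN = "[R]X{5,20}[RKS][YFW][DE][VIL]X{8}[KR][KR]X{0,2}[DE]"
_KR15_ROLES = {
    0: Role.ANCHOR,
    2: Role.PURINE_BINDING,
    4: Role.SUBSTRATE_SPECIFICITY,
    8: Role.TRANSITION_STATE,
    10: Role.METAL_BINDING,
}

_PRESET_NOTES = {
    "gc_core": "guanylate-cyclase parent motif",
    "ac_core": "adenylate-cyclase core motif (substrate position swapped to [DE])",
    "ac_anchored": "core motif with upstream pyrophosphate-binding [R] anchor",
    "ac_fv5": "core motif with hydrophobic [FV] pinned at position 5",
    "ac_kr15": "anchored motif with a second [KR] transition-state residue",
    "functional_core": "relaxed motif keeping only functionally assigned residues",
}


def _build_preset(name: str) -> Motif:
    gc = parse_motif(_GC_PATTERN, "gc_core", _GC_ROLES)
    if name == "gc_core":
        return gc
    ac = substitute_position(gc, 2, ResidueClass.of("DE")).with_name("ac_core")
    if name == "ac_core":
        return ac
    if name == "ac_anchored":
        return add_upstream_anchor(
            ac, ResidueClass.of("R"), 5, 20).with_name("ac_anchored")
    if name == "ac_fv5":
        return constrain_wildcard(
            ac, 5, ResidueClass.of("FV"), Role.HYDROPHOBIC_POCKET
        ).with_name("ac_fv5")
    if name == "ac_kr15":
        return parse_motif(_KR15_PATTERN, "ac_kr15", _KR15_ROLES)
    if name == "functional_core":
        # relax the non-functional positions 2 and 4 of the core to wildcards
        relaxed = substitute_position(ac, 1, ResidueClass.wildcard())
        relaxed = substitute_position(relaxed, 3, ResidueClass.wildcard())
        return relaxed.with_name("functional_core")
    raise KeyError(name)


_PRESET_ORDER = ("gc_core", "ac_core", "ac_anchored", "ac_fv5", "ac_kr15",
                 "functional_core")


def preset_names() -> tuple:
    """Names of the built-in motifs, in stable order."""
    return _PRESET_ORDER


def preset(name: str) -> Motif:
    """Return a built-in motif by name."""
    if name not in _PRESET_ORDER:
        raise KeyError(
            f"unknown preset {name!r}; valid names: {', '.join(_PRESET_ORDER)}")
    return _build_preset(name)


def preset_catalogue() -> list:
    """Catalogue of all presets as plain dicts (YAML/JSON friendly)."""
    out = []
    for name in _PRESET_ORDER:
        m = preset(name)
        roles = {}
        for i, start, _end in m.expanded_extents():
            el = m.elements[i]
            if el.role is not Role.NONE:
                roles[start] = el.role.value
        out.append({
            "name": name,
            "pattern": motif_to_string(m),
            "min_span": m.min_span,
            "max_span": m.max_span,
            "roles": roles,
            "note": _PRESET_NOTES[name],
        })
    return out
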