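"""Shorthand lipid nomenclature: parsing, validation and formatting.

Lipid *species* are identified by class plus the total number of acyl-chain
carbon atoms and double bonds (``TG 52:3``, ``PC 36:4``); glycerol-backbone
and head-group carbons are not counted.  Lipid *molecular species* resolve
the constituent fatty acyl chains (``TG 16:0_18:1_18:2``): an underscore
separator means the sn-positions are unknown, a slash (``TG 17:0/17:0/17:0``)
means they are known.

The class registry is data-driven so that minor phospholipid classes can be
added without touching the parser.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "LipidClass",
    "SpeciesKey",
    "MolecularSpeciesKey",
    "NomenclatureError",
    "register_class",
    "registered_classes",
    "class_arity",
    "parse_species",
    "parse_molecular_species",
    "species_of",
]


class NomenclatureError(ValueError):
    """Raised for names that do not conform to the shorthand grammar."""


@dataclass(frozen=True)
class LipidClass:
    """A registered lipid class.

    ``arities`` is the set of acyl-chain counts a molecular-species name of
    this class may carry.  DG accepts 2 or 3 annotated positions because
    some tables write diacylglycerols with an explicit empty backbone slot.
    """

    code: str
    arities: frozenset[int] = field(default_factory=frozenset)

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.code


# class code -> LipidClass; glycerolipids first, then the glycerophospholipids
_REGISTRY: dict[str, LipidClass] = {}


def register_class(code: str, arities) -> LipidClass:
    """Register (or re-register) a lipid class with its allowed chain counts."""
    if not code or not code.isalpha():
        raise NomenclatureError(f"invalid class code: {code!r}")
    cls = LipidClass(code=code, arities=frozenset(int(a) for a in arities))
    _REGISTRY[code] = cls
    return cls


for _code, _ar in [("TG", (3,)), ("DG", (2, 3)), ("PC", (2,)),
                   ("PE", (2,)), ("PS", (2,)), ("PI", (2,))]:
    register_class(_code, _ar)


def registered_classes() -> tuple[str, ...]:
    return tuple(_REGISTRY)


def class_arity(code: str) -> frozenset[int]:
    """Allowed chain counts for a class code."""
    return _lookup(code).arities


def _lookup(code: str) -> LipidClass:
    try:
        return _REGISTRY[code]
    except KeyError:
        raise NomenclatureError(
            f"unknown lipid class {code!r} (registered: {', '.join(_REGISTRY)})"
        ) from None


@dataclass(frozen=True, order=True)
class SpeciesKey:
    """A lipid species: class + total acyl carbons : total double bonds."""

    lipid_class: str
    carbons: int
    double_bonds: int

    def __post_init__(self) -> None:
        _lookup(self.lipid_class)
        if self.carbons < 0 or self.double_bonds < 0:
            raise NomenclatureError(f"negative counts in {self!r}")
        if self.double_bonds > self.carbons:
            raise NomenclatureError(
                f"{self.lipid_class} {self.carbons}:{self.double_bonds}: "
                "double bonds exceed carbons"
            )

    def __str__(self) -> str:
        return f"{self.lipid_class} {self.carbons}:{self.double_bonds}"


@dataclass(frozen=True)
class MolecularSpeciesKey:
    """A lipid molecular species with its acyl chains resolved.

    ``sn_known`` records the separator used: ``/`` (positions known) or
    ``_`` (positions unknown).
    """

    lipid_class: str
    chains: tuple[tuple[int, int], ...]
    sn_known: bool

    def __post_init__(self) -> None:
        cls = _lookup(self.lipid_class)
        if len(self.chains) not in cls.arities:
            raise NomenclatureError(
                f"{self.lipid_class} molecular species must have "
                f"{sorted(cls.arities)} chains, got {len(self.chains)}"
            )
        for c, db in self.chains:
            if c < 0 or db < 0 or db > c:
                raise NomenclatureError(f"invalid chain {c}:{db}")

    def __str__(self) -> str:
        sep = "/" if self.sn_known else "_"
        body = sep.join(f"{c}:{db}" for c, db in self.chains)
        return f"{self.lipid_class} {body}"


_CHAIN = r"(\d+):(\d+)"
_SPECIES_RE = re.compile(r"^([A-Za-z]+)\s*(\d+):(\d+)$")


def parse_species(name: str) -> SpeciesKey:
    """Parse a species name such as ``TG 52:3`` or ``PC36:4``.

    Whitespace between class code and counts is optional; the canonical form
    (single ASCII space) is emitted by ``str()``.
    """
    if not isinstance(name, str) or not name.strip():
        raise NomenclatureError("empty species name")
    m = _SPECIES_RE.match(name.strip())
    if m is None:
        raise NomenclatureError(f"malformed species name: {name!r}")
    code, carbons, db = m.group(1), int(m.group(2)), int(m.group(3))
    return SpeciesKey(lipid_class=_lookup(code).code, carbons=carbons,
                      double_bonds=db)


_MOL_RE = re.compile(r"^([A-Za-z]+)\s*((?:\d+:\d+)(?:[/_]\d+:\d+)+)$")


def parse_molecular_species(name: str) -> MolecularSpeciesKey:
    """Parse a molecular-species name such as ``TG 16:0_18:1_18:2``.

    The separator must be uniform: all ``_`` (sn unknown) or all ``/``
    (sn known); mixing them is an error.
    """
    if not isinstance(name, str) or not name.strip():
        raise NomenclatureError("empty molecular species name")
    m = _MOL_RE.match(name.strip())
    if m is None:
        raise NomenclatureError(f"malformed molecular species name: {name!r}")
    code, body = m.group(1), m.group(2)
    seps = set(re.findall(r"[/_]", body))
    if len(seps) != 1:
        raise NomenclatureError(f"mixed sn separators in {name!r}")
    sep = seps.pop()
    chains = tuple(
        (int(c), int(db))
        for c, db in (chunk.split(":") for chunk in body.split(sep))
    )
    return MolecularSpeciesKey(lipid_class=_lookup(code).code, chains=chains,
                               sn_known=(sep == "/"))


def species_of(molecular: MolecularSpeciesKey) -> SpeciesKey:
    """Collapse a molecular species to its species key (sum rule)."""
    return SpeciesKey(
        lipid_class=molecular.lipid_class,
        carbons=sum(c for c, _ in molecular.chains),
        double_bonds=sum(db for _, db in molecular.chains),
    )


def parse_any(name: str) -> SpeciesKey | MolecularSpeciesKey:
    """Parse either a species or a molecular-species name."""
    if "/" in name or "_" in name:
        return parse_molecular_species(name)
    return parse_species(name)


def lipid_class_of(key: SpeciesKey | MolecularSpeciesKey) -> str:
    return key.lipid_class
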