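"""Substructure registry and coarse/fine grouping strategies.

The framework segments ten cardiac substructures: the four chambers
(left/right ventricle, left/right atrium), three medium vessels
(ascending aorta, descending aorta, pulmonary artery) and three small
vessels (pulmonary vein, inferior vena cava, superior vena cava).
Integer label codes are fixed here once, so that label maps, phantom
fixtures and reports are all mutually consistent:

    LV=1, RV=2, LA=3, RA=4, AA=5, DA=6, PA=7, PV=8, IVC=9, SVC=10

A :class:`GroupingScheme` partitions the ten codes into a coarse group
(CG), segmented by the first-stage network, and a fine group (FG),
segmented by the second-stage network with the CG masks injected as
anatomical-prior channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "Substructure",
    "GroupingScheme",
    "REGISTRY",
    "CODES",
    "ACRONYMS",
    "get",
    "builtin_groupings",
    "default_grouping",
    "get_grouping",
    "remap_labels",
    "invert_remap",
    "write_registry",
    "read_registry",
]


@dataclass(frozen=True)
class Substructure:
    """One cardiac substructure: integer label code plus identity."""

    code: int
    acronym: str
    full_name: str
    size_class: str  # "large" | "medium" | "small"


REGISTRY: tuple[Substructure, ...] = (
    Substructure(1, "LV", "left ventricle", "large"),
    Substructure(2, "RV", "right ventricle", "large"),
    Substructure(3, "LA", "left atrium", "large"),
    Substructure(4, "RA", "right atrium", "large"),
    Substructure(5, "AA", "ascending aorta", "medium"),
    Substructure(6, "DA", "descending aorta", "medium"),
    Substructure(7, "PA", "pulmonary artery", "medium"),
    Substructure(8, "PV", "pulmonary vein", "small"),
    Substructure(9, "IVC", "inferior vena cava", "small"),
    Substructure(10, "SVC", "superior vena cava", "small"),
)

CODES: tuple[int, ...] = tuple(s.code for s in REGISTRY)
ACRONYMS: tuple[str, ...] = tuple(s.acronym for s in REGISTRY)

_BY_ACRONYM = {s.acronym: s for s in REGISTRY}
_BY_CODE = {s.code: s for s in REGISTRY}


def get(key: int | str) -> Substructure:
    """Look up a substructure by integer code or acronym."""
    if isinstance(key, str):
        try:
            return _BY_ACRONYM[key.upper()]
        except KeyError:
            raise KeyError(f"unknown substructure acronym: {key!r}") from None
    try:
        return _BY_CODE[int(key)]
    except KeyError:
        raise KeyError(f"unknown substructure code: {key!r}") from None


def codes_of(acronyms: Iterable[str]) -> frozenset[int]:
    return frozenset(get(a).code for a in acronyms)


@dataclass(frozen=True)
class GroupingScheme:
    """A partition of the ten substructure codes into CG and FG."""

    name: str
    coarse: frozenset[int]
    fine: frozenset[int]
    default: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        coarse = frozenset(self.coarse)
        fine = frozenset(self.fine)
        object.__setattr__(self, "coarse", coarse)
        object.__setattr__(self, "fine", fine)
        if not coarse or not fine:
            raise ValueError(f"{self.name}: neither group may be empty")
        if coarse & fine:
            raise ValueError(f"{self.name}: groups overlap: {sorted(coarse & fine)}")
        if coarse | fine != set(CODES):
            missing = set(CODES) - (coarse | fine)
            extra = (coarse | fine) - set(CODES)
            raise ValueError(
                f"{self.name}: groups must partition codes 1..10 "
                f"(missing {sorted(missing)}, foreign {sorted(extra)})"
            )

    @property
    def coarse_acronyms(self) -> tuple[str, ...]:
        return tuple(get(c).acronym for c in sorted(self.coarse))

    @property
    def fine_acronyms(self) -> tuple[str, ...]:
        return tuple(get(c).acronym for c in sorted(self.fine))


def builtin_groupings() -> list[GroupingScheme]:
    """The three built-in CG/FG grouping strategies.

    * ``group1`` follows circulatory anatomy (systemic-circulation
      vessels grouped with LV and RA).
    * ``group2`` groups by size: the four chambers form the CG and all
      vessels the FG.  It is the default strategy of the framework.
    * ``group3`` groups structures with no mutual connection.
    """
    return [
        GroupingScheme(
            "group1",
            codes_of(["LV", "RA", "AA", "DA", "SVC", "IVC"]),
            codes_of(["LA", "RV", "PV", "PA"]),
        ),
        GroupingScheme(
            "group2",
            codes_of(["LA", "LV", "RA", "RV"]),
            codes_of(["AA", "DA", "PA", "PV", "SVC", "IVC"]),
            default=True,
        ),
        GroupingScheme(
            "group3",
            codes_of(["LA", "LV", "PV", "AA", "DA"]),
            codes_of(["RA", "RV", "IVC", "SVC", "PA"]),
        ),
    ]


def default_grouping() -> GroupingScheme:
    """The size-based grouping (chambers coarse, vessels fine)."""
    return next(g for g in builtin_groupings() if g.default)


def get_grouping(name: str) -> GroupingScheme:
    for g in builtin_groupings():
        if g.name == name:
            return g
    raise KeyError(f"unknown grouping scheme: {name!r}")


def remap_labels(
    labels: np.ndarray, keep: Iterable[int]
) -> tuple[np.ndarray, dict[int, int]]:
    """Restrict a label map to ``keep`` and relabel densely.

    Codes in ``keep`` are mapped, in ascending original-code order, to
    the contiguous range ``1..len(keep)``; every other voxel becomes
    background (0).  Returns the remapped array and the code table
    ``{dense -> original}`` needed to invert the mapping.
    """
    labels = np.asanyarray(labels)
    keep_sorted = sorted(set(int(k) for k in keep))
    if any(k not in _BY_CODE for k in keep_sorted):
        bad = [k for k in keep_sorted if k not in _BY_CODE]
        raise ValueError(f"keep contains non-registry codes: {bad}")
    present = np.unique(labels)
    unknown = [int(v) for v in present if int(v) not in (0, *CODES)]
    if unknown:
        raise ValueError(f"label map contains unknown label value(s): {unknown}")
    lut = np.zeros(max(CODES) + 1, dtype=labels.dtype)
    table: dict[int, int] = {}
    for dense, code in enumerate(keep_sorted, start=1):
        lut[code] = dense
        table[dense] = code
    return lut[labels], table


def invert_remap(dense_labels: np.ndarray, table: dict[int, int]) -> np.ndarray:
    """Map densely-relabelled values back to original registry codes."""
    dense_labels = np.asanyarray(dense_labels)
    if dense_labels.size:
        top = int(dense_labels.max())
        if top > len(table):
            raise ValueError(
                f"dense label {top} has no entry in code table of size {len(table)}"
            )
    lut = np.zeros(len(table) + 1, dtype=dense_labels.dtype)
    for dense, code in table.items():
        lut[dense] = code
    return lut[dense_labels]


def write_registry(path) -> None:
    """Serialize the registry as ``code,acronym,full name`` lines."""
    with open(path, "w") as fh:
        for s in REGISTRY:
            fh.write(f"{s.code},{s.acronym},{s.full_name}\n")


def read_registry(path) -> list[Substructure]:
    """Read a ``code,acronym,name`` table (adapter for foreign label
    conventions); size_class is filled from the built-in registry when
    the acronym is known, else ``"unknown"``."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            code_s, acronym, name = line.split(",", 2)
            size = (
                _BY_ACRONYM[acronym].size_class
                if acronym in _BY_ACRONYM
                else "unknown"
            )
            out.append(Substructure(int(code_s), acronym, name, size))
    return out
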