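"""Per-cell categorical annotations (zones) and the map holding them.

A zone names the biological position of one cell: an epidermal-to-inner
layer stratum (L1, L2, L3), the organizing centre (OC) of the stem-cell
niche, the column of cells directly above it, a numbered organ primordium
(which keeps its layer stratum), the boundary ring around a primordium,
or ``unassigned`` for cells excluded from analysis.

Zones serialize to stable strings (``L1``, ``OC``, ``L2_above_OC``,
``primordium_2_L1``, ``boundary_2``, ``unassigned``) so that CSV and
GraphML round-trips are lossless.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import FormatError

__all__ = ["CellZone", "AnnotationMap", "parse_zone"]

_KINDS = ("layer", "oc", "above_oc", "primordium", "boundary", "unassigned")


@dataclass(frozen=True)
class CellZone:
    """One cell's zone.

    ``layer`` is the 1/2/3 stratum where it applies (layer, above_oc and
    primordium kinds); ``index`` is the primordium number for primordium
    and boundary kinds.
    """

    kind: str
    layer: int | None = None
    index: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown zone kind {self.kind!r}")
        if self.kind in ("layer", "above_oc", "primordium") and self.layer not in (1, 2, 3):
            raise ValueError(f"zone kind {self.kind!r} needs a layer in 1..3")
        if self.kind in ("primordium", "boundary") and (self.index is None or self.index < 1):
            raise ValueError(f"zone kind {self.kind!r} needs index >= 1")

    @property
    def name(self) -> str:
        """Canonical string form, used in CSV/GraphML output."""
        if self.kind == "layer":
            return f"L{self.layer}"
        if self.kind == "oc":
            return "OC"
        if self.kind == "above_oc":
            return f"L{self.layer}_above_OC"
        if self.kind == "primordium":
            return f"primordium_{self.index}_L{self.layer}"
        if self.kind == "boundary":
            return f"boundary_{self.index}"
        return "unassigned"

    @property
    def stratum(self) -> int | None:
        """The L1/L2/L3 stratum of the cell, if it has one (OC counts as L3)."""
        if self.kind == "oc":
            return 3
        return self.layer

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


def layer_zone(stratum: int) -> CellZone:
    return CellZone("layer", layer=stratum)


UNASSIGNED = CellZone("unassigned")

_PRIM_RE = re.compile(r"^primordium_(\d+)_L([123])$")
_BOUND_RE = re.compile(r"^boundary_(\d+)$")
_ABOVE_RE = re.compile(r"^L([123])_above_OC$")
_LAYER_RE = re.compile(r"^L([123])$")


def parse_zone(name: str) -> CellZone:
    """Parse a canonical zone string back into a :class:`CellZone`."""
    name = name.strip()
    if name == "OC":
        return CellZone("oc")
    if name == "unassigned":
        return UNASSIGNED
    m = _LAYER_RE.match(name)
    if m:
        return CellZone("layer", layer=int(m.group(1)))
    m = _ABOVE_RE.match(name)
    if m:
        return CellZone("above_oc", layer=int(m.group(1)))
    m = _PRIM_RE.match(name)
    if m:
        return CellZone("primordium", layer=int(m.group(2)), index=int(m.group(1)))
    m = _BOUND_RE.match(name)
    if m:
        return CellZone("boundary", index=int(m.group(1)))
    raise FormatError(f"unrecognized zone name {name!r}")


@dataclass
class AnnotationMap:
    """Mapping cell label -> :class:`CellZone`, plus the parameters that made it.

    The map is a partition: each label appears at most once.  ``provenance``
    accumulates the parameter sets of the annotation steps that produced it.
    """

    entries: dict[int, CellZone] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, label: int) -> bool:
        return int(label) in self.entries

    def __getitem__(self, label: int) -> CellZone:
        return self.entries[int(label)]

    def get(self, label: int, default: CellZone = UNASSIGNED) -> CellZone:
        return self.entries.get(int(label), default)

    def set(self, label: int, zone: CellZone) -> None:
        self.entries[int(label)] = zone

    def zone_name(self, label: int) -> str:
        return self.get(label).name

    def labels(self) -> list[int]:
        return sorted(self.entries)

    def labels_where(self, predicate) -> list[int]:
        return sorted(lab for lab, z in self.entries.items() if predicate(z))

    def labels_in_layer(self, stratum: int) -> list[int]:
        """Labels whose plain-layer zone is L<stratum> (excludes OC/above-OC)."""
        return self.labels_where(lambda z: z.kind == "layer" and z.layer == stratum)

    def zone_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for z in self.entries.values():
            counts[z.name] = counts.get(z.name, 0) + 1
        return dict(sorted(counts.items()))

    def copy(self) -> "AnnotationMap":
        return AnnotationMap(dict(self.entries), dict(self.provenance))
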