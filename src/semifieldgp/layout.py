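"""Semi-field row layout and nearest-neighbour spatial correlation structures.

The experiment is laid out as beds split into independent half-bed units,
each unit holding a 1-D sequence of sown rows at fixed spacing (0.25 m by
default).  Environmental trend along a unit is modelled through row-level
spatial effects whose correlation comes from overlapping neighbour windows:

* ``knn`` -- each target row loads an indicator on itself and its k nearest
  rows per side; the Gram matrix of these indicators, trace-normalised to a
  unit average diagonal, is the correlation structure ``S_knn``.
* ``euc`` -- loadings decay linearly with physical distance,
  ``w = 1 - d/d_max`` up to ``d_max`` (2.75 m by default), giving ``S_euc``
  which weights close neighbours relatively more than ``S_knn``.

Virtual (unsown) rows pad the edges of every unit so that each real row has
a complete neighbour window; they occupy loading columns but are never
observations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, StructureError

__all__ = [
    "RowSite",
    "Layout",
    "SpatialStructure",
    "build_layout",
    "build_s_knn",
    "build_s_euc",
    "correlation_decay",
]


@dataclass(frozen=True)
class RowSite:
    """A single row position inside one half-bed unit.

    ``index`` runs over the unit; virtual padding rows take indices below 0
    or at/above the real-row count.  ``position`` is the physical location
    along the unit in metres (``index * row_spacing``).
    """

    bed: int
    unit: int
    index: int
    position: float
    is_virtual: bool
    line: str | None = None

    def __post_init__(self) -> None:
        if self.is_virtual and self.line is not None:
            raise ConfigurationError("virtual rows cannot carry a line identifier")

    @property
    def row_id(self) -> str:
        return f"b{self.bed}u{self.unit}r{self.index}"


@dataclass(frozen=True)
class Layout:
    """Ordered collection of row sites across beds and half-bed units."""

    rows: tuple[RowSite, ...]
    row_spacing: float
    beds: int
    units_per_bed: int
    rows_per_unit: int
    pad: int

    def segments(self) -> dict[tuple[int, int], list[RowSite]]:
        """Rows grouped by (bed, unit), sorted by index."""
        out: dict[tuple[int, int], list[RowSite]] = {}
        for r in self.rows:
            out.setdefault((r.bed, r.unit), []).append(r)
        for key in out:
            out[key].sort(key=lambda r: r.index)
        return out

    @property
    def real_rows(self) -> list[RowSite]:
        return [r for r in self.rows if not r.is_virtual]

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def with_lines(self, line_map: Mapping[tuple[int, int, int], str]) -> "Layout":
        """Return a copy with line identifiers attached to real rows."""
        new_rows = []
        for r in self.rows:
            key = (r.bed, r.unit, r.index)
            if not r.is_virtual and key in line_map:
                new_rows.append(
                    RowSite(r.bed, r.unit, r.index, r.position, False, str(line_map[key]))
                )
            else:
                new_rows.append(r)
        return Layout(
            tuple(new_rows),
            self.row_spacing,
            self.beds,
            self.units_per_bed,
            self.rows_per_unit,
            self.pad,
        )

    def line_of_row(self) -> dict[str, str]:
        """Map row_id -> line id for real rows that carry one."""
        return {r.row_id: r.line for r in self.real_rows if r.line is not None}


def build_layout(
    beds: int = 2,
    units_per_bed: int = 2,
    rows_per_unit: int = 150,
    row_spacing: float = 0.25,
    k_neighbors: int = 5,
    d_max: float | None = None,
    line_map: Mapping[tuple[int, int, int], str] | None = None,
) -> Layout:
    """Build the padded row layout.

    Pad width per unit edge is ``max(k_neighbors, ceil(d_max / row_spacing))``
    so that every real row has a complete neighbour window for all
    structures later built on this layout.
    """
    if beds <= 0 or units_per_bed <= 0 or rows_per_unit <= 0:
        raise ConfigurationError("bed/unit/row counts must be positive")
    if row_spacing <= 0:
        raise ConfigurationError("row_spacing must be positive")
    if k_neighbors < 0:
        raise ConfigurationError("k_neighbors must be non-negative")
    pad = k_neighbors
    if d_max is not None:
        if d_max <= 0:
            raise ConfigurationError("d_max must be positive")
        pad = max(pad, math.ceil(d_max / row_spacing))

    rows: list[RowSite] = []
    for bed in range(1, beds + 1):
        for unit in range(1, units_per_bed + 1):
            for idx in range(-pad, rows_per_unit + pad):
                virtual = idx < 0 or idx >= rows_per_unit
                line = None
                if not virtual and line_map is not None:
                    line = line_map.get((bed, unit, idx))
                rows.append(
                    RowSite(bed, unit, idx, idx * row_spacing, virtual, line)
                )
    return Layout(tuple(rows), row_spacing, beds, units_per_bed, rows_per_unit, pad)


@dataclass
class SpatialStructure:
    """A trace-normalised nearest-neighbour correlation structure.

    ``loadings`` is the n x q matrix relating the n real target rows to the
    q real-plus-virtual rows of the layout; ``S = loadings @ loadings.T``
    scaled by ``tr/n`` so the average (here: every interior) diagonal is 1.
    """

    kind: str
    params: dict
    loadings: np.ndarray
    S: np.ndarray
    norm: float
    row_ids: list[str]
    col_ids: list[str]
    row_meta: pd.DataFrame = field(repr=False)

    @property
    def n(self) -> int:
        return self.S.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.S, index=self.row_ids, columns=self.row_ids)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    def index_of(self, row_ids: Iterable[str]) -> np.ndarray:
        pos = {rid: i for i, rid in enumerate(self.row_ids)}
        return np.array([pos[r] for r in row_ids], dtype=int)


def _segment_loadings_knn(segment: Sequence[RowSite], k: int) -> np.ndarray:
    idx = np.array([r.index for r in segment])
    real = np.array([not r.is_virtual for r in segment])
    diff = np.abs(idx[real][:, None] - idx[None, :])
    return (diff <= k).astype(float)


def _segment_loadings_euc(
    segment: Sequence[RowSite], d_max: float, restrict_to_k: int | None
) -> np.ndarray:
    pos = np.array([r.position for r in segment])
    idx = np.array([r.index for r in segment])
    real = np.array([not r.is_virtual for r in segment])
    d = np.abs(pos[real][:, None] - pos[None, :])
    w = np.clip(1.0 - d / d_max, 0.0, None)
    if restrict_to_k is not None:
        diff = np.abs(idx[real][:, None] - idx[None, :])
        w = np.where(diff <= restrict_to_k, w, 0.0)
    return w


def _assemble(layout: Layout, kind: str, params: dict, per_segment) -> SpatialStructure:
    segments = layout.segments()
    blocks = []
    row_ids: list[str] = []
    col_ids: list[str] = []
    meta_rows = []
    for key in sorted(segments):
        seg = segments[key]
        X = per_segment(seg)
        blocks.append(X)
        col_ids.extend(r.row_id for r in seg)
        for r in seg:
            if not r.is_virtual:
                row_ids.append(r.row_id)
                meta_rows.append(
                    {"bed": r.bed, "unit": r.unit, "index": r.index, "position": r.position}
                )
    n = len(row_ids)
    q = len(col_ids)
    loadings = np.zeros((n, q))
    i0 = j0 = 0
    for X in blocks:
        ni, qi = X.shape
        loadings[i0 : i0 + ni, j0 : j0 + qi] = X
        i0 += ni
        j0 += qi
    gram = loadings @ loadings.T
    norm = np.trace(gram) / n
    if norm <= 0:
        raise StructureError("degenerate spatial structure: zero trace")
    S = gram / norm
    meta = pd.DataFrame(meta_rows, index=row_ids)
    return SpatialStructure(kind, params, loadings, S, norm, row_ids, col_ids, meta)


def _check_padding(layout: Layout, required: int) -> None:
    if layout.pad < required:
        raise StructureError(
            f"layout padded with {layout.pad} virtual rows per edge; "
            f"this structure needs at least {required}"
        )


def build_s_knn(layout: Layout, k: int = 5, allow_partial: bool = False) -> SpatialStructure:
    """Indicator-window structure: unit loading on target row and k rows per side."""
    if k < 0:
        raise ConfigurationError("k must be non-negative")
    if not allow_partial:
        _check_padding(layout, k)
    return _assemble(layout, "knn", {"k": k}, lambda seg: _segment_loadings_knn(seg, k))


def build_s_euc(
    layout: Layout,
    d_max: float = 2.75,
    restrict_to_k: int | None = 5,
    allow_partial: bool = False,
) -> SpatialStructure:
    """Linear distance-decay structure: loading ``1 - d/d_max`` within the window.

    By default the neighbour set is the same k-rows-per-side window as the
    indicator structure, with the loading scaled by the distance to the
    target row over ``d_max``; this is what makes the structure weight
    close neighbours relatively more (and distant ones less) than the
    indicator window.  Set ``restrict_to_k=None`` for the alternative
    reading where every row within ``d_max`` per side contributes.
    """
    if d_max <= 0:
        raise ConfigurationError("d_max must be positive")
    if not allow_partial:
        need = math.ceil(d_max / layout.row_spacing)
        if restrict_to_k is not None:
            need = min(need, restrict_to_k)
        _check_padding(layout, need)
    return _assemble(
        layout,
        "euc",
        {"d_max": d_max, "restrict_to_k": restrict_to_k},
        lambda seg: _segment_loadings_euc(seg, d_max, restrict_to_k),
    )


def correlation_decay(structure: SpatialStructure) -> pd.DataFrame:
    """Mean correlation per distinct inter-row distance (within-unit pairs)."""
    meta = structure.row_meta
    S = structure.S
    seg_key = meta["bed"].astype(str) + ":" + meta["unit"].astype(str)
    pos = meta["position"].to_numpy()
    records: dict[float, list[float]] = {}
    keys = seg_key.to_numpy()
    n = len(pos)
    for i in range(n):
        same = keys == keys[i]
        d = np.abs(pos - pos[i])
        for j in np.nonzero(same)[0]:
            if j < i:
                continue
            dist = round(float(d[j]), 9)
            records.setdefault(dist, []).append(S[i, j])
    rows = [
        {"distance_m": dist, "mean_correlation": float(np.mean(vals))}
        for dist, vals in sorted(records.items())
    ]
    return pd.DataFrame(rows)
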