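"""Study-level models for the semi-field trial and genetic-parameter formulas.

Above-ground model (one observation per half-row):

    y = Xb + Z_g g + Z_l l + Z_ng n_g + Z_nl n_l + Z_r r
          + Z_tg t_g + Z_tl t_l + Z_s1 s1 + Z_s2 s2 + e

with g ~ N(0, G sg2) the additive genomic breeding values, l ~ N(0, I sl2)
residual line effects, n_g/n_l the genomic/line effects of the two flanking
neighbour rows (each observation loads its left and right neighbour line
with coefficient 1), r ~ N(0, I sr2) row effects, t_g/t_l genotype-by-
treatment interactions (t_g with block-diagonal kernel diag(G, G)), and
s1/s2 spatial row effects with a nearest-neighbour correlation kernel and
one variance per water treatment.  The fixed factor is the combined
unit-bed-treatment cell.

Root model (one observation per tube and imaging time point) drops the
neighbour terms, uses a bed-camera-time fixed factor and one spatial
variance per time point.

Phenotypic variance per context (treatment or time point) sums the relevant
components; narrow- and broad-sense heritabilities divide d(G)*sg2 and
sl2 + d(G)*sg2 by it.  Because the published variance-component tables are
internally consistent only when the d(G) factors are omitted, both scalings
are available (``scale_by_avg_diag``); the unscaled variant is the table
reconciliation.  GCV = 100 * sg / trait mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as _sla

from .exceptions import StructureError, ValidationError
from .genomics import Grm
from .layout import Layout, SpatialStructure, build_s_euc, build_s_knn
from .lmm import MixedLMMResults, ModelSpec, RandomTerm

__all__ = [
    "build_am",
    "build_rm",
    "phenotypic_variance",
    "heritabilities",
    "GeneticParams",
    "AboveGroundModel",
    "RootModel",
    "StudyResults",
]

TREATMENTS = ("wet", "dry")

AM_TERMS = ("g", "l", "ng", "nl", "r", "tg", "tl", "s1", "s2")


def _onehot(codes: np.ndarray, n_levels: int) -> np.ndarray:
    Z = np.zeros((len(codes), n_levels))
    valid = codes >= 0
    Z[np.nonzero(valid)[0], codes[valid]] = 1.0
    return Z


def _row_ids(data: pd.DataFrame, row_col: str = "row") -> pd.Series:
    return (
        "b" + data["bed"].astype(int).astype(str)
        + "u" + data["unit"].astype(int).astype(str)
        + "r" + data[row_col].astype(int).astype(str)
    )


def _check_rows(row_ids: pd.Series, spatial: SpatialStructure) -> None:
    known = set(spatial.row_ids)
    missing = set(row_ids) - known
    if missing:
        raise StructureError(
            f"{len(missing)} observation rows absent from the spatial layout "
            f"(e.g. {sorted(missing)[:3]}); build the layout with virtual padding"
        )


def build_am(
    data: pd.DataFrame,
    grm: Grm,
    spatial: SpatialStructure,
    response: str = "GY",
) -> ModelSpec:
    """Assemble the above-ground model for one trait.

    ``data`` needs columns bed, unit, row, treatment ('wet'/'dry'), line and
    the response.  Neighbour loadings are derived from the physical row
    adjacency within each half-bed unit; edge rows flanked by a virtual row
    load only their single real neighbour.
    """
    req = {"bed", "unit", "row", "treatment", "line", response}
    if not req.issubset(data.columns):
        raise ValidationError(f"missing columns: {sorted(req - set(data.columns))}")
    bad = set(data["treatment"].unique()) - set(TREATMENTS)
    if bad:
        raise ValidationError(f"unknown treatment levels: {sorted(bad)}")
    data = data.reset_index(drop=True)
    n = len(data)
    lines = list(grm.line_ids)
    line_pos = {l: i for i, l in enumerate(lines)}
    unknown = set(data["line"].astype(str)) - set(lines)
    if unknown:
        raise ValidationError(f"lines without genomic information: {sorted(unknown)[:5]}")
    L = len(lines)
    G = grm.values

    line_codes = data["line"].astype(str).map(line_pos).to_numpy()
    Z_line = _onehot(line_codes, L)

    # physical row -> spatial structure index
    rid = _row_ids(data)
    _check_rows(rid, spatial)
    spat_idx = spatial.index_of(rid)
    R = spatial.n
    Z_row = _onehot(spat_idx, R)

    # neighbour lines from physical adjacency within a unit
    row_line: dict[tuple[int, int, int], str] = {}
    for _, rec in data.iterrows():
        row_line[(int(rec["bed"]), int(rec["unit"]), int(rec["row"]))] = str(rec["line"])
    Z_nb = np.zeros((n, L))
    for i, rec in enumerate(data.itertuples(index=False)):
        key = (int(rec.bed), int(rec.unit), int(rec.row))
        for step in (-1, 1):
            nb = (key[0], key[1], key[2] + step)
            if nb in row_line:
                Z_nb[i, line_pos[row_line[nb]]] += 1.0

    # genotype-by-treatment: levels ordered (all lines wet, all lines dry)
    treat_codes = data["treatment"].map({t: i for i, t in enumerate(TREATMENTS)}).to_numpy()
    Z_tg = _onehot(treat_codes * L + line_codes, 2 * L)
    K_tg = _sla.block_diag(G, G)

    wet = treat_codes == 0
    Z_s1 = Z_row * wet[:, None]
    Z_s2 = Z_row * (~wet)[:, None]

    tg_ids = [f"{l}:{t}" for t in TREATMENTS for l in lines]
    terms = [
        RandomTerm("g", Z_line, G, lines),
        RandomTerm("l", Z_line, None, lines),
        RandomTerm("ng", Z_nb, G, lines),
        RandomTerm("nl", Z_nb, None, lines),
        RandomTerm("r", Z_row, None, spatial.row_ids),
        RandomTerm("tg", Z_tg, K_tg, tg_ids),
        RandomTerm("tl", Z_tg, None, tg_ids),
        RandomTerm("s1", Z_s1, spatial.S, spatial.row_ids),
        RandomTerm("s2", Z_s2, spatial.S, spatial.row_ids),
    ]

    fixed_factor = (
        "u" + data["unit"].astype(str) + ":b" + data["bed"].astype(str)
        + ":" + data["treatment"].astype(str)
    )
    fixed_levels = sorted(fixed_factor.unique())
    X = _onehot(fixed_factor.map({f: i for i, f in enumerate(fixed_levels)}).to_numpy(), len(fixed_levels))
    y = data[response].to_numpy(dtype=float)
    keep = np.isfinite(y)
    if not keep.all():
        X = X[keep]
        y = y[keep]
        terms = [RandomTerm(t.name, t.Z[keep], t.kernel, t.level_ids) for t in terms]
        data = data.loc[keep].reset_index(drop=True)
    return ModelSpec(
        response=response,
        y=y,
        X=X,
        terms=terms,
        fixed_names=fixed_levels,
        meta={
            "kind": "AM",
            "spatial_kind": spatial.kind,
            "line_col": data["line"].astype(str).to_numpy(),
            "treatment": data["treatment"].to_numpy(),
            "d_g": grm.avg_diag,
            "data": data,
        },
    )


def build_rm(
    data: pd.DataFrame,
    grm: Grm,
    spatial: SpatialStructure,
    response: str = "TRL",
    n_time_points: int = 3,
) -> ModelSpec:
    """Assemble the root model for one trait.

    ``data`` needs columns bed, unit, tube, time (1..n_time_points), line
    and the response; an optional ``camera`` column refines the fixed
    bed-camera-time factor (it collapses to bed-time when absent).  Repeated
    tube records across time points share the row effect; each time point
    has its own spatial variance.
    """
    req = {"bed", "unit", "tube", "time", "line", response}
    if not req.issubset(data.columns):
        raise ValidationError(f"missing columns: {sorted(req - set(data.columns))}")
    data = data.reset_index(drop=True)
    times = data["time"].astype(int)
    bad = set(times.unique()) - set(range(1, n_time_points + 1))
    if bad:
        raise ValidationError(f"unknown time points: {sorted(bad)}")
    lines = list(grm.line_ids)
    line_pos = {l: i for i, l in enumerate(lines)}
    unknown = set(data["line"].astype(str)) - set(lines)
    if unknown:
        raise ValidationError(f"lines without genomic information: {sorted(unknown)[:5]}")
    L = len(lines)
    G = grm.values

    line_codes = data["line"].astype(str).map(line_pos).to_numpy()
    Z_line = _onehot(line_codes, L)

    rid = _row_ids(data, row_col="tube")
    _check_rows(rid, spatial)
    spat_idx = spatial.index_of(rid)
    Z_row = _onehot(spat_idx, spatial.n)

    terms = [
        RandomTerm("g", Z_line, G, lines),
        RandomTerm("l", Z_line, None, lines),
        RandomTerm("r", Z_row, None, spatial.row_ids),
    ]
    t_codes = times.to_numpy()
    for k in range(1, n_time_points + 1):
        mask = t_codes == k
        terms.append(
            RandomTerm(f"s{k}", Z_row * mask[:, None], spatial.S, spatial.row_ids)
        )

    if "camera" in data.columns:
        fixed_factor = (
            "b" + data["bed"].astype(str) + ":c" + data["camera"].astype(str)
            + ":t" + times.astype(str)
        )
    else:
        fixed_factor = "b" + data["bed"].astype(str) + ":t" + times.astype(str)
    fixed_levels = sorted(fixed_factor.unique())
    X = _onehot(fixed_factor.map({f: i for i, f in enumerate(fixed_levels)}).to_numpy(), len(fixed_levels))
    y = data[response].to_numpy(dtype=float)
    keep = np.isfinite(y)
    if not keep.all():
        X = X[keep]
        y = y[keep]
        terms = [RandomTerm(t.name, t.Z[keep], t.kernel, t.level_ids) for t in terms]
        data = data.loc[keep].reset_index(drop=True)
    return ModelSpec(
        response=response,
        y=y,
        X=X,
        terms=terms,
        fixed_names=fixed_levels,
        meta={
            "kind": "RM",
            "spatial_kind": spatial.kind,
            "line_col": data["line"].astype(str).to_numpy(),
            "n_time_points": n_time_points,
            "d_g": grm.avg_diag,
            "data": data,
        },
    )


# ----------------------------------------------------------------------
# genetic parameters


def phenotypic_variance(
    params: Mapping[str, float],
    kind: str,
    context,
    d_g: float = 1.0,
    scale_by_avg_diag: bool = True,
) -> float:
    """Half-row phenotypic variance for one context (treatment/time point).

    With ``scale_by_avg_diag`` the genomic components carry the d(G) factor
    (the published formula); without it they enter unscaled (the table
    reconciliation variant).
    """
    f = d_g if scale_by_avg_diag else 1.0
    try:
        if kind == "AM":
            s_key = {"wet": "s1", "dry": "s2"}[context]
            return (
                f * params["g"] + params["l"]
                + 2 * f * params["ng"] + 2 * params["nl"]
                + params["r"] + f * params["tg"] + params["tl"]
                + params[s_key] + params["residual"]
            )
        if kind == "RM":
            return (
                f * params["g"] + params["l"] + params["r"]
                + params[f"s{int(context)}"] + params["residual"]
            )
    except KeyError as exc:
        raise StructureError(f"missing variance component {exc} for {kind} model") from exc
    raise ValidationError(f"unknown model kind {kind!r}")


@dataclass
class GeneticParams:
    """Per-context phenotypic variance, heritabilities and GCV."""

    kind: str
    scaled: bool
    d_g: float
    per_context: pd.DataFrame  # index: context; columns sigma_p, h2, H2
    gcv: float

    @property
    def h2_mean(self) -> float:
        return float(self.per_context["h2"].mean())

    @property
    def H2_mean(self) -> float:
        return float(self.per_context["H2"].mean())

    def summary(self) -> str:
        lines = [
            f"Genetic parameters ({self.kind}, "
            f"{'d(G)-scaled' if self.scaled else 'unscaled'}; d(G) = {self.d_g:.3f})",
            self.per_context.to_string(float_format=lambda v: f"{v:.4f}"),
            f"mean h2 = {self.h2_mean:.3f}   mean H2 = {self.H2_mean:.3f}   "
            f"GCV = {self.gcv:.2f}%",
        ]
        return "\n".join(lines)


def heritabilities(
    params: Mapping[str, float],
    kind: str,
    trait_mean: float,
    d_g: float,
    contexts: Sequence | None = None,
    scale_by_avg_diag: bool = True,
) -> GeneticParams:
    """Narrow/broad-sense heritabilities per context and the GCV."""
    if contexts is None:
        contexts = TREATMENTS if kind == "AM" else (1, 2, 3)
    f = d_g if scale_by_avg_diag else 1.0
    rows = {}
    for ctx in contexts:
        sp = phenotypic_variance(params, kind, ctx, d_g, scale_by_avg_diag)
        if sp <= 0:
            raise ValidationError(f"non-positive phenotypic variance in context {ctx}")
        rows[ctx] = {
            "sigma_p": sp,
            "h2": f * params["g"] / sp,
            "H2": (params["l"] + f * params["g"]) / sp,
        }
    if trait_mean <= 0:
        raise ValidationError("trait mean must be positive for GCV")
    gcv = 100.0 * float(np.sqrt(params["g"])) / trait_mean
    return GeneticParams(
        kind=kind,
        scaled=scale_by_avg_diag,
        d_g=d_g,
        per_context=pd.DataFrame.from_dict(rows, orient="index"),
        gcv=gcv,
    )


# ----------------------------------------------------------------------
# statsmodels-style front ends


class _StudyModel:
    """Shared machinery for the above-ground and root model front ends."""

    kind = ""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.model = spec.to_model()

    @property
    def response(self) -> str:
        return self.spec.response

    def fit(self, **kwargs) -> "StudyResults":
        return StudyResults(self, self.model.fit(**kwargs))


class AboveGroundModel(_StudyModel):
    """Above-ground trait model with neighbour and treatment-interaction terms."""

    kind = "AM"

    def __init__(self, data: pd.DataFrame, grm: Grm, spatial: SpatialStructure, trait: str = "GY"):
        super().__init__(build_am(data, grm, spatial, response=trait))

    @classmethod
    def from_layout(
        cls,
        data: pd.DataFrame,
        grm: Grm,
        layout: Layout,
        variant: str = "M1",
        trait: str = "GY",
        k: int = 5,
        d_max: float = 2.75,
    ) -> "AboveGroundModel":
        spatial = _variant_structure(layout, variant, k, d_max)
        return cls(data, grm, spatial, trait=trait)


class RootModel(_StudyModel):
    """Root trait model with repeated tube records and per-time spatial variances."""

    kind = "RM"

    def __init__(self, data: pd.DataFrame, grm: Grm, spatial: SpatialStructure, trait: str = "TRL"):
        super().__init__(build_rm(data, grm, spatial, response=trait))

    @classmethod
    def from_layout(
        cls,
        data: pd.DataFrame,
        grm: Grm,
        layout: Layout,
        variant: str = "M1",
        trait: str = "TRL",
        k: int = 5,
        d_max: float = 2.75,
    ) -> "RootModel":
        spatial = _variant_structure(layout, variant, k, d_max)
        return cls(data, grm, spatial, trait=trait)


def _variant_structure(layout: Layout, variant: str, k: int, d_max: float) -> SpatialStructure:
    if variant.upper().endswith("1"):
        return build_s_knn(layout, k=k)
    if variant.upper().endswith("2"):
        return build_s_euc(layout, d_max=d_max)
    raise ValidationError(f"unknown model variant {variant!r}; use M1/M2 (AM1/AM2/RM1/RM2)")


class StudyResults:
    """Fitted study model: variance components plus genetic-parameter views."""

    def __init__(self, study: _StudyModel, result: MixedLMMResults):
        self.study = study
        self.result = result

    @property
    def params(self) -> pd.Series:
        return self.result.params

    @property
    def d_g(self) -> float:
        return self.study.spec.meta["d_g"]

    @property
    def kind(self) -> str:
        return self.study.spec.meta["kind"]

    def params_dict(self) -> dict:
        return self.result.params.to_dict()

    def phenotypic_variance(self, context, scale_by_avg_diag: bool = True) -> float:
        return phenotypic_variance(
            self.params_dict(), self.kind, context, self.d_g, scale_by_avg_diag
        )

    def genetic_params(
        self, trait_mean: float | None = None, scale_by_avg_diag: bool = True
    ) -> GeneticParams:
        if trait_mean is None:
            trait_mean = float(np.mean(self.study.spec.y))
        return heritabilities(
            self.params_dict(),
            self.kind,
            trait_mean,
            self.d_g,
            scale_by_avg_diag=scale_by_avg_diag,
        )

    def summary(self) -> str:
        parts = [self.result.summary()]
        if self.result.converged:
            for scaled in (True, False):
                try:
                    parts.append(self.genetic_params(scale_by_avg_diag=scaled).summary())
                except ValidationError:
                    pass
        return "\n\n".join(parts)
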