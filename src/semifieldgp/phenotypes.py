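"""Trait derivation, root-image summarisation and data editing.

Above-ground traits: grain yield (GY, t/ha), grain protein content (GPC, %),
grain nitrogen removal derived as GNR = GY * GPC / 6.25 (kg/ha; 6.25 is the
standard nitrogen-to-protein conversion factor for cereals, the x10 factor
converts t/ha*% to kg/ha) and thousand kernel weight TKW = sample weight /
seed count * 1000 (g).

Root traits per minirhizotron tube and imaging time point: total root
length (TRL) sums visible root length over all images of the tube; shallow
(SRL) and deep (DRL) root length sum over the 100-120 cm and 120-180 cm
soil-depth windows.  The shared 120 cm boundary is counted once, in DRL
(windows [100, 120) and [120, 180]).

Editing removes per-trait values beyond +/- ``sd_limit`` standard deviations
from the mean (single pass, mean/SD from the unedited column) and records of
lines without genomic information.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = ["derive_gnr", "derive_tkw", "summarize_roots", "edit_records"]

NITROGEN_PROTEIN_FACTOR = 6.25


def derive_gnr(gy, gpc):
    """Grain nitrogen removal in kg/ha from GY (t/ha) and GPC (%)."""
    gy = np.asarray(gy, dtype=float)
    gpc = np.asarray(gpc, dtype=float)
    if np.any(gy < 0) or np.any(gpc < 0):
        raise ValidationError("GY and GPC must be non-negative")
    out = gy * gpc / NITROGEN_PROTEIN_FACTOR * 10.0
    return float(out) if out.ndim == 0 else out


def derive_tkw(sample_weight, seed_count):
    """Thousand kernel weight (g) from sample weight (g) and seed count."""
    w = np.asarray(sample_weight, dtype=float)
    n = np.asarray(seed_count, dtype=float)
    if np.any(w < 0):
        raise ValidationError("sample weight must be non-negative")
    if np.any(n <= 0):
        raise ValidationError("seed count must be positive")
    out = w / n * 1000.0
    return float(out) if out.ndim == 0 else out


def summarize_roots(
    images: pd.DataFrame,
    shallow_window: tuple[float, float] = (100.0, 120.0),
    deep_window: tuple[float, float] = (120.0, 180.0),
    group_cols: Sequence[str] = ("bed", "tube", "time"),
    depth_col: str = "depth",
    length_col: str = "length",
) -> pd.DataFrame:
    """Summarise image records into tube x time-point root traits.

    Windows are half-open [lo, hi) for the shallow band and closed [lo, hi]
    for the deep band so the shared boundary is counted exactly once.
    Groups with no images yield no record (missing, not zero).
    """
    if (images[length_col] < 0).any():
        raise ValidationError("visible root length must be non-negative")
    depth = images[depth_col]
    s_lo, s_hi = shallow_window
    d_lo, d_hi = deep_window
    work = images.assign(
        _srl=images[length_col].where((depth >= s_lo) & (depth < s_hi), 0.0),
        _drl=images[length_col].where((depth >= d_lo) & (depth <= d_hi), 0.0),
    )
    agg = (
        work.groupby(list(group_cols), sort=True)
        .agg(TRL=(length_col, "sum"), SRL=("_srl", "sum"), DRL=("_drl", "sum"))
        .reset_index()
    )
    return agg


def edit_records(
    records: pd.DataFrame,
    value_cols: Sequence[str],
    sd_limit: float = 3.0,
    group_cols: Sequence[str] | None = None,
    known_lines: Iterable[str] | None = None,
    line_col: str = "line",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the +/- sd_limit SD edit and the genotyped-lines edit.

    Per trait column, values with |x - mean| > sd_limit * SD are set to
    missing; mean and SD (sample SD) come from the unedited column in a
    single pass, optionally within ``group_cols`` groups.  Records whose
    line is absent from ``known_lines`` are dropped entirely.  Returns the
    edited table and a per-rule removal report.
    """
    if sd_limit <= 0:
        raise ValidationError("sd_limit must be positive")
    df = records.copy()
    report_rows = []

    n_no_geno = 0
    if known_lines is not None:
        known = set(map(str, known_lines))
        keep = df[line_col].astype(str).isin(known)
        n_no_geno = int((~keep).sum())
        df = df.loc[keep].copy()

    def _mask(col: pd.Series) -> pd.Series:
        m, s = col.mean(), col.std(ddof=1)
        if not np.isfinite(s) or s == 0:
            return pd.Series(False, index=col.index)
        return (col - m).abs() > sd_limit * s

    for col in value_cols:
        if group_cols:
            outlier = df.groupby(list(group_cols))[col].transform(
                lambda c: _mask(c)
            ).astype(bool)
        else:
            outlier = _mask(df[col])
        outlier &= df[col].notna()
        n_out = int(outlier.sum())
        df.loc[outlier, col] = np.nan
        report_rows.append(
            {"trait": col, "removed_outliers": n_out, "removed_no_genotype": n_no_geno}
        )

    df = df.dropna(subset=list(value_cols), how="all")
    if len(df) == 0:
        raise ValidationError("no records remain after editing")
    return df, pd.DataFrame(report_rows)
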