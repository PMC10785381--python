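"""Leave-one-line-out cross-validation and prediction-quality statistics.

The validation strategy estimates variance components and fixed effects
once, from the full data set.  Fixed-effect estimates are subtracted from
the phenotypes to give corrected phenotypes ``y_c = y - X b_hat``.  Then one
line at a time is removed and its genomic breeding value is predicted from
the remaining records through the genomic relationship matrix; variance
components are held fixed across folds.  Predictive ability (PA) is the
correlation between corrected phenotypes and the line GEBVs, compared
against the theoretical maximum ``sqrt(n h2 / (1 + (n - 1) h2))`` for a
line with ``n`` repetitions; their ratio is the prediction accuracy (ACC).
Dispersion of the predictions is measured by the regression
``b_wp = cov(g_whole, g_partial) / var(g_partial)`` (1 = no inflation).
Standard errors come from an ordinary non-parametric bootstrap; predictive
abilities of two models sharing the corrected phenotypes are compared with
the Hotelling-Williams t-test for dependent correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .exceptions import ConfigurationError, ValidationError
from .lmm import MixedLMM, MixedLMMResults

__all__ = [
    "corrected_phenotypes",
    "loo_gebv",
    "whole_gebv",
    "loo_cv",
    "predictive_ability",
    "max_potential_pa",
    "inflation_bwp",
    "bootstrap_se",
    "hotelling_williams",
    "cross_validate",
    "compare_predictive_abilities",
    "CvReport",
]


def corrected_phenotypes(result: MixedLMMResults) -> np.ndarray:
    """Phenotypes minus the full-data fixed-effect estimates, per observation."""
    return result.model.y - result.fitted_fixed()


def _term_index(model: MixedLMM, term: str) -> int:
    for i, t in enumerate(model.terms):
        if t.name == term:
            return i
    raise ConfigurationError(f"model has no random term named {term!r}")


def whole_gebv(model: MixedLMM, vcs, term: str = "g") -> pd.Series:
    """Per-line additive genomic BLUPs from the full data at fixed VCs."""
    sol = model.solve(np.asarray(vcs, dtype=float))
    return sol.blups[term]


def loo_gebv(
    model: MixedLMM,
    vcs,
    line_labels: np.ndarray,
    term: str = "g",
) -> pd.Series:
    """Leave-one-line-out GEBV for every line with observations.

    For each line, all its records are removed, the mixed-model equations
    are re-solved on the remaining data at the full-data variance
    components, and the left-out line's breeding value is predicted through
    the genomic relationship kernel.
    """
    theta = np.asarray(vcs, dtype=float)
    ti = _term_index(model, term)
    t = model.terms[ti]
    K = t.kernel if t.kernel is not None else np.eye(t.n_levels)
    level_ids = list(t.level_ids) if t.level_ids is not None else list(range(t.n_levels))
    level_pos = {l: i for i, l in enumerate(level_ids)}

    labels = np.asarray(line_labels)
    if labels.shape[0] != model.n:
        raise ValidationError("line_labels length does not match observations")

    # total random covariance at the fitted VCs, subset per fold
    C_tot = np.zeros((model.n, model.n))
    for th, C in zip(theta[:-1], model._C):
        C_tot += th * C

    out = {}
    for lab in pd.unique(labels):
        train = labels != lab
        if not train.any():
            raise ValidationError("a fold has empty training data")
        V = C_tot[np.ix_(train, train)].copy()
        V[np.diag_indices_from(V)] += theta[-1]
        cf = linalg.cho_factor(V, lower=True, check_finite=False)
        X = model.X[train]
        y = model.y[train]
        ViX = linalg.cho_solve(cf, X, check_finite=False)
        Viy = linalg.cho_solve(cf, y, check_finite=False)
        XtViX = X.T @ ViX
        beta = np.linalg.pinv(XtViX) @ (X.T @ Viy)
        Py = Viy - ViX @ beta
        u = theta[ti] * (K @ (t.Z[train].T @ Py))
        out[lab] = float(u[level_pos[lab]])
    return pd.Series(out, name=f"gebv_{term}_loo")


# backwards-compatible spec name
loo_cv = loo_gebv


def predictive_ability(y_c: np.ndarray, gebv: np.ndarray) -> float:
    """Pearson correlation between corrected phenotypes and paired GEBVs."""
    y_c = np.asarray(y_c, dtype=float)
    gebv = np.asarray(gebv, dtype=float)
    if y_c.size < 3:
        raise ValidationError("need at least 3 paired values")
    if np.std(y_c) == 0 or np.std(gebv) == 0:
        raise ValidationError("zero variance: predictive ability undefined")
    return float(np.corrcoef(y_c, gebv)[0, 1])


def max_potential_pa(h2: float, n_reps: float) -> float:
    """Theoretical ceiling on PA given heritability and mean replication."""
    if not 0.0 <= h2 <= 1.0:
        raise ValidationError("h2 must lie in [0, 1]")
    if n_reps < 1:
        raise ValidationError("n_reps must be at least 1")
    return float(np.sqrt(n_reps * h2 / (1.0 + (n_reps - 1.0) * h2)))


def inflation_bwp(ghat_whole: np.ndarray, ghat_partial: np.ndarray) -> float:
    """Regression of whole-data genetic values on cross-validated ones."""
    gw = np.asarray(ghat_whole, dtype=float)
    gp = np.asarray(ghat_partial, dtype=float)
    if gw.shape != gp.shape:
        raise ValidationError("paired vectors have different lengths")
    v = np.var(gp, ddof=1)
    if v == 0:
        raise ValidationError("zero variance in partial-data predictions")
    c = np.cov(gw, gp, ddof=1)[0, 1]
    return float(c / v)


def bootstrap_se(
    statistic,
    data: np.ndarray | pd.DataFrame,
    B: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Ordinary non-parametric bootstrap SE of a statistic of data rows.

    Resamples rows with replacement at full sample size.  Returns
    ``(se, 1.96 * se)``; deterministic for a given seed.
    """
    if B < 2:
        raise ValidationError("need at least 2 bootstrap replicates")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = data.to_numpy() if isinstance(data, pd.DataFrame) else np.asarray(data)
    n = arr.shape[0]
    vals = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        vals[b] = statistic(arr[idx])
    se = float(np.std(vals, ddof=1))
    return se, 1.96 * se


def hotelling_williams(r12: float, r13: float, r23: float, n: int) -> tuple[float, float]:
    """Williams' t for two dependent correlations sharing variable 1.

    Returns the t statistic (df = n - 3) and the two-sided p-value.
    """
    if n <= 3:
        raise ValidationError("need n > 3")
    for r in (r12, r13, r23):
        if not -1.0 < r < 1.0:
            raise ValidationError("correlations must lie in (-1, 1)")
    detR = 1.0 - r12**2 - r13**2 - r23**2 + 2.0 * r12 * r13 * r23
    rbar = (r12 + r13) / 2.0
    denom = 2.0 * ((n - 1.0) / (n - 3.0)) * detR + rbar**2 * (1.0 - r23) ** 3
    t = (r12 - r13) * np.sqrt((n - 1.0) * (1.0 + r23) / denom)
    p = 2.0 * stats.t.sf(abs(t), df=n - 3)
    return float(t), float(p)


@dataclass
class CvReport:
    """Per-line GEBVs and the derived prediction-quality statistics."""

    gebv_partial: pd.Series
    gebv_whole: pd.Series
    y_corrected: np.ndarray
    line_labels: np.ndarray
    pa: float
    max_pa: float
    acc: float
    b_wp: float
    pa_se: float
    b_wp_se: float
    h2: float
    n_reps: float
    n_bootstrap: int

    @property
    def obs_gebv(self) -> np.ndarray:
        return self.gebv_partial.loc[self.line_labels].to_numpy()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gebv_loo": self.gebv_partial, "gebv_whole": self.gebv_whole}
        )

    def summary(self) -> str:
        return "\n".join(
            [
                "Leave-one-line-out cross-validation",
                f"  lines: {len(self.gebv_partial)}   observations: {len(self.y_corrected)}"
                f"   bootstrap replicates: {self.n_bootstrap}",
                f"  PA    = {self.pa:.3f} +/- {1.96 * self.pa_se:.3f} (95% CI)",
                f"  maxPA = {self.max_pa:.3f} (h2 = {self.h2:.3f}, n = {self.n_reps:.1f})",
                f"  ACC   = {self.acc:.3f}",
                f"  b_wp  = {self.b_wp:.3f} +/- {1.96 * self.b_wp_se:.3f} (95% CI)",
            ]
        )

    def plot(self, ax=None):
        """Scatter of corrected phenotypes against LOO GEBVs."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.obs_gebv, self.y_corrected, s=8, alpha=0.5)
        ax.set_xlabel("LOO GEBV")
        ax.set_ylabel("corrected phenotype")
        ax.set_title(f"PA = {self.pa:.3f}")
        return ax


def cross_validate(
    study_results,
    h2: float | None = None,
    n_reps: float | None = None,
    bootstrap: int = 10_000,
    seed: int = 0,
    level: str = "observation",
    term: str = "g",
) -> CvReport:
    """Full LOO-CV report for a fitted study model.

    ``level`` chooses whether PA pairs GEBVs with every observation
    ('observation', the default) or with line means ('line').  ``h2``
    defaults to the mean table-scale (unscaled) narrow-sense heritability of
    the fit; ``n_reps`` defaults to the mean number of records per line.
    """
    res = study_results.result
    model = res.model
    theta = res.params.to_numpy()
    labels = np.asarray(study_results.study.spec.meta["line_col"])

    y_c = corrected_phenotypes(res)
    gebv_p = loo_gebv(model, theta, labels, term=term)
    gebv_w = whole_gebv(model, theta, term=term).loc[gebv_p.index]

    if level == "line":
        means = pd.Series(y_c).groupby(labels).mean()
        pairs = np.column_stack([means.loc[gebv_p.index], gebv_p.to_numpy()])
    elif level == "observation":
        pairs = np.column_stack([y_c, gebv_p.loc[labels].to_numpy()])
    else:
        raise ConfigurationError("level must be 'observation' or 'line'")
    pa = predictive_ability(pairs[:, 0], pairs[:, 1])

    if n_reps is None:
        n_reps = len(labels) / len(pd.unique(labels))
    if h2 is None:
        h2 = float(
            np.clip(study_results.genetic_params(scale_by_avg_diag=False).h2_mean, 0.0, 1.0)
        )
    mp = max_potential_pa(h2, n_reps)
    acc = pa / mp if mp > 0 else np.nan

    b_wp = inflation_bwp(gebv_w.to_numpy(), gebv_p.to_numpy())

    rng = np.random.default_rng(seed)
    pa_se, _ = bootstrap_se(
        lambda a: np.corrcoef(a[:, 0], a[:, 1])[0, 1], pairs, B=bootstrap, seed=rng
    )
    line_pairs = np.column_stack([gebv_w.to_numpy(), gebv_p.to_numpy()])

    def _bwp(a):
        v = np.var(a[:, 1], ddof=1)
        return np.cov(a[:, 0], a[:, 1], ddof=1)[0, 1] / v if v > 0 else np.nan

    b_wp_se, _ = bootstrap_se(_bwp, line_pairs, B=bootstrap, seed=rng)

    return CvReport(
        gebv_partial=gebv_p,
        gebv_whole=gebv_w,
        y_corrected=y_c,
        line_labels=labels,
        pa=pa,
        max_pa=mp,
        acc=acc,
        b_wp=b_wp,
        pa_se=pa_se,
        b_wp_se=b_wp_se,
        h2=h2,
        n_reps=float(n_reps),
        n_bootstrap=bootstrap,
    )


def compare_predictive_abilities(report_a: CvReport, report_b: CvReport) -> dict:
    """Hotelling-Williams comparison of two models' PAs on shared phenotypes."""
    if len(report_a.y_corrected) != len(report_b.y_corrected):
        raise ValidationError("reports do not share the same observations")
    n = len(report_a.y_corrected)
    r23 = float(np.corrcoef(report_a.obs_gebv, report_b.obs_gebv)[0, 1])
    t, p = hotelling_williams(report_a.pa, report_b.pa, r23, n)
    return {"t": t, "p_value": p, "r12": report_a.pa, "r13": report_b.pa, "r23": r23, "n": n}
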