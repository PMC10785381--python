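"""Linear mixed model engine: AI-REML with EM fallback, BLUP/BLUE solutions.

Model:  y = X b + sum_i Z_i u_i + e,   u_i ~ N(0, K_i * sigma_i^2),
        e ~ N(0, I * sigma_e^2),

with K_i a supplied positive semi-definite kernel (genomic relationship,
spatial correlation, block-diagonal kernel) or the identity.  Variance
components are estimated by maximising the restricted likelihood with
average-information (AI) updates taken on the log-variance scale (so a
proposed update can never cross zero) after a couple of monotone EM
burn-in iterations.  The AI step is clipped and step-halved until it does
not decrease the restricted likelihood; when no fraction of it is
acceptable (or a parameter would leave its bounds) the update falls back
to the monotone EM step.  Variances are floored at ``floor_scale`` times
the phenotypic variance and reported at the floor rather than dropped.

The restricted log-likelihood convention includes the ``-log|X'X|`` term so
that values agree exactly with the error-contrast definition
``log N(A'y; 0, A'VA)`` for any orthonormal basis A of the null space of X'.

Dense linear algebra throughout: the intended problem sizes (around one
thousand observations, a few hundred effect levels) never require sparse
methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .exceptions import ConfigurationError, StructureError, ValidationError

__all__ = ["RandomTerm", "ModelSpec", "MixedLMM", "MixedLMMResults", "BlupSolution"]


@dataclass
class RandomTerm:
    """One random term: loading matrix Z (n x q) and optional kernel K (q x q)."""

    name: str
    Z: np.ndarray
    kernel: np.ndarray | None = None
    level_ids: Sequence | None = None

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.ndim != 2:
            raise StructureError(f"term {self.name}: Z must be 2-D")
        if self.kernel is not None:
            K = np.asarray(self.kernel, dtype=float)
            if K.shape != (self.Z.shape[1], self.Z.shape[1]):
                raise StructureError(
                    f"term {self.name}: kernel dimension {K.shape} does not match "
                    f"level count {self.Z.shape[1]}"
                )
            if not np.allclose(K, K.T, atol=1e-8):
                raise StructureError(f"term {self.name}: kernel not symmetric")
            w = np.linalg.eigvalsh(K)
            if w[0] < -1e-6 * max(1.0, w[-1]):
                raise StructureError(f"term {self.name}: kernel not positive semi-definite")
            self.kernel = K
        if self.level_ids is not None and len(self.level_ids) != self.Z.shape[1]:
            raise StructureError(f"term {self.name}: level_ids length mismatch")

    @property
    def n_levels(self) -> int:
        return self.Z.shape[1]

    def cov_contribution(self) -> np.ndarray:
        """Z K Z' (or Z Z' for identity kernel), the n x n covariance share."""
        if self.kernel is None:
            return self.Z @ self.Z.T
        return self.Z @ self.kernel @ self.Z.T


@dataclass
class ModelSpec:
    """A realised model design: response, fixed design and random terms."""

    response: str
    y: np.ndarray
    X: np.ndarray
    terms: list[RandomTerm]
    fixed_names: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def to_model(self) -> "MixedLMM":
        return MixedLMM(self.y, self.X, self.terms, fixed_names=self.fixed_names)


def _reduce_rank(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Drop linearly dependent columns in first-occurrence order."""
    keep: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) > len(keep):
            keep.append(j)
    dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
    return X[:, keep], [names[j] for j in keep], dropped


class MixedLMM:
    """Mixed linear model with supplied-kernel random terms, fitted by AI-REML."""

    N_EM_BURNIN = 2  # EM iterations before the first AI update

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        terms: Sequence[RandomTerm],
        fixed_names: Sequence[str] | None = None,
    ):
        y = np.asarray(y, dtype=float).ravel()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != y.shape[0]:
            raise ValidationError("X and y have different numbers of observations")
        for t in terms:
            if t.Z.shape[0] != y.shape[0]:
                raise StructureError(f"term {t.name}: Z row count does not match y")
        names = list(fixed_names) if fixed_names is not None else [
            f"x{j}" for j in range(X.shape[1])
        ]
        X, names, dropped = _reduce_rank(X, names)
        self.y = y
        self.X = X
        self.fixed_names = names
        self.dropped_fixed = dropped
        self.terms = list(terms)
        self.n, self.p = X.shape
        if self.n <= self.p:
            raise ValidationError("more fixed-effect levels than observations")
        # n x n covariance contribution of each term, computed once
        self._C = [t.cov_contribution() for t in self.terms]
        sign, logdet_xtx = np.linalg.slogdet(X.T @ X)
        self._logdet_xtx = logdet_xtx
        self.param_names = [t.name for t in self.terms] + ["residual"]

    # ------------------------------------------------------------------
    def _build_v(self, theta: np.ndarray) -> np.ndarray:
        V = np.zeros((self.n, self.n))
        for th, C in zip(theta[:-1], self._C):
            V += th * C
        V[np.diag_indices_from(V)] += theta[-1]
        return V

    def profile_loglik(self, vcs: Sequence[float]) -> float:
        """Restricted log-likelihood at fixed variance components."""
        theta = np.asarray(vcs, dtype=float)
        if theta.shape != (len(self.terms) + 1,):
            raise ConfigurationError(
                f"expected {len(self.terms) + 1} variance components, got {theta.shape}"
            )
        return self._loglik(theta)

    def _loglik(self, theta: np.ndarray) -> float:
        V = self._build_v(theta)
        try:
            cf = linalg.cho_factor(V, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return -np.inf
        logdet_v = 2.0 * np.sum(np.log(np.diag(cf[0])))
        ViX = linalg.cho_solve(cf, self.X, check_finite=False)
        Viy = linalg.cho_solve(cf, self.y, check_finite=False)
        XtViX = self.X.T @ ViX
        try:
            cfx = linalg.cho_factor(XtViX, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return -np.inf
        logdet_x = 2.0 * np.sum(np.log(np.diag(cfx[0])))
        Xty = self.X.T @ Viy
        beta = linalg.cho_solve(cfx, Xty, check_finite=False)
        ypy = float(self.y @ Viy - Xty @ beta)
        return -0.5 * (
            (self.n - self.p) * np.log(2.0 * np.pi)
            + logdet_v
            + logdet_x
            - self._logdet_xtx
            + ypy
        )

    def _state(self, theta: np.ndarray) -> dict:
        """Full REML state: V^-1, P, Py, beta and the log-likelihood."""
        V = self._build_v(theta)
        cf = linalg.cho_factor(V, lower=True, check_finite=False)
        logdet_v = 2.0 * np.sum(np.log(np.diag(cf[0])))
        inv_tri, info = linalg.lapack.dpotri(cf[0], lower=1)
        if info != 0:
            raise linalg.LinAlgError("dpotri failed")
        Vinv = np.tril(inv_tri) + np.tril(inv_tri, -1).T
        ViX = Vinv @ self.X
        XtViX = self.X.T @ ViX
        cfx = linalg.cho_factor(XtViX, lower=True, check_finite=False)
        logdet_x = 2.0 * np.sum(np.log(np.diag(cfx[0])))
        XtViX_inv = linalg.cho_solve(cfx, np.eye(self.p), check_finite=False)
        P = Vinv - ViX @ XtViX_inv @ ViX.T
        P = (P + P.T) / 2.0
        Py = P @ self.y
        beta = XtViX_inv @ (ViX.T @ self.y)
        ll = -0.5 * (
            (self.n - self.p) * np.log(2.0 * np.pi)
            + logdet_v
            + logdet_x
            - self._logdet_xtx
            + float(self.y @ Py)
        )
        return {
            "P": P,
            "Py": Py,
            "beta": beta,
            "beta_cov": XtViX_inv,
            "loglik": ll,
        }

    def _derivative_parts(self, state: dict) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """tr(P V_i), y'P V_i P y and the AI matrix for every parameter."""
        P, Py = state["P"], state["Py"]
        m = len(self.terms) + 1
        tr_pc = np.empty(m)
        ypcpy = np.empty(m)
        W = np.empty((self.n, m))
        for i, C in enumerate(self._C):
            tr_pc[i] = float(np.sum(P * C))  # both symmetric
            w = C @ Py
            W[:, i] = w
            ypcpy[i] = float(Py @ w)
        tr_pc[-1] = float(np.trace(P))
        W[:, -1] = Py
        ypcpy[-1] = float(Py @ Py)
        AI = 0.5 * (W.T @ (P @ W))
        AI = (AI + AI.T) / 2.0
        return tr_pc, ypcpy, AI

    def fit(
        self,
        start: Sequence[float] | None = None,
        maxiter: int = 200,
        rtol: float = 1e-8,
        ltol: float = 1e-9,
        floor_scale: float = 1e-8,
    ) -> "MixedLMMResults":
        """Maximise the restricted likelihood over the variance components."""
        m = len(self.terms) + 1
        vary = max(float(np.var(self.y)), 1e-12)
        floor = floor_scale * vary
        if start is None:
            theta = np.full(m, vary / m)
        else:
            theta = np.asarray(start, dtype=float).copy()
            if theta.shape != (m,):
                raise ConfigurationError(f"start must have length {m}")
        theta = np.maximum(theta, floor)
        qs = np.array([t.n_levels for t in self.terms] + [self.n], dtype=float)
        # a term no observation loads is unidentifiable: report it at the floor
        unused = np.array([not np.any(C) for C in self._C] + [False])
        theta[unused] = floor

        trace: list[dict] = []
        converged = False
        prev_ll = -np.inf
        prev_rel = np.inf
        step_kind = "init"
        state = None
        best_ll, best_theta = -np.inf, theta.copy()
        pinned = unused.copy()
        stall = 0  # consecutive iterations of tiny (but non-converged) gain
        for it in range(maxiter):
            state = self._state(theta)
            ll = state["loglik"]
            trace.append({"theta": theta.copy(), "loglik": ll, "step": step_kind})
            if ll > best_ll:
                best_ll, best_theta = ll, theta.copy()
            if it > 0 and (prev_rel < rtol or abs(ll - prev_ll) < ltol):
                converged = True
                break
            # ridge-walk detector: steady but slow progress over the last
            # ten iterations (well above the convergence tolerance yet far
            # below useful speed) earns a full AI jump below
            if it >= 10:
                window_gain = ll - trace[-11]["loglik"]
                stall = 1 if 1e-3 < window_gain < 1.0 else 0
            else:
                stall = 0
            tr_pc, ypcpy, AI = self._derivative_parts(state)
            scores = -0.5 * (tr_pc - ypcpy)
            # active set: a component below 1e-4 of the phenotypic variance
            # whose gradient points downhill is pinned at the floor (it
            # would otherwise decay over hundreds of EM iterations, and its
            # near-boundary curvature poisons the AI system).  Pinning is
            # permanent within a fit; re-releasing causes limit cycles when
            # a component's optimum sits near the pinning threshold
            pinned |= (theta <= 1e-4 * vary) & (scores < 0.0)
            snapped = bool(np.any(pinned & (theta > floor)))
            free = ~pinned
            # EM candidate: monotone (up to pinning) and always in-bounds
            theta_em = np.maximum(theta + (theta**2 / qs) * (ypcpy - tr_pc), floor)
            theta_em[pinned] = floor
            # AI candidate on the log-variance scale over the free set: a
            # multiplicative update cannot cross zero, and the step is
            # clipped (factor e^3 at most) and halved until the restricted
            # likelihood does not decrease; otherwise take the EM step
            new_theta, step = theta_em, "em+snap" if snapped else "em"
            if it >= self.N_EM_BURNIN and free.any():
                th_f = theta[free]
                AIp = AI[np.ix_(free, free)] * np.outer(th_f, th_f)
                try:
                    d = np.linalg.solve(AIp + 1e-10 * np.eye(len(th_f)),
                                        th_f * scores[free])
                    d = np.clip(d, -3.0, 3.0)
                    if stall:
                        # the iterate is crawling along a likelihood ridge:
                        # take the full AI step with a bounded dip to leave
                        # it (the best visited point is restored at the end
                        # if the excursion never pays off)
                        cand = theta.copy()
                        cand[free] = np.maximum(th_f * np.exp(d), floor)
                        cand[pinned] = floor
                        ll_cand = self._loglik(cand)
                        if np.isfinite(ll_cand) and ll_cand >= ll - 50.0:
                            new_theta, step = cand, "ai-jump"
                            stall = 0
                    if step not in ("ai-jump",):
                        fallback = None
                        for frac in (1.0, 0.5, 0.25, 0.1, 0.03, 0.01):
                            cand = theta.copy()
                            cand[free] = np.maximum(th_f * np.exp(frac * d), floor)
                            cand[pinned] = floor
                            ll_cand = self._loglik(cand)
                            if np.isfinite(ll_cand) and ll_cand >= ll - 1e-8:
                                new_theta = cand
                                step = "ai+snap" if snapped else "ai"
                                break
                            if frac == 0.25 and np.isfinite(ll_cand) and ll_cand >= ll - 0.5:
                                fallback = cand
                        else:
                            # no monotone fraction and negligible EM gain:
                            # accept a damped AI step with a bounded dip
                            ll_em = self._loglik(theta_em)
                            if fallback is not None and ll_em - ll < 1e-3:
                                new_theta, step = fallback, "ai-dip"
                except np.linalg.LinAlgError:
                    pass
            prev_rel = float(np.max(np.abs(new_theta - theta) / np.maximum(theta, floor)))
            prev_ll = ll
            theta = new_theta
            step_kind = step
        else:
            state = self._state(theta)
            trace.append({"theta": theta.copy(), "loglik": state["loglik"], "step": step_kind})
        if state["loglik"] < best_ll - 1e-8:
            # a non-monotone excursion ended below the best visited point
            theta = best_theta
            state = self._state(theta)

        _, _, AI = self._derivative_parts(state)
        try:
            ai_inv = np.linalg.inv(AI)
        except np.linalg.LinAlgError:
            ai_inv = np.linalg.pinv(AI)
        bse = np.sqrt(np.maximum(np.diag(ai_inv), 0.0))
        return MixedLMMResults(
            model=self,
            params=pd.Series(theta, index=self.param_names),
            bse=pd.Series(bse if converged else np.full(m, np.nan), index=self.param_names),
            fe_params=pd.Series(state["beta"], index=self.fixed_names),
            fe_cov=pd.DataFrame(state["beta_cov"], index=self.fixed_names, columns=self.fixed_names),
            loglike=state["loglik"],
            converged=converged,
            n_iter=len(trace),
            trace=trace,
            floor=floor,
            _Py=state["Py"],
        )

    def solve(self, vcs: Sequence[float]) -> "BlupSolution":
        """BLUE/BLUP solution at fixed variance components.

        Random-effect predictions are ``sigma_i^2 K_i Z_i' P y``; levels
        with no observations are predicted through the kernel, which is the
        genomic-prediction contract.
        """
        theta = np.asarray(vcs, dtype=float)
        if np.any(theta[:-1] < 0) or theta[-1] <= 0:
            raise ConfigurationError("variance components must be non-negative, residual positive")
        state = self._state(theta)
        blups = _blups_from_py(self.terms, theta, state["Py"])
        return BlupSolution(
            fixed_effects=pd.Series(state["beta"], index=self.fixed_names),
            blups=blups,
            loglik=state["loglik"],
            Py=state["Py"],
        )


def _blups_from_py(terms: Sequence[RandomTerm], theta: np.ndarray, Py: np.ndarray) -> dict:
    out: dict[str, pd.Series] = {}
    for th, t in zip(theta[: len(terms)], terms):
        u = th * (t.Z.T @ Py)
        if t.kernel is not None:
            u = t.kernel @ u
        idx = list(t.level_ids) if t.level_ids is not None else list(range(t.n_levels))
        out[t.name] = pd.Series(u, index=idx, name=t.name)
    return out


@dataclass
class BlupSolution:
    fixed_effects: pd.Series
    blups: dict
    loglik: float
    Py: np.ndarray


@dataclass
class MixedLMMResults:
    """REML estimates, AI-based standard errors, BLUE/BLUPs and diagnostics."""

    model: MixedLMM
    params: pd.Series
    bse: pd.Series
    fe_params: pd.Series
    fe_cov: pd.DataFrame
    loglike: float
    converged: bool
    n_iter: int
    trace: list
    floor: float
    _Py: np.ndarray = field(repr=False, default=None)

    @cached_property
    def blups(self) -> dict:
        """Random-effect predictions per term at the REML estimates."""
        return _blups_from_py(self.model.terms, self.params.to_numpy(), self._Py)

    @property
    def at_floor(self) -> pd.Series:
        return self.params <= self.floor * (1.0 + 1e-6)

    def fitted_fixed(self) -> np.ndarray:
        return self.model.X @ self.fe_params.to_numpy()

    def loglik_trace(self) -> np.ndarray:
        return np.array([t["loglik"] for t in self.trace])

    def summary(self) -> str:
        lines = [
            "Mixed linear model (AI-REML)",
            f"  observations: {self.model.n}   fixed levels: {self.model.p}",
            f"  converged: {self.converged}   iterations: {self.n_iter}"
            f"   REML logL: {self.loglike:.4f}",
            "",
            f"  {'component':<14}{'estimate':>14}{'SE':>14}{'at floor':>10}",
        ]
        for name in self.params.index:
            se = self.bse[name]
            se_s = f"{se:.4g}" if np.isfinite(se) else "--"
            lines.append(
                f"  {name:<14}{self.params[name]:>14.6g}{se_s:>14}"
                f"{'yes' if self.at_floor[name] else 'no':>10}"
            )
        lines.append("")
        lines.append(f"  {'fixed effect':<20}{'estimate':>14}{'SE':>14}")
        for name in self.fe_params.index:
            lines.append(
                f"  {name:<20}{self.fe_params[name]:>14.6g}"
                f"{np.sqrt(self.fe_cov.loc[name, name]):>14.4g}"
            )
        if self.model.dropped_fixed:
            lines.append(f"  dropped (rank deficiency): {', '.join(self.model.dropped_fixed)}")
        return "\n".join(lines)
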