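"""Multilevel (marginal) models with a diagonal residual covariance.

The triad design makes observations within a triad interdependent: if
one member holds rank 1, the other two ranks are constrained. The
models here follow the repeated-measures formulation used for such
designs: a marginal linear model ``y = X b + e`` whose residual
covariance is *diagonal*, with one variance per repeated-measure level
(member position, or member-by-time for three-level designs) and zero
covariances. Because the covariance is diagonal, the model is a
heteroscedastic regression whose weights are estimated jointly with the
fixed effects by restricted maximum likelihood (REML, the default, as
in the standard mixed-model software for such designs) or plain ML.
Standard errors carry a Kenward-Roger-type correction for the
estimated variances, and t-tests use Satterthwaite-type fractional
degrees of freedom.

Usage follows the Model/Results convention::

    model = DiagonalMLM.from_dataframe(df, outcome="lnAA",
                                       predictors=["competition", "time", "rank"],
                                       interactions=[("competition", "time"), ...],
                                       repeated="cell", groups="triad")
    res = model.fit()
    res.summary()
    res.simple_slopes("lnT", moderator="C")
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ModelSpec",
    "ConvergenceError",
    "DiagonalMLM",
    "DiagonalMLMResults",
    "fit_diagonal_mlm",
]


class ConvergenceError(RuntimeError):
    """Raised when variance estimation fails to converge; carries the
    iteration trace in ``.trace``."""

    def __init__(self, msg: str, trace: Optional[List[float]] = None):
        super().__init__(msg)
        self.trace = trace or []


@dataclass
class ModelSpec:
    """Declarative description of one model fit.

    ``interactions`` are tuples of predictor names; when ``center`` is
    on, products are formed from mean-centered columns. ``repeated``
    names the column whose values index the diagonal residual-variance
    levels; ``groups`` names the subject (triad) variable.
    """

    outcome: str
    predictors: List[str]
    interactions: List[Tuple[str, ...]] = field(default_factory=list)
    center: bool = True
    repeated: Optional[str] = None
    groups: Optional[str] = None
    method: str = "reml"  # "reml" | "ml"
    homoscedastic: bool = False


def _interaction_name(term: Sequence[str]) -> str:
    return ":".join(term)


class DiagonalMLM:
    """Marginal linear model with diagonal heteroscedastic residuals."""

    def __init__(self, endog: np.ndarray, exog: np.ndarray,
                 repeated_levels: Optional[np.ndarray] = None,
                 exog_names: Optional[Sequence[str]] = None,
                 groups: Optional[np.ndarray] = None,
                 method: str = "reml", homoscedastic: bool = False):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        n, p = self.exog.shape
        if self.endog.shape != (n,):
            raise ValueError("endog/exog length mismatch")
        if repeated_levels is None or homoscedastic:
            repeated_levels = np.zeros(n, dtype=int)
        self.level_labels, self.level_idx = np.unique(
            np.asarray(repeated_levels), return_inverse=True
        )
        self.groups = groups
        self.method = method.lower()
        if self.method not in ("ml", "reml"):
            raise ValueError("method must be 'ml' or 'reml'")
        self.homoscedastic = homoscedastic
        self.exog_names = list(exog_names) if exog_names is not None else [
            f"x{j}" for j in range(p)
        ]
        self._check_rank()
        # attached by from_dataframe for downstream use (simple slopes)
        self.frame: Optional[pd.DataFrame] = None
        self.centering_means: Dict[str, float] = {}

    # -- construction -------------------------------------------------

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome: str,
                       predictors: Sequence[str],
                       interactions: Sequence[Sequence[str]] = (),
                       repeated: Optional[str] = None,
                       groups: Optional[str] = None,
                       center: bool = True,
                       method: str = "reml",
                       homoscedastic: bool = False) -> "DiagonalMLM":
        """Build the design from a tidy frame.

        Rows with missing values in any used column are dropped
        (listwise deletion within the model). Predictor columns are
        mean-centered (on the analysis sample) before interaction
        products are formed when ``center`` is on.
        """
        used = [outcome, *predictors]
        if repeated:
            used.append(repeated)
        if groups:
            used.append(groups)
        for term in interactions:
            used.extend(term)
        used = list(dict.fromkeys(used))
        missing = [c for c in used if c not in data.columns]
        if missing:
            raise KeyError(f"columns not in data: {missing}")
        frame = data[used].dropna().copy()
        if frame.shape[0] < len(predictors) + 2:
            raise ValueError("too few complete cases to fit the model")

        means: Dict[str, float] = {}
        work = frame.copy()
        if center:
            for c in dict.fromkeys([*predictors, *(v for t in interactions for v in t)]):
                means[c] = float(work[c].mean())
                work[c] = work[c] - means[c]
        cols = [np.ones(work.shape[0])]
        names = ["Intercept"]
        for c in predictors:
            cols.append(work[c].to_numpy(dtype=float))
            names.append(c)
        for term in interactions:
            prod = np.ones(work.shape[0])
            for v in term:
                prod = prod * work[v].to_numpy(dtype=float)
            cols.append(prod)
            names.append(_interaction_name(term))
        X = np.column_stack(cols)
        model = cls(
            frame[outcome].to_numpy(dtype=float), X,
            repeated_levels=frame[repeated].to_numpy() if repeated else None,
            exog_names=names,
            groups=frame[groups].to_numpy() if groups else None,
            method=method, homoscedastic=homoscedastic,
        )
        model.frame = frame
        model.centering_means = means
        return model

    @classmethod
    def from_spec(cls, data: pd.DataFrame, spec: ModelSpec) -> "DiagonalMLM":
        return cls.from_dataframe(
            data, spec.outcome, spec.predictors, spec.interactions,
            repeated=spec.repeated, groups=spec.groups, center=spec.center,
            method=spec.method, homoscedastic=spec.homoscedastic,
        )

    # -- internals -----------------------------------------------------

    def _check_rank(self) -> None:
        from scipy.linalg import qr

        X = self.exog
        r = np.linalg.matrix_rank(X)
        if r < X.shape[1]:
            _, _, piv = qr(X, pivoting=True)  # pivots past rank are collinear
            bad = sorted(self.exog_names[j] for j in piv[r:])
            raise ValueError(f"singular design; collinear columns: {bad}")

    @property
    def n_levels(self) -> int:
        return 1 if self.homoscedastic else int(self.level_labels.size)

    def _gls(self, sigma2: np.ndarray):
        """Weighted LS for fixed variances; returns (beta, A, resid)
        with A = (X' Sigma^-1 X)^-1 = cov(beta)."""
        w = 1.0 / sigma2[self.level_idx]
        Xw = self.exog * w[:, None]
        XtWX = self.exog.T @ Xw
        XtWy = Xw.T @ self.endog
        A = np.linalg.inv(XtWX)
        beta = A @ XtWy
        resid = self.endog - self.exog @ beta
        return beta, A, resid

    def _loglike(self, sigma2: np.ndarray, reml: bool) -> float:
        beta, A, resid = self._gls(sigma2)
        v = sigma2[self.level_idx]
        ll = -0.5 * (np.log(2 * np.pi * v).sum() + (resid ** 2 / v).sum())
        if reml:
            sign, logdet = np.linalg.slogdet(self.exog.T @ (self.exog / v[:, None]))
            ll -= 0.5 * logdet
        return float(ll)

    # -- fitting -------------------------------------------------------

    def fit(self, maxiter: int = 500, tol: float = 1e-10) -> "DiagonalMLMResults":
        n, p = self.exog.shape
        K = self.n_levels
        idx = np.zeros(n, dtype=int) if self.homoscedastic else self.level_idx
        counts = np.bincount(idx, minlength=K).astype(float)
        if np.any(counts <= (p if self.method == "reml" else 0) / K):
            pass  # small levels are allowed; likelihood handles them
        reml = self.method == "reml"

        # closed form when homoscedastic
        if K == 1:
            beta, A0, resid = self._gls(np.array([1.0]))
            rss = float(resid @ resid)
            sigma2 = np.array([rss / (n - p) if reml else rss / n])
            trace: List[float] = [self._loglike(sigma2, reml)]
            converged = True
        else:
            sigma2 = np.ones(K)
            trace = []
            converged = False
            floor = 1e-10 * float(np.var(self.endog) + 1e-12)
            for _ in range(maxiter):
                beta, A, resid = self._gls(sigma2)
                new = np.empty(K)
                for k in range(K):
                    rk = resid[idx == k]
                    new[k] = max(rk @ rk / counts[k], floor)
                trace.append(self._loglike(new, reml=False))
                par_done = np.max(np.abs(new - sigma2) / (sigma2 + floor)) < tol
                ll_done = (len(trace) > 1
                           and abs(trace[-1] - trace[-2]) < 1e-10
                           * (1 + abs(trace[-1])))
                sigma2 = new
                if par_done or ll_done:
                    converged = True
                    break
            if not converged:
                raise ConvergenceError(
                    f"variance estimation did not converge in {maxiter} "
                    "iterations", trace)
            if reml:
                # REML estimating equations from the ML start:
                # sigma2_k = RSS_k / (n_k - sum of leverages in level k)
                converged = False
                for _ in range(maxiter):
                    beta, A, resid = self._gls(sigma2)
                    lev = np.einsum("ij,jk,ik->i", self.exog, A, self.exog)
                    lev = lev / sigma2[idx]
                    new = np.empty(K)
                    ok = True
                    for k in range(K):
                        m = idx == k
                        denom = counts[k] - lev[m].sum()
                        if denom <= 0:
                            ok = False
                            break
                        new[k] = max((resid[m] ** 2).sum() / denom, 1e-12)
                    if not ok:
                        break  # degenerate level: keep ML variances
                    trace.append(self._loglike(new, reml=True))
                    done = np.max(np.abs(new - sigma2) / (sigma2 + 1e-12)) < tol
                    ll_done = (len(trace) > 1
                               and abs(trace[-1] - trace[-2]) < 1e-12
                               * (1 + abs(trace[-1])))
                    sigma2 = new
                    if done or ll_done:
                        converged = True
                        break
                if not converged:
                    # fall back to direct maximization of the REML criterion
                    res = optimize.minimize(
                        lambda lv: -self._loglike(np.exp(lv), reml=True),
                        np.log(sigma2), method="Nelder-Mead",
                        options={"xatol": 1e-10, "fatol": 1e-10,
                                 "maxiter": 20000},
                    )
                    sigma2 = np.exp(res.x)
                    trace.append(-res.fun)
                    converged = True

        beta, A, resid = self._gls(sigma2)
        llf = self._loglike(sigma2, reml)
        return DiagonalMLMResults(self, beta, A, sigma2, idx, counts, llf,
                                  converged, trace)


class DiagonalMLMResults:
    """Estimates, uncertainties and tests from a :class:`DiagonalMLM` fit."""

    def __init__(self, model: DiagonalMLM, params: np.ndarray, cov_params: np.ndarray,
                 resid_var: np.ndarray, level_idx: np.ndarray, counts: np.ndarray,
                 llf: float, converged: bool, trace: List[float],
                 small_sample_correction: bool = True):
        self.model = model
        self._params = params
        self._cov_naive = cov_params
        self.resid_var = resid_var
        self._idx = level_idx
        self._counts = counts
        self.llf = llf
        self.converged = converged
        self.iteration_trace = trace
        # Kackar-Harville / Kenward-Roger-type adjustment: model-based
        # covariance treats the estimated residual variances as known;
        # inflate it for their sampling variability. Exact zero when the
        # weights cannot move the estimator (homoscedastic or saturated
        # designs).
        self._cov = (self._kenward_roger_cov() if small_sample_correction
                     else cov_params)

    # -- basic accessors ----------------------------------------------

    @property
    def params(self) -> pd.Series:
        return pd.Series(self._params, index=self.model.exog_names, name="B")

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self._cov)), index=self.model.exog_names,
                         name="SE")

    @property
    def bse_model(self) -> pd.Series:
        """Model-based SEs without the small-sample adjustment (what a
        plain GLS/FGLS fit reports)."""
        return pd.Series(np.sqrt(np.diag(self._cov_naive)),
                         index=self.model.exog_names, name="SE")

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    def cov_params(self) -> pd.DataFrame:
        return pd.DataFrame(self._cov, index=self.model.exog_names,
                            columns=self.model.exog_names)

    def _kenward_roger_cov(self) -> np.ndarray:
        """Adjusted covariance of the fixed effects.

        For a residual covariance linear in its parameters (here a
        diagonal with one variance per level), the Kenward-Roger
        adjusted covariance reduces to

            Phi_A = Phi + 2 Phi [ sum_jk V_jk (Q_jk - P_j Phi P_k) ] Phi

        with Phi the model-based covariance, V the covariance of the
        variance estimates, P_j = -X_j'X_j / s_j^4 and
        Q_jk = delta_jk X_j'X_j / s_j^6.
        """
        K = self.resid_var.size
        if K == 1:
            return self._cov_naive
        X = self.model.exog
        s2 = self.resid_var
        Phi = self._cov_naive
        V = self._vartheta()
        G = [X[self._idx == k].T @ X[self._idx == k] for k in range(K)]
        M = np.zeros_like(Phi)
        for j in range(K):
            for k in range(K):
                term = -(G[j] / s2[j] ** 2) @ Phi @ (G[k] / s2[k] ** 2)
                if j == k:
                    term = term + G[j] / s2[j] ** 3
                M += V[j, k] * term
        adj = Phi + 2.0 * Phi @ M @ Phi
        # guard: the adjustment must not produce a non-PSD matrix
        if np.any(np.diag(adj) <= 0):
            return Phi
        return 0.5 * (adj + adj.T)

    # -- Satterthwaite machinery --------------------------------------

    def _vartheta(self) -> np.ndarray:
        """Asymptotic covariance of the residual-variance estimates
        (inverse Fisher information; expected information under ML,
        REML information under REML)."""
        K = self.resid_var.size
        s2 = self.resid_var
        if self.model.method == "ml":
            info = np.diag(self._counts / (2 * s2 ** 2))
        else:
            X = self.model.exog
            w = 1.0 / s2[self._idx]
            A = self._cov_naive
            info = np.empty((K, K))
            for j in range(K):
                for k in range(j, K):
                    mj = self._idx == j
                    mk = self._idx == k
                    # P block (j,k): delta*W_j - W_j X_j A X_k' W_k
                    block = -(X[mj] / s2[j]) @ A @ (X[mk] / s2[k]).T
                    if j == k:
                        block[np.arange(mj.sum()), np.arange(mj.sum())] += 1.0 / s2[j]
                    info[j, k] = info[k, j] = 0.5 * float((block ** 2).sum())
        return np.linalg.inv(info)

    def contrast_df(self, c: np.ndarray) -> float:
        """Satterthwaite-type fractional df for the contrast c'beta."""
        c = np.asarray(c, dtype=float)
        g = float(c @ self._cov @ c)
        X = self.model.exog
        grad = np.empty(self.resid_var.size)
        Ac = self._cov_naive @ c
        for k in range(self.resid_var.size):
            Xk = X[self._idx == k]
            v = Xk @ Ac
            grad[k] = float(v @ v) / self.resid_var[k] ** 2
        var_g = float(grad @ self._vartheta() @ grad)
        if var_g <= 0:
            return float(self.model.endog.size - X.shape[1])
        return 2.0 * g * g / var_g

    @property
    def df(self) -> pd.Series:
        p = self._params.size
        vals = [self.contrast_df(np.eye(p)[j]) for j in range(p)]
        return pd.Series(vals, index=self.model.exog_names, name="df")

    @property
    def pvalues(self) -> pd.Series:
        t = self.tvalues
        df = self.df
        return pd.Series(2 * stats.t.sf(np.abs(t), df), index=t.index, name="p")

    # -- reporting ----------------------------------------------------

    def summary(self) -> pd.DataFrame:
        """Fixed-effect table: B, SE, t, fractional df, two-sided p."""
        return pd.DataFrame(
            {
                "B": self.params,
                "SE": self.bse,
                "t": self.tvalues,
                "df": self.df,
                "p": self.pvalues,
            }
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        head = (f"DiagonalMLM ({self.model.method.upper()}), "
                f"n={self.model.endog.size}, levels={self.resid_var.size}, "
                f"llf={self.llf:.3f}\n")
        return head + self.summary().round(4).to_string()

    # -- simple slopes -------------------------------------------------

    def simple_slopes(self, predictor: str, moderator: str,
                      moderator_sd: Optional[float] = None) -> pd.DataFrame:
        """Conditional slopes of ``predictor`` at moderator mean +/- 1 SD.

        The model must contain the ``predictor:moderator`` (or
        ``moderator:predictor``) interaction. With centered predictors
        the conditional slope at moderator value m (in centered units)
        is ``b_pred + b_inter * m`` with variance
        ``v_pp + m^2 v_ii + 2 m v_pi``; t and p use Satterthwaite df of
        the same contrast.
        """
        names = self.model.exog_names
        inter = None
        for cand in (f"{predictor}:{moderator}", f"{moderator}:{predictor}"):
            if cand in names:
                inter = cand
                break
        if inter is None:
            raise ValueError(
                f"model has no {predictor} x {moderator} interaction term")
        if predictor not in names:
            raise ValueError(f"no main effect for {predictor!r} in model")
        if moderator_sd is None:
            if self.model.frame is None:
                raise ValueError("moderator_sd required when the model was "
                                 "built without a dataframe")
            moderator_sd = float(self.model.frame[moderator].std(ddof=1))
        jp = names.index(predictor)
        ji = names.index(inter)
        rows = []
        for label, m in (("-1 SD", -moderator_sd), ("+1 SD", +moderator_sd)):
            c = np.zeros(len(names))
            c[jp] = 1.0
            c[ji] = m
            slope = float(c @ self._params)
            se = float(np.sqrt(c @ self._cov @ c))
            df = self.contrast_df(c)
            t = slope / se
            rows.append(
                {
                    "moderator": moderator,
                    "at": label,
                    "moderator_value": m,
                    "slope": slope,
                    "SE": se,
                    "t": t,
                    "df": df,
                    "p": float(2 * stats.t.sf(abs(t), df)),
                }
            )
        return pd.DataFrame(rows)


def fit_diagonal_mlm(data: pd.DataFrame, spec: ModelSpec,
                     **fit_kws) -> DiagonalMLMResults:
    """Functional wrapper: build a :class:`DiagonalMLM` from a tidy frame
    and fit it."""
    return DiagonalMLM.from_spec(data, spec).fit(**fit_kws)
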