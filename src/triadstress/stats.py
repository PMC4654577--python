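"""Descriptive and inferential statistics for the saliva panel and
session metrics.

Covers the analyte transforms (lnT, lnAA; cortisol left on its raw
scale), one-tailed paired t-tests, prior/post correlations, proportion
summaries of the stress ratios, and post-hoc power of the joint F-test
of a multiple regression via the noncentral F distribution with
Cohen's f-squared as the noncentrality basis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "transform_panel",
    "paired_t_one_tailed",
    "pearson_r",
    "PowerResult",
    "posthoc_power_f",
    "cohen_f2_label",
    "proportion_summary",
]

RAW_COLUMNS = ["T_prior", "T_post", "C_prior", "C_post", "AA_prior", "AA_post"]


def transform_panel(raw: pd.DataFrame) -> pd.DataFrame:
    """Derive the analysis columns from a raw saliva panel.

    Input columns: ``subject, triad, study`` plus prior/post testosterone
    (``T_prior``/``T_post``, pg/mL), cortisol (``C_*``, ug/dL) and
    alpha-amylase (``AA_*``, U/mL); missing assays are NaN. T and AA are
    log-transformed (their distributions are right-skewed); C is left
    untransformed. Adds prior-to-post changes (post minus prior) and the
    per-analyte mean level; a subject missing the post sample falls back
    to the prior level for the mean, flagged in ``mean_incomplete``.
    """
    bad = []
    for col in RAW_COLUMNS:
        if col in raw.columns:
            neg = raw.loc[raw[col].notna() & (raw[col] <= 0), "subject"]
            bad.extend((col, s) for s in neg)
    if bad:
        raise ValueError(f"nonpositive analyte values for: {bad}")
    panel = raw.copy()
    for pre in ("prior", "post"):
        panel[f"lnT_{pre}"] = np.log(panel[f"T_{pre}"])
        panel[f"lnAA_{pre}"] = np.log(panel[f"AA_{pre}"])
    for var in ("lnT", "C", "lnAA"):
        panel[f"{var}_change"] = panel[f"{var}_post"] - panel[f"{var}_prior"]
        panel[f"{var}_mean"] = panel[[f"{var}_prior", f"{var}_post"]].mean(
            axis=1, skipna=True
        )
    panel["mean_incomplete"] = (
        panel[[f"{v}_post" for v in ("lnT", "C", "lnAA")]].isna().any(axis=1)
        & panel[[f"{v}_prior" for v in ("lnT", "C", "lnAA")]].notna().any(axis=1)
    )
    return panel


def paired_t_one_tailed(x: Sequence[float], y: Sequence[float],
                        direction: str = "greater") -> Tuple[float, int, float]:
    """Classical paired t-test with a one-tailed p.

    ``direction="greater"`` tests mean(x - y) > 0; ``"less"`` the
    opposite. Pairs with a missing member are dropped. Returns
    ``(t, df, p)`` with df = n - 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    d = x[keep] - y[keep]
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 complete pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences")
    t = d.mean() / (sd / np.sqrt(n))
    if direction == "greater":
        p = float(sps.t.sf(t, n - 1))
    elif direction == "less":
        p = float(sps.t.cdf(t, n - 1))
    else:
        raise ValueError("direction must be 'greater' or 'less'")
    return float(t), n - 1, p


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation over pairwise-complete observations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# post-hoc power for the joint F-test of a multiple regression
# ---------------------------------------------------------------------------

def cohen_f2_label(f2: float) -> str:
    """Cohen's conventional effect-size labels for f-squared
    (0.02 small, 0.15 medium, 0.35 large)."""
    if f2 >= 0.35:
        return "large"
    if f2 >= 0.15:
        return "medium"
    if f2 >= 0.02:
        return "small"
    return "negligible"


@dataclass(frozen=True)
class PowerResult:
    r_squared: float
    n: int
    n_predictors: int
    alpha: float
    f2: float
    noncentrality: float
    df1: int
    df2: int
    power: float
    effect_label: str


def posthoc_power_f(r_squared: float, n: int, n_predictors: int,
                    alpha: float = 0.05,
                    lambda_convention: str = "n") -> PowerResult:
    """Post-hoc power of the joint F-test of a multiple regression.

    Effect size f^2 = R^2 / (1 - R^2); the noncentrality is
    ``lambda = f^2 * N`` by default (``lambda_convention="n"``) or
    ``f^2 * (df1 + df2 + 1)`` with ``"df"``. Power is the upper-tail
    mass of the noncentral F beyond the central critical value at
    ``alpha``.
    """
    if not 0 <= r_squared < 1:
        raise ValueError("r_squared must lie in [0, 1)")
    if n_predictors < 1:
        raise ValueError("need at least one predictor")
    if n <= n_predictors + 1:
        raise ValueError("need n > n_predictors + 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    f2 = r_squared / (1.0 - r_squared)
    df1 = int(n_predictors)
    df2 = int(n - n_predictors - 1)
    if lambda_convention == "n":
        lam = f2 * n
    elif lambda_convention == "df":
        lam = f2 * (df1 + df2 + 1)
    else:
        raise ValueError("lambda_convention must be 'n' or 'df'")
    crit = sps.f.ppf(1 - alpha, df1, df2)
    power = float(sps.ncf.sf(crit, df1, df2, lam)) if lam > 0 else alpha
    return PowerResult(r_squared, int(n), int(n_predictors), alpha, f2, lam,
                       df1, df2, power, cohen_f2_label(f2))


# ---------------------------------------------------------------------------
# proportion summaries of the stress ratios
# ---------------------------------------------------------------------------

def proportion_summary(metrics: pd.DataFrame,
                       study: Optional[pd.Series] = None) -> pd.DataFrame:
    """Percentages of subjects showing the stress signature.

    From a tidy metrics frame (one row per subject, columns as produced
    by :func:`triadstress.ppg.metrics_frame`): the share with a
    speaking/listening TBV ratio strictly < 1, with a speaking/listening
    pulse ratio strictly > 1, and with *both* a faster pulse and lower
    TBV during conversation than during the video. Missing ratios are
    excluded from each denominator. Returns one row per study plus a
    ``combined`` row, with percentages and counts.
    """
    df = metrics.copy()
    if study is not None:
        df["study"] = np.asarray(study)
    elif "study" not in df.columns:
        df["study"] = "all"

    def _one(sub: pd.DataFrame, label) -> dict:
        out = {"study": label, "n_subjects": int(sub.shape[0])}
        tbv = sub["tbv_speak_listen_ratio"].dropna()
        pulse = sub["bpm_speak_listen_ratio"].dropna()
        out["pct_tbv_speak_listen_lt_1"] = (
            100.0 * (tbv < 1).mean() if tbv.size else np.nan
        )
        out["pct_pulse_speak_listen_gt_1"] = (
            100.0 * (pulse > 1).mean() if pulse.size else np.nan
        )
        both = sub.dropna(subset=["tbv_conv_video_ratio", "bpm_conv_video_ratio"])
        hit = (both["tbv_conv_video_ratio"] < 1) & (both["bpm_conv_video_ratio"] > 1)
        out["pct_both_faster_pulse_lower_tbv"] = (
            100.0 * hit.mean() if both.shape[0] else np.nan
        )
        out["n_both_faster_pulse_lower_tbv"] = int(hit.sum())
        return out

    rows = [_one(g, lab) for lab, g in df.groupby("study")]
    rows.append(_one(df, "combined"))
    return pd.DataFrame(rows)
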