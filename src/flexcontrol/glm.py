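"""Trial-level behavioural analysis: exclusions, residualized GLM, normality.

The analysis pipeline mirrors standard conflict-task practice: error trials,
post-error trials, reaction-time outliers (>2.5 s.d. from the subject's grand
mean), post-outlier trials and burn-in trials are excluded; the model-derived
regressors (flexible learning rate, predicted conflict, congruency, and their
interactions) are standardized on the retained trials; and each regressor's
unique contribution to reaction speed is assessed by first residualizing it
against the others (Frisch–Waugh–Lovell), then testing the per-subject
coefficients against zero across subjects.

The conflict-by-congruency interaction enters as the standardized unsigned
control prediction error ``|o - f_hat|``.  Because ``|o - f| = o + f - 2*o*f``
its residual against the main effects is exactly ``-2`` times the residual of
the plain product, so inference is equivalent to the product regressor up to
sign; this orientation makes the coefficient directly readable as "slower
responses under larger prediction error".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EXCLUSION_PRIORITY",
    "DESIGN_COLUMNS",
    "GLMEffect",
    "apply_exclusions",
    "build_design",
    "residualized_effect",
    "group_ttest",
    "ks_normality",
]

# when several rules hit one trial, the first matching reason wins
EXCLUSION_PRIORITY = ["error", "post_error", "outlier", "post_outlier", "burn_in"]

DESIGN_COLUMNS = [
    "alpha", "conflict", "congruency",
    "alpha_x_conflict", "alpha_x_congruency", "cpe",
    "alpha_x_conflict_x_congruency", "const",
]


def apply_exclusions(trials: pd.DataFrame, sd_threshold: float = 2.5) -> pd.DataFrame:
    """Annotate a trial table with exclusion flags; returns a copy.

    Outlier status is judged against the subject's grand mean and s.d. of
    correct-response RTs (error trials carry no meaningful RT).  Post-error
    and post-outlier flags do not cross run boundaries.  Burn-in trials
    (block 1 of each run) are always excluded.
    """
    out = trials.copy().reset_index(drop=True)
    reason = pd.Series("none", index=out.index, dtype=object)

    for _, idx in out.groupby("subject_id", sort=False).groups.items():
        sub = out.loc[idx]
        correct = sub["correct"].astype(bool)
        rt = sub["rt_ms"].where(correct)
        mu, sd = rt.mean(), rt.std()  # over correct trials only
        error = ~correct
        outlier = correct & ((rt - mu).abs() > sd_threshold * sd) if sd > 0 else correct & False
        run = sub["run_index"]
        same_run = run.eq(run.shift(1))
        post_error = error.shift(1, fill_value=False) & same_run
        post_outlier = outlier.shift(1, fill_value=False) & same_run
        burn = sub["block_index"] == 1

        flags = {
            "error": error, "post_error": post_error, "outlier": outlier,
            "post_outlier": post_outlier, "burn_in": burn,
        }
        sub_reason = pd.Series("none", index=sub.index, dtype=object)
        for name in reversed(EXCLUSION_PRIORITY):  # apply lowest priority first
            sub_reason[flags[name]] = name
        reason.loc[idx] = sub_reason

    out["exclusion_reason"] = reason
    out["excluded"] = reason != "none"
    if out["excluded"].all():
        raise ValueError("all trials excluded")
    return out


def build_design(trace: pd.DataFrame, o_seq, mask) -> pd.DataFrame:
    """Seven model-derived regressors plus a constant, on retained trials.

    ``trace`` must align row-for-row with ``o_seq``; ``mask`` marks retained
    trials and is applied before standardization (excluded trials' model
    estimates are discarded, not re-estimated).  Main effects are z-scored;
    interactions are products of the standardized mains, except the
    conflict-by-congruency term which enters as the standardized unsigned
    prediction error ``|o - f_hat|`` (see module docstring).  The empirical
    correlation between the learning-rate and conflict columns is not removed,
    only reported by downstream residualization.
    """
    o = np.asarray(o_seq, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if len(trace) != o.size:
        raise ValueError("trace and congruency sequence differ in length")
    alpha = trace["alpha_hat"].to_numpy()[mask]
    f = trace["f_hat"].to_numpy()[mask]
    o_r = o[mask]
    cpe = np.abs(o_r - f)

    def z(x, label):
        s = x.std()
        if s == 0:
            raise ValueError(f"zero-variance design column: {label}")
        return (x - x.mean()) / s

    za, zf, zo = z(alpha, "alpha"), z(f, "conflict"), z(o_r, "congruency")
    X = pd.DataFrame(
        {
            "alpha": za,
            "conflict": zf,
            "congruency": zo,
            "alpha_x_conflict": za * zf,
            "alpha_x_congruency": za * zo,
            "cpe": z(cpe, "cpe"),
            "alpha_x_conflict_x_congruency": za * zf * zo,
            "const": 1.0,
        }
    )
    return X


def residualized_effect(rs, X: pd.DataFrame, test_label: str) -> float:
    """Coefficient of a regressor after residualizing it against the others.

    The test column is regressed on all remaining columns (constant
    included); the residual then enters the RS model alongside the other
    columns, and its coefficient is returned.  By the Frisch–Waugh–Lovell
    theorem this equals the test variable's coefficient in the full joint fit.
    """
    y = np.asarray(rs, dtype=float)
    if test_label not in X.columns:
        raise KeyError(test_label)
    others = X.drop(columns=[test_label]).to_numpy()
    x = X[test_label].to_numpy()
    coef, _, rank, _ = np.linalg.lstsq(others, x, rcond=None)
    if rank < others.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design")
    resid = x - others @ coef
    full = np.column_stack([resid, others])
    beta, _, rank, _ = np.linalg.lstsq(full, y, rcond=None)
    if rank < full.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design")
    return float(beta[0])


@dataclass
class GLMEffect:
    """Group-level one-sample t-test of per-subject coefficients."""

    label: str
    coefficients: np.ndarray
    mean: float
    t: float
    df: int
    p: float


def group_ttest(coefficients, label: str = "") -> GLMEffect:
    """Two-sided one-sample t-test of per-subject coefficients against zero."""
    c = np.asarray(coefficients, dtype=float)
    if c.size < 2:
        raise ValueError("need at least 2 subjects")
    if c.std(ddof=1) == 0:
        if c.mean() == 0:  # perfectly null sample: no evidence either way
            return GLMEffect(label=label, coefficients=c, mean=0.0, t=0.0,
                             df=c.size - 1, p=1.0)
        raise ValueError("zero variance across subjects with nonzero mean")
    res = stats.ttest_1samp(c, 0.0)
    return GLMEffect(
        label=label,
        coefficients=c,
        mean=float(c.mean()),
        t=float(res.statistic),
        df=c.size - 1,
        p=float(res.pvalue),
    )


def ks_normality(
    rs_by_condition: dict[str, np.ndarray],
    alpha: float = 0.05,
    min_n: int = 20,
) -> pd.DataFrame:
    """Kolmogorov–Smirnov normality screen per condition, BH-FDR corrected.

    Each condition's reaction speeds are tested against a Gaussian with the
    sample's own mean and s.d.; conditions with fewer than ``min_n``
    observations are skipped with a warning.  ``normal`` is True where the
    FDR-adjusted p exceeds ``alpha`` (the distribution is not significantly
    non-Gaussian; with estimated parameters this screen is conservative).
    """
    import warnings

    from statsmodels.stats.multitest import multipletests

    rows = []
    for label, values in rs_by_condition.items():
        v = np.asarray(values, dtype=float)
        v = v[np.isfinite(v)]
        if v.size < min_n:
            warnings.warn(f"condition {label!r}: only {v.size} observations; skipped")
            continue
        stat, p = stats.kstest(v, "norm", args=(v.mean(), v.std(ddof=1)))
        rows.append({"condition": label, "n": v.size, "ks_stat": stat, "p": p})
    result = pd.DataFrame(rows)
    if len(result):
        _, p_adj, _, _ = multipletests(result["p"], alpha=alpha, method="fdr_bh")
        result["p_fdr"] = p_adj
        result["normal"] = result["p_fdr"] > alpha
    return result
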