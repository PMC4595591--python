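"""BIC model evidence and random-effects group-level model selection.

Two per-subject evidence measures are supported: a reaction-speed BIC, with
-2 ln L approximated by n * ln(residual variance) of the model's RS
prediction, and a congruency BIC built from each trial's likelihood of the
observed congruency, 1 - |o - f|.  Group-level comparison follows the
random-effects Bayesian model selection approach of Stephan et al.: a
variational Dirichlet posterior over model frequencies in the population,
with exceedance probabilities (the belief that a given model is the most
frequent one) estimated by Monte-Carlo sampling from that posterior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma

__all__ = ["bic_rs", "bic_congruency", "BMSResult", "group_bms"]


def bic_rs(residuals, n_params: int = 0) -> float:
    """Reaction-speed BIC: ``n * ln(mean squared residual) + n_params * ln(n)``."""
    r = np.asarray(residuals, dtype=float)
    n = r.size
    if n < 2:
        raise ValueError("need at least 2 residuals")
    sigma2 = float(np.mean(r * r))
    if sigma2 < 1e-12:
        warnings.warn("zero residual variance; floored at 1e-12")
        sigma2 = 1e-12
    return n * np.log(sigma2) + n_params * np.log(n)


def bic_congruency(f_seq, o_seq, n_params: int = 0) -> float:
    """Congruency BIC from per-trial likelihoods ``1 - |o - f|`` (floored 1e-12)."""
    f = np.asarray(f_seq, dtype=float)
    o = np.asarray(o_seq, dtype=float)
    if f.shape != o.shape:
        raise ValueError("f and o sequences differ in length")
    lik = np.maximum(1.0 - np.abs(o - f), 1e-12)
    n = f.size
    return float(-2.0 * np.log(lik).sum() + n_params * np.log(n))


@dataclass
class BMSResult:
    """Posterior over model frequencies from random-effects model selection."""

    model_names: list[str]
    dirichlet_alpha: np.ndarray
    expected_frequencies: np.ndarray
    exceedance: np.ndarray
    mc_samples: int
    converged: bool
    n_iterations: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.model_names,
                "dirichlet_alpha": self.dirichlet_alpha,
                "expected_frequency": self.expected_frequencies,
                "exceedance_probability": self.exceedance,
            }
        )


def group_bms(
    evidence: pd.DataFrame | np.ndarray,
    mc_samples: int = 100_000,
    seed: int | np.random.Generator = 0,
    evidence_is_bic: bool = True,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> BMSResult:
    """Random-effects group model selection from per-subject evidence.

    ``evidence`` is subjects x models; BIC values by default, converted to log
    model evidence as -BIC/2.  A uniform Dirichlet(1, ..., 1) prior over model
    frequencies is updated variationally: subject responsibilities are
    softmaxed log evidences augmented by the digamma of the current Dirichlet
    counts, iterated until the counts change by less than ``tol``.  Exceedance
    probabilities are Monte-Carlo estimates of each model being the most
    frequent, from ``mc_samples`` Dirichlet draws.
    """
    if isinstance(evidence, pd.DataFrame):
        names = [str(c) for c in evidence.columns]
        lme = evidence.to_numpy(dtype=float)
    else:
        lme = np.asarray(evidence, dtype=float)
        names = [f"model_{i}" for i in range(lme.shape[1])]
    if lme.ndim != 2 or lme.shape[1] < 2:
        raise ValueError("evidence must be subjects x (>=2 models)")
    if not np.all(np.isfinite(lme)):
        raise ValueError("evidence contains non-finite entries")
    if evidence_is_bic:
        lme = -lme / 2.0
    lme = lme - lme.max(axis=1, keepdims=True)  # per-subject shift, softmax-invariant

    n_sub, n_mod = lme.shape
    alpha0 = np.ones(n_mod)
    alpha = alpha0.copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = lme + digamma(alpha) - digamma(alpha.sum())
        w = np.exp(w - w.max(axis=1, keepdims=True))
        u = w / w.sum(axis=1, keepdims=True)
        new_alpha = alpha0 + u.sum(axis=0)
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            converged = True
            break
        alpha = new_alpha
    if not converged:
        warnings.warn(
            f"group BMS did not converge in {max_iter} iterations; "
            f"last Dirichlet counts {alpha}"
        )

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=int(mc_samples))
    winners = np.argmax(draws, axis=1)
    exceedance = np.bincount(winners, minlength=n_mod) / draws.shape[0]
    return BMSResult(
        model_names=names,
        dirichlet_alpha=alpha,
        expected_frequencies=alpha / alpha.sum(),
        exceedance=exceedance,
        mc_samples=int(mc_samples),
        converged=converged,
        n_iterations=it,
    )
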