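"""Discrete-grid Bayesian filter over (flexible learning rate, predicted conflict).

The model tracks two latent quantities on a joint probability grid:

* ``alpha`` — the flexible learning rate, a belief about the volatility
  (rate of change) of control demand in the environment, in (0, 1);
* ``f`` — the predicted conflict level, the believed probability that the
  upcoming trial is incongruent, in (0, 1).

Per trial the filter (i) lets ``alpha`` either persist or jump uniformly to
any other value (stickiness ``k_stay``), (ii) propagates ``f`` through a
beta kernel whose width grows with ``alpha`` — believing the environment is
volatile widens the prediction — and (iii) conditions on the observed
congruency and, optionally, the observed reaction speed (RS = 1/RT), whose
congruency-specific Gaussian emission has a mean linear in ``f``.

The pre-stimulus posterior means of ``alpha`` and ``f`` behave like a
Rescorla–Wagner learner whose learning rate is itself learned, which is the
point of the model: a single agent that integrates over long horizons in
stable environments and over short horizons in volatile ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BeliefGrid",
    "Hyperparameters",
    "GridConfig",
    "init_grid",
    "make_propagation_kernel",
    "transition_alpha",
    "propagate_f",
    "update_congruency",
    "update_rs",
    "estimation_uncertainty",
    "filter_subject",
    "fit_hyperparameters_em",
]

_NORM_TOL = 1e-10


@dataclass
class Hyperparameters:
    """Emission and transition hyperparameters of the flexible control model.

    ``a_*`` and ``b_*`` give the congruency-specific linear mapping from
    predicted conflict to mean reaction speed, RS ~ N(a_c + b_c * f, sigma_c),
    in s^-1.  ``k_stay`` is the per-trial probability that the flexible
    learning rate keeps its value rather than jumping uniformly.
    """

    k_stay: float = 0.95
    a_con: float = 2.6
    b_con: float = -0.4
    sigma_con: float = 0.25
    a_inc: float = 2.0
    b_inc: float = 0.4
    sigma_inc: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 < self.k_stay < 1.0:
            raise ValueError(f"k_stay must be in (0,1), got {self.k_stay}")
        if self.sigma_con <= 0 or self.sigma_inc <= 0:
            raise ValueError("emission noise s.d. must be positive")

    def emission(self, o: int) -> tuple[float, float, float]:
        """Return ``(a, b, sigma)`` for congruency ``o`` (1 = incongruent)."""
        if o:
            return self.a_inc, self.b_inc, self.sigma_inc
        return self.a_con, self.b_con, self.sigma_con

    def jittered(self, rng: np.random.Generator, rel: float = 0.1) -> "Hyperparameters":
        """Multiplicatively jitter the emission parameters by U(1-rel, 1+rel)."""
        j = lambda x: float(x * rng.uniform(1 - rel, 1 + rel))
        return replace(
            self,
            a_con=j(self.a_con), b_con=j(self.b_con), sigma_con=j(self.sigma_con),
            a_inc=j(self.a_inc), b_inc=j(self.b_inc), sigma_inc=j(self.sigma_inc),
        )


def _midpoints(n: int) -> np.ndarray:
    return (np.arange(n) + 0.5) / n


@dataclass
class GridConfig:
    """Discretization and propagation settings for the belief grid.

    The beta-kernel parameter sum is ``s(alpha) = s_min + kernel_scale/alpha``,
    strictly decreasing in ``alpha`` so that higher believed volatility widens
    the conflict prediction.  ``kernel_param`` selects whether the kernel is
    centred on the previous conflict level by its mean (default) or its mode.
    """

    n_alpha: int = 50
    n_f: int = 50
    kernel_scale: float = 2.0
    s_min: float = 2.0
    kernel_param: str = "mean"  # or "mode"

    def __post_init__(self) -> None:
        if self.n_alpha < 10 or self.n_f < 10:
            raise ValueError("grid sizes must be >= 10")
        if self.kernel_param not in ("mean", "mode"):
            raise ValueError(f"unknown kernel_param {self.kernel_param!r}")
        if self.s_min + self.kernel_scale <= 2.0:
            # s(alpha) -> s_min + kernel_scale as alpha -> 1; the beta mode
            # is undefined at parameter sums <= 2.
            raise ValueError("s(alpha) must exceed 2 everywhere")

    def s_of_alpha(self, alpha: np.ndarray | float) -> np.ndarray | float:
        return self.s_min + self.kernel_scale / alpha


@dataclass
class BeliefGrid:
    """Joint probability mass over (alpha, f) nodes.

    ``mass[i, j]`` is the probability of ``alpha_nodes[i]`` and ``f_nodes[j]``;
    it sums to one to within 1e-10 after every operation.
    """

    alpha_nodes: np.ndarray
    f_nodes: np.ndarray
    mass: np.ndarray

    def copy(self) -> "BeliefGrid":
        return BeliefGrid(self.alpha_nodes, self.f_nodes, self.mass.copy())

    @property
    def alpha_marginal(self) -> np.ndarray:
        return self.mass.sum(axis=1)

    @property
    def f_marginal(self) -> np.ndarray:
        return self.mass.sum(axis=0)

    @property
    def alpha_mean(self) -> float:
        return float(self.alpha_marginal @ self.alpha_nodes)

    @property
    def f_mean(self) -> float:
        return float(self.f_marginal @ self.f_nodes)

    def check_normalized(self) -> None:
        total = self.mass.sum()
        if abs(total - 1.0) > _NORM_TOL:
            raise ValueError(f"belief mass {total} deviates from 1")


def init_grid(n_alpha: int = 50, n_f: int = 50) -> BeliefGrid:
    """Uniform prior belief on midpoint nodes of (0,1) x (0,1)."""
    if n_alpha <= 0 or n_f <= 0:
        raise ValueError("grid sizes must be positive")
    mass = np.full((n_alpha, n_f), 1.0 / (n_alpha * n_f))
    return BeliefGrid(_midpoints(n_alpha), _midpoints(n_f), mass)


def make_propagation_kernel(
    alpha_nodes: np.ndarray,
    f_nodes: np.ndarray,
    s_of_alpha: Callable[[np.ndarray], np.ndarray] | None = None,
    kernel_param: str = "mean",
) -> np.ndarray:
    """Row-stochastic beta kernels ``K[a, f_old, f_new]`` for every alpha node.

    For each alpha the conditional distribution of the new conflict level is a
    beta density centred on ``f_old`` (by mean or mode) with parameter sum
    ``s(alpha)``; rows are renormalized on the grid.  Higher alpha gives a
    smaller sum, hence a wider kernel.
    """
    from scipy import stats

    if s_of_alpha is None:
        s_of_alpha = GridConfig().s_of_alpha
    f = np.asarray(f_nodes)
    K = np.empty((len(alpha_nodes), len(f), len(f)))
    for i, alpha in enumerate(alpha_nodes):
        s = float(s_of_alpha(alpha))
        if s <= 2.0:
            raise ValueError(f"beta parameter sum s(alpha)={s} <= 2 at alpha={alpha}")
        if kernel_param == "mode":
            a = f * (s - 2.0) + 1.0
            b = (1.0 - f) * (s - 2.0) + 1.0
        else:
            a = f * s
            b = (1.0 - f) * s
        pdf = stats.beta.pdf(f[None, :], a[:, None], b[:, None])
        K[i] = pdf / pdf.sum(axis=1, keepdims=True)
    return K


def _renormalize(belief: BeliefGrid) -> BeliefGrid:
    total = belief.mass.sum()
    if total <= 0 or not np.isfinite(total):
        raise FloatingPointError("belief mass vanished or overflowed")
    belief.mass /= total
    return belief


def transition_alpha(belief: BeliefGrid, k_stay: float) -> BeliefGrid:
    """Sticky-or-uniform-jump transition of the learning-rate marginal.

    With probability ``k_stay`` the learning rate keeps its value; otherwise it
    jumps uniformly over all alpha nodes.  Applied per f-slice, so the
    f-marginal is unchanged.
    """
    if not 0.0 < k_stay < 1.0:
        raise ValueError(f"k_stay must be in (0,1), got {k_stay}")
    n_alpha = belief.mass.shape[0]
    mixed = k_stay * belief.mass + (1.0 - k_stay) * belief.mass.sum(axis=0, keepdims=True) / n_alpha
    return _renormalize(BeliefGrid(belief.alpha_nodes, belief.f_nodes, mixed))


def propagate_f(belief: BeliefGrid, kernel: np.ndarray | None = None,
                cfg: GridConfig | None = None) -> BeliefGrid:
    """Spread conflict-level beliefs through the alpha-dependent beta kernel."""
    if kernel is None:
        cfg = cfg or GridConfig(n_alpha=len(belief.alpha_nodes), n_f=len(belief.f_nodes))
        kernel = make_propagation_kernel(
            belief.alpha_nodes, belief.f_nodes, cfg.s_of_alpha, cfg.kernel_param
        )
    new = np.einsum("af,afg->ag", belief.mass, kernel)
    return _renormalize(BeliefGrid(belief.alpha_nodes, belief.f_nodes, new))


def update_congruency(belief: BeliefGrid, o: int) -> BeliefGrid:
    """Condition on observed congruency: likelihood ``f**o * (1-f)**(1-o)``."""
    like = belief.f_nodes if o else 1.0 - belief.f_nodes
    new = belief.mass * like[None, :]
    return _renormalize(BeliefGrid(belief.alpha_nodes, belief.f_nodes, new))


def update_rs(belief: BeliefGrid, rs: float, o: int, hyper: Hyperparameters) -> BeliefGrid:
    """Condition on observed reaction speed under the Gaussian emission.

    A missing RS (error / no-response trial, encoded as NaN or None) leaves
    the belief unchanged: only the congruency observation is available then.
    Computed in log space to survive extreme observations.
    """
    if rs is None or not np.isfinite(rs):
        return belief
    a, b, sigma = hyper.emission(int(o))
    z = (rs - (a + b * belief.f_nodes)) / sigma
    loglike = -0.5 * z * z
    like = np.exp(loglike - loglike.max())
    new = belief.mass * like[None, :]
    return _renormalize(BeliefGrid(belief.alpha_nodes, belief.f_nodes, new))


def estimation_uncertainty(belief: BeliefGrid) -> float:
    """Standard deviation of the predicted-conflict marginal."""
    p = belief.f_marginal
    mu = p @ belief.f_nodes
    var = p @ (belief.f_nodes - mu) ** 2
    return float(np.sqrt(max(var, 0.0)))


def _rs_predictive_loglik(belief: BeliefGrid, rs: float, o: int,
                          hyper: Hyperparameters) -> float:
    """log p(rs | belief, o): the one-step-ahead RS predictive density."""
    a, b, sigma = hyper.emission(int(o))
    z = (rs - (a + b * belief.f_nodes)) / sigma
    dens = np.exp(-0.5 * z * z) / (np.sqrt(2.0 * np.pi) * sigma)
    p = float(belief.f_marginal @ dens)
    return float(np.log(max(p, 1e-300)))


def filter_subject(
    o_seq: Sequence[int] | np.ndarray,
    rs_seq: Sequence[float] | np.ndarray | None,
    hyper: Hyperparameters,
    cfg: GridConfig | None = None,
    collect_loglik: bool = False,
):
    """Run the flexible control filter over a subject's full trial sequence.

    ``o_seq`` is the chronological binary congruency sequence concatenated
    across runs (all trials included; exclusions are applied only downstream).
    ``rs_seq`` gives reaction speeds in s^-1 with NaN for trials without a
    response; pass ``None`` for the congruency-only belief-update variant.

    Returns a :class:`pandas.DataFrame` trace with one row per trial holding
    the pre-stimulus posterior summaries ``alpha_hat``, ``f_hat``,
    ``est_uncertainty`` (s.d. of the conflict marginal) and the control
    prediction error ``cpe = |o - f_hat|``.  ``pc_x_cong`` is a convenience
    column with the within-trace standardized conflict-by-congruency product;
    the behavioural GLM rebuilds its regressors on retained trials only.

    With ``collect_loglik`` the one-step-ahead RS predictive log-likelihood is
    returned alongside the trace.
    """
    o_arr = np.asarray(o_seq, dtype=int)
    if o_arr.size == 0:
        raise ValueError("empty trial sequence")
    if rs_seq is None:
        rs_arr = np.full(o_arr.size, np.nan)
    else:
        rs_arr = np.asarray(rs_seq, dtype=float)
        if rs_arr.size != o_arr.size:
            raise ValueError("congruency and RS sequences differ in length")

    cfg = cfg or GridConfig()
    belief = init_grid(cfg.n_alpha, cfg.n_f)
    kernel = make_propagation_kernel(
        belief.alpha_nodes, belief.f_nodes, cfg.s_of_alpha, cfg.kernel_param
    )

    n = o_arr.size
    alpha_hat = np.empty(n)
    f_hat = np.empty(n)
    unc = np.empty(n)
    loglik = 0.0
    for i in range(n):
        belief = transition_alpha(belief, hyper.k_stay)
        belief = propagate_f(belief, kernel)
        alpha_hat[i] = belief.alpha_mean
        f_hat[i] = belief.f_mean
        unc[i] = estimation_uncertainty(belief)
        if collect_loglik and np.isfinite(rs_arr[i]):
            loglik += _rs_predictive_loglik(belief, rs_arr[i], o_arr[i], hyper)
        belief = update_congruency(belief, o_arr[i])
        belief = update_rs(belief, rs_arr[i], o_arr[i], hyper)

    cpe = np.abs(o_arr - f_hat)
    zf = (f_hat - f_hat.mean()) / f_hat.std() if f_hat.std() > 0 else np.zeros(n)
    zo = (o_arr - o_arr.mean()) / o_arr.std() if o_arr.std() > 0 else np.zeros(n)
    trace = pd.DataFrame(
        {
            "trial": np.arange(n),
            "congruency": o_arr,
            "alpha_hat": alpha_hat,
            "f_hat": f_hat,
            "est_uncertainty": unc,
            "cpe": cpe,
            "pc_x_cong": zf * zo,
        }
    )
    if collect_loglik:
        return trace, loglik
    return trace


def fit_hyperparameters_em(
    o_seq: Sequence[int] | np.ndarray,
    rs_seq: Sequence[float] | np.ndarray,
    cfg: GridConfig | None = None,
    init: Hyperparameters | None = None,
    tol: float = 1e-4,
    max_iter: int = 100,
    sigma_floor: float = 1e-3,
):
    """Fit the RS-emission hyperparameters by expectation-maximization.

    E-step: filter the sequence with the current hyperparameters to obtain the
    pre-stimulus conflict predictions ``f_hat``.  M-step: per congruency,
    ordinary least squares of RS on ``f_hat`` updates the intercept, slope and
    residual s.d.  Iterates until the largest absolute parameter change drops
    below ``tol``, the one-step-ahead RS predictive objective stops improving
    (forward filtering carries no exact ascent guarantee, so a stalled
    objective marks convergence and the previous parameters are kept), or
    ``max_iter`` is reached.  ``k_stay`` is not optimized.

    Returns ``(hyper, trace, objective)`` where ``objective`` lists the
    one-step-ahead RS predictive log-likelihood per accepted iteration; the
    trace is the E-step output of the returned parameters.
    """
    import warnings

    o_arr = np.asarray(o_seq, dtype=int)
    rs_arr = np.asarray(rs_seq, dtype=float)
    valid = np.isfinite(rs_arr)
    for o in (0, 1):
        if np.sum(valid & (o_arr == o)) < 2:
            raise ValueError("need >= 2 valid-RS trials per congruency")

    hyper = init or Hyperparameters()
    objective: list[float] = []
    best: tuple | None = None  # (hyper, trace)
    for _ in range(max_iter):
        trace, ll = filter_subject(o_arr, rs_arr, hyper, cfg, collect_loglik=True)
        if objective and ll < objective[-1]:
            hyper, trace = best  # ascent stalled: keep the previous parameters
            break
        objective.append(ll)
        best = (hyper, trace)
        f_hat = trace["f_hat"].to_numpy()
        new = {}
        for o, (a_k, b_k, s_k) in ((0, ("a_con", "b_con", "sigma_con")),
                                   (1, ("a_inc", "b_inc", "sigma_inc"))):
            sel = valid & (o_arr == o)
            x, y = f_hat[sel], rs_arr[sel]
            if y.std() < 1e-12 or x.std() < 1e-12:
                if y.std() < 1e-12:
                    warnings.warn("degenerate (constant) RS; slope set to 0")
                b = 0.0
                a = float(y.mean())
            else:
                b, a = np.polyfit(x, y, 1)
            resid = y - (a + b * x)
            new[a_k] = float(a)
            new[b_k] = float(b)
            new[s_k] = max(float(resid.std()), sigma_floor)
        delta = max(abs(new[k] - getattr(hyper, k)) for k in new)
        if delta < tol:
            break
        hyper = replace(hyper, **new)
    else:
        hyper, trace = best  # max_iter reached; keep the last evaluated params
    return hyper, trace, objective
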