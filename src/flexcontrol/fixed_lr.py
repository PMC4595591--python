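"""Fixed learning-rate Rescorla–Wagner comparator models.

Two comparators to the flexible control model: a delta-rule learner with a
single learning rate for the whole task, and one with two learning rates —
one applied on stable runs, one on volatile runs (run type known a priori).
The best rate(s) are found by exhaustive search over a grid (default 0.01 to
0.5 in steps of 0.001), minimizing either the reaction-speed BIC or the
congruency-prediction BIC; the congruency-specific RS emission (intercept and
slope on the conflict prediction) is profiled out by least squares exactly as
for the flexible model, so the BIC parameter count holds only the learning
rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .comparison import bic_congruency, bic_rs

__all__ = ["FixedLRFit", "default_lr_grid", "rw_trace", "search_lr", "profiled_rs_residuals"]


def default_lr_grid() -> np.ndarray:
    """The exhaustive-search grid: 0.01 to 0.5 inclusive, step 0.001 (491 values)."""
    return np.round(np.arange(10, 501) * 0.001, 3)


@dataclass
class FixedLRFit:
    """Result of an exhaustive fixed-LR search."""

    lrs: tuple[float, ...]  # (lr,) or (lr_stable, lr_volatile)
    objective: str  # "bic_rs" | "bic_cong"
    f_seq: np.ndarray  # pre-update conflict prediction per trial (full sequence)
    rs_residual_variance: float
    bic_rs: float
    bic_cong: float

    @property
    def n_params(self) -> int:
        return len(self.lrs)


def rw_trace(o_seq, lr: float | np.ndarray, f0: float = 0.5,
             lr_by_trial: np.ndarray | None = None) -> np.ndarray:
    """Delta-rule conflict predictions, pre-update per trial.

    ``f_1 = f0``; ``f_{i+1} = f_i + lr_i * (o_i - f_i)``.  A scalar ``lr``
    applies throughout; ``lr_by_trial`` overrides it per trial (used for the
    two-LR model where the rate depends on run type).
    """
    o = np.asarray(o_seq, dtype=float)
    if lr_by_trial is None:
        lr_by_trial = np.full(o.shape, float(lr))
        if not 0.0 < float(lr) < 1.0:
            raise ValueError(f"learning rate must be in (0,1), got {lr}")
    f = np.empty(o.shape)
    cur = float(f0)
    for i in range(o.size):
        f[i] = cur
        cur = cur + lr_by_trial[i] * (o[i] - cur)
    return f


def _profiled_rs_stats(f, rs, o, mask):
    """Per-congruency OLS of RS on f over masked trials; pooled residual SS.

    ``f`` may be (n,) or (n_candidates, n); returns mean squared residual
    with per-candidate vectorization.
    """
    f = np.atleast_2d(f)
    sse = np.zeros(f.shape[0])
    n_total = 0
    for c in (0, 1):
        sel = mask & (o == c) & np.isfinite(rs)
        y = rs[sel]
        x = f[:, sel]
        n = y.size
        n_total += n
        if n == 0:
            continue
        sx, sy = x.sum(axis=1), y.sum()
        sxx, sxy, syy = (x * x).sum(axis=1), x @ y, y @ y
        vx = sxx - sx * sx / n
        cxy = sxy - sx * sy / n
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = np.where(vx > 0, cxy / np.where(vx > 0, vx, 1.0), 0.0)
        sse += (syy - sy * sy / n) - slope * cxy
    return sse / n_total, n_total


def _cong_loglik(f, o, mask):
    """Sum of log(1 - |o - f|) over masked trials, floored at 1e-12."""
    f = np.atleast_2d(f)
    lik = 1.0 - np.abs(o[None, mask] - f[:, mask])
    return np.log(np.maximum(lik, 1e-12)).sum(axis=1)


def search_lr(
    o_seq,
    rs_seq,
    objective: str = "bic_rs",
    grid: np.ndarray | None = None,
    two_lr: bool = False,
    run_is_volatile: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    f0: float = 0.5,
) -> FixedLRFit:
    """Exhaustive learning-rate search minimizing the chosen BIC.

    ``mask`` restricts the BIC to the analysed (retained) trials while the
    delta-rule trace always runs over the full concatenated sequence.  For the
    two-LR model the product grid is scanned with the stable-run rate as the
    slow axis; ties resolve to the smallest rate(s).
    """
    if objective not in ("bic_rs", "bic_cong"):
        raise ValueError(f"unknown objective {objective!r}")
    o = np.asarray(o_seq, dtype=float)
    rs = np.full(o.shape, np.nan) if rs_seq is None else np.asarray(rs_seq, dtype=float)
    mask = np.ones(o.shape, bool) if mask is None else np.asarray(mask, bool)
    grid = default_lr_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty learning-rate grid")

    if two_lr:
        if run_is_volatile is None:
            raise ValueError("two-LR search needs per-trial run type")
        vol = np.asarray(run_is_volatile, bool)
        g = grid.size
        lr_s = np.repeat(grid, g)  # slow axis: stable rate
        lr_v = np.tile(grid, g)
        # iterate trials, vectorized over the candidate product grid
        f = np.full(g * g, f0)
        n_params = 2
        sse_parts = _OnlineProfiler(o, rs, mask)
        cong_ll = np.zeros(g * g)
        for i in range(o.size):
            if mask[i]:
                sse_parts.add(i, f)
                cong_ll += np.log(np.maximum(1.0 - np.abs(o[i] - f), 1e-12))
            lr_i = lr_v if vol[i] else lr_s
            f = f + lr_i * (o[i] - f)
        sigma2, n = sse_parts.mean_squared_residual()
        bic_rs_all = n * np.log(np.maximum(sigma2, 1e-12)) + n_params * np.log(n)
        bic_cong_all = -2.0 * cong_ll + n_params * np.log(n)
        scores = bic_rs_all if objective == "bic_rs" else bic_cong_all
        best = int(np.argmin(scores))  # lexicographic grid => smallest rates win ties
        lrs = (float(lr_s[best]), float(lr_v[best]))
        lr_by_trial = np.where(vol, lrs[1], lrs[0])
        f_best = rw_trace(o, lrs[0], f0, lr_by_trial=lr_by_trial)
    else:
        traces = np.empty((grid.size, o.size))
        for j, lr in enumerate(grid):
            traces[j] = rw_trace(o, lr, f0)
        n_params = 1
        sigma2, n = _profiled_rs_stats(traces, rs, o, mask)
        bic_rs_all = n * np.log(np.maximum(sigma2, 1e-12)) + n_params * np.log(n)
        bic_cong_all = -2.0 * _cong_loglik(traces, o, mask) + n_params * np.log(n)
        scores = bic_rs_all if objective == "bic_rs" else bic_cong_all
        best = int(np.argmin(scores))
        lrs = (float(grid[best]),)
        f_best = traces[best]

    resid_var, n = _profiled_rs_stats(f_best, rs, o, mask)
    return FixedLRFit(
        lrs=lrs,
        objective=objective,
        f_seq=f_best,
        rs_residual_variance=float(resid_var[0]),
        bic_rs=bic_rs(profiled_rs_residuals(f_best, rs, o, mask), n_params=n_params),
        bic_cong=bic_congruency(f_best[mask], o[mask], n_params=n_params),
    )


class _OnlineProfiler:
    """Accumulates per-congruency OLS sufficient statistics trial by trial,
    vectorized over LR candidates, so the two-LR product-grid search never
    materializes the full candidate-by-trial trace."""

    def __init__(self, o, rs, mask):
        self.o, self.rs = o, rs
        self._st = {
            c: {"n": 0, "sy": 0.0, "syy": 0.0, "sx": None, "sxx": None, "sxy": None}
            for c in (0, 1)
        }

    def add(self, i, f):
        if not np.isfinite(self.rs[i]):
            return
        st = self._st[int(self.o[i])]
        if st["sx"] is None:
            st["sx"], st["sxx"], st["sxy"] = (np.zeros_like(f) for _ in range(3))
        y = self.rs[i]
        st["n"] += 1
        st["sy"] += y
        st["syy"] += y * y
        st["sx"] += f
        st["sxx"] += f * f
        st["sxy"] += f * y

    def mean_squared_residual(self):
        sse = None
        n_total = 0
        for st in self._st.values():
            n = st["n"]
            if n == 0 or st["sx"] is None:
                continue
            n_total += n
            vx = st["sxx"] - st["sx"] * st["sx"] / n
            cxy = st["sxy"] - st["sx"] * st["sy"] / n
            slope = np.where(vx > 0, cxy / np.where(vx > 0, vx, 1.0), 0.0)
            part = (st["syy"] - st["sy"] * st["sy"] / n) - slope * cxy
            sse = part if sse is None else sse + part
        return sse / n_total, n_total


def profiled_rs_residuals(f, rs, o, mask):
    """Residuals of RS on f, per congruency OLS, over masked valid trials."""
    res = []
    for c in (0, 1):
        sel = mask & (o == c) & np.isfinite(rs)
        x, y = f[sel], rs[sel]
        if x.size == 0:
            continue
        if x.std() > 0:
            b, a = np.polyfit(x, y, 1)
        else:
            b, a = 0.0, y.mean()
        res.append(y - (a + b * x))
    return np.concatenate(res)
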