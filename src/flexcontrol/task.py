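"""Trial-sequence design and synthetic-subject behaviour for the
volatility-modulated conflict (face-word Stroop) task.

The task has eight runs of five blocks.  Every run opens with a 16-trial
burn-in block at 50% incongruent that resets conflict predictions to a common
baseline; the four following 20-trial blocks hold the incongruent proportion
either fixed at 20% or 80% (stable runs) or alternate it 20<->80 every block
(volatile runs).  Block composition uses exact counts — a 20-trial block at
80% contains exactly 16 incongruent trials, uniformly shuffled — so that the
overall incongruent incidence is exactly 0.5 within the stable-run set and
within the volatile-run set.

Simulated subjects respond with reaction speeds (RS = 1/RT, s^-1) drawn from
congruency-specific Gaussians whose means are linear in the model's
pre-stimulus conflict prediction, with errors and slow outliers injected at
configurable rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .beliefs import GridConfig, Hyperparameters, filter_subject

__all__ = [
    "RunDesign",
    "GeneratorParams",
    "TRIAL_COLUMNS",
    "make_block",
    "make_run",
    "default_run_designs",
    "make_experiment",
    "simulate_subject",
    "write_trials",
    "read_trials",
]

#: CSV schema for trial tables.  RT stored in milliseconds, RS in 1/seconds.
TRIAL_COLUMNS = [
    "subject_id", "run_index", "run_type", "block_index", "trial_index",
    "congruency", "correct", "rt_ms", "rs", "excluded", "exclusion_reason",
]

BURN_IN_TRIALS = 16
BLOCK_TRIALS = 20
N_BLOCKS = 5
RUN_TRIALS = BURN_IN_TRIALS + (N_BLOCKS - 1) * BLOCK_TRIALS  # 96


@dataclass
class RunDesign:
    """Block-level layout of one run."""

    run_type: str  # "stable" | "volatile"
    start_high: bool  # first post-burn-in block at 80% incongruent?
    block_props: list[float] = field(init=False)
    trials_per_block: list[int] = field(init=False)

    def __post_init__(self) -> None:
        if self.run_type not in ("stable", "volatile"):
            raise ValueError(f"unknown run_type {self.run_type!r}")
        hi, lo = 0.8, 0.2
        first = hi if self.start_high else lo
        if self.run_type == "stable":
            props = [first] * 4
        else:
            second = lo if self.start_high else hi
            props = [first, second, first, second]
        self.block_props = [0.5] + props
        self.trials_per_block = [BURN_IN_TRIALS] + [BLOCK_TRIALS] * 4


@dataclass
class GeneratorParams:
    """Behaviour-generator settings for one synthetic subject."""

    hyper: Hyperparameters = field(default_factory=Hyperparameters)
    error_rate: float = 0.058
    outlier_rate: float = 0.01
    outlier_scale: float = 3.0
    rs_floor: float = 0.1  # s^-1; keeps RT finite

    def __post_init__(self) -> None:
        for name in ("error_rate", "outlier_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.hyper.sigma_con <= 0 or self.hyper.sigma_inc <= 0:
            raise ValueError("emission noise s.d. must be positive")


def make_block(n_trials: int, p_incongruent: float, rng: np.random.Generator) -> np.ndarray:
    """Exact-count congruency sequence: ``round(n*p)`` incongruent trials, shuffled.

    The expected count must be an integer — the design fixes block
    composition exactly rather than sampling i.i.d.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    expected = n_trials * p_incongruent
    k = round(expected)
    if abs(expected - k) > 1e-9:
        raise ValueError(
            f"n_trials * p_incongruent = {expected} is not an integer; "
            "the block design uses exact congruency counts"
        )
    block = np.concatenate([np.ones(k, dtype=int), np.zeros(n_trials - k, dtype=int)])
    rng.shuffle(block)
    return block


def make_run(design: RunDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Generate one run's 96 congruencies with block labels (burn-in = block 1)."""
    frames = []
    for b, (n, p) in enumerate(zip(design.trials_per_block, design.block_props), start=1):
        frames.append(pd.DataFrame({
            "block_index": b,
            "congruency": make_block(n, p, rng),
        }))
    run = pd.concat(frames, ignore_index=True)
    run.insert(0, "run_type", design.run_type)
    run["trial_index"] = np.arange(1, len(run) + 1)
    return run


def default_run_designs() -> list[RunDesign]:
    """The counterbalanced set: 2 x stable-low/high, 2 x volatile starting low/high."""
    return [
        RunDesign("stable", start_high=False), RunDesign("stable", start_high=False),
        RunDesign("stable", start_high=True), RunDesign("stable", start_high=True),
        RunDesign("volatile", start_high=False), RunDesign("volatile", start_high=False),
        RunDesign("volatile", start_high=True), RunDesign("volatile", start_high=True),
    ]


def _validate_run_mix(designs: Sequence[RunDesign]) -> None:
    key = lambda d: (d.run_type, d.start_high)
    counts = {}
    for d in designs:
        counts[key(d)] = counts.get(key(d), 0) + 1
    want = {("stable", False): 2, ("stable", True): 2,
            ("volatile", False): 2, ("volatile", True): 2}
    if counts != want:
        raise ValueError(
            "run mix must contain 2 of each (stable/volatile x start-low/high); "
            f"got {counts}"
        )


def make_experiment(
    seed: int | np.random.Generator,
    order: Sequence[RunDesign] | None = None,
    subject_id: str = "sim01",
) -> pd.DataFrame:
    """Full 8-run, 768-trial congruency table for one subject.

    ``order`` must hold 4 stable runs (2 at 20%, 2 at 80%) and 4 volatile runs
    (2 of each start direction); the default counterbalanced set is shuffled
    by the seeded generator, mirroring the between-subject counterbalancing.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if order is None:
        designs = default_run_designs()
        perm = rng.permutation(len(designs))
        order = [designs[i] for i in perm]
    _validate_run_mix(order)
    frames = []
    for r, design in enumerate(order, start=1):
        run = make_run(design, rng)
        run.insert(0, "run_index", r)
        frames.append(run)
    table = pd.concat(frames, ignore_index=True)
    table.insert(0, "subject_id", subject_id)
    return table


def simulate_subject(
    trials: pd.DataFrame,
    params: GeneratorParams,
    rng: np.random.Generator,
    cfg: GridConfig | None = None,
) -> pd.DataFrame:
    """Simulate RS and accuracy for a congruency table.

    The latent conflict predictions come from the congruency-only belief
    filter (the generative belief-update model); per trial
    ``RS ~ N(a_c + b_c * f_hat, sigma_c)`` truncated at ``rs_floor``.  Errors
    are injected i.i.d. at ``error_rate`` (error trials carry no RT); a
    fraction ``outlier_rate`` of correct trials get their RT scaled by
    ``outlier_scale`` so the downstream >2.5 s.d. filter has work to do.
    """
    out = trials.copy().reset_index(drop=True)
    o = out["congruency"].to_numpy(dtype=int)
    trace = filter_subject(o, None, params.hyper, cfg)
    f_hat = trace["f_hat"].to_numpy()

    a = np.where(o == 1, params.hyper.a_inc, params.hyper.a_con)
    b = np.where(o == 1, params.hyper.b_inc, params.hyper.b_con)
    sigma = np.where(o == 1, params.hyper.sigma_inc, params.hyper.sigma_con)
    rs = rng.normal(a + b * f_hat, sigma)
    rs = np.maximum(rs, params.rs_floor)

    correct = rng.random(len(out)) >= params.error_rate
    outlier = correct & (rng.random(len(out)) < params.outlier_rate)
    rs[outlier] /= params.outlier_scale
    rs[~correct] = np.nan

    out["correct"] = correct
    out["rs"] = rs
    out["rt_ms"] = 1000.0 / rs
    out["excluded"] = False
    out["exclusion_reason"] = "none"
    return out[TRIAL_COLUMNS]


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False, columns=TRIAL_COLUMNS)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    return df
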