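"""End-to-end orchestration: simulate a cohort, fit all models, compare, test.

``reproduce`` runs the full synthetic study: 21 simulated subjects on the
counterbalanced 8-run design, per-subject jittered emission parameters, EM
fitting of the flexible control model, exhaustive fixed-LR comparator
searches under both evidence measures, random-effects group model selection,
the volatility and tracking signatures, and the residualized behavioural GLM.
Everything is driven by one ``RunConfig`` and one integer seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .beliefs import GridConfig, Hyperparameters, filter_subject, fit_hyperparameters_em
from .comparison import bic_congruency, bic_rs, group_bms
from .fixed_lr import profiled_rs_residuals, search_lr
from .glm import DESIGN_COLUMNS, apply_exclusions, build_design, group_ttest, ks_normality, residualized_effect
from .task import GeneratorParams, make_block, make_experiment, simulate_subject

__all__ = ["RunConfig", "simulate_cohort", "fit_subject", "tracking_check", "reproduce"]

logger = logging.getLogger("flexcontrol")

MODEL_NAMES = ["flexible", "one_lr", "two_lr"]


@dataclass
class RunConfig:
    """Serializable settings for a full reproduction run."""

    seed: int = 0
    n_subjects: int = 21
    # belief grid
    n_alpha: int = 50
    n_f: int = 50
    kernel_scale: float = 2.0
    s_min: float = 2.0
    kernel_param: str = "mean"
    k_stay: float = 0.95
    # generator
    error_rate: float = 0.058
    outlier_rate: float = 0.01
    outlier_scale: float = 3.0
    rs_floor: float = 0.1
    subject_jitter: float = 0.1
    emission: dict = field(default_factory=lambda: dict(
        a_con=2.6, b_con=-0.4, sigma_con=0.25,
        a_inc=2.0, b_inc=0.4, sigma_inc=0.25,
    ))
    # EM
    em_tol: float = 1e-4
    em_max_iter: int = 100
    # LR search
    lr_grid_start: float = 0.01
    lr_grid_stop: float = 0.5
    lr_grid_step: float = 0.001
    # group model selection
    mc_samples: int = 100_000

    def grid_config(self) -> GridConfig:
        return GridConfig(
            n_alpha=self.n_alpha, n_f=self.n_f, kernel_scale=self.kernel_scale,
            s_min=self.s_min, kernel_param=self.kernel_param,
        )

    def base_hyper(self) -> Hyperparameters:
        return Hyperparameters(k_stay=self.k_stay, **self.emission)

    def lr_grid(self) -> np.ndarray:
        n = int(round((self.lr_grid_stop - self.lr_grid_start) / self.lr_grid_step)) + 1
        return np.round(self.lr_grid_start + self.lr_grid_step * np.arange(n), 9)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.md5(blob).hexdigest()[:10]


def simulate_cohort(cfg: RunConfig):
    """Simulate the cohort; returns (trial table, per-subject true parameters)."""
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_subjects)
    frames, true_params = [], {}
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        sid = f"sub{i + 1:02d}"
        hyper = cfg.base_hyper().jittered(rng, cfg.subject_jitter)
        params = GeneratorParams(
            hyper=hyper, error_rate=cfg.error_rate, outlier_rate=cfg.outlier_rate,
            outlier_scale=cfg.outlier_scale, rs_floor=cfg.rs_floor,
        )
        trials = make_experiment(rng, subject_id=sid)
        frames.append(simulate_subject(trials, params, rng, cfg.grid_config()))
        true_params[sid] = hyper
    return pd.concat(frames, ignore_index=True), true_params


def fit_subject(trials: pd.DataFrame, cfg: RunConfig) -> dict:
    """Fit flexible + fixed-LR models to one subject's annotated trial table.

    Expects exclusion flags already set.  The models see the full concatenated
    sequence (all trials included); BICs are computed on the retained trials,
    with the congruency-specific RS emission profiled out identically for all
    three models, so the BIC parameter count holds only the learning rates
    (0, 1, 2).  The flexible model's conflict predictions for the comparison
    come from its congruency-driven belief core (zero free parameters); the
    RS-augmented filter supplies the trial-level trace used by the
    behavioural analyses.
    """
    o = trials["congruency"].to_numpy(dtype=int)
    rs = trials["rs"].to_numpy(dtype=float)
    retained = ~trials["excluded"].to_numpy(dtype=bool)
    volatile = trials["run_type"].eq("volatile").to_numpy()
    grid_cfg = cfg.grid_config()

    hyper, trace, objective = fit_hyperparameters_em(
        o, rs, grid_cfg, init=Hyperparameters(k_stay=cfg.k_stay),
        tol=cfg.em_tol, max_iter=cfg.em_max_iter,
    )
    core_trace = filter_subject(o, None, Hyperparameters(k_stay=cfg.k_stay), grid_cfg)
    f_flex = core_trace["f_hat"].to_numpy()
    bics_rs = {"flexible": bic_rs(profiled_rs_residuals(f_flex, rs, o, retained), 0)}
    bics_cong = {"flexible": bic_congruency(f_flex[retained], o[retained], 0)}

    lr_grid = cfg.lr_grid()
    fits = {}
    for name, two in (("one_lr", False), ("two_lr", True)):
        fits[name] = {}
        for objective_name in ("bic_rs", "bic_cong"):
            fit = search_lr(
                o, rs, objective=objective_name, grid=lr_grid, two_lr=two,
                run_is_volatile=volatile, mask=retained,
            )
            fits[name][objective_name] = fit
        bics_rs[name] = fits[name]["bic_rs"].bic_rs
        bics_cong[name] = fits[name]["bic_cong"].bic_cong

    return {
        "hyper": hyper,
        "trace": trace,
        "core_trace": core_trace,
        "em_objective": objective,
        "fixed_fits": fits,
        "bic_rs": bics_rs,
        "bic_cong": bics_cong,
    }


def tracking_check(cfg: RunConfig, seed: int, n_trials: int = 400,
                   p: float = 0.8, last: int = 100) -> float:
    """Mean conflict prediction over the last trials of a stationary stream.

    The stream is built from exact-count 20-trial blocks at proportion ``p``
    and filtered with congruency only, mirroring the generative belief model.
    """
    rng = np.random.default_rng(seed)
    blocks = [make_block(20, p, rng) for _ in range(n_trials // 20)]
    o = np.concatenate(blocks)
    trace = filter_subject(o, None, cfg.base_hyper(), cfg.grid_config())
    return float(trace["f_hat"].tail(last).mean())


def _volatility_stats(trials: pd.DataFrame, traces: dict[str, pd.DataFrame]) -> dict:
    """Run-type contrast of the flexible LR, post-burn-in, per subject."""
    diffs = []
    for sid, sub in trials.groupby("subject_id", sort=False):
        alpha = traces[sid]["alpha_hat"].to_numpy()
        post = (sub["block_index"] > 1).to_numpy()
        vol = sub["run_type"].eq("volatile").to_numpy()
        diffs.append(alpha[post & vol].mean() - alpha[post & ~vol].mean())
    diffs = np.asarray(diffs)
    effect = group_ttest(diffs, "alpha_volatile_minus_stable")
    return {
        "per_subject_diff": diffs,
        "fraction_positive": float(np.mean(diffs > 0)),
        "t": effect.t,
        "p": effect.p,
    }


def _switch_time_course(trials: pd.DataFrame, traces: dict[str, pd.DataFrame],
                        window: int = 5) -> dict:
    """Group-mean LR rise after proportion-congruency switches in volatile runs,
    and the decline from early to late within the post-switch blocks."""
    rises, declines = [], []
    for sid, sub in trials.groupby("subject_id", sort=False):
        alpha = traces[sid]["alpha_hat"].to_numpy()
        sub = sub.reset_index(drop=True)
        vol = sub["run_type"].eq("volatile")
        starts = sub.index[
            vol & (sub["block_index"] > 2)
            & (sub["block_index"] != sub["block_index"].shift(1))
        ]
        # rise: first post-switch trials vs the trials just before the switch;
        # decline: late block vs the immediate post-rise window
        r = [alpha[i:i + window].mean() - alpha[i - window:i].mean() for i in starts]
        d = [alpha[i + 15:i + 20].mean() - alpha[i + window:i + 2 * window].mean() for i in starts]
        rises.append(np.mean(r))
        declines.append(np.mean(d))
    return {
        "mean_rise": float(np.mean(rises)),
        "mean_decline": float(np.mean(declines)),
        "per_subject_rise": np.asarray(rises),
    }


def _group_glm(trials: pd.DataFrame, traces: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Residualized trial-level GLM per subject; group t-tests per regressor."""
    labels = [c for c in DESIGN_COLUMNS if c != "const"]
    coefs = {lab: [] for lab in labels}
    for sid, sub in trials.groupby("subject_id", sort=False):
        retained = ~sub["excluded"].to_numpy(dtype=bool)
        o = sub["congruency"].to_numpy(dtype=int)
        X = build_design(traces[sid], o, retained)
        rs = sub["rs"].to_numpy(dtype=float)[retained]
        for lab in labels:
            coefs[lab].append(residualized_effect(rs, X, lab))
    rows = []
    for lab in labels:
        eff = group_ttest(coefs[lab], lab)
        rows.append({"variable": lab, "mean_beta": eff.mean, "t": eff.t,
                     "df": eff.df, "p": eff.p})
    return pd.DataFrame(rows)


def reproduce(cfg: RunConfig | None = None, out_dir=None) -> dict:
    """Run the complete synthetic study and collect its headline quantities.

    Returns a report dict with the group model-selection results under both
    evidence measures, the volatility and tracking signatures, the group GLM
    table, and per-subject bookkeeping.  With ``out_dir`` the report, config
    and BIC tables are also written, file names carrying the config hash and
    seed.
    """
    cfg = cfg or RunConfig()
    logger.info("simulating cohort: %d subjects, seed %d", cfg.n_subjects, cfg.seed)
    trials, true_params = simulate_cohort(cfg)
    trials = apply_exclusions(trials)

    traces, core_traces, bic_rows = {}, {}, []
    for sid, sub in trials.groupby("subject_id", sort=False):
        logger.info("fitting %s", sid)
        fit = fit_subject(sub.reset_index(drop=True), cfg)
        traces[sid] = fit["trace"]
        core_traces[sid] = fit["core_trace"]
        bic_rows.append({
            "subject_id": sid,
            **{f"rs_{m}": fit["bic_rs"][m] for m in MODEL_NAMES},
            **{f"cong_{m}": fit["bic_cong"][m] for m in MODEL_NAMES},
        })
    bic_table = pd.DataFrame(bic_rows).set_index("subject_id")

    bms_rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0xB35)))
    bms = {}
    for objective, prefix in (("rs", "rs_"), ("congruency", "cong_")):
        ev = bic_table[[prefix + m for m in MODEL_NAMES]].copy()
        ev.columns = MODEL_NAMES
        bms[objective] = group_bms(ev, mc_samples=cfg.mc_samples, seed=bms_rng)

    report = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_subjects": cfg.n_subjects,
        "accuracy": float(trials["correct"].mean()),
        "bic_table": bic_table,
        "bms": bms,
        "exceedance": {
            obj: dict(zip(MODEL_NAMES, bms[obj].exceedance)) for obj in bms
        },
        "volatility": _volatility_stats(trials, traces),
        "volatility_core": _volatility_stats(trials, core_traces),
        "switch": _switch_time_course(trials, traces),
        "tracking_f_mean": tracking_check(cfg, seed=cfg.seed + 1),
        "glm": _group_glm(trials, traces),
        "marginal_congruency": _marginal_congruency(trials),
        "ks": _cohort_ks(trials),
    }
    if out_dir is not None:
        _write_report(report, cfg, Path(out_dir))
    return report


def _marginal_congruency(trials: pd.DataFrame) -> dict:
    """Per-subject mean RS difference (incongruent - congruent), retained trials.

    Negative values mean slower responding under conflict (the Stroop effect
    on speed, Fig-2e style)."""
    ret = trials[~trials["excluded"]]
    diffs = []
    for _, sub in ret.groupby("subject_id", sort=False):
        by = sub.groupby("congruency")["rs"].mean()
        diffs.append(by.get(1, np.nan) - by.get(0, np.nan))
    eff = group_ttest(diffs, "rs_incongruent_minus_congruent")
    return {"per_subject_diff": np.asarray(diffs), "mean": eff.mean,
            "t": eff.t, "p": eff.p}


def _cohort_ks(trials: pd.DataFrame) -> dict:
    """KS normality screen of retained RS per subject x congruency."""
    groups = {
        f"{sid}_{'inc' if o else 'con'}": g["rs"].to_numpy()
        for (sid, o), g in trials[~trials["excluded"]].groupby(
            ["subject_id", "congruency"], sort=False)
    }
    table = ks_normality(groups)
    return {
        "fraction_normal": float(table["normal"].mean()) if len(table) else np.nan,
        "table": table,
    }


def _write_report(report: dict, cfg: RunConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    tag = f"{report['config_hash']}_seed{cfg.seed}"
    cfg.to_yaml(out_dir / f"config_{tag}.yaml")
    report["bic_table"].to_csv(out_dir / f"bic_{tag}.csv")
    report["glm"].to_csv(out_dir / f"glm_{tag}.csv", index=False)
    plain = {
        "config_hash": report["config_hash"],
        "seed": report["seed"],
        "accuracy": report["accuracy"],
        "exceedance": report["exceedance"],
        "volatility_fraction_positive": report["volatility"]["fraction_positive"],
        "volatility_t": report["volatility"]["t"],
        "volatility_p": report["volatility"]["p"],
        "volatility_core_fraction_positive": report["volatility_core"]["fraction_positive"],
        "switch_mean_rise": report["switch"]["mean_rise"],
        "switch_mean_decline": report["switch"]["mean_decline"],
        "tracking_f_mean": report["tracking_f_mean"],
        "ks_fraction_normal": report["ks"]["fraction_normal"],
    }
    (out_dir / f"report_{tag}.json").write_text(json.dumps(plain, indent=2))
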