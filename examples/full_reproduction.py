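"""The complete synthetic study: 21 subjects, all models, all signatures.

Runs generation -> EM fitting -> exhaustive fixed-LR searches -> BIC ->
random-effects group model selection -> volatility/tracking signatures ->
behavioural GLM, and prints the headline quantities.  Takes a couple of
minutes on one CPU; outputs (config, BIC table, GLM table, report JSON) are
written to ./reproduction_output, file names carrying the config hash and
seed.
"""

from flexcontrol.pipeline import RunConfig, reproduce

cfg = RunConfig(seed=1)
report = reproduce(cfg, out_dir="reproduction_output")

print(f"cohort: {report['n_subjects']} subjects, accuracy {report['accuracy']:.3f}")
for obj in ("rs", "congruency"):
    exc = report["exceedance"][obj]["flexible"]
    print(f"flexible-model exceedance ({obj} evidence): {exc:.3f}")
v = report["volatility_core"]
print(f"LR volatile > stable: {v['fraction_positive']:.0%} of subjects "
      f"(paired t = {v['t']:.1f}, p = {v['p']:.2g})")
print(f"LR rise within 5 trials of a switch: {report['switch']['mean_rise']:+.4f}; "
      f"late-block decline: {report['switch']['mean_decline']:+.4f}")
print(f"stationary tracking of p=0.8: mean predicted conflict "
      f"{report['tracking_f_mean']:.3f} over the last 100 trials")
glm = report["glm"].set_index("variable")
for var in ("congruency", "cpe"):
    row = glm.loc[var]
    print(f"GLM {var}: beta {row['mean_beta']:+.3f}, t({row['df']:.0f}) = "
          f"{row['t']:.2f}, p = {row['p']:.2g}")
print(f"KS normality: {report['ks']['fraction_normal']:.0%} of cells Gaussian")
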