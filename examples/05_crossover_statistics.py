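"""Fit the daily crossover mixed model and the repeated-measures model.

Model 1 (per cow x period daily means): treatment + period fixed, cow
random.  Model 2 (within-day series): treatment x time + period fixed,
cow and sampling day random, AR(1) residual correlation along each
cow x period x day trace; N2O proportions are analysed on the log scale.
"""

import rumengas as rg

study = rg.generate_study(rg.GeneratorParams(seed=42))

# -- daily crossover model --------------------------------------------------
fit = rg.fit_crossover(study["summaries"], "ch4_g_d")
print(f"daily CH4: urea {fit.lsmeans['urea']:.0f} vs nitrate "
      f"{fit.lsmeans['nitrate']:.0f} g/d "
      f"(effect {fit.treatment_effect:+.1f} +/- {fit.se:.1f}, "
      f"t({fit.dfs}) = {fit.t_stat:.2f}, P = {fit.p_treatment:.3f} -> "
      f"{rg.significance_label(fit.p_treatment)})")
print(f"variance components: cow {fit.variance_components['cow']:.0f}, "
      f"residual {fit.variance_components['residual']:.0f} (g/d)^2\n")

# -- repeated-measures model on the hourly chamber trace --------------------
trt = study["summaries"][["cow_id", "period", "treatment"]]
hourly = (study["chamber"].merge(trt, on=["cow_id", "period"])
          .rename(columns={"hour_rel_feeding": "time"}))
rfit = rg.fit_ar1_repeated(hourly, rg.RepeatedModelSpec("ch4"))
print(f"hourly CH4: rho_hat = {rfit.rho_hat:.2f}; "
      f"P(Trt) = {rfit.f_tests['treatment']['p']:.4f}, "
      f"P(Time) = {rfit.f_tests['time']['p']:.4f}, "
      f"P(Trt x Time) = {rfit.f_tests['treatment_x_time']['p']:.4f}")
print("The interaction reflects the flattened post-feeding peak under nitrate.\n")

# -- log-scale analysis of headspace N2O ------------------------------------
corrected = (rg.correct_air_contamination(study["headspace"])
             .merge(trt, on=["cow_id", "period"])
             .rename(columns={"time_rel_feeding": "time"}))
nfit = rg.fit_ar1_repeated(corrected, rg.RepeatedModelSpec("n2o", transform="log"))
u, n = nfit.treatment_lsmeans["urea"], nfit.treatment_lsmeans["nitrate"]
print(f"headspace N2O (back-transformed LSMEANS): urea {u[0]:.4f} vs nitrate "
      f"{n[0]:.4f} vol% (P = {nfit.f_tests['treatment']['p']:.2g})")
print("Back-transformed means are geometric means: the right summary for the")
print("right-skewed N2O proportions.")
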