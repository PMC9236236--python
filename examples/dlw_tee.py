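"""Doubly-labeled-water walk-through: simulate a trial, refit it, print the chain.

Generates an isotope washout series for a female-like animal (total body
water 5.856 kg, food quotient 0.93, true TEE ~288 kcal/day, 20.9 g dose,
blood samples at ~6.5 h and 7 d) with 1% enrichment noise, then runs the
full analysis chain: log-linear washout fits -> dilution spaces -> total
body water -> CO2 production -> Weir conversion to kcal/day.
"""

from zooenergetics import dlw
from zooenergetics.simulate import DlwScenario, simulate_dlw

scenario = DlwScenario(noise_cv=0.01, seed=42)
samples, truth = simulate_dlw(scenario)

fits = {}
for isotope in ("deuterium", "oxygen18"):
    sub = samples[samples["isotope"] == isotope]
    background = float(sub.loc[sub["is_background"], "enrichment_ppm"].iloc[0])
    post = sub[~sub["is_background"]]
    fits[isotope] = dlw.fit_isotope_kinetics(
        post["time_since_dose_d"], post["enrichment_ppm"],
        background=background, isotope=isotope,
    )
    print(f"{isotope:9s}  k = {fits[isotope].k:.4f} /d   "
          f"zero-time excess = {fits[isotope].intercept_excess:.1f} ppm")

spaces, comp, energy = dlw.tee_from_fits(
    scenario.dose, fits["deuterium"], fits["oxygen18"],
    fq=scenario.fq, body_mass=scenario.body_mass,
)

print(f"\ndilution spaces: N_D = {spaces.N_D:.1f} mol, N_O = {spaces.N_O:.1f} mol "
      f"(ratio {spaces.ratio:.3f}), pooled N = {spaces.N_pooled:.1f} mol")
print(f"total body water = {comp.TBW:.2f} kg -> fat-free mass {comp.FFM:.1f} kg, "
      f"body fat {comp.pct_fat:.1f}%")
print(f"rCO2 = {energy.rco2:.3f} mol/day; TEE = {energy.tee_kcal:.0f} kcal/day "
      f"({energy.tee_kj:.0f} kJ/day, {energy.tee_per_mbw:.0f} kcal/day/kg^0.75)")
print(f"true TEE was {truth['TEE_kcal']:.0f} kcal/day; "
      f"error {100 * abs(energy.tee_kcal - truth['TEE_kcal']) / truth['TEE_kcal']:.1f}%")
print("\nAt zero noise the chain inverts exactly.  With 1% enrichment noise, "
      "expect ~10-15% TEE error for this animal: its unusually low metabolism "
      "makes the isotope rate gap (1.007 k_O - 1.043 k_D) small, so TEE "
      "inherits the measurement noise amplified — see docs/methods.md.")
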