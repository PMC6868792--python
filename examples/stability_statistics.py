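"""Temporal- and postural-stability statistics on synthetic session tables.

Synthesizes a per-trial metrics table with known coefficients, fits the
stability regression (intercept + controller + controller-specific week
slopes), lets a nested-model ANOVA decide on the interaction, and runs a
Kruskal-Wallis test across simulated arm-posture conditions.
"""

import numpy as np

import myoknn as mk

truth = (66.9, -21.8, 3.4, 0.6)
table = mk.simulate_stability_table(coeffs=truth, noise_sd=15.0,
                                    n_per_cell=40, seed=0)
res = mk.fit_stability_regression(table, response="path_efficiency")
print("path-efficiency stability regression "
      "(y = b0 + b1*knn + b2*week*intact + b3*week*knn):")
for name, est, se, p, t in zip(res.names, res.estimates, res.std_errors,
                               res.p_values, truth):
    print(f"  {name:9s} = {est:7.2f} (SE {se:.2f}, p = {p:.3g}; truth {t})")
print(f"  R^2 = {res.r_squared:.3f}")

anova = mk.compare_models_anova(table, response="path_efficiency")
print(f"interaction ANOVA: F = {anova['F']:.1f}, p = {anova['p']:.3g} "
      f"-> {anova['selected']} model retained")

rng = np.random.default_rng(0)
postures = [rng.normal(5.0, 1.5, 16) for _ in range(6)]  # 6 arm postures
H, p = mk.kruskal_wallis(postures)
print(f"Kruskal-Wallis across 6 simulated arm postures: H = {H:.2f}, "
      f"p = {p:.2f}")
print("-> every estimate sits within ~2 SE of its generating value, and "
      "identical posture distributions are (correctly) not flagged")
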