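"""Compare copy number between sexual and asexual lineages.

Quantifies a simulated cohort, then runs the comparison battery: the Pearson
correlation matrix across unit genes (the evidence that the unit moves as a
whole), Mann-Whitney U and Kruskal-Wallis rank tests with Benjamini-Hochberg
adjustment, and the phylogenetic Poisson GEE that asks whether asexuality
predicts copy number once shared ancestry is priced in.
"""

from tandemcn import SimulationConfig, fit_mode_gee, simulate_all
from tandemcn.pipeline import quantify
from tandemcn.simulate import SHARED_UNIT_GENES
from tandemcn.stats import compare_modes, pearson_matrix

sim = simulate_all(SimulationConfig(seed=42))
table, _, _ = quantify(sim)

r, _ = pearson_matrix(table.values[list(SHARED_UNIT_GENES)])
print("pairwise Pearson r across 45S + histone genes "
      f"(min {r.to_numpy().min():.3f}):")
print(r.round(2).to_string())

print("\nrank tests (BH-adjusted within the KW family):")
print(compare_modes(table.values, sim.metadata).round(6).to_string(index=False))

fit = fit_mode_gee(table.values, sim.metadata, sim.tree, gene="5.8S")
print("\nphylogenetic Poisson GEE, 5.8S copy number ~ reproductive mode:")
print(fit.summary().round(4).to_string())
print(f"dispersion {fit.dispersion:.2f}, converged in {fit.n_iter} iterations")
# exp(asexual coefficient) is the estimated fold-increase in asexuals.  Its
# Wald p is much larger than the rank tests' because the phylogenetic model
# prices in shared ancestry: this cohort plants copy numbers independently of
# the tree, so closely related lineages disagree far more than the working
# correlation expects and the fit charges that to dispersion.  On cohorts
# whose copy numbers actually evolve along the tree the same fitter is well
# calibrated (type-I ~5% under the null) and detects a 10x effect with high
# power -- see the calibration tests.
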