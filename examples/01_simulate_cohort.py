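"""Simulate a snail-like cohort and look at what the generator planted.

Builds the default 26-lineage cohort (10 sexual diploids, 11 triploid and
5 tetraploid asexuals), each lineage carrying a planted per-haploid copy
number of the 13 kb tandem rDNA-histone unit, then prints the truth table
and writes all pipeline input files to disk.
"""

from tandemcn import SimulationConfig, simulate_all
from tandemcn.simulate import write_cohort

config = SimulationConfig(seed=42)
sim = simulate_all(config)

print(sim.truth.to_string(index=False))
print()
print(f"unit length: {sim.reference.unit_length} bp, "
      f"{sim.reference.n_units} tandem copies on the repeat scaffold")
print(f"candidate single-copy exons: {len(sim.reference.candidate_exons)} "
      f"(of which {int((sim.reference.candidate_exons['copy_factor'] > 1).sum())} "
      "planted high-copy decoys)")

paths = write_cohort(sim, "scratch/example_cohort")
print(f"\nwrote {len(paths)} inputs under scratch/example_cohort/")
# The truth table is the oracle: 'copy_number' is what the estimator must
# recover, 'expected_proportion' what the read-fraction estimator must match.
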