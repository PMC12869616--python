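"""Generate a study-shaped synthetic RPPA dataset with known truth.

Seven treatment arms (untreated, vehicle, insulin, two amyloid-beta
isoforms alone and with insulin) x 3 replicates across four runs, with
probe scenarios (attenuated / reversed / saturated insulin responses,
invariant anchors, batch-sensitive probes) recorded in a truth table.
"""

import rppashift as rs

config = rs.SimulationConfig()  # study-shaped defaults: 268 probes, 21 samples
matrix, samples, annot, truth = rs.generate_dataset(config, seed=1)

print(f"expression matrix: {matrix.shape[0]} probes x {matrix.shape[1]} samples")
print(f"phospho probes: {int(annot.data['is_phospho'].sum())}")
print("samples per (group, batch):")
print(samples.data.groupby(['batch', 'group'], observed=True).size().to_string())
print("\nscenario mix (truth the pipeline should recover):")
print(truth['scenario'].value_counts().to_string())
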