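"""Two-population phantom study: malignant vs neuron-like nuclear shape.

Generates the default two-group population (larger, rounder, less dense
nuclei in the "Mock" malignant-like group; smaller, more elongated,
denser nuclei in the "S1.1" neuron-like group; n = 20 per group),
measures every nucleus, and tests each contrast with Student's t-test.
"""

import pandas as pd

from nucleomorph import generate_population, measure_nuclei, morphometry_group_tests
from nucleomorph.phantom import PopulationSpec

pop = PopulationSpec(seed=8)
samples, truth = generate_population(pop)

rows = []
for sample in samples:
    rec = measure_nuclei(sample.image, sample.labels)[0]
    rows.append({
        "group": sample.group,
        "volume_um3": rec.volume_um3,
        "elongation": rec.elongation,
        "compactness_norm": rec.compactness_norm,
        "chromatin_density": rec.chromatin_density,
    })
table = pd.DataFrame(rows)

print(table.groupby("group").agg(["mean", "std"]).round(3), "\n")
result = morphometry_group_tests(table)
print(result.round(4))

# Expected direction: S1.1 nuclei are smaller (lower volume), more
# elongated, and denser; stars follow *p<=0.05, **p<=0.01, ***p<=0.001.
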