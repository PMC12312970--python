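"""Comparative-Cq fold induction and plate-array percent-of-control.

Small worked qPCR and luminescence tables: fold change by the ddCq method
with GAPDH normalization, blank-corrected plate-array normalization, and
a two-group Student's t-test with significance stars.
"""

import pandas as pd

from nucleomorph import compare_groups, fold_induction, plate_normalize

# qPCR: target 2 cycles earlier in treated cells at equal reference
cq = pd.DataFrame(
    [
        ("mock_1", "Mock", "NDM29", 27.1), ("mock_1", "Mock", "GAPDH", 19.9),
        ("mock_2", "Mock", "NDM29", 27.3), ("mock_2", "Mock", "GAPDH", 20.1),
        ("s11_1", "S1.1", "NDM29", 24.0), ("s11_1", "S1.1", "GAPDH", 20.0),
        ("s11_2", "S1.1", "NDM29", 24.2), ("s11_2", "S1.1", "GAPDH", 20.2),
    ],
    columns=["sample", "group", "gene", "cq"],
)
fold = fold_induction(cq, target_gene="NDM29", ref_gene="GAPDH",
                      control_group="Mock")
print("NDM29 fold induction vs Mock:")
print(fold.round(2).to_string(), "\n")
# ddCq = -3.2: the treated group expresses ~9.2x the control.

# plate array: blank-corrected, GAPDH-normalized, percent of control
plate = pd.DataFrame(
    [
        ("A1", "IL8", "Mock", 1400.0), ("A2", "GAPDH", "Mock", 2100.0),
        ("B1", "IL8", "S1.1", 750.0), ("B2", "GAPDH", "S1.1", 2100.0),
    ],
    columns=["well", "gene", "group", "luminescence"],
)
print("plate array, percent of control:")
print(plate_normalize(plate, blank=100.0).round(1), "\n")

# group comparison with the star convention *<=0.05 **<=0.01 ***<=0.001
mock_volumes = [640.2, 611.8, 660.9, 625.4, 648.8]
s11_volumes = [492.1, 470.3, 505.6, 481.0, 499.7]
result = compare_groups(mock_volumes, s11_volumes)
print(f"volume t-test: t = {result.t_statistic:.2f}, "
      f"p = {result.p_value:.2e} {result.stars}")
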