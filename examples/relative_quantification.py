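"""Livak 2^-ddCT quantification of a case/control cohort.

Simulates triplicate CT tables for 47 case and 20 control samples with a
planted -1.32-cycle dCT effect (a ~2.5-fold expression difference) and
recovers the fold change and its significance.
"""

from pseudoquant.quant import compare_groups, efficiency_from_dilution, fold_change
from pseudoquant.synthetic import CohortConfig, cohort_delta_cts, generate_ct_table

table = generate_ct_table(CohortConfig(seed=7))
dcts = cohort_delta_cts(table, target="IVS9", reference="ACTB")
case = dcts.loc[dcts.group == "case", "delta_ct"]
control = dcts.loc[dcts.group == "control", "delta_ct"]

fc = fold_change(case, control)
test = compare_groups(case, control)
print(f"mean dCT case    = {case.mean():.3f}")
print(f"mean dCT control = {control.mean():.3f}")
print(f"ddCT = {fc.delta_delta_ct:.3f} cycles -> fold change = {fc.fold_change:.2f}")
print(f"student t = {test.t:.2f}, df = {test.df:.0f}, p = {test.p:.2e}")

# a standard curve for the same assay: a dilution series at efficiency 0.92
slope = -1 / __import__("math").log10(1.92)
points = [(x, 24 + slope * x) for x in (0, -1, -2, -3, -4)]
eff = efficiency_from_dilution(points)
print(f"standard curve slope = {eff.slope:.3f} -> efficiency E = {eff.efficiency:.2f}")

# Lower dCT means more transcript, so a negative ddCT in cases gives a
# fold change above 1: the case group transcribes ~2.5x more target RNA.
# Efficiency is reported for assay QC but does not correct the fold change.
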