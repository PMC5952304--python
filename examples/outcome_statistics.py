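"""Outcome statistics on the study's published count tables.

Exact tests on the 2x2 tables, the incidence/frequency reduction
arithmetic, and 2^-ΔΔCT relative quantification with a geometric-mean
housekeeping control.
"""

from ictal import (ContingencyTable2x2, GroupOutcome, QPCRPlate,
                   ddct_fold_change, fisher_exact_two_sided,
                   fjb_protection_class, frequency_reduction,
                   incidence_reduction, mann_whitney)

# --- spontaneous recurrent seizures: 10/10 diazepam vs 3/11 urethane rats
p = fisher_exact_two_sided(ContingencyTable2x2(10, 0, 3, 8))
print(f"SRS incidence, diazepam vs urethane: p = {p:.3f} (Fisher exact)")

urethane = GroupOutcome("urethane", 11, n_positive=3, events_total=7)
diazepam = GroupOutcome("diazepam", 10, n_positive=10, events_total=76)
print(f"incidence reduction: {incidence_reduction(urethane, diazepam)}%")
print(f"frequency reduction: {frequency_reduction(urethane, diazepam):.1f}%")

# --- hippocampal neurodegeneration (>10 FJB+ cells per section)
for region, cells in [("CA1", (8, 1, 2, 13)), ("CA3", (7, 2, 1, 14))]:
    p = fisher_exact_two_sided(ContingencyTable2x2(*cells))
    print(f"{region} degeneration, diazepam vs urethane: p = {p:.4f}")
print("254 FJB+ cells/section ->", fjb_protection_class(254))
print("5 FJB+ cells/section   ->", fjb_protection_class(5))

# --- Mann-Whitney on small samples takes the exact enumeration path
u, p = mann_whitney([260, 180, 310, 254], [4, 6, 5, 3])
print(f"FJB counts diazepam vs urethane (toy n=4): U = {u:.0f}, p = {p:.3f}")

# --- 2^-ΔΔCT with the geometric mean of ACTB/GAPDH/HPRT1 as control
hk = {"ACTB": 18.2, "GAPDH": 17.3, "HPRT1": 21.3}
plate = QPCRPlate(
    samples={
        "ctl_1": dict(hk, CCL2=25.1), "ctl_2": dict(hk, CCL2=24.9),
        "se_1": dict(hk, CCL2=20.6), "se_2": dict(hk, CCL2=20.4),
    },
    groups={"ctl_1": "control", "ctl_2": "control",
            "se_1": "dfp_se", "se_2": "dfp_se"},
)
print(f"housekeeping CT geometric mean: "
      f"{plate.housekeeping_geomean('ctl_1'):.1f} cycles")
folds = ddct_fold_change(plate, "CCL2")
print(f"CCL2 fold change, SE vs control: "
      f"{folds['group_mean']['dfp_se']:.1f}x")
# A ~4.5-cycle earlier CT for the target gene corresponds to a ~23-fold
# induction of the transcript relative to controls.
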