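"""Benign/malignant biomarker statistics on a synthetic cohort.

Draws a 35-benign / 25-malignant cohort from the published per-group
parameter distributions, then runs the full diagnostic evaluation: Wilcoxon
rank-sum (chi-squared for the binary SVP), ROC with AUC / sensitivity /
specificity at the Youden cutoff, bootstrap CIs, and the multivariable
logistic combination of the four-biomarker panel (mvFD, SVP, BA, MD).
"""

import warnings

from vesselmorph import evaluate_cohort, make_cohort

warnings.simplefilter("ignore")

cohort = make_cohort(n_benign=35, n_malignant=25, seed=1)
table, panel = evaluate_cohort(cohort, n_boot=2000, seed=1)

print(f"{'parameter':<12}{'p-value':>12}{'Sen%':>8}{'Sp%':>8}{'AUC%':>8}   95% CI")
for _, row in table.iterrows():
    print(
        f"{row.parameter:<12}{row.p_value:>12.2e}{row.sen_pct:>8.1f}"
        f"{row.sp_pct:>8.1f}{row.auc_pct:>8.1f}   "
        f"[{row.ci_lo_pct:.1f} - {row.ci_hi_pct:.1f}]"
    )

print()
print(
    f"panel (mvFD, SVP, BA, MD): AUC {panel.auc_pct:.2f}%, "
    f"Sen {panel.sensitivity_pct:.1f}%, Sp {panel.specificity_pct:.1f}%"
)
print()
print("Malignant lesions show higher mvFD/MD/VDR and lower BA. The headline")
print("parameters (SVP, VDR, mvFD, MD mean/max, BA mean/min) separate the")
print("groups at p < 0.05, while MD min and BA median/max typically do not —")
print("the same split of significant and non-significant statistics seen in")
print("patients. The combined panel tracks or beats the best single parameter")
print("in-sample.")
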