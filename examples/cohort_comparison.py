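"""Run the full study-style analysis on one synthetic cohort.

Generates 50 seeded patients, applies the SPECT abnormality gate, scores
the VR battery, and runs the statistical comparison: laterality t-tests,
SVM classification of clinically important motor dysfunction (UPDRS-III >
10) with cross-validated ROC analysis, logistic regression, and SVM
regression of the UPDRS-III score with a 70/30 hold-out.
"""

import vrmotor as vm

patients = vm.generate_cohort(vm.CohortConfig(n_patients=50, rng_seed=42))
report = vm.analyze_cohort(patients)
d = report.to_dict()

ex = d["exclusions"]
print(f"generated {ex['n_generated']}, enrolled {ex['n_enrolled']} "
      f"(normal scans excluded: {ex['normal_scan_ids']})")
print(f"VR completed by {ex['n_vr_complete']} patients\n")

print("CID classification (cross-validated AUC):")
for name in ("vr_no_cv", "vr", "spect", "spect_meds"):
    e = d["table3_classification"][name]
    extra = f", p vs VR = {e['p_vs_vr']:.3f}" if "p_vs_vr" in e else ""
    print(f"  {name:10s} AUC = {e['auc']:.3f} "
          f"(95% CI {e['ci95'][0]:.3f}-{e['ci95'][1]:.3f}){extra}")

print("\nUPDRS-III regression (held-out test split):")
for name in ("vr", "spect"):
    s = d["table5_regression"][name]["test"]
    print(f"  {name:6s} R^2 = {s['r_squared']:.3f} (n={s['n']}, p={s['p_value']:.3f})")

print("\n-> VR features detect and predict motor dysfunction far better than")
print("   the weakly coupled SPECT binding ratios, the pattern this analysis")
print("   is designed to expose; the medication flag barely changes SPECT.")
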