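"""Simulate a matched three-group cohort and run the full risk analysis.

The simulator draws subject-level BPER per phase from truncated normals
(cancer > benign > control, premenopausal > postmenopausal, rising with
phase). The analysis then mirrors the study design: Mann-Whitney and ROC
per phase, maximal-AUC phase, Youden cutoff, and the odds ratio at that
cutoff.
"""

import json

import bpeq

cohort = bpeq.simulate_cohort(101, seed=0)  # 101 subjects per group
print(f"{len(cohort)} subjects; premenopausal "
      f"{(cohort.menopause == 'premenopausal').sum() // 3} per group")

report = bpeq.analyze_cohort(cohort)
for meno in ("premenopausal", "postmenopausal"):
    entry = report[meno]["cancer_vs_control"]
    aucs = {p: v["auc"] for p, v in entry["phases"].items()}
    print(f"\n{meno} cancer vs control")
    print(f"  AUC per phase: {aucs}")
    print(f"  best phase: {entry['best_phase']}, cutoff {entry['cutoff']}% "
          f"(sens {entry['sensitivity_pct']}%, spec {entry['specificity_pct']}%)")
    print(f"  OR {entry['odds_ratio']} (95% CI {entry['or_ci'][0]}-{entry['or_ci'][1]}), "
          f"chi-square p {entry['p_chi2']}")
print("\nfull report:", json.dumps(report, indent=2)[:200], "...")
# High-BPER subjects (>= cutoff) carry several-fold higher odds of being in
# the cancer group, mirroring the association the pipeline is built to detect.
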