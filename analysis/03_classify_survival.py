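"""Fit the BCCP on the mouse classes and stratify every cohort's survival.

The classifier is validated first by leave-one-out cross-validation on the
mouse set (rerunning gene selection inside each fold), then applied to each
median-centered cohort. Per cohort: Kaplan-Meier curves by predicted group,
the log-rank comparison, and a multivariate Cox fit of the group indicator
adjusted for log2 AFP and stage.
"""

import numpy as np

from _common import COHORTS, data_path, out_path

from arid1a_hcc import io as pio
from arid1a_hcc.bccp import (center_cohort, classify_cohort, fit_bccp,
                             loocv_misclassification)
from arid1a_hcc.signature import GeneSignature, case_insensitive_ortholog_map
from arid1a_hcc.survival import cox_fit, km_estimate, logrank_test


def main() -> None:
    mouse = pio.read_expression_tsv(data_path("mouse_expression.tsv"))
    labels = pio.read_labels_tsv(data_path("mouse_labels.tsv"))
    sig = GeneSignature.from_tsv(out_path("signature.tsv"))
    human_sig = GeneSignature.from_tsv(out_path("signature_human.tsv"))

    rate, _ = loocv_misclassification(mouse, labels, low_class="KO",
                                      classes=("WT", "KO"))
    print(f"mouse LOOCV misclassification: {rate:.3f}")

    mapping = case_insensitive_ortholog_map(sig.genes, human_sig.genes)
    model = fit_bccp(center_cohort(mouse.rename(index=mapping)), labels,
                     human_sig, low_class="KO")
    model.to_text(out_path("bccp_model.txt"))

    for name in COHORTS:
        expr = pio.read_expression_tsv(data_path(f"{name}_expression.tsv"))
        clinical = pio.read_table_tsv(data_path(f"{name}_clinical.tsv"))
        cls = classify_cohort(model, center_cohort(expr))
        cls.to_tsv(out_path(f"{name}_classification.tsv"))
        agreement = (cls.labels.map({"signature-low": "low",
                                     "signature-high": "high"})
                     == clinical["true_class"]).mean()

        lr = logrank_test(clinical["time"], clinical["event"], cls.labels)
        for label in ("signature-low", "signature-high"):
            members = cls.labels[cls.labels == label].index
            km = km_estimate(clinical.loc[members, "time"],
                             clinical.loc[members, "event"])
            km.to_tsv(out_path(f"{name}_km_{label.split('-')[1]}.tsv"))
        cox = cox_fit(clinical.assign(
            group_low=(cls.labels == "signature-low").astype(int),
            log2_afp=np.log2(clinical["afp"])),
            ["group_low", "log2_afp", "stage"])
        cox.to_tsv(out_path(f"{name}_cox.tsv"))
        hr = cox.hr("group_low")
        lo, hi = cox.table.loc["group_low", ["ci_lower", "ci_upper"]]
        print(f"{name}: {cls.n_low}/{len(cls.table)} signature-low, truth "
              f"agreement {agreement:.3f}, log-rank p {lr.p_value:.3g}, "
              f"adjusted group HR {hr:.3f} (95% CI {lo:.3f}-{hi:.3f})")


if __name__ == "__main__":
    main()
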