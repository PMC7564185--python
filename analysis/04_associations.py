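"""Co-occurrence of the predicted subtype with a comparator subtype call.

Cross-tabulates the cohort-1 BCCP labels against a noisy comparator labeling
(the planted truth with 10% flips, standing in for an independent
poor-prognosis subtype classifier) and tests association by Pearson
chi-square. Also recomputes the published NCIP co-occurrence arithmetic from
its printed counts as a reference point.
"""

import numpy as np
import pandas as pd

from _common import SEED, data_path, out_path

from arid1a_hcc import io as pio
from arid1a_hcc.association import association_report, chi_square_test, crosstab
from arid1a_hcc.datasets import NCIP_COHORT1_TABLE


def main() -> None:
    clinical = pio.read_table_tsv(data_path("cohort1_clinical.tsv"))
    cls = pd.read_csv(out_path("cohort1_classification.tsv"), sep="\t",
                      index_col="sample_id")["label"]

    rng = np.random.default_rng(SEED + 500)
    flip = rng.random(len(clinical)) < 0.10
    comparator = pd.Series(
        np.where(clinical["true_class"].eq("low") ^ flip, "poor", "good"),
        index=clinical.index, name="subtype")
    pio.write_labels_tsv(comparator, out_path("comparator_subtype_labels.tsv"))

    table = crosstab(cls, comparator,
                     row_order=("signature-low", "signature-high"),
                     col_order=("poor", "good"))
    result = chi_square_test(table)
    report = association_report("BCCP vs comparator subtype", table, result)
    print(report)

    published = chi_square_test(NCIP_COHORT1_TABLE)
    report += "\n\n" + association_report("published NCIP co-occurrence (counts "
                                          "transcribed from the study)",
                                          NCIP_COHORT1_TABLE, published)
    out_path("association_report.txt").write_text(report + "\n")
    print(f"\npublished NCIP fixture: chi-square p = {published.p_value:.3g}")


if __name__ == "__main__":
    main()
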