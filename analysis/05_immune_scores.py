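"""Immune composite scores by predicted subtype.

IFNG6 (mean log2 of the six interferon-gamma response genes) and the
cytolytic score (mean log2 of GZMA and PRF1) per sample, compared between the
predicted groups with Welch's t; plus the per-gene checkpoint panel with the
nominal p < 0.01 flag and a BH-adjusted column.
"""

import pandas as pd

from _common import data_path, out_path

from arid1a_hcc import io as pio
from arid1a_hcc.immune_scores import (CHECKPOINT_INHIBITORY,
                                      CHECKPOINT_STIMULATORY, GeneSetRegistry,
                                      checkpoint_gene_comparison,
                                      compare_score_groups, score_table)


def main() -> None:
    expr = pio.read_expression_tsv(data_path("cohort1_expression.tsv"))
    groups = pd.read_csv(out_path("cohort1_classification.tsv"), sep="\t",
                         index_col="sample_id")["label"]

    registry = GeneSetRegistry()
    scores = score_table(expr, registry, {"IFNG6": "mean", "CYT": "mean"})
    pio.write_table_tsv(scores, out_path("immune_scores.tsv"))
    comparison = compare_score_groups(scores, groups)
    comparison.to_csv(out_path("immune_score_comparison.tsv"), sep="\t",
                      index_label="score", float_format="%.10g")
    for name, row in comparison.iterrows():
        print(f"{name}: low-group mean {row['mean1']:.2f} vs high-group "
              f"{row['mean0']:.2f} (difference {row['difference']:.2f}, "
              f"p = {row['p_value']:.3g})")

    panel = CHECKPOINT_STIMULATORY + CHECKPOINT_INHIBITORY
    checkpoints = checkpoint_gene_comparison(expr, groups, panel)
    checkpoints.to_csv(out_path("checkpoint_genes.tsv"), sep="\t",
                       float_format="%.10g")
    flagged = checkpoints.index[checkpoints["flagged"].astype(bool)].tolist()
    print(f"checkpoint genes flagged at p<0.01: {', '.join(flagged)}")


if __name__ == "__main__":
    main()
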