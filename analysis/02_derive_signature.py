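"""Derive the knockout-vs-wildtype signature and map it across species.

Pooled-t statistics per gene, thresholded at p < 0.05 and |log2 ratio| > 0.5;
the retained genes (training t statistic as weight) form the signature, which
is then translated to human symbols by case-insensitive matching and
intersected with each cohort's gene universe — the cross-cohort attrition
table mirrors how a mouse signature shrinks when carried into human data.
"""

from _common import COHORTS, data_path, out_path

from arid1a_hcc import io as pio
from arid1a_hcc.signature import (case_insensitive_ortholog_map, compute_gene_stats,
                                  derive_signature, map_orthologs,
                                  shared_gene_overlap)


def main() -> None:
    expr = pio.read_expression_tsv(data_path("mouse_expression.tsv"))
    labels = pio.read_labels_tsv(data_path("mouse_labels.tsv"))
    stats = compute_gene_stats(expr, labels, classes=("WT", "KO"))
    sig = derive_signature(stats)
    sig.to_tsv(out_path("signature.tsv"))
    sig.to_gmt(out_path("signature.gmt"), name="ARID1A")
    print(f"signature: {len(sig)} genes ({sig.n_up} up / {sig.n_down} down) "
          f"at p<{sig.p_threshold}, |log2 ratio|>{sig.lfc_threshold}")

    universes = {name: pio.read_expression_tsv(
        data_path(f"{name}_expression.tsv")).index for name in COHORTS}
    mapping = case_insensitive_ortholog_map(sig.genes,
                                            next(iter(universes.values())))
    human_sig = map_orthologs(sig, mapping)
    human_sig.to_tsv(out_path("signature_human.tsv"))
    overlap = shared_gene_overlap(human_sig, universes)
    overlap.to_csv(out_path("signature_cohort_overlap.tsv"), sep="\t",
                   index_label="cohort")
    print(f"mapped to human symbols: {len(human_sig)} genes "
          f"({human_sig.entries.attrs.get('n_unmapped', 0)} unmapped)")
    print(f"shared by all cohorts: {overlap.loc['shared_all', 'n_genes']}")


if __name__ == "__main__":
    main()
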