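"""Simulate the study's inputs with planted ground truth.

Generates the two-class mouse liver experiment (10 wild-type vs 10 knockout,
50 of 1000 genes shifted by 4 log2 units), then three patient cohorts sized
like the published ones (242 / 188 / 139) embedding the derived signature in
40% of samples at hazard ratio 2. Writes every input as TSV under
results/analysis/data/ plus a JSON manifest of the truth parameters.
"""

import dataclasses
import json

from _common import COHORTS, SEED, data_path

from arid1a_hcc import io as pio
from arid1a_hcc.signature import compute_gene_stats, derive_signature
from arid1a_hcc.synthetic_data import (CohortSimTruth, default_mouse_truth,
                                       simulate_cohort, simulate_mouse_experiment)


def main() -> None:
    data_path("x").parent.mkdir(parents=True, exist_ok=True)
    truth = default_mouse_truth(seed=SEED)
    expr, labels, truth = simulate_mouse_experiment(1000, truth.n_per_group, truth)
    pio.write_expression_tsv(expr, data_path("mouse_expression.tsv"))
    pio.write_labels_tsv(labels, data_path("mouse_labels.tsv"))
    print(f"mouse experiment: {expr.shape[0]} genes x {expr.shape[1]} samples, "
          f"{len(truth.de_genes)} planted DE genes at effect {truth.effect_size}")

    # cohorts embed the signature the mouse data actually yields
    sig = derive_signature(compute_gene_stats(expr, labels, classes=("WT", "KO")))
    manifest = {"mouse": dataclasses.asdict(truth) | {"de_directions": None},
                "cohorts": {}}
    for i, (name, n) in enumerate(COHORTS.items()):
        ctruth = CohortSimTruth(seed=SEED + 100 + i)
        cexpr, clinical, ctruth = simulate_cohort(n, sig, ctruth)
        pio.write_expression_tsv(cexpr, data_path(f"{name}_expression.tsv"))
        pio.write_table_tsv(clinical, data_path(f"{name}_clinical.tsv"))
        n_low = int((clinical["true_class"] == "low").sum())
        manifest["cohorts"][name] = dataclasses.asdict(ctruth) | {"n_samples": n}
        print(f"{name}: n={n}, {n_low} planted signature-low "
              f"({100 * n_low / n:.1f}%), hazard ratio {ctruth.hazard_ratio}")
    data_path("truth_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")


if __name__ == "__main__":
    main()
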