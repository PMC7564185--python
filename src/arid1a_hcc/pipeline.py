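"""End-to-end orchestration from a single plain-text (YAML) config.

``run_full_pipeline`` executes simulate -> derive-signature -> map-orthologs
-> fit-BCCP (+ LOOCV) -> classify each cohort -> survival -> association ->
immune scores -> multi-omic, writing every artifact as TSV/GMT/SEG/JSON under
the configured output directory plus a checksum manifest. All randomness is
spawned deterministically from the single config seed, so two runs with the
same config produce byte-identical output.

One log line per stage records input shapes and attrition (genes dropped,
samples excluded) so the signature's journey across species and cohorts is
auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .association import chi_square_test, crosstab, association_report
from .bccp import (center_cohort, classify_cohort, fit_bccp,
                   loocv_misclassification)
from .errors import ConfigError
from .immune_scores import (CHECKPOINT_INHIBITORY, CHECKPOINT_STIMULATORY,
                            GeneSetRegistry, checkpoint_gene_comparison,
                            compare_score_groups, score_table)
from .multiomic import (cin_score, group_feature_comparison, mutation_enrichment,
                        pearson, variant_class_distribution)
from .signature import (case_insensitive_ortholog_map, compute_gene_stats,
                        derive_signature, map_orthologs, shared_gene_overlap)
from .survival import cox_fit, km_estimate, logrank_test
from .synthetic_data import (CohortSimTruth, default_mouse_truth,
                             simulate_cohort, simulate_mouse_experiment,
                             simulate_multiomic)

logger = logging.getLogger(__name__)


@dataclass
class CohortSpec:
    name: str
    n_samples: int
    low_fraction: float = 0.4
    hazard_ratio: float = 2.0
    baseline_hazard: float = 0.01
    censor_rate: float = 0.005
    effect_size: float = 4.0
    noise_sd: float = 1.0


@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips through YAML unchanged."""

    seed: int = 17
    out_dir: str = "results/run"
    p_threshold: float = 0.05
    lfc_threshold: float = 0.5
    posterior_cutoff: float = 0.5
    welch: bool = False
    chi_square_correction: bool = False
    score_method: str = "mean"
    mouse_n_genes: int = 1000
    mouse_n_de: int = 50
    mouse_n_per_group: int = 10
    mouse_effect_size: float = 4.0
    mouse_noise_sd: float = 0.5
    cohorts: list[CohortSpec] = field(default_factory=lambda: [
        CohortSpec("cohort1", 242),
        CohortSpec("cohort2", 188),
        CohortSpec("cohort3", 139),
    ])
    multiomic_cohort: str = "cohort1"
    subtype_flip_rate: float = 0.1  # label noise of the comparator subtype call

    def validate(self) -> None:
        if not (0 < self.p_threshold <= 1):
            raise ConfigError("p_threshold must be in (0,1]")
        if self.lfc_threshold < 0:
            raise ConfigError("lfc_threshold must be >= 0")
        if not (0 < self.posterior_cutoff < 1):
            raise ConfigError("posterior_cutoff must be in (0,1)")
        if self.mouse_n_de > self.mouse_n_genes:
            raise ConfigError("mouse_n_de cannot exceed mouse_n_genes")
        names = [c.name for c in self.cohorts]
        if len(set(names)) != len(names) or not names:
            raise ConfigError("cohort names must be unique and non-empty")
        if self.multiomic_cohort not in names:
            raise ConfigError(f"multiomic_cohort {self.multiomic_cohort!r} unknown")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        if not Path(path).exists():
            raise ConfigError(f"config file not found: {path}")
        d = yaml.safe_load(Path(path).read_text()) or {}
        cohorts = [CohortSpec(**c) for c in d.pop("cohorts", [])]
        cfg = cls(**d) if not cohorts else cls(**d, cohorts=cohorts)
        cfg.validate()
        return cfg


def demo_config(seed: int = 17, out_dir: str = "results/demo") -> PipelineConfig:
    """Small separable synthetic reproduction of the study design."""
    return PipelineConfig(seed=seed, out_dir=out_dir,
                          cohorts=[CohortSpec("cohort1", 242),
                                   CohortSpec("cohort2", 188),
                                   CohortSpec("cohort3", 139)])


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; return the run report (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    report: dict = {"stages": {}, "seed": config.seed}

    def save(name: str, writer) -> Path:
        path = out / name
        writer(path)
        artifacts.append(path)
        return path

    root_ss = np.random.SeedSequence(config.seed)
    children = iter(root_ss.spawn(64))

    # -- stage: simulate mouse experiment -----------------------------------
    truth = default_mouse_truth(
        n_genes=config.mouse_n_genes, n_de=config.mouse_n_de,
        effect_size=config.mouse_effect_size,
        n_per_group=config.mouse_n_per_group,
        noise_sd=config.mouse_noise_sd, seed=_child_seed(next(children)))
    mouse_expr, mouse_labels, truth = simulate_mouse_experiment(
        config.mouse_n_genes, config.mouse_n_per_group, truth)
    save("mouse_expression.tsv", lambda p: pio.write_expression_tsv(mouse_expr, p))
    save("mouse_labels.tsv", lambda p: pio.write_labels_tsv(mouse_labels, p))
    logger.info("stage simulate-mouse: %d genes x %d samples, %d planted",
                *mouse_expr.shape, len(truth.de_genes))
    report["stages"]["simulate_mouse"] = {
        "n_genes": int(mouse_expr.shape[0]), "n_samples": int(mouse_expr.shape[1]),
        "n_planted": len(truth.de_genes)}

    # -- stage: derive signature --------------------------------------------
    stats = compute_gene_stats(mouse_expr, mouse_labels, welch=config.welch,
                               classes=("WT", "KO"))
    sig = derive_signature(stats, config.p_threshold, config.lfc_threshold)
    save("signature.tsv", sig.to_tsv)
    save("signature.gmt", lambda p: sig.to_gmt(p, name="ARID1A"))
    logger.info("stage derive-signature: %d genes (%d up / %d down)",
                len(sig), sig.n_up, sig.n_down)
    report["stages"]["derive_signature"] = {
        "n_genes": len(sig), "n_up": sig.n_up, "n_down": sig.n_down,
        "planted_recovered": len(set(sig.genes) & set(truth.de_genes))}

    # -- stage: LOOCV on the mouse set ---------------------------------------
    loocv_rate, folds = loocv_misclassification(
        mouse_expr, mouse_labels, low_class="KO", classes=("WT", "KO"),
        p_threshold=config.p_threshold, lfc_threshold=config.lfc_threshold)
    save("loocv_folds.tsv", lambda p: folds.to_csv(p, sep="\t", float_format="%.10g"))
    logger.info("stage loocv: misclassification rate %.3f", loocv_rate)
    report["stages"]["loocv"] = {"misclassification_rate": loocv_rate}

    # -- stage: simulate cohorts, map signature across species ---------------
    cohort_data: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    for spec in config.cohorts:
        ctruth = CohortSimTruth(
            low_fraction=spec.low_fraction, hazard_ratio=spec.hazard_ratio,
            baseline_hazard=spec.baseline_hazard, censor_rate=spec.censor_rate,
            effect_size=spec.effect_size, noise_sd=spec.noise_sd,
            seed=_child_seed(next(children)))
        expr, clinical, ctruth = simulate_cohort(spec.n_samples, sig, ctruth)
        cohort_data[spec.name] = (expr, clinical)
        save(f"{spec.name}_expression.tsv", lambda p, e=expr: pio.write_expression_tsv(e, p))
        save(f"{spec.name}_clinical.tsv", lambda p, c=clinical: pio.write_table_tsv(c, p))
        logger.info("stage simulate-%s: %d genes x %d samples, low fraction %.3f",
                    spec.name, *expr.shape, spec.low_fraction)

    first = config.cohorts[0].name
    mapping = case_insensitive_ortholog_map(sig.genes, cohort_data[first][0].index)
    human_sig = map_orthologs(sig, mapping)
    overlap = shared_gene_overlap(
        human_sig, {n: e.index for n, (e, _) in cohort_data.items()})
    save("signature_cohort_overlap.tsv",
         lambda p: overlap.to_csv(p, sep="\t", index_label="cohort"))
    report["stages"]["map_orthologs"] = {
        "n_mapped": len(human_sig),
        "n_unmapped": int(human_sig.entries.attrs.get("n_unmapped", 0)),
        "shared_all_cohorts": int(overlap.loc["shared_all", "n_genes"])}

    # -- stage: fit BCCP on the (centered, ortholog-renamed) mouse data ------
    mouse_human = center_cohort(mouse_expr.rename(index=mapping))
    model = fit_bccp(mouse_human, mouse_labels, human_sig, low_class="KO",
                     cutoff=config.posterior_cutoff)
    save("bccp_model.txt", model.to_text)
    report["stages"]["fit_bccp"] = {"n_genes": int(len(model.weights))}

    # -- stage: classify + survival per cohort -------------------------------
    classifications: dict[str, pd.Series] = {}
    for spec in config.cohorts:
        expr, clinical = cohort_data[spec.name]
        cls = classify_cohort(model, center_cohort(expr))
        save(f"{spec.name}_classification.tsv", cls.to_tsv)
        agreement = float((cls.labels.map({"signature-low": "low",
                                           "signature-high": "high"})
                           == clinical["true_class"]).mean())
        classifications[spec.name] = cls.labels

        groups = cls.labels
        lr = logrank_test(clinical["time"], clinical["event"], groups)
        for label in ("signature-low", "signature-high"):
            members = groups[groups == label].index
            km = km_estimate(clinical.loc[members, "time"],
                             clinical.loc[members, "event"])
            save(f"{spec.name}_km_{label.split('-')[1]}.tsv", km.to_tsv)
        cox_df = clinical.assign(
            group_low=(groups == "signature-low").astype(int),
            log2_afp=np.log2(clinical["afp"]))
        cox = cox_fit(cox_df, ["group_low", "log2_afp", "stage"])
        save(f"{spec.name}_cox.tsv", cox.to_tsv)
        logger.info("stage survival-%s: %d/%d low, log-rank p %.3g, group HR %.3f",
                    spec.name, cls.n_low, len(groups), lr.p_value,
                    cox.hr("group_low"))
        report["stages"][f"classify_{spec.name}"] = {
            "n_low": cls.n_low, "n_samples": int(len(groups)),
            "genes_used": cls.genes_used, "truth_agreement": agreement,
            "logrank_p": lr.p_value, "logrank_statistic": lr.statistic,
            "cox_group_hr": cox.hr("group_low"),
            "cox_group_p": float(cox.table.loc["group_low", "p_value"])}

    # -- stage: subtype co-occurrence ----------------------------------------
    expr1, clinical1 = cohort_data[first]
    rng = np.random.default_rng(_child_seed(next(children)))
    flip = rng.random(len(clinical1)) < config.subtype_flip_rate
    other = np.where(clinical1["true_class"].eq("low") ^ flip, "poor", "good")
    other_labels = pd.Series(other, index=clinical1.index, name="subtype")
    save("comparator_subtype_labels.tsv",
         lambda p: pio.write_labels_tsv(other_labels, p))
    table = crosstab(classifications[first], other_labels,
                     row_order=("signature-low", "signature-high"),
                     col_order=("poor", "good"))
    assoc = chi_square_test(table, correction=config.chi_square_correction)
    save("association_report.txt",
         lambda p: Path(p).write_text(
             association_report("BCCP vs comparator subtype", table, assoc) + "\n"))
    report["stages"]["associate"] = {
        "chi_square": assoc.statistic, "p_value": assoc.p_value,
        "low_poor_pct": float(assoc.row_percentages[0, 0]),
        "high_poor_pct": float(assoc.row_percentages[1, 0])}

    # -- stage: immune scores ------------------------------------------------
    registry = GeneSetRegistry()
    scores = score_table(expr1, registry,
                         {"IFNG6": config.score_method, "CYT": config.score_method})
    save("immune_scores.tsv", lambda p: pio.write_table_tsv(scores, p))
    cmp_scores = compare_score_groups(scores, classifications[first])
    save("immune_score_comparison.tsv",
         lambda p: cmp_scores.to_csv(p, sep="\t", index_label="score",
                                     float_format="%.10g"))
    checkpoints = checkpoint_gene_comparison(
        expr1, classifications[first],
        CHECKPOINT_STIMULATORY + CHECKPOINT_INHIBITORY)
    save("checkpoint_genes.tsv",
         lambda p: checkpoints.to_csv(p, sep="\t", float_format="%.10g"))
    report["stages"]["immune_scores"] = {
        name: {"p_value": float(cmp_scores.loc[name, "p_value"]),
               "difference": float(cmp_scores.loc[name, "difference"])}
        for name in cmp_scores.index}
    report["stages"]["immune_scores"]["n_checkpoint_flagged"] = int(
        checkpoints["flagged"].sum())

    # -- stage: multi-omic layer ---------------------------------------------
    omics = simulate_multiomic(
        n_samples=len(clinical1), mrna=expr1.loc["ARID1A"],
        seed=_child_seed(next(children)), groups=clinical1["true_class"])
    save("multiomic_samples.tsv", lambda p: pio.write_table_tsv(omics.samples, p))
    save("multiomic_segments.seg", lambda p: pio.write_seg(omics.segments, p))
    save("multiomic_mutations.maf.tsv", lambda p: pio.write_maf(omics.maf, p))

    groups1 = classifications[first].map({"signature-low": "low",
                                          "signature-high": "high"})
    cors = {layer: pearson(omics.samples["mrna"], omics.samples[layer])
            for layer in ("protein", "cna", "methylation")}
    cin = cin_score(omics.segments)
    feats = omics.samples.assign(cin=cin)
    comparisons = {f: group_feature_comparison(feats, groups1, f)
                   for f in ("mrna", "methylation", "cin", "protein")}
    enrich = mutation_enrichment(omics.mutations, groups1)
    save("mutation_enrichment.tsv",
         lambda p: enrich.to_csv(p, sep="\t", float_format="%.10g"))
    vclass = variant_class_distribution(omics.maf, "ARID1A")
    report["stages"]["multiomic"] = {
        "correlations": {k: {"r": v.r, "n": v.n_pairs, "p": v.p_value}
                         for k, v in cors.items()},
        "group_comparisons": {k: {"p_value": v["p_value"],
                                  "difference": v["difference"]}
                              for k, v in comparisons.items()},
        "mutation_p": {g: float(enrich.loc[g, "p_value"])
                       for g in ("TP53", "AXIN1", "TSC2")},
        "arid1a_variant_class_pct": {k: float(v) for k, v in vclass.items()},
    }

    # -- manifest and report -------------------------------------------------
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    artifacts.append(report_path)
    config_path = out / "config.yaml"
    config.to_yaml(config_path)
    artifacts.append(config_path)
    pio.write_manifest(artifacts, out / "manifest.json",
                       params={"seed": config.seed})
    logger.info("pipeline complete: %d artifacts in %s", len(artifacts), out)
    return report
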