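"""Ground-truth recovery and calibration experiments on the generators.

Each function runs a Monte-Carlo experiment against the synthetic-data
module's planted truth and returns summary rates: signature recovery and
false-positive control, BCCP label agreement, Cox confidence-interval
coverage at the planted hazard ratio, and type-I error calibration of the
log-rank and Welch tests under null generators. The same functions back the
test suite and the results-reproduction script.

All experiments derive their per-replicate seeds from a single base seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bccp import center_cohort, classify_cohort, fit_bccp
from .immune_scores import IFNG6, composite_score, welch_compare
from .multiomic import pearson
from .signature import (GeneSignature, case_insensitive_ortholog_map,
                        compute_gene_stats, derive_signature, map_orthologs)
from .survival import cox_fit, logrank_test
from .synthetic_data import (CohortSimTruth, default_mouse_truth,
                             simulate_cohort, simulate_mouse_experiment,
                             simulate_multiomic)


def _seeds(base_seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(base_seed).generate_state(n) % (2 ** 31)]


def _toy_signature(n_genes: int = 6) -> GeneSignature:
    """Minimal alternating-direction signature for cohort-only experiments."""
    entries = pd.DataFrame({
        "weight": [(10.0 if i % 2 == 0 else -10.0) for i in range(n_genes)],
        "direction": ["up" if i % 2 == 0 else "down" for i in range(n_genes)],
    }, index=pd.Index([f"SIG{i:03d}" for i in range(n_genes)], name="gene_id"))
    return GeneSignature(entries=entries)


def signature_recovery(n_seeds: int = 20, n_genes: int = 1000, n_de: int = 50,
                       effect_size: float = 4.0, noise_sd: float = 0.5,
                       n_per_group: int = 10, base_seed: int = 0) -> dict:
    """Planted-gene recovery of signature derivation across seeds.

    Returns the fraction of planted genes recovered (pooled over seeds), the
    worst per-seed recovery, and the largest per-seed false-positive rate
    among null genes.
    """
    recoveries, fp_rates = [], []
    for seed in _seeds(base_seed, n_seeds):
        truth = default_mouse_truth(n_genes, n_de, effect_size=effect_size,
                                    n_per_group=n_per_group, noise_sd=noise_sd,
                                    seed=seed)
        expr, labels, truth = simulate_mouse_experiment(n_genes, n_per_group, truth)
        stats = compute_gene_stats(expr, labels, classes=("WT", "KO"))
        sig = derive_signature(stats)
        planted = set(truth.de_genes)
        recoveries.append(len(planted & set(sig.genes)) / len(planted))
        fp_rates.append(len(set(sig.genes) - planted) / (n_genes - n_de))
    return {"mean_recovery": float(np.mean(recoveries)),
            "min_recovery": float(np.min(recoveries)),
            "max_false_positive_rate": float(np.max(fp_rates)),
            "n_seeds": n_seeds}


def null_signature_type1(n_seeds: int = 50, n_genes: int = 500,
                         n_per_group: int = 10, base_seed: int = 1) -> dict:
    """With zero planted effect, fraction of genes called at p < 0.05."""
    rates = []
    for seed in _seeds(base_seed, n_seeds):
        truth = default_mouse_truth(n_genes, 0, effect_size=0.0,
                                    n_per_group=n_per_group, seed=seed)
        expr, labels, _ = simulate_mouse_experiment(n_genes, n_per_group, truth)
        stats = compute_gene_stats(expr, labels, classes=("WT", "KO"))
        rates.append(float((stats["p_value"] < 0.05).mean()))
    return {"mean_rate": float(np.mean(rates)), "n_seeds": n_seeds,
            "n_tests": n_seeds * n_genes}


def bccp_cohort_agreement(n_seeds: int = 5, n_samples: int = 400,
                          low_fraction: float = 0.4, effect_size: float = 4.0,
                          base_seed: int = 2) -> dict:
    """End-to-end label agreement with the planted cohort classes.

    Each replicate runs the whole cross-species path: mouse simulation,
    signature derivation, ortholog mapping, BCCP fit on the centered mouse
    data, cohort classification.
    """
    agreements = []
    for seed in _seeds(base_seed, n_seeds):
        truth = default_mouse_truth(seed=seed)
        expr, labels, _ = simulate_mouse_experiment(1000, truth.n_per_group, truth)
        sig = derive_signature(compute_gene_stats(expr, labels, classes=("WT", "KO")))
        ctruth = CohortSimTruth(low_fraction=low_fraction,
                                effect_size=effect_size, seed=seed + 1)
        cexpr, clinical, _ = simulate_cohort(n_samples, sig, ctruth)
        mapping = case_insensitive_ortholog_map(sig.genes, cexpr.index)
        model = fit_bccp(center_cohort(expr.rename(index=mapping)), labels,
                         map_orthologs(sig, mapping), low_class="KO")
        cls = classify_cohort(model, center_cohort(cexpr))
        predicted = cls.labels.map({"signature-low": "low", "signature-high": "high"})
        agreements.append(float((predicted == clinical["true_class"]).mean()))
    return {"mean_agreement": float(np.mean(agreements)),
            "min_agreement": float(np.min(agreements)), "n_seeds": n_seeds}


def cox_ci_coverage(n_reps: int = 500, n_samples: int = 400,
                    hazard_ratio: float = 2.0, base_seed: int = 3) -> dict:
    """Coverage of the Cox 95% CI for the planted group hazard ratio,
    adjusting for the (confounded-by-class) AFP covariate."""
    sig = _toy_signature()
    covered = 0
    for seed in _seeds(base_seed, n_reps):
        ctruth = CohortSimTruth(hazard_ratio=hazard_ratio, seed=seed)
        _, clinical, _ = simulate_cohort(n_samples, sig, ctruth,
                                         n_background_genes=0)
        df = clinical.assign(
            group_low=(clinical["true_class"] == "low").astype(int),
            log2_afp=np.log2(clinical["afp"]))
        fit = cox_fit(df, ["group_low", "log2_afp"])
        lo, hi = fit.table.loc["group_low", ["ci_lower", "ci_upper"]]
        covered += int(lo <= hazard_ratio <= hi)
    return {"coverage": covered / n_reps, "n_reps": n_reps,
            "hazard_ratio": hazard_ratio}


def logrank_type1(n_reps: int = 1000, n_samples: int = 200, alpha: float = 0.05,
                  base_seed: int = 4) -> dict:
    """Rejection rate of the log-rank test between true classes when the
    planted hazard ratio is 1 (null calibration)."""
    sig = _toy_signature()
    rejections = 0
    for seed in _seeds(base_seed, n_reps):
        ctruth = CohortSimTruth(hazard_ratio=1.0, low_fraction=0.5, seed=seed)
        _, clinical, _ = simulate_cohort(n_samples, sig, ctruth,
                                         n_background_genes=0)
        res = logrank_test(clinical["time"], clinical["event"],
                           clinical["true_class"])
        rejections += int(res.p_value < alpha)
    return {"rate": rejections / n_reps, "n_reps": n_reps, "alpha": alpha,
            "mc_3se": 3 * float(np.sqrt(alpha * (1 - alpha) / n_reps))}


def logrank_power(n_reps: int = 200, n_samples: int = 400,
                  hazard_ratio: float = 2.0, alpha: float = 0.05,
                  base_seed: int = 5) -> dict:
    """Rejection rate at the planted hazard ratio (power under the generator)."""
    sig = _toy_signature()
    rejections = 0
    for seed in _seeds(base_seed, n_reps):
        ctruth = CohortSimTruth(hazard_ratio=hazard_ratio, seed=seed)
        _, clinical, _ = simulate_cohort(n_samples, sig, ctruth,
                                         n_background_genes=0)
        res = logrank_test(clinical["time"], clinical["event"],
                           clinical["true_class"])
        rejections += int(res.p_value < alpha)
    return {"rate": rejections / n_reps, "n_reps": n_reps}


def welch_type1(n_reps: int = 1000, n_samples: int = 200, alpha: float = 0.05,
                base_seed: int = 6) -> dict:
    """Type-I rate of the Welch comparison of the IFNG6 composite between the
    true classes when no immune shift is planted."""
    sig = _toy_signature()
    rejections = 0
    for seed in _seeds(base_seed, n_reps):
        ctruth = CohortSimTruth(low_fraction=0.5, immune_shift=0.0, seed=seed)
        expr, clinical, _ = simulate_cohort(n_samples, sig, ctruth,
                                            n_background_genes=0)
        score, _ = composite_score(expr, IFNG6, method="mean")
        res = welch_compare(score, clinical["true_class"])
        rejections += int(res["p_value"] < alpha)
    return {"rate": rejections / n_reps, "n_reps": n_reps, "alpha": alpha,
            "mc_3se": 3 * float(np.sqrt(alpha * (1 - alpha) / n_reps))}


def pearson_target_recovery(n_seeds: int = 100, n_samples: int = 181,
                            target_r: float = 0.36, base_seed: int = 7) -> dict:
    """Sample Pearson r of the planted protein~mRNA correlation across seeds."""
    rs = []
    for seed in _seeds(base_seed, n_seeds):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
        mrna = pd.Series(rng.normal(1.2, 0.7, n_samples),
                         index=[f"P{i:04d}" for i in range(n_samples)])
        omics = simulate_multiomic(n_samples, mrna,
                                   target_r={"protein": target_r},
                                   seed=seed, protein_fraction=1.0)
        rs.append(pearson(omics.samples["mrna"], omics.samples["protein"]).r)
    rs = np.asarray(rs)
    return {"mean_r": float(rs.mean()), "target_r": target_r,
            "max_abs_deviation": float(np.abs(rs - target_r).max()),
            "n_seeds": n_seeds}
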