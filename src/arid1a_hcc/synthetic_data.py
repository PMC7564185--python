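"""Synthetic data with recorded ground truth for every pipeline input.

Three generators emulate the study design end to end:

* a two-class mouse experiment (wild-type vs knockout liver) with a planted
  set of differentially expressed genes on the log2 scale;
* human tumor cohorts whose expression embeds the (ortholog-mapped) mouse
  signature in a known fraction of signature-low samples, with exponential
  survival times at a planted hazard ratio, independent exponential
  censoring, and clinical covariates (AFP, stage) elevated in the low class;
* a multi-omic layer (protein, methylation, copy-number segments, somatic
  mutations) with planted correlations to mRNA and planted group enrichment.

Noise is independent Gaussian per gene on the log2 scale. Seeds are explicit
arguments everywhere; the same seed gives bit-identical output.

Default parameters are the study conditions the generators emulate: a mouse
experiment with 50 planted genes shifted by 4 log2 units (noise SD 0.5,
10 animals per class), cohorts with 40% signature-low samples at hazard
ratio 2, and multi-omic correlation targets 0.36 (protein), 0.32 (copy
number) and -0.22 (methylation) at the reported platform sample sizes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .signature import GeneSignature

BASELINE_LOG2 = 8.0

# immune genes carried in every simulated cohort, with the planted shift of
# each (log2 units, added to signature-low samples; 0 = null gene)
IFNG6_GENES = ["CXCL9", "CXCL10", "IDO1", "IFNG", "HLA-DRA", "STAT1"]
CYT_GENES = ["GZMA", "PRF1"]
STIMULATORY_PANEL = ["CD27", "CD28", "CD40", "CD40LG", "CD226", "ICOS",
                     "IL2RB", "TNFRSF9", "TNFRSF18"]
INHIBITORY_PANEL = ["CD276", "LAG3", "PDCD1", "CD274", "CTLA4"]
SUPPRESSED_IN_LOW = ["CD28", "CD40", "CD226", "IL2RB"]
ELEVATED_IN_HIGH = ["CD276", "LAG3"]


@dataclass
class MouseSimTruth:
    """Ground truth of the simulated knockout experiment."""

    de_genes: list[str]
    effect_size: float = 4.0
    n_per_group: int = 10
    noise_sd: float = 0.5
    seed: int = 0
    de_directions: dict[str, int] = field(default_factory=dict)  # gene -> +1/-1

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise InvalidArgumentError("n_per_group must be >= 2")
        if not (self.noise_sd > 0):
            raise InvalidArgumentError("noise_sd must be > 0")


@dataclass
class CohortSimTruth:
    """Ground truth of one simulated patient cohort."""

    low_fraction: float = 0.4
    hazard_ratio: float = 2.0
    baseline_hazard: float = 0.01   # events per time unit (months)
    censor_rate: float = 0.005     # independent censoring hazard
    seed: int = 0
    effect_size: float = 4.0       # log2 shift of signature genes in low samples
    noise_sd: float = 1.0
    immune_shift: float = 1.0      # log2 down-shift of planted immune genes in low
    afp_mu: float = 5.2            # log-ng/mL location in the high class
    afp_shift: float = 0.9         # added to afp_mu in the low class
    afp_sigma: float = 1.5

    def __post_init__(self) -> None:
        if not (0 < self.low_fraction < 1):
            raise InvalidArgumentError("low_fraction must be in (0,1)")
        if not (self.hazard_ratio > 0):
            raise InvalidArgumentError("hazard_ratio must be > 0")
        if not (self.baseline_hazard > 0):
            raise InvalidArgumentError("baseline_hazard must be > 0")
        if self.censor_rate < 0:
            raise InvalidArgumentError("censor_rate must be >= 0")


def default_mouse_truth(n_genes: int = 1000, n_de: int = 50, effect_size: float = 4.0,
                        n_per_group: int = 10, noise_sd: float = 0.5,
                        seed: int = 0) -> MouseSimTruth:
    """Truth object planting the first ``n_de`` genes of a ``gene0001``-style
    universe, alternating up/down so the signature has both directions."""
    if n_de > n_genes:
        raise InvalidArgumentError("n_de cannot exceed n_genes")
    genes = mouse_gene_universe(n_genes)[:n_de]
    return MouseSimTruth(de_genes=genes, effect_size=effect_size,
                         n_per_group=n_per_group, noise_sd=noise_sd, seed=seed)


def mouse_gene_universe(n_genes: int) -> list[str]:
    return [f"Gene{i + 1:05d}" for i in range(n_genes)]


def simulate_mouse_experiment(n_genes: int, n_per_group: int, truth: MouseSimTruth
                              ) -> tuple[pd.DataFrame, pd.Series, MouseSimTruth]:
    """Two-class expression matrix with planted differential genes.

    All genes share a common baseline mean; each planted gene's knockout mean
    differs by ``effect_size`` (alternating sign across the planted list).
    Returns (genes x samples matrix, WT/KO labels, echoed truth with the
    planted directions filled in).
    """
    if n_genes <= 0 or n_per_group <= 0:
        raise InvalidArgumentError("dimensions must be positive")
    if n_genes < len(truth.de_genes):
        raise InvalidArgumentError("n_genes smaller than the planted gene list")
    truth = dataclasses.replace(truth, n_per_group=n_per_group)

    genes = mouse_gene_universe(n_genes)
    universe = set(genes)
    if not set(truth.de_genes) <= universe:
        raise InvalidArgumentError("de_genes must be a subset of the gene universe")

    rng = np.random.default_rng(truth.seed)
    samples = [f"WT{i + 1:02d}" for i in range(n_per_group)] + \
              [f"KO{i + 1:02d}" for i in range(n_per_group)]
    labels = pd.Series(["WT"] * n_per_group + ["KO"] * n_per_group,
                       index=pd.Index(samples, name="sample_id"), name="group")

    means = np.full((n_genes, 2 * n_per_group), BASELINE_LOG2)
    directions = {g: (1 if i % 2 == 0 else -1) for i, g in enumerate(truth.de_genes)}
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g, d in directions.items():
        means[gene_pos[g], n_per_group:] += d * truth.effect_size

    values = means + rng.normal(0.0, truth.noise_sd, size=means.shape)
    expr = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=samples)
    truth = dataclasses.replace(truth, de_directions=directions)
    return expr, labels, truth


def _simulate_survival(rng: np.random.Generator, is_low: np.ndarray,
                       truth: CohortSimTruth) -> tuple[np.ndarray, np.ndarray]:
    hazard = truth.baseline_hazard * truth.hazard_ratio ** is_low.astype(float)
    t_event = rng.exponential(1.0 / hazard)
    if truth.censor_rate > 0:
        t_censor = rng.exponential(1.0 / truth.censor_rate, size=len(is_low))
    else:
        t_censor = np.full(len(is_low), np.inf)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    return time, event


def simulate_cohort(n_samples: int, signature: GeneSignature, truth: CohortSimTruth,
                    n_background_genes: int = 200, uppercase_ids: bool = True,
                    ) -> tuple[pd.DataFrame, pd.DataFrame, CohortSimTruth]:
    """Patient cohort embedding the signature in a planted low fraction.

    The expression universe is the signature's genes (uppercased by default,
    emulating human ortholog symbols), background null genes, the immune
    panels, and an ARID1A row with the low group's mean shifted down.
    Signature-low samples have each signature gene shifted by ``effect_size``
    in the direction the signature records; planted immune genes are shifted
    down by ``immune_shift``. The clinical table carries true class, observed
    time, event flag, log-normal AFP (elevated in low) and tumor stage.
    """
    if len(signature) == 0:
        raise InvalidArgumentError("signature is empty")
    if n_samples < 2:
        raise InvalidArgumentError("n_samples must be >= 2")

    rng = np.random.default_rng(truth.seed)
    sig_genes = [g.upper() if uppercase_ids else g for g in signature.genes]
    sig_sign = np.where(signature.entries["direction"].to_numpy() == "up", 1.0, -1.0)
    background = [f"BG{i + 1:05d}" for i in range(n_background_genes)]
    immune = IFNG6_GENES + CYT_GENES + STIMULATORY_PANEL + INHIBITORY_PANEL
    genes = sig_genes + background + immune + ["ARID1A"]
    if len(set(genes)) != len(genes):
        raise InvalidArgumentError("gene universe collision between signature and panels")

    samples = [f"P{i + 1:04d}" for i in range(n_samples)]
    is_low = rng.random(n_samples) < truth.low_fraction

    means = np.full((len(genes), n_samples), BASELINE_LOG2)
    means[:len(sig_genes), :] += np.outer(sig_sign * truth.effect_size,
                                          is_low.astype(float))
    shifted_immune = set(IFNG6_GENES + CYT_GENES + SUPPRESSED_IN_LOW + ELEVATED_IN_HIGH)
    for j, g in enumerate(immune):
        if g in shifted_immune:
            means[len(sig_genes) + len(background) + j, is_low] -= truth.immune_shift
    # ARID1A mRNA itself: group means mirroring the reported 1.27 vs 1.05 log2
    arid1a_mean = np.where(is_low, 1.05, 1.27)
    means[-1, :] = arid1a_mean

    values = means + rng.normal(0.0, truth.noise_sd, size=means.shape)
    values[-1, :] = arid1a_mean + rng.normal(0.0, 0.7, size=n_samples)
    expr = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=samples)

    time, event = _simulate_survival(rng, is_low, truth)
    afp = np.exp(rng.normal(truth.afp_mu + truth.afp_shift * is_low.astype(float),
                            truth.afp_sigma))
    stage_p_low = np.array([0.27, 0.40, 0.33])
    stage_p_high = np.array([0.40, 0.46, 0.14])
    stage = np.array([rng.choice([1, 2, 3], p=stage_p_low if lo else stage_p_high)
                      for lo in is_low])
    clinical = pd.DataFrame({
        "time": time, "event": event, "afp": afp, "stage": stage,
        "true_class": np.where(is_low, "low", "high"),
    }, index=pd.Index(samples, name="sample_id"))
    return expr, clinical, truth


DEFAULT_TARGET_R = {"protein": 0.36, "cna": 0.32, "methylation": -0.22}
DEFAULT_MUTATION_RATES = {
    # gene -> (rate in low group, rate in high group)
    "TP53": (0.40, 0.15), "AXIN1": (0.15, 0.05), "TSC2": (0.12, 0.03),
    "ARID1A": (0.118, 0.057), "CTNNB1": (0.25, 0.25), "ALB": (0.12, 0.12),
}
ARID1A_VARIANT_CLASS_P = {"truncating": 24 / 33, "missense": 8 / 33,
                          "in_frame": 1 / 33}
GENERIC_VARIANT_CLASS_P = {"missense": 0.6, "truncating": 0.35, "in_frame": 0.05}


@dataclass
class MultiOmicTable:
    """Per-sample omic features plus mutation flags and copy-number segments."""

    samples: pd.DataFrame        # columns: mrna, protein, methylation, cna
    mutations: pd.DataFrame      # samples x genes binary flags
    segments: pd.DataFrame       # SEG-style table
    maf: pd.DataFrame            # sample, gene, variant_class
    target_r: dict[str, float]
    seed: int


def _correlated(rng: np.random.Generator, z: np.ndarray, r: float) -> np.ndarray:
    """Standard-normal variate with population Pearson r against standardized z."""
    if r == 1.0:
        return z.copy()
    if r == -1.0:
        return -z
    return r * z + np.sqrt(1.0 - r * r) * rng.standard_normal(len(z))


def simulate_multiomic(n_samples: int, mrna: pd.Series,
                       target_r: dict[str, float] | None = None, seed: int = 0,
                       groups: pd.Series | None = None,
                       protein_fraction: float = 181 / 371,
                       methylation_group_shift: float = 0.1,
                       seg_sd: tuple[float, float] = (0.25, 0.15),
                       mutation_rates: dict[str, tuple[float, float]] | None = None,
                       ) -> MultiOmicTable:
    """Multi-omic layer with planted mRNA correlations and group enrichment.

    ``mrna`` supplies the per-sample scalar expression the other layers are
    calibrated against (population Pearson r per layer from ``target_r``).
    Protein is observed only for a ``protein_fraction`` subset (pairwise
    deletion downstream). Methylation betas get ``methylation_group_shift``
    added in the low group; segment log2 ratios are noisier in the low group
    (``seg_sd`` = (low, high) SDs), planting higher chromosomal instability;
    mutation flags follow per-group Bernoulli rates.
    """
    target_r = dict(DEFAULT_TARGET_R if target_r is None else target_r)
    for layer, r in target_r.items():
        if not (-1.0 <= r <= 1.0):
            raise InvalidArgumentError(f"target_r[{layer!r}]={r} outside [-1,1]")
    mrna = mrna.iloc[:n_samples]
    if len(mrna) != n_samples:
        raise InvalidArgumentError("mrna shorter than n_samples")
    samples = list(mrna.index)
    # salted stream: never replays default_rng(seed) draws a caller may have
    # used to build the mrna vector itself
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6F6D]))

    if groups is None:
        is_low = np.zeros(n_samples, dtype=bool)
    else:
        is_low = (groups.reindex(samples).astype(str) == "low").to_numpy()

    x = mrna.to_numpy(dtype=float)
    if x.std() == 0:
        raise InvalidArgumentError("mrna has zero variance")
    z = (x - x.mean()) / x.std()

    protein = _correlated(rng, z, target_r.get("protein", 0.0))
    observed = rng.random(n_samples) < protein_fraction
    protein = np.where(observed, protein, np.nan)

    meth_latent = _correlated(rng, z, target_r.get("methylation", 0.0))
    methylation = np.clip(0.3 + 0.1 * meth_latent
                          + methylation_group_shift * is_low.astype(float),
                          0.0, 1.0)
    cna = _correlated(rng, z, target_r.get("cna", 0.0))

    table = pd.DataFrame({"mrna": x, "protein": protein,
                          "methylation": methylation, "cna": cna},
                         index=pd.Index(samples, name="sample_id"))

    segments = _simulate_segments(rng, samples, is_low, seg_sd)
    mutations, maf = _simulate_mutations(
        rng, samples, is_low,
        DEFAULT_MUTATION_RATES if mutation_rates is None else mutation_rates)
    return MultiOmicTable(samples=table, mutations=mutations, segments=segments,
                          maf=maf, target_r=target_r, seed=seed)


def _simulate_segments(rng: np.random.Generator, samples: list[str],
                       is_low: np.ndarray, seg_sd: tuple[float, float],
                       n_chroms: int = 5, chrom_len: int = 100_000_000,
                       segments_per_chrom: int = 8) -> pd.DataFrame:
    sd_low, sd_high = seg_sd
    rows = []
    for i, s in enumerate(samples):
        sd = sd_low if is_low[i] else sd_high
        for chrom in range(1, n_chroms + 1):
            cuts = np.sort(rng.integers(1, chrom_len,
                                        size=segments_per_chrom - 1))
            bounds = np.concatenate([[0], cuts, [chrom_len]])
            for k in range(segments_per_chrom):
                start, end = int(bounds[k]), int(bounds[k + 1])
                if end <= start:
                    end = start + 1
                rows.append((s, f"chr{chrom}", start, end,
                             max(1, (end - start) // 10_000),
                             float(rng.normal(0.0, sd))))
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end",
                                       "num_mark", "seg_mean"])


def _simulate_mutations(rng: np.random.Generator, samples: list[str],
                        is_low: np.ndarray,
                        rates: dict[str, tuple[float, float]],
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    genes = sorted(rates)
    flags = pd.DataFrame(0, index=pd.Index(samples, name="sample_id"),
                         columns=genes, dtype=int)
    maf_rows = []
    for g in genes:
        r_low, r_high = rates[g]
        p = np.where(is_low, r_low, r_high)
        hit = rng.random(len(samples)) < p
        flags[g] = hit.astype(int)
        class_p = ARID1A_VARIANT_CLASS_P if g == "ARID1A" else GENERIC_VARIANT_CLASS_P
        classes = list(class_p)
        probs = np.array([class_p[c] for c in classes])
        probs = probs / probs.sum()
        for s in np.array(samples)[hit]:
            maf_rows.append((s, g, rng.choice(classes, p=probs)))
    maf = pd.DataFrame(maf_rows, columns=["sample", "gene", "variant_class"])
    return flags, maf
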