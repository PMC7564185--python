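"""Multi-platform correlates of the signature-low subtype.

Pearson correlation of ARID1A mRNA with protein (RPPA-like), gene-level copy
number, and promoter methylation; Welch comparisons of omic features between
the dichotomized groups; a chromosomal-instability (CIN) score from
copy-number segments; and per-gene mutation enrichment by Fisher's exact
test with BH adjustment.

Missing omic values are handled by pairwise deletion (protein is typically
available for only a subset of samples), never casewise.

CIN is defined here as the fraction of total segmented genome length whose
segment log2 copy ratio exceeds 0.2 in absolute value — a conventional
gain/loss threshold; the cutoff is a parameter isolated in
:func:`cin_score`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .association import ContingencyTable2x2, fisher_exact
from .errors import InvalidArgumentError, UndefinedCorrelationError
from .immune_scores import welch_compare

CIN_THRESHOLD = 0.2


@dataclass
class CorrelationResult:
    r: float
    n_pairs: int
    p_value: float


def pearson(x: pd.Series, y: pd.Series) -> CorrelationResult:
    """Pearson correlation over complete pairs (pairwise deletion).

    Two-sided p from t = r sqrt((n-2)/(1-r^2)); requires >= 3 complete pairs
    and non-zero variance in both arguments.
    """
    common = x.dropna().index.intersection(y.dropna().index)
    if len(common) < 3:
        raise InvalidArgumentError(f"need >= 3 complete pairs, got {len(common)}")
    xv = x[common].to_numpy(dtype=float)
    yv = y[common].to_numpy(dtype=float)
    if xv.std() == 0 or yv.std() == 0:
        raise UndefinedCorrelationError("zero variance in an argument")
    r, p = sps.pearsonr(xv, yv)
    return CorrelationResult(r=float(r), n_pairs=int(len(common)), p_value=float(p))


def group_feature_comparison(samples: pd.DataFrame, groups: pd.Series,
                             feature: str) -> dict:
    """Welch t comparison of one omic feature between the two groups."""
    if feature not in samples.columns:
        raise InvalidArgumentError(f"feature {feature!r} not in table")
    return welch_compare(samples[feature], groups)


def cin_score(segments: pd.DataFrame, threshold: float = CIN_THRESHOLD) -> pd.Series:
    """Per-sample chromosomal instability: length fraction with |log2 ratio| > threshold.

    ``segments`` is a SEG-style table (sample, chrom, start, end, num_mark,
    seg_mean). Samples with no segments get NaN (missing, not an error).
    """
    seg = segments.copy()
    seg["length"] = seg["end"].astype(float) - seg["start"].astype(float)
    if (seg["length"] <= 0).any():
        raise InvalidArgumentError("segments must have positive length")
    seg["altered"] = (seg["seg_mean"].astype(float).abs() > threshold) * seg["length"]
    by_sample = seg.groupby("sample")[["length", "altered"]].sum()
    return (by_sample["altered"] / by_sample["length"]).rename("cin")


def summarize_methylation(beta: pd.DataFrame, probe_map: pd.Series) -> pd.DataFrame:
    """Gene-level methylation: mean beta over each gene's probes.

    ``beta`` is probes x samples in [0,1]; ``probe_map`` maps probe id -> gene.
    """
    vals = beta.to_numpy(dtype=float)
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
        raise InvalidArgumentError("beta values must lie in [0,1]")
    common = beta.index.intersection(probe_map.index)
    if len(common) == 0:
        raise InvalidArgumentError("probe map covers no probes in the matrix")
    return beta.loc[common].groupby(probe_map[common]).mean()


def mutation_enrichment(mutations: pd.DataFrame, groups: pd.Series,
                        exclude_unmutated_from_bh: bool = True) -> pd.DataFrame:
    """Per-gene 2x2 (group x mutated) Fisher exact tests.

    ``mutations`` is samples x genes with binary flags. The first sorted group
    label is treated as rows[0]. Genes mutated in nobody report p = 1 and are
    excluded from BH adjustment by default.
    """
    groups = groups.astype(str)
    common = mutations.index.intersection(groups.index)
    if len(common) == 0:
        raise InvalidArgumentError("mutation table and groups share no samples")
    mut = mutations.loc[common]
    grp = groups[common]
    names = sorted(grp.unique())
    if len(names) != 2:
        raise InvalidArgumentError(f"need exactly 2 groups, got {names}")
    in0 = (grp == names[0]).to_numpy()

    rows = []
    for gene in mut.columns:
        flags = mut[gene].astype(int).to_numpy()
        a = int(flags[in0].sum()); b = int((~flags[in0].astype(bool)).sum())
        c = int(flags[~in0].sum()); d = int((~flags[~in0].astype(bool)).sum())
        if a + c == 0:
            p = 1.0
        else:
            p = fisher_exact(ContingencyTable2x2(a, b, c, d,
                                                 row_names=(names[0], names[1]),
                                                 col_names=("mut", "wt")))
        rate0 = a / max(a + b, 1)
        rate1 = c / max(c + d, 1)
        rows.append({"gene": gene, "n_mut_group0": a, "n_mut_group1": c,
                     "rate_group0": rate0, "rate_group1": rate1,
                     "direction": ("enriched_in_" + names[0]) if rate0 > rate1
                                  else (("enriched_in_" + names[1]) if rate1 > rate0
                                        else "equal"),
                     "p_value": p, "any_mutated": (a + c) > 0})
    table = pd.DataFrame(rows).set_index("gene")
    mask = table["any_mutated"] if exclude_unmutated_from_bh else pd.Series(
        True, index=table.index)
    table["p_adj_bh"] = np.nan
    if mask.any():
        table.loc[mask, "p_adj_bh"] = multipletests(
            table.loc[mask, "p_value"], method="fdr_bh")[1]
    table.attrs["groups"] = names
    return table


def maf_to_flags(maf: pd.DataFrame, samples: list[str]) -> pd.DataFrame:
    """Binary samples x genes mutation matrix from a MAF-like call table."""
    flags = pd.DataFrame(0, index=pd.Index(samples, name="sample_id"),
                         columns=sorted(maf["gene"].unique()), dtype=int)
    for _, row in maf.iterrows():
        if row["sample"] in flags.index:
            flags.loc[row["sample"], row["gene"]] = 1
    return flags


def variant_class_distribution(maf: pd.DataFrame, gene: str) -> pd.Series:
    """Percent breakdown of a gene's mutations by variant class
    (truncating / missense / in-frame as recorded in the calls)."""
    calls = maf[maf["gene"] == gene]
    if len(calls) == 0:
        raise InvalidArgumentError(f"no calls for gene {gene!r}")
    counts = calls["variant_class"].value_counts()
    return (100.0 * counts / counts.sum()).rename("percent")
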