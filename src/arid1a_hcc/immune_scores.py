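"""Composite immune-activity scores and checkpoint-gene comparisons.

Built-in sets:

* IFNG6 — six interferon-gamma response genes (CXCL9, CXCL10, IDO1, IFNG,
  HLA-DRA, STAT1); the composite is their average log2 expression per sample,
  a reported predictor of anti-PD-1 response.
* CYT — cytolytic activity: mean log2 expression of granzyme A (GZMA) and
  perforin (PRF1), the two effectors up-regulated on CD8+ T-cell activation
  (on the log scale this is the log geometric mean of the transcripts).

The 105-gene immune signature (IS) score is a user-supplied GMT set scored
with gene-wise z-score averaging (``zmean``), since it mixes genes of very
different dynamic range. Checkpoint stimulatory/inhibitory gene lists are
likewise inputs, with small defaults covering the genes discussed in the HCC
setting.

Group comparisons use Welch's t by default (Mann-Whitney behind a flag);
checkpoint genes are flagged at nominal p < 0.01 with a BH-adjusted column
emitted alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import InvalidArgumentError

IFNG6 = ["CXCL9", "CXCL10", "IDO1", "IFNG", "HLA-DRA", "STAT1"]
CYT = ["GZMA", "PRF1"]
CHECKPOINT_STIMULATORY = ["CD27", "CD28", "CD40", "CD40LG", "CD226", "ICOS",
                          "IL2RB", "TNFRSF9", "TNFRSF18"]
CHECKPOINT_INHIBITORY = ["CD276", "LAG3", "PDCD1", "CD274", "CTLA4"]


@dataclass
class GeneSetRegistry:
    """Named gene sets; seeded with the built-ins, extendable from GMT."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        defaults = {"IFNG6": IFNG6, "CYT": CYT,
                    "CHECKPOINT_STIM": CHECKPOINT_STIMULATORY,
                    "CHECKPOINT_INHIB": CHECKPOINT_INHIBITORY}
        for name, genes in defaults.items():
            self.sets.setdefault(name, list(genes))
        for name, genes in self.sets.items():
            if not genes:
                raise InvalidArgumentError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise InvalidArgumentError(f"gene set {name!r} has duplicates")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def add_gmt(self, path) -> None:
        from .io import read_gmt

        self.sets.update(read_gmt(path))


def composite_score(expr: pd.DataFrame, genes: list[str],
                    method: str = "mean") -> tuple[pd.Series, list[str]]:
    """Per-sample composite over the set genes present in the matrix.

    ``mean``: arithmetic mean of log2 expression. ``zmean``: mean of gene-wise
    z-scores (each gene standardized across samples first). Returns the score
    series and the list of set genes actually found; none found is an error.
    """
    present = [g for g in genes if g in expr.index]
    if not present:
        raise InvalidArgumentError("no set genes present in expression matrix")
    sub = expr.loc[present]
    if method == "mean":
        score = sub.mean(axis=0)
    elif method == "zmean":
        sd = sub.std(axis=1, ddof=1).replace(0.0, np.nan)
        z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
        score = z.mean(axis=0)
    else:
        raise InvalidArgumentError(f"unknown method {method!r}")
    return score.rename(None), present


def score_table(expr: pd.DataFrame, registry: GeneSetRegistry,
                set_methods: dict[str, str]) -> pd.DataFrame:
    """Score several sets at once: {set name: method} -> samples x scores.

    Coverage (genes found / requested) is recorded in ``attrs['coverage']``.
    """
    cols, coverage = {}, {}
    for name, method in set_methods.items():
        score, present = composite_score(expr, registry[name], method=method)
        cols[name] = score
        coverage[name] = (len(present), len(registry[name]), method)
    table = pd.DataFrame(cols)
    table.attrs["coverage"] = coverage
    return table


def _two_group(values: pd.Series, groups: pd.Series) -> tuple[np.ndarray, np.ndarray, str, str]:
    groups = groups.astype(str)
    common = values.index.intersection(groups.index)
    values, groups = values[common], groups[common]
    names = sorted(groups.unique())
    if len(names) != 2:
        raise InvalidArgumentError(f"need exactly 2 groups, got {names}")
    x0 = values[groups == names[0]].dropna().to_numpy(dtype=float)
    x1 = values[groups == names[1]].dropna().to_numpy(dtype=float)
    if len(x0) < 2 or len(x1) < 2:
        raise InvalidArgumentError("each group needs >= 2 non-missing values")
    return x0, x1, names[0], names[1]


def welch_compare(values: pd.Series, groups: pd.Series,
                  method: str = "welch") -> dict:
    """Two-sided two-group comparison of one score/feature.

    Welch t by default (difference of means with a 95% CI); Mann-Whitney U
    behind ``method='mannwhitney'``. Exactly identical groups are reported as
    t = 0, p = 1.
    """
    x0, x1, g0, g1 = _two_group(values, groups)
    diff = float(x1.mean() - x0.mean())
    if method == "mannwhitney":
        stat, p = sps.mannwhitneyu(x1, x0, alternative="two-sided")
        ci = (np.nan, np.nan)
        stat = float(stat)
    elif method == "welch":
        se2 = x0.var(ddof=1) / len(x0) + x1.var(ddof=1) / len(x1)
        if se2 == 0:
            stat, p, ci = 0.0, 1.0, (diff, diff)
        else:
            res = sps.ttest_ind(x1, x0, equal_var=False)
            stat, p = float(res.statistic), float(res.pvalue)
            df = res.df
            half = sps.t.ppf(0.975, df) * np.sqrt(se2)
            ci = (diff - half, diff + half)
    else:
        raise InvalidArgumentError(f"unknown method {method!r}")
    return {"group0": g0, "group1": g1, "n0": len(x0), "n1": len(x1),
            "mean0": float(x0.mean()), "mean1": float(x1.mean()),
            "difference": diff, "ci_lower": float(ci[0]), "ci_upper": float(ci[1]),
            "statistic": stat, "p_value": float(p),
            "direction": "higher_in_group1" if diff > 0
                         else ("higher_in_group0" if diff < 0 else "equal")}


def compare_score_groups(scores: pd.DataFrame, groups: pd.Series,
                         method: str = "welch") -> pd.DataFrame:
    """Compare every score column between the two groups; one row per score."""
    rows = {name: welch_compare(scores[name], groups, method=method)
            for name in scores.columns}
    return pd.DataFrame.from_dict(rows, orient="index")


def checkpoint_gene_comparison(expr: pd.DataFrame, groups: pd.Series,
                               genes: list[str], flag_p: float = 0.01) -> pd.DataFrame:
    """Per-gene Welch comparison for checkpoint genes.

    Genes absent from the matrix appear with ``present=False`` and NaN stats.
    ``flagged`` marks nominal p < ``flag_p``; a BH-adjusted column is included
    for transparency but does not drive the flag.
    """
    rows = []
    for g in genes:
        if g not in expr.index:
            rows.append({"gene": g, "present": False})
            continue
        r = welch_compare(expr.loc[g], groups)
        r.update({"gene": g, "present": True})
        rows.append(r)
    table = pd.DataFrame(rows).set_index("gene")
    if not table["present"].any():
        raise InvalidArgumentError("none of the checkpoint genes present")
    mask = table["present"].astype(bool) & table["p_value"].notna()
    table["p_adj_bh"] = np.nan
    if mask.any():
        table.loc[mask, "p_adj_bh"] = multipletests(
            table.loc[mask, "p_value"], method="fdr_bh")[1]
    table["flagged"] = mask & (table["p_value"] < flag_p)
    return table
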