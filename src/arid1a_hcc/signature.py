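"""Differential-expression signature derivation and cross-species transfer.

A two-class gene-expression experiment (here, Arid1a wild-type vs knockout
mouse liver) is reduced to per-gene pooled-variance two-sample t statistics.
Genes passing both a raw p-value cutoff and an absolute log2-ratio cutoff form
the signature; each retained gene carries its training t statistic as weight
(the compound-covariate convention) and a direction (up/down in class1
relative to class0).

The log2-ratio threshold is applied to the absolute ratio: a signature built
this way contains both up- and down-regulated genes, which is what the
downstream compound covariate expects.

Cross-species transfer maps gene identifiers through an ortholog table; the
default table is a case-insensitive symbol match (mouse "Arid1a" -> human
"ARID1A"), overridable by an explicit two-column mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import EmptySignatureError, InsufficientReplicationError, InvalidArgumentError

logger = logging.getLogger(__name__)

STAT_COLUMNS = ["mean_class0", "mean_class1", "log2_ratio", "t_stat", "p_value"]


@dataclass
class GeneSignature:
    """Weighted gene list: weight = training t statistic, direction = its sign.

    ``entries`` is a DataFrame indexed by gene_id with columns
    ``weight`` (float) and ``direction`` ("up"/"down").
    """

    entries: pd.DataFrame
    p_threshold: float = 0.05
    lfc_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.entries.index.duplicated().any():
            raise InvalidArgumentError("signature entries must be unique by gene_id")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> list[str]:
        return list(self.entries.index)

    @property
    def weights(self) -> pd.Series:
        return self.entries["weight"]

    @property
    def n_up(self) -> int:
        return int((self.entries["direction"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.entries["direction"] == "down").sum())

    def to_tsv(self, path: str | Path) -> None:
        self.entries.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path, p_threshold: float = 0.05,
                 lfc_threshold: float = 0.5) -> "GeneSignature":
        entries = pd.read_csv(path, sep="\t", index_col="gene_id")
        entries.index = entries.index.astype(str)
        return cls(entries=entries[["weight", "direction"]],
                   p_threshold=p_threshold, lfc_threshold=lfc_threshold)

    def to_gmt(self, path: str | Path, name: str = "signature") -> None:
        from .io import write_gmt

        up = [g for g, d in self.entries["direction"].items() if d == "up"]
        down = [g for g, d in self.entries["direction"].items() if d == "down"]
        write_gmt({f"{name}_UP": up, f"{name}_DOWN": down}, path)


def _split_classes(expr: pd.DataFrame, labels: pd.Series,
                   classes: tuple[str, str] | None = None,
                   ) -> tuple[list[str], list[str], list[str]]:
    """Return (class names, class0 samples, class1 samples) for a binary labeling.

    ``classes`` pins (reference, treatment) explicitly — e.g. ("WT", "KO") so
    log2 ratios read KO minus WT; the default is alphabetical order.
    """
    labels = labels.dropna().astype(str)
    unknown = labels.index.difference(expr.columns)
    if len(unknown):
        raise InvalidArgumentError(f"labeled samples not in matrix: {list(unknown)[:5]}")
    observed = sorted(labels.unique())
    if len(observed) != 2:
        raise InvalidArgumentError(f"need exactly 2 classes, got {observed}")
    if classes is None:
        classes = tuple(observed)
    elif sorted(classes) != observed:
        raise InvalidArgumentError(f"classes {classes} do not match labels {observed}")
    classes = list(classes)
    s0 = list(labels.index[labels == classes[0]])
    s1 = list(labels.index[labels == classes[1]])
    return classes, s0, s1


def compute_gene_stats(expr: pd.DataFrame, labels: pd.Series,
                       welch: bool = False,
                       classes: tuple[str, str] | None = None) -> pd.DataFrame:
    """Per-gene two-sample t statistics between the two label classes.

    ``classes`` fixes the (class0, class1) orientation — pass ("WT", "KO") so
    a positive log2 ratio means up in the knockout; by default classes are
    taken in alphabetical order.

    Pooled-variance t by default (df = n0 + n1 - 2); Welch as an option.
    Genes are dropped when either class has fewer than 2 non-missing values or
    when the pooled variance is zero while the means differ (degenerate);
    dropped genes are logged and recorded in ``result.attrs``.

    Returns a DataFrame indexed by gene_id with columns ``mean_class0``,
    ``mean_class1``, ``log2_ratio`` (class1 - class0), ``t_stat``, ``p_value``.
    """
    classes, s0, s1 = _split_classes(expr, labels, classes)
    if len(s0) < 2 or len(s1) < 2:
        raise InsufficientReplicationError(
            f"each class needs >= 2 samples (got {len(s0)} and {len(s1)})")

    x0 = expr[s0].to_numpy(dtype=float)
    x1 = expr[s1].to_numpy(dtype=float)
    n0 = (~np.isnan(x0)).sum(axis=1)
    n1 = (~np.isnan(x1)).sum(axis=1)
    usable = (n0 >= 2) & (n1 >= 2)

    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # genes failing the >=2 non-missing rule produce dof warnings here
        # and are discarded below
        warnings.simplefilter("ignore", RuntimeWarning)
        m0 = np.nanmean(x0, axis=1)
        m1 = np.nanmean(x1, axis=1)
        v0 = np.nanvar(x0, axis=1, ddof=1)
        v1 = np.nanvar(x1, axis=1, ddof=1)

    diff = m1 - m0
    if welch:
        se2 = v0 / n0 + v1 / n1
        df = se2 ** 2 / ((v0 / n0) ** 2 / (n0 - 1) + (v1 / n1) ** 2 / (n1 - 1))
        se = np.sqrt(se2)
    else:
        sp2 = ((n0 - 1) * v0 + (n1 - 1) * v1) / (n0 + n1 - 2)
        df = (n0 + n1 - 2).astype(float)
        se = np.sqrt(sp2 * (1.0 / n0 + 1.0 / n1))

    zero_se = se == 0
    degenerate = usable & zero_se & (diff != 0)
    flat = usable & zero_se & (diff == 0)
    keep = usable & ~degenerate

    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero_se, 0.0, diff / np.where(zero_se, 1.0, se))
        p = 2.0 * sps.t.sf(np.abs(t), df)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    t[flat] = 0.0
    p[flat] = 1.0

    stats = pd.DataFrame(
        {"mean_class0": m0, "mean_class1": m1, "log2_ratio": diff,
         "t_stat": t, "p_value": p},
        index=expr.index)[["mean_class0", "mean_class1", "log2_ratio", "t_stat", "p_value"]]
    result = stats[keep]

    dropped_missing = list(expr.index[~usable])
    dropped_degenerate = list(expr.index[degenerate])
    if dropped_missing:
        logger.warning("dropped %d genes with <2 non-missing values in a class",
                       len(dropped_missing))
    if dropped_degenerate:
        logger.warning("dropped %d zero-variance genes with unequal class means",
                       len(dropped_degenerate))
    result.attrs["classes"] = classes
    result.attrs["dropped_missing"] = dropped_missing
    result.attrs["dropped_degenerate"] = dropped_degenerate
    return result


def derive_signature(stats: pd.DataFrame, p_threshold: float = 0.05,
                     lfc_threshold: float = 0.5) -> GeneSignature:
    """Threshold gene statistics into a signature.

    Retains genes with ``p_value < p_threshold`` and ``|log2_ratio| >
    lfc_threshold``; weight is the training t statistic, direction its sign.
    Raises :class:`EmptySignatureError` if nothing passes.
    """
    if p_threshold <= 0 or lfc_threshold < 0:
        raise InvalidArgumentError("thresholds must be positive")
    if len(stats) == 0:
        raise EmptySignatureError("no gene statistics supplied")
    passed = stats[(stats["p_value"] < p_threshold)
                   & (stats["log2_ratio"].abs() > lfc_threshold)]
    if len(passed) == 0:
        raise EmptySignatureError(
            f"no genes pass p<{p_threshold} and |log2 ratio|>{lfc_threshold}")
    entries = pd.DataFrame({
        "weight": passed["t_stat"],
        "direction": np.where(passed["t_stat"] > 0, "up", "down"),
    }, index=passed.index)
    sig = GeneSignature(entries=entries, p_threshold=p_threshold,
                        lfc_threshold=lfc_threshold)
    logger.info("signature: %d genes (%d up / %d down)", len(sig), sig.n_up, sig.n_down)
    return sig


def case_insensitive_ortholog_map(source_genes, target_genes) -> dict[str, str]:
    """Default cross-species map: match symbols ignoring case (Arid1a -> ARID1A)."""
    by_upper = {}
    for t in target_genes:
        by_upper.setdefault(str(t).upper(), str(t))
    return {str(s): by_upper[str(s).upper()] for s in source_genes
            if str(s).upper() in by_upper}


def read_ortholog_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (source gene, target gene), header optional via names."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise InvalidArgumentError("ortholog map needs two columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def map_orthologs(sig: GeneSignature, mapping: dict[str, str]) -> GeneSignature:
    """Translate signature gene ids through an ortholog map.

    Unmapped entries are dropped (counted in ``entries.attrs['n_unmapped']``);
    when several source genes map to one target, the entry with the larger
    |weight| wins and the discards are logged.
    """
    if not mapping:
        raise InvalidArgumentError("ortholog map is empty")
    mapped = sig.entries[sig.entries.index.isin(mapping)].copy()
    n_unmapped = len(sig) - len(mapped)
    mapped["target"] = [mapping[g] for g in mapped.index]
    mapped = mapped.sort_values("weight", key=np.abs, ascending=False)
    collided = mapped["target"].duplicated()
    if collided.any():
        logger.warning("ortholog collisions: discarded %d lower-|weight| entries",
                       int(collided.sum()))
    mapped = mapped[~collided].set_index("target")[["weight", "direction"]]
    mapped.index.name = "gene_id"
    mapped = mapped.sort_index()
    out = GeneSignature(entries=mapped, p_threshold=sig.p_threshold,
                        lfc_threshold=sig.lfc_threshold)
    out.entries.attrs["n_unmapped"] = n_unmapped
    if n_unmapped:
        logger.info("ortholog mapping dropped %d unmapped genes", n_unmapped)
    return out


def shared_gene_overlap(sig: GeneSignature, universes: dict[str, pd.Index]) -> pd.DataFrame:
    """Report how many signature genes each cohort's gene universe contains and
    the count shared by all cohorts (signature-attrition audit)."""
    rows = {}
    shared = set(sig.genes)
    for name, universe in universes.items():
        present = set(sig.genes) & set(map(str, universe))
        rows[name] = len(present)
        shared &= present
    rows["shared_all"] = len(shared)
    return pd.DataFrame.from_dict(rows, orient="index", columns=["n_genes"])
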