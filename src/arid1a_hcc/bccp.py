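"""Bayesian compound covariate predictor (BCCP).

Each sample is projected onto a single compound covariate

    c_s = sum_j w_j x_{js}

over the signature genes, with the training t statistics as weights w_j.
The two training classes induce Gaussian class-conditional models
N(mu_0, sigma^2) and N(mu_1, sigma^2) for c (variance pooled across classes),
and a new sample's posterior probability of the signature-low class follows
from Bayes' rule with equal priors by default. Samples are dichotomized at a
posterior cutoff of 0.5; a posterior of exactly 0.5 is assigned to the
signature-high class (strict inequality for "low").

When a target cohort lacks some signature genes, the model is restricted to
the gene intersection and the Gaussian parameters are recomputed by projecting
the cached training expression onto the same reduced gene set — this keeps
the class-conditional model calibrated to the covariate actually computed,
instead of rescaling weights.

Posteriors are evaluated in log space with a log-sum-exp guard.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import (DegenerateTrainingError, EmptySignatureError,
                     InsufficientOverlapError, InsufficientReplicationError,
                     InvalidArgumentError)
from .signature import GeneSignature, compute_gene_stats, derive_signature

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


def center_cohort(expr: pd.DataFrame) -> pd.DataFrame:
    """Median-center every gene row within the cohort (idempotent)."""
    return expr.sub(expr.median(axis=1, skipna=True), axis=0)


@dataclass
class BCCPModel:
    """Fitted compound-covariate classifier.

    ``weights`` maps gene_id -> training t statistic. ``mu_low``/``mu_high``
    are the class means of the training compound covariate and ``sigma`` its
    pooled within-class SD. ``training_expr`` caches the training expression
    restricted to the signature genes so class parameters can be recomputed on
    a gene subset at classification time.
    """

    weights: pd.Series
    mu_low: float
    mu_high: float
    sigma: float
    prior_low: float = 0.5
    cutoff: float = 0.5
    low_class: str = "low"
    high_class: str = "high"
    training_expr: pd.DataFrame | None = None
    training_labels: pd.Series | None = None
    pooled_variance: bool = True

    def __post_init__(self) -> None:
        if len(self.weights) == 0:
            raise InvalidArgumentError("model weights empty")
        if not (self.sigma > 0):
            raise DegenerateTrainingError("pooled SD of compound covariate is zero")
        if not (0 < self.prior_low < 1):
            raise InvalidArgumentError("prior must be in (0,1)")
        if not (0 < self.cutoff < 1):
            raise InvalidArgumentError("cutoff must be in (0,1)")

    # -- persistence: a single versioned text file ---------------------------
    def to_text(self, path: str | Path) -> None:
        lines = [f"#bccp_model\tversion={MODEL_FORMAT_VERSION}",
                 f"#mu_low\t{self.mu_low:.12g}",
                 f"#mu_high\t{self.mu_high:.12g}",
                 f"#sigma\t{self.sigma:.12g}",
                 f"#prior_low\t{self.prior_low:.12g}",
                 f"#cutoff\t{self.cutoff:.12g}",
                 f"#low_class\t{self.low_class}",
                 f"#high_class\t{self.high_class}",
                 "#weights\tgene_id\tweight"]
        for g, w in self.weights.items():
            lines.append(f"W\t{g}\t{w:.12g}")
        if self.training_expr is not None:
            lines.append("#training\tgene_id\t" + "\t".join(self.training_expr.columns))
            lines.append("L\t-\t" + "\t".join(self.training_labels[c]
                                              for c in self.training_expr.columns))
            for g, row in self.training_expr.iterrows():
                lines.append("T\t" + str(g) + "\t"
                             + "\t".join(f"{v:.12g}" for v in row.to_numpy()))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_text(cls, path: str | Path) -> "BCCPModel":
        header: dict[str, str] = {}
        weights: dict[str, float] = {}
        train_cols: list[str] | None = None
        train_rows: dict[str, list[float]] = {}
        labels: list[str] | None = None
        for line in Path(path).read_text().splitlines():
            if not line:
                continue
            fields = line.split("\t")
            if line.startswith("#training"):
                train_cols = fields[2:]
            elif line.startswith("#") and len(fields) >= 2 and not line.startswith("#weights"):
                header[fields[0][1:]] = fields[1]
            elif fields[0] == "W":
                weights[fields[1]] = float(fields[2])
            elif fields[0] == "L":
                labels = fields[2:]
            elif fields[0] == "T":
                train_rows[fields[1]] = [float(v) for v in fields[2:]]
        training_expr = None
        training_labels = None
        if train_cols is not None:
            training_expr = pd.DataFrame.from_dict(train_rows, orient="index",
                                                   columns=train_cols)
            training_labels = pd.Series(labels, index=train_cols)
        return cls(weights=pd.Series(weights),
                   mu_low=float(header["mu_low"]), mu_high=float(header["mu_high"]),
                   sigma=float(header["sigma"]), prior_low=float(header["prior_low"]),
                   cutoff=float(header["cutoff"]), low_class=header["low_class"],
                   high_class=header["high_class"],
                   training_expr=training_expr, training_labels=training_labels)


def compound_covariate(expr: pd.DataFrame, weights: pd.Series) -> pd.Series:
    """c_s = sum_j w_j x_{js} over the weight genes (all must be present)."""
    missing = weights.index.difference(expr.index)
    if len(missing):
        raise InsufficientOverlapError(f"genes missing from matrix: {list(missing)[:5]}")
    x = expr.loc[weights.index].to_numpy(dtype=float)
    return pd.Series(weights.to_numpy() @ x, index=expr.columns, name="compound_covariate")


def _class_params(c: pd.Series, labels: pd.Series, low_class: str, high_class: str,
                  pooled: bool = True) -> tuple[float, float, float]:
    c_low = c[labels[labels == low_class].index].to_numpy()
    c_high = c[labels[labels == high_class].index].to_numpy()
    mu_low = float(c_low.mean())
    mu_high = float(c_high.mean())
    if pooled:
        n_l, n_h = len(c_low), len(c_high)
        sp2 = (((n_l - 1) * c_low.var(ddof=1) + (n_h - 1) * c_high.var(ddof=1))
               / (n_l + n_h - 2))
        sigma = float(np.sqrt(sp2))
    else:
        sigma = float(np.sqrt((c_low.var(ddof=1) + c_high.var(ddof=1)) / 2))
    return mu_low, mu_high, sigma


def fit_bccp(expr: pd.DataFrame, labels: pd.Series, sig: GeneSignature,
             low_class: str, prior_low: float = 0.5, cutoff: float = 0.5,
             pooled_variance: bool = True) -> BCCPModel:
    """Fit the BCCP on a labeled training matrix.

    ``low_class`` names the label treated as signature-low (e.g. "KO").
    Signature genes absent from the matrix are dropped with a warning; fewer
    than 2 usable genes raises :class:`InsufficientOverlapError`.
    """
    if len(sig) == 0:
        raise EmptySignatureError("cannot fit BCCP on an empty signature")
    labels = labels.astype(str)
    classes = sorted(labels.unique())
    if low_class not in classes or len(classes) != 2:
        raise InvalidArgumentError(f"low_class {low_class!r} not one of two classes {classes}")
    high_class = next(c for c in classes if c != low_class)
    if (labels == low_class).sum() < 2 or (labels == high_class).sum() < 2:
        raise InsufficientReplicationError("each class needs >= 2 samples")

    present = sig.entries.index.intersection(expr.index)
    n_missing = len(sig) - len(present)
    if n_missing:
        logger.warning("fit_bccp: %d signature genes absent from training matrix",
                       n_missing)
    if len(present) < min(2, len(sig)):
        raise InsufficientOverlapError(
            f"only {len(present)} of {len(sig)} signature genes present")
    weights = sig.weights.loc[present]

    train = expr.loc[present, labels.index]
    c = compound_covariate(train, weights)
    mu_low, mu_high, sigma = _class_params(c, labels, low_class, high_class,
                                           pooled=pooled_variance)
    if not (sigma > 0):
        raise DegenerateTrainingError("training compound covariate has zero spread")
    return BCCPModel(weights=weights, mu_low=mu_low, mu_high=mu_high, sigma=sigma,
                     prior_low=prior_low, cutoff=cutoff,
                     low_class=low_class, high_class=high_class,
                     training_expr=train, training_labels=labels,
                     pooled_variance=pooled_variance)


def posterior_low(c, mu_low: float, mu_high: float, sigma: float,
                  prior_low: float = 0.5) -> np.ndarray:
    """P(low | c) under the two Gaussian class-conditional densities,
    computed in log space."""
    c = np.asarray(c, dtype=float)
    log_lo = np.log(prior_low) - 0.5 * ((c - mu_low) / sigma) ** 2
    log_hi = np.log1p(-prior_low) - 0.5 * ((c - mu_high) / sigma) ** 2
    both = np.stack([log_lo, log_hi])
    return np.exp(log_lo - logsumexp(both, axis=0))


@dataclass
class CohortClassification:
    """Per-sample posterior and dichotomized label for one cohort."""

    table: pd.DataFrame  # columns: compound_covariate, posterior_low, label
    genes_used: int
    genes_requested: int

    @property
    def labels(self) -> pd.Series:
        return self.table["label"]

    @property
    def n_low(self) -> int:
        return int((self.table["label"] == "signature-low").sum())

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out["genes_used"] = self.genes_used
        out.to_csv(path, sep="\t", index_label="sample_id", float_format="%.10g")


def classify_cohort(model: BCCPModel, expr: pd.DataFrame) -> CohortClassification:
    """Classify a (pre-centered) cohort with a fitted BCCP model.

    The model is restricted to the genes the cohort shares with the signature;
    class-conditional parameters are recomputed from the cached training data
    on that same subset.
    """
    present = model.weights.index.intersection(expr.index)
    if len(present) < min(2, len(model.weights)):
        raise InsufficientOverlapError(
            f"only {len(present)} of {len(model.weights)} model genes present in cohort")

    weights = model.weights.loc[present]
    if len(present) < len(model.weights):
        if model.training_expr is None:
            raise InsufficientOverlapError(
                "gene subset requested but model carries no cached training data")
        c_train = compound_covariate(model.training_expr.loc[present], weights)
        mu_low, mu_high, sigma = _class_params(
            c_train, model.training_labels, model.low_class, model.high_class,
            pooled=model.pooled_variance)
        if not (sigma > 0):
            raise DegenerateTrainingError("reduced-gene training covariate degenerate")
        logger.info("classify: restricted model from %d to %d genes",
                    len(model.weights), len(present))
    else:
        mu_low, mu_high, sigma = model.mu_low, model.mu_high, model.sigma

    c = compound_covariate(expr.loc[present], weights)
    post = posterior_low(c.to_numpy(), mu_low, mu_high, sigma, model.prior_low)
    label = np.where(post > model.cutoff, "signature-low", "signature-high")
    table = pd.DataFrame({"compound_covariate": c, "posterior_low": post,
                          "label": label}, index=expr.columns)
    return CohortClassification(table=table, genes_used=int(len(present)),
                                genes_requested=int(len(model.weights)))


def loocv_misclassification(expr: pd.DataFrame, labels: pd.Series, low_class: str,
                            p_threshold: float = 0.05, lfc_threshold: float = 0.5,
                            classes: tuple[str, str] | None = None,
                            ) -> tuple[float, pd.DataFrame]:
    """Leave-one-out misclassification rate of the full procedure.

    For every held-out sample the entire pipeline — gene statistics, signature
    thresholding, BCCP fit — is re-run on the remaining samples, so gene
    selection happens inside each fold (no selection bias). A fold whose
    signature comes out empty counts its held-out sample as misclassified.

    Returns (rate, per-fold table with predicted/true labels).
    """
    labels = labels.astype(str)
    if expr.shape[1] < 3:
        raise InvalidArgumentError("LOOCV needs at least 3 samples")
    rows = []
    for held in labels.index:
        rest = labels.drop(held)
        try:
            stats = compute_gene_stats(expr[rest.index], rest, classes=classes)
            sig = derive_signature(stats, p_threshold, lfc_threshold)
            model = fit_bccp(expr[rest.index], rest, sig, low_class=low_class)
            c = compound_covariate(expr.loc[model.weights.index, [held]], model.weights)
            post = float(posterior_low(c.to_numpy(), model.mu_low, model.mu_high,
                                       model.sigma, model.prior_low)[0])
            pred = low_class if post > model.cutoff else model.high_class
            rows.append((held, labels[held], pred, post, len(model.weights), ""))
        except (EmptySignatureError, InsufficientReplicationError,
                InsufficientOverlapError, DegenerateTrainingError) as exc:
            logger.warning("LOOCV fold %s failed (%s); counted as misclassified",
                           held, type(exc).__name__)
            rows.append((held, labels[held], "<failed>", np.nan, 0,
                         type(exc).__name__))
    folds = pd.DataFrame(rows, columns=["sample_id", "true", "predicted",
                                        "posterior_low", "n_genes", "error"]
                         ).set_index("sample_id")
    rate = float((folds["true"] != folds["predicted"]).mean())
    return rate, folds
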