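"""Co-occurrence of the signature-low subtype with other molecular subtypes.

Two binary sample labelings are cross-tabulated into a 2x2 table over their
sample intersection, and association is tested with the Pearson chi-square
test (no Yates correction by default, available by flag) or Fisher's exact
test for small counts. Other subtype labels (NCIP A/B, hepatic stem cell,
silence-of-Hippo, SNUR) are inputs — they come from their own papers'
classifiers and are never re-derived here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.contingency_tables import Table2x2

from .errors import DegenerateTableError, InvalidArgumentError


@dataclass
class ContingencyTable2x2:
    """Counts a,b / c,d: rows = first labeling (e.g. low/high), columns =
    second labeling (e.g. poor/good prognosis subtype)."""

    a: int
    b: int
    c: int
    d: int
    row_names: tuple[str, str] = ("low", "high")
    col_names: tuple[str, str] = ("poor", "good")
    n_excluded: int = 0

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in counts):
            raise InvalidArgumentError("counts must be non-negative")
        if sum(counts) == 0:
            raise InvalidArgumentError("table total must be positive")

    @property
    def counts(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    @property
    def row_percentages(self) -> np.ndarray:
        """Percent of each row falling in the first column (and its complement)."""
        t = self.counts
        return 100.0 * t / t.sum(axis=1, keepdims=True)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts.astype(int), index=list(self.row_names),
                            columns=list(self.col_names))


def crosstab(groups_a: pd.Series, groups_b: pd.Series,
             row_order: tuple[str, str] | None = None,
             col_order: tuple[str, str] | None = None) -> ContingencyTable2x2:
    """Cross-tabulate two binary labelings over their sample intersection.

    Samples missing from either labeling are excluded and counted in
    ``n_excluded``. Row/column category order defaults to sorted labels;
    pass ``row_order``/``col_order`` to pin e.g. ("signature-low",
    "signature-high") x ("poor", "good").
    """
    a = groups_a.dropna().astype(str)
    b = groups_b.dropna().astype(str)
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise InvalidArgumentError("labelings share no samples")
    n_excluded = len(set(a.index) | set(b.index)) - len(common)
    a, b = a[common], b[common]
    rows = row_order or tuple(sorted(a.unique()))
    cols = col_order or tuple(sorted(b.unique()))
    if len(rows) != 2 or len(cols) != 2:
        raise InvalidArgumentError("both labelings must be binary")
    ct = pd.crosstab(a, b).reindex(index=list(rows), columns=list(cols), fill_value=0)
    return ContingencyTable2x2(
        a=int(ct.iloc[0, 0]), b=int(ct.iloc[0, 1]),
        c=int(ct.iloc[1, 0]), d=int(ct.iloc[1, 1]),
        row_names=tuple(rows), col_names=tuple(cols), n_excluded=n_excluded)


@dataclass
class AssociationResult:
    statistic: float
    p_value: float
    df: int
    expected: np.ndarray
    row_percentages: np.ndarray
    odds_ratio: float
    or_ci: tuple[float, float]
    small_expected_warning: bool = False


def _check_margins(table: ContingencyTable2x2) -> None:
    t = table.counts
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DegenerateTableError("table has an all-zero row or column")


def chi_square_test(table: ContingencyTable2x2, correction: bool = False) -> AssociationResult:
    """Pearson chi-square on a 2x2 table, df=1.

    Yates continuity correction is off by default; any expected count < 5
    sets ``small_expected_warning`` recommending Fisher's exact test.
    """
    _check_margins(table)
    stat, p, dof, expected = sps.chi2_contingency(table.counts, correction=correction)
    t = table.counts
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = Table2x2(t)
        odds = float(t2.oddsratio)
        ci = tuple(float(v) for v in t2.oddsratio_confint(0.05))
    return AssociationResult(
        statistic=float(stat), p_value=float(p), df=int(dof), expected=expected,
        row_percentages=table.row_percentages, odds_ratio=odds, or_ci=ci,
        small_expected_warning=bool((expected < 5).any()))


def fisher_exact(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities of
    tables (with the observed margins) no more likely than the observed one."""
    _check_margins(table)
    _, p = sps.fisher_exact(table.counts, alternative="two-sided")
    return float(p)


def association_report(name: str, table: ContingencyTable2x2,
                       result: AssociationResult) -> str:
    """Human-readable block summarizing one signature-pair comparison."""
    rp = result.row_percentages
    lines = [f"== {name} ==",
             table.to_frame().to_string(),
             (f"{table.row_names[0]}: {table.a}/{table.a + table.b} "
              f"({rp[0, 0]:.1f}%) in {table.col_names[0]}"),
             (f"{table.row_names[1]}: {table.c}/{table.c + table.d} "
              f"({rp[1, 0]:.1f}%) in {table.col_names[0]}"),
             (f"chi-square = {result.statistic:.3f} (df={result.df}), "
              f"p = {result.p_value:.3g}"),
             (f"odds ratio = {result.odds_ratio:.3f} "
              f"(95% CI {result.or_ci[0]:.3f}-{result.or_ci[1]:.3f})")]
    if result.small_expected_warning:
        lines.append("warning: expected count < 5; prefer Fisher's exact test")
    if table.n_excluded:
        lines.append(f"excluded {table.n_excluded} samples missing from a labeling")
    return "\n".join(lines)
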