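"""Published count fixtures transcribed from the HCC study tables.

These are *inputs* — printed patient counts from the published cohort
analyses — kept here so prevalences, row percentages and the subtype
co-occurrence test can be recomputed from them. Percentages are never stored,
always recomputed.

Note the published tables are internally inconsistent in two places and are
transcribed verbatim: the NCIP comparison denominators (94 + 153 = 247) do
not equal the cohort's n = 242, and the cohort-2/cohort-3 sample counts are
swapped between the methods and results sections.
"""

from __future__ import annotations

from .association import ContingencyTable2x2

# signature-low prevalence: (n_low, n_total) per cohort
LOW_PREVALENCE_COUNTS: dict[str, tuple[int, int]] = {
    "cohort1": (94, 242),
    "cohort2": (63, 139),
    "cohort3": (76, 188),
    "tcga": (201, 371),
}

# NCIP co-occurrence in cohort 1: rows = signature-low/high,
# columns = NCIP A (poor prognosis) / NCIP B
NCIP_COHORT1_TABLE = ContingencyTable2x2(
    a=67, b=27, c=21, d=132,
    row_names=("signature-low", "signature-high"),
    col_names=("NCIP-A", "NCIP-B"))

# ARID1A somatic mutations in the multi-platform cohort
ARID1A_MUTATED, ARID1A_MUTATION_DENOMINATOR = 33, 367
ARID1A_VARIANT_CLASS_COUNTS = {"truncating": 24, "missense": 8, "in_frame": 1}


def prevalence_percent(n_low: int, n_total: int) -> float:
    """Percent of patients in the low group, e.g. 94/242 -> 38.8."""
    if n_total <= 0 or n_low < 0 or n_low > n_total:
        raise ValueError("need 0 <= n_low <= n_total with n_total > 0")
    return 100.0 * n_low / n_total
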