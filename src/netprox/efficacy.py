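"""Relative efficacy (RE) from adverse-event report counts.

For a drug-disease pair, adverse-event reporting systems record reaction
terms per report. RE compares the number of "drug ineffective" reports with
the count of the most common adverse reaction:

    RE = 1 - n_ineffective / n_top

RE is 1 when no ineffectiveness is reported and 0 when "drug ineffective"
is itself the most common reaction. A pair is scored only when the top
reaction has at least ``min_reports`` reports (default 10), so that the
ratio is not dominated by small-count noise. Stratified comparisons
(palliative vs non-palliative vs off-label indications, proximal vs
distant pairs) use the one-sided Mann-Whitney rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import mannwhitneyu

logger = logging.getLogger(__name__)

__all__ = [
    "EfficacyRecord",
    "relative_efficacy",
    "score_reports",
    "stratified_re_test",
    "INEFFECTIVE_REACTION",
]

#: reaction term counted as an ineffectiveness report
INEFFECTIVE_REACTION = "drug ineffective"


@dataclass
class EfficacyRecord:
    drug_id: str
    disease_id: str
    n_top: int
    n_ineffective: int
    re: float | None  # None when the pair has too few reports


def relative_efficacy(
    n_ineffective: int, n_top: int, min_reports: int = 10
) -> float | None:
    """RE = 1 - n_ineffective / n_top, clamped to [0, 1].

    Returns ``None`` (undefined) when the most common reaction has fewer
    than ``min_reports`` reports; the clamp guards the corner case where
    "drug ineffective" ties the top reaction count.
    """
    if n_ineffective < 0 or n_top < 0:
        raise ValueError("report counts must be nonnegative")
    if n_top < min_reports or n_top == 0:
        return None
    return min(1.0, max(0.0, 1.0 - n_ineffective / n_top))


def score_reports(reports: pd.DataFrame, min_reports: int = 10) -> list:
    """Aggregate a (drug_id, disease_id, reaction, count) table into records.

    ``n_top`` is the largest per-reaction count of the pair and
    ``n_ineffective`` the count of the "drug ineffective" reaction (0 when
    absent). Reaction terms are matched case-insensitively.
    """
    required = {"drug_id", "disease_id", "reaction", "count"}
    missing = required - set(reports.columns)
    if missing:
        raise ValueError(f"reports table is missing column(s) {sorted(missing)}")
    records = []
    for (drug, disease), grp in reports.groupby(["drug_id", "disease_id"], sort=True):
        counts = grp.set_index(grp["reaction"].str.lower())["count"].astype(int)
        n_top = int(counts.max())
        n_ineff = int(counts.get(INEFFECTIVE_REACTION, 0))
        records.append(
            EfficacyRecord(
                drug_id=drug,
                disease_id=disease,
                n_top=n_top,
                n_ineffective=n_ineff,
                re=relative_efficacy(n_ineff, n_top, min_reports=min_reports),
            )
        )
    return records


# default one-sided alternatives: the first-named stratum is expected to have
# *lower* RE than the second
DEFAULT_COMPARISONS = (
    ("palliative", "non_palliative"),
    ("palliative", "off_label"),
    ("distant", "proximal"),
)


def stratified_re_test(records, strata: dict, comparisons=DEFAULT_COMPARISONS) -> dict:
    """One-sided rank-sum p-values comparing RE between strata.

    ``strata`` maps ``(drug_id, disease_id)`` to a stratum label; records
    with undefined RE or without a stratum are skipped. For each comparison
    ``(low, high)`` the alternative hypothesis is that RE in ``low`` is
    stochastically smaller than in ``high`` (e.g. palliative drugs are less
    effective than non-palliative ones, distant drugs less than proximal
    ones). Exact p-values are used for small tie-free samples, the
    tie-corrected normal approximation otherwise.
    """
    values: dict[str, list] = {label: [] for label in set(strata.values())}
    for rec in records:
        if rec.re is None:
            continue
        label = strata.get((rec.drug_id, rec.disease_id))
        if label is not None:
            values[label].append(rec.re)
    out = {}
    for low, high in comparisons:
        if low not in values or high not in values:
            continue
        if not values[low] or not values[high]:
            raise ValueError(f"empty stratum in comparison {low!r} vs {high!r}")
        stat = mannwhitneyu(values[low], values[high], alternative="less")
        out[(low, high)] = float(stat.pvalue)
    return out
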