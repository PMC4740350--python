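"""Predicting side-effect-inducing proteins and adverse-vs-therapeutic proximity.

A target protein is predicted to induce a side effect when it is
over-represented among the targets of drugs exhibiting that side effect.
For every side effect reported for at least ``min_drugs`` drugs, each
target is tested with a two-sided Fisher exact test on the 2x2 drug
counts (has target / has side effect), the p-values are adjusted with
Benjamini-Hochberg within the side effect's family of tests, and targets
below the FDR threshold (default 20%) form the side-effect protein set.

Scoring a drug's proximity to such a set, side by side with its proximity
to the disease proteins, separates a plausible therapeutic association
(proximal to the disease only) from a safety caution (proximal to both).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .evaluation import ContingencyTable2x2, fisher_enrichment
from .interactome import DegreeBins, Interactome
from .proximity import PROXIMAL_CUTOFF, ProteinSet, ProximityResult, proximity_z

logger = logging.getLogger(__name__)

__all__ = [
    "TargetTest",
    "SideEffectModel",
    "AdverseTherapeuticProfile",
    "benjamini_hochberg",
    "predict_side_effect_proteins",
    "adverse_vs_therapeutic_profile",
]


@dataclass
class TargetTest:
    protein_id: str
    table: ContingencyTable2x2
    raw_p: float
    adjusted_q: float
    odds_ratio: float


@dataclass
class SideEffectModel:
    side_effect_id: str
    n_drugs: int  # drugs exhibiting the side effect in the universe
    tested_targets: list  # of TargetTest
    predicted_proteins: set

    def protein_set(self) -> ProteinSet:
        return ProteinSet(self.side_effect_id, self.predicted_proteins)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up FDR-adjusted q-values, order-preserving and capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def predict_side_effect_proteins(
    drug_targets: dict,
    drug_side_effects: dict,
    min_drugs: int = 5,
    fdr_threshold: float = 0.20,
    family: str = "per_side_effect",
    require_enrichment: bool = True,
) -> list:
    """Fisher-test enrichment of targets among drugs sharing a side effect.

    ``drug_targets`` maps drug -> set of target proteins (this defines the
    drug universe); ``drug_side_effects`` maps drug -> set of side-effect
    identifiers (drugs outside the universe are ignored). Side effects seen
    in fewer than ``min_drugs`` universe drugs are skipped. A target is
    tested for a side effect when at least one universe drug has it. The
    comparison is strict (q < threshold). ``family`` selects whether the
    BH correction runs within each side effect's tests (default) or across
    all tests globally. With ``require_enrichment`` only over-represented
    targets (sample OR > 1) can be predicted.
    """
    if not drug_targets:
        raise ValueError("empty drug universe")
    if family not in ("per_side_effect", "global"):
        raise ValueError(f"unknown BH family {family!r}")
    universe = sorted(drug_targets)
    se_drugs: dict[str, set] = {}
    for drug, ses in drug_side_effects.items():
        if drug not in drug_targets:
            logger.debug("drug %s has side effects but no targets; ignored", drug)
            continue
        for se in ses:
            se_drugs.setdefault(se, set()).add(drug)
    all_targets = sorted({t for ts in drug_targets.values() for t in ts})

    models = []
    for se in sorted(se_drugs):
        with_se = se_drugs[se]
        if len(with_se) < min_drugs:
            continue
        tests = []
        for t in all_targets:
            with_t = {d for d in universe if t in drug_targets[d]}
            a = len(with_t & with_se)
            b = len(with_t - with_se)
            c = len(with_se - with_t)
            d = len(universe) - a - b - c
            fr = fisher_enrichment(ContingencyTable2x2(a, b, c, d))
            tests.append(
                TargetTest(t, ContingencyTable2x2(a, b, c, d),
                           fr.p_two_sided, np.nan, fr.odds_ratio)
            )
        models.append(SideEffectModel(se, len(with_se), tests, set()))

    if family == "per_side_effect":
        for m in models:
            qs = benjamini_hochberg([t.raw_p for t in m.tested_targets])
            for t, q in zip(m.tested_targets, qs):
                t.adjusted_q = float(q)
    else:
        flat = [t for m in models for t in m.tested_targets]
        qs = benjamini_hochberg([t.raw_p for t in flat])
        for t, q in zip(flat, qs):
            t.adjusted_q = float(q)

    for m in models:
        m.predicted_proteins = {
            t.protein_id
            for t in m.tested_targets
            if t.adjusted_q < fdr_threshold
            and (not require_enrichment or t.odds_ratio > 1)
        }
    return models


@dataclass
class AdverseTherapeuticProfile:
    """Paired proximity of a drug to a disease and to a side-effect protein set."""

    disease: ProximityResult
    side_effect: ProximityResult | None
    caution: bool  # proximal to both the disease and the side-effect proteins
    missing_side_effect_proteins: bool = False


def adverse_vs_therapeutic_profile(
    g: Interactome,
    drug,
    disease,
    side_effect_model: SideEffectModel,
    measure: str = "closest",
    n_random: int = 1000,
    bins: DegreeBins | None = None,
    seed: int | None = None,
    cutoff: float = PROXIMAL_CUTOFF,
) -> AdverseTherapeuticProfile:
    """Score a drug against the disease proteins and the side-effect proteins.

    Both proximities use identical settings. If the side-effect model
    predicted no proteins (or none are in the network) only the disease
    proximity is computed and the profile is flagged; when the drug is
    proximal (z <= cutoff) to both sets the profile carries a caution flag,
    as proximity alone then cannot tell a treatment from an adverse effect.
    """
    rng = np.random.default_rng(seed)
    disease_res = proximity_z(
        g, disease, drug, measure=measure, n_random=n_random, bins=bins, rng=rng
    )
    disease_res.seed = seed
    se_proteins = {p for p in side_effect_model.predicted_proteins if p in g}
    if not se_proteins:
        logger.info(
            "side effect %s has no in-network predicted protein; disease-only profile",
            side_effect_model.side_effect_id,
        )
        return AdverseTherapeuticProfile(
            disease=disease_res, side_effect=None, caution=False,
            missing_side_effect_proteins=True,
        )
    se_set = ProteinSet(side_effect_model.side_effect_id, se_proteins)
    se_res = proximity_z(
        g, se_set, drug, measure=measure, n_random=n_random, bins=bins, rng=rng
    )
    se_res.seed = seed
    caution = disease_res.z <= cutoff and se_res.z <= cutoff
    return AdverseTherapeuticProfile(
        disease=disease_res, side_effect=se_res, caution=caution,
        missing_side_effect_proteins=False,
    )
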