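"""Drug-target, disease-gene and indication catalogs with curation filters.

Input tables are plain TSV:

* drug_targets:   ``drug_id  protein_id``
* disease_genes:  ``disease_id  protein_id``
* known pairs:    ``drug_id  disease_id  label_use  palliative  in_trials``
  (flag columns optional, 0/1)
* gene sets:      standard GMT (set id, description, members...)

Curation mirrors the usual network-medicine hygiene: proteins absent from
the interactome are dropped (and counted), diseases need a minimum number
of in-network genes to plausibly form a module, drugs need at least one
in-network target, and two drugs indicated for the same disease with an
identical target set are collapsed to one.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .interactome import Interactome
from .proximity import ProteinSet

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationCatalog",
    "load_catalog",
    "build_catalog",
    "enumerate_pairs",
    "overlap_category",
    "load_gene_sets",
]

KNOWN_FLAGS = ("label_use", "palliative", "in_trials")


@dataclass
class AssociationCatalog:
    """Retained drugs, diseases and annotated known indication pairs."""

    drugs: dict  # drug_id -> ProteinSet of targets
    diseases: dict  # disease_id -> ProteinSet of disease proteins
    known_pairs: dict  # (drug_id, disease_id) -> {flag: bool}
    provenance: dict = field(default_factory=dict)

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    @property
    def n_diseases(self) -> int:
        return len(self.diseases)


def _read_pairs_tsv(path, columns) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def load_catalog(
    drug_targets,
    disease_genes,
    known=None,
    g: Interactome | None = None,
    min_disease_genes: int = 20,
) -> AssociationCatalog:
    """Load the three association tables from TSV files and apply the filters."""
    dt = _read_pairs_tsv(drug_targets, ["drug_id", "protein_id"])
    dg = _read_pairs_tsv(disease_genes, ["disease_id", "protein_id"])
    targets = {d: set(grp["protein_id"]) for d, grp in dt.groupby("drug_id")}
    genes = {d: set(grp["protein_id"]) for d, grp in dg.groupby("disease_id")}
    known_map = {}
    if known is not None:
        kn = _read_pairs_tsv(known, ["drug_id", "disease_id"])
        for _, row in kn.iterrows():
            flags = {
                f: bool(int(row[f])) if f in kn.columns and pd.notna(row[f]) else False
                for f in KNOWN_FLAGS
            }
            known_map[(row["drug_id"], row["disease_id"])] = flags
    return build_catalog(targets, genes, known_map, g, min_disease_genes)


def build_catalog(
    drug_targets: dict,
    disease_genes: dict,
    known_pairs: dict | None = None,
    g: Interactome | None = None,
    min_disease_genes: int = 20,
) -> AssociationCatalog:
    """Assemble and filter a catalog from in-memory mappings.

    Filters (applied in order, all recorded in ``provenance``):

    1. proteins not in the interactome are dropped from every set;
    2. diseases with fewer than ``min_disease_genes`` in-network genes are
       removed (the floor applies after network restriction);
    3. drugs with no in-network target are removed;
    4. among drugs known-indicated for the same disease with identical
       target sets, only the lexicographically first drug is retained; a
       drug stripped of all its known indications this way is dropped.
    """
    known_pairs = dict(known_pairs or {})
    prov: dict = {"dropped_proteins": 0, "dropped_diseases": [], "dropped_drugs": []}

    def restrict(members: set) -> set:
        if g is None:
            return set(members)
        kept = {m for m in members if m in g}
        prov["dropped_proteins"] += len(members) - len(kept)
        return kept

    diseases = {}
    for did in sorted(disease_genes):
        kept = restrict(disease_genes[did])
        if len(kept) >= min_disease_genes:
            diseases[did] = ProteinSet(did, kept)
        else:
            prov["dropped_diseases"].append(did)
    drugs = {}
    for drug in sorted(drug_targets):
        kept = restrict(drug_targets[drug])
        if kept:
            drugs[drug] = ProteinSet(drug, kept)
        else:
            prov["dropped_drugs"].append(drug)

    # prune known pairs whose drug or disease did not survive
    known_pairs = {
        (dr, di): flags
        for (dr, di), flags in known_pairs.items()
        if dr in drugs and di in diseases
    }

    # per-disease duplicate-target dedup among known-indicated drugs
    had_known = {dr for dr, _ in known_pairs}
    removed_pairs = []
    for did in sorted(diseases):
        indicated = sorted(dr for dr, di in known_pairs if di == did)
        seen: dict[frozenset, str] = {}
        for dr in indicated:
            key = drugs[dr].members
            if key in seen:
                removed_pairs.append((dr, did))
            else:
                seen[key] = dr
    for pair in removed_pairs:
        del known_pairs[pair]
    prov["deduplicated_pairs"] = removed_pairs
    for dr in sorted(had_known):
        if dr in drugs and not any(d == dr for d, _ in known_pairs):
            del drugs[dr]
            prov["dropped_drugs"].append(dr)

    if not drugs or not diseases:
        raise ValueError("catalog is empty after filtering")
    logger.info(
        "catalog: %d drugs, %d diseases, %d known pairs (%d proteins dropped)",
        len(drugs), len(diseases), len(known_pairs), prov["dropped_proteins"],
    )
    return AssociationCatalog(drugs, diseases, known_pairs, prov)


def enumerate_pairs(cat: AssociationCatalog):
    """Split the full drug x disease product into known and unknown pairs.

    The two lists partition the product: ``len(known) + len(unknown) ==
    n_drugs * n_diseases``.
    """
    if not cat.drugs or not cat.diseases:
        raise ValueError("catalog is empty")
    known = sorted(cat.known_pairs)
    known_set = set(known)
    unknown = [
        (dr, di)
        for dr, di in itertools.product(sorted(cat.drugs), sorted(cat.diseases))
        if (dr, di) not in known_set
    ]
    return known, unknown


def overlap_category(cat: AssociationCatalog, drug_id: str, disease_id: str):
    """Target / disease-protein overlap class for one pair.

    Returns ``(category, count)`` with category in ``{"full_overlap",
    "partial_overlap", "no_overlap"}``: full when every target is a disease
    protein, partial when some but not all are, none otherwise.
    """
    if drug_id not in cat.drugs:
        raise KeyError(f"unknown drug {drug_id!r}")
    if disease_id not in cat.diseases:
        raise KeyError(f"unknown disease {disease_id!r}")
    T = cat.drugs[drug_id].members
    S = cat.diseases[disease_id].members
    count = len(T & S)
    if count == len(T):
        return "full_overlap", count
    if count > 0:
        return "partial_overlap", count
    return "no_overlap", 0


def load_gene_sets(path, g: Interactome | None = None, max_size: int = 50) -> list:
    """Read a GMT gene-set collection, keeping sets small enough to be specific.

    Members absent from the network are dropped; a set is retained only if,
    after restriction, it is nonempty and its *original* in-network size is
    at most ``max_size`` (large sets describe broad processes and are
    excluded from pathway ranking).
    """
    sets = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT row needs id, description and >=1 member"
                )
            set_id, members = fields[0], [m for m in fields[2:] if m]
            kept = set(members) if g is None else {m for m in members if m in g}
            if kept and len(kept) <= max_size:
                sets.append(ProteinSet(set_id, kept))
            else:
                logger.debug("gene set %s skipped (%d in-network members)",
                             set_id, len(kept))
    return sets
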