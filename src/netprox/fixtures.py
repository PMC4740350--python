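"""Synthetic interactomes with planted disease modules and drugs.

These generators emulate the statistical structure the real analysis runs
on -- a heavy-tailed connected network, diseases forming connected modules,
drugs whose targets sit at a controlled distance from a module, FAERS-style
adverse-event counts, and drug/side-effect incidence -- so that the whole
pipeline can be exercised and benchmarked without any external download.
Every generated table uses the same TSV schemas the real loaders read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .interactome import Interactome, build_degree_bins
from .proximity import ProteinSet

logger = logging.getLogger(__name__)

__all__ = [
    "FixtureSpec",
    "StandardFixture",
    "generate_network",
    "plant_disease_module",
    "plant_drug",
    "generate_reports",
    "generate_incidence",
    "standard_fixture",
    "write_fixture",
]


@dataclass
class FixtureSpec:
    """Parameters of one synthetic study.

    Defaults describe the benchmark used throughout the test suite: a
    1,000-node preferential-attachment network (m=2 edges per new node,
    mean degree ~4), three planted disease modules of 25 proteins
    (comfortably above the 20-gene disease floor), and 60 drugs with 3
    targets each -- half planted proximal (targets within one step of
    their disease module, mirroring the observed locality of therapeutic
    action), half planted far (every target at least 4 steps away).
    """

    n_nodes: int = 1000
    attachment: int = 2
    n_diseases: int = 3
    module_size: int = 25
    n_drugs: int = 60
    targets_per_drug: int = 3
    proximal_fraction: float = 0.5
    proximal_distances: tuple = (0, 1)
    far_distance: int = 4
    re_means: dict = field(
        default_factory=lambda: {"palliative": 0.55, "non_palliative": 0.9, "off_label": 0.8}
    )
    n_top_range: tuple = (20, 200)
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 50:
            raise ValueError("n_nodes must be >= 50")
        if self.module_size < 20:
            raise ValueError("module_size must be >= 20 (disease-gene floor)")


def _node_name(i: int) -> str:
    return f"G{i:04d}"


def generate_network(
    n_nodes: int = 1000, attachment: int = 2, rng=None
) -> Interactome:
    """Connected scale-free-like network via preferential attachment.

    Preferential attachment is used rather than a configuration model
    because it is connected by construction and has the heavy degree tail
    that makes degree binning matter. Node labels are zero-padded strings.
    Deterministic for a fixed seed.
    """
    if n_nodes < 50:
        raise ValueError("n_nodes must be >= 50")
    rng = np.random.default_rng(rng)
    seed = int(rng.integers(2**31 - 1))
    g = nx.barabasi_albert_graph(n_nodes, attachment, seed=seed)
    g = nx.relabel_nodes(g, {i: _node_name(i) for i in g.nodes})
    return Interactome(g)


def plant_disease_module(g: Interactome, size: int, rng=None, seed_node=None) -> ProteinSet:
    """Grow a connected node set by randomized breadth-first expansion.

    Starting from ``seed_node`` (random if omitted), neighbors of the
    current set are added one at a time, drawn uniformly from the frontier,
    until ``size`` nodes are collected. The induced subgraph is connected
    by construction.
    """
    if size > len(g):
        raise ValueError(f"module size {size} exceeds network size {len(g)}")
    rng = np.random.default_rng(rng)
    nodes = g.nodes
    if seed_node is None:
        seed_node = nodes[int(rng.integers(len(nodes)))]
    elif seed_node not in g:
        raise KeyError(f"seed node {seed_node!r} not in the network")
    module = {seed_node}
    frontier = set(g.graph.neighbors(seed_node))
    while len(module) < size:
        if not frontier:
            raise ValueError(f"component exhausted at {len(module)} nodes")
        pick = sorted(frontier)[int(rng.integers(len(frontier)))]
        module.add(pick)
        frontier |= set(g.graph.neighbors(pick))
        frontier -= module
    return ProteinSet(f"module_{seed_node}", module)


def _distance_to_module(g: Interactome, module) -> np.ndarray:
    idx = g.indices(sorted(module.members if isinstance(module, ProteinSet) else module))
    return g.distance_matrix()[idx].min(axis=0)


def plant_drug(
    g: Interactome,
    module: ProteinSet,
    planted_distance,
    targets_per_drug: int,
    rng=None,
    far_distance: int = 4,
) -> ProteinSet:
    """Target set whose members all lie in a requested distance class.

    ``planted_distance`` is 0 (inside the module), a positive integer
    (every target's closest distance to the module is exactly that), or
    ``"far"`` (every target at least ``far_distance`` away). Raises when
    the requested class is empty or too small in this network.
    """
    rng = np.random.default_rng(rng)
    dvec = _distance_to_module(g, module)
    nodes = np.array(g.nodes, dtype=object)
    if planted_distance == "far":
        mask = dvec >= far_distance
    else:
        mask = dvec == int(planted_distance)
    candidates = nodes[mask]
    if len(candidates) < targets_per_drug:
        raise ValueError(
            f"distance class {planted_distance!r} has {len(candidates)} node(s); "
            f"need {targets_per_drug}"
        )
    picks = rng.choice(len(candidates), size=targets_per_drug, replace=False)
    return ProteinSet("drug", {str(candidates[int(i)]) for i in picks})


def degree_stratified_drugs(
    g: Interactome,
    bins,
    n_drugs: int,
    targets_per_drug: int = 2,
    rng=None,
) -> dict:
    """Drug target sets spread across the degree spectrum.

    Each drug draws all its targets from one degree bin chosen uniformly
    at random among the bins, so the ensemble's mean target degree varies
    widely instead of concentrating at the low-degree mode of a scale-free
    network. This is the ensemble used to probe degree bias of distance
    measures: hubs are topologically closer to everything, so a raw
    distance anticorrelates with target degree while the degree-matched
    z-score should not.
    """
    rng = np.random.default_rng(rng)
    drugs = {}
    for j in range(n_drugs):
        _, _, members = bins.bins[int(rng.integers(len(bins.bins)))]
        if targets_per_drug > len(members):
            raise ValueError("degree bin smaller than targets_per_drug")
        picks = rng.choice(len(members), size=targets_per_drug, replace=False)
        drug_id = f"ens{j:03d}"
        drugs[drug_id] = ProteinSet(drug_id, {members[int(i)] for i in picks})
    return drugs


def generate_reports(
    pairs_with_strata: dict,
    re_means: dict,
    rng=None,
    n_top_range: tuple = (20, 200),
    dispersion: float = 1.0,
    excluded_pairs=(),
) -> pd.DataFrame:
    """FAERS-style per-pair reaction counts with stratum-controlled efficacy.

    ``pairs_with_strata`` maps (drug_id, disease_id) to a stratum label
    with an entry in ``re_means``. For each pair the most common reaction
    gets ``n_top`` reports (uniform in ``n_top_range``, always >= 10) and
    the "drug ineffective" count is Binomial(n_top, (1 - re_mean) *
    dispersion-free), so the realized RE is centred on the stratum mean.
    With ``dispersion=0`` the counts are the deterministic expectation.
    Pairs listed in ``excluded_pairs`` get fewer than 10 reports so the
    scorer flags them undefined.
    """
    rng = np.random.default_rng(rng)
    rows = []
    for (drug, disease), stratum in sorted(pairs_with_strata.items()):
        if stratum not in re_means:
            raise KeyError(f"stratum {stratum!r} has no RE mean")
        n_top = int(rng.integers(n_top_range[0], n_top_range[1] + 1))
        p_ineff = 1.0 - re_means[stratum]
        if dispersion == 0:
            n_ineff = int(round(n_top * p_ineff))
        else:
            n_ineff = int(rng.binomial(n_top, p_ineff))
        n_ineff = min(n_ineff, n_top)  # top reaction stays the top reaction
        rows.append((drug, disease, "nausea", n_top))
        if n_ineff > 0:
            rows.append((drug, disease, "drug ineffective", n_ineff))
    for drug, disease in sorted(excluded_pairs):
        rows.append((drug, disease, "nausea", 5))
    return pd.DataFrame(rows, columns=["drug_id", "disease_id", "reaction", "count"])


def generate_incidence(
    drug_targets: dict,
    side_effect_proteins: dict,
    rng=None,
    p_hit: float = 0.9,
    p_background: float = 0.05,
) -> dict:
    """Drug -> side-effect incidence driven by planted causal proteins.

    A drug exhibits a side effect with probability ``p_hit`` when it
    targets at least one of the side effect's causal proteins and with
    ``p_background`` otherwise, emulating target-mediated adverse events.
    """
    rng = np.random.default_rng(rng)
    out: dict[str, set] = {d: set() for d in drug_targets}
    for se in sorted(side_effect_proteins):
        causal = set(side_effect_proteins[se])
        for drug in sorted(drug_targets):
            p = p_hit if drug_targets[drug] & causal else p_background
            if rng.random() < p:
                out[drug].add(se)
    return out


@dataclass
class StandardFixture:
    """A fully wired synthetic study: network, catalog entities and truth."""

    spec: FixtureSpec
    network: Interactome
    diseases: dict  # disease_id -> ProteinSet
    drugs: dict  # drug_id -> ProteinSet
    known_pairs: dict  # (drug_id, disease_id) -> flags
    planted_class: dict  # drug_id -> "proximal" | "far"


def standard_fixture(spec: FixtureSpec | None = None, seed: int | None = None) -> StandardFixture:
    """Generate the benchmark study described by ``FixtureSpec``.

    Drugs are split between the planted-proximal and planted-far classes
    and assigned round-robin to the diseases; each assignment becomes a
    known pair. All randomness flows from one seed.
    """
    if spec is None:
        spec = FixtureSpec()
    if seed is not None:
        spec = FixtureSpec(**{**spec.__dict__, "seed": seed})
    rng = np.random.default_rng(spec.seed)
    g = generate_network(spec.n_nodes, spec.attachment, rng=rng)
    diseases = {}
    for i in range(spec.n_diseases):
        module = plant_disease_module(g, spec.module_size, rng=rng)
        did = f"disease{i:02d}"
        diseases[did] = ProteinSet(did, module.members)
    disease_ids = sorted(diseases)
    n_proximal = int(round(spec.n_drugs * spec.proximal_fraction))
    drugs, known, planted = {}, {}, {}
    for j in range(spec.n_drugs):
        did = disease_ids[j % len(disease_ids)]
        if j < n_proximal:
            dist = spec.proximal_distances[j % len(spec.proximal_distances)]
            cls = "proximal"
        else:
            dist = "far"
            cls = "far"
        tset = plant_drug(
            g, diseases[did], dist, spec.targets_per_drug,
            rng=rng, far_distance=spec.far_distance,
        )
        drug_id = f"drug{j:03d}"
        drugs[drug_id] = ProteinSet(drug_id, tset.members)
        known[(drug_id, did)] = {"label_use": True, "palliative": False, "in_trials": False}
        planted[drug_id] = cls
    return StandardFixture(
        spec=spec, network=g, diseases=diseases, drugs=drugs,
        known_pairs=known, planted_class=planted,
    )


def write_fixture(fixture: StandardFixture, outdir, rng=None) -> dict:
    """Write a fixture to TSV files in the schemas the loaders read.

    Emits network.tsv, disease_genes.tsv, drug_targets.tsv, known.tsv,
    reports.tsv and incidence.tsv; returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(fixture.spec.seed if rng is None else rng)
    paths = {}

    paths["network"] = outdir / "network.tsv"
    with open(paths["network"], "w") as fh:
        for e in sorted(tuple(sorted(edge)) for edge in fixture.network.edges):
            fh.write(f"{e[0]}\t{e[1]}\n")

    paths["disease_genes"] = outdir / "disease_genes.tsv"
    rows = [
        (did, p)
        for did in sorted(fixture.diseases)
        for p in sorted(fixture.diseases[did].members)
    ]
    pd.DataFrame(rows, columns=["disease_id", "protein_id"]).to_csv(
        paths["disease_genes"], sep="\t", index=False
    )

    paths["drug_targets"] = outdir / "drug_targets.tsv"
    rows = [
        (dr, p)
        for dr in sorted(fixture.drugs)
        for p in sorted(fixture.drugs[dr].members)
    ]
    pd.DataFrame(rows, columns=["drug_id", "protein_id"]).to_csv(
        paths["drug_targets"], sep="\t", index=False
    )

    paths["known"] = outdir / "known.tsv"
    rows = [
        (dr, di, int(f["label_use"]), int(f["palliative"]), int(f["in_trials"]))
        for (dr, di), f in sorted(fixture.known_pairs.items())
    ]
    pd.DataFrame(
        rows, columns=["drug_id", "disease_id", "label_use", "palliative", "in_trials"]
    ).to_csv(paths["known"], sep="\t", index=False)

    # efficacy reports: planted-far known pairs act as the palliative stratum
    strata = {
        pair: ("palliative" if fixture.planted_class[pair[0]] == "far" else "non_palliative")
        for pair in fixture.known_pairs
    }
    reports = generate_reports(strata, fixture.spec.re_means, rng=rng,
                               n_top_range=fixture.spec.n_top_range)
    paths["reports"] = outdir / "reports.tsv"
    reports.to_csv(paths["reports"], sep="\t", index=False)

    # side-effect incidence keyed to each disease module as a causal set
    se_proteins = {
        f"se_{did}": set(sorted(fixture.diseases[did].members)[:5])
        for did in sorted(fixture.diseases)
    }
    incidence = generate_incidence(
        {d: set(ps.members) for d, ps in fixture.drugs.items()}, se_proteins, rng=rng
    )
    paths["incidence"] = outdir / "incidence.tsv"
    rows = [(dr, se) for dr in sorted(incidence) for se in sorted(incidence[dr])]
    pd.DataFrame(rows, columns=["drug_id", "side_effect_id"]).to_csv(
        paths["incidence"], sep="\t", index=False
    )
    return paths
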