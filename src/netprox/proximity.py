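"""Set-set network distances and the degree-preserving randomization z-score.

Given a disease protein set S and a drug target set T on the interactome,
five topological distance measures are provided:

* ``closest``    -- mean over targets of the distance to the nearest disease
                    protein (zero only when every target is a disease protein)
* ``shortest``   -- mean over all target/disease-protein pairs
* ``kernel``     -- exponentially path-length-penalized variant,
                    -(1/|T|) sum_t ln[(1/|S|) sum_s exp(-(d(s,t)+1))]
* ``centre``     -- mean distance from the targets to the disease protein of
                    highest closeness centrality (ties averaged)
* ``separation`` -- between-set closest distance minus the mean of the two
                    within-set closest distances (self-distance infinite)

An observed distance d is standardized against a reference distribution
obtained by re-evaluating the same measure on randomly drawn node sets that
match S and T in size and degree (degree-binned sampling), giving the
relative proximity z = (d - mu) / sigma. Negative z means the drug's targets
sit closer to the disease module than degree-matched chance expects.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .interactome import DegreeBins, Interactome, build_degree_bins

logger = logging.getLogger(__name__)

MEASURES = ("closest", "shortest", "kernel", "centre", "separation")

#: classification cutoff on z below (inclusive of) which a pair is proximal
PROXIMAL_CUTOFF = -0.15
#: stricter cutoff defining "significantly proximal" pairs
SIGNIFICANT_CUTOFF = -2.0

__all__ = [
    "MEASURES",
    "PROXIMAL_CUTOFF",
    "SIGNIFICANT_CUTOFF",
    "ProteinSet",
    "ProximityResult",
    "distance",
    "distance_closest",
    "distance_shortest",
    "distance_kernel",
    "distance_centre",
    "distance_separation",
    "reference_distribution",
    "proximity_z",
    "classify_proximal",
    "drug_drug_proximity",
    "rank_pathways",
]


@dataclass(frozen=True)
class ProteinSet:
    """A named, nonempty set of node identifiers (targets, disease proteins...)."""

    id: str
    members: frozenset

    def __post_init__(self):
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValueError(f"protein set {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.members)

    def restricted_to(self, g: Interactome) -> "ProteinSet":
        """Drop members absent from the network (logged)."""
        kept = frozenset(m for m in self.members if m in g)
        dropped = len(self.members) - len(kept)
        if dropped:
            logger.info("%s: dropped %d member(s) not in the network", self.id, dropped)
        return ProteinSet(self.id, kept)


@dataclass
class ProximityResult:
    """One (source set, target set, measure) proximity evaluation."""

    source_id: str
    target_id: str
    measure: str
    d: float
    mu: float
    sigma: float
    z: float
    n_random: int
    seed: int | None = None
    degenerate: bool = False  # sigma == 0 in the reference distribution

    @property
    def classification(self) -> str:
        return classify_proximal(self.z)


def _members(s) -> list:
    if isinstance(s, ProteinSet):
        return sorted(s.members)
    return sorted(set(s))


def _set_id(s, default: str) -> str:
    return s.id if isinstance(s, ProteinSet) else default


def _check_sets(g: Interactome, *sets) -> None:
    for s in sets:
        members = _members(s)
        if not members:
            raise ValueError("protein set must be nonempty")
        missing = [m for m in members if m not in g]
        if missing:
            raise KeyError(f"node(s) not in the interactome: {missing[:5]}")


# -- batched measure kernels ------------------------------------------------
# Each takes the distance matrix D and index arrays of shape (n, |S|) and
# (n, |T|); row r is one (S', T') replicate. Returns an (n,) float vector.


def _cross(D: np.ndarray, S: np.ndarray, T: np.ndarray) -> np.ndarray:
    return D[S[:, :, None], T[:, None, :]].astype(np.float64)


def _batch_closest(D, S, T):
    return _cross(D, S, T).min(axis=1).mean(axis=1)


def _batch_shortest(D, S, T):
    return _cross(D, S, T).mean(axis=(1, 2))


def _batch_kernel(D, S, T):
    w = np.exp(-(_cross(D, S, T) + 1.0))
    return (-np.log(w.mean(axis=1))).mean(axis=1)


def _batch_centre(D, S, T, closeness: np.ndarray):
    sub = _cross(D, S, T)  # (n, |S|, |T|)
    clo = closeness[S]  # (n, |S|)
    tied = clo == clo.max(axis=1, keepdims=True)
    per_t = (sub * tied[:, :, None]).sum(axis=1) / tied.sum(axis=1)[:, None]
    return per_t.mean(axis=1)


def _within_closest_mean(D, X) -> np.ndarray:
    """Mean over set members of the distance to the nearest *other* member.

    Self-distances are treated as infinite; for singleton sets the
    within-set term is defined as 0.
    """
    n, k = X.shape
    if k == 1:
        return np.zeros(n)
    sub = D[X[:, :, None], X[:, None, :]].astype(np.float64)
    eye = np.eye(k, dtype=bool)
    sub[:, eye] = np.inf
    return sub.min(axis=2).mean(axis=1)


def _batch_separation(D, S, T):
    sub = _cross(D, S, T)  # (n, |S|, |T|)
    # between-set closest, averaged over every node of both sets
    s_to_t = sub.min(axis=2).sum(axis=1)
    t_to_s = sub.min(axis=1).sum(axis=1)
    d_st = (s_to_t + t_to_s) / (S.shape[1] + T.shape[1])
    d_ss = _within_closest_mean(D, S)
    d_tt = _within_closest_mean(D, T)
    return d_st - (d_ss + d_tt) / 2.0


def _closeness_vector(g: Interactome) -> np.ndarray:
    D = g.distance_matrix()
    n = D.shape[0]
    sums = np.where(D >= 0, D, 0).sum(axis=1, dtype=np.int64)
    reach = (D >= 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        clo = np.where(sums > 0, (reach - 1) / sums, 0.0)
    return clo


def _evaluate_batch(g: Interactome, measure: str, S: np.ndarray, T: np.ndarray) -> np.ndarray:
    D = g.distance_matrix()
    if measure == "closest":
        return _batch_closest(D, S, T)
    if measure == "shortest":
        return _batch_shortest(D, S, T)
    if measure == "kernel":
        return _batch_kernel(D, S, T)
    if measure == "centre":
        return _batch_centre(D, S, T, _closeness_vector(g))
    if measure == "separation":
        return _batch_separation(D, S, T)
    raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")


# -- public distance functions ---------------------------------------------


def distance(g: Interactome, S, T, measure: str = "closest") -> float:
    """Observed distance between disease set S and target set T."""
    _check_sets(g, S, T)
    s_idx = g.indices(_members(S))[None, :]
    t_idx = g.indices(_members(T))[None, :]
    return float(_evaluate_batch(g, measure, s_idx, t_idx)[0])


def distance_closest(g: Interactome, S, T) -> float:
    """Mean over t in T of min over s in S of d(s, t)."""
    return distance(g, S, T, "closest")


def distance_shortest(g: Interactome, S, T) -> float:
    """Mean of d(s, t) over all pairs (s, t) in S x T."""
    return distance(g, S, T, "shortest")


def distance_kernel(g: Interactome, S, T) -> float:
    """Exponential-penalty distance; longer paths contribute less."""
    return distance(g, S, T, "kernel")


def distance_centre(g: Interactome, S, T) -> float:
    """Mean distance from T to the most central member(s) of S."""
    return distance(g, S, T, "centre")


def distance_separation(g: Interactome, S, T) -> float:
    """Between-set closest distance minus mean within-set closest distance."""
    return distance(g, S, T, "separation")


# -- randomization null model ----------------------------------------------


def _grouped_indices(g: Interactome, members: list, bins: DegreeBins):
    """Group a template's members by degree bin as index arrays."""
    degree = g.degree
    groups: dict[tuple[int, int], list] = {}
    for node in members:
        lo, hi, _ = bins.bin_for_degree(degree[node])
        groups.setdefault((lo, hi), []).append(node)
    out = []
    for (lo, hi), nodes in sorted(groups.items()):
        bin_members = bins.bin_for_degree(lo)[2]
        if len(nodes) > len(bin_members):
            raise ValueError(
                f"cannot sample {len(nodes)} distinct nodes from degree bin "
                f"[{lo},{hi}) of size {len(bin_members)}"
            )
        out.append((g.indices(bin_members), len(nodes)))
    return out


def _sample_matched(groups, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n degree-matched replicates; shape (n, set size).

    Within each degree bin the draws of one replicate are distinct.
    Vectorized uniform draws with targeted redraws on the (rare) rows
    containing collisions.
    """
    columns = []
    for member_idx, count in groups:
        m = len(member_idx)
        draw = rng.integers(0, m, size=(n, count))
        if count > 1:
            bad = np.nonzero(
                (np.diff(np.sort(draw, axis=1), axis=1) == 0).any(axis=1)
            )[0]
            for r in bad:
                draw[r] = rng.choice(m, size=count, replace=False)
        columns.append(member_idx[draw])
    return np.concatenate(columns, axis=1)


def reference_distribution(
    g: Interactome,
    S,
    T,
    measure: str = "closest",
    n_random: int = 1000,
    bins: DegreeBins | None = None,
    rng: np.random.Generator | int | None = None,
):
    """Null distribution of the measure over degree-matched random set pairs.

    Both sets are randomized simultaneously and independently; each
    replicate draws a set matching S and a set matching T in size and
    degree bins. Returns ``(mu, sigma, samples)`` where sigma uses the
    population (n) denominator.
    """
    if n_random < 2:
        raise ValueError("n_random must be >= 2")
    _check_sets(g, S, T)
    if bins is None:
        bins = build_degree_bins(g)
    rng = np.random.default_rng(rng)
    s_groups = _grouped_indices(g, _members(S), bins)
    t_groups = _grouped_indices(g, _members(T), bins)
    S_rand = _sample_matched(s_groups, n_random, rng)
    T_rand = _sample_matched(t_groups, n_random, rng)
    samples = _evaluate_batch(g, measure, S_rand, T_rand)
    return float(samples.mean()), float(samples.std(ddof=0)), samples


def proximity_z(
    g: Interactome,
    S,
    T,
    measure: str = "closest",
    n_random: int = 1000,
    bins: DegreeBins | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ProximityResult:
    """Relative proximity between disease set S and drug target set T.

    ``z = (d - mu) / sigma`` against the degree-matched reference
    distribution. When the reference is degenerate (sigma == 0) the result
    is flagged: z is 0 if d equals mu and signed infinity otherwise.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    d = distance(g, S, T, measure)
    mu, sigma, _ = reference_distribution(
        g, S, T, measure, n_random=n_random, bins=bins, rng=rng
    )
    degenerate = sigma == 0.0
    if degenerate:
        z = 0.0 if d == mu else math.copysign(math.inf, d - mu)
    else:
        z = (d - mu) / sigma
    return ProximityResult(
        source_id=_set_id(T, "targets"),
        target_id=_set_id(S, "disease"),
        measure=measure,
        d=d,
        mu=mu,
        sigma=sigma,
        z=z,
        n_random=n_random,
        seed=seed,
        degenerate=degenerate,
    )


def classify_proximal(z: float, cutoff: float = PROXIMAL_CUTOFF) -> str:
    """``"proximal"`` iff z <= cutoff (boundary inclusive), else ``"distant"``.

    Passing ``cutoff=SIGNIFICANT_CUTOFF`` (-2) classifies "significantly
    proximal" pairs.
    """
    if math.isnan(z):
        raise ValueError("z is NaN")
    return "proximal" if z <= cutoff else "distant"


def drug_drug_proximity(
    g: Interactome,
    T1,
    T2,
    measure: str = "closest",
    n_random: int = 1000,
    bins: DegreeBins | None = None,
    seed: int | None = None,
) -> tuple[ProximityResult, ProximityResult]:
    """Proximity between two drugs' target sets, in both directions.

    The machinery is identical to drug-disease proximity with one drug's
    target set standing in the disease-set role; the closest measure is not
    symmetric, so both orientations are returned as ``(T1 vs T2-as-disease,
    T2 vs T1-as-disease)``.
    """
    rng = np.random.default_rng(seed)
    fwd = proximity_z(g, T2, T1, measure=measure, n_random=n_random, bins=bins, rng=rng)
    rev = proximity_z(g, T1, T2, measure=measure, n_random=n_random, bins=bins, rng=rng)
    for r in (fwd, rev):
        r.seed = seed
    return fwd, rev


def rank_pathways(
    g: Interactome,
    targets,
    pathways: Sequence[ProteinSet],
    measure: str = "closest",
    n_random: int = 1000,
    bins: DegreeBins | None = None,
    seed: int | None = None,
) -> list[ProximityResult]:
    """Rank gene sets (e.g. pathways) by their proximity to a drug's targets.

    Returns results sorted by ascending z (most proximal first).
    """
    if bins is None:
        bins = build_degree_bins(g)
    rng = np.random.default_rng(seed)
    results = []
    for pw in pathways:
        res = proximity_z(
            g, pw, targets, measure=measure, n_random=n_random, bins=bins, rng=rng
        )
        res.seed = seed
        results.append(res)
    return sorted(results, key=lambda r: r.z)
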