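# Methods

## Model

All computations run on an undirected, unweighted protein–protein
interaction network restricted to its largest connected component, so
every pairwise shortest-path distance is finite. Distances are unweighted
BFS path lengths; the implementation caches the all-pairs distance matrix
(int32, computed with `scipy.sparse.csgraph`) because every proximity
evaluation re-reads thousands of entries. This favors speed over memory
and is sized for networks up to a few tens of thousands of nodes — a
13k-node interactome needs roughly 700 MB; beyond that a per-source BFS
backend would be the right extension.

### Distance measures

For disease proteins *S* and drug targets *T*:

* **closest** — `(1/|T|) Σ_t min_s d(s,t)`. Zero iff every target is a
  disease protein. The default everywhere, as it is the best discriminator
  of known indications.
* **shortest** — `(1/|T|·|S|) Σ_t Σ_s d(s,t)`.
* **kernel** — `−(1/|T|) Σ_t ln[(1/|S|) Σ_s e^{−(d(s,t)+1)}]`. The +1
  offset makes coincident nodes contribute `e^{−1}` rather than 1, so the
  measure stays positive; longer paths decay exponentially.
* **centre** — mean distance from the targets to the disease protein of
  maximal closeness centrality within the network; when several disease
  proteins tie, distances to all tied centres are averaged. Closeness is
  the standard normalized form `(n−1)/Σ_v d(u,v)`; any strictly monotone
  variant selects the same argmax, which is all the centre needs.
* **separation** — `⟨d_ST⟩ − (⟨d_SS⟩ + ⟨d_TT⟩)/2`, where `⟨d_ST⟩`
  averages each node's closest distance to the opposite set over all
  nodes of both sets, and the within-set terms use the modified closest
  distance with self-distance infinite. For a singleton set the
  within-set term is defined as 0 — the alternative (infinite) would make
  the measure unusable for one-target drugs, which are common. Separation
  may be negative (overlapping sets).

### Randomization null model and z-score

An observed distance is standardized against a reference distribution
obtained by redrawing **both** sets simultaneously and independently,
matching each set's size and degree composition. Nodes are grouped into
degree bins built greedily from the lowest degree upward, extending each
bin's upper bound minimally until it holds at least 100 nodes (an
undersized tail bin is merged into its predecessor). Binning prevents the
null from resampling the same few hubs, which a per-degree match would
force on a scale-free network. Within one randomized set draws are
distinct (a protein set has no duplicates); overlap *between* the two
randomized sets is allowed, since they model independently chosen groups.

With 1,000 draws (default), `z = (d − μ)/σ`, σ with the population (n)
denominator — at n = 1000 the n vs n−1 choice is far below reporting
precision. If σ = 0 (degenerate null, e.g. templates covering entire
bins, or very few draws), z is defined as 0 when d = μ and signed
infinity otherwise, flagged on the result. A pair is *proximal* when
z ≤ −0.15 (boundary inclusive) and *significantly proximal* when z ≤ −2.
Drug–drug similarity reuses the identical machinery with one drug's
targets in the disease-set role; since the closest measure is asymmetric
both orientations are reported.

All randomness flows from one caller-supplied seed (`numpy` Generator);
results are bit-reproducible at fixed seed, iteration count and library
versions.

## Catalog curation

Proteins absent from the network are dropped from every set (counted in
the provenance report). A disease is retained only with ≥ 20 in-network
genes — the floor applies after network restriction — so that it
plausibly induces a module. Drugs need ≥ 1 in-network target. Among drugs
known-indicated for the same disease with identical target sets, the
lexicographically first drug id is kept (the source data does not say
which duplicate to keep; lexicographic choice makes curation
deterministic); a drug stripped of all its known indications this way is
dropped entirely. Gene-set collections (GMT) are restricted to the
network and capped at 50 in-network members, since larger sets describe
broad processes rather than specific pathways.

## Evaluation

Proximity is "smaller is better", so all rankings score by −z. AUC is the
trapezoidal area of the ROC curve swept over distinct score values, which
equals the normalized Mann–Whitney statistic with half credit for ties.
Because unknown pairs outnumber known ones ~45:1, a balanced AUC redraws
(default) 402 negatives 100 times and reports mean ± s.d. The operating
cutoff is the point where sensitivity (`fraction of known with z ≤ c`)
and specificity (`fraction of negatives with z > c`) cross, located by
linear interpolation on a 0.05-step grid spanning the observed z range;
F-scores per grid point are returned alongside. Both all-unknown and
balanced negatives can be supplied — the choice is the caller's, as the
published analysis is ambiguous on this point.

Enrichment odds ratios are the sample (cross-product) `ad/bc` estimate,
which is how the published 2×2 enrichments are stated; the conditional
MLE from the exact test is also emitted for reference. A zero `bc` margin
yields an infinite OR with a flag.

## Relative efficacy

`RE = 1 − n_ineffective/n_top`, clamped to [0,1] because "drug
ineffective" can itself tie the top reaction. The ≥ 10-report floor
applies to the top-reaction count, not the total. Stratified comparisons
(palliative vs non-palliative vs off-label, distant vs proximal) use the
one-sided Mann–Whitney test with fixed directions (palliative lower,
distant lower); `scipy` selects the exact small-sample p-value when there
are no ties and the tie-corrected normal approximation otherwise.

## Side-effect proteins

For each side effect reported for ≥ 5 drugs of the universe (the drugs
with known targets), every protein targeted by ≥ 1 drug is tested with a
two-sided Fisher exact test on the drug counts (has target × has side
effect). BH correction is applied per side effect across its tested
targets — the wording of the source procedure supports per-side-effect
families, and a global-family mode is available via `family="global"`.
Prediction requires q strictly < 0.20 *and* sample OR > 1: the two-sided
test would otherwise also flag significantly depleted targets, which
cannot sensibly "induce" the effect. The adverse-vs-therapeutic profile
computes z to the disease proteins and to the predicted side-effect
proteins with identical settings; proximity to both raises a caution
flag, and an empty predicted set yields a flagged disease-only profile.

## Synthetic data

The generators emulate the statistical shape of the real inputs, not
their content:

* **network** — preferential attachment (default 1,000 nodes, m = 2,
  mean degree ≈ 4), chosen over a configuration model because it is
  connected by construction and heavy-tailed, so degree binning matters.
  Real curated interactomes are denser and carry literature bias toward
  well-studied proteins; neither is replicated.
* **disease modules** — randomized BFS growth from a random seed node,
  giving connected 25-node modules (above the 20-gene floor).
* **drugs** — 3 targets each, drawn from an exact distance class around
  a module: planted-proximal drugs alternate classes 0 and 1 (mirroring
  the observed locality of therapeutic action within two links);
  planted-far drugs take every target ≥ 4 steps away. On 1,000-node
  m = 2 graphs the ≥ 4 class reliably holds a few dozen nodes; the small
  studies used in smoke tests shrink the far threshold to 3, since
  400-node graphs have no distance-4 periphery.
* **degree-stratified ensemble** — for bias analyses, each drug draws
  its targets from one randomly chosen degree bin, spreading mean target
  degree across the spectrum instead of concentrating at the scale-free
  mode; uniform sampling would leave too few high-degree drugs for a
  rank correlation to resolve the hub effect.
* **reports / incidence** — binomial "drug ineffective" counts around
  stratum RE means (palliative 0.55, non-palliative 0.9, off-label 0.8)
  with the top reaction count uniform in [20, 200]; side-effect
  incidence is target-mediated (probability 0.9 when a drug hits a
  causal protein, 0.05 background).

Passing the planted-recovery benchmark shows the machinery separates
module-directed from remote target sets under a degree-matched null; it
does not certify performance on real curated catalogs, whose label noise,
incompleteness and bias the fixtures deliberately omit.

## Problem sizes and numerical choices

The benchmark study (1,000 nodes, 3 × 25-protein modules, 60 drugs,
1,000 null draws per pair) and the 200-drug bias ensemble (500 draws per
drug) run in seconds thanks to the cached distance matrix and vectorized
batch sampling; these sizes give Monte-Carlo error well below the effect
sizes being asserted. Exact-enumeration checks use C6, where the null for
singleton sets is uniform over all 36 ordered node pairs (μ = 1.5,
σ ≈ 0.9574). Ties in closeness for the centre measure are detected by
exact float equality, which is safe because tied closeness arises from
identical integer distance sums. Degenerate inputs (empty sets,
out-of-network nodes, single-class ROC labels, zero-margin tables,
undefined RE) raise or flag rather than returning silent defaults.

## Known limitations

* Dense distance-matrix caching bounds the practical network size.
* Weighted or directed networks, diffusion/random-walk proximity and
  drug-combination proximity are out of scope.
* The AUC-difference comparison between measures is not implemented as a
  DeLong test; rankings can be compared by their balanced-AUC resampling
  distributions instead.
* Identifier vocabularies are taken verbatim; no cross-vocabulary name
  normalization is attempted.
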