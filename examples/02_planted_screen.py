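"""Drug-repurposing screen on a synthetic study with planted ground truth.

Generates the benchmark study (1,000-node scale-free network, 3 disease
modules of 25 proteins, 60 drugs: half with targets inside/beside their
disease module, half targeting a remote region), scores every known pair,
and evaluates how well relative proximity recovers the planted classes.
"""

import numpy as np

from netprox import balanced_auc, build_degree_bins, classify_proximal, optimal_cutoff, proximity_z
from netprox.fixtures import FixtureSpec, standard_fixture

fx = standard_fixture(FixtureSpec(seed=0))
g = fx.network
bins = build_degree_bins(g)
print(f"network: {len(g)} proteins, {g.number_of_edges()} interactions")
print(f"{len(fx.diseases)} diseases x {len(fx.drugs)} drugs, "
      f"{len(fx.known_pairs)} known pairs\n")

rng = np.random.default_rng(123)
z = {}
for dr, di in sorted(fx.known_pairs):
    z[dr] = proximity_z(g, fx.diseases[di], fx.drugs[dr],
                        n_random=1000, bins=bins, rng=rng).z

prox = sorted(dr for dr in z if fx.planted_class[dr] == "proximal")
far = sorted(dr for dr in z if fx.planted_class[dr] == "far")
print(f"planted proximal drugs: mean z = {np.mean([z[d] for d in prox]):+.2f}")
print(f"planted far drugs:      mean z = {np.mean([z[d] for d in far]):+.2f}")

sens = np.mean([classify_proximal(z[d]) == "proximal" for d in prox])
spec = np.mean([classify_proximal(z[d]) == "distant" for d in far])
mean_auc, sd_auc = balanced_auc([-z[d] for d in prox], [-z[d] for d in far],
                                n_neg=len(far), reps=50, rng=rng)
cut = optimal_cutoff([z[d] for d in prox], [z[d] for d in far])
print(f"\nclassification at z <= -0.15: sensitivity {sens:.2f}, "
      f"specificity {spec:.2f}")
print(f"balanced AUC = {mean_auc:.3f} +/- {sd_auc:.3f}")
print(f"sensitivity/specificity curves cross at z* = {cut.cutoff:+.2f}")
print("\nAUC near 1 means z separates drugs aimed at the disease module")
print("from drugs targeting an unrelated part of the interactome.")
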