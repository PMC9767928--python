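"""Rank every enzyme by upstream/downstream footprint imbalance.

Joins each enzyme's signed dissipation weights with the differential
t-values and computes the imbalance score sum(w*t)/sum(|w|): a large
positive score means the enzyme's downstream metabolites accumulate while
its upstream metabolites deplete — the signature of a flux-limiting
perturbation at that enzyme.
"""

from ocean import (
    FixtureSpec,
    build_forest,
    build_instance_graph,
    collapse_to_base_names,
    default_planted_root,
    differential_pipeline,
    footprint_scatter,
    imbalance_scores,
    signed_weights,
)
from ocean.simulate import make_abundances, make_network

spec = FixtureSpec(topology="chain", n_species=8, seed=7, effect_size=3.0)
network = make_network(spec)
root = default_planted_root(network)
spec = FixtureSpec(topology="chain", n_species=8, seed=7, effect_size=3.0,
                   planted_enzyme=root)
matrix, _ = make_abundances(spec, network)
stats = differential_pipeline(matrix, ("CASE", "CTRL"))

weights = signed_weights(build_forest(build_instance_graph(network)), 0.8)
weights = collapse_to_base_names(weights, network.base_names(), 0.8)

scores = imbalance_scores(weights, stats)
print("enzymes ranked by |imbalance|   (perturbed:", root + ")")
print(scores.round(3).to_string())
print()
scatter = footprint_scatter(weights, stats, None, root)
print("footprint scatter of the top enzyme (dot_size = |t x weight|):")
print(scatter.round(3).to_string(index=False))
print()
print("The perturbed enzyme tops the ranking: every metabolite downstream of")
print("it has positive weight and positive t, every upstream one negative")
print("weight and negative t, so the products w*t all align.")
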