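"""Detect regulatory path motifs on simulated perturbation data.

Builds a synthetic integrated network (directed TRI and PhI layers, an
undirected PPI layer) with a planted PPI-TRI motif — each perturbed
cause reaches 8 of its differentially expressed targets through one
protein partner — plus 20 noise targets per cause, then scores all 39
path types of length up to three under both null models.
"""

from pathmotifs import (
    SyntheticSpec,
    all_path_types,
    network_enrichment_many,
    perturbation_enrichment_many,
    simulate,
)

spec = SyntheticSpec(seed=7)
net, ce, truth = simulate(spec)
print(f"integrated network: " + ", ".join(
    f"{lab} {len(layer)} edges" for lab, layer in net.layers.items()))
print(f"cause-effect data: {len(ce.causes)} causes, {ce.n_pairs} pairs "
      f"({len(truth)} planted)")

types = all_path_types(net.labels, max_length=3)
perturb = perturbation_enrichment_many(net, ce, types, n_random=999, seed=1)
network = network_enrichment_many(net, ce, types, n_random=999, seed=1)

print(f"\n{'type':<14}{'observed':>9}{'null mean':>11}{'p (perturb)':>13}{'p (network)':>13}")
net_by_type = {r.path_type: r for r in network}
for r in sorted(perturb, key=lambda r: r.p_value)[:5]:
    rn = net_by_type[r.path_type]
    print(f"{r.path_type.name:<14}{r.observed:>9}{r.null_mean:>11.1f}"
          f"{r.p_value:>13.2e}{rn.p_value:>13.2e}")

sig = {r.path_type.name for r in perturb if r.p_value < 0.01} & \
      {r.path_type.name for r in network if r.p_value < 0.01}
print(f"\nmotifs flagged by BOTH null models at p < 0.01: {sorted(sig)}")
print("A type is a motif when real perturbed genes are reached by its paths")
print("far more often than random gene sets (perturbation null) and than")
print("degree-matched rewired path projections (network null).")
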