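"""Per-cause path specificity and overall coverage summaries.

For each perturbed cause, a hypergeometric test asks whether the genes
reachable from it by one path type overlap its differentially
expressed targets more than chance; coverage summaries report which
fraction of all cause-effect pairs the enriched motifs explain and how
that explanation splits across motifs.
"""

from pathmotifs import (
    PathType,
    SyntheticSpec,
    fraction_explained,
    motif_abundance,
    per_cause_specificity,
    simulate,
)

spec = SyntheticSpec(seed=7)
net, ce, _ = simulate(spec)

types = [PathType.parse(n) for n in
         ["TRI", "PPI-TRI", "TRI-TRI", "PPI-PPI-TRI", "PPI-PhI-TRI"]]
table = per_cause_specificity(net, ce, types)
print("most specific path per cause (hypergeometric reach test):")
best = table.groupby("cause", sort=True).head(1)
print(best.to_string(index=False))

enriched = [PathType.parse("PPI-TRI")]
frac = fraction_explained(ce, net, enriched)
print(f"\nPPI-TRI explains {100 * frac:.1f}% of the {ce.n_pairs} "
      "cause-effect pairs")

fractions = motif_abundance(ce, net, types)
print("\nrelative share of explained (pair, type) assignments:")
for pt, f in sorted(fractions.items(), key=lambda kv: -kv[1]):
    print(f"  {pt.name:<14}{100 * f:5.1f}%")
print("The planted PPI-TRI path dominates per-cause specificity, while the")
print("remaining shares reflect chance connections through the sparse layers.")
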