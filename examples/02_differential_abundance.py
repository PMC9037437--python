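"""Detect Severe-enriched taxa with rarefaction, filters and Cliff's delta.

Generates an overdispersed 300-taxon community with 12 planted
Severe-enriched species (log2 fold change 2, mirroring the Bacteroidia
signature), runs the standard pipeline — rarefy to 48,000 reads with
seed 711, drop taxa under 20 % prevalence, renormalize, keep taxa above
0.1 % mean abundance — and prints the detected taxa.
"""

import pandas as pd

import baripath as bp
from baripath.synthetic_data import default_planted_taxa

labels = pd.Series(["Severe"] * 30 + ["Mild"] * 30,
                   index=[f"S{i:02d}" for i in range(60)], name="group")
spec = bp.CommunitySpec(n_taxa=300, planted_taxa=default_planted_taxa(12, 2.0),
                        depth_mean=50_000, seed=711)
cm = bp.generate_counts(spec, labels)

cm = bp.filter_prevalence(bp.rarefy(cm, 48_000, seed=711), 0.20)
rel = bp.relative_abundance(cm)
rel = rel.loc[bp.filter_mean_abundance(rel, 0.001)]
print(f"{rel.shape[0]} taxa survive the prevalence and abundance filters")

res = bp.differential_abundance(rel, labels)
hits = res[res["q"] < 0.1].sort_values("delta", ascending=False)
planted = {t for t, _ in spec.planted_taxa}
print(f"\n{len(hits)} taxa at q < 0.1 "
      f"({sum(t in planted for t in hits.index)}/12 planted recovered):")
print(hits[["delta", "ci_low", "ci_high", "p_welch", "q"]].round(4).to_string())
print("\npositive delta = enriched in the Severe group; the CI is the")
print("95% interval on Cliff's delta, q the BH-adjusted Welch p-value")

D = bp.bray_curtis(bp.relative_abundance(bp.aggregate_rank(cm, "genus")))
db = bp.dbrda_univariate(D, labels.eq("Severe").astype(float), seed=711)
print(f"\ndbRDA: cluster explains {db['r2_adj_pct']:.2f}% of genus-level "
      f"community variation (p = {db['p']:.3f})")
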