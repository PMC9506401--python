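"""Descriptive summaries: phylum roll-ups, richness, PCA, ordered heatmaps.

Shows the figure-style data products: phylum composition of the uncommon
community, per-group OTU richness, binary PCA of presence profiles, and a
Bray-Curtis-ordered, colour-binned heatmap with plant-grouping detection.
"""

import rarebiome as rb
from rarebiome import summaries
from rarebiome.summaries import richness

sim = rb.simulate(rb.SimulationConfig(rng_seed=0))
res = rb.run_marker(sim.counts["ITS"], sim.metadata, sim.taxonomy["ITS"])
rel, pres = res.rel, res.pres

unc = res.uncommon[("root", "soil")]
ps = summaries.phylum_rollup(rel, unc, sim.taxonomy["ITS"])
print(f"soil-grown roots: {ps.total_uncommon} uncommon OTUs "
      f"({ps.percent_uncommon_of_total:.0f}% of the compartment's OTUs)")
for ph, n in sorted(ps.n_otus.items(), key=lambda kv: -kv[1]):
    print(f"  {ph:20s} {n:3d} OTUs, {ps.mean_read_percent[ph]:5.1f}% of reads on average")

substrate = pres.values.index.get_level_values("substrate")
rich = richness(pres.values).groupby(substrate).mean()
print("\nmean OTU richness per collapsed group:")
print(rich.round(1).to_string())

scores, ev = summaries.binary_pca(pres.values.astype(int))
print(f"binary PCA: PC1 explains {ev[0] / ev.sum():.0%} of presence variance")

# Bray-Curtis-ordered heatmap of soil-grown roots, with plant groupings
comp_sand = rel.compartment("root", "sand")
comp_soil = rel.compartment("root", "soil")
both = comp_sand.add_suffix("").set_axis([f"{h}-sand" for h in comp_sand.index]).T.join(
    comp_soil.set_axis([f"{h}-soil" for h in comp_soil.index]).T
).T
d = summaries.bray_curtis_matrix(both)
order, _ = summaries.cluster_order(d)
labels = {lbl: tuple(lbl.rsplit("-", 1)) for lbl in both.index}
grouped_hosts = summaries.detect_plant_groupings(order, labels)
print(f"hosts whose sand/soil root samples cluster together "
      f"(seed-transmission signature): {grouped_hosts}")
binned = summaries.bin_heatmap_frame(both)
print(f"heatmap bin matrix shape {binned.shape}; bins 0..6 "
      "(0%, <=0.1, <=0.25, <=0.5, <=1, <=5, >5)")
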