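"""Screen a compartment for uncommon and abundant-uncommon OTUs.

Uncommon = detected in at most 9 of the 17 host species of a compartment
(occupancy below 53%); abundant-uncommon additionally exceeds a peak
relative abundance of 5% in at least one host group.
"""

import rarebiome as rb

sim = rb.simulate(rb.SimulationConfig(rng_seed=0))
grouped = rb.collapse_replicates(sim.counts["ITS"], sim.metadata)
rel = rb.relative_abundance(grouped, "ITS")
pres = rb.presence(rel, 0.0)

occ = rb.species_occupancy(pres, "root", "soil")
unc = rb.screen_uncommon(occ, max_hosts=9)
cutoff = rb.occupancy_cutoff_fraction(17, 9)
print(f"soil-grown roots: {len(occ)} OTUs detected, "
      f"{len(unc.otu_ids)} uncommon (occupancy <= {cutoff:.1%})")

abundant = rb.screen_abundant(rel, unc, min_peak_percent=5.0)
print(f"abundant-uncommon (> 5% peak): {len(abundant)} OTUs, e.g. {abundant[:4]}")

top = rb.top_uncommon(rel, unc, n=40)
print(f"top-40 most abundant uncommon OTUs (heatmap rows), first 5: {top[:5]}")
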