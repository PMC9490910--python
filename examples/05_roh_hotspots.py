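"""Detect runs of homozygosity and their population-level hotspots.

ROH use the scanning-window protocol (50-SNP window, 1 het allowed,
>= 65 SNPs, >= 1 Mb, >= 1 SNP per 50 kb); hotspots are SNPs whose ROH
occurrence reaches the top 0.5% — islands of homozygosity that mark
putative selection.
"""

import polyselect as ps

g, samples, _ = ps.simulate(ps.SimConfig(seed=5))
segments = ps.detect_roh(g, ps.ROHParams())
print(f"{len(segments)} ROH segments in {g.n_samples} animals")
if len(segments):
    print(f"mean length {segments['length'].mean()/1e6:.2f} Mb, "
          f"mean SNPs {segments['n_snps'].mean():.0f}")

occurrence, hotspots = ps.roh_hotspots(segments, g.variants, g.n_samples,
                                       top_fraction=0.005)
print(f"{len(hotspots)} hotspot SNPs; max occurrence "
      f"{occurrence.max():.1%} of animals")
print("\nHotspot SNPs sit where many animals share long homozygous "
      "stretches — candidate swept regions.")
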