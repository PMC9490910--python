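"""Generation Proxy Selection Mapping on a selected vs a drift-only herd.

Age at the reference date is the response; the GRM absorbs drift, so
q < 0.1 discoveries mark loci moving faster than pedigree drift allows.
The drift-only control should yield (close to) none.
"""

import numpy as np

import polyselect as ps

for label, drift in (("selected herd", False), ("drift-only control", True)):
    g, samples, _ = ps.simulate(ps.SimConfig(seed=3, drift_only=drift))
    grm = ps.compute_grm(g)
    rec = ps.gpsm_scan(g, samples, grm, mode="p3d")
    n_sig = int((rec["q"] < 0.1).sum())
    lam = ps.genomic_inflation(rec["p"].dropna())
    print(f"{label}: {n_sig} discoveries at q<0.1, lambda = {lam:.2f}, "
          f"min p = {np.nanmin(rec['p']):.1e}")

print("\nDiscoveries concentrate in the selected herd; lambda near 1 in "
      "the control shows the mixed model is calibrated against drift.")
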