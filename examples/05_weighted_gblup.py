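"""Iterative weighted GBLUP on a sparse genetic architecture.

When few QTL carry the genetic variance, reweighting markers by their
back-solved squared effects concentrates the kernel on the causal regions
and can beat plain GBLUP; the loop runs 4 iterations and reports the third.
"""

import numpy as np

from aquagp import mixedmodel as mm, simdata, wgblup

arch = simdata.TraitArchitecture(class_proportions=(0.997, 0, 0, 0.003), target_h2=0.25)
ds = simdata.simulate_dataset(
    n_sires=10, n_dams=5, n_blocks=2, n_families=60,
    family_size_law=("constant", 12), n_markers=2000, arch=arch, seed=5,
)
spec = mm.ModelSpec("y", ds.fixed_factors, [])
trace = wgblup.run_wgblup(ds.genotypes, ds.phenotypes, spec)

for t, pred in enumerate(trace.predictions):
    r = np.corrcoef(pred.gebv[ds.true_bv.index], ds.true_bv)[0, 1]
    w = trace.weights[t].weights
    print(f"iteration {t}: corr(GEBV, true BV) = {r:.3f}   "
          f"top-1% weight share = {np.sort(w)[-len(w)//100:].sum()/w.sum():.2f}")
print(f"reported result: iteration {trace.report_iteration}")
# Iteration 0 is plain (blended) GBLUP. Weight mass moving into the top
# percentile shows the kernel zooming in on the few large QTL.
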