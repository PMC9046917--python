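"""Quality control and naive imputation on a dataset with missing calls.

Applies the standard marker/sample filters (MAF < 0.01, call rate < 0.90,
HWE p < 1e-7, sample call rate < 0.90) and mean-imputes what remains.
"""

import numpy as np

from aquagp import genio, simdata

ds = simdata.simulate_dataset(
    n_sires=8, n_dams=4, n_blocks=2, n_families=40,
    family_size_law=("constant", 12), n_markers=1500,
    arch=simdata.TraitArchitecture(missing_rate=0.03), seed=2,
)
g = ds.genotypes
print(f"input: {g.n_samples} samples × {g.n_markers} markers, "
      f"{np.isnan(g.dosages).mean():.1%} missing")

filtered, report = genio.qc_filter(g)
print(f"removed — MAF: {report.markers_removed_maf}, "
      f"call rate: {report.markers_removed_call_rate}, "
      f"HWE: {report.markers_removed_hwe}, "
      f"samples: {report.samples_removed_call_rate}")

imputed = genio.impute_missing(filtered, "marker_mean")
print(f"after imputation: {np.isnan(imputed.dosages).sum()} missing calls; "
      f"{imputed.imputed_mask.sum()} dosages filled with 2p̂")
# Markers failing MAF here are mostly rare variants that drifted during the
# founder bottleneck; HWE removals are rare because genotypes are simulated
# under random mating.
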