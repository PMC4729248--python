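"""Expected spectra from the exact coalescent engine, and model residuals.

The engine computes, for any registered demography, the expected joint SFS
at theta = 1 (entry = half the expected branch length subtending each
configuration).  Multiplying by theta gives expected site counts, which a
Poisson draw turns into a synthetic dataset; Anscombe residuals then show
the (variance-stabilised) model-minus-data discrepancies.
"""

import numpy as np

import demosfs as d
from demosfs.synthetic_data import TRUE_TRIO_PARAMS

model = d.get_model("trio_6param")
params = np.array([TRUE_TRIO_PARAMS[p] for p in model.param_names])

expected = d.expected_sfs(model, params, fold=True)
print(f"expected folded SFS at theta=1: total mass {expected.sum():.4f}")

theta = 5000.0
data = d.sample_sfs_poisson(expected, theta, seed=4)
print(f"Poisson dataset at theta={theta:.0f}: {data.sum():.0f} sites")

resid = d.anscombe_residuals(expected.scaled(theta), data)
print(f"Anscombe residuals (model - data): mean {resid.mean():.3f}, "
      f"max |r| {np.abs(resid).max():.2f}")
# For a correctly specified model the residuals behave like standard
# normals: mean near 0 and few values beyond +/-3.
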