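"""Estimate immune-cell fractions from bulk mixtures by nu-SVR.

Draws 20 in-silico bulk samples as Dirichlet mixtures of a 5-cell-type
signature matrix plus noise, deconvolves them with the linear-kernel
nu-SVR procedure (nu grid 0.25/0.5/0.75, negative weights clipped,
normalized to sum 1), and reports recovery against the known fractions
plus the permutation significance of each fit.
"""

import numpy as np

from metaquad import SimulationConfig, deconvolve, simulate_cohorts, simulate_mixture

# the generator's block signature stands in for an LM22-style reference
cfg = SimulationConfig(seed=5)
*_, signature = simulate_cohorts(cfg)

mixtures, truth = simulate_mixture(signature, n_mix=20, noise_sd=0.5, seed=6)
est = deconvolve(mixtures, signature, n_perm=200, seed=7)

err = np.abs(est.fractions.to_numpy() - truth.to_numpy())
print(f"mean |estimated - true| fraction: {err.mean():.3f} (max {err.max():.3f})")
for ct in signature.columns:
    r = np.corrcoef(truth[ct], est.fractions[ct])[0, 1]
    print(f"  {ct}: truth-estimate r = {r:.3f}")
print(f"permutation P < 0.05 for {(est.p_perm < 0.05).sum()}/20 samples "
      "(all should pass: every sample is a genuine mixture)")
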