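"""Fit a polymer network to a noisy synthetic Hi-C matrix.

Generates the benchmark model (two TAD blocks and one loop on a 60-bead
backbone), corrupts its exact contact matrix with 10% lognormal noise, and
fits a valid spring-constant matrix back.  The Pearson correlation (PCC)
scores overall agreement; the distance-corrected PCC removes the trivial
genomic-distance decay first, so it only credits genuine structure.
"""

from hicdyn import OptimizationConfig, forward_map, optimize
from hicdyn.synthetic import default_fixture_spec, make_noisy_contacts, make_tad_model

K_true = make_tad_model(default_fixture_spec())
C_noisy = make_noisy_contacts(K_true, "lognormal", noise_sigma=0.1, seed=7)

result = optimize(C_noisy, OptimizationConfig(max_iterations=2000))

print(f"input: 60x60 contact matrix, lognormal noise sigma = 0.1")
print(f"iterations: {result.n_iterations}  converged: {result.converged}")
print(f"final cost: {result.cost_history[-1]:.4f} "
      f"(residual sum of squares / 2; noise bounds it away from 0)")
print(f"PCC(C_opt, C_input) = {result.pcc:.4f}")
print(f"distance-corrected PCC = {result.distance_corrected_pcc:.4f}")
# Both correlations near 0.98 mean the fit recovers the TADs and the loop
# up to the injected noise; on a noise-free input both reach 1.0.
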