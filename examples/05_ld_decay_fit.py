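"""Fit the Hill–Weir linkage-disequilibrium decay model.

r^2-vs-distance pairs (as produced by plink --r2) are fitted with the
drift–recombination expectation E[r^2](C = rho*d, n); the fit reports the
per-bp coefficient rho, the half-decay distance and the distance where the
curve drops below r^2 = 0.1.
"""

from pangraphkit.popgen import fit_ld_decay, hill_weir_expected_r2
from pangraphkit.simulate import sample_ld_pairs

rho_true = 5e-4
pairs = sample_ld_pairs(rho=rho_true, n=100, n_pairs=10_000, noise_sd=0.05, seed=1)
fit = fit_ld_decay(pairs, n=100)

print(f"true rho      : {rho_true:.3e}")
print(f"fitted rho    : {fit.rho:.3e} ({100 * abs(fit.rho - rho_true) / rho_true:.1f}% off)")
print(f"r^2 at d = 0  : {hill_weir_expected_r2(0, 100):.3f}")
print(f"half-decay    : {fit.half_decay_bp:.0f} bp")
print(f"decay to <0.1 : {fit.min_decay_bp:.0f} bp")
# Half-decay is where the fitted curve falls to half its zero-distance
# value; rapid decay (a few kb) is typical of outcrossing wild grapes.
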