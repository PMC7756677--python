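"""Log-normal data: analysis on log10 scale, back-transformed to ratios.

Assay values spanning orders of magnitude (here a synthetic fraction-unbound
style data set of 11 compounds, X/Y ratio log-normal) are log10-transformed,
the tolerance intervals computed, then exponentiated: bounds become fold
changes and the tolerated 20% relative difference maps to the asymmetric
ratio band (0.8, 1.25).
"""

from tolagree import AcceptanceSpec, analyze, antilog_intervals, lognormal_fixture

sample = lognormal_fixture(11, log10_bias=0.03, log10_sd=0.25,
                           base_log10_level=-1.5, seed=17,
                           method_names=("flux", "literature"))

result = analyze(sample, beta=0.95, gamma=0.80, transform="log10",
                 acceptance=AcceptanceSpec(0.2, ratio_fraction=0.2))
ratios = antilog_intervals(result, base=10)

print(f"n={result.summary.n}, log10 mean diff={result.summary.mean_diff:.3f}, "
      f"log10 SD={result.summary.sd_diff:.3f}")
for kind in ("PI_bTI", "bgTI_exact"):
    iv = ratios.intervals[kind]
    print(f"{kind:10s} ratio interval [{iv.lower:.2f}, {iv.upper:.2f}]  "
          f"(geometric center {iv.center:.2f})")
print(f"acceptance ratio band: {ratios.acceptance.ratio_bounds}")
print(f"decision: {ratios.decision}")
# The fold-change interval reads: 95% of future X/Y ratios are expected
# between the two bounds; equivalence needs that whole range inside
# (0.80, 1.25).
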