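"""Detect signal-dependent noise in a simulated ROI series.

Fits a constant-variance AR model and correlates its squared residuals with
the squared lagged signal, under three residual models; a positive,
significant correlation means the noise level follows the signal level and a
constant-variance causality model is misspecified.
"""

from gcsdn import NetworkSpec, binned_profile, sdn_test, simulate_var_bekk
from gcsdn.sdn import sdn_pairs

net = NetworkSpec(
    regions=("x",), self_coeffs={"x": 0.5},
    var_coeffs={("x", "x"): 0.5},  # own-signal variance coupling = SDN
    base_noise={"x": 1.0},
)
series = [simulate_var_bekk(net, 2000, seed=j)[:, 0] for j in range(5)]

for kind in ("ar", "ar_quadratic", "fourier6"):
    res = sdn_test(series, kind, order=1, pooled=True)
    print(f"{kind:>12s}: r = {res.correlation:+.3f}, p = {res.p_value:.2e} "
          f"({res.pairs_used} of {res.pairs_offered} pairs after 3-sigma filter)")
# All three residual models agree -> the correlation is not a model artifact.

prof = binned_profile(sdn_pairs(series[0], "ar"), n_bins=7)
print("binned noise-vs-signal profile slope:", round(prof.slope, 3),
      "(positive slope = noise grows with signal strength)")
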