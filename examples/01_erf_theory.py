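"""Analytic effective-receptive-field (ERF) design rules.

Evaluates the enlargement ratio of a dilated side branch and the shrinkage
ratio of a residual side branch over feature depth, plus the side-kernel
design rule that fixes the dilated branch's kernel.
"""

from mismatch import (ErfRatioInputs, binomial_path_weight, erf_ratio_nasb,
                      erf_ratio_pasb, minimal_side_kernel)

print("Side-kernel design rule (main kernel K = 3):")
print(f"  minimal admissible side kernel : {minimal_side_kernel(3, doubling=False)}")
print(f"  doubled design choice          : {minimal_side_kernel(3, doubling=True)}")
print()
print("Residual ensemble path weights (two layers, p = 0.5):")
for k in range(3):
    print(f"  paths using {k} layer(s): weight {binomial_path_weight(2, k, 0.5):.2f}")
print()
print(" depth n | dilating ratio (K'=9) | eroding ratio")
for n in (1, 2, 5, 10, 100):
    pasb = erf_ratio_pasb(ErfRatioInputs(K=3, K_side=9, n=n))
    nasb = erf_ratio_nasb(n)
    print(f"  {n:6d} | {pasb:20.4f} | {nasb:.4f}")
print()
print("The dilating ratio stays above 1 (gate sees more than the main"
      " branch); the eroding ratio stays below 1 and tends to 1 with depth.")
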