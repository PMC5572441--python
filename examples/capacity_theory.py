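"""Capacity theory of the binary associative memory, without any spikes.

Computes the expected false positives of a workload, the recallable
information and the information-optimal number of stored samples for the
published workload sizes.
"""

from binam import (
    DataParameters,
    capacity_estimate,
    expected_false_positives,
    optimal_sample_count,
)

for m, n in [(112, 128), (64, 96), (400, 400), (2500, 400)]:
    n_star = optimal_sample_count(m, n, 4, 4)
    print(f"(m={m:4d}, n={n:4d}, c=d=4): optimal sample count N* = {n_star}")

params = DataParameters(m=112, n=128, c=4, d=4, N=735)
est = capacity_estimate(params)
print(f"\nWorkload {params}:")
print(f"  expected false positives per sample (Eq.-style estimate): "
      f"{expected_false_positives(params):.2f} of {params.n - params.d} zero bits")
print(f"  expected recallable information I_th = {est.I_th:,.0f} bits "
      f"({est.I_th / params.N:.2f} bits/sample)")
print(f"  random-matrix information baseline I_rand = {est.baseline.I_rand:,.0f} bits "
      f"({est.baseline.I_rand / est.I_th:.1%} of I_th)")
# A memory filled to the optimal sample count still recalls ~16 bits per
# sample; the random baseline shows how much 'information' a saturated
# (useless) memory would fake, which must stay small for I_n to mean anything.
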