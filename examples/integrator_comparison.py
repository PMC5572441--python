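"""Accuracy cost of fixed-step integration, measured by the benchmark.

Runs a scaled-down single-spike workload with the adaptive RKF45 reference
integrator and with naive explicit Euler steps of 0.1 and 1.0 ms.  The
normalised information turns integration error into a single number.
"""

import warnings

from binam import IntegratorConfig, run_benchmark
from binam.presets import benchmark_config

warnings.filterwarnings("ignore", message=".*I_rand.*")

base = benchmark_config("a").replace(m=48, n=48, N=140, repetitions=3)
for label, integ in [
    ("rkf45, 0.1 ms grid", IntegratorConfig(method="rkf45", dt=0.1)),
    ("euler, 0.1 ms step", IntegratorConfig(method="euler", dt=0.1)),
    ("euler, 1.0 ms step", IntegratorConfig(method="euler", dt=1.0)),
]:
    r = run_benchmark(base.replace(integrator=integ))
    print(f"{label}: I_n = {r.I_n:.3f}  alpha_n = {r.alpha_n:+.3f}  "
          f"beta_n = {r.beta_n:.3f}")
# At 0.1 ms the explicit Euler step matches the adaptive reference; at
# 1.0 ms the membrane overshoots the threshold between checks, producing a
# burst of spurious spikes (positive alpha_n) and roughly halving the
# recallable information — the signature of an under-resolved fixed-step
# integrator.
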