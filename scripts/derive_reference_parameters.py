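"""Derive the reference neuron parameter presets for benchmark setups (a)-(d).

For each of the four operation modes — (a) single spike/single neuron,
(b) single spike/population, (c) burst/single neuron, (d) burst/population —
this script runs the package's parameter-selection pipeline
(:func:`binam.tuning.tune_threshold_parameters`): Nelder-Mead maximisation
of the Student-t surrogate over (v_th, g_leak, w) from random restarts,
re-ranking of the local optima by the joint empirical probability of the
count targets under 2 ms spike-time jitter, and a final empirical grid
refinement of the threshold potential.  The resulting values are frozen as
``binam.presets.REFERENCE_SETS``.

Run from the repository root:

    python scripts/derive_reference_parameters.py
"""

import time

from binam.network import NeuronParameters
from binam.tuning import (
    empirical_probability,
    threshold_objectives,
    tune_threshold_parameters,
)

STARTS = {
    "a": NeuronParameters(v_th=-57.0, g_leak=20.0, w=10.0),
    "b": NeuronParameters(v_th=-64.7, g_leak=20.0, w=1.0),
    "c": NeuronParameters(v_th=-64.7, g_leak=20.0, w=1.0),
    "d": NeuronParameters(v_th=-62.0, g_leak=89.0, w=1.0),
}

MODES = {"a": (1, 1), "b": (1, 4), "c": (4, 1), "d": (4, 4)}


def derive(setup: str, seed: int = 2017):
    s, omega = MODES[setup]
    t0 = time.time()
    p = tune_threshold_parameters(
        c=4, s=s, omega=omega, initial=STARTS[setup], seed=seed
    )
    objectives = threshold_objectives(c=4, s=s, omega=omega, target=1)
    det = empirical_probability(p, objectives, trials=1, sigma_t=0.0)
    jit = empirical_probability(p, objectives, trials=400, seed=seed + 1)
    print(
        f"setup {setup} ({time.time() - t0:.0f} s): "
        f"v_th={p.v_th:.4f} g_leak={p.g_leak:.4f} w={p.w:.4f}"
    )
    print(f"  P(target | deterministic)={det}  P(target | jitter 2 ms)={jit}")
    return p


if __name__ == "__main__":
    for setup in "abcd":
        p = derive(setup)
        print(
            f'    "{setup}": NeuronParameters(v_th={p.v_th:.6f}, '
            f"g_leak={p.g_leak:.6f}, w={p.w:.6f}),"
        )
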