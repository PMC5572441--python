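"""Named parameter sets and ready-made benchmark configurations.

``PARAMETER_SETS`` holds the published default IfCondExp parameter sets
I-III verbatim.  As shipped, these printed values do not implement the
spike-count threshold function the memory requires: for set II the total
synaptic charge of the 16 input spikes of the population configuration
(16 x 1 nS x tau_exc = 2 ms) bounds the depolarisation at 12.8 mV from
rest, short of the 15.3 mV threshold distance for any leak conductance and
any integrator, and exact integration shows the same shortfall for sets I
and III in their configurations.  ``REFERENCE_SETS`` therefore provides
threshold-correct parameters for the four benchmark operation modes,
derived with the package's own optimisation procedure
(``scripts/derive_reference_parameters.py``: Student-t surrogate over the
fractional spike count, Nelder-Mead with random restarts, empirical
verification at zero and 2 ms jitter).

``BENCHMARK_SIZES`` collects the published workload dimensions so any row
of the high-workload benchmark table is a one-call reproduction via
:func:`benchmark_config`.
"""

from __future__ import annotations

from .bench import ExperimentConfig
from .network import NeuronParameters, ParameterRange
from .simulator import IntegratorConfig

__all__ = [
    "PARAMETER_SETS",
    "REFERENCE_SETS",
    "SPIKEY_RANGE",
    "SETUP_MODES",
    "BENCHMARK_SIZES",
    "benchmark_config",
]

#: Published default parameter sets (I-III), kept verbatim for reference.
PARAMETER_SETS = {
    "I": NeuronParameters(v_th=-57.0, g_leak=20.0, w=10.0),
    "II": NeuronParameters(v_th=-64.7, g_leak=20.0, w=1.0),
    "III": NeuronParameters(v_th=-62.0, g_leak=89.0, w=1.0),
}

#: Experimentally determined parameter range of the Spikey chip, with the
#: 4-bit synaptic weight discretisation (steps of 1 nS up to 15 nS).
SPIKEY_RANGE = ParameterRange(
    bounds={
        "v_rest": (-80.0, -55.0),
        "v_th": (-80.0, -55.0),
        "v_reset": (-80.0, -55.0),
        "g_leak": (20.0, 40.0),
        "w": (0.0, 15.0),
    },
    w_step=1.0,
)

#: Burst length and population multiplicity of the four operation modes.
SETUP_MODES = {
    "a": (1, 1),  # single spike, single neuron
    "b": (1, 4),  # single spike, population
    "c": (4, 1),  # burst, single neuron
    "d": (4, 4),  # burst, population
}

#: Threshold-correct reference parameters per operation mode, derived by
#: scripts/derive_reference_parameters.py (seed 2017).  All four threshold
#: objectives are met with probability one for deterministic stimuli and
#: >= 0.9875 under 2 ms spike-time jitter; the leak conductance sits at the
#: recovery bound g_leak = 20 nS (membrane time constant 10 ms), which the
#: 100 ms presentation period requires for neurons to return to rest
#: between samples.
REFERENCE_SETS = {
    "a": NeuronParameters(v_th=-74.25, g_leak=20.0, w=3.622895),
    "b": NeuronParameters(v_th=-74.25, g_leak=20.0, w=0.905724),
    "c": NeuronParameters(v_th=-59.75, g_leak=20.0, w=4.0),
    "d": NeuronParameters(v_th=-64.75, g_leak=20.0, w=0.742997),
}

#: Published high-workload data dimensions (m, n, N) per platform class.
#: Setups (a)/(c) use the wide input sizes, (b)/(d) the population sizes.
BENCHMARK_SIZES = {
    ("a", "ess"): (112, 128, 735),
    ("a", "spikey"): (256, 384, 4619),
    ("c", "ess"): (112, 128, 735),
    ("c", "spikey"): (256, 384, 4619),
    ("b", "ess"): (28, 32, 54),
    ("b", "spikey"): (64, 96, 324),
    ("b", "spinnaker"): (400, 400, 7499),
    ("b", "spinnaker-wide"): (2500, 400, 46866),
    ("d", "ess"): (28, 32, 54),
    ("d", "spikey"): (64, 96, 324),
    ("d", "spinnaker"): (400, 400, 7499),
    ("d", "spinnaker-wide"): (2500, 400, 46866),
}


def benchmark_config(
    setup: str,
    size: str = "ess",
    neuron: NeuronParameters | None = None,
    integrator: IntegratorConfig | None = None,
    data_seed: int = 1,
    jitter_seed: int = 2,
    **overrides,
) -> ExperimentConfig:
    """Benchmark configuration for an operation mode at a published size.

    ``setup`` is one of ``"a"``-``"d"``; ``size`` selects the workload
    dimensions (``"ess"``, ``"spikey"``, ``"spinnaker"``,
    ``"spinnaker-wide"``).  The neuron defaults to the derived reference set
    of the mode; keyword overrides are forwarded to the config.
    """
    if setup not in SETUP_MODES:
        raise KeyError(f"unknown setup {setup!r}; expected one of a-d")
    key = (setup, size)
    if key not in BENCHMARK_SIZES:
        raise KeyError(f"no published size {size!r} for setup {setup!r}")
    s, omega = SETUP_MODES[setup]
    m, n, N = BENCHMARK_SIZES[key]
    return ExperimentConfig(
        m=m,
        n=n,
        c=4,
        d=4,
        N=N,
        s=s,
        omega=omega,
        neuron=neuron if neuron is not None else REFERENCE_SETS[setup],
        integrator=integrator if integrator is not None else IntegratorConfig(),
        data_seed=data_seed,
        jitter_seed=jitter_seed,
        **overrides,
    )
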