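"""End-to-end benchmark execution, metric normalisation, sweeps, efficiency.

One benchmark run executes the full pipeline: generate a balanced dataset,
train the binary memory, build the spiking network, encode the keys as
jittered spike trains, execute them on a (black-box) back-end, decode the
output spike counts and compare against the stored values.  The headline
metric is the normalised information ``I_n = I / I_th`` where the baseline
``I_th`` (and the expected false-positive level ``alpha_th``) is computed
from the *ideal McCulloch-Pitts recall of the same trained matrix on the
same dataset* — so a substrate that reproduces the binary memory exactly
scores precisely ``I_n = 1``, ``alpha_n = 0``, ``beta_n = 0``.  The signed
``alpha_n`` maps a false-positive shortage to [-1, 0) and a surplus to
(0, 1]; ``beta_n`` is the false-negative count relative to ``d``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codec import EncodingSpec, decode, encode
from .core import (
    DataParameters,
    PatternDataset,
    generate_dataset,
    information_bits,
    optimal_sample_count,
    random_baseline,
    recall_matrix,
    train,
)
from .network import NeuronParameters, build_network, run_backend
from .simulator import IntegratorConfig

logger = logging.getLogger("binam")

__all__ = [
    "ExperimentConfig",
    "BenchmarkResult",
    "EfficiencyResult",
    "evaluate_metrics",
    "run_benchmark",
    "score_recall",
    "sweep_1d",
    "sweep_2d",
    "energy_efficiency",
    "results_to_frame",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """A complete benchmark experiment description.

    ``N=None`` selects the information-optimal sample count for
    ``(m, n, c, d)``.  ``repeat_mode`` chooses between averaging runs with
    different data/jitter seeds (``"seed"``, the sweep convention) and
    re-running the identical input (``"input"``, the convention used to
    average trials on non-deterministic analog hardware).
    """

    m: int
    n: int
    c: int = 4
    d: int = 4
    N: int | None = None
    s: int = 1
    omega: int = 1
    delta_t: float = 2.0
    sigma_t: float = 2.0
    T: float = 100.0
    neuron: NeuronParameters = field(default_factory=NeuronParameters)
    integrator: IntegratorConfig = field(default_factory=IntegratorConfig)
    backend: str = "builtin"
    c_th: int | None = None
    repetitions: int = 1
    repeat_mode: str = "seed"
    data_seed: int = 1
    jitter_seed: int = 2

    def __post_init__(self) -> None:
        if self.repeat_mode not in ("seed", "input"):
            raise ValueError("repeat_mode must be 'seed' or 'input'")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")

    def resolve_N(self) -> int:
        if self.N is not None:
            return self.N
        return optimal_sample_count(self.m, self.n, self.c, self.d)

    def data_parameters(self) -> DataParameters:
        return DataParameters(m=self.m, n=self.n, c=self.c, d=self.d, N=self.resolve_N())

    def encoding(self, jitter_seed: int | None = None) -> EncodingSpec:
        return EncodingSpec(
            s=self.s,
            delta_t=self.delta_t,
            sigma_t=self.sigma_t,
            T=self.T,
            omega=self.omega,
            seed=self.jitter_seed if jitter_seed is None else jitter_seed,
        )

    def replace(self, **kwargs) -> "ExperimentConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["neuron"] = self.neuron.as_dict()
        doc["integrator"] = dataclasses.asdict(self.integrator)
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "ExperimentConfig":
        doc = dict(doc)
        if isinstance(doc.get("neuron"), dict):
            doc["neuron"] = NeuronParameters(**doc["neuron"])
        if isinstance(doc.get("integrator"), dict):
            doc["integrator"] = IntegratorConfig(**doc["integrator"])
        return cls(**doc)

    @property
    def config_hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha1(text.encode()).hexdigest()[:10]


@dataclass
class BenchmarkResult:
    """Metrics of one benchmark run (or the mean over repetitions)."""

    I: float
    I_th: float
    I_n: float
    alpha_bar: float
    beta_bar: float
    alpha_n: float
    beta_n: float
    t: float = 0.0
    N: int = 0
    I_rand: float = float("nan")
    alphas: np.ndarray | None = None
    betas: np.ndarray | None = None
    runs: list | None = None

    @property
    def t_per_sample_ms(self) -> float:
        return 1000.0 * self.t / self.N if self.N else float("nan")

    def to_dict(self, per_sample: bool = False) -> dict:
        doc = {
            "I_bits": self.I,
            "I_th_bits": self.I_th,
            "I_n": self.I_n,
            "alpha_bar": self.alpha_bar,
            "beta_bar": self.beta_bar,
            "alpha_n": self.alpha_n,
            "beta_n": self.beta_n,
            "t_s": self.t,
            "t_per_sample_ms": self.t_per_sample_ms,
            "N": self.N,
            "I_rand_bits": self.I_rand,
        }
        if per_sample and self.alphas is not None:
            doc["alphas"] = [float(a) for a in self.alphas]
            doc["betas"] = [float(b) for b in self.betas]
        return doc


def evaluate_metrics(
    Y_recalled: np.ndarray,
    dataset: PatternDataset,
    c_th: int | None = None,
    M: np.ndarray | None = None,
) -> BenchmarkResult:
    """Score a recalled output matrix against a dataset.

    Per sample, ``alpha_k`` counts recalled bits not stored and ``beta_k``
    stored bits not recalled.  The baseline (``I_th``, ``alpha_th``) is the
    ideal binary recall of the trained matrix at threshold ``c_th`` on the
    very same dataset, so it reflects the realised false positives of this
    workload rather than their expectation over random datasets.
    """
    p = dataset.params
    Y_recalled = np.asarray(Y_recalled)
    if Y_recalled.shape != dataset.Y.shape:
        raise ValueError(
            f"recalled matrix shape {Y_recalled.shape} does not match dataset "
            f"{dataset.Y.shape}"
        )
    threshold = p.c if c_th is None else c_th
    if M is None:
        M = train(dataset)
    ideal = recall_matrix(M, dataset.X, threshold=threshold)
    stored = dataset.Y.astype(bool)
    a_th = np.sum(ideal.astype(bool) & ~stored, axis=1).astype(float)
    b_th = np.sum(~ideal.astype(bool) & stored, axis=1).astype(float)
    I_th = information_bits(p.n, p.d, a_th, b_th)
    alpha_th = float(np.mean(a_th))

    rec = Y_recalled.astype(bool)
    alphas = np.sum(rec & ~stored, axis=1).astype(float)
    betas = np.sum(~rec & stored, axis=1).astype(float)
    I = information_bits(p.n, p.d, alphas, betas)
    alpha_bar = float(np.mean(alphas))
    beta_bar = float(np.mean(betas))

    if alpha_bar <= alpha_th:
        alpha_n = alpha_bar / alpha_th - 1.0 if alpha_th > 0 else 0.0
    else:
        alpha_n = (alpha_bar - alpha_th) / (p.n - p.d - alpha_th)
    base = random_baseline(p, threshold)
    if I_th > 0 and base.I_rand / I_th > 0.05:
        warnings.warn(
            f"I_rand/I_th = {base.I_rand / I_th:.2f} > 0.05: the memory is close "
            "to saturation and I_n is not meaningful for this configuration",
            stacklevel=2,
        )
    return BenchmarkResult(
        I=I,
        I_th=I_th,
        I_n=I / I_th if I_th > 0 else 0.0,
        alpha_bar=alpha_bar,
        beta_bar=beta_bar,
        alpha_n=float(alpha_n),
        beta_n=beta_bar / p.d,
        N=p.N,
        I_rand=base.I_rand,
        alphas=alphas,
        betas=betas,
    )


def score_recall(
    output_spikes,
    dataset: PatternDataset,
    omega: int = 1,
    T: float = 100.0,
    c_th: int | None = None,
) -> BenchmarkResult:
    """Score externally produced output spike trains against a dataset.

    This is the black-box hardware scoring path: any substrate that returns
    channel/time records for the ``n * omega`` output neurons can be
    evaluated without using the built-in simulator.
    """
    p = dataset.params
    Y = decode(output_spikes, p.n, omega, T, p.N)
    return evaluate_metrics(Y, dataset, c_th=c_th)


def _single_run(
    config: ExperimentConfig, data_seed: int, jitter_seed: int
) -> BenchmarkResult:
    params = config.data_parameters()
    if params.N == 0:
        raise ValueError("benchmark needs at least one sample")
    t0 = time.perf_counter()
    dataset = generate_dataset(params, seed=data_seed)
    M = train(dataset)
    net = build_network(M, omega=config.omega, params=config.neuron)
    spikes = encode(dataset.X, config.encoding(jitter_seed))
    t_setup = time.perf_counter() - t0
    out, elapsed = run_backend(
        net, spikes, backend=config.backend,
        options={"integrator": config.integrator},
    )
    Y = decode(out, params.n, config.omega, config.T, params.N)
    result = evaluate_metrics(Y, dataset, c_th=config.c_th, M=M)
    result.t = elapsed
    logger.debug(
        "run m=%d n=%d N=%d: setup %.2fs backend %.2fs I_n=%.4f",
        params.m, params.n, params.N, t_setup, elapsed, result.I_n,
    )
    return result


def run_benchmark(config: ExperimentConfig) -> BenchmarkResult:
    """Execute a benchmark experiment, averaging over its repetitions."""
    runs = []
    for rep in range(config.repetitions):
        if config.repeat_mode == "seed":
            run = _single_run(config, config.data_seed + rep, config.jitter_seed + rep)
        else:
            run = _single_run(config, config.data_seed, config.jitter_seed)
        runs.append(run)
    if len(runs) == 1:
        return runs[0]
    mean = lambda name: float(np.mean([getattr(r, name) for r in runs]))
    return BenchmarkResult(
        I=mean("I"),
        I_th=mean("I_th"),
        I_n=mean("I_n"),
        alpha_bar=mean("alpha_bar"),
        beta_bar=mean("beta_bar"),
        alpha_n=mean("alpha_n"),
        beta_n=mean("beta_n"),
        t=mean("t"),
        N=runs[0].N,
        I_rand=runs[0].I_rand,
        runs=runs,
    )


_SWEEPABLE = ("m", "n", "c", "d", "N")


def sweep_1d(
    base: ExperimentConfig,
    parameter: str,
    values,
    repetitions: int | None = None,
) -> pd.DataFrame:
    """One-dimensional sweep over a data parameter.

    Returns one row per value with the metrics averaged over repetitions and
    the random-baseline information of the swept configuration; infeasible
    values are kept as rows marked ``status='failed'`` and the sweep
    continues.
    """
    if parameter not in _SWEEPABLE:
        raise ValueError(f"parameter must be one of {_SWEEPABLE}")
    rows = []
    for value in values:
        config = base.replace(**{parameter: int(value)})
        if repetitions is not None:
            config = config.replace(repetitions=repetitions)
        row = {"parameter": parameter, "value": value, "status": "ok"}
        try:
            result = run_benchmark(config)
            row.update(result.to_dict())
        except Exception as exc:  # noqa: BLE001 - sweep must survive bad points
            row["status"] = "failed"
            row["error"] = str(exc)
            logger.warning("sweep point %s=%s failed: %s", parameter, value, exc)
        rows.append(row)
    return pd.DataFrame(rows)


def sweep_2d(
    base: ExperimentConfig, v_th_values, w_values
) -> dict:
    """Two-dimensional sweep over threshold potential and synaptic weight.

    Returns grids (``len(v_th_values) x len(w_values)``) of ``I_n``,
    ``alpha_n`` and ``beta_n``; infeasible parameter combinations yield NaN.
    """
    v_th_values = np.asarray(v_th_values, dtype=float)
    w_values = np.asarray(w_values, dtype=float)
    if len(v_th_values) == 0 or len(w_values) == 0:
        raise ValueError("sweep grids must be non-empty")
    shape = (len(v_th_values), len(w_values))
    grids = {k: np.full(shape, np.nan) for k in ("I_n", "alpha_n", "beta_n")}
    for i, v_th in enumerate(v_th_values):
        for j, w in enumerate(w_values):
            try:
                neuron = base.neuron.replace(v_th=float(v_th), w=float(w))
            except ValueError:
                continue
            try:
                result = run_benchmark(base.replace(neuron=neuron))
            except Exception as exc:  # noqa: BLE001
                logger.warning("sweep point v_th=%s w=%s failed: %s", v_th, w, exc)
                continue
            grids["I_n"][i, j] = result.I_n
            grids["alpha_n"][i, j] = result.alpha_n
            grids["beta_n"][i, j] = result.beta_n
    grids["v_th"] = v_th_values
    grids["w"] = w_values
    return grids


@dataclass(frozen=True)
class EfficiencyResult:
    """Energy bookkeeping of a benchmark execution."""

    E_eff: float  # I_n-weighted recalled samples per joule [1/J]
    P: float  # power [W]
    E: float  # energy [J]
    E_per_sample: float  # [J]


def energy_efficiency(
    I_n: float,
    N: int,
    power_w: float | None = None,
    t_s: float | None = None,
    energy_j: float | None = None,
) -> EfficiencyResult:
    """Samples recallable per joule, weighted by the normalised information.

    ``E_eff = I_n * N / E`` with ``E = P * t`` (or the energy given
    directly).  Power measurement itself is out of scope — the inputs are
    externally supplied readings.
    """
    if energy_j is None:
        if power_w is None or t_s is None:
            raise ValueError("need either energy_j or both power_w and t_s")
        if power_w <= 0 or t_s <= 0:
            raise ValueError("power and time must be positive")
        energy_j = power_w * t_s
    elif energy_j <= 0:
        raise ValueError("energy must be positive")
    power = power_w if power_w is not None else energy_j / t_s if t_s else float("nan")
    return EfficiencyResult(
        E_eff=I_n * N / energy_j,
        P=power,
        E=energy_j,
        E_per_sample=energy_j / N,
    )


def results_to_frame(entries) -> pd.DataFrame:
    """Flatten ``(config, result)`` pairs into the standard result table."""
    rows = []
    for config, result in entries:
        row = {
            "config_hash": config.config_hash,
            "m": config.m,
            "n": config.n,
            "c": config.c,
            "d": config.d,
            "N": result.N,
            "s": config.s,
            "omega": config.omega,
            "backend": config.backend,
            "integrator": config.integrator.method,
            "dt": config.integrator.dt,
            "seed": config.data_seed,
        }
        row.update(result.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
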