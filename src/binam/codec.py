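"""Translation between binary patterns and spike trains.

Input patterns are presented one sample per period of ``T`` (100 ms by
default).  A one-bit is represented by a burst of ``s`` spikes at inter-spike
interval ``delta_t`` on each of its ``omega`` redundant channels; every spike
receives independent Gaussian timing jitter of standard deviation
``sigma_t``.  Output spike trains are decoded back to binary matrices by
counting spikes of each ``omega``-neuron population inside each presentation
window; a bit is set when the summed count reaches ``omega``.

The decision threshold deliberately reads "count >= omega" rather than a
strict "count > omega": with ``s = 1`` a correctly tuned neuron emits exactly
one spike per presented one-bit, so a strict threshold could never be met in
the burst-less single-neuron configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["EncodingSpec", "SpikeTrainSet", "encode", "decode"]


@dataclass(frozen=True)
class EncodingSpec:
    """Parameters of the burst/population spike encoding.

    s
        Spikes per burst (1 = burst-less).
    delta_t
        Intra-burst inter-spike interval in ms; the nominal per-synapse rate
        during a burst is ``1/delta_t`` (500 /s at the 2 ms default).
    sigma_t
        Gaussian spike-time jitter SD in ms.
    T
        Sample presentation period in ms.
    omega
        Population multiplicity (redundant channels per logical bit).
    seed
        Seed of the dedicated jitter RNG stream, decoupled from the pattern
        generator so changing the data seed leaves the jitter pattern of a
        fixed spike schedule untouched.
    """

    s: int = 1
    delta_t: float = 2.0
    sigma_t: float = 2.0
    T: float = 100.0
    omega: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s < 1 or self.omega < 1:
            raise ValueError("s and omega must be positive integers")
        if self.delta_t <= 0 or self.T <= 0:
            raise ValueError("delta_t and T must be positive")
        if self.sigma_t < 0:
            raise ValueError("sigma_t must be non-negative")
        if self.s * self.delta_t >= self.T:
            raise ValueError("burst (s * delta_t) must fit inside the presentation period T")


@dataclass
class SpikeTrainSet:
    """Per-channel sorted spike times in milliseconds."""

    trains: list = field(default_factory=list)
    duration: float = 0.0

    def __post_init__(self) -> None:
        self.trains = [np.asarray(t, dtype=float) for t in self.trains]

    @property
    def n_channels(self) -> int:
        return len(self.trains)

    @property
    def n_spikes(self) -> int:
        return int(sum(len(t) for t in self.trains))

    def to_frame(self) -> pd.DataFrame:
        """Two-column (channel_id, time_ms) representation, channel-major."""
        ch = np.concatenate(
            [np.full(len(t), i, dtype=int) for i, t in enumerate(self.trains)]
        ) if self.trains else np.empty(0, dtype=int)
        times = np.concatenate(self.trains) if self.trains else np.empty(0)
        return pd.DataFrame({"channel_id": ch, "time_ms": np.round(times, 2)})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, n_channels: int | None = None, duration: float | None = None
    ) -> "SpikeTrainSet":
        df = pd.read_csv(path)
        if not {"channel_id", "time_ms"} <= set(df.columns):
            raise ValueError("spike CSV needs 'channel_id' and 'time_ms' columns")
        n_ch = int(df["channel_id"].max()) + 1 if len(df) else 0
        if n_channels is not None:
            n_ch = max(n_ch, n_channels)
        trains = [
            np.sort(df.loc[df["channel_id"] == i, "time_ms"].to_numpy(dtype=float))
            for i in range(n_ch)
        ]
        dur = duration if duration is not None else (df["time_ms"].max() if len(df) else 0.0)
        return cls(trains=trains, duration=float(dur))


def encode(X: np.ndarray, spec: EncodingSpec) -> SpikeTrainSet:
    """Encode an ``N x m`` binary matrix as jittered burst spike trains.

    Channel layout is population-blocked: logical bit ``i`` owns channels
    ``i*omega .. i*omega + omega - 1``.  For sample ``k`` with bit ``i`` set,
    each of those channels nominally fires at ``k*T + j*delta_t`` for
    ``j = 0..s-1``; jitter is i.i.d. per spike per channel, jittered times are
    clamped to be non-negative and each channel is re-sorted.
    """
    X = np.atleast_2d(np.asarray(X))
    N, m = X.shape
    rng = np.random.default_rng(spec.seed)
    duration = N * spec.T
    nominal_burst = np.arange(spec.s) * spec.delta_t
    trains: list[np.ndarray] = [np.empty(0) for _ in range(m * spec.omega)]
    # Deterministic iteration order (bit-major, then channel) fixes the jitter
    # stream for equal (X, spec).
    for i in range(m):
        samples = np.nonzero(X[:, i])[0]
        if len(samples) == 0:
            continue
        nominal = (samples[:, None] * spec.T + nominal_burst[None, :]).ravel()
        for p in range(spec.omega):
            times = nominal.copy()
            if spec.sigma_t > 0:
                times = times + rng.normal(0.0, spec.sigma_t, size=times.shape)
            np.clip(times, 0.0, None, out=times)
            trains[i * spec.omega + p] = np.sort(times)
    return SpikeTrainSet(trains=trains, duration=duration)


def decode(
    output: SpikeTrainSet, n: int, omega: int, T: float, N: int
) -> np.ndarray:
    """Decode output spike trains to an ``N x n`` binary matrix.

    Bit ``(k, j)`` is set iff the ``omega`` neurons of population ``j``
    together emit at least ``omega`` spikes inside the half-open window
    ``[k*T, (k+1)*T)``.  Spikes outside ``[0, N*T)`` trigger a warning and
    are attributed to the nearest window.
    """
    if output.n_channels != n * omega:
        raise ValueError(
            f"expected {n * omega} output channels, got {output.n_channels}"
        )
    counts = np.zeros((N, n), dtype=np.int64)
    edges = np.arange(N + 1) * T
    stray = 0
    for ch, times in enumerate(output.trains):
        if len(times) == 0:
            continue
        stray += int(np.sum((times < 0) | (times >= N * T)))
        idx = np.clip(np.searchsorted(edges, times, side="right") - 1, 0, N - 1)
        np.add.at(counts, (idx, ch // omega), 1)
    if stray:
        warnings.warn(
            f"{stray} output spikes outside [0, {N * T}) ms attributed to the nearest window",
            stacklevel=2,
        )
    return (counts >= omega).astype(np.uint8)
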