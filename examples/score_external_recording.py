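"""Score an externally produced spike recording (the black-box path).

Any neuromorphic platform can be benchmarked by exporting this package's
network description and input spike trains, executing them remotely, and
scoring the recorded output CSV against the dataset.  Here the "external
platform" is simulated by writing the built-in substrate's output to CSV
and reading it back.
"""

import tempfile
from pathlib import Path

from binam import (
    DataParameters,
    EncodingSpec,
    SpikeTrainSet,
    build_network,
    encode,
    generate_dataset,
    run_backend,
    score_recall,
    train,
)
from binam.presets import REFERENCE_SETS

params = DataParameters(m=16, n=16, c=4, d=4, N=20)
dataset = generate_dataset(params, seed=1)
net = build_network(train(dataset), omega=1, params=REFERENCE_SETS["a"])
inputs = encode(dataset.X, EncodingSpec(s=1, sigma_t=2.0, seed=2))

with tempfile.TemporaryDirectory() as tmp:
    net_json = Path(tmp) / "network.json"
    in_csv = Path(tmp) / "inputs.csv"
    out_csv = Path(tmp) / "recorded.csv"
    net.to_json(net_json)          # what an external adapter receives
    inputs.to_csv(in_csv)
    outputs, wall = run_backend(net, inputs)   # stand-in for the hardware run
    outputs.to_csv(out_csv)

    recorded = SpikeTrainSet.from_csv(out_csv, n_channels=net.n_neurons,
                                      duration=inputs.duration)
    result = score_recall(recorded, dataset)

print(f"network: {net.n_inputs} channels, {net.n_neurons} neurons, "
      f"{net.n_synapses} synapses; execution {wall:.2f} s")
print(f"I_n = {result.I_n:.4f}  alpha_n = {result.alpha_n:+.4f}  "
      f"beta_n = {result.beta_n:.4f}")
# The CSV + JSON pair is the entire contract between the benchmark and a
# hardware platform: no simulator internals cross that boundary.
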