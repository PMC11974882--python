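"""Full representation benchmark on the default synthetic phantom.

Generates the two-class astrogliosis-like phantom (SNR 30, effect size
0.15), runs the paired-bootstrap protocol (here 10 resamples for a
quick demo; the study condition is 30), and prints the mean-kappa grid:
methods as rows, representations as columns.
"""

import warnings

import numpy as np

from mdmri import (BenchmarkConfig, astrogliosis_config, generate_dataset,
                   run_benchmark)

warnings.filterwarnings("ignore")

dataset = generate_dataset(astrogliosis_config(
    effect_size=0.15, snr=30.0, noise_model="rician", seed=0))
print(f"phantom: {dataset.n_voxels} voxels, "
      f"{dataset.signals.shape[1]} acquisitions, "
      f"failed inversions: {len(dataset.failed_voxels)}")

config = BenchmarkConfig(n_boot=10, seed=0)
report = run_benchmark(dataset, config)

header = "        " + "".join(f"{r:>9}" for r in config.representations)
print("\nmean Cohen's kappa (10 paired 50/50 resamples)")
print(header)
for i, method in enumerate(config.methods):
    row = report.mean_table()[i]
    print(f"{method:>7} " + "".join(f"{v:9.3f}" for v in row))
print("\nrow-wise best representation:", report.annotations()["row_max"])
# the 'signal' column winning each row is the central claim: the raw
# measurements carry at least as much label information as any
# reconstructed 2-D spectrum, consistent with the DPI
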