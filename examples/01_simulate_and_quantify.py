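"""Simulate a small deletion study and recover the counts from raw reads.

Builds a toy genome with miRNA hairpins (some inside the deletion interval),
draws NB counts for 4 control and 4 case libraries, writes FASTQ reads with
isomiR offsets / errors / adapters / background, and runs the quantifier.
"""

import math
import tempfile
from pathlib import Path

from mirdel import SimulationConfig, build_toy_reference, simulate_counts, synthesize_reads
from mirdel.quantify import quantify

config = SimulationConfig(
    n_control=4,
    n_case=4,
    n_mirnas=15,
    mean_expression=(math.log(120.0), 0.8),
    seed=42,
)
ref = build_toy_reference(config)
truth = simulate_counts(ref, config)

outdir = Path(tempfile.mkdtemp(prefix="mirdel_example_"))
paths = synthesize_reads(truth, ref, config, outdir)
print(f"simulated {len(truth.provenance)} reads for {len(config.samples)} libraries -> {outdir}")

result = quantify(paths, ref)
true = truth.true_counts.to_numpy()
err = abs(result.counts.to_numpy() - true).sum() / true.sum()
print(f"counts matrix: {result.counts.shape[0]} matures x {result.counts.shape[1]} samples")
print(f"relative count deficit vs truth: {err:.1%} "
      f"(~7% adapterless reads are unrecoverable; errors lose a further ~2%)")
print("\nper-sample read fates (fractions):")
print(result.fate_fractions().round(3).to_string())
# the miRNA column is the usable signal; background categories mimic the
# non-miRNA small-RNA content of a real library
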