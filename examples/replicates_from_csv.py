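"""Repeated measures read from a wide-format CSV.

Each subject was measured three times by method X (columns R1..R3) and once
by method Y.  Replicates are averaged per subject per method before
differencing, so the tolerance intervals describe differences of
per-subject means.
"""

import tempfile
from pathlib import Path

import numpy as np

from tolagree import analyze, read_paired_csv

rng = np.random.default_rng(7)
truth = rng.normal(50, 5, size=12)
rows = ["subject,R1,R2,R3,Y"]
for i, t in enumerate(truth):
    reps = t + 0.4 + rng.normal(0, 0.8, size=3)     # X: bias 0.4, noisy reps
    y = t + rng.normal(0, 0.5)
    rows.append(f"s{i}," + ",".join(f"{v:.3f}" for v in reps) + f",{y:.3f}")

csv_path = Path(tempfile.mkdtemp()) / "replicates.csv"
csv_path.write_text("\n".join(rows) + "\n")

sample = read_paired_csv(csv_path, x_cols=["R1", "R2", "R3"], y_cols=["Y"])
result = analyze(sample, beta=0.95, gamma=0.80)

print(f"subjects: {sample.n_subjects}, X replicates: {sample.x_values.shape[1]}")
s = result.summary
print(f"mean of per-subject mean differences = {s.mean_diff:.3f} (true bias 0.4)")
pi = result.intervals["PI_bTI"]
print(f"95% betaTI on mean differences: [{pi.lower:.3f}, {pi.upper:.3f}]")
# The interval covers where a future subject's mean X-Y difference is
# expected to fall; replicate-level noise is reduced by the averaging.
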