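"""Score a trajectory CSV against ground truth.

Builds a toy example in memory: three fish over ten frames, one of them
tracked wrongly for the last six frames.  The report shows how the seven
metrics respond — precision drops to 24/30 = 0.8, the bad fish's
correct fraction (0.4) lands it in the fragments bin, and MT falls to
2/3.  Replace the frames below with `read_trajectories("pred.csv")` /
`read_trajectories("gt.csv")` to score real files, or use
`fintrack eval --pred pred.csv --gt gt.csv` from the shell.
"""

import pandas as pd

from fintrack.evaluation import compute_metrics

gt = pd.DataFrame(
    [(t, f, 5.0 * t, 300.0 * f) for f in range(3) for t in range(10)],
    columns=["frame", "id", "x", "y"],
)
pred = gt.copy()
# fish 2 drifts far off target from frame 4 onward
wrong = (pred.id == 2) & (pred.frame >= 4)
pred.loc[wrong, "y"] += 900.0

report = compute_metrics(pred, gt, tol=70.0)
print(report)
print("\ncorrect fraction per ground-truth trajectory:")
for fish, frac in sorted(report.per_trajectory.items()):
    print(f"  fish {fish}: {frac:.2f}")
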