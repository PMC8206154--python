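"""Spike-count analysis pipeline on a synthetic recording with known truth.

Generates a gain-modulated Poisson size-tuning recording (non-monotonic mean,
monotonically decreasing Fano factor), then runs the full analysis: latency
estimation from the smoothed PSTH, windowed counts, per-condition statistics,
symmetric percent FF changes across sizes, and a mean-matched small-vs-large
comparison whose matched histograms are identical by construction.
"""

import numpy as np
import pandas as pd

from gsmvar import count_spikes, estimate_latency, mean_match_ff, percent_change_ff
from gsmvar.synthetic import generate, make_size_tuning_fixture

spec = make_size_tuning_fixture(
    sizes_deg=[0.34, 0.55, 0.90, 2.4, 3.8],
    mean_targets=[3.0, 5.0, 6.0, 5.0, 4.0],
    ff_targets=[1.5, 1.4, 1.3, 1.2, 1.1],
    n_trials=2000,
    latency_ms=60.0,
    seed=11,
)
table, truth = generate(spec)

latency = estimate_latency(table, "n0")
print(f"estimated latency: {latency:.1f} ms (programmed 60.0 ms)")

counts = count_spikes(table, latency)
rows = []
for cond, sub in table.groupby("condition"):
    c = counts.loc[sub.index].to_numpy()
    rows.append(
        {
            "size_deg": float(sub["size_deg"].iloc[0]),
            "mean": c.mean(),
            "ff": c.var(ddof=1) / c.mean(),
            "ff_true": truth["conditions"][cond]["ff"],
        }
    )
stats = pd.DataFrame(rows).sort_values("size_deg")
print(stats.round(3).to_string(index=False))

ffs = stats.set_index("size_deg")["ff"]
print(
    f"\nFF change (1/2 RF -> RF)  : {percent_change_ff(ffs[0.55], ffs[0.90]):+.1f}%"
    f"\nFF change (RF -> 2 RF)    : {percent_change_ff(ffs[0.90], ffs[2.4]):+.1f}%"
    "\n(positive means variability dropped for the larger stimulus)"
)

# mean-matched comparison on pseudo-cases built from trial chunks
rng = np.random.default_rng(0)
cases = []
for cond, sub in table.groupby("condition"):
    c = counts.loc[sub.index].to_numpy()
    for chunk in np.array_split(rng.permutation(c), 40):
        cases.append(
            {"size": float(sub["size_deg"].iloc[0]), "mean": chunk.mean(),
             "ff": chunk.var(ddof=1) / chunk.mean()}
        )
df = pd.DataFrame(cases)
mm = mean_match_ff(
    df[df["size"] < 0.90][["mean", "ff"]],
    df[df["size"] > 0.90][["mean", "ff"]],
    bin_width=0.25,
    seed=1,
)
print(
    f"\nmean-matched FF change (small vs large): {mm.percent_change:+.1f}% "
    f"(paired one-sided p = {mm.p_value:.2e}, {len(mm.matched_a)} matched cases)"
)
print("The FF difference survives equating the mean spike counts exactly.")
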