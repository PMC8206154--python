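"""Trial-aligned spike-count analysis: windowing, latency, QC, Fano factors,
tuning statistics, mean matching and the associated tests.

The pipeline operates on a "trial table": a pandas DataFrame with one row per
trial and columns

    neuron, condition, trial, spike_times (array of ms relative to stimulus
    onset), duration_ms, epoch_start_ms, epoch_end_ms

plus optional condition metadata (size_deg, stim_id, surround, rf_offset_deg).
Counting windows are half-open [start, end) so no spike is counted twice.
Spike counts are taken in a window of length equal to the stimulus duration,
shifted by the neuron's response latency (50 ms until a latency is estimated);
baseline activity is counted in the fixed [-20, 30) ms window around onset.
Variance estimates use the unbiased (n-1) form throughout; bootstrap CIs are
percentile intervals at 68% coverage, resampling trials within a condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import make_smoothing_spline

__all__ = [
    "REQUIRED_COLUMNS",
    "load_trial_table",
    "save_trial_table",
    "count_spikes",
    "baseline_stats",
    "estimate_latency",
    "QCRules",
    "NeuronQC",
    "apply_inclusion",
    "ConditionStats",
    "condition_stats",
    "average_over_conditions",
    "percent_change_ff",
    "mean_match_ff",
    "significance_by_ci_overlap",
    "nearest_size",
]

REQUIRED_COLUMNS = (
    "neuron",
    "condition",
    "trial",
    "spike_times",
    "duration_ms",
    "epoch_start_ms",
    "epoch_end_ms",
)

BASELINE_WINDOW_MS = (-20.0, 30.0)
DEFAULT_LATENCY_MS = 50.0

# Cubic smoothing-spline roughness penalty for PSTH regularization, with time
# measured in seconds (penalty lam * integral of f''^2). On the 1-ms PSTH grid
# this gives an effective smoothing bandwidth of a few milliseconds, enough to
# suppress bin noise without displacing threshold crossings.
PSTH_SPLINE_PARAM = 2e-6


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    if len(table) == 0:
        raise ValueError("trial table is empty")
    if (table["duration_ms"] <= 0).any():
        raise ValueError("duration_ms must be positive")
    return table


def save_trial_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table as CSV; spike times serialized as ';'-joined ms."""
    out = table.copy()
    out["spike_times"] = out["spike_times"].map(
        lambda ts: ";".join(f"{t:.4f}" for t in np.atleast_1d(ts))
    )
    out.to_csv(path, index=False)


def load_trial_table(path: str | Path) -> pd.DataFrame:
    """Read a trial table CSV produced by this package (or matching schema)."""
    table = pd.read_csv(path)
    _validate(table)

    def parse(s) -> np.ndarray:
        if not isinstance(s, str) or s == "":
            return np.empty(0)
        return np.asarray([float(t) for t in s.split(";")])

    table["spike_times"] = table["spike_times"].map(parse)
    return table


def _counts_in(spike_times: np.ndarray, start: float, end: float) -> int:
    ts = np.atleast_1d(spike_times)
    return int(((ts >= start) & (ts < end)).sum())


def count_spikes(
    table: pd.DataFrame,
    latency_ms: float | dict = DEFAULT_LATENCY_MS,
) -> pd.Series:
    """Spike counts per trial in the half-open window
    [onset + latency, onset + latency + duration).

    ``latency_ms`` may be a scalar or a {neuron: latency} mapping. Raises if
    the window exceeds the recorded epoch for any trial.
    """
    _validate(table)
    if isinstance(latency_ms, dict):
        lat = table["neuron"].map(latency_ms).astype(float)
        if lat.isna().any():
            missing = sorted(table.loc[lat.isna(), "neuron"].unique())
            raise ValueError(f"no latency for neurons: {missing}")
    else:
        lat = pd.Series(float(latency_ms), index=table.index)
    end = lat + table["duration_ms"]
    if (end > table["epoch_end_ms"]).any():
        raise ValueError("counting window exceeds recorded epoch")
    return pd.Series(
        [
            _counts_in(ts, lo, hi)
            for ts, lo, hi in zip(table["spike_times"], lat, end)
        ],
        index=table.index,
        name="count",
    )


def baseline_stats(table: pd.DataFrame) -> pd.DataFrame:
    """Per-neuron mean and sd of spike counts in the [-20, 30) ms baseline
    window around stimulus onset, across all trials."""
    _validate(table)
    lo, hi = BASELINE_WINDOW_MS
    if (table["epoch_start_ms"] > lo).any():
        raise ValueError("epochs must include the pre-onset baseline window")
    counts = pd.Series(
        [_counts_in(ts, lo, hi) for ts in table["spike_times"]], index=table.index
    )
    out = (
        pd.DataFrame({"neuron": table["neuron"], "count": counts})
        .groupby("neuron")["count"]
        .agg(baseline_mean="mean", baseline_sd=lambda c: c.std(ddof=1) if len(c) > 1 else 0.0)
        .reset_index()
    )
    return out


def _psth_rate(sub: pd.DataFrame, t_lo: float, t_hi: float) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged firing rate (spikes/s) in 1-ms bins over [t_lo, t_hi)."""
    edges = np.arange(t_lo, t_hi + 1.0, 1.0)
    all_ts = np.concatenate([np.atleast_1d(ts) for ts in sub["spike_times"]])
    hist, _ = np.histogram(all_ts, bins=edges)
    rate = hist / len(sub) * 1000.0  # per 1-ms bin -> spikes/s
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, rate


def estimate_latency(
    table: pd.DataFrame,
    neuron,
    condition_select: str = "preferred",
    spline_param: float = PSTH_SPLINE_PARAM,
) -> float | None:
    """Response latency: first time after onset at which the spline-smoothed
    PSTH crosses baseline mean + 1 baseline sd (rates in spikes/s).

    ``condition_select``: 'preferred' smooths the PSTH at the condition with
    the largest mean evoked count (used for size-tuning data); 'smallest_size'
    uses the smallest ``size_deg`` present. Returns None when the smoothed
    PSTH never crosses threshold (neuron flagged non-responsive).
    """
    sub = table[table["neuron"] == neuron]
    if len(sub) == 0:
        raise ValueError(f"no trials for neuron {neuron!r}")
    base = baseline_stats(sub).iloc[0]
    base_win = BASELINE_WINDOW_MS[1] - BASELINE_WINDOW_MS[0]
    thr = (base["baseline_mean"] + base["baseline_sd"]) / base_win * 1000.0

    if condition_select == "preferred":
        counts = count_spikes(sub, DEFAULT_LATENCY_MS)
        by_cond = counts.groupby(sub["condition"]).mean()
        cond = by_cond.idxmax()
    elif condition_select == "smallest_size":
        if "size_deg" not in sub.columns:
            raise ValueError("smallest_size selection requires a size_deg column")
        cond = sub.loc[sub["size_deg"].idxmin(), "condition"]
    else:
        raise ValueError(f"unknown condition_select: {condition_select!r}")
    sel = sub[sub["condition"] == cond]

    t_hi = float(sel["duration_ms"].iloc[0]) + DEFAULT_LATENCY_MS
    t, rate = _psth_rate(sel, float(sel["epoch_start_ms"].max()), t_hi)
    t_sec = t / 1000.0  # the roughness penalty is defined on a seconds axis
    smooth = make_smoothing_spline(t_sec, rate, lam=spline_param)(t_sec)
    after = t > 0
    crossing = after & (smooth > thr)
    if not crossing.any():
        return None
    return float(t[crossing][0])


@dataclass
class QCRules:
    """Inclusion rules, configurable per experiment type."""

    max_avg_ff: float = 2.0
    require_responsive: bool = True
    # size-tuning centering proxies: exclude peaks at/below min or above max
    size_peak_min_deg: float | None = None
    size_peak_max_deg: float | None = None
    # anesthetized RF mapping: max distance of RF center from stimulus center
    max_rf_offset_deg: float | None = None
    # condition-level: stimuli (at size nearest this) must drive the neuron
    drive_check_size_deg: float | None = None
    # image-level: minimum surround suppression of the mean count
    min_surround_suppression: float | None = None
    # anesthetized natural-image rule: responsive to at least this many stimuli
    min_significant_stimuli: int | None = None


@dataclass
class NeuronQC:
    neuron: object
    responsive: bool
    latency_ms: float | None
    avg_ff: float
    ff_ok: bool
    centering_ok: bool
    included: bool
    rules_fired: list = field(default_factory=list)


def _per_condition_counts(table: pd.DataFrame, latency) -> pd.DataFrame:
    counts = count_spikes(table, latency)
    df = table[["neuron", "condition"]].copy()
    if "size_deg" in table.columns:
        df["size_deg"] = table["size_deg"]
    if "stim_id" in table.columns:
        df["stim_id"] = table["stim_id"]
    df["count"] = counts
    return df


def apply_inclusion(
    table: pd.DataFrame, rules: QCRules
) -> tuple[list[NeuronQC], pd.DataFrame, list[str]]:
    """Apply the inclusion criteria; returns per-neuron QC records, the
    filtered trial table (excluded neurons and conditions dropped), and a log
    of every rule that fired.

    Per neuron: must be driven above baseline + 1 sd by some stimulus
    (responsivity, which also defines the latency), average FF across
    conditions <= ``max_avg_ff``, and the centering proxies (size-tuning peak
    position, RF offset) where configured. Conditions that fail condition-
    level rules (no drive at the ~1 deg size, weak surround suppression,
    undefined FF from a zero mean) are dropped for all included neurons.
    """
    _validate(table)
    log: list[str] = []
    qc: list[NeuronQC] = []
    keep_rows = pd.Series(True, index=table.index)

    base = baseline_stats(table).set_index("neuron")
    for neuron, sub in table.groupby("neuron", sort=False):
        fired: list[str] = []
        b = base.loc[neuron]
        thr = b["baseline_mean"] + b["baseline_sd"]
        counts50 = count_spikes(sub, DEFAULT_LATENCY_MS)
        cond_means = counts50.groupby(sub["condition"]).mean()
        responsive = bool((cond_means > thr).any())
        latency = estimate_latency(table, neuron) if responsive else None
        if latency is None:
            responsive = False
        if not responsive and rules.require_responsive:
            fired.append("not_responsive")

        lat = latency if latency is not None else DEFAULT_LATENCY_MS
        counts = count_spikes(sub, lat)
        grp = counts.groupby(sub["condition"])
        means = grp.mean()
        ffs = grp.var(ddof=1) / means
        ffs = ffs[np.isfinite(ffs)]
        avg_ff = float(ffs.mean()) if len(ffs) else np.nan
        ff_ok = bool(np.isfinite(avg_ff) and avg_ff <= rules.max_avg_ff)
        if not ff_ok:
            fired.append(f"avg_ff_{avg_ff:.3g}_above_{rules.max_avg_ff}")

        centering_ok = True
        if "size_deg" in sub.columns and (
            rules.size_peak_min_deg is not None or rules.size_peak_max_deg is not None
        ):
            sizes = sub.groupby("condition")["size_deg"].first()
            peak_size = float(sizes.loc[means.idxmax()])
            if rules.size_peak_min_deg is not None and peak_size <= rules.size_peak_min_deg:
                centering_ok = False
                fired.append(f"peak_at_small_size_{peak_size:g}")
            if rules.size_peak_max_deg is not None and peak_size > rules.size_peak_max_deg:
                centering_ok = False
                fired.append(f"peak_at_large_size_{peak_size:g}")
        if rules.max_rf_offset_deg is not None and "rf_offset_deg" in sub.columns:
            off = float(sub["rf_offset_deg"].iloc[0])
            if off > rules.max_rf_offset_deg:
                centering_ok = False
                fired.append(f"rf_offset_{off:g}")

        # condition-level rules for this neuron
        if rules.drive_check_size_deg is not None and "size_deg" in sub.columns:
            sizes = sub["size_deg"].unique()
            near = nearest_size(sizes, rules.drive_check_size_deg)
            near_conds = sub[sub["size_deg"] == near]
            cm = counts.loc[near_conds.index].groupby(near_conds["condition"]).mean()
            weak = cm[cm <= thr].index
            if "stim_id" in sub.columns:
                weak_stims = sub[sub["condition"].isin(weak)]["stim_id"].unique()
                bad = sub["stim_id"].isin(weak_stims)
            else:
                bad = sub["condition"].isin(weak)
            if bad.any():
                keep_rows.loc[sub.index[bad]] = False
                log.append(f"{neuron}: conditions without drive at ~{rules.drive_check_size_deg} deg dropped")
        if rules.min_significant_stimuli is not None and "stim_id" in sub.columns:
            by_stim = counts.groupby(sub["stim_id"]).mean()
            n_sig = int((by_stim > thr).sum())
            if n_sig < rules.min_significant_stimuli:
                fired.append(f"only_{n_sig}_significant_stimuli")
        if rules.min_surround_suppression is not None and "size_deg" in sub.columns:
            # surround suppression of the mean: 1 - response(largest)/response(peak)
            key = "stim_id" if "stim_id" in sub.columns else None
            groups = sub.groupby(key) if key else [(None, sub)]
            for stim, ssub in groups:
                scounts = counts.loc[ssub.index]
                m_by_size = scounts.groupby(ssub["size_deg"]).mean()
                if m_by_size.max() <= 0:
                    continue
                supp = 1.0 - m_by_size.loc[m_by_size.index.max()] / m_by_size.max()
                if supp < rules.min_surround_suppression:
                    keep_rows.loc[ssub.index] = False
                    log.append(f"{neuron}/{stim}: weak surround suppression ({supp:.2f})")

        included = (responsive or not rules.require_responsive) and ff_ok and centering_ok
        if not included:
            keep_rows.loc[sub.index] = False
        for rule in fired:
            log.append(f"{neuron}: {rule}")
        qc.append(
            NeuronQC(
                neuron=neuron,
                responsive=responsive,
                latency_ms=latency,
                avg_ff=avg_ff,
                ff_ok=ff_ok,
                centering_ok=centering_ok,
                included=included,
                rules_fired=fired,
            )
        )
    return qc, table[keep_rows].copy(), log


@dataclass
class ConditionStats:
    mean: float
    variance: float
    ff: float  # nan when mean is 0
    n_trials: int
    mean_ci: tuple[float, float]
    ff_ci: tuple[float, float]


def condition_stats(
    counts: np.ndarray, n_boot: int = 1000, seed: int = 0, level: float = 0.68
) -> ConditionStats:
    """Mean, unbiased variance, FF and percentile bootstrap CIs for one
    condition's across-trial spike counts."""
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2:
        raise ValueError("need at least 2 trials")
    mean = float(counts.mean())
    var = float(counts.var(ddof=1))
    ff = var / mean if mean > 0 else np.nan
    rng = np.random.default_rng(seed)
    idx = rng.integers(counts.size, size=(n_boot, counts.size))
    boots = counts[idx]
    bm = boots.mean(axis=1)
    bv = boots.var(axis=1, ddof=1)
    qs = [50 * (1 - level), 50 * (1 + level)]
    mean_ci = tuple(float(q) for q in np.percentile(bm, qs))
    with np.errstate(divide="ignore", invalid="ignore"):
        bff = np.where(bm > 0, bv / bm, np.nan)
    bff = bff[np.isfinite(bff)]
    ff_ci = (
        tuple(float(q) for q in np.percentile(bff, qs)) if bff.size else (np.nan, np.nan)
    )
    return ConditionStats(mean, var, ff, int(counts.size), mean_ci, ff_ci)


def average_over_conditions(stats_df: pd.DataFrame) -> pd.Series:
    """Collapse condition-wise statistics into a single per-neuron point:
    arithmetic mean of mean counts, geometric mean of Fano factors.

    Conditions with zero or undefined FF cannot enter a geometric mean; they
    are excluded and counted in ``n_ff_excluded``.
    """
    if not {"mean", "ff"}.issubset(stats_df.columns):
        raise ValueError("expected columns 'mean' and 'ff'")
    ffs = stats_df["ff"].to_numpy(dtype=float)
    ok = np.isfinite(ffs) & (ffs > 0)
    if not ok.any():
        raise ValueError("no positive finite FFs to average")
    return pd.Series(
        {
            "mean": float(stats_df["mean"].mean()),
            "ff": float(np.exp(np.log(ffs[ok]).mean())),
            "n_ff_excluded": int((~ok).sum()),
        }
    )


def percent_change_ff(ff_alpha: float, ff_beta: float) -> float:
    """Symmetric percent difference 100*(FF_a - FF_b) / ((FF_a + FF_b)/2).

    With FF_a at the RF-sized stimulus and FF_b at roughly twice the RF,
    a positive value means variability dropped for the larger stimulus.
    """
    if ff_alpha + ff_beta <= 0:
        raise ValueError("percent change undefined when FFs sum to zero")
    return 100.0 * (ff_alpha - ff_beta) / ((ff_alpha + ff_beta) / 2.0)


@dataclass
class MeanMatchResult:
    matched_a: pd.DataFrame
    matched_b: pd.DataFrame
    ff_mean_a: float
    ff_mean_b: float
    percent_change: float
    t_stat: float
    p_value: float


def mean_match_ff(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    bin_width: float = 1.0,
    seed: int = 0,
) -> MeanMatchResult:
    """Compare FFs between two groups of (mean, ff) cases after subsampling to
    exactly identical mean-count histograms.

    Cases are binned by mean count (integer-width bins by default, since
    counts are integers); in each bin min(n_a, n_b) cases are drawn from each
    group without replacement. The matched histograms are identical by
    construction (hard-asserted). The comparison is a one-sided paired t test
    of the null that FF_a - FF_b has mean <= 0, pairing cases within bins.
    """
    rng = np.random.default_rng(seed)
    a = group_a.reset_index(drop=True)
    b = group_b.reset_index(drop=True)
    for g, name in ((a, "group_a"), (b, "group_b")):
        if not {"mean", "ff"}.issubset(g.columns):
            raise ValueError(f"{name} must have 'mean' and 'ff' columns")
    bins_a = np.floor(a["mean"].to_numpy() / bin_width).astype(int)
    bins_b = np.floor(b["mean"].to_numpy() / bin_width).astype(int)
    take_a, take_b = [], []
    for binned in sorted(set(bins_a) & set(bins_b)):
        ia = np.flatnonzero(bins_a == binned)
        ib = np.flatnonzero(bins_b == binned)
        k = min(ia.size, ib.size)
        take_a.append(rng.choice(ia, size=k, replace=False))
        take_b.append(rng.choice(ib, size=k, replace=False))
    if not take_a:
        raise ValueError("mean-count supports are disjoint; no matched cases")
    ma = a.iloc[np.concatenate(take_a)].reset_index(drop=True)
    mb = b.iloc[np.concatenate(take_b)].reset_index(drop=True)
    ha = np.bincount(np.floor(ma["mean"] / bin_width).astype(int), minlength=1)
    hb = np.bincount(np.floor(mb["mean"] / bin_width).astype(int), minlength=1)
    assert len(ma) == len(mb) and np.array_equal(ha, hb), "matched histograms differ"
    t, p = stats.ttest_rel(ma["ff"], mb["ff"], alternative="greater")
    ffa, ffb = float(ma["ff"].mean()), float(mb["ff"].mean())
    return MeanMatchResult(
        matched_a=ma,
        matched_b=mb,
        ff_mean_a=ffa,
        ff_mean_b=ffb,
        percent_change=percent_change_ff(ffa, ffb),
        t_stat=float(t),
        p_value=float(p),
    )


def significance_by_ci_overlap(
    ci_a: tuple[float, float], ci_b: tuple[float, float]
) -> bool:
    """True iff the two 68% CIs are disjoint (touching endpoints count as
    overlapping: closed-interval convention)."""
    return ci_a[1] < ci_b[0] or ci_b[1] < ci_a[0]


def nearest_size(sizes, target: float) -> float:
    """Size in ``sizes`` closest to ``target`` by absolute log-ratio (the size
    series is multiplicative, so 'closest to' is judged on a log scale)."""
    sizes = np.asarray(sorted(set(np.asarray(sizes, dtype=float))))
    if (sizes <= 0).any() or target <= 0:
        raise ValueError("sizes and target must be positive")
    return float(sizes[np.argmin(np.abs(np.log(sizes / target)))])
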