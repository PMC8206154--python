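"""Surrogate trial-aligned spike recordings with known ground truth.

Spike trains are gain-modulated (doubly stochastic) Poisson processes: on each
trial a multiplicative gain is drawn from a mean-1 gamma distribution with a
per-condition coefficient of variation, and an inhomogeneous Poisson train is
emitted — baseline rate before the neuron's latency, gain x evoked rate for
the stimulus duration, baseline again afterwards. By the law of total
variance the spike count in the evoked window then has

    FF = 1 + mean_count * gain_cv**2,

so every fixture carries an analytic Fano factor per condition. This emulates
the across-trial gain fluctuations thought to underlie super-Poisson V1
variability; sub-Poisson (FF < 1) fixtures are outside this family.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .neural import save_trial_table

__all__ = ["ConditionSpec", "GeneratorSpec", "generate", "make_size_tuning_fixture"]


@dataclass(frozen=True)
class ConditionSpec:
    condition: str
    evoked_rate_hz: float
    gain_cv: float
    size_deg: float | None = None
    surround: str | None = None

    def __post_init__(self):
        if self.evoked_rate_hz < 0 or self.gain_cv < 0:
            raise ValueError("rates and gain_cv must be nonnegative")


@dataclass(frozen=True)
class GeneratorSpec:
    conditions: tuple[ConditionSpec, ...]
    n_neurons: int = 1
    n_trials: int = 100
    baseline_rate_hz: float = 5.0
    latency_ms: float | tuple[float, ...] = 60.0
    duration_ms: float = 200.0
    epoch_start_ms: float = -50.0
    epoch_pad_ms: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.n_trials < 2:
            raise ValueError("need at least 2 trials")
        if self.baseline_rate_hz < 0:
            raise ValueError("baseline rate must be nonnegative")

    def latency_of(self, i_neuron: int) -> float:
        if isinstance(self.latency_ms, (int, float)):
            return float(self.latency_ms)
        return float(self.latency_ms[i_neuron])

    @property
    def epoch_end_ms(self) -> float:
        lat = max(self.latency_of(i) for i in range(self.n_neurons))
        return lat + self.duration_ms + self.epoch_pad_ms


def _poisson_times(rng: np.random.Generator, rate_hz: float, t0: float, t1: float) -> np.ndarray:
    """Homogeneous Poisson spike times (ms) on [t0, t1)."""
    if rate_hz <= 0 or t1 <= t0:
        return np.empty(0)
    n = rng.poisson(rate_hz * (t1 - t0) / 1000.0)
    return np.sort(rng.uniform(t0, t1, size=n))


def generate(spec: GeneratorSpec) -> tuple[pd.DataFrame, dict]:
    """Generate a trial table plus its ground-truth record.

    Ground truth per (neuron, condition): programmed latency, expected evoked
    mean count, and the analytic FF = 1 + mean * gain_cv^2.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    truth = {"conditions": {}, "latency_ms": {}, "seed": spec.seed}
    for i in range(spec.n_neurons):
        neuron = f"n{i}"
        lat = spec.latency_of(i)
        truth["latency_ms"][neuron] = lat
        for cond in spec.conditions:
            mean_count = cond.evoked_rate_hz * spec.duration_ms / 1000.0
            truth["conditions"].setdefault(
                cond.condition,
                {
                    "mean_count": mean_count,
                    "ff": 1.0 + mean_count * cond.gain_cv**2,
                    "gain_cv": cond.gain_cv,
                    "size_deg": cond.size_deg,
                    "surround": cond.surround,
                },
            )
            if cond.gain_cv > 0:
                shape = 1.0 / cond.gain_cv**2
                gains = rng.gamma(shape, scale=1.0 / shape, size=spec.n_trials)
            else:
                gains = np.ones(spec.n_trials)
            for trial in range(spec.n_trials):
                pre = _poisson_times(rng, spec.baseline_rate_hz, spec.epoch_start_ms, lat)
                ev = _poisson_times(
                    rng, gains[trial] * cond.evoked_rate_hz, lat, lat + spec.duration_ms
                )
                post = _poisson_times(
                    rng, spec.baseline_rate_hz, lat + spec.duration_ms, spec.epoch_end_ms
                )
                row = {
                    "neuron": neuron,
                    "condition": cond.condition,
                    "trial": trial,
                    "spike_times": np.concatenate([pre, ev, post]),
                    "duration_ms": spec.duration_ms,
                    "epoch_start_ms": spec.epoch_start_ms,
                    "epoch_end_ms": spec.epoch_end_ms,
                }
                if cond.size_deg is not None:
                    row["size_deg"] = cond.size_deg
                if cond.surround is not None:
                    row["surround"] = cond.surround
                rows.append(row)
    return pd.DataFrame(rows), truth


def make_size_tuning_fixture(
    sizes_deg,
    mean_targets,
    ff_targets,
    n_neurons: int = 1,
    n_trials: int = 100,
    duration_ms: float = 200.0,
    latency_ms: float = 60.0,
    baseline_rate_hz: float = 5.0,
    seed: int = 0,
) -> GeneratorSpec:
    """Build a size-tuning GeneratorSpec hitting target mean counts and FFs.

    Inverts FF = 1 + mean * gain_cv^2 to set the per-condition gain CV. FF
    targets below 1 are unreachable for a gain-modulated Poisson generator and
    raise. Typical use: non-monotonic mean series with a monotonically
    decreasing FF series, the shape the size-tuning analysis should recover.
    """
    sizes = np.asarray(sizes_deg, dtype=float)
    means = np.asarray(mean_targets, dtype=float)
    ffs = np.asarray(ff_targets, dtype=float)
    if not (sizes.size == means.size == ffs.size):
        raise ValueError("sizes, mean_targets and ff_targets must align")
    if (ffs < 1.0).any():
        raise ValueError("FF targets below 1 are outside the generator family")
    if (means <= 0).any():
        raise ValueError("mean targets must be positive")
    conds = tuple(
        ConditionSpec(
            condition=f"size_{s:g}",
            evoked_rate_hz=m / (duration_ms / 1000.0),
            gain_cv=float(np.sqrt((f - 1.0) / m)),
            size_deg=float(s),
        )
        for s, m, f in zip(sizes, means, ffs)
    )
    return GeneratorSpec(
        conditions=conds,
        n_neurons=n_neurons,
        n_trials=n_trials,
        baseline_rate_hz=baseline_rate_hz,
        latency_ms=latency_ms,
        duration_ms=duration_ms,
        seed=seed,
    )


def write_fixture(spec: GeneratorSpec, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the generated table as CSV with a JSON ground-truth sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table, truth = generate(spec)
    csv_path = out_dir / "trials.csv"
    truth_path = out_dir / "ground_truth.json"
    save_trial_table(table, csv_path)
    truth["generator_spec"] = asdict(spec)
    truth_path.write_text(json.dumps(truth, indent=2))
    return csv_path, truth_path
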