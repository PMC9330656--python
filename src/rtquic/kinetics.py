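"""Trace processing and positivity calling for seed-amplification assays.

The procedure, applied per run (one plate / one batch of samples sharing a
normalization maximum):

1. For each sample, average its replicate wells and find the contiguous 10-h
   window with the lowest mean raw fluorescence; that mean is the sample's
   baseline.
2. Subtract the baseline from every replicate reading (negatives floored at
   0) and express readings as percent of the normalization maximum — by
   default the largest baseline-adjusted reading anywhere in the run.
3. Compute a noise threshold: mean of all normalized readings between 15 and
   17 h of incubation plus three sample standard deviations.
4. A replicate crosses when any reading at or before the 80-h cutoff reaches
   the effective threshold (by default the larger of the 20%-of-maximum line
   and the noise threshold); its lag time is the first such reading time.
5. A sample is positive when at least two of its four replicates cross
   (at least 2-of-k for samples with k < 4 replicates, k >= 2 required).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .trace_io import (
    Diagnosis,
    FluorescenceTrace,
    PlateMap,
    ReplicateCall,
    SampleCall,
    Specimen,
)

__all__ = [
    "CallingConfig",
    "NormalizedTraceSet",
    "RunResult",
    "GroupKineticsSummary",
    "find_baseline_window",
    "baseline_adjust_and_normalize",
    "compute_noise_threshold",
    "call_replicate",
    "call_sample",
    "process_run",
    "summarize_group_kinetics",
]


@dataclass(frozen=True)
class CallingConfig:
    """Parameters of the calling procedure.

    Defaults encode the published protocol: 10-h baseline window, 15–17 h
    noise window with a 3-SD multiplier, 20% positivity line, 80-h cutoff,
    2-of-4 replicate rule. ``threshold_mode`` selects which threshold(s)
    apply; ``max_of_both`` (default) requires a replicate to exceed both the
    20% line and the noise floor.
    """

    baseline_window_width: float = 10.0  # hours
    noise_window: tuple[float, float] = (15.0, 17.0)  # hours, closed interval
    noise_sd_multiplier: float = 3.0
    percent_threshold: float = 20.0  # percent of normalization maximum
    cutoff_time: float = 80.0  # hours
    min_positive_replicates: int = 2
    expected_replicates: int = 4
    threshold_mode: str = "max_of_both"  # percent_only | noise_only | max_of_both
    normalization_scope: str = "run"  # run | sample

    def __post_init__(self):
        if not 0 < self.percent_threshold < 100:
            raise ValueError("percent_threshold must be in (0, 100)")
        if self.noise_window[0] >= self.noise_window[1]:
            raise ValueError("noise_window must be an increasing interval")
        if self.min_positive_replicates > self.expected_replicates:
            raise ValueError("min_positive_replicates must be <= expected_replicates")
        if self.threshold_mode not in ("percent_only", "noise_only", "max_of_both"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.normalization_scope not in ("run", "sample"):
            raise ValueError(f"unknown normalization_scope {self.normalization_scope!r}")


@dataclass(frozen=True)
class NormalizedTraceSet:
    """One sample's replicates after baseline adjustment and normalization.

    ``replicate_percent`` has shape (n_replicates, n_times); rows follow
    ``well_ids`` order. Values are percent of ``normalization_max``.
    """

    sample_id: str
    times: np.ndarray
    well_ids: tuple[str, ...]
    replicate_percent: np.ndarray
    baseline_value: float
    baseline_window: tuple[float, float]
    normalization_max: float
    normalization_scope: str
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class RunResult:
    """All per-run artefacts of the calling procedure."""

    normalized: tuple[NormalizedTraceSet, ...]
    calls: tuple[SampleCall, ...]
    noise_threshold: float | None
    effective_threshold: float
    normalization_max: float
    config: CallingConfig


@dataclass(frozen=True)
class GroupKineticsSummary:
    """Endpoint/lag summary of a group, matching figure-style averages."""

    n_samples: int
    n_positive: int
    mean_endpoint_percent: float  # over positive samples
    mean_lag_hours: float  # over crossing replicates of positive samples
    times: np.ndarray
    mean_trace: np.ndarray  # pointwise mean of positive samples' mean traces
    sd_trace: np.ndarray


# ---------------------------------------------------------------------------


def find_baseline_window(
    times: np.ndarray, mean_rfu: np.ndarray, width: float = 10.0
) -> tuple[float, float, float, bool]:
    """Locate the lowest-mean contiguous window of the given duration.

    Scans every window starting at a reading time ``t_i`` and containing all
    readings in the closed interval ``[t_i, t_i + width]``; returns
    ``(t_start, t_end, baseline_value, clipped)`` for the window with the
    smallest mean, ties broken to the earliest start. When the trace spans
    less than ``width`` the whole trace is used and ``clipped`` is True.
    """
    times = np.asarray(times, dtype=float)
    mean_rfu = np.asarray(mean_rfu, dtype=float)
    if len(times) < 2:
        raise ValueError("baseline window requires at least 2 readings")
    span = times[-1] - times[0]
    if span < width:
        return float(times[0]), float(times[-1]), float(mean_rfu.mean()), True

    # window i covers readings with times in [t_i, t_i + width]
    ends = np.searchsorted(times, times + width, side="right")  # exclusive
    valid = times + width <= times[-1] + 1e-12  # full-duration windows only
    starts = np.nonzero(valid)[0]
    csum = np.concatenate([[0.0], np.cumsum(mean_rfu)])
    counts = ends[starts] - starts
    means = (csum[ends[starts]] - csum[starts]) / counts
    idx = int(np.argmin(means))  # argmin returns first minimum: earliest tie
    best = int(starts[idx])
    t0 = float(times[best])
    t1 = float(times[ends[best] - 1])
    return t0, t1, float(means[idx]), False


def _group_by_sample(traces: Sequence[FluorescenceTrace]) -> dict[str, list[FluorescenceTrace]]:
    groups: dict[str, list[FluorescenceTrace]] = {}
    for tr in traces:
        groups.setdefault(tr.sample_id, []).append(tr)
    for sid, trs in groups.items():
        trs.sort(key=lambda t: (t.replicate_index, t.well_id))
    return groups


def baseline_adjust_and_normalize(
    traces: Sequence[FluorescenceTrace], config: CallingConfig = CallingConfig()
) -> list[NormalizedTraceSet]:
    """Baseline-adjust and normalize all traces of one run.

    The baseline is estimated on each sample's mean-of-replicates trace and
    subtracted from every replicate reading of that sample (negatives floored
    at 0). Percent values are relative to the run-wide maximum by default
    (``normalization_scope="run"``) or each sample's own maximum
    (``"sample"``), in which case every sample peaks at 100%.
    """
    groups = _group_by_sample(traces)
    if not groups:
        raise ValueError("no traces supplied")

    adjusted: dict[str, dict] = {}
    for sid, trs in groups.items():
        t0 = trs[0].times
        for tr in trs[1:]:
            if len(tr.times) != len(t0) or not np.allclose(tr.times, t0):
                raise ValueError(
                    f"sample {sid!r}: replicates are not on a common time grid"
                )
        stack = np.vstack([tr.rfu for tr in trs])
        mean_trace = stack.mean(axis=0)
        ts, te, baseline, clipped = find_baseline_window(
            t0, mean_trace, config.baseline_window_width
        )
        adj = np.maximum(stack - baseline, 0.0)
        adjusted[sid] = {
            "times": t0,
            "wells": tuple(tr.well_id for tr in trs),
            "adj": adj,
            "baseline": baseline,
            "window": (ts, te),
            "flags": ("baseline_window_clipped",) if clipped else (),
        }

    run_max = max(float(d["adj"].max()) for d in adjusted.values())
    out = []
    for sid, d in adjusted.items():
        if config.normalization_scope == "run":
            norm_max = run_max
        else:
            norm_max = float(d["adj"].max())
        if norm_max <= 0:
            raise ValueError(
                "no signal in run" if config.normalization_scope == "run"
                else f"no signal in sample {sid!r}"
            )
        out.append(
            NormalizedTraceSet(
                sample_id=sid,
                times=d["times"],
                well_ids=d["wells"],
                replicate_percent=d["adj"] / norm_max * 100.0,
                baseline_value=d["baseline"],
                baseline_window=d["window"],
                normalization_max=norm_max,
                normalization_scope=config.normalization_scope,
                flags=d["flags"],
            )
        )
    return out


def compute_noise_threshold(
    normalized: Sequence[NormalizedTraceSet],
    noise_window: tuple[float, float] = (15.0, 17.0),
    sd_multiplier: float = 3.0,
) -> float:
    """Noise threshold: mean of all normalized readings in the window + k·SD.

    Pools every replicate reading of every sample whose time lies in the
    closed interval ``noise_window``; SD is the sample standard deviation
    (ddof=1). Requires at least 2 pooled readings.
    """
    pooled = []
    lo, hi = noise_window
    for ns in normalized:
        mask = (ns.times >= lo) & (ns.times <= hi)
        if mask.any():
            pooled.append(ns.replicate_percent[:, mask].ravel())
    values = np.concatenate(pooled) if pooled else np.empty(0)
    if values.size < 2:
        raise ValueError(
            f"fewer than 2 readings in noise window [{lo}, {hi}] h; cannot set threshold"
        )
    return float(values.mean() + sd_multiplier * values.std(ddof=1))


def _effective_threshold(config: CallingConfig, noise_threshold: float | None) -> float:
    if config.threshold_mode == "percent_only":
        return config.percent_threshold
    if noise_threshold is None:
        raise ValueError(
            f"threshold_mode {config.threshold_mode!r} requires a noise threshold"
        )
    if config.threshold_mode == "noise_only":
        return noise_threshold
    return max(config.percent_threshold, noise_threshold)


def call_replicate(
    times: np.ndarray,
    percent: np.ndarray,
    config: CallingConfig,
    noise_threshold: float | None = None,
    well_id: str = "",
) -> ReplicateCall:
    """Decide whether one normalized replicate crosses before the cutoff.

    The lag time is the time of the FIRST reading at or above the effective
    threshold — no interpolation, matching the discrete reader grid. Readings
    after the cutoff (closed: ``t <= cutoff_time``) are ignored.
    """
    thr = _effective_threshold(config, noise_threshold)
    mask = np.asarray(times) <= config.cutoff_time
    t = np.asarray(times)[mask]
    y = np.asarray(percent)[mask]
    above = np.nonzero(y >= thr)[0]
    if above.size:
        return ReplicateCall(well_id=well_id, crossed=True,
                             lag_time=float(t[above[0]]), threshold_used=thr)
    return ReplicateCall(well_id=well_id, crossed=False, lag_time=None, threshold_used=thr)


def call_sample(
    normalized: NormalizedTraceSet,
    config: CallingConfig,
    noise_threshold: float | None = None,
    subject_id: str = "",
    specimen: Specimen = Specimen.NS_AN,
    diagnosis: Diagnosis = Diagnosis.PD,
) -> SampleCall:
    """Aggregate replicate calls into a sample-level positivity decision.

    Positive iff at least ``min(min_positive_replicates, k)`` of the k
    replicates cross; samples with fewer than 2 replicates are an error.
    The endpoint is the mean across replicates of the last reading at or
    before the cutoff.
    """
    k = normalized.replicate_percent.shape[0]
    if k < 2:
        raise ValueError(
            f"sample {normalized.sample_id!r}: insufficient replicates ({k} < 2)"
        )
    rep_calls = tuple(
        call_replicate(normalized.times, normalized.replicate_percent[i], config,
                       noise_threshold, well_id=normalized.well_ids[i])
        for i in range(k)
    )
    required = min(config.min_positive_replicates, k)
    n_crossed = sum(rc.crossed for rc in rep_calls)
    mask = normalized.times <= config.cutoff_time
    if not mask.any():
        raise ValueError(f"sample {normalized.sample_id!r}: no readings before cutoff")
    last = int(np.nonzero(mask)[0][-1])
    endpoint = float(normalized.replicate_percent[:, last].mean())
    flags = list(normalized.flags)
    if k < config.expected_replicates:
        flags.append(f"fewer_replicates_than_expected:{k}")
    return SampleCall(
        sample_id=normalized.sample_id,
        subject_id=subject_id,
        specimen=specimen,
        diagnosis=diagnosis,
        replicate_calls=rep_calls,
        call="positive" if n_crossed >= required else "negative",
        endpoint_mean_percent=endpoint,
        flags=tuple(flags),
    )


def process_run(
    traces: Sequence[FluorescenceTrace],
    plate_map: PlateMap,
    config: CallingConfig = CallingConfig(),
) -> RunResult:
    """Run the full calling procedure on one run's annotated traces."""
    normalized = baseline_adjust_and_normalize(traces, config)
    if config.threshold_mode == "percent_only":
        noise_thr = None
    else:
        noise_thr = compute_noise_threshold(
            normalized, config.noise_window, config.noise_sd_multiplier
        )
    calls = []
    for ns in normalized:
        e = plate_map.sample_entry(ns.sample_id)
        calls.append(
            call_sample(ns, config, noise_thr, subject_id=e.subject_id,
                        specimen=e.specimen, diagnosis=e.diagnosis)
        )
    return RunResult(
        normalized=tuple(normalized),
        calls=tuple(calls),
        noise_threshold=noise_thr,
        effective_threshold=_effective_threshold(config, noise_thr),
        normalization_max=normalized[0].normalization_max
        if config.normalization_scope == "run" else float("nan"),
        config=config,
    )


def summarize_group_kinetics(
    calls: Sequence[SampleCall],
    normalized: Sequence[NormalizedTraceSet],
    selector: Callable[[SampleCall], bool],
) -> GroupKineticsSummary:
    """Figure-style group summary: endpoint/lag means over positive samples.

    ``selector`` picks the group (e.g. by specimen and diagnosis). Endpoint
    and lag averages are taken over positive samples only, mirroring how
    positive-trace averages are plotted; the mean±SD trace is computed
    pointwise over the positive samples' mean normalized traces on their
    common grid.
    """
    ns_by_sample = {ns.sample_id: ns for ns in normalized}
    group = [c for c in calls if selector(c)]
    if not group:
        raise ValueError("empty group")
    pos = [c for c in group if c.positive]
    if pos:
        endpoint = float(np.mean([c.endpoint_mean_percent for c in pos]))
        lags = [lt for c in pos for lt in c.lag_times]
        mean_lag = float(np.mean(lags)) if lags else float("nan")
        sample_means = np.vstack(
            [ns_by_sample[c.sample_id].replicate_percent.mean(axis=0) for c in pos]
        )
        times = ns_by_sample[pos[0].sample_id].times
        mean_trace = sample_means.mean(axis=0)
        sd_trace = sample_means.std(axis=0, ddof=1) if len(pos) > 1 else np.zeros_like(mean_trace)
    else:
        endpoint = float("nan")
        mean_lag = float("nan")
        times = ns_by_sample[group[0].sample_id].times
        mean_trace = np.full_like(times, np.nan, dtype=float)
        sd_trace = np.full_like(times, np.nan, dtype=float)
    return GroupKineticsSummary(
        n_samples=len(group),
        n_positive=len(pos),
        mean_endpoint_percent=endpoint,
        mean_lag_hours=mean_lag,
        times=times,
        mean_trace=mean_trace,
        sd_trace=sd_trace,
    )
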