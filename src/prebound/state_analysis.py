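"""Frame classification, dwell detection and per-state statistics.

A dissociation trajectory's centre-of-mass distance r(t) is first smoothed
with a centred moving average (200 ps window by default), then classified:
frames below 2.75 nm are fully bound, frames with 2.75 <= r <= 3.00 nm are
in the prebound band, and frames beyond the dissociation threshold are
dissociated.  A *prebound visit* is a contiguous stretch of at least 1 ns
(inclusive) inside the band — the criterion used to decide whether a run
passed through the metastable intermediate on its way out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .collective_variables import CV_NAMES, CVSeries

__all__ = [
    "SmoothingParams",
    "StateThresholds",
    "DwellReport",
    "StateStats",
    "moving_average",
    "label_states",
    "detect_prebound_visit",
    "state_statistics",
    "overlap_coefficient",
]


@dataclass(frozen=True)
class SmoothingParams:
    """Centred moving-average smoothing; edges use truncated windows."""

    window_ps: float = 200.0

    def __post_init__(self) -> None:
        if self.window_ps <= 0:
            raise ValueError("smoothing window must be positive")


@dataclass(frozen=True)
class StateThresholds:
    """Band edges (nm) and the minimum contiguous dwell (ns) for a visit."""

    prebound_low: float = 2.75
    prebound_high: float = 3.00
    bound_center: float = 2.65
    dissociated_above: float = 3.20
    min_dwell_ns: float = 1.0

    def __post_init__(self) -> None:
        if not (self.bound_center < self.prebound_low < self.prebound_high <= self.dissociated_above):
            raise ValueError(
                "thresholds must satisfy bound_center < prebound_low < prebound_high "
                "<= dissociated_above"
            )
        if self.min_dwell_ns <= 0:
            raise ValueError("min_dwell_ns must be positive")


@dataclass
class DwellReport:
    labels: np.ndarray  # per-frame state name
    intervals: list[tuple[float, float]]  # prebound (t_start, t_end), ps
    visited_prebound: bool
    dissociation_time_ns: float | None

    def to_dict(self) -> dict:
        return {
            "visited_prebound": bool(self.visited_prebound),
            "prebound_intervals_ps": [[float(a), float(b)] for a, b in self.intervals],
            "dissociation_time_ns": None
            if self.dissociation_time_ns is None
            else float(self.dissociation_time_ns),
            "n_frames": int(len(self.labels)),
        }


def _stride_of(times: np.ndarray) -> float:
    times = np.asarray(times, dtype=float)
    if times.size < 2:
        raise ValueError("need at least two samples")
    diffs = np.diff(times)
    if not np.allclose(diffs, diffs[0], rtol=1e-6, atol=1e-9):
        raise ValueError("series must be uniformly spaced in time")
    return float(diffs[0])


def moving_average(times: np.ndarray, values: np.ndarray, params: SmoothingParams) -> np.ndarray:
    """Centred moving average over a window of ``window_ps`` picoseconds.

    The window spans ``[t - w/2, t + w/2]`` inclusive; at the edges the
    window is truncated, so the output has the input's length and no phase
    shift.  A window equal to one stride is the identity.
    """
    values = np.asarray(values, dtype=float)
    stride = _stride_of(times)
    if params.window_ps < stride - 1e-9:
        raise ValueError(
            f"smoothing window ({params.window_ps} ps) is below the stride ({stride} ps)"
        )
    half = int(np.floor(params.window_ps / (2.0 * stride) + 1e-9))
    if half == 0:
        return values.copy()
    n = values.size
    csum = np.concatenate([[0.0], np.cumsum(values)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def label_states(r_smoothed: np.ndarray, thresholds: StateThresholds) -> np.ndarray:
    """Classify each frame from the smoothed centre-of-mass distance.

    ``bound`` below the band, ``prebound`` inside it (closed on both ends),
    ``transition`` between the band and the dissociation threshold, and
    ``dissociated`` beyond it.
    """
    r = np.asarray(r_smoothed, dtype=float)
    labels = np.full(r.shape, "transition", dtype=object)
    labels[r < thresholds.prebound_low] = "bound"
    labels[(r >= thresholds.prebound_low) & (r <= thresholds.prebound_high)] = "prebound"
    labels[r > thresholds.dissociated_above] = "dissociated"
    return labels.astype(str)


def detect_prebound_visit(
    times: np.ndarray, r_smoothed: np.ndarray, thresholds: StateThresholds = StateThresholds()
) -> DwellReport:
    """Find prebound intervals and decide whether the state was visited.

    An interval is a maximal contiguous run of frames inside the band; its
    duration is ``n_frames * stride`` (each sample represents one stride of
    simulated time) and the >= min_dwell comparison is inclusive.
    """
    times = np.asarray(times, dtype=float)
    r = np.asarray(r_smoothed, dtype=float)
    if times.size == 0 or r.size == 0:
        raise ValueError("empty series")
    if times.size != r.size:
        raise ValueError("times and series lengths differ")
    stride = _stride_of(times)
    labels = label_states(r, thresholds)
    in_band = labels == "prebound"

    intervals: list[tuple[float, float]] = []
    visited = False
    min_dwell_ps = thresholds.min_dwell_ns * 1000.0
    i = 0
    n = len(in_band)
    while i < n:
        if in_band[i]:
            j = i
            while j + 1 < n and in_band[j + 1]:
                j += 1
            intervals.append((float(times[i]), float(times[j])))
            duration = (j - i + 1) * stride
            if duration >= min_dwell_ps - 1e-9:
                visited = True
            i = j + 1
        else:
            i += 1

    diss = np.nonzero(r > thresholds.dissociated_above)[0]
    dissociation_time_ns = float(times[diss[0]] / 1000.0) if diss.size else None
    return DwellReport(labels, intervals, visited, dissociation_time_ns)


@dataclass
class StateStats:
    """Per-state mean/SD of each collective variable plus sample counts."""

    table: pd.DataFrame  # index: state; columns: <cv>_mean, <cv>_sd, count

    def count(self, state: str) -> int:
        return int(self.table.loc[state, "count"]) if state in self.table.index else 0

    def mean(self, state: str, cv: str) -> float:
        return float(self.table.loc[state, f"{cv}_mean"])

    def sd(self, state: str, cv: str) -> float:
        return float(self.table.loc[state, f"{cv}_sd"])

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index_label="state")


def state_statistics(cv_series: CVSeries, labels: np.ndarray) -> StateStats:
    """Per-state mean and SD of the six collective variables.

    The SD uses the n-1 normalisation; a single-frame state is reported with
    SD 0 and its count of 1 flags the degenerate estimate.
    """
    labels = np.asarray(labels)
    if len(labels) != len(cv_series):
        raise ValueError(
            f"labels ({len(labels)}) not aligned with CV series ({len(cv_series)})"
        )
    df = cv_series.to_dataframe().drop(columns="time_ps")
    df.columns = CV_NAMES
    df["state"] = labels
    grouped = df.groupby("state")
    out = {}
    for cv in CV_NAMES:
        out[f"{cv}_mean"] = grouped[cv].mean()
        out[f"{cv}_sd"] = grouped[cv].std(ddof=1).fillna(0.0)
    out["count"] = grouped[cv].count()
    return StateStats(pd.DataFrame(out))


def overlap_coefficient(sample_a: np.ndarray, sample_b: np.ndarray, n_bins: int | None = None) -> float:
    """Histogram overlap of two samples of the same variable, in [0, 1].

    Both samples are binned on a shared grid (Freedman-Diaconis width on the
    pooled sample unless ``n_bins`` is given); the overlap is the sum of
    bin-wise minima of the two normalised histograms.  Identical samples
    give 1, disjoint-support samples give 0.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("overlap of an empty sample is undefined")
    pooled = np.concatenate([a, b])
    lo, hi = pooled.min(), pooled.max()
    if hi == lo:
        return 1.0
    if n_bins is None:
        iqr = np.subtract(*np.percentile(pooled, [75, 25]))
        width = 2.0 * iqr / pooled.size ** (1 / 3)
        n_bins = max(int(np.ceil((hi - lo) / width)), 1) if width > 0 else 10
    edges = np.linspace(lo, hi, n_bins + 1)
    pa, _ = np.histogram(a, bins=edges)
    pb, _ = np.histogram(b, bins=edges)
    return float(np.minimum(pa / a.size, pb / b.size).sum())
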