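"""RR-interval preprocessing: segmentation, uniform resampling, detrending.

Raw RR series are unevenly sampled in time (one value per heartbeat).  The
matching-pursuit stage needs fixed-length, evenly sampled, zero-mean
segments, so a 256-beat window is (i) interpolated with a natural cubic
spline through the (cumulative beat time, RR value) pairs and evaluated on
1024 equally spaced points, nominally 4 Hz, and (ii) high-pass filtered
with the smoothness-priors detrender, a regularised trend removal that
behaves like a time-varying FIR high-pass filter.

Grid convention: the segment clock starts at the beginning of the first
interval, so the grid spans ``[0, sum(intervals)]``; with 256 beats of
800 ms this gives a 204.8 s segment and an effective rate of
``1023 / 204.8 ~= 4.995`` Hz.  The effective rate is recorded on the
output and used for all band-frequency conversions; exactly 4 Hz arises
only when the 256 beats happen to span 255.75 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.interpolate import CubicSpline
from scipy.sparse.linalg import splu

__all__ = [
    "RRSeries",
    "UniformHRV",
    "take_segment",
    "resample_uniform",
    "detrend_smoothness_priors",
    "preprocess",
    "read_rr_text",
    "load_cohort",
]


@dataclass
class RRSeries:
    """Ordered beat-to-beat intervals in milliseconds with a class tag."""

    intervals: np.ndarray
    label: str = "unknown"
    subject_id: str = ""

    def __post_init__(self):
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.ndim != 1:
            raise ValueError("intervals must be one-dimensional")
        if np.any(self.intervals <= 0):
            raise ValueError("all RR intervals must be positive")

    def __len__(self) -> int:
        return self.intervals.size


@dataclass
class UniformHRV:
    """Evenly sampled (and possibly detrended) HRV segment."""

    values: np.ndarray
    fs: float  # effective sampling rate, Hz
    duration: float  # seconds spanned by the segment
    label: str = "unknown"
    subject_id: str = ""

    @property
    def n(self) -> int:
        return self.values.size


def take_segment(rr: RRSeries, start_index: int = 0, length: int = 256) -> RRSeries:
    """Contiguous sub-series of ``length`` beats starting at ``start_index``."""
    if start_index < 0 or length < 1:
        raise ValueError("start_index must be >= 0 and length >= 1")
    if start_index + length > len(rr):
        raise ValueError(
            f"segment [{start_index}, {start_index + length}) exceeds "
            f"series length {len(rr)}"
        )
    return RRSeries(
        intervals=rr.intervals[start_index : start_index + length].copy(),
        label=rr.label,
        subject_id=rr.subject_id,
    )


def resample_uniform(seg: RRSeries, n_out: int = 1024) -> UniformHRV:
    """Evenly resample an RR segment with a natural cubic spline.

    Knots sit at the cumulative beat times (end of each interval, seconds);
    the spline is evaluated on ``n_out`` points spanning ``[0, duration]``
    where ``duration = sum(intervals)``.  The short lead-in before the
    first knot is covered by the natural spline's end polynomial, which is
    exact for constant and linear series.
    """
    if len(seg) < 4:
        raise ValueError("cubic-spline resampling needs at least 4 beats")
    times = np.cumsum(seg.intervals) / 1000.0  # s
    duration = float(times[-1])
    spline = CubicSpline(times, seg.intervals, bc_type="natural", extrapolate=True)
    grid = np.linspace(0.0, duration, n_out)
    values = spline(grid)
    fs = (n_out - 1) / duration
    return UniformHRV(
        values=values, fs=fs, duration=duration,
        label=seg.label, subject_id=seg.subject_id,
    )


def _second_difference(n: int) -> sp.csc_matrix:
    return sp.diags(
        [np.ones(n - 2), -2 * np.ones(n - 2), np.ones(n - 2)],
        offsets=[0, 1, 2], shape=(n - 2, n), format="csc",
    )


def detrend_smoothness_priors(x: UniformHRV, lam: float = 500.0) -> UniformHRV:
    """Remove the smoothness-priors trend and the mean.

    The trend is ``(I + lam**2 * D2' D2)**-1 x`` with ``D2`` the second
    difference operator; the regularisation parameter ``lam`` sets the
    effective high-pass cutoff (about 0.035 Hz for lam = 500 at 4 Hz —
    larger lam removes less).  The result has its sample mean subtracted so
    the output is exactly zero-mean.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    v = np.asarray(x.values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("input contains non-finite values")
    n = v.size
    d2 = _second_difference(n)
    a = (sp.identity(n, format="csc") + lam**2 * (d2.T @ d2)).tocsc()
    trend = splu(a).solve(v)
    z = v - trend
    z = z - z.mean()
    return UniformHRV(
        values=z, fs=x.fs, duration=x.duration,
        label=x.label, subject_id=x.subject_id,
    )


def preprocess(
    rr: RRSeries,
    start_index: int = 0,
    length: int = 256,
    n_out: int = 1024,
    lam: float = 500.0,
) -> UniformHRV:
    """Segment, resample and detrend: the full preprocessing chain."""
    seg = take_segment(rr, start_index=start_index, length=length)
    uni = resample_uniform(seg, n_out=n_out)
    return detrend_smoothness_priors(uni, lam=lam)


def read_rr_text(path, label: str = "unknown", subject_id: str = "") -> RRSeries:
    """Read an RR series from plain text, one interval (ms) per line."""
    intervals = np.loadtxt(path, dtype=float, ndmin=1)
    return RRSeries(intervals=intervals, label=label,
                    subject_id=subject_id or str(path))


def load_cohort(manifest_path) -> list[RRSeries]:
    """Load a cohort written by :func:`hrvmp.synthetic.write_cohort`.

    The manifest is a CSV with columns ``filename``, ``label``,
    ``subject_id`` (paths relative to the manifest's directory).
    """
    from pathlib import Path

    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    series = []
    for _, row in manifest.iterrows():
        series.append(
            read_rr_text(
                manifest_path.parent / row["filename"],
                label=str(row["label"]),
                subject_id=str(row["subject_id"]),
            )
        )
    return series
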