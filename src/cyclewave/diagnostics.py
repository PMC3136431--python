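"""Division-event detection, synchrony metrics and chaos diagnostics.

A *division event* at a position is an upward crossing of the doubly
phosphorylated (inactive) cyclin B-Cdk1 complex past the half-maximum of
the homogeneous limit-cycle oscillation; the count of such events over a
window is what the division-count maps display.  Spatio-temporal chaos is
quantified by the space-time correlation function of the mean-centered
field, its 1/e correlation length, and the frequency-doubling index of the
inter-division-interval distribution.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .kinetics import upward_crossings

__all__ = [
    "DivisionRecord", "CorrelationSurface", "detect_divisions",
    "division_count_map", "space_time_correlation", "correlation_length",
    "frequency_doubling_index", "classify_synchrony",
]


@dataclasses.dataclass
class DivisionRecord:
    """Ordered division times per position (or per cell).

    ``times[j]`` is a strictly increasing array of event times (minutes)
    at position/cell ``j``; ``positions`` carries the coordinate (mm) or
    cell identifier.
    """

    positions: np.ndarray
    times: list[np.ndarray]

    def __post_init__(self):
        for j, tj in enumerate(self.times):
            if np.any(np.diff(tj) <= 0):
                raise ValueError(f"division times at position {j} are not "
                                 "strictly increasing")

    @property
    def counts(self) -> np.ndarray:
        return np.array([len(tj) for tj in self.times])

    def in_window(self, t_start: float, t_end: float) -> "DivisionRecord":
        return DivisionRecord(
            self.positions,
            [tj[(tj >= t_start) & (tj <= t_end)] for tj in self.times])


def detect_divisions(t: np.ndarray, trace: np.ndarray,
                     threshold: float) -> np.ndarray:
    """Times of upward threshold crossings of one ``cycB_cdk1_YpTp`` trace,
    with linear interpolation between samples."""
    return upward_crossings(t, trace, threshold)


def division_count_map(t: np.ndarray, field: np.ndarray, threshold: float,
                       window: tuple[float, float] | None = None,
                       positions: np.ndarray | None = None,
                       ) -> tuple[DivisionRecord, dict]:
    """Per-position division events of a kymograph slice.

    ``field`` has shape (time, position).  Returns the
    :class:`DivisionRecord` restricted to ``window`` (default: everything)
    and a summary dict with the count minimum, maximum and spatial
    heterogeneity (max - min).
    """
    t = np.asarray(t, dtype=float)
    field = np.asarray(field, dtype=float)
    if positions is None:
        positions = np.arange(field.shape[1], dtype=float)
    times = [detect_divisions(t, field[:, j], threshold)
             for j in range(field.shape[1])]
    rec = DivisionRecord(np.asarray(positions, dtype=float), times)
    if window is not None:
        rec = rec.in_window(*window)
    c = rec.counts
    summary = {"min": int(c.min()), "max": int(c.max()),
               "heterogeneity": int(c.max() - c.min())}
    return rec, summary


@dataclasses.dataclass
class CorrelationSurface:
    """Normalized space-time correlation C(dx, dt) of a mean-centered field.

    ``C[i, k]`` is the correlation at spatial lag ``dx[i]`` (mm, >= 0) and
    temporal lag ``dt[k]`` (min, symmetric about 0); ``variance`` is the
    zero-lag (normalizing) second moment and ``window`` the time interval
    analyzed.
    """

    dx: np.ndarray
    dt: np.ndarray
    C: np.ndarray
    variance: float
    window: tuple[float, float]
    periodic: bool

    def at_zero_time_lag(self) -> tuple[np.ndarray, np.ndarray]:
        k0 = int(np.argmin(np.abs(self.dt)))
        return self.dx, self.C[:, k0]


def space_time_correlation(t: np.ndarray, field: np.ndarray, dx_mm: float,
                           window: tuple[float, float],
                           max_dx: float | None = None,
                           max_dt: float | None = None,
                           periodic: bool = False) -> CorrelationSurface:
    """Space-time correlation function of a kymograph.

    The field is mean-centered with the average taken over both time and
    space inside ``window``; the correlation at lag (dx, dt) is the average
    product of mean-centered values over all valid position/time pairs,
    normalized by the zero-lag value.  Space wraps when ``periodic``.
    """
    t = np.asarray(t, dtype=float)
    S = np.asarray(field, dtype=float)
    m = (t >= window[0]) & (t <= window[1])
    if m.sum() < 2:
        raise ValueError("analysis window contains fewer than two samples")
    S = S[m]
    tt = t[m]
    dt_samp = float(np.mean(np.diff(tt)))
    nT, nX = S.shape
    dS = S - S.mean()

    if max_dt is None:
        max_dt = (tt[-1] - tt[0]) / 2.0
    n_dt = int(max_dt / dt_samp)
    if n_dt >= nT:
        raise ValueError("window shorter than the largest requested "
                         "temporal lag")
    if max_dx is None:
        max_dx = (nX // 2 if periodic else nX - 1) * dx_mm
    n_dx = min(int(round(max_dx / dx_mm)), nX // 2 if periodic else nX - 1)

    # correlation sums via FFT: circular in space when periodic, linear
    # (zero-padded) otherwise; always linear in time
    pT = 2 * nT
    pX = nX if periodic else 2 * nX
    F = np.fft.rfft2(dS, s=(pT, pX))
    raw = np.fft.irfft2(F * np.conj(F), s=(pT, pX))
    # raw[dt % pT, dx % pX] = sum over pairs of dS(t, x) dS(t+dt, x+dx)
    dts = np.arange(-n_dt, n_dt + 1)
    dxs = np.arange(0, n_dx + 1)
    counts_t = nT - np.abs(dts)
    counts_x = np.full(dxs.shape, nX) if periodic else nX - dxs
    C = raw[np.ix_(dts % pT, dxs % pX)].T / np.outer(counts_x, counts_t)
    variance = float(C[0, len(dts) // 2])
    if variance <= 0:
        raise ValueError("field has zero variance inside the window")
    return CorrelationSurface(dx=dxs * dx_mm, dt=dts * dt_samp,
                              C=C / variance, variance=variance,
                              window=(float(tt[0]), float(tt[-1])),
                              periodic=periodic)


NO_DECAY = "no decay within range"


def correlation_length(surface: CorrelationSurface,
                       level: float = np.exp(-1.0)) -> float | str:
    """Smallest spatial lag where the equal-time correlation falls below
    1/e, by linear interpolation; :data:`NO_DECAY` if it never does."""
    dx, c = surface.at_zero_time_lag()
    below = np.where(c < level)[0]
    if len(below) == 0:
        return NO_DECAY
    i = below[0]
    if i == 0:
        return float(dx[0])
    f = (c[i - 1] - level) / (c[i - 1] - c[i])
    return float(dx[i - 1] + f * (dx[i] - dx[i - 1]))


def _two_means_1d(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact optimal two-cluster split of 1D data (minimal within-cluster
    sum of squares over all sorted splits)."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    csum = np.cumsum(v)
    csq = np.cumsum(v ** 2)
    best, best_k = np.inf, 1
    for k in range(1, n):
        s1, q1 = csum[k - 1], csq[k - 1]
        s2, q2 = csum[-1] - s1, csq[-1] - q1
        ss = (q1 - s1 ** 2 / k) + (q2 - s2 ** 2 / (n - k))
        if ss < best:
            best, best_k = ss, k
    return v[:best_k], v[best_k:]


def frequency_doubling_index(division_times: list[np.ndarray],
                             min_events: int = 20) -> dict:
    """Ratio of the two dominant inter-division-interval cluster centers.

    Pools the intervals of all traces, splits them into two clusters by an
    exact 1D two-means on log-intervals, and returns the ratio of cluster
    centers (~2 under frequency doubling, ~1 when unimodal) together with
    the cluster weights.
    """
    intervals = np.concatenate([np.diff(tj) for tj in division_times
                                if len(tj) >= 2]) if division_times else np.array([])
    n_events = sum(len(tj) for tj in division_times)
    if n_events < min_events:
        raise ValueError(f"need at least {min_events} events, got {n_events}")
    lo, hi = _two_means_1d(np.log(intervals))
    c_lo, c_hi = np.exp(lo.mean()), np.exp(hi.mean())
    return {"ratio": float(c_hi / c_lo),
            "centers": (float(c_lo), float(c_hi)),
            "weights": (len(lo) / len(intervals), len(hi) / len(intervals)),
            "n_intervals": int(len(intervals))}


def classify_synchrony(record: DivisionRecord, period: float,
                       window: tuple[float, float],
                       time_tol_fraction: float = 0.1) -> bool:
    """Left-half/right-half synchrony criterion.

    The run is synchronous iff, inside ``window``, (i) the mean division
    count of the left half equals that of the right half (rounded), and
    (ii) corresponding division events across ALL positions lie within
    ``time_tol_fraction`` of the period of each other.  Symmetric in the
    choice of which half is "left".
    """
    rec = record.in_window(*window)
    n = len(rec.times)
    left = rec.counts[: n // 2]
    right = rec.counts[n - n // 2:]
    if round(float(left.mean())) != round(float(right.mean())):
        return False
    n_common = min(len(tj) for tj in rec.times)
    if n_common == 0:
        return max(len(tj) for tj in rec.times) == 0
    for k in range(n_common):
        tk = np.array([tj[k] for tj in rec.times])
        if tk.max() - tk.min() >= time_tol_fraction * period:
            return False
    return True
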