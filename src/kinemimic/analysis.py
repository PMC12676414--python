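"""Downstream analyses: gait cycles and latent/kinematic embeddings.

Gait cycles are segmented at stance onsets of a reference limb (contact =
foot-site height below a threshold, since the kinematic world has no contact
solver), phase-normalized to a fixed number of points by cubic
interpolation, and pooled across strides. Latent or kinematic time series
are optionally time-delay embedded (sliding window concatenation) and
projected with PCA; variance-explained fractions quantify how compressed
the representation is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from sklearn.decomposition import PCA

log = logging.getLogger(__name__)


@dataclass
class GaitCycle:
    start: int  # frame of stance onset
    end: int  # frame of the next stance onset (exclusive)
    traces: np.ndarray  # (end - start, n_joints)
    duration_s: float

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("cycle must have positive length")


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray  # (samples, k)
    variance_explained: np.ndarray  # (k,) fractions, non-increasing

    def reshape(self, clips: int, timesteps: int) -> np.ndarray:
        return self.coordinates.reshape(clips, timesteps, -1)


def detect_stance_events(
    signal: np.ndarray,
    threshold: float = 0.005,
    min_duration: int = 1,
    is_contact_flags: bool = False,
) -> np.ndarray:
    """Stance-onset frames: rising edges of the contact indicator.

    ``signal`` is either a foot-height series (contact when height <=
    threshold; the tie at exactly the threshold counts as contact) or
    boolean contact flags. Contacts shorter than ``min_duration`` frames are
    debounced away.
    """
    signal = np.asarray(signal)
    if signal.size < 2:
        raise ValueError("series too short")
    contact = signal.astype(bool) if is_contact_flags else (signal <= threshold)
    onsets = []
    run = 0
    for t in range(contact.size):
        if contact[t]:
            run += 1
            if run == min_duration:
                onsets.append(t - min_duration + 1)
        else:
            run = 0
    return np.asarray(onsets, dtype=int)


def segment_gait_cycles(
    events: np.ndarray, traces: np.ndarray, rate: float
) -> list[GaitCycle]:
    """Cycles between consecutive stance onsets of the reference limb.

    ``traces`` is (frames, n_joints); the incomplete trailing cycle (after
    the last onset) is discarded. Fewer than 2 events yields an empty list.
    """
    events = np.asarray(events, dtype=int)
    traces = np.asarray(traces, dtype=float)
    if traces.ndim == 1:
        traces = traces[:, None]
    cycles = []
    for a, b in zip(events[:-1], events[1:]):
        cycles.append(GaitCycle(int(a), int(b), traces[a:b], (b - a) / rate))
    return cycles


def phase_normalize(
    cycles: list[GaitCycle], n_points: int = 100
) -> np.ndarray:
    """Resample each cycle onto ``n_points`` uniform phase samples.

    Cubic interpolation per joint trace; endpoints are preserved exactly.
    Cycles shorter than 4 frames (insufficient cubic support) are skipped
    with a log entry. Returns (n_kept, n_points, n_joints).
    """
    out = []
    for c in cycles:
        T = c.traces.shape[0]
        if T < 4:
            log.info("skipping %d-frame gait cycle at %d: too short for cubic fit", T, c.start)
            continue
        phase = np.linspace(0.0, 1.0, T)
        target = np.linspace(0.0, 1.0, n_points)
        spline = CubicSpline(phase, c.traces, axis=0)
        out.append(spline(target))
    return np.asarray(out) if out else np.zeros((0, n_points, 0))


def time_delay_embed(series: np.ndarray, window: int) -> np.ndarray:
    """Sliding concatenation of ``window`` consecutive frames.

    (T, d) -> (T - window + 1, d * window); window = 1 is the identity.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        series = series[:, None]
    T, d = series.shape
    if window < 1:
        raise ValueError("window must be >= 1")
    if T < window:
        raise ValueError(f"series of length {T} shorter than window {window}")
    rows = [series[t : t + window].reshape(-1) for t in range(T - window + 1)]
    return np.asarray(rows)


def pca_embed(X: np.ndarray, k: int = 3) -> EmbeddingResult:
    """Mean-centered principal-component projection with variance fractions."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < k:
        raise ValueError("need at least k samples")
    pca = PCA(n_components=k)
    coords = pca.fit_transform(X)
    return EmbeddingResult(coords, pca.explained_variance_ratio_.copy())


def mean_clip_speed(root_positions: np.ndarray, rate: float) -> float:
    """Mean instantaneous speed: average frame-displacement norm times rate."""
    p = np.asarray(root_positions, dtype=float)
    if p.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    steps = np.linalg.norm(np.diff(p, axis=0), axis=1)
    return float(steps.mean() * rate)
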