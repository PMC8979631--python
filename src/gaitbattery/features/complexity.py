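"""Signal-complexity characteristics (25 named scalars).

Two families:

* Phase-plot geometry: per stride, the closed orbit traced by
  (a(t), da/dt(t)) — acceleration against its central-difference
  derivative, both z-normalised over the bout.  Orbit area comes from the
  shoelace formula; half-orbit area asymmetries quantify the imbalance of
  the orbit about its principal axes; centroid drift measures
  stride-to-stride migration of the orbit.

* Largest Lyapunov exponent by Rosenstein's algorithm: delay-embed the
  signal, track the mean log divergence of nearest neighbours (Theiler
  window excludes temporally close pairs) and fit the initial slope.
  Higher exponents indicate locally less stable gait.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.spatial import cKDTree
from scipy import stats
from shapely.geometry import Polygon, box

from ..types import AXES_RES, GaitError, GaitEvents, RawRecording, resultant
from ..segmentation import segment as make_segments

logger = logging.getLogger(__name__)

ORBIT_MEASURES = ("orbit_area_mean", "orbit_area_sd", "long_asym",
                  "short_asym", "centroid_drift")
FEATURE_NAMES = tuple(
    f"cx_{m}_{ax}" for m in ORBIT_MEASURES for ax in AXES_RES
) + tuple(f"cx_lle_{ax}" for ax in AXES_RES) + ("cx_lle_joint",)

MIN_STRIDES = 5
MIN_LLE_DURATION = 30.0  # s
DEFAULT_EMBED_DIM = 5
JOINT_EMBED_DIM = 2  # per channel for the 3-axis joint state space
FALLBACK_DELAY = 10  # samples


# --------------------------------------------------------------------------
# phase-plot geometry
# --------------------------------------------------------------------------

def shoelace_area(points: np.ndarray) -> float:
    """Absolute shoelace area of the closed curve through `points`."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * abs(float(
        np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)))


def orbit_asymmetries(points: np.ndarray) -> tuple[float, float]:
    """(long-half, short-half) area asymmetry |A+ - A-| / (A+ + A-).

    Halves are taken on either side of the orbit's first / second
    principal axis through the point centroid, so both values are
    invariant to rotation and uniform scaling.
    """
    pts = np.asarray(points, dtype=float)
    center = pts.mean(axis=0)
    centered = pts - center
    cov = np.cov(centered.T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    frame = evecs[:, order]  # columns: long axis, short axis
    local = centered @ frame
    poly = Polygon(local)
    if not poly.is_valid:
        poly = poly.buffer(0)
    if poly.area <= 0:
        raise GaitError("degenerate orbit (zero area)")
    minx, miny, maxx, maxy = poly.bounds
    pad = 1.0 + max(maxx - minx, maxy - miny)

    def split(along_y: bool) -> float:
        if along_y:  # split by the long axis (the local x-axis)
            a_pos = poly.intersection(box(minx - pad, 0, maxx + pad,
                                          maxy + pad)).area
            a_neg = poly.intersection(box(minx - pad, miny - pad,
                                          maxx + pad, 0)).area
        else:  # split by the short axis (the local y-axis)
            a_pos = poly.intersection(box(0, miny - pad, maxx + pad,
                                          maxy + pad)).area
            a_neg = poly.intersection(box(minx - pad, miny - pad,
                                          0, maxy + pad)).area
        total = a_pos + a_neg
        return abs(a_pos - a_neg) / total if total > 0 else np.nan

    return split(along_y=True), split(along_y=False)


def phase_plot_features(x: np.ndarray, fs: float,
                        stride_slices: list[tuple[int, int]]
                        ) -> dict[str, float]:
    """The 5 orbit-geometry measures for one channel.

    x is the bout-level signal; stride_slices are [start, end) sample
    ranges of the strides whose orbits are analysed (>= 5 required).
    """
    if len(stride_slices) < MIN_STRIDES:
        raise GaitError(f"phase plots require >= {MIN_STRIDES} strides")
    deriv = np.gradient(x, 1.0 / fs)
    xz = (x - x.mean()) / x.std()
    dz = (deriv - deriv.mean()) / deriv.std()
    areas, longs, shorts, centroids = [], [], [], []
    for i0, i1 in stride_slices:
        pts = np.column_stack([xz[i0:i1], dz[i0:i1]])
        if len(pts) < 4:
            continue
        area = shoelace_area(pts)
        if area <= 0:
            logger.debug("degenerate orbit skipped")
            continue
        try:
            la, sa = orbit_asymmetries(pts)
        except GaitError:
            continue
        areas.append(area)
        longs.append(la)
        shorts.append(sa)
        centroids.append(pts.mean(axis=0))
    if not areas:
        return dict.fromkeys(ORBIT_MEASURES, np.nan)
    centroids = np.asarray(centroids)
    drift = float(np.sqrt(np.mean(
        np.sum((centroids - centroids.mean(axis=0)) ** 2, axis=1))))
    return {
        "orbit_area_mean": float(np.mean(areas)),
        "orbit_area_sd": float(np.std(areas, ddof=1)) if len(areas) > 1
        else np.nan,
        "long_asym": float(np.mean(longs)),
        "short_asym": float(np.mean(shorts)),
        "centroid_drift": drift,
    }


# --------------------------------------------------------------------------
# largest Lyapunov exponent (Rosenstein)
# --------------------------------------------------------------------------

def first_minimum_ami(x: np.ndarray, max_lag: int, bins: int = 16) -> int:
    """Delay at the first local minimum of average mutual information."""
    edges = np.histogram_bin_edges(x, bins=bins)
    xd = np.clip(np.digitize(x, edges[1:-1]), 0, bins - 1)
    amis = []
    for lag in range(1, max_lag + 1):
        a, b = xd[:-lag], xd[lag:]
        joint = np.zeros((bins, bins))
        np.add.at(joint, (a, b), 1.0)
        joint /= joint.sum()
        px = joint.sum(axis=1, keepdims=True)
        py = joint.sum(axis=0, keepdims=True)
        nz = joint > 0
        amis.append(float(np.sum(
            joint[nz] * np.log(joint[nz] / (px @ py)[nz]))))
        if len(amis) >= 3 and amis[-2] < amis[-3] and amis[-2] <= amis[-1]:
            return len(amis) - 1
    logger.debug("no AMI minimum found up to lag %d; using fallback %d",
                 max_lag, FALLBACK_DELAY)
    return FALLBACK_DELAY


def _delay_embed(X: np.ndarray, dim: int, tau: int) -> np.ndarray:
    """Stacked delay embedding; X is (T,) or (T, k) -> (m, k*dim)."""
    if X.ndim == 1:
        X = X[:, None]
    T, k = X.shape
    m = T - (dim - 1) * tau
    if m < 10:
        raise GaitError("signal too short for the requested embedding")
    cols = [X[j * tau:j * tau + m, c] for c in range(k) for j in range(dim)]
    return np.column_stack(cols)


def _nearest_neighbors(E: np.ndarray, ref_idx: np.ndarray,
                       theiler: int) -> np.ndarray:
    """Nearest neighbour (among all points) of each reference point,
    outside the Theiler window; -1 where none is found."""
    n = len(E)
    tree = cKDTree(E)
    nn = np.full(len(ref_idx), -1, dtype=int)
    unresolved = np.arange(len(ref_idx))
    k_try = min(max(2 * theiler + 2, 16), n)
    while len(unresolved) and k_try <= n:
        pts = ref_idx[unresolved]
        dist, idx = tree.query(E[pts], k=k_try)
        ok_mask = np.abs(idx - pts[:, None]) > theiler
        has = ok_mask.any(axis=1)
        first = np.argmax(ok_mask, axis=1)
        nn[unresolved[has]] = idx[has, first[has]]
        unresolved = unresolved[~has]
        if k_try == n:
            break
        k_try = min(k_try * 4, n)
    return nn


def lyapunov_rosenstein(signal: np.ndarray, fs: float,
                        embed_dim: int = DEFAULT_EMBED_DIM,
                        delay: int | None = None,
                        mean_period: float | None = None,
                        fit_window: tuple[float, float] | None = None,
                        min_duration: float = MIN_LLE_DURATION) -> float:
    """Largest Lyapunov exponent (1/s) of a scalar or multichannel series.

    signal: (T,) single channel or (T, k) joint state; each channel is
    delay-embedded with `embed_dim` dimensions and common delay `delay`
    (default: first AMI minimum of the first channel, fallback 10
    samples).  mean_period (s) sets the Theiler exclusion window — one
    mean stride for gait.  fit_window (s) bounds the least-squares slope
    fit on the mean log-divergence curve; the gait default is the first
    half stride, where short noisy bouts still diverge linearly.
    """
    X = np.asarray(signal, dtype=float)
    T = X.shape[0]
    if T / fs < min_duration:
        raise GaitError(f"lyapunov estimation requires >= {min_duration:g} s")
    if embed_dim < 1 or (delay is not None and delay < 1):
        raise GaitError("embed_dim and delay must be positive")
    first_chan = X if X.ndim == 1 else X[:, 0]
    if delay is None:
        delay = first_minimum_ami(first_chan, max_lag=int(fs))
    if mean_period is None:
        mean_period = 1.0  # s; generic fallback
    if fit_window is None:
        # the nearest neighbour is a biased minimum at s=0 and its bias
        # persists (in steps) until the shift clears the full embedding
        # memory (m-1)*tau; fitting only beyond that point keeps a pure
        # noisy sinusoid at ~0 while real divergence is still growing
        start = ((embed_dim - 1) * delay + 1) / fs
        fit_window = (start, start + 0.5 * mean_period)
    fit_start, fit_time = fit_window
    theiler = max(int(round(mean_period * fs)), 1)

    E = _delay_embed(X, embed_dim, delay)
    n_emb = len(E)
    # reference-point subsampling keeps the divergence average well
    # populated while bounding the neighbour-search cost on long bouts
    ref_stride = max(1, int(np.ceil(n_emb / 2500)))
    ref_idx = np.arange(0, n_emb, ref_stride)
    nn = _nearest_neighbors(E, ref_idx, theiler)
    n_follow = int(round(fit_time * fs))
    valid = (nn >= 0) & (ref_idx + n_follow < n_emb) & \
        (nn + n_follow < n_emb)
    i_idx, j_idx = ref_idx[valid], nn[valid]
    if len(i_idx) < 10:
        logger.warning("too few valid neighbour pairs; exponent missing")
        return np.nan
    log_div = np.empty(n_follow + 1)
    for s in range(n_follow + 1):
        d = np.linalg.norm(E[i_idx + s] - E[j_idx + s], axis=1)
        d = d[d > 0]
        log_div[s] = np.mean(np.log(d)) if len(d) else np.nan
    t = np.arange(n_follow + 1) / fs
    ok = np.isfinite(log_div) & (t >= fit_start)
    if ok.sum() < 3:
        return np.nan
    slope, *_ = stats.linregress(t[ok], log_div[ok])
    return float(slope)


# --------------------------------------------------------------------------
# feature vector
# --------------------------------------------------------------------------

def complexity_vector(rec: RawRecording, ev: GaitEvents) -> dict[str, float]:
    """All 25 complexity characteristics for one preprocessed recording."""
    out = dict.fromkeys(FEATURE_NAMES, np.nan)
    res = resultant(rec.samples)
    channels = {"vt": rec.vt, "ml": rec.ml, "ap": rec.ap, "res": res}

    strides = make_segments(rec, ev, "stride")
    slices = [(s.start_idx, s.end_idx) for s in strides]
    stride_times = [(s.end_idx - s.start_idx) / rec.fs for s in strides]
    mean_stride = float(np.mean(stride_times)) if stride_times else 1.0

    for ax, x in channels.items():
        try:
            for m, v in phase_plot_features(x, rec.fs, slices).items():
                out[f"cx_{m}_{ax}"] = v
        except GaitError as exc:
            logger.warning("%s phase plot (%s): %s", rec.subject_id, ax, exc)
        try:
            out[f"cx_lle_{ax}"] = lyapunov_rosenstein(
                x, rec.fs, embed_dim=DEFAULT_EMBED_DIM,
                mean_period=mean_stride)
        except GaitError as exc:
            logger.warning("%s lyapunov (%s): %s", rec.subject_id, ax, exc)
    try:
        out["cx_lle_joint"] = lyapunov_rosenstein(
            rec.samples, rec.fs, embed_dim=JOINT_EMBED_DIM,
            mean_period=mean_stride)
    except GaitError as exc:
        logger.warning("%s lyapunov (joint): %s", rec.subject_id, exc)
    return out
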