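"""Recurrence quantification analysis of scalp EEG.

Pipeline per signal: time-delay embedding with the delay tau chosen at the
first local minimum of average mutual information (AMI, max lag 200) and the
dimension m chosen by the Kennel false-nearest-neighbor (FNN) test; a
recurrence plot thresholded at the epsilon that attains a fixed target
recurrence rate (default 0.05) outside a Theiler band; and 13 recurrence
measures: RR, DET, L, Lmax, ENTR (diagonal lines), LAM, TT, Vmax (vertical
lines), RTmax, T2, RTE (white vertical gaps / recurrence times of the second
type), and Clust, Trans (the Theiler-masked plot read as a recurrence
network's adjacency matrix).

The per-recording protocol repeatedly draws 10-s windows from the admissible
span (after trimming 4 s head and 10 s tail), runs the full analysis on each
window, and averages features over windows and then channels.

Conventions (fixed, and mirrored by the brute-force oracle in the tests):
cells inside the Theiler band count as non-recurrent everywhere; vertical
structures are extracted per column on the two admissible segments either
side of the band; white gaps are interior zero-runs strictly between
recurrence points; T2 = mean(gap) + 1; empty histograms yield 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .synthetic import EEGRecording

__all__ = [
    "EmbeddingParams",
    "RecurrencePlot",
    "RQA_FEATURE_NAMES",
    "preprocess_eeg",
    "select_delay_ami",
    "select_dim_fnn",
    "embed",
    "recurrence_matrix",
    "rqa_features",
    "rqa_protocol",
]

RQA_FEATURE_NAMES = [
    "RR", "DET", "L", "Lmax", "ENTR", "LAM", "TT", "Vmax",
    "RTmax", "T2", "RTE", "Clust", "Trans",
]


@dataclass
class EmbeddingParams:
    tau: int
    m: int

    def __post_init__(self) -> None:
        if self.tau < 1 or self.m < 1:
            raise ValueError("tau and m must be >= 1")


@dataclass
class RecurrencePlot:
    R: np.ndarray  # boolean N' x N'
    epsilon: float
    theiler: int
    rr_target: float | None
    params: EmbeddingParams | None = None

    @property
    def n_points(self) -> int:
        return self.R.shape[0]


def preprocess_eeg(
    rec: EEGRecording,
    target_fs: float = 500.0,
    band: tuple[float, float] = (1.0, 80.0),
    notch: float = 50.0,
) -> EEGRecording:
    """Downsample to 500 Hz, band-pass 1-80 Hz, notch 50 Hz, average-reference.

    Zero-phase FIR filtering via mne. An input rate below ``target_fs`` is
    kept (with a warning); below twice the band's upper edge it is rejected.
    """
    import mne

    if rec.fs < 2 * band[1]:
        raise ValueError(
            f"sampling rate {rec.fs} Hz cannot represent the {band[1]} Hz band edge"
        )
    data = rec.data.astype(np.float64)
    fs = rec.fs
    if fs > target_fs:
        data = mne.filter.resample(data, down=fs / target_fs, verbose="error")
        fs = target_fs
    elif fs < target_fs:
        warnings.warn(f"input rate {fs} Hz below {target_fs} Hz; keeping input rate")
    data = mne.filter.filter_data(data, fs, band[0], band[1], verbose="error")
    if notch and notch < fs / 2:
        data = mne.filter.notch_filter(data, fs, notch, verbose="error")
    data = data - data.mean(axis=0, keepdims=True)  # average reference
    return EEGRecording(data, fs, list(rec.channel_labels))


def _ami(x: np.ndarray, lag: int, bins: int, edges: np.ndarray) -> float:
    a = x[: x.size - lag]
    b = x[lag:]
    joint, _, _ = np.histogram2d(a, b, bins=[edges, edges])
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / np.outer(px, py)[nz])).sum())


def select_delay_ami(x: np.ndarray, max_lag: int = 200, window: int = 3) -> int:
    """First local minimum of average mutual information over lags 1..max_lag.

    A lag counts as the first minimum when its AMI is minimal within a
    +/- ``window`` lag neighborhood and strictly below the value ``window``
    lags later; the window guards against spurious dips of the histogram
    estimator (ceil(sqrt(N)) equal-width bins per marginal). Falls back
    (with a warning) to the first lag with AMI < AMI(0)/e when no local
    minimum exists.
    """
    x = np.asarray(x, dtype=float)
    if x.size <= 4 * max_lag:
        raise ValueError(f"signal too short for max_lag={max_lag}")
    if np.ptp(x) == 0:
        raise ValueError("constant signal: AMI undefined")
    bins = int(np.ceil(np.sqrt(x.size)))
    edges = np.linspace(x.min(), x.max(), bins + 1)
    ami0 = _ami(x, 0, bins, edges)
    if _ami(x, 1, bins, edges) < ami0 / np.e:
        # uncorrelated signal: the curve starts at its floor, below the
        # 1/e level, and no meaningful minimum exists
        warnings.warn("AMI below the 1/e level already at lag 1; tau=1")
        return 1
    vals = [ami0]  # vals[k] = AMI at lag k
    for lag in range(1, max_lag + 1):
        vals.append(_ami(x, lag, bins, edges))
        k = lag - window
        if k >= 1:
            lo = max(0, k - window)
            seg = vals[lo: k + window + 1]
            if vals[k] == min(seg) and vals[k] < vals[k + window]:
                return k
    ami_vals = vals[1:]
    # no local minimum: fall back to the 1/e criterion
    thresh = ami0 / np.e
    below = [i + 1 for i, v in enumerate(ami_vals) if v < thresh]
    fallback = below[0] if below else 1
    warnings.warn(f"no AMI local minimum within {max_lag} lags; tau={fallback} via 1/e rule")
    return fallback


def embed(x: np.ndarray, tau: int, m: int) -> np.ndarray:
    """Delay embedding: rows are (x_t, x_{t+tau}, ..., x_{t+(m-1)tau})."""
    x = np.asarray(x, dtype=float)
    n = x.size - (m - 1) * tau
    if n < 1:
        raise ValueError("series too short for requested embedding")
    idx = np.arange(n)[:, None] + tau * np.arange(m)[None, :]
    return x[idx]


def _fnn_fraction(
    x: np.ndarray, tau: int, m: int, rtol: float, atol: float, theiler: int
) -> float:
    """Kennel false-neighbor fraction going from dimension m to m+1."""
    n_next = x.size - m * tau  # points that survive in dimension m+1
    if n_next < 10:
        raise ValueError("series too short for FNN at this dimension")
    Y = embed(x, tau, m)[:n_next]
    tree = cKDTree(Y)
    k = min(2 * theiler + 3, n_next)
    dist, idx = tree.query(Y, k=k)
    ra = x.std()
    false = 0
    total = 0
    extra = x[m * tau:]  # the coordinate added in dimension m+1
    for i in range(n_next):
        j = -1
        for cand, d in zip(idx[i], dist[i]):
            if abs(int(cand) - i) > theiler:
                j, dij = int(cand), d
                break
        if j < 0 or dij == 0:
            continue
        total += 1
        gap = abs(extra[i] - extra[j])
        if gap / dij > rtol or np.hypot(dij, gap) / ra > atol:
            false += 1
    return false / total if total else 0.0


def select_dim_fnn(
    x: np.ndarray,
    tau: int,
    m_max: int = 10,
    rtol: float = 10.0,
    atol: float = 2.0,
    fnn_threshold: float = 0.01,
    theiler: int | None = None,
) -> int:
    """Smallest dimension whose false-neighbor fraction drops below threshold.

    Temporal neighbors within the Theiler window (default tau) are excluded
    as nearest-neighbor candidates, as appropriate for oversampled flows. If
    the threshold is never reached, the argmin dimension is returned with a
    warning.
    """
    if m_max < 2:
        raise ValueError("m_max must be >= 2")
    theiler = tau if theiler is None else theiler
    fracs = []
    for m in range(1, m_max + 1):
        f = _fnn_fraction(np.asarray(x, float), tau, m, rtol, atol, theiler)
        fracs.append(f)
        if f < fnn_threshold:
            return m  # neighbors in dimension m survive the lift: m suffices
    best = int(np.argmin(fracs)) + 1
    warnings.warn(
        f"FNN fraction never fell below {fnn_threshold}; using argmin m={best}"
    )
    return best


@lru_cache(maxsize=64)
def _admissible_mask(n: int, theiler: int) -> np.ndarray:
    i = np.arange(n)
    mask = np.abs(i[:, None] - i[None, :]) > theiler
    mask.setflags(write=False)  # cached: callers must not mutate
    return mask


def recurrence_matrix(
    x: np.ndarray,
    params: EmbeddingParams,
    rr_target: float | None = 0.05,
    theiler: int | None = None,
    epsilon: float | None = None,
    rr_tol: float = 0.005,
) -> RecurrencePlot:
    """Thresholded distance matrix of the embedded signal.

    Either ``rr_target`` (epsilon solved so the achieved recurrence rate over
    admissible cells equals the target within ``rr_tol``) or a fixed
    ``epsilon`` must be given. Euclidean norm; Theiler half-width defaults to
    tau.
    """
    theiler = params.tau if theiler is None else theiler
    Y = embed(x, params.tau, params.m)
    n = Y.shape[0]
    if n < 100:
        raise ValueError(f"embedded series too short (N'={n} < 100)")
    if Y.std() == 0:
        raise ValueError("zero-variance trajectory")
    D = cdist(Y, Y)
    mask = _admissible_mask(n, theiler)
    if epsilon is None:
        if rr_target is None:
            raise ValueError("give either rr_target or epsilon")
        dvals = D[mask]
        epsilon = float(np.quantile(dvals, rr_target))
        R = (D <= epsilon) & mask
        rr = R.sum() / mask.sum()
        if abs(rr - rr_target) > rr_tol:
            raise ValueError(
                f"recurrence rate {rr:.4f} unattainable within +/-{rr_tol} of "
                f"{rr_target} (too many tied distances)"
            )
    else:
        R = (D <= epsilon) & mask
    return RecurrencePlot(
        R=R, epsilon=float(epsilon), theiler=theiler, rr_target=rr_target,
        params=params,
    )


def _run_lengths(col: np.ndarray) -> np.ndarray:
    """Lengths of maximal 1-runs in a boolean vector."""
    if not col.any():
        return np.empty(0, dtype=int)
    padded = np.concatenate([[0], col.view(np.int8), [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return ends - starts


def _diagonal_lines(R: np.ndarray, theiler: int) -> np.ndarray:
    """Lengths of diagonal 1-runs on both sides of the Theiler band.

    R is symmetric, so upper-triangle runs are counted twice.
    """
    n = R.shape[0]
    sep = np.zeros(1, dtype=bool)
    segs = []
    for k in range(theiler + 1, n):
        segs.append(np.diagonal(R, k))
        segs.append(sep)
    if not segs:
        return np.empty(0, dtype=int)
    up = _run_lengths(np.concatenate(segs))
    return np.concatenate([up, up])  # symmetric lower triangle


def _vertical_structures(
    R: np.ndarray, theiler: int
) -> tuple[np.ndarray, np.ndarray]:
    """(vertical 1-run lengths, interior white-gap lengths) over all columns.

    Each column is split by the Theiler band into an upper and lower
    admissible segment; runs never bridge the band. White gaps are zero-runs
    strictly between two recurrence points of the same segment.
    """
    n = R.shape[0]
    # column-major flattening with one separator row; Theiler cells are
    # already zero in R, so 1-runs cannot bridge the band or the columns
    Rp = np.zeros((n + 1, n), dtype=bool)
    Rp[:n] = R
    flat = Rp.T.ravel()
    v = _run_lengths(flat)
    # white gaps: zero-runs strictly between two recurrences of the same
    # admissible segment; Theiler cells and the separator row are breaks
    ones_pos = np.flatnonzero(flat)
    if ones_pos.size < 2:
        return v, np.empty(0, dtype=int)
    same_seg = np.diff(_break_cumsum(n, theiler)[ones_pos]) == 0
    gaps = np.diff(ones_pos) - 1
    w = gaps[same_seg & (gaps > 0)]
    return v, w


@lru_cache(maxsize=64)
def _break_cumsum(n: int, theiler: int) -> np.ndarray:
    """Cumulative count of segment breaks along the column-major flattening."""
    Bp = np.ones((n + 1, n), dtype=bool)
    Bp[:n] = ~_admissible_mask(n, theiler)
    cb = np.cumsum(Bp.T.ravel())
    cb.setflags(write=False)
    return cb


def _entropy(lengths: np.ndarray) -> float:
    if lengths.size == 0:
        return 0.0
    _, counts = np.unique(lengths, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def _network_measures(R: np.ndarray) -> tuple[float, float]:
    """Mean local clustering and transitivity of the recurrence network."""
    ii, jj = np.nonzero(R)
    A = csr_matrix(
        (np.ones(ii.size, dtype=np.float64), (ii, jj)), shape=R.shape
    )
    k = np.asarray(A.sum(axis=1)).ravel()
    tri2 = np.asarray((A @ A).multiply(A).sum(axis=1)).ravel()  # 2*triangles
    denom = k * (k - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        local = np.where(denom > 0, tri2 / denom, 0.0)
    clust = float(local.mean())
    triples = denom.sum()
    trans = float(tri2.sum() / triples) if triples > 0 else 0.0
    return clust, trans


def rqa_features(rp: RecurrencePlot, lmin: int = 2, vmin: int = 2) -> pd.Series:
    """The 13 recurrence measures of a plot (see module docstring)."""
    R = rp.R
    n = R.shape[0]
    mask_count = _admissible_mask(n, rp.theiler).sum()
    n_rec = int(R.sum())
    rr = n_rec / mask_count if mask_count else 0.0

    diag = _diagonal_lines(R, rp.theiler)
    long_d = diag[diag >= lmin]
    det = float(long_d.sum() / diag.sum()) if diag.sum() else 0.0
    L = float(long_d.mean()) if long_d.size else 0.0
    lmax = int(diag.max()) if diag.size else 0
    entr = _entropy(long_d)

    vert, white = _vertical_structures(R, rp.theiler)
    long_v = vert[vert >= vmin]
    lam = float(long_v.sum() / vert.sum()) if vert.sum() else 0.0
    tt = float(long_v.mean()) if long_v.size else 0.0
    vmax = int(vert.max()) if vert.size else 0

    rtmax = int(white.max()) if white.size else 0
    t2 = float(white.mean() + 1.0) if white.size else 0.0
    rte = _entropy(white)

    clust, trans = _network_measures(R)
    return pd.Series(
        [rr, det, L, lmax, entr, lam, tt, vmax, rtmax, t2, rte, clust, trans],
        index=RQA_FEATURE_NAMES,
    )


def analyze_segment(
    x: np.ndarray,
    params: EmbeddingParams | None = None,
    rr_target: float | None = 0.05,
    epsilon: float | None = None,
    lmin: int = 2,
    vmin: int = 2,
    max_lag: int = 200,
    m_max: int = 10,
) -> tuple[pd.Series, RecurrencePlot]:
    """Full single-segment analysis: embedding selection, plot, features."""
    if params is None:
        tau = select_delay_ami(x, max_lag=max_lag)
        m = select_dim_fnn(x, tau, m_max=m_max)
        params = EmbeddingParams(tau=tau, m=m)
    rp = recurrence_matrix(x, params, rr_target=rr_target, epsilon=epsilon)
    return rqa_features(rp, lmin=lmin, vmin=vmin), rp


def rqa_protocol(
    rec: EEGRecording,
    seg_len: float = 10.0,
    n_iter: int = 1000,
    head_trim: float = 4.0,
    tail_trim: float = 10.0,
    seed: int = 0,
    rr_target: float = 0.05,
    lmin: int = 2,
    vmin: int = 2,
    max_lag: int = 200,
    m_max: int = 10,
    embed_mode: str = "per_window",
) -> pd.Series:
    """Random-segment averaging protocol over all channels.

    Per channel: draw ``n_iter`` uniformly placed ``seg_len``-second windows
    from the span left after trimming ``head_trim`` at the start and
    ``tail_trim`` at the end, analyze each window, average the 13 features
    over windows; then average across channels. ``embed_mode`` selects
    whether tau/m are re-estimated per window (default) or once per channel
    on the central window. Per-window epsilon variability is reported in the
    returned series' ``attrs['epsilon_sd']``.
    """
    if embed_mode not in ("per_window", "per_channel"):
        raise ValueError("embed_mode must be 'per_window' or 'per_channel'")
    usable = rec.duration - head_trim - tail_trim
    if usable < seg_len:
        raise ValueError(
            f"recording too short: need > {head_trim + tail_trim + seg_len:.0f} s, "
            f"got {rec.duration:.1f} s"
        )
    rng = np.random.default_rng(seed)
    n_seg = int(round(seg_len * rec.fs))
    lo = int(round(head_trim * rec.fs))
    hi = rec.data.shape[1] - int(round(tail_trim * rec.fs)) - n_seg
    chan_means = []
    eps_all = []
    for ch in range(rec.data.shape[0]):
        x = rec.data[ch]
        params = None
        if embed_mode == "per_channel":
            mid = lo + (hi - lo) // 2
            seg = x[mid: mid + n_seg]
            tau = select_delay_ami(seg, max_lag=max_lag)
            m = select_dim_fnn(seg, tau, m_max=m_max)
            params = EmbeddingParams(tau=tau, m=m)
        feats = []
        for _ in range(n_iter):
            start = int(rng.integers(lo, hi + 1))
            seg = x[start: start + n_seg]
            f, rp = analyze_segment(
                seg, params=params, rr_target=rr_target, lmin=lmin, vmin=vmin,
                max_lag=max_lag, m_max=m_max,
            )
            feats.append(f)
            eps_all.append(rp.epsilon)
        chan_means.append(pd.concat(feats, axis=1).mean(axis=1))
    out = pd.concat(chan_means, axis=1).mean(axis=1)
    out.index = RQA_FEATURE_NAMES
    out.attrs["epsilon_sd"] = float(np.std(eps_all))
    out.attrs["epsilon_mean"] = float(np.mean(eps_all))
    return out
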