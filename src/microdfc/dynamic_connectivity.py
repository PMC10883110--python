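"""Windowed mutual-information functional connectivity per microstate.

The EEG concatenated within one microstate is cut into consecutive
non-overlapping 30-s windows (trailing remainder discarded), and within
each window the mutual information

    I(x; y) = integral p(x, y) log[ p(x, y) / (p(x) p(y)) ]

is estimated between every channel pair, giving one symmetric H x H
matrix per window (H = channel count, zero diagonal by convention).

The default estimator discretizes each signal into b equiprobable
(quantile) bins and evaluates the discrete plug-in MI with a
Miller-Madow bias correction; quantile binning makes the estimate
invariant under strictly monotone rescaling of either input. A
Kraskov-style k-nearest-neighbor estimator is available behind the same
interface for continuous-density estimation. Values are reported in nats
(optionally bits) and clipped at zero.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma

logger = logging.getLogger("microdfc")

MIN_MI_SAMPLES = 100


@dataclass
class MIEstimatorConfig:
    method: str = "binned"  # binned | knn
    n_bins: int = 8
    k_neighbors: int = 4
    bias_correction: bool = True
    units: str = "nats"  # nats | bits

    def __post_init__(self) -> None:
        if self.method not in ("binned", "knn"):
            raise ValueError("method must be 'binned' or 'knn'")
        if self.method == "binned" and self.n_bins < 2:
            raise ValueError("need at least 2 bins")
        if self.method == "knn" and self.k_neighbors < 1:
            raise ValueError("need at least 1 neighbor")
        if self.units not in ("nats", "bits"):
            raise ValueError("units must be 'nats' or 'bits'")

    def convert(self, nats: float) -> float:
        return nats / math.log(2.0) if self.units == "bits" else nats


@dataclass
class WindowSet:
    """Fixed-length windows cut from one per-state concatenation."""

    windows: list[np.ndarray]
    window_samples: int
    state: int
    fs: float
    subject_id: str = ""
    group: str | None = None
    boundary_indices: list[int] = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return len(self.windows)


@dataclass
class MIMatrixStack:
    """N symmetric H x H MI matrices for one (group, state)."""

    matrices: np.ndarray  # (N, H, H)
    state: int
    group: str | None = None
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=np.float64)
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValueError("matrices must be an (N, H, H) array")

    @property
    def n_windows(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_channels(self) -> int:
        return self.matrices.shape[1]


def window_signal(
    concatenated: np.ndarray,
    fs: float,
    window_s: float = 30.0,
    state: int = 0,
    subject_id: str = "",
    group: str | None = None,
    boundary_indices: list[int] | None = None,
) -> WindowSet:
    """Cut a channels x samples matrix into consecutive whole windows.

    The window count is floor(total / (window_s * fs)); a trailing
    remainder shorter than one window is discarded.
    """
    concatenated = np.atleast_2d(np.asarray(concatenated, dtype=np.float64))
    w = int(round(window_s * fs))
    if w < 1:
        raise ValueError("window must span at least one sample")
    total = concatenated.shape[1]
    n_win = total // w
    windows = [concatenated[:, i * w : (i + 1) * w] for i in range(n_win)]
    return WindowSet(
        windows=windows, window_samples=w, state=state, fs=fs,
        subject_id=subject_id, group=group,
        boundary_indices=list(boundary_indices or []),
    )


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


def quantile_bin(v: np.ndarray, b: int) -> np.ndarray:
    """Rank-based equiprobable binning into codes 0..b-1 (stable ties)."""
    n = v.size
    ranks = np.empty(n, dtype=np.int64)
    ranks[np.argsort(v, kind="stable")] = np.arange(n)
    return (ranks * b) // n


def _entropy_from_counts(counts: np.ndarray, n: int) -> tuple[float, int]:
    nz = counts[counts > 0]
    p = nz / n
    return float(-(p * np.log(p)).sum()), int(nz.size)


def _mi_from_codes(
    bx: np.ndarray, by: np.ndarray, bxc: int, byc: int, bias_correction: bool
) -> float:
    """Plug-in MI of two discrete code vectors, optionally Miller-Madow."""
    n = bx.size
    joint = np.bincount(bx * byc + by, minlength=bxc * byc)
    hx, kx = _entropy_from_counts(joint.reshape(bxc, byc).sum(axis=1), n)
    hy, ky = _entropy_from_counts(joint.reshape(bxc, byc).sum(axis=0), n)
    hxy, kxy = _entropy_from_counts(joint, n)
    mi = hx + hy - hxy
    if bias_correction:
        mi += (kx + ky - kxy - 1) / (2.0 * n)
    return max(mi, 0.0)


def _mi_knn(x: np.ndarray, y: np.ndarray, k: int) -> float:
    """Kraskov-Stoegbauer-Grassberger (algorithm 1) MI estimate in nats."""
    n = x.size
    # deterministic tie-breaking jitter, scaled far below signal resolution
    jit = np.random.default_rng(12345)
    xs = x + 1e-10 * x.std() * jit.standard_normal(n)
    ys = y + 1e-10 * y.std() * jit.standard_normal(n)
    pts = np.column_stack([xs, ys])
    tree = cKDTree(pts)
    dist, _ = tree.query(pts, k=k + 1, p=np.inf)
    eps = dist[:, -1]
    xs_sorted = np.sort(xs)
    ys_sorted = np.sort(ys)
    nx = (
        np.searchsorted(xs_sorted, xs + eps, side="left")
        - np.searchsorted(xs_sorted, xs - eps, side="right")
    )
    ny = (
        np.searchsorted(ys_sorted, ys + eps, side="left")
        - np.searchsorted(ys_sorted, ys - eps, side="right")
    )
    mi = digamma(k) + digamma(n) - float(np.mean(digamma(nx + 1) + digamma(ny + 1)))
    # nx/ny include the point itself; the +1 in psi follows KSG's convention
    return max(mi, 0.0)


def estimate_mi(x: np.ndarray, y: np.ndarray, cfg: MIEstimatorConfig | None = None) -> float:
    """Mutual information between two equal-length sample vectors."""
    cfg = cfg or MIEstimatorConfig()
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise ValueError("inputs must have equal length")
    if x.size < MIN_MI_SAMPLES:
        raise ValueError(f"need at least {MIN_MI_SAMPLES} samples, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant input vector: MI is zero by convention")
        return 0.0
    if cfg.method == "binned":
        b = cfg.n_bins
        mi = _mi_from_codes(quantile_bin(x, b), quantile_bin(y, b), b, b, cfg.bias_correction)
    else:
        mi = _mi_knn(x, y, cfg.k_neighbors)
    return cfg.convert(mi)


def connectivity_matrix(window: np.ndarray, cfg: MIEstimatorConfig | None = None) -> np.ndarray:
    """Pairwise MI matrix of one channels x samples window.

    Symmetric with a zero diagonal; constant channels contribute zero MI
    to all their pairs.
    """
    cfg = cfg or MIEstimatorConfig()
    window = np.atleast_2d(np.asarray(window, dtype=np.float64))
    H, n = window.shape
    if H < 2:
        raise ValueError("need at least 2 channels")
    out = np.zeros((H, H))
    if cfg.method == "binned":
        b = cfg.n_bins
        valid = np.ptp(window, axis=1) > 0
        if not valid.all():
            logger.warning("constant channel(s) in window: their MI set to 0")
        codes = np.zeros((H, n), dtype=np.int64)
        for i in np.flatnonzero(valid):
            codes[i] = quantile_bin(window[i], b)
        for i in range(H):
            if not valid[i]:
                continue
            for j in range(i + 1, H):
                if not valid[j]:
                    continue
                mi = _mi_from_codes(codes[i], codes[j], b, b, cfg.bias_correction)
                out[i, j] = out[j, i] = cfg.convert(mi)
    else:
        for i in range(H):
            for j in range(i + 1, H):
                try:
                    mi = estimate_mi(window[i], window[j], cfg)
                except ValueError as exc:
                    logger.warning("MI failed for pair (%d, %d): %s", i, j, exc)
                    mi = 0.0
                out[i, j] = out[j, i] = mi
    return out


def stack_from_windows(
    window_sets: list[WindowSet],
    cfg: MIEstimatorConfig | None = None,
    group: str | None = None,
) -> MIMatrixStack:
    """Compute one MI matrix per window over several subjects' window sets."""
    if not window_sets:
        raise ValueError("no window sets supplied")
    state = window_sets[0].state
    if any(ws.state != state for ws in window_sets):
        raise ValueError("window sets must share the microstate")
    mats, sids = [], []
    for ws in window_sets:
        for w in ws.windows:
            mats.append(connectivity_matrix(w, cfg))
            sids.append(ws.subject_id)
    H = window_sets[0].windows[0].shape[0] if mats else 0
    matrices = np.asarray(mats) if mats else np.zeros((0, H, H))
    return MIMatrixStack(matrices=matrices, state=state, group=group, subject_ids=sids)


def group_average_difference(stack_a: MIMatrixStack, stack_b: MIMatrixStack) -> np.ndarray:
    """Entrywise mean(A) - mean(B) over windows; antisymmetric under swap."""
    if stack_a.n_windows == 0 or stack_b.n_windows == 0:
        raise ValueError("cannot average an empty MI stack")
    if stack_a.n_channels != stack_b.n_channels:
        raise ValueError("channel count mismatch between stacks")
    if stack_a.state != stack_b.state:
        raise ValueError("stacks belong to different microstates")
    return stack_a.matrices.mean(axis=0) - stack_b.matrices.mean(axis=0)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_stack(
    stack: MIMatrixStack, out_dir: str | Path, channel_labels: list[str] | None = None
) -> Path:
    """One CSV per window plus a manifest JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    H = stack.n_channels
    header = ",".join(channel_labels or [f"CH{i}" for i in range(H)])
    names = []
    for i, mat in enumerate(stack.matrices):
        name = f"window{i:04d}.csv"
        np.savetxt(out_dir / name, mat, fmt="%.9f", delimiter=",", header=header, comments="")
        names.append(name)
    manifest = {
        "state": stack.state,
        "group": stack.group,
        "n_windows": stack.n_windows,
        "subject_ids": stack.subject_ids,
        "files": names,
    }
    (out_dir / "stack.json").write_text(json.dumps(manifest, indent=1))
    return out_dir


def write_difference_matrix(
    diff: np.ndarray, path: str | Path, channel_labels: list[str] | None = None
) -> Path:
    path = Path(path)
    header = ",".join(channel_labels or [f"CH{i}" for i in range(diff.shape[0])])
    np.savetxt(path, diff, fmt="%.9f", delimiter=",", header=header, comments="")
    return path
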