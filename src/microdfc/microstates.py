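"""Polarity-invariant microstate clustering, backfitting and segmentation.

EEG microstates are brief (~80-120 ms) epochs during which the scalp
potential topography stays quasi-stable. The analysis here follows the
classical modified k-means scheme:

1. topographies at GFP peaks are clustered per subject, ignoring polarity
   (a map and its negation are the same microstate);
2. the individual template maps are pooled and clustered again at the
   group level;
3. the group templates are backfitted to every sample of each recording,
   followed by a minimum-duration temporal smoothing.

Fit quality is measured by the global explained variance

    GEV = sum_j (GFP_j * C_j)^2 / sum_j GFP_j^2,

where C_j is the (polarity-invariant) spatial correlation between item j
and its assigned template. Because the items are weighted by their squared
GFP, high-power topographies dominate the criterion.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment

from .montage import MONTAGE_32, channel_positions_2d
from .signal_core import Recording

CANONICAL_STATE_NAMES = "ABCDEFGHIJKLMNOP"
UNASSIGNED = -1


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class TemplateSet:
    """k unit-norm, zero-mean microstate topographies."""

    maps: np.ndarray
    level: str = "individual"  # individual | group | truth
    gev: float | None = None
    state_names: list[str] | None = None
    channel_labels: list[str] | None = None

    def __post_init__(self) -> None:
        maps = np.atleast_2d(np.asarray(self.maps, dtype=np.float64))
        maps = maps - maps.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(maps, axis=1)
        if (norms == 0).any():
            raise ValueError("template maps must have nonzero spatial variance")
        self.maps = maps / norms[:, None]
        if self.state_names is None:
            self.state_names = list(CANONICAL_STATE_NAMES[: self.k])
        if len(self.state_names) != self.k:
            raise ValueError("one state name per template required")

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


@dataclass
class LabelSequence:
    """Per-sample microstate assignment plus its spatial-correlation trace.

    ``corr_all`` (k x n) keeps the correlation of every sample with every
    template; the smoothing step needs it to arbitrate between flanking
    states.
    """

    labels: np.ndarray
    corr: np.ndarray
    fs: float
    corr_all: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.corr = np.asarray(self.corr, dtype=np.float64)
        if self.labels.shape != self.corr.shape:
            raise ValueError("labels and corr must have equal length")

    @property
    def n_samples(self) -> int:
        return self.labels.size


@dataclass
class ClusteringResult:
    templates: TemplateSet
    assignments: np.ndarray
    gev: float
    inertia: float


# ---------------------------------------------------------------------------
# correlation primitives
# ---------------------------------------------------------------------------


def spatial_correlation(a, b, ignore_polarity: bool = True) -> float:
    """Pearson correlation of two topographies across channels.

    With ``ignore_polarity`` the absolute value is returned, matching the
    sign-invariance of the clustering.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.size != b.size:
        raise ValueError("topographies must have equal length")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("correlation undefined for a zero-variance topography")
    r = float(np.clip(a @ b / (na * nb), -1.0, 1.0))
    return abs(r) if ignore_polarity else r


def _center_normalize(maps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise center and unit-normalize; returns (normalized, gfp)."""
    maps = np.asarray(maps, dtype=np.float64)
    centered = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    if (norms == 0).any():
        raise ValueError("zero-variance topography among clustering items")
    gfp = norms / math.sqrt(maps.shape[1])
    return centered / norms[:, None], gfp


def compute_gev(gfp_at_items, corr_at_items) -> float:
    """GFP^2-weighted mean squared correlation (global explained variance)."""
    g = np.asarray(gfp_at_items, dtype=np.float64)
    c = np.asarray(corr_at_items, dtype=np.float64)
    if g.shape != c.shape:
        raise ValueError("gfp and correlation vectors must have equal length")
    if (g < 0).any():
        raise ValueError("GFP values must be nonnegative")
    if (np.abs(c) > 1 + 1e-12).any():
        raise ValueError("correlations must lie in [-1, 1]")
    denom = float(np.sum(g**2))
    if denom == 0:
        raise ValueError("GEV undefined when all GFP values are zero")
    return float(np.sum((g * c) ** 2) / denom)


# ---------------------------------------------------------------------------
# modified (polarity-invariant) k-means
# ---------------------------------------------------------------------------


def _dominant_pattern(centered_maps: np.ndarray) -> np.ndarray:
    """First principal spatial pattern of a set of zero-mean maps.

    Equivalent to the sign-aligned, GFP^2-weighted mean direction: the
    dominant eigenvector of sum_j u_j u_j^T, which is invariant to the
    polarity of every item.
    """
    _, _, vt = np.linalg.svd(centered_maps, full_matrices=False)
    v = vt[0]
    # deterministic sign convention
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    return v / np.linalg.norm(v)


def modified_kmeans(
    peak_maps: np.ndarray,
    k: int,
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 200,
    level: str = "individual",
    channel_labels: list[str] | None = None,
) -> ClusteringResult:
    """Polarity-invariant k-means over GFP-peak topographies.

    Alternates (i) assignment of every item to the template with the
    highest absolute spatial correlation and (ii) template update as the
    dominant spatial pattern of the assigned raw maps (GFP^2-weighted by
    construction). The best of ``n_restarts`` random initializations by
    GEV is returned.
    """
    peak_maps = np.atleast_2d(np.asarray(peak_maps, dtype=np.float64))
    J = peak_maps.shape[0]
    if not 1 <= k <= J:
        raise ValueError(f"need 1 <= k <= J, got k={k}, J={J}")
    norm_maps, gfp = _center_normalize(peak_maps)
    centered = norm_maps * (gfp * math.sqrt(peak_maps.shape[1]))[:, None]

    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(max(1, n_restarts)):
        init_idx = rng.choice(J, size=k, replace=False)
        templates = norm_maps[init_idx].copy()
        assign = np.full(J, -1, dtype=np.intp)
        for _ in range(max_iter):
            corr = np.abs(norm_maps @ templates.T)  # (J, k)
            new_assign = np.argmax(corr, axis=1)
            # re-seed empty clusters from the worst-fit item
            fit = corr[np.arange(J), new_assign]
            for c in range(k):
                if not (new_assign == c).any():
                    worst = int(np.argmin(fit))
                    new_assign[worst] = c
                    fit[worst] = 1.0
            if (new_assign == assign).all():
                break
            assign = new_assign
            for c in range(k):
                members = centered[assign == c]
                templates[c] = _dominant_pattern(members)
        corr = np.abs(norm_maps @ templates.T)
        assign = np.argmax(corr, axis=1)
        fit = corr[np.arange(J), assign]
        gev = compute_gev(gfp, fit)
        if best is None or gev > best[0]:
            best = (gev, templates.copy(), assign.copy())

    gev, templates, assign = best
    fit = np.abs(norm_maps @ templates.T)[np.arange(J), assign]
    inertia = float(np.sum(gfp**2 * (1.0 - fit**2)))
    tset = TemplateSet(
        maps=templates, level=level, gev=gev, channel_labels=channel_labels
    )
    return ClusteringResult(
        templates=tset, assignments=assign, gev=gev, inertia=inertia
    )


def _holdout_gev(items_norm: np.ndarray, items_gfp: np.ndarray, templates: np.ndarray) -> float:
    corr = np.abs(items_norm @ templates.T)
    fit = corr.max(axis=1)
    return compute_gev(items_gfp, fit)


def select_optimal_k(
    peak_maps: np.ndarray,
    k_range: tuple[int, int] = (4, 6),
    seed: int = 0,
    n_restarts: int = 10,
    gain_threshold: float = 0.01,
) -> int:
    """Choose the number of microstate classes by split-half validated GEV.

    Templates are fitted on the even-indexed GFP-peak maps and evaluated
    on the odd-indexed maps; k is increased from the lower bound as long
    as an extra class raises the held-out GEV by more than
    ``gain_threshold``. The criterion is deliberately simple and is
    exposed so alternatives can be plugged in.
    """
    k_min, k_max = k_range
    if k_min > k_max:
        raise ValueError("k_range must be (min, max) with min <= max")
    if k_min == k_max:
        return k_min
    peak_maps = np.atleast_2d(np.asarray(peak_maps, dtype=np.float64))
    train = peak_maps[0::2]
    heldout = peak_maps[1::2]
    if min(len(train), len(heldout)) < k_max:
        raise ValueError("not enough peak maps for split-half k selection")
    ho_norm, ho_gfp = _center_normalize(heldout)

    cv = {}
    for i, k in enumerate(range(k_min, k_max + 1)):
        res = modified_kmeans(train, k, n_restarts=n_restarts, seed=seed + 101 * i)
        cv[k] = _holdout_gev(ho_norm, ho_gfp, res.templates.maps)
    chosen = k_min
    for k in range(k_min + 1, k_max + 1):
        if cv[k] - cv[chosen] > gain_threshold:
            chosen = k
        else:
            break
    return chosen


def group_templates(
    individual_sets: list[TemplateSet],
    k_range: tuple[int, int] = (4, 6),
    seed: int = 0,
    n_restarts: int = 20,
    gain_threshold: float = 0.01,
) -> ClusteringResult:
    """Cluster pooled individual template maps into group-level templates.

    Individual maps enter as items with unit weights (they are unit-norm,
    so their GFP weights are all equal). State names are assigned from the
    canonical archetypes when the channel labels are known.
    """
    if not individual_sets:
        raise ValueError("at least one individual template set required")
    n_ch = individual_sets[0].n_channels
    if any(s.n_channels != n_ch for s in individual_sets):
        raise ValueError("all individual template sets must share the channel count")
    pooled = np.vstack([s.maps for s in individual_sets])
    k_min, k_max = k_range
    if k_min == k_max:
        k = k_min
    else:
        k = select_optimal_k(
            pooled, k_range, seed=seed, n_restarts=n_restarts,
            gain_threshold=gain_threshold,
        )
    res = modified_kmeans(
        pooled, k, n_restarts=n_restarts, seed=seed, level="group",
        channel_labels=individual_sets[0].channel_labels,
    )
    res.templates.state_names = assign_state_names(res.templates)
    return res


# ---------------------------------------------------------------------------
# canonical state naming
# ---------------------------------------------------------------------------


def archetype_maps(channel_labels: list[str]) -> dict[str, np.ndarray]:
    """Idealized A-E topographies over the montage geometry.

    A: left-frontal to right-posterior diagonal gradient; B: the opposite
    diagonal; C: anterior-posterior (horizontal split); D: central arc
    (center vs periphery); E: left-right symmetric midline pattern.
    """
    pos = np.asarray(channel_positions_2d(channel_labels), dtype=np.float64)
    x, y = pos[:, 0], pos[:, 1]
    raw = {
        "A": y - x,
        "B": y + x,
        "C": y,
        "D": -(x**2 + y**2),
        "E": -(x**2),
    }
    out = {}
    for name, m in raw.items():
        m = m - m.mean()
        out[name] = m / np.linalg.norm(m)
    return out


def assign_state_names(templates: TemplateSet) -> list[str]:
    """Match templates to archetypes A-E by maximal total |correlation|.

    Extra templates beyond the five archetypes get the next free letters.
    Falls back to plain alphabetical names when the montage geometry is
    unknown.
    """
    labels = templates.channel_labels
    if labels is None or any(lab.upper() not in MONTAGE_32 for lab in labels):
        return list(CANONICAL_STATE_NAMES[: templates.k])
    arch = archetype_maps(labels)
    arch_names = list(arch)
    A = np.vstack([arch[n] for n in arch_names])
    corr = np.abs(templates.maps @ A.T)  # (k, 5)
    rows, cols = linear_sum_assignment(-corr)
    names: list[str | None] = [None] * templates.k
    for r, c in zip(rows, cols):
        names[r] = arch_names[c]
    spare = iter(n for n in CANONICAL_STATE_NAMES if n not in set(filter(None, names)))
    return [n if n is not None else next(spare) for n in names]


def match_templates(maps_a: np.ndarray, maps_b: np.ndarray) -> np.ndarray:
    """Polarity-invariant optimal matching of two template stacks.

    Returns ``perm`` with ``maps_a[i] ~ maps_b[perm[i]]`` maximizing the
    total absolute spatial correlation (Hungarian assignment).
    """
    a, _ = _center_normalize(np.atleast_2d(maps_a))
    b, _ = _center_normalize(np.atleast_2d(maps_b))
    corr = np.abs(a @ b.T)
    rows, cols = linear_sum_assignment(-corr)
    perm = np.empty(len(rows), dtype=np.intp)
    perm[rows] = cols
    return perm


# ---------------------------------------------------------------------------
# backfitting and temporal smoothing
# ---------------------------------------------------------------------------


def backfit(rec: Recording, templates: TemplateSet) -> LabelSequence:
    """Assign every sample to the best-correlating template (|corr|).

    Zero-variance samples inherit the previous label (leading ones take
    the first valid label). Ties break toward the lowest state index.
    """
    if rec.n_channels != templates.n_channels:
        raise ValueError("recording and templates disagree on channel count")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(data, axis=0)
    valid = norms > 0
    safe = np.where(valid, norms, 1.0)
    corr_all = np.abs(templates.maps @ (data / safe))  # (k, n)
    corr_all[:, ~valid] = 0.0
    labels = np.argmax(corr_all, axis=0).astype(np.int64)
    corr = corr_all[labels, np.arange(labels.size)]
    if not valid.all():
        idx = np.where(valid, np.arange(labels.size), -1)
        np.maximum.accumulate(idx, out=idx)
        first_valid = np.argmax(valid) if valid.any() else None
        if first_valid is not None:
            idx[idx < 0] = int(np.argmax(valid))
            labels = labels[idx]
            corr = np.where(valid, corr, 0.0)
        # all-invalid recording keeps argmax labels (all zeros by tie-break)
    return LabelSequence(labels=labels, corr=corr, fs=rec.fs, corr_all=corr_all)


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal constant runs as (start, stop, label), stop exclusive."""
    boundaries = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], boundaries))
    stops = np.concatenate((boundaries, [labels.size]))
    return [(int(a), int(b), int(labels[a])) for a, b in zip(starts, stops)]


def min_segment_samples(min_duration_ms: float, fs: float) -> int:
    return int(math.ceil(min_duration_ms * fs / 1000.0))


def smooth_labels(seq: LabelSequence, min_duration_ms: float = 20.0) -> LabelSequence:
    """Reject microstate runs shorter than the minimum duration.

    Short runs are eliminated shortest-first: each one is handed to its
    flanking runs at the sample split that maximizes the total spatial
    correlation with the flanking templates (per-sample correlations
    decide where the boundary falls; the handover is kept contiguous so
    no new runs are created). Every merge removes at least one run, so
    the procedure terminates with every surviving run at least
    ceil(min_duration_ms * fs / 1000) samples long — 5 samples at 250 Hz
    for the 20-ms default — unless the whole sequence is shorter than
    that, in which case it collapses to the single best-fitting state.
    """
    if seq.corr_all is None:
        raise ValueError("smoothing needs the full correlation trace (corr_all)")
    import heapq

    min_len = min_segment_samples(min_duration_ms, seq.fs)
    corr_all = seq.corr_all
    n = seq.labels.size
    if n == 0 or min_len <= 1:
        return replace(seq, labels=seq.labels.copy(), corr=seq.corr.copy())

    runs = _runs(seq.labels)
    start = [r[0] for r in runs]
    stop = [r[1] for r in runs]
    lab = [r[2] for r in runs]
    m = len(runs)
    prv = list(range(-1, m - 1))
    nxt = list(range(1, m + 1))
    nxt[-1] = -1
    alive = [True] * m
    version = [0] * m
    heap = [(stop[i] - start[i], i, 0) for i in range(m) if stop[i] - start[i] < min_len]
    heapq.heapify(heap)

    def touch(i: int) -> None:
        version[i] += 1
        if stop[i] - start[i] < min_len:
            heapq.heappush(heap, (stop[i] - start[i], i, version[i]))

    n_alive = m
    while heap:
        length, i, ver = heapq.heappop(heap)
        if not alive[i] or ver != version[i] or stop[i] - start[i] >= min_len:
            continue
        if n_alive == 1:
            break
        p, q = prv[i], nxt[i]
        a, b = start[i], stop[i]
        # unlink the short run
        alive[i] = False
        version[i] += 1
        n_alive -= 1
        if p >= 0:
            nxt[p] = q
        if q >= 0:
            prv[q] = p
        if p < 0:
            start[q] = a
            touch(q)
        elif q < 0:
            stop[p] = b
            touch(p)
        elif lab[p] == lab[q]:
            # same state on both sides: the three runs fuse into one
            stop[p] = stop[q]
            alive[q] = False
            version[q] += 1
            n_alive -= 1
            nxt[p] = nxt[q]
            if nxt[q] >= 0:
                prv[nxt[q]] = p
            touch(p)
        else:
            # split the run where the cumulative correlation advantage of
            # the previous flank over the next flank is maximal
            gain = np.concatenate(
                ([0.0], np.cumsum(corr_all[lab[p], a:b] - corr_all[lab[q], a:b]))
            )
            s = int(np.argmax(gain))
            stop[p] = a + s
            start[q] = a + s
            touch(p)
            touch(q)

    labels = np.empty(n, dtype=np.int64)
    remaining = 0
    for i in range(m):
        if alive[i] and stop[i] > start[i]:
            labels[start[i] : stop[i]] = lab[i]
            remaining += 1
    if remaining == 1 and n < min_len:
        labels[:] = int(np.argmax(corr_all.mean(axis=1)))
    corr = corr_all[labels, np.arange(n)]
    return LabelSequence(labels=labels, corr=corr, fs=seq.fs, corr_all=corr_all)


def extract_segments(
    rec: Recording, seq: LabelSequence, state: int
) -> tuple[np.ndarray, float]:
    """Concatenate (in temporal order) all samples labeled ``state``."""
    if rec.n_samples != seq.n_samples:
        raise ValueError("recording and label sequence length mismatch")
    mask = seq.labels == state
    return rec.data[:, mask], float(mask.sum() / rec.fs)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_template_set(tset: TemplateSet, path: str | Path) -> Path:
    path = Path(path)
    header = "\t".join(tset.channel_labels or [f"CH{i}" for i in range(tset.n_channels)])
    np.savetxt(path, tset.maps, fmt="%.9f", delimiter="\t", header=header, comments="")
    meta = {
        "k": tset.k,
        "level": tset.level,
        "gev": tset.gev,
        "state_names": tset.state_names,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))
    return path


def read_template_set(path: str | Path) -> TemplateSet:
    path = Path(path)
    with open(path) as fh:
        labels = fh.readline().strip().split("\t")
    maps = np.atleast_2d(np.loadtxt(path, delimiter="\t", skiprows=1))
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return TemplateSet(
        maps=maps,
        level=meta.get("level", "individual"),
        gev=meta.get("gev"),
        state_names=meta.get("state_names"),
        channel_labels=labels,
    )


def write_label_sequence(seq: LabelSequence, path: str | Path) -> Path:
    """Run-length-encoded JSON of a label sequence."""
    path = Path(path)
    runs = [[int(a), int(b), int(lab)] for a, b, lab in _runs(seq.labels)]
    payload = {"fs": seq.fs, "n_samples": seq.n_samples, "runs": runs}
    path.write_text(json.dumps(payload))
    return path


def write_label_sequence_csv(seq: LabelSequence, path: str | Path,
                             state_names: list[str] | None = None) -> Path:
    """Per-sample CSV: sample index, state index, state name, correlation."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("sample,state,state_name,corr\n")
        for t, (lab, corr) in enumerate(zip(seq.labels, seq.corr)):
            name = state_names[lab] if state_names else CANONICAL_STATE_NAMES[lab]
            fh.write(f"{t},{lab},{name},{corr:.6f}\n")
    return path


def read_label_sequence(path: str | Path) -> LabelSequence:
    payload = json.loads(Path(path).read_text())
    labels = np.empty(payload["n_samples"], dtype=np.int64)
    for a, b, lab in payload["runs"]:
        labels[a:b] = lab
    return LabelSequence(
        labels=labels, corr=np.zeros(labels.size), fs=payload["fs"]
    )
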