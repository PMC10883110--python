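"""Feature tables, the statistical (filter) stage, and mRMR ranking.

Each window's symmetric MI matrix is vectorized into its upper triangle
(H = 32 channels -> 496 channel-pair features). Per microstate, windows
of both groups form the original feature matrix O; per column the two
groups are compared with an independent-samples t-test when both groups
pass Shapiro-Wilk normality, otherwise with a Mann-Whitney rank-sum
test, and columns significant after Bonferroni correction (p < alpha /
n_tests, here 0.01/496) form the total feature subset (TFS).

The TFS is then ranked by minimum-redundancy maximum-relevance (mRMR):
greedy forward selection maximizing

    Phi(f) = I(f; c) - (1/|S|) * sum_{f_i in S} I(f; f_i),

the canonical mutual-information-difference realization of the
relevance-minus-redundancy objective. Feature MI uses the same
quantile-binning estimator as the connectivity stage (class labels stay
discrete).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .dynamic_connectivity import MIEstimatorConfig, MIMatrixStack, _mi_from_codes, quantile_bin

SHAPIRO_ALPHA = 0.05
DEFAULT_ALPHA = 0.01
DEFAULT_N_TESTS = 496


def upper_triangle_pairs(h: int) -> list[tuple[int, int]]:
    """Row-major upper-triangle (i < j) channel-pair order."""
    return [(i, j) for i in range(h) for j in range(i + 1, h)]


def vectorize_upper_triangle(matrix: np.ndarray) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Row-major upper triangle (diagonal excluded) of a symmetric matrix."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-9):
        raise ValueError("matrix must be symmetric")
    h = matrix.shape[0]
    iu = np.triu_indices(h, k=1)
    return matrix[iu].copy(), upper_triangle_pairs(h)


def unvectorize_upper_triangle(vec: np.ndarray, h: int) -> np.ndarray:
    """Inverse of :func:`vectorize_upper_triangle` (zero diagonal)."""
    out = np.zeros((h, h))
    iu = np.triu_indices(h, k=1)
    out[iu] = vec
    return out + out.T


@dataclass
class FeatureTable:
    """Windows x channel-pair features with per-row group labels."""

    values: np.ndarray
    labels: np.ndarray  # per-row class, e.g. "MCS"/"VS"
    pair_index: list[tuple[int, int]]
    state: int
    channel_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        self.labels = np.asarray(self.labels)
        if self.labels.size != self.values.shape[0]:
            raise ValueError("one label per row required")
        if len(self.pair_index) != self.values.shape[1]:
            raise ValueError("one channel pair per column required")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def pair_name(self, col: int) -> str:
        i, j = self.pair_index[col]
        if self.channel_labels:
            return f"{self.channel_labels[i]}-{self.channel_labels[j]}"
        return f"CH{i}-CH{j}"


def build_feature_table(
    stacks: list[MIMatrixStack], channel_labels: list[str] | None = None
) -> FeatureTable:
    """Vectorize the windows of the per-group stacks of one microstate."""
    if not stacks:
        raise ValueError("no MI stacks supplied")
    state = stacks[0].state
    if any(s.state != state for s in stacks):
        raise ValueError("stacks must share the microstate")
    rows, labels = [], []
    pairs = None
    for s in stacks:
        for mat in s.matrices:
            vec, pairs = vectorize_upper_triangle(mat)
            rows.append(vec)
            labels.append(s.group)
    if not rows:
        raise ValueError("stacks contain no windows")
    return FeatureTable(
        values=np.vstack(rows), labels=np.asarray(labels),
        pair_index=pairs, state=state, channel_labels=channel_labels,
    )


@dataclass
class TfsResult:
    """Columns surviving the Bonferroni-corrected two-sample screen."""

    kept_columns: np.ndarray  # ordered by ascending p
    p_values: np.ndarray  # per input column
    test_used: list[str]  # per input column: "t" | "mann-whitney"
    alpha_corrected: float


def _column_test(a: np.ndarray, b: np.ndarray) -> tuple[float, str]:
    """Two-sample comparison with normality-dependent test choice."""

    def normal(v: np.ndarray) -> bool:
        if np.ptp(v) == 0:
            return False  # constant: treat as non-normal
        return stats.shapiro(v).pvalue > SHAPIRO_ALPHA

    if normal(a) and normal(b):
        return float(stats.ttest_ind(a, b, equal_var=True).pvalue), "t"
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 1.0, "mann-whitney"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue), "mann-whitney"


def statistical_filter(
    table: FeatureTable,
    alpha: float = DEFAULT_ALPHA,
    n_tests: int = DEFAULT_N_TESTS,
) -> TfsResult:
    """Per-column group comparison with a fixed Bonferroni divisor.

    The divisor stays at ``n_tests`` (496 for a 32-channel montage) even
    when fewer columns are present, keeping the family-wise error bound
    conservative.
    """
    classes = np.unique(table.labels)
    if classes.size != 2:
        raise ValueError(f"exactly two classes required, got {list(classes)}")
    mask_a = table.labels == classes[0]
    if min(mask_a.sum(), (~mask_a).sum()) < 3:
        raise ValueError("each class needs at least 3 rows")
    threshold = alpha / n_tests
    a = table.values[mask_a]
    b = table.values[~mask_a]
    const_a = np.ptp(a, axis=0) == 0
    const_b = np.ptp(b, axis=0) == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pa = np.where(const_a, 0.0, stats.shapiro(a, axis=0).pvalue)
        pb = np.where(const_b, 0.0, stats.shapiro(b, axis=0).pvalue)
        normal = (pa > SHAPIRO_ALPHA) & (pb > SHAPIRO_ALPHA)
        p_t = stats.ttest_ind(a, b, axis=0, equal_var=True).pvalue
        p_u = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided").pvalue
    p_values = np.where(normal, p_t, p_u)
    tests = ["t" if nm else "mann-whitney" for nm in normal]
    # degenerate columns the vectorized tests cannot score
    for col in np.flatnonzero(~np.isfinite(p_values)):
        p_values[col], tests[col] = _column_test(a[:, col], b[:, col])
    kept = np.flatnonzero(p_values < threshold)
    kept = kept[np.argsort(p_values[kept], kind="stable")]
    return TfsResult(
        kept_columns=kept, p_values=p_values, test_used=tests,
        alpha_corrected=threshold,
    )


@dataclass
class MrmrRanking:
    order: np.ndarray  # selected column indices, in selection order
    scores: np.ndarray  # Phi value at each selection step
    relevance: np.ndarray | None = None  # I(f; c) per candidate column

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=np.intp)
        if np.unique(self.order).size != self.order.size:
            raise ValueError("ranking must be duplicate-free")


def mrmr_rank(
    table: FeatureTable,
    m: int | None = None,
    cfg: MIEstimatorConfig | None = None,
    columns: np.ndarray | None = None,
) -> MrmrRanking:
    """Greedy forward mRMR over the given columns (default: all).

    Step 1 picks the column maximizing I(f; c); step k > 1 maximizes
    I(f; c) minus the mean MI with the already-selected columns. Ties
    break toward the lower column index. Deterministic.
    """
    cfg = cfg or MIEstimatorConfig()
    cols = np.arange(table.n_features) if columns is None else np.asarray(columns, dtype=np.intp)
    if m is None:
        m = cols.size
    if not 1 <= m <= cols.size:
        raise ValueError(f"need 1 <= m <= {cols.size}, got {m}")
    b = cfg.n_bins
    _, y = np.unique(table.labels, return_inverse=True)
    n_classes = int(y.max()) + 1
    codes = {int(c): quantile_bin(table.values[:, c], b) for c in cols}
    relevance = {
        c: _mi_from_codes(codes[c], y, b, n_classes, cfg.bias_correction)
        for c in codes
    }
    red_cache: dict[tuple[int, int], float] = {}

    def redundancy(a: int, s: int) -> float:
        key = (min(a, s), max(a, s))
        if key not in red_cache:
            red_cache[key] = _mi_from_codes(codes[a], codes[s], b, b, cfg.bias_correction)
        return red_cache[key]

    selected: list[int] = []
    scores: list[float] = []
    remaining = [int(c) for c in cols]
    red_sum = {c: 0.0 for c in remaining}
    for _ in range(m):
        best_c, best_phi = None, -np.inf
        for c in remaining:
            phi = relevance[c]
            if selected:
                phi -= red_sum[c] / len(selected)
            if phi > best_phi:  # strict: ties keep the earlier (lower) index
                best_c, best_phi = c, phi
        selected.append(best_c)
        scores.append(best_phi)
        remaining.remove(best_c)
        for c in remaining:
            red_sum[c] += redundancy(c, best_c)
    rel = np.array([relevance[c] for c in selected])
    return MrmrRanking(order=np.asarray(selected), scores=np.asarray(scores), relevance=rel)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def write_feature_table(table: FeatureTable, path: str | Path) -> Path:
    path = Path(path)
    header = "group," + ",".join(table.pair_name(c) for c in range(table.n_features))
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for lab, row in zip(table.labels, table.values):
            fh.write(str(lab) + "," + ",".join(f"{v:.9f}" for v in row) + "\n")
    return path


def write_selection_report(
    table: FeatureTable,
    tfs: TfsResult,
    ranking: MrmrRanking | None,
    path: str | Path,
) -> Path:
    report = {
        "state": table.state,
        "alpha_corrected": tfs.alpha_corrected,
        "tfs": [
            {
                "column": int(c),
                "pair": table.pair_name(int(c)),
                "p": float(tfs.p_values[int(c)]),
                "test": tfs.test_used[int(c)],
            }
            for c in tfs.kept_columns
        ],
        "mrmr": None
        if ranking is None
        else [
            {
                "column": int(c),
                "pair": table.pair_name(int(c)),
                "phi": float(s),
            }
            for c, s in zip(ranking.order, ranking.scores)
        ],
    }
    path = Path(path)
    path.write_text(json.dumps(report, indent=1))
    return path
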