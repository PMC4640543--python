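"""Object-similarity back-ends and rating-matrix utilities.

Three metrics turn inferred object representations into a 16 x 16
similarity matrix:

* **MVH-M** -- modality-independent: the Zhang-Shasha ordered tree edit
  distance between canonical spatial trees (unit-cost rename / insert /
  delete; a node's label is its symbol plus, for S nodes, its voxel
  coordinate, and the part id for terminals);
* **MVH-V** -- visual: Euclidean distance between rendered pixel vectors;
* **MVH-H** -- haptic: Euclidean distance between grasp feature vectors.

Distances are converted to similarities by negation followed by min-max
scaling over all unordered pairs, so the diagonal maps to 1 and the most
dissimilar pair to 0 (any affine choice leaves Pearson correlations
unchanged).  The module also builds subject- and condition-level matrices
from long-format rating tables and the within/between-condition
correlation summaries used to compare them.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .forward import GraspConfig, RenderConfig, haptic_features, render_views
from .grammar import Node, ObjectRepresentation, canonicalize

# ---------------------------------------------------------------------------
# Zhang-Shasha ordered tree edit distance


def _node_label(node: Node) -> tuple:
    if node.symbol == "S":
        return ("S", node.coord)
    return (node.symbol,)


class _PostorderTree:
    """Postorder arrays (labels, leftmost-leaf indices, keyroots) used by
    the Zhang-Shasha dynamic program."""

    def __init__(self, root: Node):
        self.labels: list[tuple] = []
        self.lmld: list[int] = []  # leftmost leaf descendant, postorder index

        def walk(node: Node) -> int:
            first_leaf = None
            for child in node.children:
                leaf = walk(child)
                if first_leaf is None:
                    first_leaf = leaf
            idx = len(self.labels)
            self.labels.append(_node_label(node))
            self.lmld.append(first_leaf if first_leaf is not None else idx)
            return self.lmld[idx]

        walk(root)
        n = len(self.labels)
        seen: set[int] = set()
        keyroots = []
        for i in range(n - 1, -1, -1):
            if self.lmld[i] not in seen:
                keyroots.append(i)
                seen.add(self.lmld[i])
        self.keyroots = sorted(keyroots)


def zhang_shasha(a: Node, b: Node) -> int:
    """Minimal unit-cost edit script length between two ordered labeled
    trees (rename / delete / insert, all cost 1)."""
    ta, tb = _PostorderTree(a), _PostorderTree(b)
    na, nb = len(ta.labels), len(tb.labels)
    dist = np.zeros((na, nb), dtype=np.int64)

    for i in ta.keyroots:
        for j in tb.keyroots:
            li, lj = ta.lmld[i], tb.lmld[j]
            m, n = i - li + 2, j - lj + 2
            fd = np.zeros((m, n), dtype=np.int64)
            fd[:, 0] = np.arange(m)
            fd[0, :] = np.arange(n)
            for x in range(1, m):
                ai = li + x - 1
                for y in range(1, n):
                    bj = lj + y - 1
                    if ta.lmld[ai] == li and tb.lmld[bj] == lj:
                        cost = 0 if ta.labels[ai] == tb.labels[bj] else 1
                        fd[x, y] = min(
                            fd[x - 1, y] + 1,
                            fd[x, y - 1] + 1,
                            fd[x - 1, y - 1] + cost,
                        )
                        dist[ai, bj] = fd[x, y]
                    else:
                        p = ta.lmld[ai] - li
                        q = tb.lmld[bj] - lj
                        fd[x, y] = min(
                            fd[x - 1, y] + 1,
                            fd[x, y - 1] + 1,
                            fd[p, q] + dist[ai, bj],
                        )
    return int(dist[na - 1, nb - 1])


def tree_edit_distance(a: ObjectRepresentation, b: ObjectRepresentation) -> int:
    """Tree edit distance between two representations in canonical form.

    Canonicalization supplies the sibling order the metric needs; the
    result is symmetric and zero iff the canonical forms are identical.
    """
    return zhang_shasha(canonicalize(a).root, canonicalize(b).root)


# ---------------------------------------------------------------------------
# similarity matrices


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise-similarity matrix with object labels."""

    values: np.ndarray
    labels: list[str]
    metric: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("similarity matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.labels)

    def pair_vector(self) -> np.ndarray:
        """The unordered-pair vectorization (n(n+1)/2 entries; 136 for 16
        objects, one per point in the model-vs-ratings scatter plots)."""
        iu = np.triu_indices(self.n)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def _distances_to_similarity(dist: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(dist.shape[0])
    lo, hi = dist[iu].min(), dist[iu].max()
    if hi == lo:
        raise ValueError("all pairwise distances are equal; scaling undefined")
    return (hi - dist) / (hi - lo)


def _labels_for(reps: list[ObjectRepresentation], labels) -> list[str]:
    if labels is not None:
        return list(labels)
    from .stimuli import code_string, part_code_of

    try:
        return [code_string(part_code_of(r)) for r in reps]
    except ValueError:
        return [str(i) for i in range(len(reps))]


def mvh_m_similarity(
    reps: list[ObjectRepresentation], labels=None
) -> SimilarityMatrix:
    """Modality-independent similarity: scaled negative tree edit distance."""
    if len(reps) < 2:
        raise ValueError("need at least two representations")
    n = len(reps)
    canon = [canonicalize(r) for r in reps]
    dist = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        dist[i, j] = dist[j, i] = zhang_shasha(canon[i].root, canon[j].root)
    return SimilarityMatrix(
        _distances_to_similarity(dist), _labels_for(reps, labels), "MVH-M"
    )


def _feature_similarity(
    reps, features: list[np.ndarray], labels, metric: str
) -> SimilarityMatrix:
    if len(reps) < 2:
        raise ValueError("need at least two representations")
    mat = np.stack(features).astype(float)
    diff = mat[:, None, :] - mat[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    return SimilarityMatrix(
        _distances_to_similarity(dist), _labels_for(reps, labels), metric
    )


def mvh_v_similarity(
    reps: list[ObjectRepresentation],
    render_cfg: RenderConfig | None = None,
    labels=None,
    templates=None,
) -> SimilarityMatrix:
    """Visual-space similarity: scaled negative Euclidean pixel distance."""
    feats = [render_views(r, render_cfg, templates).vector for r in reps]
    return _feature_similarity(reps, feats, labels, "MVH-V")


def mvh_h_similarity(
    reps: list[ObjectRepresentation],
    grasp_cfg: GraspConfig | None = None,
    labels=None,
    templates=None,
) -> SimilarityMatrix:
    """Haptic-space similarity: scaled negative Euclidean grasp distance."""
    feats = [haptic_features(r, grasp_cfg, templates).vector for r in reps]
    return _feature_similarity(reps, feats, labels, "MVH-H")


# ---------------------------------------------------------------------------
# correlations


def pearson_r(a: SimilarityMatrix, b: SimilarityMatrix) -> float:
    """Pearson correlation over the unordered-pair vectorizations."""
    if a.labels != b.labels:
        raise ValueError("matrices must share labels")
    va, vb = a.pair_vector(), b.pair_vector()
    if np.std(va) == 0 or np.std(vb) == 0:
        raise ValueError("zero variance in pair vector; correlation undefined")
    return float(stats.pearsonr(va, vb).statistic)


def fisher_z(r: float) -> float:
    """Fisher z-transformation, atanh(r); requires r in (-1, 1)."""
    if not -1.0 < r < 1.0:
        raise ValueError("fisher_z requires r strictly inside (-1, 1)")
    return math.atanh(r)


# ---------------------------------------------------------------------------
# rating tables -> matrices


def _matrix_from_ratings(df: pd.DataFrame, labels: list[str]) -> np.ndarray:
    n = len(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    sums = np.zeros((n, n))
    counts = np.zeros((n, n))
    for a, b, rating in zip(df["object_a"], df["object_b"], df["rating"]):
        i, j = index[a], index[b]
        sums[i, j] += rating
        counts[i, j] += 1
        if i != j:
            sums[j, i] += rating
            counts[j, i] += 1
    missing = [
        (labels[i], labels[j])
        for i, j in zip(*np.where(counts == 0))
        if i <= j
    ]
    if missing:
        raise ValueError(f"ratings missing for pairs: {missing[:10]}")
    return sums / counts


def subject_matrices(
    ratings: pd.DataFrame,
) -> dict[str, dict[str, SimilarityMatrix]]:
    """Per-subject similarity matrices, averaging each subject's ratings
    over blocks (and presentation order) for every unordered pair.

    Returns ``{condition: {subject: SimilarityMatrix}}``; raises if any
    subject is missing one of the 136 pairs.
    """
    labels = sorted(set(ratings["object_a"]) | set(ratings["object_b"]))
    out: dict[str, dict[str, SimilarityMatrix]] = {}
    for (condition, subject), df in ratings.groupby(["condition", "subject"]):
        mat = _matrix_from_ratings(df, labels)
        out.setdefault(condition, {})[subject] = SimilarityMatrix(
            mat, labels, "ratings"
        )
    return out


def condition_matrix(per_subject: dict[str, SimilarityMatrix]) -> SimilarityMatrix:
    """Condition-level matrix: the mean of the subject-level matrices."""
    mats = list(per_subject.values())
    values = np.mean([m.values for m in mats], axis=0)
    return SimilarityMatrix(values, mats[0].labels, "ratings")


def correlation_table(
    matrices: dict[str, dict[str, SimilarityMatrix]]
) -> pd.DataFrame:
    """Mean +/- sd of subject-pair correlations for every condition pair.

    Within a condition every ordered pair of distinct subjects counts
    (n(n-1) pairs, e.g. 42 for 7 subjects); across two conditions every
    subject pairing counts (n*m, e.g. 49 for 7 vs 7).
    """
    conditions = list(matrices)
    rows = []
    for ca, cb in itertools.combinations_with_replacement(conditions, 2):
        rs = []
        if ca == cb:
            subs = list(matrices[ca].values())
            for a, b in itertools.permutations(subs, 2):
                rs.append(pearson_r(a, b))
        else:
            for a in matrices[ca].values():
                for b in matrices[cb].values():
                    rs.append(pearson_r(a, b))
        rows.append(
            {
                "condition_a": ca,
                "condition_b": cb,
                "mean_r": float(np.mean(rs)),
                "sd_r": float(np.std(rs, ddof=1)) if len(rs) > 1 else 0.0,
                "n_pairs": len(rs),
            }
        )
    return pd.DataFrame(rows)


def bootstrap_correlations(
    matrices: dict[str, dict[str, SimilarityMatrix]],
    replications: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap mean +/- sd of condition-level matrix correlations.

    Each replication resamples subjects with replacement within every
    condition and rebuilds the condition-level matrices.  For a pair of
    distinct conditions the correlation of the two resampled matrices is
    recorded; within a condition the correlation of two independent
    resamples is used (a same-matrix correlation is identically 1).
    """
    rng = np.random.default_rng(seed)
    conditions = list(matrices)

    def resample(condition: str) -> SimilarityMatrix:
        subs = list(matrices[condition].values())
        picks = rng.integers(len(subs), size=len(subs))
        return condition_matrix({i: subs[k] for i, k in enumerate(picks)})

    sums: dict[tuple[str, str], list[float]] = {
        pair: [] for pair in itertools.combinations_with_replacement(conditions, 2)
    }
    for _ in range(replications):
        level = {c: resample(c) for c in conditions}
        for ca, cb in sums:
            if ca == cb:
                r = pearson_r(level[ca], resample(ca))
            else:
                r = pearson_r(level[ca], level[cb])
            sums[(ca, cb)].append(r)
    rows = [
        {
            "condition_a": ca,
            "condition_b": cb,
            "mean_r": float(np.mean(rs)),
            "sd_r": float(np.std(rs, ddof=1)),
            "n_replications": replications,
        }
        for (ca, cb), rs in sums.items()
    ]
    return pd.DataFrame(rows)
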