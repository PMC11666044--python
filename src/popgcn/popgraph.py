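"""Population-graph construction from fused multimodal features.

Nodes are subjects; each node carries the concatenation of a standardized
imaging-feature block and a standardized clinical (non-imaging) block. Edges
are assigned by one of two rules applied to a convex blend of per-block
pairwise affinities with usage ratio ``beta`` (``beta=1``: imaging only,
``beta=0``: non-imaging only):

* cosine rule — keep the blended cosine similarity as an edge weight wherever
  it is at least the threshold ``alpha_cs`` (inclusive);
* Euclidean rule — connect (unweighted) wherever the blended per-feature
  Euclidean distance is at most ``q_ed``, the ``alpha_ed``-th percentile of
  the strictly-upper-triangular blended distances.

Both rules would always connect a node to itself (self-cosine 1, self-distance
0), and the GCN normalisation separately adds one self-loop per node.  To
avoid double-weighting, adjacency matrices are stored with a zero diagonal and
exactly one unit self-loop is added during normalisation; edge accounting
reports self-edges as present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "FeatureBlock",
    "Standardizer",
    "GraphConfig",
    "PopulationGraph",
    "fit_standardizer",
    "concat_features",
    "cosine_affinity",
    "euclidean_affinity",
    "blend_affinity",
    "threshold_cosine",
    "threshold_euclidean",
    "normalize_adjacency",
    "edge_composition",
    "build_population_graph",
]

_ZERO_NORM_EPS = 1e-12


@dataclass
class FeatureBlock:
    matrix: np.ndarray  # N x p
    kind: str  # "imaging" | "non-imaging"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] < 1:
            raise ValueError("feature matrix must be N x p with p >= 1")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix must be finite")
        if self.kind not in ("imaging", "non-imaging"):
            raise ValueError(f"kind must be 'imaging' or 'non-imaging', got {self.kind!r}")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]


@dataclass
class Standardizer:
    """Column mean/SD estimated on training rows only (population SD).

    Columns that are constant on the training rows are flagged and mapped to
    zero everywhere, so they carry no information instead of exploding.
    """

    mean: np.ndarray
    sd: np.ndarray
    zero_sd: np.ndarray  # boolean flags

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        sd = np.where(self.zero_sd, 1.0, self.sd)
        Z = (X - self.mean) / sd
        Z[:, self.zero_sd] = 0.0
        return Z


def fit_standardizer(block: FeatureBlock, train_idx: np.ndarray) -> Standardizer:
    train_idx = np.asarray(train_idx)
    if train_idx.size == 0:
        raise ValueError("train_idx must be non-empty")
    Xtr = block.matrix[train_idx]
    mean = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)  # population SD (ddof=0)
    return Standardizer(mean=mean, sd=sd, zero_sd=sd < _ZERO_NORM_EPS)


def concat_features(img: FeatureBlock | np.ndarray, nimg: FeatureBlock | np.ndarray) -> np.ndarray:
    """Fuse imaging and non-imaging blocks, imaging columns first."""
    a = img.matrix if isinstance(img, FeatureBlock) else np.asarray(img, float)
    b = nimg.matrix if isinstance(nimg, FeatureBlock) else np.asarray(nimg, float)
    if b.size == 0:
        return a.copy()
    if a.shape[0] != b.shape[0]:
        raise ValueError(f"row-count mismatch: {a.shape[0]} vs {b.shape[0]}")
    return np.hstack([a, b])


def cosine_affinity(Z: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity; diagonal 1; rows with ~zero norm get 0."""
    Z = np.asarray(Z, dtype=np.float64)
    norms = np.linalg.norm(Z, axis=1)
    zero = norms < _ZERO_NORM_EPS
    safe = np.where(zero, 1.0, norms)
    U = Z / safe[:, None]
    A = U @ U.T
    A[zero, :] = 0.0
    A[:, zero] = 0.0
    np.clip(A, -1.0, 1.0, out=A)
    np.fill_diagonal(A, 1.0)
    return A


def euclidean_affinity(Z: np.ndarray, p: int | None = None) -> np.ndarray:
    """Pairwise Euclidean distance divided by the feature count ``p``.

    Dividing by ``p`` keeps distances from different-width blocks comparable
    before blending.
    """
    Z = np.asarray(Z, dtype=np.float64)
    if p is None:
        p = Z.shape[1]
    if p <= 0:
        raise ValueError(f"feature count must be positive, got {p}")
    return squareform(pdist(Z)) / p


def blend_affinity(A_img: np.ndarray, A_nimg: np.ndarray, beta: float) -> np.ndarray:
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must be in [0, 1], got {beta}")
    A_img = np.asarray(A_img, float)
    A_nimg = np.asarray(A_nimg, float)
    if A_img.shape != A_nimg.shape:
        raise ValueError("affinity shapes differ")
    if beta == 0.0:
        return A_nimg.copy()
    if beta == 1.0:
        return A_img.copy()
    return beta * A_img + (1.0 - beta) * A_nimg


def threshold_cosine(M: np.ndarray, alpha_cs: float) -> np.ndarray:
    """Weighted adjacency: keep blended similarities >= alpha_cs (inclusive)."""
    M = np.asarray(M, float)
    A = np.where(M >= alpha_cs, M, 0.0)
    np.fill_diagonal(A, 0.0)
    return A


def threshold_euclidean(M: np.ndarray, alpha_ed: float) -> tuple[np.ndarray, float]:
    """Binary adjacency from the blended-distance percentile cutoff.

    ``q_ed`` is the ``alpha_ed``-th percentile (linear interpolation) of the
    strictly-upper-triangular entries of ``M``; pairs with distance <= q_ed
    (inclusive) are connected. Returns ``(A, q_ed)``.
    """
    M = np.asarray(M, float)
    if not 0.0 < alpha_ed <= 100.0:
        raise ValueError(f"alpha_ed must be in (0, 100], got {alpha_ed}")
    n = M.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes for a distance quantile")
    iu = np.triu_indices(n, k=1)
    q_ed = float(np.percentile(M[iu], alpha_ed))
    A = (M <= q_ed).astype(np.float64)
    np.fill_diagonal(A, 0.0)
    return A, q_ed


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric normalisation with one added self-loop per node.

    A_hat = D~^{-1/2} (A + I) D~^{-1/2} with D~ the (weighted) degree matrix
    of A + I.
    """
    A = np.asarray(A, float)
    if A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    At = A + np.eye(A.shape[0])
    d = At.sum(axis=1)
    dinv = 1.0 / np.sqrt(d)
    return dinv[:, None] * At * dinv[None, :]


@dataclass
class GraphConfig:
    measure: str = "euclidean"  # "cosine" | "euclidean"
    beta: float = 0.5
    alpha_cs: float | None = None  # cosine-similarity threshold
    alpha_ed: float | None = None  # distance percentile rank in (0, 100]
    q_ed: float | None = field(default=None, compare=False)  # derived cutoff

    def __post_init__(self):
        if self.measure not in ("cosine", "euclidean"):
            raise ValueError(f"measure must be cosine|euclidean, got {self.measure!r}")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")
        if self.measure == "cosine":
            if self.alpha_cs is None:
                raise ValueError("cosine measure requires alpha_cs")
            if self.alpha_ed is not None:
                raise ValueError("alpha_ed is not used with the cosine measure")
        else:
            if self.alpha_ed is None:
                raise ValueError("euclidean measure requires alpha_ed")
            if self.alpha_cs is not None:
                raise ValueError("alpha_cs is not used with the euclidean measure")


@dataclass
class PopulationGraph:
    X: np.ndarray  # N x (p_img + p_nimg) fused node features
    A: np.ndarray  # adjacency, zero diagonal
    A_hat: np.ndarray  # normalized adjacency
    labels: np.ndarray
    train_mask: np.ndarray
    val_mask: np.ndarray
    test_mask: np.ndarray
    config: GraphConfig | None = None

    def __post_init__(self):
        n = self.X.shape[0]
        for name in ("A", "A_hat"):
            m = getattr(self, name)
            if m.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}")
        masks = np.stack([self.train_mask, self.val_mask, self.test_mask])
        if masks.sum(axis=0).max() > 1:
            raise ValueError("train/val/test masks must be disjoint")

    @property
    def n(self) -> int:
        return self.X.shape[0]


def _masks_from_indices(n, train_idx, val_idx, test_idx):
    masks = []
    for idx in (train_idx, val_idx, test_idx):
        m = np.zeros(n, dtype=bool)
        m[np.asarray(idx)] = True
        masks.append(m)
    return masks


def build_population_graph(
    img: FeatureBlock,
    nimg: FeatureBlock,
    labels: np.ndarray,
    config: GraphConfig,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    test_idx: np.ndarray,
) -> PopulationGraph:
    """Standardize on training rows, fuse, assign edges, normalize.

    Both blocks are standardized with training-row statistics before edge
    assignment and before fusion into the node feature matrix.
    """
    if img.n != nimg.n:
        raise ValueError("imaging and non-imaging blocks must share N")
    z_img = fit_standardizer(img, train_idx).transform(img.matrix)
    z_nimg = fit_standardizer(nimg, train_idx).transform(nimg.matrix)
    X = concat_features(z_img, z_nimg)
    if config.measure == "cosine":
        M = blend_affinity(cosine_affinity(z_img), cosine_affinity(z_nimg), config.beta)
        A = threshold_cosine(M, config.alpha_cs)
    else:
        M = blend_affinity(
            euclidean_affinity(z_img, img.p),
            euclidean_affinity(z_nimg, nimg.p),
            config.beta,
        )
        A, q_ed = threshold_euclidean(M, config.alpha_ed)
        config.q_ed = q_ed
    A_hat = normalize_adjacency(A)
    train_mask, val_mask, test_mask = _masks_from_indices(
        img.n, train_idx, val_idx, test_idx
    )
    return PopulationGraph(
        X=X,
        A=A,
        A_hat=A_hat,
        labels=np.asarray(labels),
        train_mask=train_mask,
        val_mask=val_mask,
        test_mask=test_mask,
        config=config,
    )


def edge_composition(A: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Per-label-pair edge accounting.

    For a same-label group of size n the number of possible edges is
    n + n(n-1)/2 (every self-edge counts as always present, since a node is
    maximally similar to itself); for two different labels of sizes n1, n2 it
    is n1*n2.  Counted edges are the off-diagonal edges of ``A`` between the
    groups plus the n self-edges for same-label rows.
    """
    A = np.asarray(A)
    labels = np.asarray(labels)
    if len(labels) != A.shape[0]:
        raise ValueError("labels length must match adjacency size")
    present = A != 0
    uniq = np.unique(labels)
    rows = []
    for i, li in enumerate(uniq):
        gi = labels == li
        ni = int(gi.sum())
        for lj in uniq[i:]:
            gj = labels == lj
            nj = int(gj.sum())
            if li == lj:
                sub = present[np.ix_(gi, gi)]
                n_edges = int(np.triu(sub, k=1).sum()) + ni  # + self-edges
                possible = ni + ni * (ni - 1) // 2
            else:
                n_edges = int(present[np.ix_(gi, gj)].sum())
                possible = ni * nj
            rows.append(
                {
                    "pair": f"{li}-{lj}",
                    "n_edges": n_edges,
                    "n_possible": possible,
                    "percentage": 100.0 * n_edges / possible,
                }
            )
    return pd.DataFrame(rows)
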