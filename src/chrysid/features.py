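"""Deep-feature analysis: affinity propagation clustering and PCA accounting.

After training, the shared flatten-layer feature (512-dim at the default
preset) is extracted per image and, for cultivar-level analysis, mean-pooled
per cultivar.  Two analyses probe what those features encode:

* **Affinity propagation (AP)** — exemplar-based clustering by message
  passing.  Similarity is negative squared Euclidean distance; the diagonal
  preference (median of the off-diagonal similarities by default) controls
  how many exemplars emerge.  Responsibilities and availabilities are damped
  with factor ``lambda`` and iteration stops once the exemplar set has been
  stable for a window of consecutive iterations.
* **PCA** — eigenvalues of the (by default) correlation matrix, with the
  accounting used in variance tables: importance of a component is
  ``100 * eigenvalue / total variance`` (total = number of retained columns
  for standardized data) and the cumulative proportion is its running sum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .manifest import Manifest
from .nn.resnet import MultiHeadResNet

__all__ = ["FeatureMatrix", "extract_features", "cultivar_mean_features",
           "APConfig", "APResult", "affinity_propagation", "adjusted_rand_index",
           "PCAResult", "pca", "variance_accounting", "label_projection_report"]


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions of the same items."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("partitions must label the same items")
    n = len(a)
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    contingency = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(contingency, (ai, bi), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_cells = comb2(contingency).sum()
    sum_rows = comb2(contingency.sum(axis=1)).sum()
    sum_cols = comb2(contingency.sum(axis=0)).sum()
    expected = sum_rows * sum_cols / comb2(n)
    max_index = 0.5 * (sum_rows + sum_cols)
    if max_index == expected:
        return 1.0
    return float((sum_cells - expected) / (max_index - expected))


@dataclass
class FeatureMatrix:
    """n x d feature matrix with row labels and optional annotations."""

    X: np.ndarray
    row_labels: list[str]
    annotations: pd.DataFrame | None = None  # color/petal/flower per row

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if len(self.row_labels) != self.X.shape[0]:
            raise ValueError("row labels must cover all rows")
        if not np.isfinite(self.X).all():
            raise ValueError("non-finite feature values")

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.X, index=self.row_labels)
        if self.annotations is not None:
            df = pd.concat([self.annotations.set_index(pd.Index(self.row_labels)), df], axis=1)
        df.to_csv(path, index_label="row")

    @classmethod
    def from_csv(cls, path, annotation_cols=("cultivar_id", "petal_type",
                                             "flower_type", "color_class")) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col="row")
        ann_cols = [c for c in annotation_cols if c in df.columns]
        ann = df[ann_cols] if ann_cols else None
        X = df.drop(columns=ann_cols).to_numpy(float)
        return cls(X=X, row_labels=[str(i) for i in df.index],
                   annotations=ann.reset_index(drop=True) if ann is not None else None)


def extract_features(net: MultiHeadResNet, X: np.ndarray,
                     row_labels: list[str] | None = None,
                     batch: int = 64) -> FeatureMatrix:
    """Per-image shared features (inference mode, deterministic)."""
    feats = []
    for s in range(0, len(X), batch):
        _, f = net.forward_logits(X[s:s + batch], training=False)
        feats.append(f)
    F = np.concatenate(feats)
    labels = row_labels if row_labels is not None else [str(i) for i in range(len(F))]
    return FeatureMatrix(X=F, row_labels=list(labels))


def cultivar_mean_features(fm: FeatureMatrix, manifest: Manifest,
                           color_of: dict[str, str] | None = None) -> FeatureMatrix:
    """Mean-pool image features per cultivar (rows follow manifest order)."""
    if len(fm.X) != len(manifest):
        raise ValueError("feature rows do not map 1:1 onto manifest rows")
    df = pd.DataFrame(fm.X)
    df["cultivar_id"] = manifest.df["cultivar_id"].to_numpy()
    pooled = df.groupby("cultivar_id", sort=True).mean()
    cultivars = pooled.index.tolist()
    ann_rows = (manifest.df.drop_duplicates("cultivar_id")
                .set_index("cultivar_id").loc[cultivars])
    ann = pd.DataFrame({
        "cultivar_id": cultivars,
        "petal_type": ann_rows["petal_type"].to_numpy(),
        "flower_type": ann_rows["flower_type"].to_numpy(),
    })
    if color_of is not None:
        ann["color_class"] = [color_of.get(c) for c in cultivars]
    return FeatureMatrix(X=pooled.to_numpy(), row_labels=cultivars, annotations=ann)


# -- affinity propagation -----------------------------------------------------

@dataclass(frozen=True)
class APConfig:
    damping: float = 0.9
    max_iterations: int = 1000
    stable_window: int = 100        # consecutive iterations with a fixed exemplar set
    preference: float | str = "median"

    def __post_init__(self) -> None:
        if not (0.5 <= self.damping < 1.0):
            raise ValueError("damping must lie in [0.5, 1)")
        if self.stable_window > self.max_iterations:
            raise ValueError("stable window exceeds the iteration budget")


@dataclass
class APResult:
    exemplar_of: np.ndarray       # per-row index of its exemplar
    exemplars: np.ndarray         # sorted unique exemplar indices
    n_clusters: int
    iterations: int
    converged: bool
    labels: np.ndarray = field(default=None)  # 0..n_clusters-1, aligned with exemplars

    def __post_init__(self) -> None:
        if self.labels is None:
            lut = {e: i for i, e in enumerate(self.exemplars)}
            self.labels = np.array([lut[e] for e in self.exemplar_of])


def similarity_matrix(X: np.ndarray) -> np.ndarray:
    """Negative squared Euclidean distances."""
    sq = (X**2).sum(axis=1)
    return -(sq[:, None] + sq[None, :] - 2.0 * X @ X.T)


def affinity_propagation(F: FeatureMatrix | np.ndarray,
                         cfg: APConfig = APConfig(),
                         S: np.ndarray | None = None) -> APResult:
    """Exemplar clustering by damped responsibility/availability passing.

    Either a feature matrix (similarity = negative squared distance) or a
    precomputed similarity matrix ``S`` may be given.  The preference is
    written on the diagonal; ``"median"`` uses the median of the off-diagonal
    similarities.  Iteration stops when the exemplar set is unchanged for
    ``stable_window`` consecutive iterations, or at ``max_iterations``.
    """
    if S is None:
        X = F.X if isinstance(F, FeatureMatrix) else np.asarray(F, dtype=float)
        if not np.isfinite(X).all():
            raise ValueError("non-finite features")
        S = similarity_matrix(X)
    else:
        S = np.array(S, dtype=float, copy=True)
    n = S.shape[0]
    if n == 1:
        return APResult(exemplar_of=np.zeros(1, int), exemplars=np.zeros(1, int),
                        n_clusters=1, iterations=0, converged=True)

    off = ~np.eye(n, dtype=bool)
    pref = float(np.median(S[off])) if cfg.preference == "median" else float(cfg.preference)
    np.fill_diagonal(S, pref)

    lam = cfg.damping
    R = np.zeros((n, n))
    A = np.zeros((n, n))
    idx = np.arange(n)
    prev_exemplars: np.ndarray | None = None
    stable = 0
    it = 0
    converged = False
    for it in range(1, cfg.max_iterations + 1):
        # responsibilities
        AS = A + S
        first = AS.argmax(axis=1)
        m1 = AS[idx, first]
        AS[idx, first] = -np.inf
        m2 = AS.max(axis=1)
        AS[idx, first] = m1
        Rnew = S - m1[:, None]
        Rnew[idx, first] = S[idx, first] - m2
        R = lam * R + (1 - lam) * Rnew
        # availabilities
        Rp = np.maximum(R, 0.0)
        np.fill_diagonal(Rp, R.diagonal())
        colsum = Rp.sum(axis=0)
        Anew = np.minimum(0.0, colsum[None, :] - Rp)
        Anew[idx, idx] = colsum - R.diagonal()
        A = lam * A + (1 - lam) * Anew

        exemplars = idx[(A.diagonal() + R.diagonal()) > 0]
        if prev_exemplars is not None and np.array_equal(exemplars, prev_exemplars) \
                and len(exemplars) > 0:
            stable += 1
            if stable >= cfg.stable_window:
                converged = True
                break
        else:
            stable = 0
        prev_exemplars = exemplars

    exemplars = idx[(A.diagonal() + R.diagonal()) > 0]
    if len(exemplars) == 0:
        # degenerate run: fall back to the best self-evidence point
        exemplars = np.array([int(np.argmax(A.diagonal() + R.diagonal()))])
    assign = exemplars[np.argmax(S[:, exemplars], axis=1)]
    assign[exemplars] = exemplars
    return APResult(exemplar_of=assign, exemplars=np.sort(exemplars),
                    n_clusters=len(exemplars), iterations=it, converged=converged)


# -- PCA ----------------------------------------------------------------------

@dataclass
class PCAResult:
    eigenvalues: np.ndarray     # descending
    importance: np.ndarray      # percent of total variance
    cumulative: np.ndarray      # running sum of importance
    scores: np.ndarray          # n x 2 projections on the first two components
    components: np.ndarray      # r x d orthonormal rows (loadings), descending
    standardized: bool
    total_variance: float
    dropped_columns: list[int] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        """Eigenvalue / importance / cumulative accounting table."""
        return pd.DataFrame({
            "Principal components": [f"PC{i+1}" for i in range(len(self.eigenvalues))],
            "Eigenvalues": self.eigenvalues,
            "Importance of components": self.importance,
            "Cumulative proportion": self.cumulative,
        })


def variance_accounting(eigenvalues: np.ndarray, total_variance: float
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Importance (%) and cumulative proportion implied by eigenvalues."""
    ev = np.asarray(eigenvalues, dtype=float)
    importance = 100.0 * ev / float(total_variance)
    return importance, np.cumsum(importance)


def pca(F: FeatureMatrix | np.ndarray, standardize: bool = True) -> PCAResult:
    """Eigen-decomposition of the covariance (or correlation) of the features.

    Standardized mode centers and scales columns to unit variance, so the
    total variance equals the number of retained columns; zero-variance
    columns are dropped with a warning.  Component score signs are fixed by
    making each component's largest-magnitude loading positive.
    """
    X = F.X if isinstance(F, FeatureMatrix) else np.asarray(F, dtype=float)
    n, d = X.shape
    if n < 2:
        raise ValueError("PCA needs at least two rows")
    Xc = X - X.mean(axis=0)
    dropped: list[int] = []
    if standardize:
        sd = Xc.std(axis=0, ddof=1)
        keep = sd > 0
        dropped = list(np.flatnonzero(~keep))
        if dropped:
            warnings.warn(f"dropping {len(dropped)} zero-variance columns before "
                          "standardization", stacklevel=2)
            Xc = Xc[:, keep]
            sd = sd[keep]
        Xc = Xc / sd
        total = float(Xc.shape[1])
    else:
        total = float(Xc.var(axis=0, ddof=1).sum())

    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = (s**2) / (n - 1)
    order = np.argsort(-eig, kind="stable")
    eig = eig[order]
    Vt = Vt[order].copy()
    importance, cumulative = variance_accounting(eig, total)

    # deterministic sign convention: largest-magnitude loading positive
    for j in range(Vt.shape[0]):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            Vt[j] = -Vt[j]
    scores = Xc @ Vt[:2].T
    if scores.shape[1] == 1:
        scores = np.column_stack([scores[:, 0], np.zeros(n)])
    return PCAResult(eigenvalues=eig, importance=importance, cumulative=cumulative,
                     scores=scores, components=Vt, standardized=standardize,
                     total_variance=total, dropped_columns=dropped)


def label_projection_report(P: PCAResult, annotations: pd.Series | np.ndarray
                            ) -> pd.DataFrame:
    """Per-label centroid and dispersion of the first-two-component scores."""
    ann = pd.Series(np.asarray(annotations))
    if len(ann) != len(P.scores):
        raise ValueError("annotations must cover all rows")
    if ann.isna().any():
        raise ValueError("missing annotation")
    rows = []
    for label, idx in ann.groupby(ann).groups.items():
        pts = P.scores[np.asarray(idx)]
        centroid = pts.mean(axis=0)
        disp = float(np.sqrt(((pts - centroid) ** 2).sum(axis=1).mean()))
        rows.append({"label": label, "n": len(pts), "pc1": centroid[0],
                     "pc2": centroid[1], "dispersion": disp})
    return pd.DataFrame(rows).set_index("label")


def plot_projection(P: PCAResult, annotations, path=None, title: str = ""):
    """Scatter of the first two components colored by label (optional)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ann = pd.Series(np.asarray(annotations))
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, idx in ann.groupby(ann).groups.items():
        pts = P.scores[np.asarray(idx)]
        ax.scatter(pts[:, 0], pts[:, 1], s=12, label=str(label))
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7, markerscale=0.8)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
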