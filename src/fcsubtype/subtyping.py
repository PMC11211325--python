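"""Autoencoder embedding, Ward clustering, and cluster-number selection.

FC vectors (length n(n-1)/2, i.e. 64,620 at full 360-region scale) are
too high-dimensional for distance-based clustering to behave well, so
subjects are first compressed with a small fully connected autoencoder
(default 256 -> 64 -> 16 latent, ReLU hidden units, linear latent and
output, mean-squared reconstruction loss, Adam).  Training is denoising
by default: each epoch the inputs are corrupted with Gaussian noise
while the clean vectors remain the reconstruction target.  At cohort
sample sizes (tens of subjects) a plain autoencoder reaches zero
reconstruction error by memorisation and its latent geometry becomes
arbitrary; the corruption forces the encoder to be smooth, so nearby
connectomes stay nearby in the latent space.  FC features are kept on
their native correlation scale (no per-edge standardisation): all edges
already share units, and variance-equalising them inflates edges that
carry nothing but sampling noise.

The latent vectors are clustered agglomeratively with Ward linkage for
every candidate k in 2..9; the number of clusters is chosen by joint
internal-index evaluation: the k with the highest Silhouette Coefficient
wins, with the Davies-Bouldin score (lower is better) breaking ties.
The full quality map is retained so other selection rules can be applied.

Only AD subjects are meant to be clustered; restricting the input is the
caller's responsibility (see :mod:`fcsubtype.pipeline`).

The autoencoder is implemented directly on numpy: cohort-scale inputs
(tens of subjects) train full-batch in seconds and stay bitwise
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, pdist, squareform

from .errors import DivergenceError

__all__ = [
    "AutoencoderConfig",
    "LatentEmbedding",
    "ClusterAssignment",
    "standardize_features",
    "Autoencoder",
    "train_autoencoder",
    "pca_embedding",
    "ward_cluster",
    "clustering_quality",
    "select_k",
]


@dataclass
class AutoencoderConfig:
    input_dim: int
    hidden_dims: tuple[int, ...] = (256, 64)
    latent_dim: int = 16
    epochs: int = 500
    batch_size: int | None = None  # None = full batch
    learning_rate: float = 1e-3
    corruption_sd: float = 0.2  # denoising input noise; 0 = plain autoencoder
    seed: int = 0

    def __post_init__(self) -> None:
        dims = (self.input_dim, *self.hidden_dims, self.latent_dim)
        if any(a <= b for a, b in zip(dims, dims[1:])):
            raise ValueError(f"encoder dims must strictly decrease, got {dims}")


@dataclass
class LatentEmbedding:
    subject_ids: list[str]
    z: np.ndarray
    final_train_loss: float
    loss_history: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class ClusterAssignment:
    subject_ids: list[str]
    labels: np.ndarray  # 1-based; 1 = largest cluster
    k: int
    linkage: str = "ward"
    quality: dict[int, tuple[float, float]] = field(default_factory=dict)


def standardize_features(X: np.ndarray) -> np.ndarray:
    """Z-score each feature over subjects; zero-variance features -> 0."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


class Autoencoder:
    """Symmetric fully connected autoencoder with Adam, on numpy.

    Encoder layers use ReLU except the final (latent) layer, which is
    linear; the decoder mirrors the encoder with a linear output layer.
    """

    def __init__(self, cfg: AutoencoderConfig):
        self.cfg = cfg
        dims = [cfg.input_dim, *cfg.hidden_dims, cfg.latent_dim,
                *reversed(cfg.hidden_dims), cfg.input_dim]
        self.n_encoder_layers = len(cfg.hidden_dims) + 1
        rng = np.random.default_rng(cfg.seed)
        self.W = [rng.standard_normal((din, dout)) * np.sqrt(2.0 / din)
                  for din, dout in zip(dims, dims[1:])]
        self.b = [np.zeros(dout) for dout in dims[1:]]
        # linear layers: latent (end of encoder) and reconstruction output
        self._linear = {self.n_encoder_layers - 1, len(self.W) - 1}
        self._mW = [np.zeros_like(w) for w in self.W]
        self._vW = [np.zeros_like(w) for w in self.W]
        self._mb = [np.zeros_like(v) for v in self.b]
        self._vb = [np.zeros_like(v) for v in self.b]
        self._t = 0

    def _forward(self, x: np.ndarray) -> list[np.ndarray]:
        acts = [x]
        for li, (w, b) in enumerate(zip(self.W, self.b)):
            h = acts[-1] @ w + b
            if li not in self._linear:
                h = np.maximum(h, 0.0)
            acts.append(h)
        return acts

    def encode(self, x: np.ndarray) -> np.ndarray:
        h = np.asarray(x, dtype=float)
        for li in range(self.n_encoder_layers):
            h = h @ self.W[li] + self.b[li]
            if li not in self._linear:
                h = np.maximum(h, 0.0)
        return h

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(x, dtype=float))[-1]

    def loss(self, x: np.ndarray) -> float:
        return float(np.mean((self.reconstruct(x) - x) ** 2))

    def train_step(self, x: np.ndarray, target: np.ndarray | None = None) -> float:
        """One gradient step reconstructing ``target`` from input ``x``.

        ``target`` defaults to ``x``; passing the clean data while ``x``
        is a corrupted copy gives the denoising objective.
        """
        target = x if target is None else target
        acts = self._forward(x)
        xhat = acts[-1]
        err = xhat - target
        batch_loss = float(np.mean(err ** 2))
        # backprop MSE: dL/dxhat = 2 err / (B * D)
        delta = 2.0 * err / err.size
        gW = [np.empty(0)] * len(self.W)
        gb = [np.empty(0)] * len(self.b)
        for li in range(len(self.W) - 1, -1, -1):
            if li not in self._linear:
                delta = delta * (acts[li + 1] > 0)
            gW[li] = acts[li].T @ delta
            gb[li] = delta.sum(axis=0)
            if li > 0:
                delta = delta @ self.W[li].T
        self._adam(gW, gb)
        return batch_loss

    def _adam(self, gW, gb, beta1=0.9, beta2=0.999, eps=1e-8) -> None:
        self._t += 1
        lr = self.cfg.learning_rate
        c1 = 1 - beta1 ** self._t
        c2 = 1 - beta2 ** self._t
        for i in range(len(self.W)):
            for g, m, v, p in ((gW[i], self._mW[i], self._vW[i], self.W[i]),
                               (gb[i], self._mb[i], self._vb[i], self.b[i])):
                m *= beta1
                m += (1 - beta1) * g
                v *= beta2
                v += (1 - beta2) * g * g
                p -= lr * (m / c1) / (np.sqrt(v / c2) + eps)


def train_autoencoder(X: np.ndarray, cfg: AutoencoderConfig,
                      subject_ids: list[str] | None = None,
                      standardize: bool = False) -> tuple[Autoencoder, LatentEmbedding]:
    """Train on all subjects and return their latent embedding.

    With ``cfg.corruption_sd > 0`` (the default) training is denoising:
    each epoch reconstructs the clean vectors from a freshly corrupted
    copy.  ``loss_history`` records the clean-input reconstruction loss
    per epoch.  Deterministic under ``cfg.seed`` (weight init, corruption
    noise and any minibatch shuffling all derive from it).  Raises
    :class:`DivergenceError` with a lower-learning-rate hint if the loss
    goes non-finite.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 subjects")
    if not np.all(np.isfinite(X)):
        raise ValueError("inputs must be finite")
    if subject_ids is None:
        subject_ids = [f"S{i:03d}" for i in range(X.shape[0])]
    Xs = standardize_features(X) if standardize else X
    model = Autoencoder(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    n = Xs.shape[0]
    bs = cfg.batch_size or n
    losses = np.empty(cfg.epochs)
    for epoch in range(cfg.epochs):
        if cfg.corruption_sd > 0:
            Xin = Xs + rng.standard_normal(Xs.shape) * cfg.corruption_sd
        else:
            Xin = Xs
        if bs >= n:
            model.train_step(Xin, target=Xs)
        else:
            order = rng.permutation(n)
            for i in range(0, n, bs):
                model.train_step(Xin[order[i:i + bs]], target=Xs[order[i:i + bs]])
        losses[epoch] = model.loss(Xs)
        if not np.isfinite(losses[epoch]):
            raise DivergenceError(
                f"non-finite loss at epoch {epoch + 1}; try a lower learning rate "
                f"(current {cfg.learning_rate})")
    z = model.encode(Xs)
    emb = LatentEmbedding(list(subject_ids), z, float(losses[-1]), losses)
    return model, emb


def pca_embedding(X: np.ndarray, dim: int,
                  subject_ids: list[str] | None = None,
                  standardize: bool = False) -> LatentEmbedding:
    """Top principal components of the (standardised) features.

    A linear fallback for the autoencoder; useful to confirm that
    downstream conclusions do not depend on the nonlinear embedding.
    """
    from sklearn.decomposition import PCA

    X = np.asarray(X, dtype=float)
    Xs = standardize_features(X) if standardize else X
    dim = min(dim, min(Xs.shape) - 1)
    z = PCA(n_components=dim, svd_solver="full").fit_transform(Xs)
    ids = list(subject_ids) if subject_ids is not None else [f"S{i:03d}" for i in range(len(Xs))]
    return LatentEmbedding(ids, z, float("nan"))


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k by descending size; ties keep first-seen order."""
    uniq, counts = np.unique(labels, return_counts=True)
    first_seen = {u: int(np.argmax(labels == u)) for u in uniq}
    order = sorted(uniq, key=lambda u: (-counts[list(uniq).index(u)], first_seen[u]))
    mapping = {old: new + 1 for new, old in enumerate(order)}
    return np.asarray([mapping[v] for v in labels], dtype=int)


def ward_cluster(z: LatentEmbedding, k: int) -> ClusterAssignment:
    """Agglomerative Ward clustering of the latent vectors into k clusters."""
    n = z.z.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    tree = linkage(z.z, method="ward")
    labels = _relabel_by_size(fcluster(tree, t=k, criterion="maxclust"))
    if np.unique(labels).size != k:
        raise ValueError(
            f"Ward tree cannot be cut into {k} clusters (duplicate points?); "
            f"got {np.unique(labels).size}")
    return ClusterAssignment(list(z.subject_ids), labels, k)


def clustering_quality(z: LatentEmbedding | np.ndarray,
                       labels: ClusterAssignment | np.ndarray) -> tuple[float, float]:
    """Silhouette Coefficient and Davies-Bouldin score of a labelling.

    Silhouette per point: (b - a) / max(a, b) with a = mean distance to
    the point's own cluster and b = the smallest mean distance to another
    cluster; singleton clusters contribute 0 and so do points where both
    a and b are 0.  Davies-Bouldin: mean over clusters of the largest
    (s_i + s_j) / d_ij with s the mean distance to the cluster centroid
    and d the distance between centroids; coincident centroids with zero
    scatter contribute 0 rather than dividing by zero.
    """
    pts = z.z if isinstance(z, LatentEmbedding) else np.asarray(z, dtype=float)
    lab = labels.labels if isinstance(labels, ClusterAssignment) else np.asarray(labels)
    uniq = np.unique(lab)
    if uniq.size < 2:
        raise ValueError("need at least 2 clusters")
    n = pts.shape[0]
    D = squareform(pdist(pts))
    members = {u: np.flatnonzero(lab == u) for u in uniq}

    sil = np.zeros(n)
    for i in range(n):
        own = members[lab[i]]
        if own.size == 1:
            continue  # singleton convention: 0
        a = D[i, own].sum() / (own.size - 1)
        b = min(D[i, members[u]].mean() for u in uniq if u != lab[i])
        m = max(a, b)
        sil[i] = (b - a) / m if m > 0 else 0.0

    cents = np.vstack([pts[members[u]].mean(axis=0) for u in uniq])
    scatter = np.asarray([np.linalg.norm(pts[members[u]] - cents[j], axis=1).mean()
                          for j, u in enumerate(uniq)])
    M = cdist(cents, cents)
    k = uniq.size
    db_terms = np.zeros(k)
    for i in range(k):
        worst = 0.0
        for j in range(k):
            if j == i:
                continue
            s = scatter[i] + scatter[j]
            if M[i, j] > 0:
                worst = max(worst, s / M[i, j])
            elif s > 0:
                worst = np.inf
        db_terms[i] = worst
    return float(sil.mean()), float(db_terms.mean())


def select_k(z: LatentEmbedding, k_min: int = 2, k_max: int = 9) -> ClusterAssignment:
    """Sweep k, score each Ward labelling, and pick the best.

    Selection is silhouette-primary (higher wins) with Davies-Bouldin as
    tie-breaker (lower wins) and the smaller k as the final tie-break.
    The returned assignment carries the full quality map over the sweep.
    """
    n = z.z.shape[0]
    k_max = min(k_max, n - 1)
    if k_min > k_max:
        raise ValueError(f"empty k range [{k_min}, {k_max}]")
    quality: dict[int, tuple[float, float]] = {}
    assignments: dict[int, ClusterAssignment] = {}
    for k in range(k_min, k_max + 1):
        try:
            a = ward_cluster(z, k)
        except ValueError:
            continue  # duplicate points: this k is unattainable, skip it
        quality[k] = clustering_quality(z, a)
        assignments[k] = a
    if not quality:
        raise ValueError("no candidate k produced a valid clustering")
    best = min(quality, key=lambda k: (-quality[k][0], quality[k][1], k))
    chosen = assignments[best]
    chosen.quality = quality
    return chosen
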