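"""Multivariate stack for volatile profiles: scaling, PCA, HCA, k-means, OPLS-DA.

All methods are implemented directly on numpy linear algebra so that
every numerical convention (scaling, deflation, sign fixing, tie
breaking, seeding) is explicit and bit-stable:

* ``zscore`` — columnwise autoscaling with the sample (n-1) standard
  deviation; constant columns map to all-zero and are flagged degenerate
  rather than dropped.
* ``pca`` — SVD of the scaled matrix; deterministic sign convention
  (largest-magnitude loading entry positive per component).
* ``hca_ward`` — agglomerative clustering under Ward's minimum-variance
  criterion via the Lance-Williams recurrence on squared Euclidean
  distances; heights follow the usual convention in which two singleton
  points merge at their Euclidean distance.
* ``kmeans`` — Lloyd iterations from k-means++ starts, best of
  ``n_restarts`` by the within-cluster sum of squares (WCSS); nearest
  center ties break to the lowest center index.
* ``opls_da`` — two-class orthogonal projections to latent structures:
  class-orthogonal variation is stripped from X before a single
  predictive PLS component is extracted, so with zero orthogonal
  components the model reduces exactly to one-component PLS1.
* ``vip`` — variable importance in projection over the predictive
  component (the dominant convention for OPLS-DA VIP); an
  orthogonal-inclusive variant is available. VIP scores always satisfy
  mean(VIP^2) = 1.
* ``permutation_test`` — class-label permutation null for the OPLS-DA
  R2Y, p = (1 + #{R2Y_perm >= R2Y_obs}) / (1 + n_perm).

Randomized operations take explicit integer seeds; nothing reads the
wall clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScaledMatrix",
    "PCAResult",
    "HCAResult",
    "KMeansResult",
    "OPLSModel",
    "zscore",
    "pca",
    "hca_ward",
    "kmeans",
    "opls_da",
    "vip",
    "permutation_test",
]


# ---------------------------------------------------------------------------
# scaling


@dataclass
class ScaledMatrix:
    """Autoscaled samples x variables matrix with scaling parameters kept."""

    values: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    degenerate: np.ndarray  # True for columns that were constant

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]


def zscore(matrix: np.ndarray) -> ScaledMatrix:
    """Columnwise (x - mean) / sd with sample (ddof=1) standard deviation.

    Constant columns become all-zero and are flagged ``degenerate``.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    degenerate = sd == 0
    safe_sd = np.where(degenerate, 1.0, sd)
    values = (X - mean) / safe_sd
    values[:, degenerate] = 0.0
    return ScaledMatrix(values=values, mean=mean, sd=sd, degenerate=degenerate)


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    """Scores, orthonormal loadings and explained-variance ratios.

    ``explained_variance_ratio`` is relative to the total variance of the
    input, so it sums to 1 only when every component is retained.
    """

    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # variables x components
    explained_variance_ratio: np.ndarray


def pca(matrix: ScaledMatrix, n_components: int) -> PCAResult:
    """Principal component analysis by SVD of the (already scaled) matrix."""
    X = matrix.values
    limit = min(matrix.n_samples - 1, matrix.n_variables)
    if not 1 <= n_components <= limit:
        raise ValueError(f"n_components must be in [1, {limit}], got {n_components}")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total = float((s**2).sum())
    ratio = (s**2) / total if total > 0 else np.zeros_like(s)
    scores = U[:, :n_components] * s[:n_components]
    loadings = Vt[:n_components].T
    # sign convention: largest-|entry| of each loading column positive
    for j in range(n_components):
        k = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=ratio[:n_components],
    )


# ---------------------------------------------------------------------------
# hierarchical clustering (Ward / Euclidean)


@dataclass
class HCAResult:
    """Agglomerative merge history in linkage-matrix form.

    ``merges`` has one row per merge: (cluster a, cluster b, height,
    size of the new cluster), with original items numbered 0..n-1 and the
    cluster formed at step i numbered n+i. Ward with Euclidean distances
    is reducible, so heights are non-decreasing.
    """

    merges: np.ndarray  # (n-1) x 4

    @property
    def n_items(self) -> int:
        return self.merges.shape[0] + 1


def hca_ward(matrix: ScaledMatrix | np.ndarray) -> HCAResult:
    """Ward's-method agglomeration via the Lance-Williams recurrence."""
    X = matrix.values if isinstance(matrix, ScaledMatrix) else np.asarray(matrix, float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items to cluster")

    # squared Ward distances; for singletons d^2 = squared Euclidean distance
    diff = X[:, None, :] - X[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)

    active = {i: (i, 1) for i in range(n)}  # slot -> (cluster label, size)
    d2 = d2.astype(float)
    np.fill_diagonal(d2, np.inf)
    merges = np.empty((n - 1, 4))
    next_label = n
    slots = list(range(n))

    for step in range(n - 1):
        # nearest active pair; ties break to smallest (i, j)
        best = (np.inf, None)
        for ai in range(len(slots)):
            i = slots[ai]
            for aj in range(ai + 1, len(slots)):
                j = slots[aj]
                if d2[i, j] < best[0]:
                    best = (d2[i, j], (i, j))
        dmin2, (i, j) = best
        li, ni = active[i]
        lj, nj = active[j]
        a, b = sorted((li, lj))
        merges[step] = (a, b, np.sqrt(dmin2), ni + nj)

        # Lance-Williams Ward update into slot i
        for k in slots:
            if k in (i, j):
                continue
            nk = active[k][1]
            tot = ni + nj + nk
            d2[i, k] = d2[k, i] = (
                (ni + nk) * d2[i, k] + (nj + nk) * d2[j, k] - nk * dmin2
            ) / tot
        active[i] = (next_label, ni + nj)
        del active[j]
        slots.remove(j)
        d2[j, :] = np.inf
        d2[:, j] = np.inf
        next_label += 1

    return HCAResult(merges=merges)


# ---------------------------------------------------------------------------
# k-means


@dataclass
class KMeansResult:
    """Best-of-restarts Lloyd solution with its WCSS trace."""

    labels: np.ndarray  # item -> cluster index in 0..k-1
    centers: np.ndarray  # k x variables
    wcss: float
    wcss_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    first = int(rng.integers(n))
    centers[0] = X[first]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total == 0:  # all points coincide with chosen centers
            idx = int(rng.integers(n))
        else:
            idx = int(rng.choice(n, p=d2 / total))
        centers[j] = X[idx]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(axis=1))
    return centers


def _assign(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    # argmin breaks ties toward the lowest center index
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def _wcss(X: np.ndarray, centers: np.ndarray, labels: np.ndarray) -> float:
    return float(((X - centers[labels]) ** 2).sum())


def kmeans(
    matrix: ScaledMatrix | np.ndarray,
    k: int,
    seed: int,
    n_restarts: int = 50,
    max_iter: int = 300,
) -> KMeansResult:
    """Lloyd's algorithm from k-means++ starts, best of ``n_restarts`` by WCSS."""
    X = matrix.values if isinstance(matrix, ScaledMatrix) else np.asarray(matrix, float)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    rng = np.random.default_rng(seed)

    best: KMeansResult | None = None
    for _ in range(n_restarts):
        centers = _kmeanspp_init(X, k, rng)
        labels = _assign(X, centers)
        trace = [_wcss(X, centers, labels)]
        for _ in range(max_iter):
            new_centers = centers.copy()
            for j in range(k):
                members = X[labels == j]
                if len(members):
                    new_centers[j] = members.mean(axis=0)
                else:
                    # re-seed an emptied cluster at the worst-fit point
                    far = int(((X - centers[labels]) ** 2).sum(axis=1).argmax())
                    new_centers[j] = X[far]
            new_labels = _assign(X, new_centers)
            centers = new_centers
            trace.append(_wcss(X, centers, new_labels))
            if np.array_equal(new_labels, labels):
                labels = new_labels
                break
            labels = new_labels
        candidate = KMeansResult(
            labels=labels,
            centers=centers,
            wcss=_wcss(X, centers, labels),
            wcss_trace=np.array(trace),
        )
        if best is None or candidate.wcss < best.wcss:
            best = candidate
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# OPLS-DA


@dataclass
class OPLSModel:
    """Two-class OPLS model: one predictive + n_ortho orthogonal components."""

    t: np.ndarray  # predictive scores (samples)
    w: np.ndarray  # predictive weights (variables, unit norm)
    p: np.ndarray  # predictive loadings (variables)
    q: float  # y-loading of the predictive component
    t_ortho: np.ndarray  # samples x n_ortho
    w_ortho: np.ndarray  # variables x n_ortho
    p_ortho: np.ndarray  # variables x n_ortho
    r2x: float
    r2y: float
    y: np.ndarray  # centered +/-1 coded response actually fitted
    classes: tuple
    vip: np.ndarray = field(default_factory=lambda: np.empty(0))
    permutation_p: float | None = None

    @property
    def n_ortho(self) -> int:
        return self.t_ortho.shape[1]

    def predictive_scores_by_class(self) -> dict:
        pos, neg = self.classes
        return {pos: self.t[self.y > 0], neg: self.t[self.y < 0]}


def _code_labels(y) -> tuple[np.ndarray, tuple]:
    labels = np.asarray(y)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ValueError(f"OPLS-DA needs exactly 2 classes, got {classes}")
    neg, pos = classes
    coded = np.where(labels == pos, 1.0, -1.0)
    return coded - coded.mean(), (pos, neg)


def opls_da(X: ScaledMatrix | np.ndarray, y, n_ortho: int = 1) -> OPLSModel:
    """Fit a two-class OPLS-DA model with one predictive component.

    ``y`` holds two distinct class labels, coded +/-1 and centered. Each
    orthogonal round removes from X the systematic variation uncorrelated
    with y (Trygg-Wold deflation); the final predictive component is a
    one-component PLS1 fit of the filtered matrix, so ``n_ortho=0`` *is*
    PLS1. Rounds stop early if no orthogonal variation remains.
    """
    Xs = X.values if isinstance(X, ScaledMatrix) else np.asarray(X, float)
    if Xs.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    if n_ortho < 0:
        raise ValueError("n_ortho must be >= 0")
    yc, classes = _code_labels(y)
    if len(yc) != Xs.shape[0]:
        raise ValueError("X and y disagree on sample count")

    Xd = Xs.copy()
    ssx_total = float((Xs**2).sum())
    t_os, w_os, p_os = [], [], []
    for _ in range(n_ortho):
        w = Xd.T @ yc
        nw = np.linalg.norm(w)
        if nw == 0:
            break
        w = w / nw
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-12:  # no y-orthogonal structure left
            break
        w_o = w_o / n_o
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        t_os.append(t_o)
        w_os.append(w_o)
        p_os.append(p_o)

    w = Xd.T @ yc
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("X carries no covariance with the class labels")
    w = w / nw
    t = Xd @ w
    p = Xd.T @ t / (t @ t)
    q = float(yc @ t / (t @ t))

    r2y = float(q**2 * (t @ t) / (yc @ yc))
    modeled = (t @ t) * (p @ p) + sum((to @ to) * (po @ po) for to, po in zip(t_os, p_os))
    r2x = float(modeled / ssx_total) if ssx_total > 0 else 0.0

    model = OPLSModel(
        t=t,
        w=w,
        p=p,
        q=q,
        t_ortho=np.column_stack(t_os) if t_os else np.empty((Xs.shape[0], 0)),
        w_ortho=np.column_stack(w_os) if w_os else np.empty((Xs.shape[1], 0)),
        p_ortho=np.column_stack(p_os) if p_os else np.empty((Xs.shape[1], 0)),
        r2x=r2x,
        r2y=r2y,
        y=yc,
        classes=classes,
    )
    model.vip = vip(model)
    return model


def vip(model: OPLSModel, include_orthogonal: bool = False) -> np.ndarray:
    """Variable importance in projection; satisfies mean(VIP^2) = 1.

    The default scores variables on the predictive component only
    (weights normalized, weighted by the y-variance it explains), the
    dominant convention for OPLS-DA VIP. With ``include_orthogonal`` the
    orthogonal components enter weighted by the X-variance they model.
    """
    p_vars = model.w.shape[0]
    w2 = model.w**2  # unit norm already
    if not include_orthogonal or model.n_ortho == 0:
        return np.sqrt(p_vars * w2)
    ssy = model.r2y
    ssx_o = np.array(
        [
            (model.t_ortho[:, a] @ model.t_ortho[:, a]) * (model.p_ortho[:, a] @ model.p_ortho[:, a])
            for a in range(model.n_ortho)
        ]
    )
    ssx_o = ssx_o / ssx_o.sum() * (1.0 - ssy) if ssx_o.sum() > 0 else ssx_o
    num = ssy * w2
    for a in range(model.n_ortho):
        wo = model.w_ortho[:, a]
        num = num + ssx_o[a] * (wo**2) / (wo @ wo)
    return np.sqrt(p_vars * num / (ssy + ssx_o.sum()))


def permutation_test(
    X: ScaledMatrix | np.ndarray,
    y,
    n_ortho: int = 1,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Label-permutation p-value for the OPLS-DA R2Y.

    p = (1 + #{permuted models with R2Y exceeding observed}) / (1 + n_perm).
    A sampled permutation that reproduces the original labeling (or its
    complement) yields the observed R2Y bit-for-bit and does not count
    as exceeding it; with few samples such collisions are frequent
    (3 vs 3 has only 20 distinct assignments) and counting them would
    put a floor of ~0.1 under every p-value.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(y)
    observed = opls_da(X, labels, n_ortho=n_ortho).r2y
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        try:
            r2y = opls_da(X, perm, n_ortho=n_ortho).r2y
        except ValueError:  # degenerate permutation (no covariance left)
            r2y = 0.0
        if r2y > observed + 1e-12:
            count += 1
    return (1 + count) / (1 + n_perm)
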