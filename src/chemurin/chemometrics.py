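"""PCA + canonical discriminant machinery (DAPC).

DAPC here means: consolidate spectral variance with PCA, keep the leading
components explaining a target fraction of variance (default 99%), then run
a canonical (linear discriminant) analysis on those PC scores.  Canonical
axes are eigenvectors of the within-class-scatter-whitened between-class
scatter; classification assigns each spectrum to the nearest class centroid
(Euclidean distance) in canonical space, which under the whitening equals a
Mahalanobis rule in score space.

Deterministic conventions:

* every PC / canonical axis is oriented so its largest-magnitude element is
  positive;
* all generalized eigen-axes are retained (for g classes only g-1 carry
  between-class separation; trailing eigenvalues are ~0 but the axes keep the
  geometry reproducible);
* nearest-centroid ties break to the earlier label in the model's ordered
  class list (order of first appearance in the training labels).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA as _SKPCA

from .errors import SingularScatterError

SERIAL_VERSION = 1

#: Raman band assignments used for annotating influential wavenumbers.
BAND_ANNOTATIONS = (
    (776.0, "phosphatidylinositol"),
    (826.0, "nucleic acids"),
    (890.0, "collagen/protein/amide III"),
    (898.0, "glucose"),
    (931.0, "glucose"),
    (1002.0, "urea"),
    (1004.0, "collagen/protein/amide III"),
    (1007.0, "collagen/protein/amide III"),
    (1055.0, "nucleic acids"),
    (1060.0, "glucose"),
    (1078.0, "nucleic acids"),
    (1105.0, "glucose"),
    (1237.0, "collagen/protein/amide III"),
    (1242.0, "collagen/protein/amide III"),
    (1318.0, "collagen/protein/amide III; nucleic acids"),
)


def annotate_band(wavenumber, window=5.0):
    """Assignments within ``window`` cm^-1 of a wavenumber, joined by '; '."""
    hits = [a for w, a in BAND_ANNOTATIONS if abs(w - wavenumber) <= window]
    return "; ".join(dict.fromkeys(hits)) if hits else ""


def _orient_columns(mat):
    """Flip column signs so each column's largest-|.| entry is positive."""
    mat = np.array(mat, dtype=float, copy=True)
    for j in range(mat.shape[1]):
        col = mat[:, j]
        k = int(np.argmax(np.abs(col)))
        if col[k] < 0:
            mat[:, j] = -col
    return mat


@dataclass(frozen=True)
class PCModel:
    """Fitted PCA: grid, mean row, orthonormal loadings, variance fractions.

    ``loadings`` has one column per component (grid-points x components);
    ``n_selected`` is the smallest k whose cumulative explained-variance
    fraction reaches the retention target.
    """

    grid: np.ndarray
    mean_row: np.ndarray
    loadings: np.ndarray
    variance_fractions: np.ndarray
    n_selected: int
    retention: float

    def transform(self, rows, n_components=None):
        k = self.n_selected if n_components is None else n_components
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        if rows.shape[1] != self.mean_row.size:
            raise ValueError(
                f"row length {rows.shape[1]} does not match model grid "
                f"({self.mean_row.size} points)"
            )
        return (rows - self.mean_row) @ self.loadings[:, :k]


def fit_pca(matrix, retention=0.99, grid=None, max_components=None):
    """PCA with the cumulative-variance retention rule.

    Parameters
    ----------
    matrix : (n_samples, n_points) array
    retention : float in (0, 1]
        Keep the smallest number of leading components whose cumulative
        explained-variance fraction reaches this target.
    grid : optional wavenumber vector carried along for loading lookups.
    max_components : optional hard cap applied after the retention rule
        (used by cross-validation to keep downstream scatter invertible).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("fit_pca needs a 2-D matrix with at least 2 rows")
    if not 0 < retention <= 1:
        raise ValueError("retention must be in (0, 1]")
    pca = _SKPCA(n_components=None, svd_solver="full")
    pca.fit(X)
    loadings = _orient_columns(pca.components_.T)
    fractions = pca.explained_variance_ratio_
    cum = np.cumsum(fractions)
    n_selected = int(np.searchsorted(cum, retention - 1e-12) + 1)
    n_selected = min(n_selected, fractions.size)
    if max_components is not None:
        n_selected = max(1, min(n_selected, int(max_components)))
    if grid is None:
        grid = np.arange(X.shape[1], dtype=float)
    return PCModel(
        grid=np.asarray(grid, dtype=float),
        mean_row=pca.mean_.copy(),
        loadings=loadings,
        variance_fractions=fractions.copy(),
        n_selected=n_selected,
        retention=float(retention),
    )


# ---------------------------------------------------------------------------
# scatter matrices, MANOVA


def _class_order(labels):
    return list(dict.fromkeys(labels))


def _scatter(scores, labels):
    """Within-class (W), between-class (B) and total (T) SSCP matrices."""
    X = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    grand = X.mean(axis=0)
    W = np.zeros((X.shape[1], X.shape[1]))
    B = np.zeros_like(W)
    order = _class_order(labels)
    for lab in order:
        sub = X[labels == lab]
        mu = sub.mean(axis=0)
        d = sub - mu
        W += d.T @ d
        m = (mu - grand)[:, None]
        B += sub.shape[0] * (m @ m.T)
    centered = X - grand
    T = centered.T @ centered
    return W, B, T, order


def manova_significance(scores, labels, alpha=0.05):
    """Wilks' lambda and the estimated group-separation dimension.

    Lambda = det(W)/det(T) in [0, 1]; smaller means stronger separation.
    The dimension estimate follows the classical Bartlett sequence of
    chi-square tests on the canonical eigenvalues: ``dims`` is the smallest d
    for which the test of "separation dimension <= d" is not rejected.
    """
    X = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    order = _class_order(labels)
    g = len(order)
    n, p = X.shape
    if g < 2:
        raise ValueError("MANOVA needs at least 2 classes")
    counts = [int(np.sum(labels == lab)) for lab in order]
    if min(counts) < 2:
        raise ValueError("every class needs at least 2 samples")
    if p >= n - g:
        raise SingularScatterError(
            f"{p} components with only {n} samples in {g} classes leaves the "
            "within-class scatter rank-deficient; retain fewer components"
        )
    W, B, T, _ = _scatter(X, labels)
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_w <= 0 or sign_t <= 0:
        raise SingularScatterError(
            "singular within-class or total scatter; retain fewer components"
        )
    lam = float(np.exp(logdet_w - logdet_t))
    lam = min(max(lam, 0.0), 1.0)

    eigvals = _canonical_eigvals(W, B)
    dims = 0
    for d in range(0, min(p, g - 1)):
        tail = eigvals[d:]
        statistic = (n - 1 - (p + g) / 2.0) * np.sum(np.log1p(tail))
        df = (p - d) * (g - 1 - d)
        if df <= 0:
            break
        pval = stats.chi2.sf(statistic, df)
        if pval > alpha:
            break
        dims = d + 1
    return lam, dims


def _whitening_root(W, n_minus_1):
    """Inverse square root of the within-class covariance W/(n-1)."""
    Wc = W / n_minus_1
    vals, vecs = np.linalg.eigh(Wc)
    tol = vals.max() * 1e-10 if vals.size else 0.0
    if vals.size == 0 or vals.min() <= tol:
        raise SingularScatterError(
            "within-class scatter is singular; reduce the PCA retention "
            "target (fewer components) or add samples"
        )
    return vecs @ np.diag(vals ** -0.5) @ vecs.T


def _canonical_eigvals(W, B):
    vals = np.linalg.eigvals(np.linalg.solve(W, B))
    vals = np.sort(np.abs(np.real(vals)))[::-1]
    return vals


@dataclass(frozen=True)
class DAPCModel:
    """Fitted DAPC: PCA stage plus canonical coefficients and centroids.

    ``canonical_coefficients`` maps retained PC scores to canonical
    coordinates (n_selected x n_canonicals, with n_canonicals = n_selected);
    ``centroids`` holds per-class means in canonical space, rows aligned with
    ``class_labels``.
    """

    pc_model: PCModel
    canonical_coefficients: np.ndarray
    eigenvalues: np.ndarray
    class_labels: tuple
    centroids: np.ndarray

    @property
    def n_canonicals(self):
        return self.canonical_coefficients.shape[1]

    # -- projection -------------------------------------------------------

    def canonical_coords(self, rows):
        scores = self.pc_model.transform(rows)
        return scores @ self.canonical_coefficients

    def predict_rows(self, rows):
        """Nearest-centroid labels (and coordinates) for spectrum rows."""
        coords = self.canonical_coords(rows)
        d2 = ((coords[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        idx = np.argmin(d2, axis=1)  # argmin returns the first minimum: tie rule
        labels = [self.class_labels[i] for i in idx]
        return labels, coords

    # -- serialization ----------------------------------------------------

    def to_json(self, path=None):
        doc = {
            "version": SERIAL_VERSION,
            "grid": self.pc_model.grid.tolist(),
            "mean_row": self.pc_model.mean_row.tolist(),
            "loadings": self.pc_model.loadings.tolist(),
            "variance_fractions": self.pc_model.variance_fractions.tolist(),
            "n_selected": int(self.pc_model.n_selected),
            "retention": float(self.pc_model.retention),
            "canonical_coefficients": self.canonical_coefficients.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "class_labels": list(self.class_labels),
            "centroids": self.centroids.tolist(),
        }
        text = json.dumps(doc)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source):
        if isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        if doc.get("version") != SERIAL_VERSION:
            raise ValueError(f"unsupported model version {doc.get('version')!r}")
        pc = PCModel(
            grid=np.array(doc["grid"], dtype=float),
            mean_row=np.array(doc["mean_row"], dtype=float),
            loadings=np.array(doc["loadings"], dtype=float),
            variance_fractions=np.array(doc["variance_fractions"], dtype=float),
            n_selected=int(doc["n_selected"]),
            retention=float(doc["retention"]),
        )
        return cls(
            pc_model=pc,
            canonical_coefficients=np.array(doc["canonical_coefficients"], dtype=float),
            eigenvalues=np.array(doc["eigenvalues"], dtype=float),
            class_labels=tuple(doc["class_labels"]),
            centroids=np.array(doc["centroids"], dtype=float),
        )


def fit_dapc(scores, labels, pc_model=None):
    """Canonical discriminant analysis on PC scores.

    Canonical axes are eigenvectors of the symmetrized whitened
    between-class scatter ``Wc^{-1/2} Bc Wc^{-1/2}`` (covariances with n-1
    denominators), ordered by decreasing eigenvalue; all axes are retained.
    """
    X = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    order = _class_order(labels)
    if len(order) < 2:
        raise ValueError("fit_dapc needs at least 2 classes")
    n = X.shape[0]
    W, B, _, _ = _scatter(X, labels)
    root = _whitening_root(W, n - 1)
    M = root @ (B / (n - 1)) @ root
    M = (M + M.T) / 2.0
    vals, vecs = np.linalg.eigh(M)
    idx = np.argsort(vals)[::-1]
    vals = np.clip(vals[idx], 0.0, None)
    A = _orient_columns(root @ vecs[:, idx])
    coords = X @ A
    centroids = np.vstack([coords[labels == lab].mean(axis=0) for lab in order])
    if pc_model is None:
        pc_model = PCModel(
            grid=np.arange(X.shape[1], dtype=float),
            mean_row=np.zeros(X.shape[1]),
            loadings=np.eye(X.shape[1]),
            variance_fractions=np.full(X.shape[1], 1.0 / X.shape[1]),
            n_selected=X.shape[1],
            retention=1.0,
        )
    return DAPCModel(
        pc_model=pc_model,
        canonical_coefficients=A,
        eigenvalues=vals,
        class_labels=tuple(order),
        centroids=centroids,
    )


def fit_dapc_pipeline(matrix, labels, retention=0.99, grid=None):
    """PCA (retention rule, capped for scatter invertibility) then DAPC."""
    X = np.asarray(matrix, dtype=float)
    labels = list(labels)
    g = len(set(labels))
    cap = max(1, X.shape[0] - g - 1)
    pc = fit_pca(X, retention=retention, grid=grid, max_components=cap)
    scores = pc.transform(X)
    return fit_dapc(scores, labels, pc_model=pc)


def predict(model, row):
    """Classify one preprocessed spectrum row; returns (label, coords)."""
    labels, coords = model.predict_rows(np.atleast_2d(row))
    return labels[0], coords[0]


def top_loadings(model, axis=("canonical", 0), k=10, annotation_window=5.0):
    """Wavenumbers ranked by |weight| on a PC or canonical axis.

    ``axis`` is ("pc", i) or ("canonical", i).  Canonical weights are the PC
    loadings composed with the canonical coefficients, i.e. the weight each
    grid point carries on that canonical axis.  Returns a list of
    ``(wavenumber, weight, annotation)`` tuples, annotation attached when a
    known band lies within ``annotation_window`` cm^-1.
    """
    kind, index = axis
    pc = model.pc_model
    if kind == "pc":
        if not 0 <= index < pc.loadings.shape[1]:
            raise IndexError(f"pc axis {index} out of range")
        weights = pc.loadings[:, index]
    elif kind == "canonical":
        if not 0 <= index < model.n_canonicals:
            raise IndexError(f"canonical axis {index} out of range")
        weights = pc.loadings[:, : pc.n_selected] @ model.canonical_coefficients[:, index]
    else:
        raise ValueError("axis kind must be 'pc' or 'canonical'")
    n = weights.size
    if k > n:
        warnings.warn(f"k={k} exceeds grid size {n}; clamping", stacklevel=2)
        k = n
    ranked = np.argsort(np.abs(weights))[::-1][:k]
    return [
        (float(pc.grid[i]), float(weights[i]), annotate_band(pc.grid[i], annotation_window))
        for i in ranked
    ]
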