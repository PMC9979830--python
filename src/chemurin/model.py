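"""Model/Results front end for the DAPC pipeline.

`RamanDAPC` is the model object (data + settings); `fit()` returns a
`RamanDAPCResults` carrying the fitted PCA/canonical parameters, MANOVA
diagnostics and, on request, leave-one-out validation — presented the way
statistical modelling packages expose estimates: ``results.summary()``,
``results.predict(...)``, serialization, plotting.
"""

from __future__ import annotations

import numpy as np

from . import chemometrics as chem
from .preprocess import PreprocessConfig, preprocess_pipeline
from .validation import (
    ConfusionMatrix,
    loocv_predict,
    metrics_from_confusion,
    multiclass_report,
)


class RamanDAPC:
    """Discriminant analysis of principal components over spectrum rows.

    Parameters
    ----------
    matrix : (n_samples, n_points) array
        Preprocessed spectra, one unit-norm row per sample.
    labels : sequence of class labels, aligned with rows.
    grid : optional wavenumber vector (cm^-1) for loading lookups.
    retention : float
        Fraction of dataset variance the retained PCs must explain (0.99 by
        default, following the screening pipeline's convention).
    """

    def __init__(self, matrix, labels, grid=None, retention=0.99):
        self.matrix = np.asarray(matrix, dtype=float)
        self.labels = list(labels)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.labels):
            raise ValueError("matrix rows and labels must be aligned")
        self.grid = None if grid is None else np.asarray(grid, dtype=float)
        self.retention = float(retention)

    @classmethod
    def from_spectra(cls, sset, config=None, retention=0.99):
        """Build from a harmonized :class:`~chemurin.spectra.SpectrumSet`,
        running the full pre-processing chain first."""
        if config is None:
            config = PreprocessConfig()
        matrix, labels, grid = preprocess_pipeline(sset, config)
        return cls(matrix, labels, grid=grid, retention=retention)

    def fit(self):
        dapc = chem.fit_dapc_pipeline(
            self.matrix, self.labels, retention=self.retention, grid=self.grid
        )
        scores = dapc.pc_model.transform(self.matrix)
        try:
            wilks, dims = chem.manova_significance(scores, self.labels)
        except Exception:
            wilks, dims = None, None  # descriptive only; small folds may lack df
        return RamanDAPCResults(self, dapc, wilks, dims)

    def loocv(self):
        """Leave-one-out predicted labels (PCA and DAPC refit per fold)."""
        return loocv_predict(
            self.matrix, self.labels, retention=self.retention, grid=self.grid
        )


class RamanDAPCResults:
    """Fitted DAPC with diagnostics.

    Attributes
    ----------
    dapc : chemometrics.DAPCModel
        The fitted parameter container (PCA stage, canonical coefficients,
        centroids, eigenvalues).
    wilks_lambda : float or None
        MANOVA Wilks' lambda of the retained PC scores (None when the
        scatter test is not computable for the data's shape).
    separation_dims : int or None
        Estimated number of significant separation dimensions.
    """

    def __init__(self, model, dapc, wilks_lambda, separation_dims):
        self.model = model
        self.dapc = dapc
        self.wilks_lambda = wilks_lambda
        self.separation_dims = separation_dims

    # -- accessors --------------------------------------------------------

    @property
    def n_components(self):
        return self.dapc.pc_model.n_selected

    @property
    def n_canonicals(self):
        return self.dapc.n_canonicals

    @property
    def class_labels(self):
        return list(self.dapc.class_labels)

    def predict(self, rows):
        labels, _ = self.dapc.predict_rows(rows)
        return labels

    def canonical_coords(self, rows=None):
        rows = self.model.matrix if rows is None else rows
        return self.dapc.canonical_coords(rows)

    def top_loadings(self, axis=("canonical", 0), k=10):
        return chem.top_loadings(self.dapc, axis=axis, k=k)

    def loocv_report(self):
        """LOOCV confusion and panel; multiclass falls back to per-class
        one-vs-rest panels plus overall accuracy."""
        preds = self.model.loocv()
        classes = self.class_labels
        if len(classes) == 2:
            cm = ConfusionMatrix.from_labels(self.model.labels, preds, classes[0])
            return cm, metrics_from_confusion(cm)
        return multiclass_report(self.model.labels, preds, classes)

    # -- persistence ------------------------------------------------------

    def save(self, path):
        self.dapc.to_json(path)
        return path

    @staticmethod
    def load_parameters(path):
        return chem.DAPCModel.from_json(path)

    # -- presentation -----------------------------------------------------

    def summary(self):
        pc = self.dapc.pc_model
        counts = {c: self.model.labels.count(c) for c in self.class_labels}
        lines = [
            "Raman DAPC results",
            "==================",
            f"samples:              {self.model.matrix.shape[0]}",
            f"grid points:          {self.model.matrix.shape[1]}",
            f"classes:              "
            + ", ".join(f"{c} (n={n})" for c, n in counts.items()),
            f"variance retention:   {pc.retention:.2f}",
            f"PCs retained:         {pc.n_selected}"
            f"  (cumulative variance "
            f"{np.sum(pc.variance_fractions[: pc.n_selected]):.4f})",
            f"canonical axes:       {self.n_canonicals}",
            "leading eigenvalues:  "
            + ", ".join(f"{v:.4g}" for v in self.dapc.eigenvalues[:6]),
        ]
        if self.wilks_lambda is not None:
            lines.append(f"Wilks' lambda:        {self.wilks_lambda:.4g} "
                         f"(separation dims: {self.separation_dims})")
        return "\n".join(lines)

    def plot_canonicals(self, axes=(0, 1), ax=None):
        """Scatter the training samples in canonical space, one marker set
        per class."""
        import matplotlib.pyplot as plt

        coords = self.canonical_coords()
        i, j = axes
        if ax is None:
            _, ax = plt.subplots()
        labels = np.asarray(self.model.labels)
        for lab in self.class_labels:
            pts = coords[labels == lab]
            if self.n_canonicals > max(i, j):
                ax.scatter(pts[:, i], pts[:, j], label=str(lab), s=18)
        ax.set_xlabel(f"Canonical {i + 1}")
        ax.set_ylabel(f"Canonical {j + 1}")
        ax.legend()
        return ax
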