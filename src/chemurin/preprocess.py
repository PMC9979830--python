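"""Spectral pre-processing chain.

The fixed stage order is: replicate averaging -> truncation to the working
window (default 400-1,800 cm^-1) -> ISREA node-based baselining -> vector
normalization.  Each sample ends up represented exactly once, as a unit-norm,
baseline-corrected intensity vector on the shared grid.

ISREA forms the baseline from a cubic spline anchored at a small set of
user-chosen wavenumber "nodes" (eight or fewer).  Anchors start on the
spectrum itself and are iteratively lowered wherever the spline overshoots
the signal, so the converged baseline hugs the smooth background from below
while sharp bands survive subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.interpolate import CubicSpline

from .errors import ConvergenceError, GridRangeError, SpectrumValidationError
from .spectra import RamanSpectrum, SpectrumSet

TRUNCATION_LOW = 400.0
TRUNCATION_HIGH = 1800.0

#: Node presets used by the study's analyses (all bounded by 400 and 1,800).
NODE_PRESETS = {
    "fig1": (400, 950, 1100, 1475, 1800),
    "analysis1": (400, 846, 944, 988, 1031, 1196, 1665, 1800),
    "analysis2": (400, 433, 666, 722, 764, 1469, 1479, 1800),
    "dkd": (400, 917, 940, 1058, 1558, 1800),
    "imn": (400, 510, 1121, 1488, 1618, 1623, 1704, 1800),
    "mn": (400, 463, 1460, 1483, 1508, 1681, 1800),
    "rn": (400, 1202, 1232, 1271, 1323, 1516, 1717, 1800),
}


@dataclass(frozen=True)
class NodeSet:
    """Ordered ISREA node wavenumbers segmenting the working window."""

    nodes: np.ndarray

    def __post_init__(self):
        nodes = np.asarray(self.nodes, dtype=float)
        object.__setattr__(self, "nodes", nodes)
        if nodes.ndim != 1 or not (2 <= nodes.size <= 8):
            raise ValueError(f"NodeSet needs 2-8 nodes, got {nodes.size}")
        if np.any(np.diff(nodes) <= 0):
            raise ValueError("nodes must be strictly increasing")

    @classmethod
    def from_preset(cls, name):
        try:
            return cls(np.asarray(NODE_PRESETS[name], dtype=float))
        except KeyError:
            raise KeyError(
                f"unknown node preset {name!r}; known presets: {sorted(NODE_PRESETS)}"
            ) from None

    def __len__(self):
        return self.nodes.size


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunables for the pre-processing chain.

    ``isrea_tolerance`` is relative to the spectrum's maximum absolute
    intensity; convergence requires the baseline nowhere to exceed the signal
    by more than that amount.
    """

    truncation_low: float = TRUNCATION_LOW
    truncation_high: float = TRUNCATION_HIGH
    nodes: NodeSet = field(default_factory=lambda: NodeSet.from_preset("fig1"))
    isrea_tolerance: float = 1e-4
    isrea_max_iterations: int = 100
    normalize: bool = True

    def __post_init__(self):
        if not self.truncation_low < self.truncation_high:
            raise ValueError("truncation_low must be < truncation_high")
        n = self.nodes.nodes
        if n[0] < self.truncation_low or n[-1] > self.truncation_high:
            raise ValueError("nodes must lie inside the truncation window")
        if not (self.isrea_tolerance > 0):
            raise ValueError("isrea_tolerance must be positive")
        if self.isrea_max_iterations < 1:
            raise ValueError("isrea_max_iterations must be >= 1")

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        nodes = doc.pop("nodes", None)
        if isinstance(nodes, str):
            nodeset = NodeSet.from_preset(nodes)
        elif nodes is not None:
            nodeset = NodeSet(np.asarray(nodes, dtype=float))
        else:
            nodeset = NodeSet.from_preset("fig1")
        return cls(nodes=nodeset, **doc)

    def to_yaml(self, path):
        doc = {
            "truncation_low": float(self.truncation_low),
            "truncation_high": float(self.truncation_high),
            "nodes": [float(x) for x in self.nodes.nodes],
            "isrea_tolerance": float(self.isrea_tolerance),
            "isrea_max_iterations": int(self.isrea_max_iterations),
            "normalize": bool(self.normalize),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)
        return path


# ---------------------------------------------------------------------------
# stages


def average_replicates(sset):
    """Collapse replicate scans to one mean spectrum per sample.

    Requires a harmonized set.  The output keeps the manifest untouched and
    assigns replicate_index 0 to every averaged spectrum.
    """
    if sset.grid is None:
        raise SpectrumValidationError("average_replicates requires a harmonized set")
    out = []
    for sid in sset.sample_ids:
        reps = sorted(sset.spectra_for(sid), key=lambda s: s.replicate_index)
        if not reps:
            raise SpectrumValidationError(f"sample {sid!r} has zero replicates")
        mean = np.mean([s.intensities for s in reps], axis=0)
        out.append(RamanSpectrum(sid, 0, sset.grid.copy(), mean))
    return SpectrumSet(spectra=out, manifest=sset.manifest, grid=sset.grid.copy())


def truncate(spectrum, low=TRUNCATION_LOW, high=TRUNCATION_HIGH):
    """Keep grid points p with low <= p <= high (closed interval)."""
    if not low < high:
        raise ValueError("low must be < high")
    mask = (spectrum.wavenumbers >= low) & (spectrum.wavenumbers <= high)
    if not mask.any():
        raise GridRangeError(
            f"{spectrum.sample_id}: truncation to [{low}, {high}] leaves no points"
        )
    if mask.all():
        return spectrum
    return replace(
        spectrum,
        wavenumbers=spectrum.wavenumbers[mask],
        intensities=spectrum.intensities[mask],
    )


def _spline(x, y):
    # cubic where possible; two anchors degrade to a straight line
    if x.size >= 3:
        return CubicSpline(x, y, bc_type="not-a-knot")
    return lambda q: np.interp(q, x, y)


def isrea_baseline(spectrum, nodes, tolerance=1e-4, max_iterations=100):
    """Iterative spline-rubberband (ISREA-style) baseline correction.

    Anchors initialize at the spectrum's intensity at each node wavenumber
    (linear interpolation when a node sits between grid points).  Each
    iteration fits a cubic spline through the anchors, finds where the
    spline exceeds the signal, and lowers the anchors bounding each violating
    segment by that segment's worst overshoot.  Convergence means the
    baseline nowhere exceeds the signal by more than
    ``tolerance * max|intensity|``.

    Returns ``(corrected, baseline, iterations)``; corrected intensities may
    be negative (no clipping).
    """
    w = spectrum.wavenumbers
    y = spectrum.intensities
    node_x = np.asarray(nodes.nodes if isinstance(nodes, NodeSet) else nodes, dtype=float)
    if node_x[0] < w[0] or node_x[-1] > w[-1]:
        raise GridRangeError(
            f"nodes [{node_x[0]}, {node_x[-1]}] outside spectrum range "
            f"[{w[0]}, {w[-1]}]"
        )
    scale = float(np.max(np.abs(y)))
    if scale == 0.0:
        zeros = np.zeros_like(y)
        return (replace(spectrum, intensities=zeros),
                replace(spectrum, intensities=zeros), 0)
    tol_abs = tolerance * scale

    anchors = np.interp(node_x, w, y)
    # segment index of every grid point: 0 .. n_nodes-2
    seg = np.clip(np.searchsorted(node_x, w, side="right") - 1, 0, node_x.size - 2)

    baseline = None
    for iteration in range(1, max_iterations + 1):
        baseline = _spline(node_x, anchors)(w)
        excess = baseline - y
        worst = np.zeros(node_x.size - 1)
        np.maximum.at(worst, seg, excess)
        if np.all(worst <= tol_abs):
            corrected = y - baseline
            return (
                replace(spectrum, intensities=corrected),
                replace(spectrum, intensities=baseline),
                iteration,
            )
        drop = np.where(worst > tol_abs, worst, 0.0)
        # an interior anchor bounds two segments; lower it by the larger overshoot
        delta = np.zeros_like(anchors)
        delta[:-1] = drop
        delta[1:] = np.maximum(delta[1:], drop)
        anchors = anchors - delta

    raise ConvergenceError(
        f"ISREA did not converge in {max_iterations} iterations "
        f"(tolerance {tolerance:g} relative)",
        corrected=y - baseline,
        baseline=baseline,
        iterations=max_iterations,
    )


def vector_normalize(spectrum):
    """Scale intensities to unit Euclidean norm."""
    norm = float(np.linalg.norm(spectrum.intensities))
    if norm == 0.0:
        raise SpectrumValidationError(
            f"{spectrum.sample_id}: cannot normalize an all-zero spectrum"
        )
    return replace(spectrum, intensities=spectrum.intensities / norm)


def preprocess_pipeline(sset, config=None):
    """Run average -> truncate -> ISREA -> normalize over a harmonized set.

    Returns ``(matrix, labels, grid)`` with one row per sample, ordered by
    manifest order.
    """
    if config is None:
        config = PreprocessConfig()
    if sset.grid is None:
        raise SpectrumValidationError("preprocess_pipeline requires a harmonized set")
    averaged = average_replicates(sset)
    label_map = sset.manifest.labels()
    rows, labels = [], []
    grid = None
    for spec in averaged.spectra:
        t = truncate(spec, config.truncation_low, config.truncation_high)
        corrected, _, _ = isrea_baseline(
            t, config.nodes, config.isrea_tolerance, config.isrea_max_iterations
        )
        final = vector_normalize(corrected) if config.normalize else corrected
        if grid is None:
            grid = final.wavenumbers
        rows.append(final.intensities)
        labels.append(label_map[spec.sample_id])
    matrix = np.vstack(rows) if rows else np.empty((0, 0))
    return matrix, labels, grid
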