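"""One-vs-rest screening models and cohort screening.

A screen relabels a cohort into a "positive" union of disease classes and a
"negative" union of everything the screen is allowed to treat as disease-free,
optionally excluding samples whose class membership is ambiguous (the study's
dual-pathology DKD+IMN sample is the canonical case).  The screen model is a
two-class DAPC validated by leave-one-out; applied to an unlabeled cohort it
reports per-sample calls and the fraction screening positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .chemometrics import DAPCModel, fit_dapc_pipeline
from .errors import OrphanClassError
from .preprocess import NodeSet, PreprocessConfig
from .spectra import SampleManifest, SpectrumSet
from .validation import (
    ChanceBounds,
    ConfusionMatrix,
    MetricPanel,
    chance_bounds,
    loocv_predict,
    metrics_from_confusion,
)
from .preprocess import preprocess_pipeline

log = logging.getLogger("chemurin.screening")

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class ScreenDefinition:
    """A named binary screen over manifest class labels.

    ``positive_classes`` and ``negative_classes`` are disjoint, non-empty
    label sets; ``excluded_classes`` are dropped before evaluation (samples
    belonging to no listed class are likewise left out and counted as
    excluded).  A manifest lacking one of the positive/negative classes
    fails loudly at partition time; excluded classes may be absent.
    """

    name: str
    positive_classes: frozenset
    negative_classes: frozenset
    excluded_classes: frozenset = frozenset()
    node_preset: str = "fig1"

    def __post_init__(self):
        pos = frozenset(self.positive_classes)
        neg = frozenset(self.negative_classes)
        exc = frozenset(self.excluded_classes)
        object.__setattr__(self, "positive_classes", pos)
        object.__setattr__(self, "negative_classes", neg)
        object.__setattr__(self, "excluded_classes", exc)
        if not pos or not neg:
            raise ValueError(f"screen {self.name!r}: both label sets must be non-empty")
        overlap = pos & neg
        if overlap:
            raise ValueError(
                f"screen {self.name!r}: positive and negative sets overlap: {sorted(overlap)}"
            )


#: Screens mirroring the study's analyses, expressed over the atomic class
#: labels produced by :func:`chemurin.simulate.preset_cohort`.  The dual
#: DKD+IMN sample is excluded wherever it can be neither cleanly positive nor
#: negative.
SCREEN_PRESETS = {
    # two-class biopsy contrast: DKD vs IMN, dual sample omitted
    "dkd_vs_imn": ScreenDefinition(
        name="dkd_vs_imn",
        positive_classes=frozenset({"DKD/NO", "DKD/OV"}),
        negative_classes=frozenset({"IMN/DM+", "IMN/DM-"}),
        excluded_classes=frozenset({"DKD/IMN"}),
        node_preset="analysis1",
    ),
    # DKD among a mixed 150-sample population
    "dkd_screen": ScreenDefinition(
        name="dkd_screen",
        positive_classes=frozenset({"DKD/NO", "DKD/OV"}),
        negative_classes=frozenset(
            {"IMN/DM+", "IMN/DM-", "RN", "OT", "PATH", "DM-", "HEALTHY", "SURINE"}
        ),
        excluded_classes=frozenset({"DKD/IMN"}),
        node_preset="dkd",
    ),
    # non-diabetic IMN among DKD + un-biopsied diabetics (181 samples)
    "imn_dm_neg_screen": ScreenDefinition(
        name="imn_dm_neg_screen",
        positive_classes=frozenset({"IMN/DM-"}),
        negative_classes=frozenset({"DKD/NO", "DKD/OV", "DKD/OT", "DM+"}),
        excluded_classes=frozenset({"DKD/IMN"}),
        node_preset="imn",
    ),
    # diabetic IMN among healthy/controls/non-diabetic patients (134 samples)
    "imn_dm_pos_screen": ScreenDefinition(
        name="imn_dm_pos_screen",
        positive_classes=frozenset({"IMN/DM+", "DKD/IMN"}),
        negative_classes=frozenset({"HEALTHY", "SURINE", "PATH", "DM-", "RN", "OT"}),
        node_preset="imn",
    ),
    # pure DKD vs non-diabetic pathology controls (18 samples)
    "dkdno_vs_path": ScreenDefinition(
        name="dkdno_vs_path",
        positive_classes=frozenset({"DKD/NO"}),
        negative_classes=frozenset({"PATH"}),
        node_preset="analysis1",
    ),
    # pure DKD vs IMN (20 samples)
    "dkdno_vs_imn": ScreenDefinition(
        name="dkdno_vs_imn",
        positive_classes=frozenset({"DKD/NO"}),
        negative_classes=frozenset({"IMN/DM+", "IMN/DM-"}),
        node_preset="analysis1",
    ),
}


@dataclass
class ScreenReport:
    """Outcome of building or applying a screen."""

    name: str
    nodes: np.ndarray
    per_sample_calls: list  # (sample_id, POSITIVE/NEGATIVE)
    n_evaluated: int
    n_excluded: int
    confusion: ConfusionMatrix | None = None
    metrics: MetricPanel | None = None
    chance: ChanceBounds | None = None
    positives_fraction: float | None = None


@dataclass
class ScreenModel:
    """A trained screen: the two-class DAPC plus its preprocessing config."""

    definition: ScreenDefinition
    dapc: DAPCModel
    config: PreprocessConfig


def partition_manifest(manifest, defn):
    """Split sample ids into (positive, negative, excluded) per a definition.

    Samples in ``excluded_classes`` or in no referenced class are excluded.
    Raises :class:`OrphanClassError` when a referenced positive or negative
    class is absent from the manifest.
    """
    labels = manifest.labels()
    present = set(labels.values())
    missing = sorted((defn.positive_classes | defn.negative_classes) - present)
    if missing:
        raise OrphanClassError(
            f"screen {defn.name!r}: manifest lacks referenced class(es): {missing}"
        )
    pos = [s for s, c in labels.items() if c in defn.positive_classes]
    neg = [s for s, c in labels.items() if c in defn.negative_classes]
    exc = [s for s, c in labels.items()
           if c not in defn.positive_classes and c not in defn.negative_classes]
    return pos, neg, exc


def _binary_manifest(sset, pos, neg):
    keep = set(pos) | set(neg)
    calls = {s: POSITIVE for s in pos}
    calls.update({s: NEGATIVE for s in neg})
    entries = sset.manifest.entries
    entries = entries[entries["sample_id"].isin(keep)].copy()
    entries["class_label"] = entries["sample_id"].map(calls)
    sub = SpectrumSet(
        spectra=[s for s in sset.spectra if s.sample_id in keep],
        manifest=SampleManifest(entries),
        grid=sset.grid,
    )
    return sub


def build_screen(sset, defn, config=None, retention=0.99):
    """Train a binary screen and validate it by leave-one-out.

    Returns ``(ScreenModel, ScreenReport)``.  The model is fit on the whole
    evaluated subset; the report's confusion and metric panel come from the
    leave-one-out predictions.
    """
    if isinstance(defn, str):
        defn = SCREEN_PRESETS[defn]
    if config is None:
        config = PreprocessConfig(nodes=NodeSet.from_preset(defn.node_preset))
    pos, neg, exc = partition_manifest(sset.manifest, defn)
    if len(pos) < 2 or len(neg) < 2:
        raise OrphanClassError(
            f"screen {defn.name!r}: needs >= 2 samples per subclass "
            f"(got {len(pos)} positive, {len(neg)} negative)"
        )
    sub = _binary_manifest(sset, pos, neg)
    matrix, labels, grid = preprocess_pipeline(sub, config)
    n_eval = len(labels)
    log.info(
        "stage=build_screen screen=%s n_samples=%d n_excluded=%d",
        defn.name, n_eval, len(exc),
    )
    preds = loocv_predict(matrix, labels, retention=retention, grid=grid)
    sample_ids = sub.sample_ids
    cm = ConfusionMatrix.from_labels(labels, preds, POSITIVE)
    report = ScreenReport(
        name=defn.name,
        nodes=config.nodes.nodes.copy(),
        per_sample_calls=list(zip(sample_ids, preds)),
        n_evaluated=n_eval,
        n_excluded=len(exc),
        confusion=cm,
        metrics=metrics_from_confusion(cm),
        chance=chance_bounds(cm.n_positive, cm.n),
    )
    dapc = fit_dapc_pipeline(matrix, labels, retention=retention, grid=grid)
    return ScreenModel(definition=defn, dapc=dapc, config=config), report


def screen_cohort(model, unlabeled):
    """Apply a trained screen to an unlabeled cohort.

    Returns a :class:`ScreenReport` with per-sample calls and the fraction of
    the cohort calling positive; no truth, so no metric panel.
    """
    if len(unlabeled) == 0:
        raise ValueError("cannot screen an empty cohort")
    matrix, _, grid = preprocess_pipeline(unlabeled, model.config)
    if grid.size != model.dapc.pc_model.grid.size or not np.allclose(
        grid, model.dapc.pc_model.grid
    ):
        raise ValueError("cohort grid does not match the screen model's grid")
    preds, _ = model.dapc.predict_rows(matrix)
    sample_ids = unlabeled.sample_ids
    n_pos = sum(1 for p in preds if p == POSITIVE)
    log.info(
        "stage=screen_cohort screen=%s n_samples=%d n_positive=%d",
        model.definition.name, len(preds), n_pos,
    )
    return ScreenReport(
        name=model.definition.name,
        nodes=model.config.nodes.nodes.copy(),
        per_sample_calls=list(zip(sample_ids, preds)),
        n_evaluated=len(preds),
        n_excluded=0,
        positives_fraction=n_pos / len(preds),
    )
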