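"""Raman spectrum containers and plain-text I/O.

Spectra are exchanged as CSV in two dialects:

* ``long``  — columns ``sample_id, replicate, wavenumber, intensity``, one row
  per measured point.
* ``wide``  — first column ``wavenumber``, every further column one spectrum
  with header ``sample_id:replicate``.

A cohort additionally carries a manifest (columns ``sample_id, class_label,
diabetic_flag``) assigning each sample a class label.  Wavenumber units are
cm^-1 throughout and grids are treated as point samples, not bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    GridRangeError,
    ManifestError,
    SpectrumParseError,
    SpectrumValidationError,
)

DIABETIC_FLAGS = ("DM+", "DM-", "unknown")

#: Class vocabulary seeded from the study census; the vocabulary is open —
#: any other label is accepted by the manifest.
KNOWN_CLASS_LABELS = (
    "DKD", "IMN", "DM+", "DM-", "DKD/IMN", "DKD/OT", "DKD/NO", "DKD/OV",
    "IMN/DM+", "IMN/DM-", "MN", "RN", "OT", "PATH", "HEALTHY", "SURINE",
)


@dataclass(frozen=True)
class RamanSpectrum:
    """A single Raman scan: an ordered wavenumber grid with intensities.

    Parameters
    ----------
    sample_id : str
        Opaque sample identifier.
    replicate_index : int
        Non-negative replicate number within the sample.
    wavenumbers : ndarray
        Strictly increasing Raman shifts in cm^-1, length >= 2.
    intensities : ndarray
        Detector intensities (arbitrary units), same length, all finite.
    """

    sample_id: str
    replicate_index: int
    wavenumbers: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "intensities", y)
        if self.replicate_index < 0:
            raise SpectrumValidationError(
                f"{self.sample_id}: replicate_index must be non-negative"
            )
        if w.ndim != 1 or y.ndim != 1 or w.size != y.size:
            raise SpectrumValidationError(
                f"{self.sample_id}: wavenumbers and intensities must be "
                f"1-D vectors of equal length (got {w.shape} vs {y.shape})"
            )
        if w.size < 2:
            raise SpectrumValidationError(
                f"{self.sample_id}: spectrum needs at least 2 grid points"
            )
        if not np.all(np.isfinite(w)):
            raise SpectrumValidationError(f"{self.sample_id}: non-finite wavenumber")
        if np.any(np.diff(w) <= 0):
            raise SpectrumValidationError(
                f"{self.sample_id}: wavenumbers must be strictly increasing"
            )
        if not np.all(np.isfinite(y)):
            raise SpectrumValidationError(
                f"{self.sample_id}: NaN or infinite intensity"
            )

    def __len__(self):
        return self.wavenumbers.size


@dataclass(frozen=True)
class SampleManifest:
    """Sample-to-class assignment table.

    ``entries`` is a DataFrame with columns ``sample_id, class_label,
    diabetic_flag``; sample ids are unique.
    """

    entries: pd.DataFrame

    def __post_init__(self):
        df = pd.DataFrame(self.entries).copy()
        required = ["sample_id", "class_label"]
        for col in required:
            if col not in df.columns:
                raise ManifestError(f"manifest missing required column {col!r}")
        if "diabetic_flag" not in df.columns:
            df["diabetic_flag"] = "unknown"
        df["sample_id"] = df["sample_id"].astype(str)
        df["class_label"] = df["class_label"].astype(str)
        df["diabetic_flag"] = df["diabetic_flag"].astype(str)
        bad_flag = ~df["diabetic_flag"].isin(DIABETIC_FLAGS)
        if bad_flag.any():
            raise ManifestError(
                "diabetic_flag must be one of "
                f"{DIABETIC_FLAGS}; got {sorted(df.loc[bad_flag, 'diabetic_flag'].unique())}"
            )
        dup = df["sample_id"].duplicated()
        if dup.any():
            raise ManifestError(
                f"duplicate sample_id in manifest: {sorted(df.loc[dup, 'sample_id'].unique())}"
            )
        df = df.reset_index(drop=True)
        object.__setattr__(self, "entries", df)

    @classmethod
    def from_records(cls, records):
        """Build from an iterable of (sample_id, class_label[, diabetic_flag])."""
        rows = []
        for rec in records:
            rec = tuple(rec)
            if len(rec) == 2:
                rec = rec + ("unknown",)
            rows.append(rec)
        return cls(pd.DataFrame(rows, columns=["sample_id", "class_label", "diabetic_flag"]))

    @property
    def sample_ids(self):
        return list(self.entries["sample_id"])

    def label_of(self, sample_id):
        hit = self.entries.loc[self.entries["sample_id"] == sample_id, "class_label"]
        if hit.empty:
            raise ManifestError(f"sample {sample_id!r} not present in manifest")
        return hit.iloc[0]

    def labels(self):
        """Mapping sample_id -> class_label."""
        return dict(zip(self.entries["sample_id"], self.entries["class_label"]))

    def __len__(self):
        return len(self.entries)


@dataclass
class SpectrumSet:
    """A cohort of spectra plus its manifest.

    ``grid`` is None until :func:`harmonize_grid` establishes a shared
    wavenumber vector; afterwards every member spectrum lies on it.
    """

    spectra: list
    manifest: SampleManifest
    grid: np.ndarray | None = field(default=None)

    def __post_init__(self):
        labels = set(self.manifest.entries["sample_id"])
        missing = sorted({s.sample_id for s in self.spectra} - labels)
        if missing:
            raise ManifestError(
                f"spectra reference sample_ids absent from manifest: {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
        if self.grid is not None:
            self.grid = np.asarray(self.grid, dtype=float)
            for s in self.spectra:
                if s.wavenumbers.size != self.grid.size or not np.array_equal(
                    s.wavenumbers, self.grid
                ):
                    raise SpectrumValidationError(
                        f"{s.sample_id}: spectrum grid differs from the set grid"
                    )

    @property
    def sample_ids(self):
        """Unique sample ids, in manifest order, restricted to samples with spectra."""
        present = {s.sample_id for s in self.spectra}
        return [sid for sid in self.manifest.sample_ids if sid in present]

    def spectra_for(self, sample_id):
        return [s for s in self.spectra if s.sample_id == sample_id]

    def subset(self, sample_ids):
        """Restrict to the given samples (manifest rows and spectra)."""
        keep = set(sample_ids)
        entries = self.manifest.entries[self.manifest.entries["sample_id"].isin(keep)]
        return SpectrumSet(
            spectra=[s for s in self.spectra if s.sample_id in keep],
            manifest=SampleManifest(entries),
            grid=self.grid,
        )

    def __len__(self):
        return len(self.spectra)


# ---------------------------------------------------------------------------
# reading


def _read_csv(path):
    try:
        return pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise SpectrumParseError(f"{path}: {exc}") from exc


def _to_float(series, path, colname):
    out = pd.to_numeric(series, errors="coerce")
    bad = out.isna() & (series.astype(str).str.strip() != "")
    empty = series.astype(str).str.strip() == ""
    bad = bad | empty
    if bad.any():
        line = int(bad.idxmax()) + 2  # header + 1-based
        raise SpectrumParseError(
            f"{path}: malformed value in column {colname!r} at line {line}"
        )
    return out.astype(float).to_numpy()


def read_manifest(path):
    """Read a manifest CSV (sample_id, class_label[, diabetic_flag])."""
    df = _read_csv(path)
    return SampleManifest(df)


def write_manifest(manifest, path):
    manifest.entries.to_csv(path, index=False)
    return path


def _default_manifest(sample_ids):
    return SampleManifest.from_records((sid, "UNLABELED") for sid in sample_ids)


def read_spectra(path, layout="long", manifest=None):
    """Read spectra from CSV and assemble a :class:`SpectrumSet`.

    Parameters
    ----------
    path : path-like
        Spectra CSV in the requested layout.
    layout : {"long", "wide"}
    manifest : SampleManifest, path-like or None
        Class assignments.  A path is read with :func:`read_manifest`; None
        synthesizes an UNLABELED manifest (the join with a real manifest is
        validated strictly when one is supplied).
    """
    if layout not in ("long", "wide"):
        raise ValueError(f"unknown layout {layout!r}")
    df = _read_csv(path)
    spectra = []
    if layout == "long":
        required = ["sample_id", "replicate", "wavenumber", "intensity"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SpectrumParseError(f"{path}: long layout missing columns {missing}")
        wn = _to_float(df["wavenumber"], path, "wavenumber")
        it = _to_float(df["intensity"], path, "intensity")
        rep = _to_float(df["replicate"], path, "replicate").astype(int)
        work = pd.DataFrame(
            {"sample_id": df["sample_id"].astype(str), "replicate": rep,
             "wavenumber": wn, "intensity": it}
        )
        # preserve file order within each spectrum: validation catches
        # non-increasing grids rather than silently sorting them away
        for (sid, r), grp in work.groupby(["sample_id", "replicate"], sort=True):
            spectra.append(
                RamanSpectrum(sid, int(r), grp["wavenumber"].to_numpy(),
                              grp["intensity"].to_numpy())
            )
    else:
        if df.shape[1] < 1:
            raise SpectrumParseError(f"{path}: wide layout needs a wavenumber column")
        first = df.columns[0]
        wn = _to_float(df[first], path, first)
        for col in df.columns[1:]:
            sid, _, rep = col.rpartition(":")
            if not sid:
                raise SpectrumParseError(
                    f"{path}: wide header {col!r} is not 'sample_id:replicate'"
                )
            try:
                rep = int(rep)
            except ValueError:
                raise SpectrumParseError(
                    f"{path}: wide header {col!r} has non-integer replicate"
                ) from None
            spectra.append(RamanSpectrum(sid, rep, wn, _to_float(df[col], path, col)))

    if manifest is None:
        manifest = _default_manifest(
            dict.fromkeys(s.sample_id for s in spectra)  # ordered unique
        )
    elif not isinstance(manifest, SampleManifest):
        manifest = read_manifest(manifest)

    sset = SpectrumSet(spectra=spectra, manifest=manifest)
    grids = {s.wavenumbers.tobytes() for s in spectra}
    if len(grids) == 1 and spectra:
        sset.grid = spectra[0].wavenumbers.copy()
    return sset


# ---------------------------------------------------------------------------
# grid harmonization


def harmonize_grid(sset, target="intersection"):
    """Put every spectrum of a set onto one shared wavenumber grid.

    ``target`` is an explicit wavenumber vector, or ``"intersection"`` for the
    grid points common to all member spectra.  Resampling is linear and never
    extrapolates: a target point outside any spectrum's native coverage raises
    :class:`GridRangeError`.  Spectra already on the target grid are returned
    bitwise-unchanged, which makes the operation idempotent.
    """
    if not sset.spectra:
        return SpectrumSet(spectra=[], manifest=sset.manifest, grid=None)
    if isinstance(target, str):
        if target != "intersection":
            raise ValueError(f"unknown target {target!r}")
        grid = sset.spectra[0].wavenumbers
        for s in sset.spectra[1:]:
            grid = np.intersect1d(grid, s.wavenumbers)
        if grid.size < 2:
            raise GridRangeError(
                "spectra share fewer than 2 common grid points; "
                "pass an explicit target grid instead"
            )
    else:
        grid = np.asarray(target, dtype=float)
        if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
            raise ValueError("target grid must be a strictly increasing vector")

    out = []
    for s in sset.spectra:
        if grid[0] < s.wavenumbers[0] or grid[-1] > s.wavenumbers[-1]:
            raise GridRangeError(
                f"{s.sample_id}: target grid [{grid[0]}, {grid[-1]}] exceeds native "
                f"coverage [{s.wavenumbers[0]}, {s.wavenumbers[-1]}]; extrapolation "
                "is not performed"
            )
        if s.wavenumbers.size == grid.size and np.array_equal(s.wavenumbers, grid):
            out.append(s)
        else:
            out.append(
                replace(s, wavenumbers=grid.copy(),
                        intensities=np.interp(grid, s.wavenumbers, s.intensities))
            )
    return SpectrumSet(spectra=out, manifest=sset.manifest, grid=grid.copy())


# ---------------------------------------------------------------------------
# writing


def write_spectra(sset, path, layout="long"):
    """Write a harmonized set to CSV; inverse of :func:`read_spectra`.

    Floats are written with ``repr`` round-trip precision, so
    read(write(S)) reproduces intensities to well below 1e-9.
    """
    if layout not in ("long", "wide"):
        raise ValueError(f"unknown layout {layout!r}")
    if layout == "wide" and sset.spectra:
        if sset.grid is None:
            raise SpectrumValidationError("wide layout requires a harmonized set")
    if layout == "long":
        frames = [
            pd.DataFrame(
                {"sample_id": s.sample_id, "replicate": s.replicate_index,
                 "wavenumber": s.wavenumbers, "intensity": s.intensities}
            )
            for s in sset.spectra
        ]
        if frames:
            df = pd.concat(frames, ignore_index=True)
        else:
            df = pd.DataFrame(columns=["sample_id", "replicate", "wavenumber", "intensity"])
    else:
        data = {"wavenumber": sset.grid if sset.spectra else []}
        for s in sset.spectra:
            data[f"{s.sample_id}:{s.replicate_index}"] = s.intensities
        df = pd.DataFrame(data)
    df.to_csv(path, index=False)
    return path
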