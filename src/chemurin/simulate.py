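"""Synthetic urine-Raman cohort generator.

Synthetic spectra carry the statistical structure the analysis pipeline
assumes — multi-peak Gaussian band profiles whose amplitudes differ by class,
a smooth fluorescence-like background (cubic drift plus a broad hump) with
per-sample jitter, and i.i.d. Gaussian replicate noise — without pretending
to be physically realistic urine Raman.  They exist so every pipeline stage
is testable end to end with known ground truth.

Class signatures place the disease effects on the bands the analysis
attributes them to (glucose, urea, protein/amide III, nucleic acids);
``effect_size`` scales every class multiplier's deviation from 1, so
``effect_size=0`` produces exchangeable classes and ``effect_size=1`` the
default ~2x amplitude shifts at the glucose and urea bands against a 10%
within-class amplitude CV.

All randomness flows from a single seed through per-sample and per-replicate
``numpy.random.SeedSequence`` substreams, so cohorts are reproducible
piecewise and bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import RamanSpectrum, SampleManifest, SpectrumSet

DEFAULT_GRID = np.arange(400.0, 1800.0 + 1e-9, 2.0)  # ~700 points, 2 cm^-1 spacing

#: per-class amplitude multipliers by band group, at effect_size = 1
CLASS_SIGNATURES = {
    "DKD": {"glucose": 2.0, "urea": 1.6, "protein": 0.75},
    "IMN": {"protein": 1.6, "nucleic": 1.35, "glucose": 0.9},
    "MN": {"protein": 1.8, "urea": 0.85},
    "RN": {"nucleic": 1.9, "urea": 0.8, "protein": 1.2},
    "OT": {"protein": 1.25, "nucleic": 1.15},
    "DM+": {"glucose": 1.7, "urea": 1.2},
    "DM-": {},
    "PATH": {"protein": 1.4, "nucleic": 1.2, "urea": 0.9},
    "HEALTHY": {"glucose": 0.7, "urea": 0.9},
    "SURINE": {},
}
# subdivided classes share their parent disease signature; the dual
# DKD+IMN patient blends both
_ALIASES = {
    "DKD/NO": "DKD",
    "DKD/OV": "DKD",
    "DKD/OT": "DKD",
    "IMN/DM+": "IMN",
    "IMN/DM-": "IMN",
}


def _signature(label):
    if label in CLASS_SIGNATURES:
        return CLASS_SIGNATURES[label]
    if label in _ALIASES:
        return CLASS_SIGNATURES[_ALIASES[label]]
    if label == "DKD/IMN":
        a, b = CLASS_SIGNATURES["DKD"], CLASS_SIGNATURES["IMN"]
        keys = set(a) | set(b)
        return {k: (a.get(k, 1.0) + b.get(k, 1.0)) / 2.0 for k in keys}
    return {}


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian Raman band with class-dependent amplitude."""

    center: float
    width: float  # Gaussian sigma, cm^-1
    base_amplitude: float
    group: str = "other"
    class_multipliers: dict = field(default_factory=dict)
    amplitude_cv: float = 0.10

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.base_amplitude < 0 or self.amplitude_cv < 0:
            raise ValueError("base_amplitude and amplitude_cv must be >= 0")

    def multiplier(self, label, effect_size):
        m = self.class_multipliers.get(label)
        if m is None:
            m = _signature(label).get(self.group, 1.0)
        return 1.0 + effect_size * (m - 1.0)


def default_bands():
    """The annotated band set: urea, glucose, protein/amide III, nucleic
    acids, phosphatidylinositol, plus neutral filler bands."""
    spec = [
        (776, 7, 6, "phosphatidylinositol"),
        (826, 7, 6, "nucleic"),
        (890, 7, 8, "protein"),
        (898, 7, 10, "glucose"),
        (931, 7, 10, "glucose"),
        (1002, 6, 30, "urea"),
        (1007, 7, 10, "protein"),
        (1055, 7, 7, "nucleic"),
        (1060, 7, 9, "glucose"),
        (1078, 7, 7, "nucleic"),
        (1105, 7, 8, "glucose"),
        (1237, 8, 9, "protein"),
        (1242, 8, 9, "protein"),
        (1318, 8, 8, "protein"),
        # neutral bands common to all classes
        (640, 9, 5, "other"),
        (1450, 9, 12, "other"),
        (1660, 10, 14, "other"),
    ]
    return tuple(BandSpec(c, w, a, g) for c, w, a, g in spec)


@dataclass(frozen=True)
class BaselineSpec:
    """Smooth background: cubic drift plus a broad fluorescence hump.

    The polynomial is evaluated on the unit-rescaled wavenumber axis;
    ``jitter_cv`` is the per-sample coefficient-of-variation applied to each
    coefficient independently.
    """

    poly_coefficients: tuple = (50.0, 25.0, -15.0, 6.0)
    hump_height: float = 40.0
    hump_center: float = 1200.0
    hump_width: float = 350.0
    jitter_cv: float = 0.15


@dataclass(frozen=True)
class SimConfig:
    """Full description of one synthetic cohort."""

    class_sizes: dict
    grid: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.copy())
    bands: tuple = field(default_factory=default_bands)
    effect_size: float = 1.0
    baseline: BaselineSpec = field(default_factory=BaselineSpec)
    replicate_noise_sd: float = 0.5
    replicates_per_sample: int = 10
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=float))
        if not self.class_sizes:
            raise ValueError("class_sizes must be non-empty")
        if any(v < 1 for v in self.class_sizes.values()):
            raise ValueError("class sizes must be >= 1")
        if len(self.bands) == 0:
            raise ValueError("band list must be non-empty")
        if self.replicates_per_sample < 1:
            raise ValueError("replicates_per_sample must be >= 1")

    def with_(self, **kwargs):
        from dataclasses import replace

        return replace(self, **kwargs)


_DM_POS = {"DM+", "IMN/DM+", "DKD/NO", "DKD/OV", "DKD/OT", "DKD/IMN", "DKD"}
_DM_NEG = {"DM-", "IMN/DM-", "PATH", "IMN"}


def _diabetic_flag(label):
    if label in _DM_POS:
        return "DM+"
    if label in _DM_NEG:
        return "DM-"
    return "unknown"


def _variance_scale(label):
    # the urinalysis control is deliberately the quietest class
    return 0.25 if label == "SURINE" else 1.0


def simulate_cohort(config):
    """Generate a labeled cohort; returns ``(SpectrumSet, truth)``.

    Per sample the noiseless signal is the sum of Gaussian bands with
    class- and sample-dependent amplitudes plus the jittered baseline; each
    replicate adds i.i.d. Gaussian noise of sd ``replicate_noise_sd``.
    ``truth`` is a DataFrame of the generating parameters (band amplitudes
    and baseline coefficients per sample).
    """
    grid = config.grid
    root = np.random.SeedSequence(config.seed)
    n_samples = sum(config.class_sizes.values())
    sample_seeds = root.spawn(n_samples)

    profiles = np.stack(
        [np.exp(-0.5 * ((grid - b.center) / b.width) ** 2) for b in config.bands]
    )

    spectra, manifest_rows, truth_rows = [], [], []
    k = 0
    for label, size in config.class_sizes.items():
        vscale = _variance_scale(label)
        for i in range(size):
            sid = f"{label}_{i:03d}"
            ss = sample_seeds[k]
            k += 1
            streams = ss.spawn(1 + config.replicates_per_sample)
            rng = np.random.default_rng(streams[0])

            # one concentration draw per molecular group: a metabolite's
            # concentration scales all of its bands together
            draws = {}
            for band in config.bands:
                if band.group in draws:
                    continue
                cv = band.amplitude_cv * vscale
                if cv > 0:
                    sig = np.sqrt(np.log1p(cv**2))
                    draws[band.group] = np.exp(rng.normal(0.0, sig) - sig**2 / 2.0)
                else:
                    draws[band.group] = 1.0
            amps = np.array([
                band.base_amplitude
                * band.multiplier(label, config.effect_size)
                * draws[band.group]
                for band in config.bands
            ])

            bl = config.baseline
            jit = bl.jitter_cv * vscale
            coeffs = np.array(bl.poly_coefficients, dtype=float)
            coeffs = coeffs * (1.0 + rng.normal(0.0, jit, size=coeffs.size))
            hump = bl.hump_height * (1.0 + rng.normal(0.0, jit))
            u = (grid - grid[0]) / (grid[-1] - grid[0])
            background = np.polyval(coeffs[::-1], u) + hump * np.exp(
                -0.5 * ((grid - bl.hump_center) / bl.hump_width) ** 2
            )

            signal = amps @ profiles + background
            for r in range(config.replicates_per_sample):
                noise_rng = np.random.default_rng(streams[1 + r])
                noisy = signal + noise_rng.normal(
                    0.0, config.replicate_noise_sd, size=grid.size
                )
                spectra.append(RamanSpectrum(sid, r, grid.copy(), noisy))

            manifest_rows.append((sid, label, _diabetic_flag(label)))
            truth = {"sample_id": sid, "class_label": label}
            for band, amp in zip(config.bands, amps):
                truth[f"amp_{band.center:g}"] = amp
            for ci, cval in enumerate(coeffs):
                truth[f"baseline_c{ci}"] = cval
            truth["baseline_hump"] = hump
            truth_rows.append(truth)

    manifest = SampleManifest.from_records(manifest_rows)
    sset = SpectrumSet(spectra=spectra, manifest=manifest, grid=grid.copy())
    return sset, pd.DataFrame(truth_rows)


def control_spectra(config, n):
    """A SURINE-like control class: same generator, quarter variability."""
    if n < 2:
        raise ValueError("need at least 2 control spectra")
    sub = config.with_(class_sizes={"SURINE": int(n)})
    sset, _ = simulate_cohort(sub)
    return sset


#: study-census class sizes used by the ``table1`` preset (disjoint atomic
#: labels; groups such as "all DKD" or "all IMN" are unions over these)
TABLE1_CLASS_SIZES = {
    "DKD/NO": 9,
    "DKD/OV": 2,
    "DKD/IMN": 1,
    "DKD/OT": 3,
    "IMN/DM+": 5,
    "IMN/DM-": 6,
    "MN": 6,
    "RN": 3,
    "OT": 4,
    "PATH": 9,
    "DM+": 161,
    "DM-": 65,
    "HEALTHY": 25,
    "SURINE": 22,
}

_PRESETS = {
    # 11 DKD vs 11 IMN, ten replicate scans each
    "analysis1": {"DKD/NO": 9, "DKD/OV": 2, "IMN/DM+": 5, "IMN/DM-": 6},
    # 150-sample screening population with 11 DKD positives
    "analysis4": {
        "DKD/NO": 9, "DKD/OV": 2, "IMN/DM+": 5, "IMN/DM-": 6,
        "RN": 3, "OT": 4, "PATH": 9, "DM-": 65, "HEALTHY": 25, "SURINE": 22,
    },
    "table1": TABLE1_CLASS_SIZES,
}


def preset_cohort(name, seed=0, effect_size=1.0, replicates_per_sample=10):
    """A :class:`SimConfig` mirroring one of the study's cohort layouts."""
    try:
        sizes = dict(_PRESETS[name])
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available presets: {sorted(_PRESETS)}"
        ) from None
    return SimConfig(
        class_sizes=sizes,
        seed=seed,
        effect_size=effect_size,
        replicates_per_sample=replicates_per_sample,
    )


def effect_band_centers(config, label_a, label_b, min_ratio=1.05):
    """Band centers whose class multipliers differ between two labels."""
    out = []
    for band in config.bands:
        ma = band.multiplier(label_a, config.effect_size)
        mb = band.multiplier(label_b, config.effect_size)
        if max(ma, mb) / max(min(ma, mb), 1e-12) >= min_ratio:
            out.append(band.center)
    return out
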