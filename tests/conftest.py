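import numpy as np
import pytest

from chemurin import (
    RamanSpectrum,
    SampleManifest,
    SpectrumSet,
    preset_cohort,
    simulate_cohort,
)


def make_set(intensities_by_key, wavenumbers, labels=None):
    """Build a harmonized SpectrumSet from {(sample_id, replicate): vector}."""
    w = np.asarray(wavenumbers, dtype=float)
    spectra = [
        RamanSpectrum(sid, rep, w.copy(), np.asarray(y, dtype=float))
        for (sid, rep), y in intensities_by_key.items()
    ]
    sids = list(dict.fromkeys(sid for sid, _ in intensities_by_key))
    if labels is None:
        labels = {sid: "UNLABELED" for sid in sids}
    manifest = SampleManifest.from_records((sid, labels[sid]) for sid in sids)
    return SpectrumSet(spectra=spectra, manifest=manifest, grid=w.copy())


@pytest.fixture(scope="session")
def grid400():
    """Working-window grid at 2 cm^-1 spacing (701 points)."""
    return np.arange(400.0, 1800.0 + 1e-9, 2.0)


@pytest.fixture(scope="session")
def analysis1_cohort():
    """One simulated 11-vs-11 cohort with the default effect, reused
    wherever a realistic small cohort is needed."""
    cfg = preset_cohort("analysis1", seed=11, effect_size=1.0)
    sset, truth = simulate_cohort(cfg)
    return cfg, sset, truth
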