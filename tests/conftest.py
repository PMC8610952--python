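import numpy as np
import pytest

from akiwatch.preprocess import HourlySeries
from akiwatch.synthetic import CohortConfig, generate_cohort


def make_series(uo, scr=None, patient_id="P0", ibw=70.0):
    """HourlySeries straight from arrays (creatinine defaults to a flat 1.0)."""
    uo = np.asarray(uo, dtype=float)
    scr = np.full(len(uo), 1.0) if scr is None else np.asarray(scr, dtype=float)
    return HourlySeries(
        patient_id=patient_id,
        uo_ml=uo * ibw,
        uo_mlkg_h=uo,
        scr_mg_dl=scr,
        uo_imputed=np.zeros(len(uo), dtype=bool),
        scr_imputed=np.zeros(len(uo), dtype=bool),
        ibw_kg=ibw,
    )


def noise_free_config(**overrides) -> CohortConfig:
    """Hourly charting, no stochastic noise: the label-recovery regime."""
    base = dict(noise_sd=0.0, uo_gap_max_hours=1, uo_gap_geometric_p=1.0)
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def small_noise_free_cases():
    """60 noise-free all-case stays with known injected stage and onset."""
    return generate_cohort(noise_free_config(n_patients=60, prevalence=1.0, seed=42))


@pytest.fixture(scope="session")
def small_controls():
    """200 control stays (prevalence zero) at default noise settings."""
    return generate_cohort(CohortConfig(n_patients=200, prevalence=0.0, seed=43))
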