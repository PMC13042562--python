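import numpy as np
import pytest

from pathomil import CohortSpec, gen_beer_lambert_tile, gen_cohort

# canonical H&E optical-density stain vectors (rows), unit-normalized
HE_STAINS = np.array([[0.65, 0.70, 0.29], [0.07, 0.99, 0.11]])
HE_STAINS = HE_STAINS / np.linalg.norm(HE_STAINS, axis=1, keepdims=True)

ALT_STAINS = np.array([[0.55, 0.75, 0.37], [0.17, 0.92, 0.35]])
ALT_STAINS = ALT_STAINS / np.linalg.norm(ALT_STAINS, axis=1, keepdims=True)


def phantom_concentrations(seed: int = 0, size: int = 128) -> np.ndarray:
    """Two-stain concentration fields with many near-pure-stain pixels,
    so the angular extremes of the optical-density cloud reach the true
    stain directions."""
    rng = np.random.default_rng(seed)
    z = rng.beta(0.4, 0.4, (size, size))  # U-shaped mixing fraction
    total = rng.uniform(0.3, 1.5, (size, size))
    return np.stack([total * z, total * (1.0 - z)])


def angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    return float(np.degrees(np.arccos(np.clip(u @ v, -1.0, 1.0))))


def outcome_arrays(bags, endpoint: str = "os"):
    t = np.array([getattr(b, endpoint).time for b in bags])
    e = np.array([getattr(b, endpoint).event for b in bags])
    return t, e


@pytest.fixture(scope="session")
def he_phantom():
    """A Beer-Lambert phantom tile with known H&E stain vectors."""
    conc = phantom_concentrations(seed=0)
    return gen_beer_lambert_tile(HE_STAINS, conc), conc


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-patient cohort with a real risk effect, reused across tests."""
    return gen_cohort(
        CohortSpec(
            n_patients=60,
            patches_per_patient=(20, 40),
            risk_effect_theta=1.0,
            prob_shift_kappa=1.5,
            censor_rate=0.3,
            seed=7,
        )
    )
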