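"""Synthetic tiles, stain phantoms and survival cohorts with known structure.

Everything downstream of this module (stain normalization, patch scoring,
multi-instance aggregation, signature fitting, survival evaluation) is tested
against data generated here, where the ground truth — stain vectors, latent
risk, hazard effects — is known by construction.

All generators are deterministic given their spec (which embeds a seed) and
use a private :class:`numpy.random.Generator`; no global RNG state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TileFixtureSpec",
    "CohortSpec",
    "SyntheticCohort",
    "PatchPrediction",
    "SurvivalOutcome",
    "PatientBag",
    "gen_tiles",
    "gen_beer_lambert_tile",
    "gen_cohort",
    "split_ids",
    "cohort_to_frames",
]

# Weibull shape for event times; scale set so the median at zero linear
# predictor is ~24 months (OS) / ~16 months (RFS), on the month time scale.
WEIBULL_SHAPE = 1.2
OS_MEDIAN_MONTHS = 24.0
RFS_MEDIAN_MONTHS = 16.0
# Patch probabilities scatter around their logistic mean with a Beta of
# fixed concentration; larger values mean less within-patient heterogeneity.
BETA_CONCENTRATION = 8.0
# Administrative censoring window, months.
CENSOR_WINDOW = (6.0, 60.0)


# ---------------------------------------------------------------------------
# core record types shared across the pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatchPrediction:
    """One tile's two-decimal probability and binary label."""

    patient_id: str
    slide_id: str
    prob: float
    pred: int

    def __post_init__(self) -> None:
        q = round(self.prob * 100)
        if not (0 <= q <= 100 and abs(self.prob * 100 - q) < 1e-6):
            raise ValueError(f"prob must be a two-decimal value in [0, 1], got {self.prob}")
        if self.pred != int(self.prob > 0.5):
            raise ValueError("pred must equal [prob > 0.5]")


@dataclass(frozen=True)
class SurvivalOutcome:
    """(time in months, event flag); event=1 means death (OS) or recurrence/death (RFS)."""

    time: float
    event: int

    def __post_init__(self) -> None:
        if not (np.isfinite(self.time) and self.time > 0):
            raise ValueError(f"survival time must be finite and positive, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event flag must be 0 or 1, got {self.event}")


@dataclass
class PatientBag:
    """All patch predictions of one patient plus outcomes and covariates."""

    patient_id: str
    predictions: list[PatchPrediction]
    os: SurvivalOutcome
    rfs: SurvivalOutcome
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.predictions:
            raise ValueError("a patient bag needs at least one patch prediction")
        if any(p.patient_id != self.patient_id for p in self.predictions):
            raise ValueError("all predictions in a bag must share the bag's patient_id")

    @property
    def probs(self) -> np.ndarray:
        return np.array([p.prob for p in self.predictions])

    @property
    def preds(self) -> np.ndarray:
        return np.array([p.pred for p in self.predictions])


# ---------------------------------------------------------------------------
# tile fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TileFixtureSpec:
    """Two-class tile images differing in dark-blob (pseudo-nucleus) density."""

    n_tiles: int
    tile_size: int = 512
    class_fraction: float = 0.5
    blob_density_by_class: tuple[float, float] = (5.0, 40.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tiles <= 0 or self.tile_size <= 0:
            raise ValueError("n_tiles and tile_size must be positive")
        if not 0.0 <= self.class_fraction <= 1.0:
            raise ValueError("class_fraction must lie in [0, 1]")
        if min(self.blob_density_by_class) < 0:
            raise ValueError("blob densities must be nonnegative")


def gen_tiles(spec: TileFixtureSpec) -> tuple[list[np.ndarray], np.ndarray]:
    """Generate labeled RGB tiles on a pink (eosin-like) background.

    Class-1 tiles carry a higher expected count of dark blue-purple blobs,
    mimicking nucleus-dense tumour tissue versus sparse stroma.

    Returns
    -------
    tiles : list of uint8 arrays of shape (tile_size, tile_size, 3)
    labels : int array of 0/1 class labels
    """
    rng = np.random.default_rng(spec.seed)
    n1 = int(round(spec.n_tiles * spec.class_fraction))
    labels = np.zeros(spec.n_tiles, dtype=int)
    labels[:n1] = 1
    rng.shuffle(labels)

    ts = spec.tile_size
    yy, xx = np.mgrid[0:ts, 0:ts]
    blob_radius = max(2.0, ts / 32.0)
    background = np.array([235.0, 200.0, 220.0])  # pale pink
    blob_color = np.array([70.0, 50.0, 120.0])    # hematoxylin-dark purple

    tiles: list[np.ndarray] = []
    for lab in labels:
        img = background + rng.normal(0.0, 4.0, size=(ts, ts, 3))
        n_blobs = rng.poisson(spec.blob_density_by_class[lab])
        for _ in range(n_blobs):
            cy, cx = rng.uniform(0, ts, size=2)
            r = blob_radius * rng.uniform(0.6, 1.4)
            mask = (yy - cy) ** 2 + (xx - cx) ** 2 < r**2
            img[mask] = blob_color + rng.normal(0.0, 6.0, size=3)
        tiles.append(np.clip(img, 0, 255).astype(np.uint8))
    return tiles, labels


def gen_beer_lambert_tile(
    stain_vectors: np.ndarray, concentration_fields: np.ndarray
) -> np.ndarray:
    """Render an RGB tile from two stains under the Beer–Lambert law.

    ``pixel = 255 * exp(-(c1*s1 + c2*s2))`` per channel, rounded to 8 bit.
    Serves as a phantom with known ground-truth stain vectors for testing
    stain-normalization fitting.

    Parameters
    ----------
    stain_vectors : (2, 3) array of nonnegative unit optical-density vectors.
    concentration_fields : (2, H, W) array of nonnegative concentrations.
    """
    s = np.asarray(stain_vectors, dtype=float)
    c = np.asarray(concentration_fields, dtype=float)
    if s.shape != (2, 3):
        raise ValueError("stain_vectors must have shape (2, 3)")
    if c.ndim != 3 or c.shape[0] != 2:
        raise ValueError("concentration_fields must have shape (2, H, W)")
    if np.any(s < 0) or np.any(c < 0):
        raise ValueError("stain vectors and concentrations must be nonnegative")
    norms = np.linalg.norm(s, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("stain vectors must be unit-norm")
    if abs(float(s[0] @ s[1])) > 1.0 - 1e-6:
        raise ValueError("stain vectors must not be parallel")
    od = c[0, :, :, None] * s[0] + c[1, :, :, None] * s[1]
    return np.clip(np.rint(255.0 * np.exp(-od)), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# survival cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Generating parameters of a synthetic patient cohort.

    A scalar latent risk ``r ~ N(0, 1)`` per patient drives both the patch
    probability distribution (logit shift ``prob_shift_kappa * r``) and the
    Weibull event hazard (log-hazard ``risk_effect_theta * r``), plus
    correlated covariates: high CA19-9 sampled with log-odds
    ``ca199_assoc * r``, adjuvant chemotherapy whose log-HR differs between
    the latent-risk halves, and a per-center log-hazard frailty.
    """

    n_patients: int
    patches_per_patient: int | tuple[int, int] = 50
    risk_effect_theta: float = 1.0
    prob_shift_kappa: float = 1.5
    censor_rate: float = 0.3
    chemo_benefit_high: float = 0.0
    chemo_benefit_low: float = 0.0
    ca199_assoc: float = 0.0
    ca199_effect_high: float = 0.0
    ca199_effect_low: float = 0.0
    n_centers: int = 1
    center_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be at least 2")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must lie in [0, 1)")
        lo, hi = self._patch_range()
        if lo <= 0 or hi < lo:
            raise ValueError("patches_per_patient must be a positive count or range")
        if self.n_centers <= 0:
            raise ValueError("n_centers must be positive")
        if self.center_sd < 0:
            raise ValueError("center_sd must be nonnegative")

    def _patch_range(self) -> tuple[int, int]:
        if isinstance(self.patches_per_patient, tuple):
            return self.patches_per_patient
        return (self.patches_per_patient, self.patches_per_patient)


@dataclass
class SyntheticCohort:
    bags: list[PatientBag]
    latent_risk: np.ndarray
    truth: CohortSpec


def _weibull_times(rng: np.random.Generator, log_hazard: np.ndarray, median0: float) -> np.ndarray:
    """Proportional-hazards Weibull times; median `median0` at zero log-hazard."""
    scale0 = median0 / math.log(2.0) ** (1.0 / WEIBULL_SHAPE)
    e = rng.exponential(size=log_hazard.shape)
    return scale0 * (e / np.exp(log_hazard)) ** (1.0 / WEIBULL_SHAPE)


def gen_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Simulate a cohort of patient bags coupled to Weibull survival times.

    See :class:`CohortSpec` for the generating model. Censoring is
    administrative: a randomly chosen ``censor_rate`` fraction of patients has
    follow-up ending at a uniform time in [6, 60] months, truncated below the
    patient's own OS event time so the nominal censoring rate is realized.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    r = rng.standard_normal(n)
    high_half = r >= np.median(r)

    centers = rng.integers(0, spec.n_centers, size=n)
    frailty = rng.normal(0.0, spec.center_sd, size=spec.n_centers)[centers]
    chemo = rng.integers(0, 2, size=n)
    p_ca199 = 1.0 / (1.0 + np.exp(-spec.ca199_assoc * r))
    ca199 = (rng.uniform(size=n) < p_ca199).astype(int)

    chemo_eff = np.where(high_half, spec.chemo_benefit_high, spec.chemo_benefit_low)
    ca199_eff = np.where(high_half, spec.ca199_effect_high, spec.ca199_effect_low)
    lp = spec.risk_effect_theta * r + frailty + chemo_eff * chemo + ca199_eff * ca199

    t_os = _weibull_times(rng, lp, OS_MEDIAN_MONTHS)
    t_rfs = np.minimum(_weibull_times(rng, lp, RFS_MEDIAN_MONTHS), t_os)

    # administrative censoring hitting the nominal rate on OS
    censor_time = np.full(n, np.inf)
    n_cens = int(round(spec.censor_rate * n))
    idx = rng.choice(n, size=n_cens, replace=False)
    c = rng.uniform(*CENSOR_WINDOW, size=n_cens)
    forced = c >= t_os[idx]
    c[forced] = t_os[idx][forced] * rng.uniform(0.5, 0.95, size=int(forced.sum()))
    censor_time[idx] = c

    os_event = (t_os <= censor_time).astype(int)
    os_time = np.minimum(t_os, censor_time)
    rfs_event = (t_rfs <= censor_time).astype(int)
    rfs_time = np.minimum(t_rfs, censor_time)

    lo, hi = spec._patch_range()
    mean_prob = 1.0 / (1.0 + np.exp(-spec.prob_shift_kappa * r))
    bags: list[PatientBag] = []
    for i in range(n):
        pid = f"P{i:04d}"
        m = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        a = mean_prob[i] * BETA_CONCENTRATION
        b = (1.0 - mean_prob[i]) * BETA_CONCENTRATION
        probs = np.round(rng.beta(a, b, size=m), 2)
        preds = [
            PatchPrediction(pid, f"{pid}_S1", float(p), int(p > 0.5)) for p in probs
        ]
        bags.append(
            PatientBag(
                patient_id=pid,
                predictions=preds,
                os=SurvivalOutcome(float(os_time[i]), int(os_event[i])),
                rfs=SurvivalOutcome(float(rfs_time[i]), int(rfs_event[i])),
                covariates={
                    "ca199_group": int(ca199[i]),
                    "chemo": int(chemo[i]),
                    "center": int(centers[i]),
                    "latent_high": int(high_half[i]),
                },
            )
        )
    return SyntheticCohort(bags=bags, latent_risk=r, truth=spec)


def split_ids(ids: Sequence, train_frac: float = 0.7, seed: int = 0) -> tuple[list, list]:
    """Randomly partition ids into training/validation with floor convention.

    ``n_train = floor(train_frac * n)``: e.g. a 7:3 split of 365 patients
    yields 255 training and 110 validation ids.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie in (0, 1)")
    ids = list(ids)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = math.floor(train_frac * len(ids))
    train = [ids[i] for i in order[:n_train]]
    val = [ids[i] for i in order[n_train:]]
    return train, val


def cohort_to_frames(cohort: SyntheticCohort) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten a cohort into (patches, clinical) tables for CSV round-trips."""
    patch_rows = [
        {"patient_id": p.patient_id, "slide_id": p.slide_id, "prob": p.prob, "pred": p.pred}
        for bag in cohort.bags
        for p in bag.predictions
    ]
    clin_rows = [
        {
            "patient_id": bag.patient_id,
            "os_months": bag.os.time,
            "os_event": bag.os.event,
            "rfs_months": bag.rfs.time,
            "rfs_event": bag.rfs.event,
            **{k: bag.covariates[k] for k in ("ca199_group", "chemo", "center")},
        }
        for bag in cohort.bags
    ]
    return pd.DataFrame(patch_rows), pd.DataFrame(clin_rows)
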