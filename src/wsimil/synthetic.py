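"""Synthetic image cohorts with a planted, recoverable relapse-risk signal.

The generator emulates the statistical structure the downstream analysis
assumes, without claiming histologic realism:

* each patient carries a latent scalar risk ``r ~ Normal(0, latent_risk_sd)``;
* relapse times are exponential with hazard
  ``baseline_hazard * exp(hazard_coefficient * r)``, censored by an
  independent uniform dropout time and administratively at
  ``censor_horizon_days`` (5 years by default);
* tissue images are blob-structured background/stroma/epithelium/artifact
  label masks rendered to H&E-like RGB, where the epithelium texture's mean
  intensity and spatial frequency shift monotonically with ``r`` and every
  slide additionally carries a patient-specific texton-density signature — a
  63-dimensional profile of how densely each motif of a fixed texture
  dictionary is sprinkled over its tissue (the signal the self-supervised
  identity pretext task can learn);
* a feature-space path (:func:`generate_feature_bags`) draws per-patch
  feature vectors from the same composition/risk model directly, emulating
  what the trained encoder would produce, for experiments where rendering
  full images is unnecessary.

Defaults are calibrated so that a five-year cohort has an event fraction
near 0.30 and the true latent risk attains a concordance index of about
0.75 against the generated survival times (the ceiling any model can hope
to approach on these cohorts).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .bags import InstanceBag
from .misl import concordance_index
from .tiling import (
    LABEL_ARTIFACT,
    LABEL_BACKGROUND,
    LABEL_EPITHELIUM,
    LABEL_STROMA,
    assign_cluster,
)

# Base H&E-like colors per mask class (R, G, B), uint8 scale.
_CLASS_COLORS = {
    LABEL_BACKGROUND: (242.0, 240.0, 243.0),
    LABEL_STROMA: (228.0, 160.0, 200.0),
    LABEL_EPITHELIUM: (130.0, 85.0, 160.0),
    LABEL_ARTIFACT: (90.0, 70.0, 60.0),
}

#: size of the fixed texton dictionary; each slide's identity is its
#: 63-dimensional density profile over these motifs
IDENTITY_BASIS_SIZE = 63


@dataclass
class CohortSpec:
    """Study-condition parameters of a synthetic cohort.

    The defaults are the package's reference conditions: ~30% events within
    the 5-year horizon and a latent-risk concordance ceiling of ~0.75.
    """

    n_patients: int = 100
    image_size_px: int = 1024
    latent_risk_sd: float = 1.0
    hazard_coefficient: float = 1.05  # log-hazard per unit latent risk
    baseline_hazard: float = 2.2e-4  # events/day at r = 0
    censor_horizon_days: int = 1826
    texture_shift_scale: float = 12.0  # gray levels per unit latent risk
    artifact_fraction: float = 0.03
    rng_seed: int = 0
    tissue_fraction: float = 0.75  # fraction of slide area covered by tissue
    identity_texture_scale: float = 32.0  # gray-level amplitude of the slide signature

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be at least 2")
        if self.image_size_px < 1024 or self.image_size_px % 1024:
            raise ValueError("image_size_px must be a positive multiple of 1024")
        if self.censor_horizon_days <= 0:
            raise ValueError("censor_horizon_days must be positive")
        if not 0.0 <= self.artifact_fraction <= 1.0:
            raise ValueError("artifact_fraction must lie in [0, 1]")
        if not 0.05 <= self.tissue_fraction <= 1.0:
            raise ValueError("tissue_fraction must lie in [0.05, 1]")
        for name in ("latent_risk_sd", "baseline_hazard", "texture_shift_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SyntheticPatient:
    patient_id: str
    latent_risk: float
    time_days: int
    event: int
    covariates: dict = field(default_factory=dict)


def _patient_rng(spec: CohortSpec, patient_id: str, stream: str) -> np.random.Generator:
    digest = hashlib.sha256(f"{stream}:{patient_id}".encode()).digest()
    sub = int.from_bytes(digest[:4], "little")
    return np.random.default_rng(np.random.SeedSequence([spec.rng_seed, sub]))


def generate_cohort(spec: CohortSpec) -> tuple[list[SyntheticPatient], pd.DataFrame]:
    """Draw patients, relapse times, censoring, and covariates.

    Censoring is the minimum of an independent uniform dropout time (on
    (0, 2 * horizon], so roughly half of censorings are administrative) and
    the administrative horizon. Covariates are binary clinicopathological
    stand-ins (stage, grade, reTUR finding) whose prevalence follows a
    BCG-treated cohort and which are mildly associated with the latent risk.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, 0]))
    n = spec.n_patients
    risk = rng.normal(0.0, spec.latent_risk_sd, size=n)
    rate = spec.baseline_hazard * np.exp(spec.hazard_coefficient * risk)
    t_event = rng.exponential(1.0 / rate)
    t_drop = rng.uniform(0.0, 2.0 * spec.censor_horizon_days, size=n)

    def _cov(base_logit: float, slope: float) -> np.ndarray:
        p = 1.0 / (1.0 + np.exp(-(base_logit + slope * risk)))
        return (rng.uniform(size=n) < p).astype(int)

    covs = {
        "stage_pt1": _cov(-0.45, 0.55),   # ~39% pT1
        "grade_g3": _cov(0.16, 0.45),     # ~54% G3
        "retur_positive": _cov(-0.05, 0.65),  # ~49% residual tumor at reTUR
    }

    patients = []
    for i in range(n):
        censor = min(t_drop[i], spec.censor_horizon_days)
        observed = min(t_event[i], censor)
        event = int(t_event[i] <= censor)
        days = int(max(1, round(observed)))
        if days >= spec.censor_horizon_days:
            days = spec.censor_horizon_days
            event = 0  # administrative censoring at the horizon
        patients.append(
            SyntheticPatient(
                patient_id=f"P{i:04d}",
                latent_risk=float(risk[i]),
                time_days=days,
                event=event,
                covariates={k: int(v[i]) for k, v in covs.items()},
            )
        )
    return patients, cohort_frame(patients)


def cohort_frame(patients: list[SyntheticPatient]) -> pd.DataFrame:
    rows = []
    for p in patients:
        row = {"patient_id": p.patient_id, "time_days": p.time_days,
               "event": p.event, "latent_risk": p.latent_risk}
        row.update(p.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort_csv(patients: list[SyntheticPatient], path: str | Path) -> None:
    cohort_frame(patients).to_csv(path, index=False)


def oracle_c_index(patients: list[SyntheticPatient]) -> float:
    """Concordance of the true latent risk against the generated survival —
    the ceiling for any model trained on this cohort."""
    return concordance_index(
        [p.latent_risk for p in patients],
        [p.time_days for p in patients],
        [p.event for p in patients],
    )


# ---------------------------------------------------------------------------
# Image rendering
# ---------------------------------------------------------------------------

_MOTIF_STAMP_Q = 10  # stamp side in quarter-resolution pixels (40 px full-res)
#: expected motif occurrences per 256-px patch at density multiplier 1
MOTIF_RATE_PER_PATCH = 15.0


def _motif_dictionary() -> np.ndarray:
    """Fixed texton dictionary: (63, 10, 10, 3) colored radial stamps.

    The dictionary is a package constant (not cohort randomness): slides
    differ only in how *densely* each motif is sprinkled over their tissue.
    """
    m = _MOTIF_STAMP_Q
    coords = np.arange(m) - (m - 1) / 2.0
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    rad = np.hypot(yy, xx)

    def dot(sigma):
        return np.exp(-0.5 * (rad / sigma) ** 2)

    def ring(r0, width):
        return np.exp(-0.5 * ((rad - r0) / width) ** 2)

    # rotation/flip-invariant radial profiles: slide identity survives the
    # dihedral training augmentation
    shapes = [
        dot(0.9), dot(1.6), dot(2.6),
        ring(2.2, 0.7), ring(3.3, 0.7), ring(4.3, 0.7),
        dot(1.0) - 0.8 * ring(3.0, 0.8),  # center dot with dark halo
        ring(2.0, 0.5) + ring(4.0, 0.5),  # double ring
        dot(3.5) - dot(1.2),  # hollow blob
    ]
    colors = np.array([
        [1.0, -0.5, -0.5], [-0.5, 1.0, -0.5], [-0.5, -0.5, 1.0],
        [1.0, 1.0, -1.0], [1.0, -1.0, 1.0], [-1.0, 1.0, 1.0],
        [1.0, 1.0, 1.0],
    ])
    colors /= np.linalg.norm(colors, axis=1, keepdims=True)
    motifs = []
    for shape in shapes:
        peak = max(float(np.max(np.abs(shape))), 1e-9)
        for color in colors:
            motifs.append((shape / peak)[:, :, None] * color[None, None, :])
    assert len(motifs) == IDENTITY_BASIS_SIZE
    return np.stack(motifs)


_MOTIFS = _motif_dictionary()


def _signature_texture(
    size: int, signature: np.ndarray, amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Render the slide's identity signature as texton-density texture
    at quarter resolution, (H/4, W/4, 3).

    Each of the 63 dictionary motifs is stamped at Poisson-random positions
    with slide-specific density ``MOTIF_RATE_PER_PATCH * multiplier`` per
    256-px patch and peak amplitude ``0.8 * amplitude`` gray levels. The
    placements are patient random noise; the *density profile* across
    motifs is the statistic that identifies the slide, estimable from a
    patch sampled anywhere on it.
    """
    q = size // 4
    canvas = np.zeros((3, q * q), dtype=np.float32)
    n_patches = (size / 256.0) ** 2
    peak = 0.8 * amplitude
    m = _MOTIF_STAMP_Q
    dy, dx = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
    offsets = (dy * q + dx).ravel()
    for k, mult in enumerate(signature):
        n = rng.poisson(MOTIF_RATE_PER_PATCH * mult * n_patches)
        if n == 0:
            continue
        ys = rng.integers(0, q - m, size=n)
        xs = rng.integers(0, q - m, size=n)
        idx = ((ys * q + xs)[:, None] + offsets[None, :]).ravel()
        stamp = (peak * _MOTIFS[k]).astype(np.float32)
        for ch in range(3):
            weights = np.broadcast_to(
                stamp[:, :, ch].ravel(), (n, m * m)).ravel()
            canvas[ch] += np.bincount(idx, weights=weights, minlength=q * q)
    return canvas.reshape(3, q, q).transpose(1, 2, 0)


def patient_signature(spec: CohortSpec, patient_id: str) -> np.ndarray:
    """Per-slide motif-density multipliers, length ``IDENTITY_BASIS_SIZE``,
    uniform on [0.1, 2.2] (fixed given spec seed + patient id)."""
    rng = _patient_rng(spec, patient_id, "signature")
    return rng.uniform(0.1, 2.2, size=IDENTITY_BASIS_SIZE)


def generate_tissue_image(
    spec: CohortSpec, patient: SyntheticPatient
) -> tuple[np.ndarray, np.ndarray]:
    """Render one slide: (RGB uint8 image, integer label mask).

    The mask is blob-structured (smoothed-noise fields thresholded by
    quantiles) so 1024-px patches span the full stroma/epithelium
    composition range. Epithelium texture statistics shift with the
    patient's latent risk: mean intensity by ``texture_shift_scale * r``
    gray levels and texture correlation length shrinking as risk grows.
    """
    size = spec.image_size_px
    if size % 1024:
        raise ValueError("image_size_px must be a multiple of 1024")
    rng = _patient_rng(spec, patient.patient_id, "image")

    # -- label mask (layout fields synthesized at 1/8 resolution) -------
    c8 = size // 8
    tissue_field = gaussian_filter(rng.normal(size=(c8, c8)), sigma=c8 / 10)
    epi_field = gaussian_filter(rng.normal(size=(c8, c8)), sigma=c8 / 14)
    up8 = lambda f: np.repeat(np.repeat(f, 8, axis=0), 8, axis=1)
    tissue_field, epi_field = up8(tissue_field), up8(epi_field)
    mask = np.full((size, size), LABEL_BACKGROUND, dtype=np.uint8)
    tissue = tissue_field > np.quantile(tissue_field, 1.0 - spec.tissue_fraction)
    epi_cut = np.quantile(epi_field[tissue], 0.5) if tissue.any() else 0.0
    mask[tissue & (epi_field <= epi_cut)] = LABEL_STROMA
    mask[tissue & (epi_field > epi_cut)] = LABEL_EPITHELIUM
    if spec.artifact_fraction > 0:
        art_field = up8(gaussian_filter(rng.normal(size=(c8, c8)), sigma=c8 / 5))
        art = art_field > np.quantile(art_field, 1.0 - spec.artifact_fraction)
        mask[art & tissue] = LABEL_ARTIFACT

    # -- RGB rendering (textures synthesized at 1/4 resolution) ---------
    q = size // 4
    mask_q = mask[::4, ::4]
    base_q = np.empty((q, q, 3), dtype=np.float32)
    for label, color in _CLASS_COLORS.items():
        sel = mask_q == label
        for ch in range(3):
            base_q[sel, ch] = color[ch]
    # feather class boundaries: keeps edge energy below the texture scales
    for ch in range(3):
        base_q[:, :, ch] = gaussian_filter(base_q[:, :, ch], sigma=3.0)

    shift = spec.texture_shift_scale * patient.latent_risk
    # epithelium texture: correlation length shrinks (frequency grows) with risk
    sigma_e = float(np.clip(1.5 / (1.0 + 0.04 * max(shift, -20.0)), 0.5, 3.0))
    epi_tex = gaussian_filter(rng.standard_normal((q, q), dtype=np.float32), sigma=sigma_e)
    epi_tex *= 5.0 / max(epi_tex.std(), 1e-9)
    stroma_tex = gaussian_filter(rng.standard_normal((q, q), dtype=np.float32), sigma=1.25)
    stroma_tex *= 4.0 / max(stroma_tex.std(), 1e-9)

    epi_q = mask_q == LABEL_EPITHELIUM
    stroma_q = mask_q == LABEL_STROMA
    for ch in range(3):
        base_q[epi_q, ch] += epi_tex[epi_q] - shift
        base_q[stroma_q, ch] += stroma_tex[stroma_q]

    sig_tex = _signature_texture(
        size, patient_signature(spec, patient.patient_id),
        spec.identity_texture_scale, rng,
    )
    tissue_q = epi_q | stroma_q
    base_q += sig_tex * tissue_q[:, :, None]
    image = np.repeat(np.repeat(base_q, 4, axis=0), 4, axis=1)

    image += 3.0 * rng.standard_normal(size=image.shape, dtype=np.float32)  # sensor noise
    return np.clip(np.rint(image), 0, 255).astype(np.uint8), mask


# ---------------------------------------------------------------------------
# Feature-space path
# ---------------------------------------------------------------------------

#: relative strength of the risk signal per pyramid level. The profile is
#: chosen so the *effective* per-bag information (amplitude x sqrt of the
#: number of instances at that level) decreases with finer scale: the signal
#: lives in tissue architecture, not cytology.
SCALE_SIGNAL = {1024: 1.0, 512: 0.4, 256: 0.1}

FEATURE_VARIANTS = ("multires", "1024", "512", "256")


def generate_feature_bags(
    spec: CohortSpec,
    patients: list[SyntheticPatient],
    variant: str = "multires",
    d: int = 64,
    n_top_patches: int = 8,
    noise_sd: float = 1.0,
    signal_scale: float = 3.0,
) -> list[InstanceBag]:
    """Draw per-patch feature vectors directly from the generative model.

    Emulates the encoder output on rendered patches: each patient gets
    ``n_top_patches`` 1024-px patches with random stroma/epithelium
    composition; a patch's feature at pyramid level L is
    ``base + r * signal_scale * SCALE_SIGNAL[L] * epithelium_frac * u_L + noise``
    with fixed unit directions ``u_L``. The ``multires`` variant concatenates
    [256 ‖ 512 ‖ 1024] per leaf (instance length 3*d, cluster from the
    1024-px ancestor); single-level variants use that level's vectors alone.
    """
    if variant not in FEATURE_VARIANTS:
        raise ValueError(f"variant must be one of {FEATURE_VARIANTS}")
    dir_rng = np.random.default_rng(np.random.SeedSequence(192837465))
    u = {lvl: dir_rng.normal(size=d) for lvl in (1024, 512, 256)}
    u = {lvl: v / np.linalg.norm(v) for lvl, v in u.items()}
    base = {lvl: dir_rng.normal(0.0, 0.5, size=d) for lvl in (1024, 512, 256)}

    bags = []
    for patient in patients:
        rng = _patient_rng(spec, patient.patient_id, f"features:{variant}:{d}")
        r = patient.latent_risk
        instances, clusters = [], []
        for _ in range(n_top_patches):
            tissue = rng.uniform(0.5, 1.0)
            epi_frac = float(tissue * rng.beta(1.2, 1.2))
            stroma_frac = float(tissue - epi_frac)
            cluster = assign_cluster(stroma_frac, epi_frac)

            def level_vec(lvl: int, e_frac: float) -> np.ndarray:
                amp = r * signal_scale * SCALE_SIGNAL[lvl] * e_frac
                return base[lvl] + amp * u[lvl] + rng.normal(0.0, noise_sd, size=d)

            if variant == "1024":
                instances.append(level_vec(1024, epi_frac))
                clusters.append(cluster)
            elif variant == "512":
                for _c in range(4):
                    e_child = float(np.clip(epi_frac + rng.normal(0, 0.08), 0, 1))
                    instances.append(level_vec(512, e_child))
                    clusters.append(cluster)
            elif variant == "256":
                for _c in range(8):
                    e_leaf = float(np.clip(epi_frac + rng.normal(0, 0.12), 0, 1))
                    instances.append(level_vec(256, e_leaf))
                    clusters.append(cluster)
            else:  # multires
                v1024 = level_vec(1024, epi_frac)
                for _c in range(2):
                    e_child = float(np.clip(epi_frac + rng.normal(0, 0.08), 0, 1))
                    v512 = level_vec(512, e_child)
                    for _l in range(2):
                        e_leaf = float(np.clip(e_child + rng.normal(0, 0.12), 0, 1))
                        instances.append(
                            np.concatenate([level_vec(256, e_leaf), v512, v1024])
                        )
                        clusters.append(cluster)
        bags.append(
            InstanceBag(
                patient_id=patient.patient_id,
                instances=np.asarray(instances),
                cluster_labels=clusters,
                time_days=float(patient.time_days),
                event=int(patient.event),
            )
        )
    return bags
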