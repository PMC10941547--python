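"""Synthetic CT-like volumes and a two-arm cohort generator.

No patient-level data from the study are public, so this module generates
inputs carrying the statistical structure the analysis assumes:

* 3D volumes with a spherical lesion whose interior texture (spatial
  autocorrelation length of a Gaussian random field) depends on a
  responder/non-responder texture class, a homogeneous muscle reference
  region, and background — so GLCM contrast/variance features separate the
  classes in a controllable way;
* a two-arm cohort (ICI + chemotherapy vs chemotherapy alone) in which the
  dynamic EV PD-L1 change and the radiomic texture parameter are shifted in
  ICI-arm non-responders only, tumor change (%) follows the non-responder
  latent score in the ICI arm, and tissue PD-L1 TPS is independent noise in
  [0, 100].

Everything is fully determined by the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ParameterError, ValidationError
from .features import extract_all, feature_registry
from .io import CTVolume, VOISet

__all__ = [
    "ImageSimSpec",
    "CohortSimSpec",
    "DEFAULT_MODEL_FEATURES",
    "default_model_feature_codes",
    "simulate_volume",
    "simulate_cohort",
]

# Texture classes: correlation length (Gaussian smoothing sigma, voxels) of
# the lesion's random field.  Non-responder lesions are coarser.
TEXTURE_SIGMA = {"responder": 0.7, "nonresponder": 1.8}

BACKGROUND_HU = -50.0
MUSCLE_HU = 50.0
LESION_HU = 30.0

# Human-readable names of the 6 radiomic features the combined model uses by
# default; resolved to registry codes (TL_Fxxx columns) at run time.
DEFAULT_MODEL_FEATURES: tuple[str, ...] = (
    "Mean of Contrast (G=8)",
    "Mean of Entropy (G=16)",
    "Range of Difference Variance (G=32)",
    "Mean of Inverse Difference Moment (G=32)",
    "Mean of Correlation (G=64)",
    "Variance of Contrast (G=128)",
)

# loadings of each default feature on the latent texture parameter
_FEATURE_LOADINGS = np.array([0.6, 0.6, 0.5, -0.6, -0.5, 0.5])


def default_model_feature_codes(prefix: str = "TL") -> list[str]:
    """Registry codes (e.g. ``TL_F050``) of the 6 default model features."""
    reg = feature_registry()
    lookup = dict(zip(reg["name"], reg["code"]))
    return [f"{prefix}_{lookup[name]}" for name in DEFAULT_MODEL_FEATURES]


@dataclass
class ImageSimSpec:
    """Configuration of one synthetic CT-like volume."""

    grid_shape: tuple[int, int, int] = (40, 40, 40)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lesion_radius_mm: float = 8.0
    lesion_center: tuple[float, float, float] | None = None
    muscle_offset: tuple[int, int, int] = (2, 2, 2)
    muscle_size: tuple[int, int, int] = (8, 8, 8)
    texture_class: str = "responder"
    texture_sigma: float | None = None  # overrides texture_class when set
    texture_amplitude: float = 20.0
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(n) < 8 for n in self.grid_shape):
            raise ParameterError(f"grid_shape axes must all be >= 8, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ParameterError(f"spacing_mm must be positive, got {self.spacing_mm}")
        if self.texture_class not in TEXTURE_SIGMA:
            raise ParameterError(f"texture_class must be one of {sorted(TEXTURE_SIGMA)}")
        if self.lesion_radius_mm <= 0:
            raise ParameterError("lesion_radius_mm must be positive")
        if self.noise_sd < 0 or self.texture_amplitude < 0:
            raise ParameterError("noise_sd and texture_amplitude must be >= 0")


def _sphere_mask(shape, spacing, center, radius_mm) -> np.ndarray:
    grids = np.meshgrid(*(np.arange(n) * s for n, s in zip(shape, spacing)), indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius_mm ** 2


def simulate_volume(spec: ImageSimSpec) -> tuple[CTVolume, VOISet]:
    """Generate one volume with lesion (``TL_1``) and muscle masks.

    The lesion interior is ``LESION_HU`` plus a unit-variance Gaussian
    random field (white noise smoothed to the class correlation length)
    scaled by ``texture_amplitude``; muscle and background are homogeneous.
    Additive measurement noise (``noise_sd``) and the texture field are
    drawn from independent RNG streams, so changing the texture class
    alters voxels inside the lesion mask only.
    """
    shape = tuple(int(n) for n in spec.grid_shape)
    spacing = tuple(float(s) for s in spec.spacing_mm)
    center = spec.lesion_center
    if center is None:
        center = tuple((n - 1) * s * 0.6 for n, s in zip(shape, spacing))

    lesion = _sphere_mask(shape, spacing, center, spec.lesion_radius_mm)
    if not lesion.any():
        raise ParameterError("lesion sphere contains no voxel; enlarge radius or grid")

    muscle = np.zeros(shape, dtype=bool)
    mo, ms = spec.muscle_offset, spec.muscle_size
    muscle[mo[0]:mo[0] + ms[0], mo[1]:mo[1] + ms[1], mo[2]:mo[2] + ms[2]] = True
    if not muscle.any():
        raise ParameterError("muscle box is empty")
    if (muscle & lesion).any():
        raise ParameterError("lesion and muscle VOIs overlap; adjust placement")

    noise_rng, texture_rng = [np.random.default_rng(s) for s in
                              np.random.SeedSequence(spec.seed).spawn(2)]

    data = np.full(shape, BACKGROUND_HU)
    data[muscle] = MUSCLE_HU
    data[lesion] = LESION_HU

    if spec.texture_amplitude > 0:
        sigma = spec.texture_sigma if spec.texture_sigma is not None \
            else TEXTURE_SIGMA[spec.texture_class]
        white = texture_rng.standard_normal(shape)
        field = ndimage.gaussian_filter(white, sigma=sigma, mode="reflect")
        sd = field[lesion].std()
        if sd > 0:
            field = (field - field[lesion].mean()) / sd
        data[lesion] += spec.texture_amplitude * field[lesion]
    else:
        texture_rng.standard_normal(shape)  # keep stream alignment across configs

    if spec.noise_sd > 0:
        data += spec.noise_sd * noise_rng.standard_normal(shape)

    volume = CTVolume(data, spacing)
    voi = VOISet(lesion_masks={"TL_1": lesion}, muscle_mask=muscle)
    return volume, voi


@dataclass
class CohortSimSpec:
    """Configuration of the two-arm synthetic cohort.

    Effect sizes are standardized mean differences (non-responders minus
    responders) applied in the ICI arm only; the chemotherapy arm carries no
    biomarker signal by default, mirroring the ICI-specificity of the
    combined biomarker.
    """

    n_ici: int = 17
    n_chemo: int = 13
    effect_delta_ev: float = 1.0
    effect_radiomics: float = 1.0
    responder_fraction_ici: float = 0.6
    responder_fraction_chemo: float = 0.5
    tps_alpha: float = 0.5
    tps_beta: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ici < 2 or self.n_chemo < 2:
            raise ParameterError("need at least 2 patients per arm")
        for f in (self.responder_fraction_ici, self.responder_fraction_chemo):
            if not 0.0 < f < 1.0:
                raise ParameterError(f"responder fraction must be in (0,1), got {f}")
        if self.tps_alpha <= 0 or self.tps_beta <= 0:
            raise ParameterError("TPS beta-distribution parameters must be positive")


def _truncated_normal(rng, loc, scale, lo, hi, size):
    out = np.empty(size)
    todo = np.arange(size)
    while todo.size:
        draw = rng.normal(loc if np.isscalar(loc) else loc[todo], scale, todo.size)
        ok = (draw > lo) & (draw < hi)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def simulate_cohort(spec: CohortSimSpec, images: bool = False,
                    image_spec: ImageSimSpec | None = None,
                    ) -> tuple[pd.DataFrame, dict[str, tuple[CTVolume, VOISet]] | None]:
    """Generate the per-patient clinical + radiomic table (and volumes).

    Returns ``(records, volumes)``.  ``records`` has one row per patient:
    ``patient_id, arm, durable_responder, response_category,
    tumor_change_pct, delta_ev_pdl1, tissue_pdl1_tps`` plus the 6 default
    model feature columns (``TL_Fxxx``).  With ``images=True`` each patient
    additionally gets a simulated volume whose lesion correlation length
    tracks the patient's texture parameter, and the feature columns are
    replaced by actual extractor output (all 400 ``TL_Fxxx`` columns).

    Response categories follow RECIST-style tumor-change cutoffs (PR at
    <= -30%, PD at >= +20%), and responders (PR or SD at ~6 months) are
    generated with tumor change below the PD threshold so that category and
    durable-responder label are always mutually consistent.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])

    rows = []
    arms = ["ICI"] * spec.n_ici + ["chemo"] * spec.n_chemo
    fracs = [spec.responder_fraction_ici] * spec.n_ici + [spec.responder_fraction_chemo] * spec.n_chemo
    n = len(arms)

    responder = rng.random(n) < np.asarray(fracs)
    is_ici = np.asarray([a == "ICI" for a in arms])
    nonresp = ~responder

    # latent standardized biomarker draws; effects shift ICI non-responders
    t = rng.standard_normal(n) + spec.effect_radiomics * (is_ici & nonresp)
    dev = rng.standard_normal(n) + spec.effect_delta_ev * (is_ici & nonresp)
    latent = (t + dev) / np.sqrt(2.0)

    # tumor change consistent with responder status (PR/SD vs PD), nudged by
    # the latent score inside the admissible range
    change = np.empty(n)
    r_idx = np.where(responder)[0]
    nr_idx = np.where(nonresp)[0]
    change[r_idx] = _truncated_normal(rng, -35.0, 25.0, -95.0, 15.0, r_idx.size)
    change[nr_idx] = _truncated_normal(rng, 55.0, 45.0, 22.0, 290.0, nr_idx.size)
    nudge = np.where(is_ici, 4.0 * latent, 0.0)
    change[r_idx] = np.clip(change[r_idx] + nudge[r_idx], -99.0, 14.0)
    change[nr_idx] = np.clip(change[nr_idx] + nudge[nr_idx], 21.0, 295.0)

    category = np.where(change <= -30.0, "PR", np.where(change >= 20.0, "PD", "SD"))
    tps = 100.0 * rng.beta(spec.tps_alpha, spec.tps_beta, n)

    feature_codes = default_model_feature_codes()
    feats = np.empty((n, len(feature_codes)))
    for k, lam in enumerate(_FEATURE_LOADINGS):
        feats[:, k] = lam * t + np.sqrt(max(0.0, 1.0 - lam ** 2)) * rng.standard_normal(n)

    for i in range(n):
        rows.append({
            "patient_id": f"P{i + 1:03d}",
            "arm": arms[i],
            "durable_responder": bool(responder[i]),
            "response_category": str(category[i]),
            "tumor_change_pct": float(change[i]),
            "delta_ev_pdl1": float(dev[i]),
            "tissue_pdl1_tps": float(tps[i]),
            **{code: float(feats[i, k]) for k, code in enumerate(feature_codes)},
        })
    records = pd.DataFrame(rows)

    volumes: dict[str, tuple[CTVolume, VOISet]] | None = None
    if images:
        base = image_spec or ImageSimSpec()
        volumes = {}
        reg_codes = feature_registry()["code"].to_numpy()
        all_cols = {f"TL_{c}": np.empty(n) for c in reg_codes}
        child_seeds = np.random.SeedSequence(spec.seed + 1).generate_state(n) % (2 ** 31)
        for i in range(n):
            # coarser texture for higher latent texture parameter
            sigma = float(np.clip(1.0 + 0.35 * t[i], 0.3, 3.0))
            vspec = ImageSimSpec(
                grid_shape=base.grid_shape, spacing_mm=base.spacing_mm,
                lesion_radius_mm=base.lesion_radius_mm, lesion_center=base.lesion_center,
                muscle_offset=base.muscle_offset,
                muscle_size=base.muscle_size, texture_sigma=sigma,
                texture_amplitude=base.texture_amplitude, noise_sd=base.noise_sd,
                seed=int(child_seeds[i]))
            vol, voi = simulate_volume(vspec)
            volumes[records.loc[i, "patient_id"]] = (vol, voi)
            vec = extract_all(vol, voi)["TL_1"]
            for code, val in vec.items():
                all_cols[f"TL_{code}"][i] = val
        extracted = pd.DataFrame(all_cols, index=records.index)
        records = pd.concat(
            [records.drop(columns=[c for c in records.columns if c in extracted.columns]),
             extracted], axis=1)
    return records, volumes
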