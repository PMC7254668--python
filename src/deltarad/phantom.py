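"""Synthetic paired pre-/post-chemotherapy DCE-MRI phantoms.

The generator produces spherical lesions with four-phase enhancement
kinetics on a weakly textured background, together with ground-truth masks,
single-slice seed masks, response labels and molecular subtypes, so that
every downstream stage (segmentation, standardization, feature extraction,
modeling) can be exercised without patient data.

Modeled behaviour
-----------------
* Lesion voxels follow a wash-in/plateau enhancement curve (one multiplier
  per phase, pre-contrast multiplier fixed at 1); background does not
  enhance, emulating fat-suppressed T1-weighted acquisition.
* A smooth multiplicative texture field inside the lesion keeps
  co-occurrence statistics non-degenerate.
* Complete responders (pCR) shrink and lose enhancement after chemotherapy
  but retain a faint residual "tumor bed" so post-treatment segmentation is
  well posed; non-responders re-present the lesion at full size with a new
  noise realization.
* A per-exam global gain jitter emulates inter-scan intensity scale
  differences, which the histogram-standardization stage removes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion, gaussian_filter

from .core import (
    LABEL_NO_PCR,
    LABEL_PCR,
    LABELS,
    SUBTYPES,
    TIMING_AFTER,
    TIMING_BEFORE,
    DCESeries,
    TumorMask,
)

#: Molecular-subtype proportions used by default when sampling a cohort
#: (HR+HER2-, HR+HER2+, HR-HER2+, TN).
DEFAULT_SUBTYPE_PROPORTIONS = (0.342, 0.234, 0.162, 0.262)


@dataclass
class PhantomParams:
    """Configuration of the synthetic DCE-MRI phantom generator.

    Attributes
    ----------
    volume_shape : tuple of int
        Voxels per axis of every phase volume.
    voxel_spacing : tuple of float
        Millimetres per voxel.
    lesion_radius_range : tuple of float
        Pre-treatment lesion radius range in mm, sampled uniformly.
    background_level : float
        Baseline signal intensity (arbitrary units).
    enhancement_curve : tuple of float
        Four per-phase intensity multipliers for lesion voxels; index 0 is
        the pre-contrast reference and must equal 1.
    responder_shrinkage : float in [0, 1]
        Fraction by which a pCR lesion's post-treatment enhancement and
        radius are reduced.
    texture_amplitude : float
        Relative amplitude of the smooth multiplicative texture field
        inside the lesion.
    background_texture_amplitude : float
        Same for the background (emulates parenchymal structure).
    noise_sd : float
        Additive noise scale (intensity units).
    noise_model : {"gaussian", "rician"}
        Additive Gaussian noise by default; Rician available as a flag.
    scale_jitter : float
        Half-width of the uniform per-exam global gain factor.
    tumor_bed_radius : float
        Minimum residual lesion radius (mm) of a pCR post-treatment exam.
    tumor_bed_enhancement : float
        Minimum residual enhancement fraction of a pCR post-treatment exam.
    seed : int
        Master RNG seed; generation is deterministic given the seed.
    """

    volume_shape: tuple[int, int, int] = (30, 30, 30)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lesion_radius_range: tuple[float, float] = (4.0, 8.0)
    background_level: float = 100.0
    enhancement_curve: tuple[float, float, float, float] = (1.0, 2.2, 2.6, 2.4)
    responder_shrinkage: float = 0.7
    texture_amplitude: float = 0.15
    background_texture_amplitude: float = 0.05
    noise_sd: float = 5.0
    noise_model: str = "gaussian"
    scale_jitter: float = 0.15
    tumor_bed_radius: float = 2.5
    tumor_bed_enhancement: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.enhancement_curve) != 4:
            raise ValueError("enhancement_curve must have one entry per phase")
        if abs(self.enhancement_curve[0] - 1.0) > 1e-12:
            raise ValueError("enhancement_curve[0] must be 1 (pre-contrast)")
        if any(c < 1.0 for c in self.enhancement_curve[1:]):
            raise ValueError("post-contrast multipliers must be >= 1")
        if not 0.0 <= self.responder_shrinkage <= 1.0:
            raise ValueError("responder_shrinkage must lie in [0, 1]")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")
        r_max_vox = self.lesion_radius_range[1] / min(self.voxel_spacing)
        # the lesion plus a 5-voxel background margin must fit in the volume
        if 2 * (r_max_vox + 5) > min(self.volume_shape):
            raise ValueError(
                "volume_shape too small for lesion_radius_range "
                "(need a 5-voxel background margin)"
            )


@dataclass
class PhantomLesion:
    """One simulated lesion: paired exams, truth masks, seeds and metadata."""

    pre_exam: DCESeries
    post_exam: DCESeries
    truth_mask_pre: TumorMask
    truth_mask_post: TumorMask
    seed_slice_pre: TumorMask
    seed_slice_post: TumorMask
    label: str
    subtype: str
    lesion_id: str = "lesion"


def _smooth_field(rng: np.random.Generator, shape, sigma: float = 1.5) -> np.ndarray:
    """Zero-mean, unit-sd smooth random field (low-pass filtered noise)."""
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    sd = f.std()
    if sd == 0:
        return np.zeros(shape)
    return (f - f.mean()) / sd


def _add_noise(vol: np.ndarray, sd: float, model: str, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return vol
    if model == "gaussian":
        return vol + sd * rng.standard_normal(vol.shape)
    # Rician: magnitude of complex Gaussian noise around the signal
    re = vol + sd * rng.standard_normal(vol.shape)
    im = sd * rng.standard_normal(vol.shape)
    return np.hypot(re, im)


def _sphere_mask(shape, spacing, center_vox, radius_mm) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum(((g - c) * sp) ** 2 for g, c, sp in zip(grids, center_vox, spacing))
    return d2 <= radius_mm**2


def _seed_slice(truth: np.ndarray, center_z: int) -> np.ndarray:
    """Conservative single-slice seed: central truth slice eroded by 1 voxel."""
    zs = np.nonzero(truth.any(axis=(0, 1)))[0]
    z = int(center_z)
    if z not in zs:
        z = int(zs[len(zs) // 2])
    plane = truth[:, :, z]
    eroded = binary_erosion(plane)
    if not eroded.any():
        eroded = plane
    seed = np.zeros_like(truth)
    seed[:, :, z] = eroded
    return seed


def _make_exam(
    params: PhantomParams,
    timing: str,
    center: np.ndarray,
    radius_mm: float,
    enh_fraction: float,
    rng: np.random.Generator,
) -> tuple[DCESeries, TumorMask, TumorMask]:
    shape = params.volume_shape
    lesion = _sphere_mask(shape, params.voxel_spacing, center, radius_mm)
    texture = 1.0 + params.texture_amplitude * _smooth_field(rng, shape)
    bg_texture = 1.0 + params.background_texture_amplitude * _smooth_field(rng, shape)
    gain = 1.0 + params.scale_jitter * (2.0 * rng.uniform() - 1.0)

    phases = np.empty((4,) + tuple(shape), dtype=np.float64)
    for k, mult in enumerate(params.enhancement_curve):
        eff = 1.0 + (mult - 1.0) * enh_fraction
        vol = params.background_level * bg_texture.copy()
        vol[lesion] = params.background_level * texture[lesion] * eff
        vol *= gain
        phases[k] = _add_noise(vol, params.noise_sd * gain, params.noise_model, rng)

    series = DCESeries(phases, spacing=params.voxel_spacing, exam_timing=timing)
    truth = TumorMask(lesion, provenance="truth")
    seed = TumorMask(_seed_slice(lesion, round(center[2])), provenance="seed")
    return series, truth, seed


def generate_lesion(
    params: PhantomParams,
    label: str,
    subtype: str = SUBTYPES[0],
    lesion_id: str = "lesion",
    rng: np.random.Generator | None = None,
) -> PhantomLesion:
    """Generate one paired pre-/post-chemotherapy phantom lesion.

    For ``label="pCR"`` the post-treatment lesion enhancement is attenuated
    by ``responder_shrinkage`` and the radius shrinks correspondingly, down
    to a faint residual tumor bed.  Deterministic for a given seed.
    """
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}")
    if subtype not in SUBTYPES:
        raise ValueError(f"subtype must be one of {SUBTYPES}")
    if rng is None:
        rng = np.random.default_rng(params.seed)

    radius = rng.uniform(*params.lesion_radius_range)
    center = np.array(params.volume_shape, dtype=float) / 2.0 - 0.5
    center = center + rng.uniform(-1.5, 1.5, size=3)

    pre_series, pre_truth, pre_seed = _make_exam(
        params, TIMING_BEFORE, center, radius, 1.0, rng
    )

    if label == LABEL_PCR:
        post_radius = max(params.tumor_bed_radius, radius * (1.0 - params.responder_shrinkage))
        post_enh = max(params.tumor_bed_enhancement, 1.0 - params.responder_shrinkage)
    else:
        post_radius = radius
        post_enh = 1.0
    post_series, post_truth, post_seed = _make_exam(
        params, TIMING_AFTER, center, post_radius, post_enh, rng
    )

    return PhantomLesion(
        pre_exam=pre_series,
        post_exam=post_series,
        truth_mask_pre=pre_truth,
        truth_mask_post=post_truth,
        seed_slice_pre=pre_seed,
        seed_slice_post=post_seed,
        label=label,
        subtype=subtype,
        lesion_id=lesion_id,
    )


def generate_cohort(
    n_lesions: int,
    pcr_fraction: float,
    params: PhantomParams,
    subtype_proportions=DEFAULT_SUBTYPE_PROPORTIONS,
) -> tuple[list[PhantomLesion], pd.DataFrame]:
    """Generate a cohort of phantom lesions with a fixed responder fraction.

    Exactly ``round(n_lesions * pcr_fraction)`` lesions (round half up) are
    complete responders.  Subtypes are sampled from
    ``subtype_proportions``.  Returns the lesions and a clinical table with
    one row per lesion (lesion_id, label, subtype).
    """
    if n_lesions < 2:
        raise ValueError("need at least 2 lesions to form both classes")
    if not 0.0 < pcr_fraction < 1.0:
        raise ValueError("pcr_fraction must lie strictly in (0, 1)")
    props = np.asarray(subtype_proportions, dtype=float)
    if props.shape != (len(SUBTYPES),) or props.sum() <= 0:
        raise ValueError("subtype_proportions must have one weight per subtype")
    props = props / props.sum()

    n_pcr = int(np.floor(n_lesions * pcr_fraction + 0.5))
    labels = np.array([LABEL_PCR] * n_pcr + [LABEL_NO_PCR] * (n_lesions - n_pcr))

    ss = np.random.SeedSequence(params.seed)
    master = np.random.default_rng(ss.spawn(1)[0])
    master.shuffle(labels)
    subtypes = master.choice(len(SUBTYPES), size=n_lesions, p=props)

    lesions: list[PhantomLesion] = []
    rows = []
    children = ss.spawn(n_lesions + 1)[1:]
    for i, child in enumerate(children):
        lid = f"lesion{i:03d}"
        lesion = generate_lesion(
            params,
            label=str(labels[i]),
            subtype=SUBTYPES[int(subtypes[i])],
            lesion_id=lid,
            rng=np.random.default_rng(child),
        )
        lesions.append(lesion)
        rows.append({"lesion_id": lid, "label": lesion.label, "subtype": lesion.subtype})
    clinical = pd.DataFrame(rows).set_index("lesion_id")
    return lesions, clinical
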