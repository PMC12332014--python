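"""Synthetic two-channel tissue-texture image generator.

No public accession exists for the patient tissue images this pipeline was
designed around, so this module renders controllable stand-ins:

* an "SHG-like" channel of anti-aliased line-segment fibers with a Gaussian
  cross-profile, whose orientations are drawn from a wrapped normal around a
  dominant angle — mimicking partially oriented collagen fibers running
  nearly parallel to the epithelium;
* a "TPF-like" channel of smooth layered intensity bands plus speckle,
  mimicking layered histopathological structures, with optional saturated
  edge blobs standing in for dye-accumulation photodamage artifacts.

Two texture classes that differ in orientation coherence and in fiber
contrast/noise produce measurably different co-occurrence statistics, which
is all the downstream texture/classification stages need; no optical
point-spread or polarization physics is simulated.

Fibers are rendered additively, so incoherent fields accumulate bright fiber
crossings — lower textural uniformity — while coherent parallel fields stay
even. This is the mechanism by which orientation coherence alone moves the
uniformity features (homogeneity, energy, ASM), not only the per-angle
contrast anisotropy.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .image_io import LabeledImage, write_image, write_mask

DEFAULT_FIELD_SIZE = (512, 512)  # pixels, matching 512 x 512 PMT acquisitions
BACKGROUND_LEVEL = 30.0
FIBER_AMPLITUDE = 90.0  # gray levels added per unit intensity_contrast at fiber core


@dataclass(frozen=True)
class TextureClassSpec:
    """Rendering parameters for one texture class.

    Parameters
    ----------
    name : str
        Class label, free form.
    fiber_orientation_deg : float
        Dominant fiber angle in [0, 180), measured from the row axis.
    orientation_coherence : float
        1 means perfectly parallel fibers; 0 means isotropic orientations.
        Orientation dispersion is wrapped-normal with
        ``sd = (1 - coherence) * 90`` degrees.
    fiber_density : float
        Expected fiber count per 100 x 100 pixel area.
    fiber_width_px : float
        Gaussian cross-profile sigma-like width of a fiber, in pixels.
    intensity_contrast : float
        Scales fiber brightness over the background.
    noise_sd : float
        Additive Gaussian read-noise standard deviation, in gray levels.
    artifact_prob : float
        Probability that the TPF channel receives a saturated edge blob.
    """

    name: str
    fiber_orientation_deg: float = 0.0
    orientation_coherence: float = 0.5
    fiber_density: float = 10.0
    fiber_width_px: float = 2.5
    intensity_contrast: float = 1.0
    noise_sd: float = 8.0
    artifact_prob: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.orientation_coherence <= 1.0:
            raise ValueError("orientation_coherence must lie in [0, 1]")
        if not 0.0 <= self.artifact_prob <= 1.0:
            raise ValueError("artifact_prob must lie in [0, 1]")
        if self.fiber_density < 0:
            raise ValueError("fiber_density must be nonnegative")
        if self.fiber_width_px <= 0:
            raise ValueError("fiber_width_px must be positive")
        if self.intensity_contrast < 0 or self.noise_sd < 0:
            raise ValueError("intensity_contrast and noise_sd must be nonnegative")


@dataclass
class StudyClass:
    """One diagnostic class of the synthetic study: labels, size, and the
    per-channel rendering specs."""

    group: str
    diagnosis: str
    n_images: int
    shg: TextureClassSpec
    tpf: TextureClassSpec
    patient_ids: tuple[str, ...]


@dataclass
class SyntheticDataset:
    """A generated study: the images, their manifest, and the master seed."""

    images: list[LabeledImage]
    manifest: pd.DataFrame
    seed: int


def _check_size(size_px: tuple[int, int]) -> tuple[int, int]:
    h, w = int(size_px[0]), int(size_px[1])
    if h < 32 or w < 32:
        raise ValueError(f"field size must be at least 32 x 32, got {h} x {w}")
    return h, w


def _draw_fiber(img: np.ndarray, r0, c0, r1, c1, width: float, amp: float) -> None:
    """Additively stamp one fiber segment with a Gaussian cross-profile."""
    h, w = img.shape
    margin = int(math.ceil(3 * width)) + 1
    rmin = max(0, int(math.floor(min(r0, r1))) - margin)
    rmax = min(h, int(math.ceil(max(r0, r1))) + margin + 1)
    cmin = max(0, int(math.floor(min(c0, c1))) - margin)
    cmax = min(w, int(math.ceil(max(c0, c1))) + margin + 1)
    if rmin >= rmax or cmin >= cmax:
        return
    rr, cc = np.meshgrid(
        np.arange(rmin, rmax, dtype=float),
        np.arange(cmin, cmax, dtype=float),
        indexing="ij",
    )
    # distance from each patch pixel to the segment (r0,c0)-(r1,c1)
    dr, dc = r1 - r0, c1 - c0
    seg_len2 = dr * dr + dc * dc
    if seg_len2 == 0:
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
    else:
        t = ((rr - r0) * dr + (cc - c0) * dc) / seg_len2
        t = np.clip(t, 0.0, 1.0)
        d2 = (rr - (r0 + t * dr)) ** 2 + (cc - (c0 + t * dc)) ** 2
    img[rmin:rmax, cmin:cmax] += amp * np.exp(-d2 / (2.0 * width * width))


def render_fiber_field(
    spec: TextureClassSpec,
    size_px: tuple[int, int] = DEFAULT_FIELD_SIZE,
    seed: int = 0,
) -> np.ndarray:
    """Render one 8-bit SHG-like field of oriented fibers.

    Fiber count is Poisson with mean ``fiber_density * H*W / 1e4``; each
    fiber's angle is the dominant orientation plus wrapped-normal scatter
    with sd ``(1 - coherence) * 90`` degrees. Identical (spec, size, seed)
    re-renders bit-identically.
    """
    h, w = _check_size(size_px)
    rng = np.random.default_rng(seed)
    img = np.full((h, w), BACKGROUND_LEVEL, dtype=float)
    n_fibers = rng.poisson(spec.fiber_density * h * w / 1e4)
    sd_deg = (1.0 - spec.orientation_coherence) * 90.0
    amp = spec.intensity_contrast * FIBER_AMPLITUDE
    for _ in range(n_fibers):
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        theta = math.radians(spec.fiber_orientation_deg + rng.normal(0.0, sd_deg))
        length = rng.uniform(0.1, 0.3) * max(h, w)
        # 0 deg runs along a row (dc > 0), angles increase counter-clockwise
        # in the usual image convention (row index grows downward)
        dr = -math.sin(theta) * length / 2.0
        dc = math.cos(theta) * length / 2.0
        fiber_amp = amp * rng.uniform(0.6, 1.0)
        _draw_fiber(img, cy - dr, cx - dc, cy + dr, cx + dc, spec.fiber_width_px, fiber_amp)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def render_tpf_channel(
    spec: TextureClassSpec,
    size_px: tuple[int, int] = DEFAULT_FIELD_SIZE,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one 8-bit TPF-like field and its artifact exclusion mask.

    The field is a smooth stack of intensity bands perpendicular to the
    dominant orientation (layered structures parallel to the epithelium)
    plus mild multiplicative speckle and additive read noise. With
    probability ``artifact_prob`` a saturated blob is stamped at a random
    image edge and marked True in the returned mask.
    """
    h, w = _check_size(size_px)
    rng = np.random.default_rng(seed)
    theta = math.radians(spec.fiber_orientation_deg)
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    # coordinate perpendicular to the layering direction
    axis = rr * math.cos(theta) + cc * math.sin(theta)
    period = rng.uniform(60.0, 120.0)
    phase = rng.uniform(0.0, 2.0 * math.pi)
    amp = spec.intensity_contrast * 45.0
    img = 70.0 + amp * np.sin(2.0 * math.pi * axis / period + phase)
    img *= 1.0 + 0.08 * rng.standard_normal(img.shape)  # speckle
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    mask = np.zeros((h, w), dtype=bool)
    if rng.random() < spec.artifact_prob:
        radius = rng.uniform(15.0, 40.0)
        side = rng.integers(4)
        if side == 0:
            cy, cx = 0.0, rng.uniform(0, w)
        elif side == 1:
            cy, cx = float(h - 1), rng.uniform(0, w)
        elif side == 2:
            cy, cx = rng.uniform(0, h), 0.0
        else:
            cy, cx = rng.uniform(0, h), float(w - 1)
        blob = (rr - cy) ** 2 + (cc - cx) ** 2 <= radius * radius
        img[blob] = 255.0
        mask |= blob
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), mask


def images_for_datapoints(n_datapoints: int, n_angles: int = 4) -> int:
    """Images needed so that per-angle feature extraction yields at least
    ``n_datapoints`` records (one record per angle per image)."""
    return -(-n_datapoints // n_angles)


def default_study_classes() -> dict[str, StudyClass]:
    """The default four-class study emulating the reported dataset shape.

    Image counts are sized so that 4-angle extraction yields 96 SHG
    datapoints for primary SCC, 120 for group1 metachronous HGD, and 84 for
    each group2 arm (24, 30, 21, 21 images). Group1 fields are spread over
    nine patients and group2 over three, mirroring the cohort sizes.

    Texture parameters encode the qualitative findings the classes must
    reproduce: carcinoma fields are the least coherent and noisiest (highest
    contrast/dissimilarity, lowest uniformity); group1 metachronous
    dysplasia is the most ordered; group2's metachronous arm is distinctly
    less ordered than group1's.
    """
    g1_patients = tuple(f"P{i:02d}" for i in range(1, 10))
    g2_patients = tuple(f"P{i:02d}" for i in range(10, 13))

    def specs(name, coherence, contrast, noise, density, width):
        shg = TextureClassSpec(
            name=name,
            fiber_orientation_deg=0.0,
            orientation_coherence=coherence,
            fiber_density=density,
            fiber_width_px=width,
            intensity_contrast=contrast,
            noise_sd=noise,
            artifact_prob=0.0,
        )
        tpf = replace(shg, artifact_prob=0.1)
        return shg, tpf

    scc_shg, scc_tpf = specs("primary_SCC", 0.2, 1.2, 10.0, 12.0, 2.5)
    mg1_shg, mg1_tpf = specs("metachronous_HGD_g1", 0.8, 0.8, 8.0, 10.0, 3.0)
    phg_shg, phg_tpf = specs("primary_HGD", 0.7, 0.85, 8.0, 10.0, 3.0)
    mg2_shg, mg2_tpf = specs("metachronous_HGD_g2", 0.45, 1.05, 9.0, 11.0, 2.5)

    return {
        "group1_primary_SCC": StudyClass(
            "group1", "primary_SCC", 24, scc_shg, scc_tpf, g1_patients
        ),
        "group1_metachronous_HGD": StudyClass(
            "group1", "metachronous_HGD", 30, mg1_shg, mg1_tpf, g1_patients
        ),
        "group2_primary_HGD": StudyClass(
            "group2", "primary_HGD", 21, phg_shg, phg_tpf, g2_patients
        ),
        "group2_metachronous_HGD": StudyClass(
            "group2", "metachronous_HGD", 21, mg2_shg, mg2_tpf, g2_patients
        ),
    }


def generate_study(
    dataset_spec: Mapping[str, StudyClass],
    seed: int,
    out_dir: str | Path | None = None,
    size_px: tuple[int, int] = DEFAULT_FIELD_SIZE,
) -> SyntheticDataset:
    """Generate a full two-channel synthetic study.

    For every class, renders ``n_images`` paired SHG/TPF fields, assigns
    patients round-robin, and (if ``out_dir`` is given) writes per-channel
    grayscale TIFFs, 0/255 PNG artifact masks, a manifest CSV and the
    generator config as YAML. Regeneration with the same seed and specs is
    bit-identical; per-group image counts match the request exactly.
    """
    if not dataset_spec:
        raise ValueError("dataset_spec must contain at least one class")
    for key, cls in dataset_spec.items():
        if cls.n_images < 1:
            raise ValueError(f"class {key!r}: n_images must be >= 1")

    images: list[LabeledImage] = []
    rows: list[dict] = []

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    for key in sorted(dataset_spec):
        cls = dataset_spec[key]
        class_ss = np.random.SeedSequence(entropy=(seed, zlib.crc32(key.encode())))
        child_seeds = class_ss.generate_state(2 * cls.n_images) % (2**31)
        for i in range(cls.n_images):
            patient = cls.patient_ids[i % len(cls.patient_ids)]
            field_id = f"{key}_f{i:03d}"
            shg_pixels = render_fiber_field(cls.shg, size_px, int(child_seeds[2 * i]))
            tpf_pixels, tpf_mask = render_tpf_channel(
                cls.tpf, size_px, int(child_seeds[2 * i + 1])
            )
            for channel, pixels, mask in (
                ("SHG", shg_pixels, None),
                ("TPF", tpf_pixels, tpf_mask if tpf_mask.any() else None),
            ):
                fname = f"{field_id}_{channel}.tif"
                mask_name = ""
                if out_dir is not None:
                    write_image(out_dir / fname, pixels)
                    if mask is not None:
                        mask_name = f"{field_id}_{channel}_mask.png"
                        write_mask(out_dir / mask_name, mask)
                images.append(
                    LabeledImage(
                        pixels=pixels.astype(np.int64),
                        channel=channel,
                        group=cls.group,
                        diagnosis=cls.diagnosis,
                        patient_id=patient,
                        field_id=field_id,
                        mask=mask,
                        levels=256,
                    )
                )
                rows.append(
                    {
                        "file": fname,
                        "channel": channel,
                        "group": cls.group,
                        "diagnosis": cls.diagnosis,
                        "patient_id": patient,
                        "field_id": field_id,
                        "mask_file": mask_name,
                    }
                )

    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
        config = {
            "seed": int(seed),
            "size_px": [int(size_px[0]), int(size_px[1])],
            "classes": {
                key: {
                    "group": cls.group,
                    "diagnosis": cls.diagnosis,
                    "n_images": cls.n_images,
                    "patient_ids": list(cls.patient_ids),
                    "shg": asdict(cls.shg),
                    "tpf": asdict(cls.tpf),
                }
                for key, cls in sorted(dataset_spec.items())
            },
        }
        with open(out_dir / "generator_config.yaml", "w") as fh:
            yaml.safe_dump(config, fh, sort_keys=True)
    return SyntheticDataset(images=images, manifest=manifest, seed=seed)
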