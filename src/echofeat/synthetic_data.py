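"""Seeded ultrasound-like lesion phantoms with planted ground truth.

Phantoms emulate the aspects of clinical B-mode appearance that the feature
set actually measures: a star-shaped hypoechoic lesion whose boundary is a
base ellipse modulated by low-order cosine harmonics (lobulation), a
controllable orientation, optional Gaussian margin blur, planted bright
discs (calcifications), concentric interior intensity bands (echo
heterogeneity) and multiplicative Gaussian speckle.  They make no attempt
at acoustic fidelity (no beamforming, attenuation or posterior features);
first- and second-order intensity statistics are what the features consume.

Every generator call is driven by a single seeded RNG, so identical specs
give bit-identical phantoms on one platform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import GenerationError, ValidationError
from .roi_io import Contour, GreyImage, boundary_pixel_set, rasterize_contour, save_image

CALC_INTENSITY = 250
_MAX_REJECTION_DRAWS = 10_000


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of one phantom lesion."""

    canvas: tuple[int, int] = (256, 256)
    r0: float = 60.0
    harmonics: tuple[tuple[int, float, float], ...] = ()  # (order k, amp a_k, phase)
    axis_ratio: float = 1.0
    rotation_deg: float = 0.0
    margin_sigma: float = 0.0
    n_calcs: int = 0
    calc_radius: int = 3
    interior_mean: float = 80.0
    exterior_mean: float = 160.0
    speckle_sigma: float = 0.08
    n_bands: int = 1
    band_spacing: float = 16.0  # grey-level gap between adjacent bands
    n_vertices: int = 720
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r0 < 20:
            raise ValidationError("r0 must be >= 20 pixels")
        if sum(abs(a) for _, a, _ in self.harmonics) >= 0.5:
            raise ValidationError("sum |a_k| must stay below 0.5 (star-shaped)")
        if self.axis_ratio < 1.0:
            raise ValidationError("axis_ratio must be >= 1")
        if not 0 <= self.rotation_deg < 180:
            raise ValidationError("rotation_deg must be in [0, 180)")
        if self.interior_mean == self.exterior_mean:
            raise ValidationError("interior and exterior means must differ")
        amp_sum = sum(abs(a) for _, a, _ in self.harmonics)
        max_r = self.r0 * np.sqrt(self.axis_ratio) * (1 + amp_sum)
        if max_r + 4 > min(self.canvas) / 2:
            raise ValidationError("canvas too small for the requested lesion")


@dataclass(frozen=True)
class PhantomTruth:
    """Planted parameters mirrored back for recovery tests."""

    contour: Contour = field(repr=False)
    rotation_deg: float = 0.0
    n_lobes: int = 0
    n_calcs: int = 0
    calc_centers: tuple[tuple[int, int], ...] = ()
    margin_sigma: float = 0.0


def radial_profile(spec: PhantomSpec, theta: np.ndarray) -> np.ndarray:
    """Boundary radius r(theta) = ellipse profile times harmonic modulation."""
    q = spec.axis_ratio
    a = spec.r0 * np.sqrt(q)
    b = spec.r0 / np.sqrt(q)
    rot = np.radians(spec.rotation_deg)
    ell = a * b / np.hypot(b * np.cos(theta - rot), a * np.sin(theta - rot))
    mod = np.ones_like(theta)
    for k, amp, phase in spec.harmonics:
        mod += amp * np.cos(k * theta + phase)
    return ell * mod


def phantom_contour(spec: PhantomSpec) -> Contour:
    theta = np.arange(spec.n_vertices) * 2 * np.pi / spec.n_vertices
    r = radial_profile(spec, theta)
    cr, cc = spec.canvas[0] / 2, spec.canvas[1] / 2
    rows = cr + r * np.sin(theta)   # theta increases clockwise on screen
    cols = cc + r * np.cos(theta)
    return Contour(np.stack([rows, cols], axis=1))


def _place_calcifications(mask: np.ndarray, spec: PhantomSpec,
                          rng: np.random.Generator) -> list[tuple[int, int]]:
    """Rejection-sample disc centres with pairwise separation >= 4*radius."""
    depth = ndimage.distance_transform_edt(mask)
    cand = np.argwhere(depth >= spec.calc_radius + 2)
    if cand.size == 0:
        raise GenerationError("no interior room for calcifications")
    min_sep = 4 * spec.calc_radius
    centers: list[tuple[int, int]] = []
    for _ in range(_MAX_REJECTION_DRAWS):
        r, c = cand[rng.integers(len(cand))]
        if all((r - r2) ** 2 + (c - c2) ** 2 >= min_sep ** 2 for r2, c2 in centers):
            centers.append((int(r), int(c)))
            if len(centers) == spec.n_calcs:
                return centers
    raise GenerationError(
        f"could not place {spec.n_calcs} calcifications after "
        f"{_MAX_REJECTION_DRAWS} rejection draws")


def make_phantom(spec: PhantomSpec) -> tuple[GreyImage, Contour, PhantomTruth]:
    """Render one phantom; identical spec (incl. seed) gives identical output."""
    rng = np.random.default_rng(spec.seed)
    contour = phantom_contour(spec)
    mask = rasterize_contour(contour, spec.canvas)

    img = np.full(spec.canvas, float(spec.exterior_mean))
    if spec.n_bands <= 1:
        img[mask] = spec.interior_mean
    else:
        # concentric equal-area bands: quantile-banded boundary distance, so
        # every band holds ~the same pixel count whatever the shape
        depth = ndimage.distance_transform_edt(mask)[mask]
        ranks = np.argsort(np.argsort(depth, kind="stable"), kind="stable")
        idx = np.clip((ranks * spec.n_bands) // depth.size, 0, spec.n_bands - 1)
        # fixed per-band spacing: each extra band adds a distinct grey level,
        # so interior heterogeneity grows monotonically with n_bands
        levels = spec.interior_mean + spec.band_spacing * (
            np.arange(spec.n_bands) - (spec.n_bands - 1) / 2)
        img[mask] = levels[idx]

    if spec.speckle_sigma > 0:
        img *= 1.0 + rng.normal(0.0, spec.speckle_sigma, size=img.shape)
    img = np.clip(img, 0, 255)

    if spec.margin_sigma > 0:
        blurred = ndimage.gaussian_filter(img, spec.margin_sigma)
        dist = ndimage.distance_transform_edt(~boundary_pixel_set(mask))
        w = np.exp(-0.5 * (dist / (3.0 * spec.margin_sigma)) ** 2)
        img = w * blurred + (1 - w) * img

    calc_centers: list[tuple[int, int]] = []
    if spec.n_calcs > 0:
        calc_centers = _place_calcifications(mask, spec, rng)
        rr = np.arange(spec.canvas[0])[:, None]
        cc = np.arange(spec.canvas[1])[None, :]
        for r, c in calc_centers:
            blob = (rr - r) ** 2 + (cc - c) ** 2 <= spec.calc_radius ** 2
            img[blob] = CALC_INTENSITY

    grey = GreyImage(np.clip(np.round(img), 0, 255).astype(np.uint8))
    orders = [k for k, a, _ in spec.harmonics if a > 0]
    truth = PhantomTruth(
        contour=contour,
        rotation_deg=spec.rotation_deg,
        n_lobes=2 * max(orders) if orders else 0,
        n_calcs=spec.n_calcs,
        calc_centers=tuple(calc_centers),
        margin_sigma=spec.margin_sigma,
    )
    return grey, contour, truth


# ---------------------------------------------------------------------------
# cohort generation

@dataclass(frozen=True)
class GroupProfile:
    """Sampling distributions for one arm of a synthetic cohort."""

    lobe_orders: tuple[int, ...] = (2, 3)
    lobe_amp: tuple[float, float] = (0.04, 0.08)
    rotation_scale_deg: float = 17.0   # half-normal scale; folded mean ~ 0.8*scale
    calc_rate: float = 3.8             # Poisson mean of planted blob count
    n_bands: int = 4
    axis_ratio: tuple[float, float] = (1.4, 1.8)
    margin_sigma: tuple[float, float] = (0.0, 2.0)


@dataclass(frozen=True)
class EffectProfile:
    """Benign/malignant arm distributions of a synthetic cohort.

    The default plants the group differences the feature set is meant to
    detect: the malignant arm gets higher-order, larger-amplitude boundary
    harmonics (more lobulation), fewer calcifications, smaller orientation
    angles, and fewer interior bands (lower texture entropy).
    """

    benign: GroupProfile = GroupProfile()
    malignant: GroupProfile = GroupProfile(
        lobe_orders=(4, 5, 6), lobe_amp=(0.06, 0.12), rotation_scale_deg=8.0,
        calc_rate=2.5, n_bands=2, axis_ratio=(1.2, 1.5))


DEFAULT_PROFILE = EffectProfile()
#: both arms drawn from the same distribution (type-I error calibration)
ZERO_EFFECT_PROFILE = EffectProfile(malignant=GroupProfile())


def sample_spec(group_profile: GroupProfile, rng: np.random.Generator,
                canvas: tuple[int, int] = (160, 160),
                r0_range: tuple[float, float] = (35.0, 45.0)) -> PhantomSpec:
    """Draw one phantom spec from a group's distributions."""
    k = int(rng.choice(group_profile.lobe_orders))
    amp = float(rng.uniform(*group_profile.lobe_amp))
    phase = float(rng.uniform(0, 2 * np.pi))
    rot = float(min(abs(rng.normal(0, group_profile.rotation_scale_deg)), 89.0))
    n_calcs = int(rng.poisson(group_profile.calc_rate))
    return PhantomSpec(
        canvas=canvas,
        r0=float(rng.uniform(*r0_range)),
        harmonics=((k, amp, phase),),
        axis_ratio=float(rng.uniform(*group_profile.axis_ratio)),
        rotation_deg=rot,
        margin_sigma=float(rng.uniform(*group_profile.margin_sigma)),
        n_calcs=n_calcs,
        n_bands=group_profile.n_bands,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


@dataclass
class CohortData:
    """In-memory cohort: rendered lesions plus manifest and truth tables."""

    lesions: list[tuple[str, str, GreyImage, Contour, PhantomTruth]]
    manifest: pd.DataFrame
    truth: pd.DataFrame


def make_cohort(n_benign: int, n_malignant: int,
                profile: EffectProfile | None = None,
                seed: int = 0,
                out_dir: str | Path | None = None,
                canvas: tuple[int, int] = (160, 160)) -> CohortData:
    """Generate a labelled two-arm cohort, optionally written to disk.

    When ``out_dir`` is given, images (PNG), contours (JSON),
    ``manifest.csv`` and ``truth.csv`` are written there and the manifest
    paths reference those files.
    """
    if n_benign < 2 or n_malignant < 2:
        raise ValidationError("need at least 2 lesions per group")
    profile = profile or DEFAULT_PROFILE
    rng = np.random.default_rng(seed)
    lesions = []
    manifest_rows = []
    truth_rows = []
    for group, n in (("benign", n_benign), ("malignant", n_malignant)):
        gp = getattr(profile, group)
        for i in range(n):
            lesion_id = f"{group}_{i:04d}"
            spec = sample_spec(gp, rng, canvas=canvas)
            img, contour, truth = make_phantom(spec)
            lesions.append((lesion_id, group, img, contour, truth))
            manifest_rows.append({
                "lesion_id": lesion_id,
                "image_path": f"{lesion_id}.png",
                "contour_path": f"{lesion_id}.json",
                "group": group,
            })
            truth_rows.append({
                "lesion_id": lesion_id,
                "group": group,
                "rotation_deg": truth.rotation_deg,
                "n_lobes": truth.n_lobes,
                "n_calcs": truth.n_calcs,
                "margin_sigma": truth.margin_sigma,
            })
    manifest = pd.DataFrame(manifest_rows)
    truth_df = pd.DataFrame(truth_rows)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for lesion_id, _, img, contour, _ in lesions:
            save_image(img, out / f"{lesion_id}.png")
            with open(out / f"{lesion_id}.json", "w") as fh:
                json.dump({"vertices": contour.vertices.tolist()}, fh)
        # paths stay relative to the manifest location so a cohort directory
        # is relocatable and byte-reproducible across output paths
        manifest.to_csv(out / "manifest.csv", index=False)
        truth_df.to_csv(out / "truth.csv", index=False)
    return CohortData(lesions=lesions, manifest=manifest, truth=truth_df)
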