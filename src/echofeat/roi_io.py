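"""Reading images and contours and building the lesion region of interest.

Everything downstream (shape, margin, calcification and texture features)
consumes a :class:`LesionROI`: the grey-scale image, a single-component
binary lesion mask, the ordered clockwise boundary traced from that mask,
and the mask centroid.  Coordinates are 0-based ``(row, col)`` with the
origin at the top-left corner; the first axis is depth (beam direction) and
the second axis is lateral.  Angles are measured from the +col axis,
increasing toward +row, i.e. clockwise as displayed on screen.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.draw import polygon as draw_polygon

from .exceptions import ValidationError

MIN_IMAGE_SIDE = 8
MIN_CONTOUR_VERTICES = 8

# Moore neighbourhood in clockwise screen order starting west:
# W, NW, N, NE, E, SE, S, SW  (row axis points down).
_MOORE = ((0, -1), (-1, -1), (-1, 0), (-1, 1),
          (0, 1), (1, 1), (1, 0), (1, -1))
_MOORE_INDEX = {off: k for k, off in enumerate(_MOORE)}


@dataclass(frozen=True)
class GreyImage:
    """8-bit single-channel image, at least 8x8 pixels."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValidationError(f"image must be 2-D, got shape {px.shape}")
        if px.shape[0] < MIN_IMAGE_SIDE or px.shape[1] < MIN_IMAGE_SIDE:
            raise ValidationError(
                f"image {px.shape} smaller than {MIN_IMAGE_SIDE}x{MIN_IMAGE_SIDE}")
        if px.dtype != np.uint8:
            if np.issubdtype(px.dtype, np.floating) or px.min() < 0 or px.max() > 255:
                raise ValidationError("intensities must be integers in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class Contour:
    """Closed boundary polygon, stored clockwise in image coordinates.

    ``vertices`` is an ``(N, 2)`` array of ``(row, col)`` points; closure is
    implied (the first vertex is not repeated at the end).
    """

    vertices: np.ndarray
    clockwise: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValidationError("contour vertices must be an (N, 2) array")
        if v.shape[0] < MIN_CONTOUR_VERTICES:
            raise ValidationError(
                f"contour needs >= {MIN_CONTOUR_VERTICES} vertices, got {v.shape[0]}")
        object.__setattr__(self, "vertices", v)

    def __len__(self) -> int:
        return self.vertices.shape[0]


@dataclass(frozen=True)
class RadialSequence:
    """Clockwise radii and angles of boundary pixels about the centroid."""

    r: np.ndarray
    theta: np.ndarray
    clockwise: bool = True

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        th = np.asarray(self.theta, dtype=float)
        if r.ndim != 1 or th.shape != r.shape:
            raise ValidationError("r and theta must be 1-D arrays of equal length")
        if r.size < MIN_CONTOUR_VERTICES:
            raise ValidationError("radial sequence shorter than 8 samples")
        if np.any(r <= 0):
            raise ValidationError("all radii must be positive")
        if np.any(th < 0) or np.any(th >= 2 * np.pi):
            raise ValidationError("angles must lie in [0, 2*pi)")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "theta", th)

    def __len__(self) -> int:
        return self.r.size


@dataclass(frozen=True)
class LesionROI:
    """The canonical unit every feature module consumes."""

    image: GreyImage
    mask: np.ndarray
    boundary: Contour = field(repr=False)
    centroid: tuple[float, float] = (0.0, 0.0)

    @property
    def area_px(self) -> int:
        """S: number of foreground pixels."""
        return int(self.mask.sum())

    @property
    def n_boundary_px(self) -> int:
        """N: number of pixels in the traced boundary sequence."""
        return len(self.boundary)

    @property
    def perimeter_px(self) -> float:
        """C: Freeman chain length of the traced boundary (pixel units)."""
        return chain_perimeter(self.boundary)


def load_image(path: str | Path) -> GreyImage:
    """Read an 8-bit PNG/TIFF; RGB is collapsed by ITU-R 601 luminance."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with Image.open(path) as im:
        if im.mode in ("RGB", "RGBA"):
            im = im.convert("RGB")
            arr = np.asarray(im, dtype=float)
            grey = 0.299 * arr[..., 0] + 0.587 * arr[..., 1] + 0.114 * arr[..., 2]
            px = np.clip(np.round(grey), 0, 255).astype(np.uint8)
        elif im.mode == "L":
            px = np.asarray(im, dtype=np.uint8)
        else:
            raise ValidationError(f"unsupported image mode {im.mode!r}; need 8-bit grey or RGB")
    return GreyImage(px)


def save_image(img: GreyImage | np.ndarray, path: str | Path) -> None:
    px = img.pixels if isinstance(img, GreyImage) else np.asarray(img, dtype=np.uint8)
    Image.fromarray(px, mode="L").save(Path(path))


def load_contour(path: str | Path) -> Contour | np.ndarray:
    """Load a contour file: JSON vertex list, or a 0/255 mask PNG.

    Returns a :class:`Contour` for JSON input and a boolean mask array for
    mask-image input; :func:`build_roi` accepts either.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            payload = json.load(fh)
        return Contour(np.asarray(payload["vertices"], dtype=float))
    img = load_image(path)
    return img.pixels > 127


def rasterize_contour(contour: Contour, shape: tuple[int, int]) -> np.ndarray:
    """Fill a contour polygon into a boolean mask (boundary-inclusive)."""
    v = contour.vertices
    m, n = shape
    if np.any(v[:, 0] < 0) or np.any(v[:, 1] < 0) or \
            np.any(v[:, 0] > m - 1) or np.any(v[:, 1] > n - 1):
        raise ValidationError("contour vertices fall outside the image")
    area2 = np.abs(np.dot(v[:, 1], np.roll(v[:, 0], -1)) -
                   np.dot(np.roll(v[:, 1], -1), v[:, 0]))
    if area2 <= 0:
        raise ValidationError("contour has zero area")
    rr, cc = draw_polygon(v[:, 0], v[:, 1], shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    if not mask.any():
        raise ValidationError("contour rasterized to an empty mask")
    mask = ndimage.binary_fill_holes(mask)
    _, n_comp = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n_comp != 1:
        raise ValidationError(f"contour rasterized to {n_comp} components, expected 1")
    return mask


def boundary_pixel_set(mask: np.ndarray) -> np.ndarray:
    """Inner boundary: foreground pixels with >= 1 background 4-neighbour.

    This is the pixel set Moore neighbour tracing visits (the 8-connected
    inner contour); every such pixel is 8-adjacent to background.
    """
    mask = np.asarray(mask, dtype=bool)
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(2, 1), border_value=0)
    return mask & ~eroded


def chain_perimeter(contour: Contour) -> float:
    """Freeman chain-code length of a traced pixel boundary (pixel units).

    Axial steps count 1, diagonal steps sqrt(2), including the closing
    step, so a rasterized disc approaches its continuous circumference and
    an axis-aligned square of side s gives exactly 4s - 4.
    """
    v = contour.vertices
    d = np.abs(np.diff(v, axis=0, append=v[:1]))
    step = np.hypot(d[:, 0], d[:, 1])
    return float(step.sum())


def trace_boundary(mask: np.ndarray) -> Contour:
    """Trace the inner boundary clockwise with Moore neighbour tracing.

    The traced sequence visits exactly the foreground pixels with a
    4-adjacent background neighbour; consecutive entries are 8-adjacent.
    Its length N is the radial sequence length; its Freeman chain length is
    the perimeter C entering the circularity ratio.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("empty mask")
    _, n_comp = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n_comp != 1:
        raise ValidationError(f"mask has {n_comp} components, expected 1")

    m, n = mask.shape

    def fg(r: int, c: int) -> bool:
        return 0 <= r < m and 0 <= c < n and mask[r, c]

    def step(p: tuple[int, int], b_idx: int):
        """First foreground Moore neighbour clockwise after the backtrack."""
        for k in range(1, 9):
            idx = (b_idx + k) % 8
            q = (p[0] + _MOORE[idx][0], p[1] + _MOORE[idx][1])
            if fg(*q):
                return k, q
        return None

    def next_backtrack(p, b_idx, k, q) -> int:
        # last background cell examined before reaching q, seen from q
        g_idx = (b_idx + k - 1) % 8
        g = (p[0] + _MOORE[g_idx][0], p[1] + _MOORE[g_idx][1])
        return _MOORE_INDEX[(g[0] - q[0], g[1] - q[1])]

    rows, cols = np.nonzero(mask)
    start = (int(rows[0]), int(cols[0]))  # topmost, then leftmost
    seq: list[tuple[int, int]] = [start]
    first = step(start, 0)                # backtrack west: background by scan order
    if first is not None:
        k, first_q = first
        b_idx = next_backtrack(start, 0, k, first_q)
        p = first_q
        # stop on repeating the initial transition start -> first_q
        # (a plain position check fails on 1-px spurs that revisit pixels)
        max_steps = 4 * int(mask.sum()) + 8
        for _ in range(max_steps):
            nxt = step(p, b_idx)
            assert nxt is not None  # p was entered from a foreground pixel
            k, q = nxt
            if p == start and q == first_q:
                break
            seq.append(p)
            b_idx = next_backtrack(p, b_idx, k, q)
            p = q
        else:
            raise ValidationError("boundary trace did not close")

    verts = np.asarray(seq, dtype=float)
    if verts.shape[0] < MIN_CONTOUR_VERTICES:
        raise ValidationError(
            f"traced boundary has {verts.shape[0]} pixels; mask too small or too thin")
    # enforce clockwise-on-screen storage (positive shoelace in (col, row))
    x, y = verts[:, 1], verts[:, 0]
    signed2 = np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)
    if signed2 < 0:
        verts = verts[::-1].copy()
    return Contour(verts, clockwise=True)


def centroid(mask: np.ndarray) -> tuple[float, float]:
    """Arithmetic mean (row, col) of the foreground pixel coordinates."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("empty mask")
    rows, cols = np.nonzero(mask)
    return float(rows.mean()), float(cols.mean())


def to_radial_sequence(boundary: Contour,
                       center: tuple[float, float]) -> RadialSequence:
    """Polar form (r_i, theta_i) of the boundary about the centroid.

    Radii are Euclidean distances in pixel units; angles are measured from
    the +col axis increasing toward +row and wrapped to [0, 2*pi).  The
    clockwise traced order (and hence the sequence length N = C) is kept.
    """
    v = boundary.vertices
    dr = v[:, 0] - center[0]
    dc = v[:, 1] - center[1]
    r = np.hypot(dr, dc)
    if np.any(r < 1e-9):
        raise ValidationError("centroid coincides with a boundary pixel")
    theta = np.mod(np.arctan2(dr, dc), 2 * np.pi)
    theta[theta >= 2 * np.pi] = 0.0
    return RadialSequence(r, theta, clockwise=boundary.clockwise)


def build_roi(image: GreyImage | np.ndarray,
              contour_or_mask: Contour | np.ndarray) -> LesionROI:
    """Assemble the canonical LesionROI from an image and a contour or mask."""
    img = image if isinstance(image, GreyImage) else GreyImage(np.asarray(image))
    if isinstance(contour_or_mask, Contour):
        mask = rasterize_contour(contour_or_mask, img.shape)
    else:
        mask = np.asarray(contour_or_mask, dtype=bool)
        if mask.shape != img.shape:
            raise ValidationError(
                f"mask shape {mask.shape} does not match image shape {img.shape}")
        if not mask.any():
            raise ValidationError("empty mask")
        mask = ndimage.binary_fill_holes(mask)
        _, n_comp = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
        if n_comp != 1:
            raise ValidationError(f"mask has {n_comp} components, expected 1")
    bnd = trace_boundary(mask)
    ctr = centroid(mask)
    bbox_r = (bnd.vertices[:, 0].min(), bnd.vertices[:, 0].max())
    bbox_c = (bnd.vertices[:, 1].min(), bnd.vertices[:, 1].max())
    if not (bbox_r[0] <= ctr[0] <= bbox_r[1] and bbox_c[0] <= ctr[1] <= bbox_c[1]):
        raise ValidationError("centroid outside the mask bounding box")
    return LesionROI(image=img, mask=mask, boundary=bnd, centroid=ctr)
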