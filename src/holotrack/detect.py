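"""Single-hologram 3D particle detection via computationally rendered dark fields.

Pipeline for one hologram (all steps exposed individually):

1. :func:`remove_background` — strip the slowly varying illumination term,
   leaving a zero-mean "dark hologram" that carries only the fringes.
2. :func:`render_dark_volume` — angular-spectrum backpropagation of the
   dark hologram to a set of planes; the modulus of each backpropagated
   field forms the dark volume DV(x, y, z): objects bright, empty space dark.
3. :func:`gradient_volume` — squared lateral gradient magnitude
   GV = (∂DV/∂x)² + (∂DV/∂y)² per plane; GV peaks at in-focus object
   edges, the sharpness signal used for axial localization.
4. :func:`max_projections` — per-pixel maxima of DV and GV along z
   (M_DV, M_GV) and the z of the GV maximum (Z_GV).
5. :func:`detection_image` — I = M_DV · M_GV, rescaled to [0, 1]; combines
   the in-object brightness of M_DV with the edge enhancement of M_GV.
6. :func:`binarize` / :func:`segment` — locally adaptive threshold, small
   object removal, hole filling, 8-connected labeling.
7. :func:`locate_z` — per object, the M_GV-weighted mean of Z_GV over the
   object's pixels (continuous, not snapped to the plane grid).
8. :func:`locate_xy` — the DV argmax pixel within the object mask at the
   plane nearest the object's z.
9. :func:`compose_edof` — an all-in-focus 2D image: per-pixel minimum of
   DV over z (suppressing twin-image haze) with each object's mask filled
   from its own focal plane.

Objects overlapping in (x, y) at different depths are reported as a single
detection — an inherent limitation of projection-based detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .config import OpticalConfig
from .errors import ConfigError, DegenerateInputError, DimensionError
from .optics import ComplexField, angular_spectrum_propagate
from .simulate import HologramFrame

logger = logging.getLogger(__name__)


@dataclass
class DarkVolume:
    """Stack of backpropagated dark-field amplitudes.

    values has shape (rows, cols, n_planes); plane_z holds the strictly
    increasing backpropagation distances (µm) of the planes.
    """

    values: np.ndarray
    plane_z: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.plane_z = np.asarray(self.plane_z, dtype=float)
        if self.values.ndim != 3:
            raise DimensionError(f"dark volume must be 3D, got {self.values.shape}")
        if self.plane_z.ndim != 1 or len(self.plane_z) != self.values.shape[2]:
            raise DimensionError("plane_z length must equal the number of planes")
        if len(self.plane_z) < 2:
            raise ConfigError("dark volume needs at least two planes")
        if np.any(np.diff(self.plane_z) <= 0):
            raise ConfigError("plane_z must be strictly increasing")


@dataclass
class GradientVolume:
    """Squared lateral gradient magnitude of a dark volume.

    values holds (∂DV/∂x)² + (∂DV/∂y)² — the focus metric itself — with the
    same shape and plane set as the parent dark volume.  The squared form
    concentrates weight on sharp in-focus edges; taking a square root would
    flatten the weighting and measurably drag the axial estimate toward the
    defocus haze.
    """

    values: np.ndarray
    plane_z: np.ndarray


@dataclass
class MaxMaps:
    """Per-pixel maxima along z of DV and GV, plus the z of the GV maximum."""

    m_dv: np.ndarray
    m_gv: np.ndarray
    z_gv: np.ndarray


@dataclass
class Detection:
    """A localized object in one frame; lengths in µm, area in pixels."""

    object_id: int
    x: float
    y: float
    z: float
    frame_index: int = 0
    mask_area: int = 0


@dataclass
class SegmentedObject:
    """Pixel set of one connected component (row-major ordered coordinates)."""

    label: int
    rows: np.ndarray
    cols: np.ndarray

    @property
    def area(self) -> int:
        return len(self.rows)


@dataclass
class TrackerParams:
    """Tuning knobs of the per-frame detection pipeline.

    plane_z: backpropagation distances of the dark-volume planes (µm).
    background_mode: "lowpass" (per-frame Gaussian normalization) or
        "temporal" (division by the per-pixel median over the sequence).
    sigma_bg: Gaussian sigma (pixels) of the lowpass background estimate;
        None picks 1/16 of the smaller image dimension.
    window: adaptive-threshold local-mean window (pixels, odd); None picks
        1/8 of the smaller image dimension.
    sensitivity: threshold offset in units of the global std of I.
    min_area: discard components smaller than this (pixels).
    border_margin: drop detections closer than this (µm) to a lateral edge.
    """

    plane_z: np.ndarray = field(default_factory=lambda: np.linspace(150.0, 260.0, 121))
    background_mode: str = "lowpass"
    sigma_bg: float | None = None
    window: int | None = None
    sensitivity: float = 1.0
    min_area: int = 4
    border_margin: float = 0.0
    compute_edof: bool = False


def default_plane_set(z2: float, sample_depth: float, n_planes: int = 121) -> np.ndarray:
    """Uniform backpropagation distances spanning the sample depth."""
    return np.linspace(z2, z2 + sample_depth, n_planes)


def remove_background(
    hologram: HologramFrame,
    mode: str = "lowpass",
    sigma_bg: float | None = None,
    stack: list[HologramFrame] | None = None,
) -> np.ndarray:
    """Return the zero-mean dark hologram with the background term removed.

    "lowpass" divides by a Gaussian-smoothed copy of the frame itself
    (single-frame operation); "temporal" divides by the per-pixel median
    over a sequence, which cancels static artifacts exactly but requires
    moving objects.  Both subtract 1 afterwards, so a fringe-free hologram
    maps to zero.
    """
    h = hologram.intensity
    if not np.any(h > 0):
        raise DegenerateInputError("hologram carries no positive intensity")
    if mode == "lowpass":
        if sigma_bg is None:
            sigma_bg = min(h.shape) / 16.0
        smooth = ndimage.gaussian_filter(h, sigma_bg)
        smooth = np.where(smooth > 0, smooth, np.finfo(float).tiny)
        return h / smooth - 1.0
    if mode == "temporal":
        if not stack:
            raise ConfigError("temporal background removal needs the frame stack")
        median = np.median(np.stack([f.intensity for f in stack]), axis=0)
        median = np.where(median > 0, median, np.finfo(float).tiny)
        return h / median - 1.0
    raise ConfigError(f"unknown background mode {mode!r}")


def render_dark_volume(
    dark_hologram: np.ndarray,
    plane_z: np.ndarray,
    config: OpticalConfig,
    dtype: np.dtype | type = np.float32,
) -> DarkVolume:
    """Backpropagate the dark hologram to every plane and store |field|.

    The FFT of the dark hologram is computed once; each plane costs one
    transfer-function multiply and one inverse FFT.
    """
    plane_z = np.asarray(plane_z, dtype=float)
    if plane_z.size == 0:
        raise ConfigError("plane set is empty")
    rows, cols = dark_hologram.shape
    out = np.empty((rows, cols, plane_z.size), dtype=dtype)
    fld = ComplexField(np.asarray(dark_hologram, dtype=complex), 0.0)
    from .optics import _axial_wavenumber, _check_field  # shared frequency grid

    _check_field(fld, config)
    kz, mask = _axial_wavenumber((rows, cols), config)
    spectrum = np.fft.fft2(fld.values)
    spectrum[~mask] = 0.0
    for i, z in enumerate(plane_z):
        back = np.fft.ifft2(spectrum * np.exp(-1j * z * kz))
        out[:, :, i] = np.abs(back)
    return DarkVolume(out, plane_z)


def gradient_volume(dv: DarkVolume, pixel_pitch: float) -> GradientVolume:
    """Per-plane squared lateral gradient magnitude of the dark volume.

    Central finite differences with replicated borders; gradients are in
    DV units per µm, so values carry (DV/µm)².
    """
    v = dv.values
    padded_y = np.pad(v, ((1, 1), (0, 0), (0, 0)), mode="edge")
    gy = (padded_y[2:] - padded_y[:-2]) / (2.0 * pixel_pitch)
    padded_x = np.pad(v, ((0, 0), (1, 1), (0, 0)), mode="edge")
    gx = (padded_x[:, 2:] - padded_x[:, :-2]) / (2.0 * pixel_pitch)
    gv = gx**2 + gy**2
    return GradientVolume(gv.astype(v.dtype, copy=False), dv.plane_z)


def max_projections(dv: DarkVolume, gv: GradientVolume) -> MaxMaps:
    """Per-pixel maxima of DV and GV along z and the z of the GV maximum.

    Ties in the GV maximum resolve to the smallest z.
    """
    if gv.values.shape != dv.values.shape:
        raise DimensionError("gradient volume shape does not match dark volume")
    m_dv = dv.values.max(axis=2)
    idx = gv.values.argmax(axis=2)  # first occurrence = smallest z
    m_gv = np.take_along_axis(gv.values, idx[:, :, None], axis=2)[:, :, 0]
    z_gv = dv.plane_z[idx]
    return MaxMaps(m_dv=m_dv, m_gv=m_gv, z_gv=z_gv)


def detection_image(maps: MaxMaps) -> np.ndarray:
    """Element-wise product M_DV · M_GV rescaled to [0, 1] by its maximum."""
    img = np.asarray(maps.m_dv, dtype=float) * np.asarray(maps.m_gv, dtype=float)
    peak = img.max()
    if peak > 0:
        img = img / peak
    return img


def binarize(
    image: np.ndarray,
    window: int | None = None,
    sensitivity: float = 1.0,
    min_area: int = 4,
) -> np.ndarray:
    """Locally adaptive threshold of the detection image.

    A pixel is foreground iff it exceeds the local mean over ``window``
    plus ``sensitivity`` times the global standard deviation; components
    smaller than ``min_area`` pixels are removed and holes filled.  The
    local offset keeps faint objects detectable next to bright ones.
    """
    if window is None:
        window = max(3, (min(image.shape) // 8) | 1)
    if window > min(image.shape):
        raise ConfigError(
            f"window {window} exceeds image size {min(image.shape)}"
        )
    local_mean = ndimage.uniform_filter(image.astype(float), size=window)
    bw = image > local_mean + sensitivity * float(image.std())
    if min_area > 1:
        labels, n = ndimage.label(bw, structure=np.ones((3, 3), dtype=int))
        if n:
            counts = np.bincount(labels.ravel())
            small = np.nonzero(counts < min_area)[0]
            bw[np.isin(labels, small[small > 0])] = False
    return ndimage.binary_fill_holes(bw)


def segment(bw: np.ndarray) -> list[SegmentedObject]:
    """8-connected component labeling of the binary mask.

    Objects are ordered by their first pixel in row-major scan order
    (top-most, then left-most).
    """
    labels, n = measure.label(bw, connectivity=2, return_num=True)
    objects = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        objects.append(SegmentedObject(label=lab, rows=rows, cols=cols))
    objects.sort(key=lambda o: (int(o.rows[0]), int(o.cols[0])))
    for new_label, obj in enumerate(objects, start=1):
        obj.label = new_label
    return objects


def locate_z(obj: SegmentedObject, maps: MaxMaps) -> float:
    """Gradient-weighted mean axial position of one object.

    z_j = Σ M_GV(x,y)·Z_GV(x,y) / Σ M_GV(x,y) over the object's pixels.
    """
    w = np.asarray(maps.m_gv, dtype=float)[obj.rows, obj.cols]
    total = w.sum()
    if total <= 0:
        raise DegenerateInputError(
            f"object {obj.label}: gradient weights sum to zero"
        )
    z = np.asarray(maps.z_gv, dtype=float)[obj.rows, obj.cols]
    return float((w * z).sum() / total)


def locate_xy(
    obj: SegmentedObject, dv: DarkVolume, z_j: float, pixel_pitch: float
) -> tuple[float, float]:
    """Lateral position: the DV argmax pixel in the object mask at the
    stack plane nearest z_j (ties toward smaller z; argmax ties resolve
    to the first pixel in row-major order)."""
    k = int(np.argmin(np.abs(dv.plane_z - z_j)))
    vals = dv.values[obj.rows, obj.cols, k]
    i = int(np.argmax(vals))
    return (float(obj.cols[i]) * pixel_pitch, float(obj.rows[i]) * pixel_pitch)


def compose_edof(
    detections: list[Detection],
    dv: DarkVolume,
    objects: list[SegmentedObject],
    dilate_px: int = 2,
) -> np.ndarray:
    """Extended-depth-of-field image: every object rendered in focus.

    Starts from the per-pixel minimum of DV over z (which suppresses the
    defocused twin-image haze) and pastes each object's dark-field values
    from the plane nearest its own z, inside its mask dilated by
    ``dilate_px`` pixels.
    """
    out = dv.values.min(axis=2).astype(float)
    shape = out.shape
    for det, obj in zip(detections, objects):
        k = int(np.argmin(np.abs(dv.plane_z - det.z)))
        mask = np.zeros(shape, dtype=bool)
        mask[obj.rows, obj.cols] = True
        if dilate_px > 0:
            mask = ndimage.binary_dilation(mask, iterations=dilate_px)
        out[mask] = dv.values[:, :, k][mask]
    return out


@dataclass
class FrameResult:
    """Everything the per-frame pipeline produced."""

    detections: list[Detection]
    objects: list[SegmentedObject]
    edof: np.ndarray | None = None


def detect_frame(
    hologram: HologramFrame,
    params: TrackerParams,
    config: OpticalConfig,
    stack: list[HologramFrame] | None = None,
) -> FrameResult:
    """Run the full detection pipeline on one hologram."""
    dark = remove_background(
        hologram, mode=params.background_mode, sigma_bg=params.sigma_bg, stack=stack
    )
    dv = render_dark_volume(dark, params.plane_z, config)
    gv = gradient_volume(dv, config.pixel_pitch)
    maps = max_projections(dv, gv)
    img = detection_image(maps)
    bw = binarize(img, params.window, params.sensitivity, params.min_area)
    objects = segment(bw)
    detections: list[Detection] = []
    kept_objects: list[SegmentedObject] = []
    fov_x, fov_y = config.field_of_view
    for obj in objects:
        try:
            z_j = locate_z(obj, maps)
        except DegenerateInputError:
            logger.info(
                "frame %d: dropped degenerate object %d", hologram.frame_index, obj.label
            )
            continue
        x_j, y_j = locate_xy(obj, dv, z_j, config.pixel_pitch)
        m = params.border_margin
        if m > 0 and not (m <= x_j <= fov_x - m and m <= y_j <= fov_y - m):
            continue
        detections.append(
            Detection(
                object_id=len(detections),
                x=x_j,
                y=y_j,
                z=z_j,
                frame_index=hologram.frame_index,
                mask_area=obj.area,
            )
        )
        kept_objects.append(obj)
    edof = compose_edof(detections, dv, kept_objects) if params.compute_edof else None
    return FrameResult(detections=detections, objects=kept_objects, edof=edof)
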