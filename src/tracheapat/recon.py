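"""Universal back-projection reconstruction and point-spread quantification.

Universal back-projection (UBP) applies the filtered term q(t) = g(t) -
t * dg/dt to each element trace and sums it over elements at the per-pixel
time of flight t = |x - r_k| / c.  For an arc detection geometry this is the
standard inversion and sharpens the boundaries the downstream morphometry
relies on.  Reconstructions of band-limited data are bipolar; ``envelope``
provides the nonnegative magnitude used for segmentation and display.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import tifffile
from scipy.signal import hilbert

from .errors import CoverageError, DetectionError
from .forward import ArrayGeometry, Sinogram, element_positions


@dataclass(frozen=True)
class GridSpec:
    """Reconstruction raster: ``origin`` is the center of pixel [0, 0] (mm)."""

    shape: tuple = (256, 256)  # (ny, nx)
    spacing: float = 0.05  # mm
    origin: tuple = (-6.375, -6.375)  # mm

    @classmethod
    def centered(cls, fov_mm: float = 12.8, spacing: float = 0.05,
                 center=(0.0, 0.0)) -> "GridSpec":
        n = int(round(fov_mm / spacing))
        o = -(n - 1) / 2.0 * spacing
        return cls(shape=(n, n), spacing=spacing,
                   origin=(center[0] + o, center[1] + o))

    def coordinates(self):
        ny, nx = self.shape
        x = self.origin[0] + self.spacing * np.arange(nx)
        y = self.origin[1] + self.spacing * np.arange(ny)
        return np.meshgrid(x, y)


@dataclass
class ReconImage:
    """Reconstructed 2-D initial-pressure map (signed, a.u.)."""

    pixels: np.ndarray  # (ny, nx)
    spacing: float  # mm
    origin: tuple  # mm
    wavelength_nm: float = 0.0

    def save_tiff(self, path):
        meta = {"spacing_mm": self.spacing, "origin_mm": list(self.origin),
                "wavelength_nm": self.wavelength_nm}
        tifffile.imwrite(path, self.pixels.astype(np.float32),
                         photometric="minisblack",
                     description=json.dumps(meta))

    @classmethod
    def load_tiff(cls, path) -> "ReconImage":
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray().astype(float)
            meta = json.loads(tf.pages[0].description)
        return cls(pixels=data, spacing=float(meta["spacing_mm"]),
                   origin=tuple(meta["origin_mm"]),
                   wavelength_nm=float(meta["wavelength_nm"]))


def save_stack(images, path):
    """Multi-wavelength stack as a multi-page float32 TIFF."""
    meta = {"spacing_mm": images[0].spacing, "origin_mm": list(images[0].origin),
            "wavelengths_nm": [im.wavelength_nm for im in images]}
    tifffile.imwrite(path, np.stack([im.pixels for im in images]).astype(np.float32),
                     photometric="minisblack",
                     description=json.dumps(meta))


def load_stack(path) -> list:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray().astype(float)
        meta = json.loads(tf.pages[0].description)
    return [ReconImage(pixels=data[i], spacing=float(meta["spacing_mm"]),
                       origin=tuple(meta["origin_mm"]), wavelength_nm=w)
            for i, w in enumerate(meta["wavelengths_nm"])]


# cache of pixel-to-element distance/weight matrices, keyed by (geometry, grid)
_DISTANCE_CACHE: dict = {}


def _distances_and_weights(geometry: ArrayGeometry, grid: GridSpec) -> tuple:
    """Per-pixel element distances and normalized solid-angle weights.

    Each element subtends, as seen from pixel x, an angle proportional to
    cos(alpha) / d where alpha is the angle between the element's inward
    normal and the direction to x.  These are the back-projection weights of
    universal back-projection, normalized so they sum to one at the array
    focus; a pixel whose detection aperture subtends less angle (the open
    side of the arc) keeps its physically lower weight sum.
    """
    key = (geometry, grid)
    if key not in _DISTANCE_CACHE:
        xx, yy = grid.coordinates()
        elems = element_positions(geometry)
        normals = -elems / np.linalg.norm(elems, axis=1, keepdims=True)
        px = np.column_stack([xx.ravel(), yy.ravel()]).astype(np.float32)
        d = np.empty((px.shape[0], elems.shape[0]), dtype=np.float32)
        w = np.empty_like(d)
        for k, (ek, nk) in enumerate(zip(elems, normals)):
            dx = px[:, 0] - ek[0]
            dy = px[:, 1] - ek[1]
            d[:, k] = np.hypot(dx, dy)
            w[:, k] = np.maximum(dx * nk[0] + dy * nk[1], 0.0) / d[:, k] ** 2
        # at the focus cos(alpha) = 1 and d = R, so the raw sum is N / R^2
        w *= geometry.arc_radius_mm**2 / geometry.n_elements
        if len(_DISTANCE_CACHE) > 8:  # bound the cache
            _DISTANCE_CACHE.clear()
        _DISTANCE_CACHE[key] = (d, w)
    return _DISTANCE_CACHE[key]


def backproject(sinogram: Sinogram, grid: GridSpec = GridSpec()) -> ReconImage:
    """Universal back-projection of one sinogram onto ``grid``.

    Solid-angle weights are normalized to sum to one at the array focus; the time
    derivative is computed by central differences, and traces are linearly
    interpolated at the per-pixel time of flight.
    """
    geometry = sinogram.geometry
    g = np.asarray(sinogram.signals, dtype=float)
    t = np.asarray(sinogram.time_us, dtype=float)
    dt = geometry.dt_us
    c = geometry.c_mm_us

    d, w = _distances_and_weights(geometry, grid)
    t_need = d.max() / c
    if t_need > t[-1]:
        raise CoverageError(
            f"sinogram covers {t[-1]:.2f} us but the grid needs {t_need:.2f} us")

    dg = np.gradient(g, dt, axis=1)
    q = g - t[None, :] * dg

    npx = d.shape[0]
    img = np.zeros(npx)
    fs = geometry.sampling_rate_mhz
    t0 = t[0]
    nt = t.size
    for k in range(geometry.n_elements):
        x = (d[:, k] / c - t0) * fs
        i0 = np.floor(x).astype(np.intp)
        np.clip(i0, 0, nt - 2, out=i0)
        frac = x - i0
        qk = q[k]
        img += w[:, k] * (qk[i0] * (1.0 - frac) + qk[i0 + 1] * frac)
    return ReconImage(pixels=img.reshape(grid.shape), spacing=grid.spacing,
                      origin=grid.origin, wavelength_nm=sinogram.wavelength_nm)


def envelope(data, axis: int | None = None) -> np.ndarray:
    """Nonnegative magnitude of a trace or image.

    For 1-D data (or when ``axis`` is given) this is the magnitude of the
    analytic signal along that axis; for images it is the absolute value.
    """
    arr = np.asarray(data, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("envelope requires finite input")
    if arr.ndim == 1 or axis is not None:
        return np.abs(hilbert(arr, axis=axis if axis is not None else -1))
    return np.abs(arr)


def isotropic_envelope(image: np.ndarray) -> np.ndarray:
    """Orientation-independent envelope via the monogenic (Riesz) signal.

    Band-limited reconstructions oscillate radially; the plain absolute
    value rectifies those oscillations into fringes.  The monogenic
    magnitude sqrt(f^2 + |R f|^2), with R the spiral-phase Riesz transform,
    demodulates the local oscillation regardless of its direction and gives
    the smooth ridge profiles the morphometry stage peaks-picks on.
    """
    img = np.asarray(image, dtype=float)
    ny, nx = img.shape
    ky = np.fft.fftfreq(ny)[:, None]
    kx = np.fft.fftfreq(nx)[None, :]
    k = np.hypot(kx, ky)
    k[0, 0] = 1.0
    riesz = np.fft.ifft2(np.fft.fft2(img) * (kx + 1j * ky) / k)
    return np.sqrt(img**2 + np.abs(riesz) ** 2)


def _fwhm_1d(profile: np.ndarray, peak_idx: int, spacing: float) -> float:
    """Sub-pixel full width at half maximum around ``peak_idx``."""
    half = profile[peak_idx] / 2.0

    def crossing(direction: int) -> float:
        i = peak_idx
        while 0 < i < profile.size - 1:
            j = i + direction
            if profile[j] < half:
                # linear interpolation between samples i and j
                frac = (profile[i] - half) / (profile[i] - profile[j])
                return abs(i - peak_idx) + frac
            i = j
        raise DetectionError("half-maximum crossing not found inside the image")

    return (crossing(-1) + crossing(+1)) * spacing


def psf_fwhm(image: ReconImage, center=None, window_mm: float = 1.5) -> tuple:
    """FWHM (um) of the envelope peak along x and y.

    Searches for the dominant peak inside a window around ``center``
    (default: image center) and measures the half-maximum width of the
    horizontal and vertical profiles through it with sub-pixel
    interpolation of the crossings.
    """
    env = envelope(image.pixels)
    ny, nx = env.shape
    if center is None:
        cy, cx = ny // 2, nx // 2
    else:
        cx = int(round((center[0] - image.origin[0]) / image.spacing))
        cy = int(round((center[1] - image.origin[1]) / image.spacing))
    w = max(1, int(round(window_mm / image.spacing)))
    y0, y1 = max(0, cy - w), min(ny, cy + w + 1)
    x0, x1 = max(0, cx - w), min(nx, cx + w + 1)
    sub = env[y0:y1, x0:x1]
    background = np.median(env)
    if sub.max() <= 5.0 * background or sub.max() == 0:
        raise DetectionError("no peak above background in the search window")
    py, px = np.unravel_index(np.argmax(sub), sub.shape)
    py += y0
    px += x0
    fwhm_x = _fwhm_1d(env[py, :], px, image.spacing) * 1000.0
    fwhm_y = _fwhm_1d(env[:, px], py, image.spacing) * 1000.0
    return fwhm_x, fwhm_y
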