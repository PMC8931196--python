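"""Band-limited photoacoustic forward model for a concave arc array.

The detector is a 128-element half-arc (180 degrees, 50 mm radius) of
point-like elements with a 5 MHz center-frequency band-pass response,
sampled at 50 MHz.  The forward model is 2-D (single cross-sectional
slice): each source pixel contributes an impulse at its time of flight with
1/(2*pi*d) cylindrical spreading, and the ideal broadband trace is convolved
with the electro-mechanical impulse response, modelled as the derivative of
a Gaussian-windowed sinusoid with a configurable fractional bandwidth.
White Gaussian noise is added per simulated frame and frames are averaged
(10 by default), emulating frame averaging used to suppress physiological
motion and boost SNR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import h5py
import numpy as np
from scipy.signal import fftconvolve

from .errors import GeometryError
from .optics import ExtinctionTable, PressureMap, pressure_from_map
from .phantom import ChromophoreMap


@dataclass(frozen=True)
class ArrayGeometry:
    """Concave detection-arc geometry and acquisition constants."""

    n_elements: int = 128
    arc_span_deg: float = 180.0
    arc_radius_mm: float = 50.0
    center_frequency_mhz: float = 5.0
    sampling_rate_mhz: float = 50.0
    speed_of_sound_m_s: float = 1500.0
    fractional_bandwidth: float = 0.7

    def __post_init__(self):
        if self.n_elements < 2:
            raise ValueError("need at least 2 elements")
        nyq_need = 2.0 * self.center_frequency_mhz * (1 + self.fractional_bandwidth / 2)
        if self.sampling_rate_mhz <= nyq_need:
            raise ValueError(
                f"sampling rate {self.sampling_rate_mhz} MHz under-samples the "
                f"{self.center_frequency_mhz} MHz band (need > {nyq_need} MHz)")
        if not 0 < self.fractional_bandwidth < 2:
            raise ValueError("fractional bandwidth must lie in (0, 2)")

    @property
    def c_mm_us(self) -> float:
        """Speed of sound in mm/us."""
        return self.speed_of_sound_m_s / 1000.0

    @property
    def dt_us(self) -> float:
        return 1.0 / self.sampling_rate_mhz


@dataclass
class Sinogram:
    """Per-element pressure time series with acquisition metadata."""

    signals: np.ndarray  # (n_elements, n_samples), a.u.
    time_us: np.ndarray  # shared uniform axis starting at >= 0
    wavelength_nm: float
    n_averages: int
    geometry: ArrayGeometry
    seed: int | None = None
    noise_sd: float = 0.0

    def save_h5(self, path):
        with h5py.File(path, "w") as f:
            f.create_dataset("signals", data=self.signals)
            f.create_dataset("time_us", data=self.time_us)
            f.attrs["wavelength_nm"] = self.wavelength_nm
            f.attrs["n_averages"] = self.n_averages
            f.attrs["noise_sd"] = self.noise_sd
            f.attrs["seed"] = -1 if self.seed is None else int(self.seed)
            for k, v in asdict(self.geometry).items():
                f.attrs[f"geometry_{k}"] = v

    @classmethod
    def load_h5(cls, path) -> "Sinogram":
        with h5py.File(path, "r") as f:
            geom = ArrayGeometry(**{
                k[len("geometry_"):]: (int(v) if k == "geometry_n_elements" else float(v))
                for k, v in f.attrs.items() if k.startswith("geometry_")})
            seed = int(f.attrs["seed"])
            return cls(signals=f["signals"][...], time_us=f["time_us"][...],
                       wavelength_nm=float(f.attrs["wavelength_nm"]),
                       n_averages=int(f.attrs["n_averages"]),
                       geometry=geom, seed=None if seed == -1 else seed,
                       noise_sd=float(f.attrs["noise_sd"]))


def element_positions(geometry: ArrayGeometry) -> np.ndarray:
    """(n, 2) element centers in mm, uniformly spaced in angle over the arc.

    The arc is centered on the +y axis: a 180-degree span covers polar
    angles 0..180 degrees (the upper half plane), leaving the -y side open.
    All elements lie at ``arc_radius_mm`` from the origin (the array focus).
    """
    span = np.deg2rad(geometry.arc_span_deg)
    angles = np.pi / 2 + np.linspace(-span / 2, span / 2, geometry.n_elements)
    return geometry.arc_radius_mm * np.column_stack([np.cos(angles), np.sin(angles)])


def impulse_response(geometry: ArrayGeometry) -> np.ndarray:
    """Transducer impulse response sampled at the acquisition rate.

    Derivative of a Gaussian-windowed sinusoid at the center frequency; the
    Gaussian is sized so the spectral FWHM equals fractional_bandwidth times
    the center frequency.  The kernel has odd length and is centered, so
    'same'-mode convolution introduces no time shift; it is normalized to
    unit peak amplitude.
    """
    fc = geometry.center_frequency_mhz
    sigma_f = geometry.fractional_bandwidth * fc / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_t = 1.0 / (2.0 * np.pi * sigma_f)
    dt = geometry.dt_us
    n_half = int(np.ceil(4.0 * sigma_t / dt))
    t = np.arange(-n_half, n_half + 1) * dt
    w = 2.0 * np.pi * fc
    g = np.exp(-t**2 / (2.0 * sigma_t**2))
    h = g * (w * np.cos(w * t) - (t / sigma_t**2) * np.sin(w * t))
    return h / np.max(np.abs(h))


def _active_pixels(p0: PressureMap):
    """Coordinates (mm) and weighted amplitudes of nonzero source pixels."""
    arr = np.asarray(p0.p0, dtype=float)
    iy, ix = np.nonzero(arr)
    x = p0.origin[0] + p0.spacing * ix
    y = p0.origin[1] + p0.spacing * iy
    area = p0.spacing**2
    return np.column_stack([x, y]), arr[iy, ix] * area


def _time_axis(geometry: ArrayGeometry, max_source_radius_mm: float) -> np.ndarray:
    t_max = (geometry.arc_radius_mm + max_source_radius_mm) / geometry.c_mm_us
    n = int(np.ceil(t_max / geometry.dt_us)) + 64  # margin for the band-pass kernel
    return np.arange(n) * geometry.dt_us


def ideal_traces(p0: PressureMap, geometry: ArrayGeometry) -> tuple:
    """Noise-free band-limited traces g_k(t); returns (signals, time_us)."""
    pos, amp = _active_pixels(p0)
    ny, nx = p0.p0.shape
    xs = (p0.origin[0], p0.origin[0] + p0.spacing * (nx - 1))
    ys = (p0.origin[1], p0.origin[1] + p0.spacing * (ny - 1))
    corner_radius = max(np.hypot(x, y) for x in xs for y in ys)
    if pos.size:
        radius = np.hypot(pos[:, 0], pos[:, 1])
        if radius.max() >= geometry.arc_radius_mm:
            raise GeometryError(
                f"source pixel at {radius.max():.1f} mm lies outside the "
                f"{geometry.arc_radius_mm} mm detection arc")
    time_us = _time_axis(geometry, min(corner_radius, geometry.arc_radius_mm))
    nt = time_us.size
    elems = element_positions(geometry)
    signals = np.zeros((geometry.n_elements, nt))
    if pos.size:
        fs = geometry.sampling_rate_mhz
        c = geometry.c_mm_us
        for k, ek in enumerate(elems):
            d = np.hypot(pos[:, 0] - ek[0], pos[:, 1] - ek[1])
            idx = np.rint(d / c * fs).astype(np.intp)
            signals[k] = np.bincount(idx, weights=amp / (2.0 * np.pi * d),
                                     minlength=nt)[:nt]
        h = impulse_response(geometry)
        signals = fftconvolve(signals, h[None, :], mode="same", axes=1)
    return signals, time_us


def add_averaged_noise(signals: np.ndarray, noise_sd: float, n_averages: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Average ``n_averages`` frames of signal + white Gaussian noise."""
    if n_averages < 1:
        raise ValueError("n_averages must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd == 0:
        return signals.copy()
    frames = signals[None] + rng.normal(0.0, noise_sd,
                                        (n_averages,) + signals.shape)
    return frames.mean(axis=0)


def simulate_signals(p0: PressureMap, geometry: ArrayGeometry = ArrayGeometry(),
                     n_averages: int = 10, noise_sd: float = 0.0,
                     seed=None) -> Sinogram:
    """Simulate one frame-averaged acquisition of a pressure map."""
    ideal, time_us = ideal_traces(p0, geometry)
    rng = np.random.default_rng(seed)
    signals = add_averaged_noise(ideal, noise_sd, n_averages, rng)
    return Sinogram(signals=signals, time_us=time_us,
                    wavelength_nm=p0.wavelength_nm, n_averages=n_averages,
                    geometry=geometry, seed=seed, noise_sd=noise_sd)


def acquire_multiwavelength(cmap: ChromophoreMap,
                            geometry: ArrayGeometry = ArrayGeometry(),
                            wavelengths=(760, 840, 910),
                            table: ExtinctionTable | None = None,
                            noise_sd: float = 0.0,
                            relative_noise: float | None = None,
                            n_averages: int = 10, seed=None,
                            grueneisen: float = 1.0, fluence=None) -> list:
    """One sinogram per wavelength under a common geometry and noise model.

    If ``relative_noise`` is given, the per-frame noise sd is that fraction
    of the peak noiseless amplitude across all wavelengths (a single
    absolute level shared by every wavelength); otherwise ``noise_sd`` is
    used as an absolute level.
    """
    if table is None:
        table = ExtinctionTable.default()
    ideal = []
    for w in wavelengths:
        p0 = pressure_from_map(cmap, w, table, fluence=fluence,
                               grueneisen=grueneisen)
        ideal.append(ideal_traces(p0, geometry))
    if relative_noise is not None:
        peak = max(np.max(np.abs(sig)) for sig, _ in ideal)
        noise_sd = relative_noise * peak

    children = np.random.SeedSequence(seed).spawn(len(wavelengths))
    out = []
    for (sig, t), w, child in zip(ideal, wavelengths, children):
        rng = np.random.default_rng(child)
        avg = add_averaged_noise(sig, noise_sd, n_averages, rng)
        out.append(Sinogram(signals=avg, time_us=t, wavelength_nm=w,
                            n_averages=n_averages, geometry=geometry,
                            seed=None, noise_sd=noise_sd))
    return out
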