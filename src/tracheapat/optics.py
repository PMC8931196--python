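"""Optical absorption and photoacoustic source generation.

Maps chromophore concentration grids to absorption coefficients through the
linear mixing model mu_a(lambda) = sum_i eps_i(lambda) * c_i, and to initial
acoustic pressure through the photoacoustic relation p0 = Gamma * mu_a * Phi
(Grueneisen efficiency times absorbed fluence).  Fluence defaults to a
uniform unit field, so concentrations recovered downstream are relative
(Gamma*Phi-scaled), as clinical multispectral optoacoustic systems report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import SpectralLookupError
from .phantom import CHROMOPHORES, ChromophoreMap

#: laser wavelengths of the default three-wavelength acquisition (nm)
DEFAULT_WAVELENGTHS = (760, 840, 910)


@dataclass(frozen=True)
class ExtinctionTable:
    """Extinction coefficients eps_i(lambda) in cm^-1 per concentration unit."""

    entries: tuple  # ((chromophore, wavelength_nm, epsilon), ...)

    def __post_init__(self):
        if any(e[2] < 0 for e in self.entries):
            raise ValueError("extinction coefficients must be non-negative")

    @property
    def wavelengths(self) -> tuple:
        return tuple(sorted({e[1] for e in self.entries}))

    @property
    def chromophores(self) -> tuple:
        present = {e[0] for e in self.entries}
        return tuple(c for c in CHROMOPHORES if c in present) + tuple(
            sorted(present - set(CHROMOPHORES)))

    def epsilon(self, chromophore: str, wavelength_nm: float) -> float:
        for c, w, eps in self.entries:
            if c == chromophore and w == wavelength_nm:
                return eps
        raise SpectralLookupError(
            f"no extinction entry for ({chromophore}, {wavelength_nm} nm); "
            "interpolation beyond listed wavelengths is not supported")

    @classmethod
    def from_csv(cls, path) -> "ExtinctionTable":
        df = pd.read_csv(path, comment="#")
        entries = tuple(
            (str(r.chromophore), float(r.wavelength_nm), float(r.epsilon))
            for r in df.itertuples())
        return cls(entries=entries)

    @classmethod
    def default(cls) -> "ExtinctionTable":
        with resources.as_file(
                resources.files("tracheapat.data") / "extinction_coefficients.csv") as p:
            return cls.from_csv(p)


@dataclass
class PressureMap:
    """Initial-pressure grid p0 (a.u.) on the same raster as its source map."""

    p0: np.ndarray  # (ny, nx), >= 0
    wavelength_nm: float
    spacing: float  # mm / pixel
    origin: tuple = (0.0, 0.0)  # mm, center of pixel [0, 0]


def absorption_map(cmap: ChromophoreMap, wavelength_nm: float,
                   table: ExtinctionTable) -> np.ndarray:
    """Pixelwise mu_a(lambda) = sum_i eps_i(lambda) * c_i, in cm^-1."""
    mu = np.zeros(cmap.shape)
    for name, grid in cmap.maps.items():
        if not np.any(grid):
            continue  # absent chromophores need no spectrum entry
        mu += table.epsilon(name, wavelength_nm) * grid
    return mu


def uniform_fluence(shape) -> np.ndarray:
    return np.ones(shape)


def exponential_fluence(cmap_or_shape, spacing: float = None, mu_eff: float = 0.0,
                        origin_y: float = None) -> np.ndarray:
    """Phi = exp(-mu_eff * depth), depth measured downward from the top row.

    ``mu_eff`` is the effective attenuation coefficient in mm^-1 (mu_eff = 0
    recovers the uniform field).  Accepts a ChromophoreMap or a bare shape
    plus spacing.
    """
    if isinstance(cmap_or_shape, ChromophoreMap):
        shape, spacing = cmap_or_shape.shape, cmap_or_shape.spacing
    else:
        shape = cmap_or_shape
        if spacing is None:
            raise ValueError("spacing required when passing a bare shape")
    depth = (shape[0] - 1 - np.arange(shape[0]))[:, None] * spacing  # mm from top
    return np.exp(-mu_eff * depth) * np.ones((1, shape[1]))


def initial_pressure(mu_a: np.ndarray, fluence=None, grueneisen: float = 1.0,
                     wavelength_nm: float = 0.0, spacing: float = 0.05,
                     origin: tuple = (0.0, 0.0)) -> PressureMap:
    """p0 = Gamma * mu_a * Phi.  ``fluence`` may be None (uniform 1),
    a scalar, or an array broadcastable to the grid."""
    if grueneisen <= 0:
        raise ValueError("Grueneisen parameter must be positive")
    phi = 1.0 if fluence is None else np.asarray(fluence, dtype=float)
    if np.any(np.asarray(phi) < 0):
        raise ValueError("fluence must be non-negative")
    p0 = grueneisen * mu_a * phi
    return PressureMap(p0=p0, wavelength_nm=wavelength_nm, spacing=spacing,
                       origin=origin)


def pressure_from_map(cmap: ChromophoreMap, wavelength_nm: float,
                      table: ExtinctionTable, fluence=None,
                      grueneisen: float = 1.0) -> PressureMap:
    """Convenience chain: concentrations -> mu_a -> p0 on the map's raster."""
    mu = absorption_map(cmap, wavelength_nm, table)
    return initial_pressure(mu, fluence=fluence, grueneisen=grueneisen,
                            wavelength_nm=wavelength_nm, spacing=cmap.spacing,
                            origin=cmap.origin)


def extinction_matrix(table: ExtinctionTable, wavelengths=DEFAULT_WAVELENGTHS,
                      chromophores=CHROMOPHORES) -> np.ndarray:
    """System matrix E with E[j, i] = eps_i(lambda_j).

    Rows follow ``wavelengths`` and columns follow ``chromophores`` in the
    order given; both orders are stable and must be used consistently by the
    unmixing stage.
    """
    return np.array([[table.epsilon(c, w) for c in chromophores]
                     for w in wavelengths])
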