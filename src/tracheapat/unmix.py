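"""Per-pixel multispectral decomposition into chromophore maps.

Solves, at every pixel, the non-negative least-squares problem
c = argmin ||E c - y||^2, c >= 0, where y is the vector of per-wavelength
envelope amplitudes and E the extinction matrix.  Four chromophores from
three wavelengths is globally underdetermined; non-negativity provides the
canonical solution.  Identifiability is a property of the composition, not
only of its size: with the bundled spectra, every mixture class the phantom
rasterizes (the HbO2/HbR vessel pair and the HbO2 + collagen + water wall)
is uniquely decodable, whereas water *without* collagen admits an equally
exact alternative representation and cannot be attributed from three
wavelengths alone.  Derived maps:
HbT = HbO2 + HbR and SO2 = HbO2 / HbT (masked at low HbT to suppress
noise-driven saturation speckle).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy.optimize import nnls

from .errors import TracheaPatError
from .optics import extinction_matrix  # noqa: F401  (re-exported convenience)
from .phantom import CHROMOPHORES

#: SO2 mask threshold: this fraction of the 99th percentile of the HbT map
SO2_MASK_FRACTION = 0.05


@dataclass
class UnmixedMaps:
    """Chromophore concentration grids plus derived hemoglobin maps."""

    maps: dict  # chromophore name -> (ny, nx) array, >= 0
    residual: np.ndarray  # per-pixel ||E c - y||
    spacing: float
    origin: tuple
    wavelengths_nm: tuple = ()

    @property
    def hbt(self) -> np.ndarray:
        return self.maps["hbo2"] + self.maps["hbr"]

    def so2(self, mask_threshold: float | None = None) -> np.ndarray:
        return oxygen_saturation(self, mask_threshold)

    def save_tiff(self, path):
        names = list(self.maps) + ["residual"]
        data = np.stack([self.maps[n] for n in self.maps] + [self.residual])
        meta = {"spacing_mm": self.spacing, "origin_mm": list(self.origin),
                "pages": names, "wavelengths_nm": list(self.wavelengths_nm)}
        tifffile.imwrite(path, data.astype(np.float32),
                         photometric="minisblack",
                     description=json.dumps(meta))
        with open(str(path) + ".json", "w") as f:
            json.dump(meta, f, indent=2)

    @classmethod
    def load_tiff(cls, path) -> "UnmixedMaps":
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray().astype(float)
            meta = json.loads(tf.pages[0].description)
        names = meta["pages"]
        maps = {n: data[i] for i, n in enumerate(names) if n != "residual"}
        return cls(maps=maps, residual=data[names.index("residual")],
                   spacing=float(meta["spacing_mm"]),
                   origin=tuple(meta["origin_mm"]),
                   wavelengths_nm=tuple(meta["wavelengths_nm"]))


def unmix(images, E: np.ndarray, chromophores=CHROMOPHORES) -> UnmixedMaps:
    """Non-negative least-squares unmixing of a co-registered stack.

    ``images`` is a sequence of ReconImage (one per wavelength, same grid);
    row j of ``E`` must correspond to images[j].  Operates on envelope
    (nonnegative) pixel values, matching the y >= 0, E >= 0, c >= 0 model.
    """
    images = list(images)
    E = np.asarray(E, dtype=float)
    if E.shape[0] != len(images):
        raise TracheaPatError(
            f"extinction matrix has {E.shape[0]} wavelength rows but the "
            f"stack holds {len(images)} images")
    shapes = {im.pixels.shape for im in images}
    if len(shapes) != 1:
        raise TracheaPatError("stack images are not co-registered (shapes differ)")

    stack = np.stack([np.abs(im.pixels) for im in images])  # (n_l, ny, nx)
    n_l, ny, nx = stack.shape
    Y = stack.reshape(n_l, -1)
    C = np.zeros((E.shape[1], ny * nx))
    res = np.zeros(ny * nx)

    # For square-or-tall systems the unconstrained solution is unique, so it
    # can shortcut NNLS wherever it is already nonnegative.  Wide systems
    # (fewer wavelengths than chromophores) go through NNLS everywhere: the
    # pseudoinverse would return the min-norm solution, not the sparse
    # nonnegative one.
    ok = np.zeros(ny * nx, dtype=bool)
    if E.shape[0] >= E.shape[1]:
        C_ls = np.linalg.pinv(E) @ Y
        ok = np.all(C_ls >= 0, axis=0)
        C[:, ok] = C_ls[:, ok]
        res[ok] = np.linalg.norm(E @ C_ls[:, ok] - Y[:, ok], axis=0)
    bad = np.nonzero(~ok)[0]
    for j in bad:
        c, r = nnls(E, Y[:, j])
        C[:, j] = c
        res[j] = r
    # exact zeros stay exactly zero
    zero = np.all(Y == 0, axis=0)
    C[:, zero] = 0.0
    res[zero] = 0.0

    maps = {name: C[i].reshape(ny, nx) for i, name in enumerate(chromophores)}
    im0 = images[0]
    return UnmixedMaps(maps=maps, residual=res.reshape(ny, nx),
                       spacing=im0.spacing, origin=im0.origin,
                       wavelengths_nm=tuple(im.wavelength_nm for im in images))


def oxygen_saturation(maps: UnmixedMaps, mask_threshold: float | None = None
                      ) -> np.ndarray:
    """SO2 = HbO2 / (HbO2 + HbR), masked (NaN) where HbT is below threshold.

    The default threshold is SO2_MASK_FRACTION of the 99th percentile of
    the HbT map, which suppresses saturation speckle in unperfused pixels.
    """
    hbt = maps.hbt
    if mask_threshold is None:
        mask_threshold = SO2_MASK_FRACTION * np.percentile(hbt, 99)
    if mask_threshold < 0:
        raise ValueError("mask threshold must be non-negative")
    so2 = np.full(hbt.shape, np.nan)
    ok = hbt >= max(mask_threshold, np.finfo(float).tiny)
    so2[ok] = maps.maps["hbo2"][ok] / hbt[ok]
    return so2


def group_contrast(maps_x: UnmixedMaps, maps_y: UnmixedMaps,
                   region_mask: np.ndarray, labels=("x", "y")) -> pd.DataFrame:
    """Mean per-chromophore signal in a region for two maps and their ratio.

    Used to check directional contrasts between disease stages (e.g.,
    collagen scar vs edema) on matched regions.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if not region_mask.any():
        raise TracheaPatError("empty region mask")
    if region_mask.shape != maps_x.residual.shape:
        raise TracheaPatError("region mask does not match the map grid")
    rows = []
    for name in maps_x.maps:
        mx = float(maps_x.maps[name][region_mask].mean())
        my = float(maps_y.maps[name][region_mask].mean())
        rows.append({"chromophore": name, f"mean_{labels[0]}": mx,
                     f"mean_{labels[1]}": my,
                     "ratio": mx / my if my != 0 else np.inf})
    return pd.DataFrame(rows)
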