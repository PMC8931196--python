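"""Parametric digital trachea phantoms.

A phantom is a 2-D tracheal cross-section modelled as a pair of concentric
disks: an air-filled lumen of radius ``lumen_radius`` surrounded by a soft-
tissue wall annulus of thickness ``wall_thickness``, optionally carrying
circular blood-vessel inclusions inside the wall.  Four cohort archetypes are
provided, mirroring the stages of benign airway stenosis:

* group A — healthy control,
* group B — mucosal edema (elevated water, thickened wall),
* group C — granulomatous hyperplasia (many vessels, thickest wall,
  smallest lumen),
* group D — cicatricial scar (elevated collagen).

Morphometric ground truth (wall thickness TWT, lumen cross-sectional area
CSA, stenosis rate SR) is stored on the phantom so downstream estimates can
be validated against it.  Chromophore composition is kept to at most three
simultaneously nonzero species per pixel so that three-wavelength spectral
unmixing of the rasterized maps is locally well-posed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import DegenerateSpecError, GeometryError

#: canonical chromophore ordering used by every map/stack in the package
CHROMOPHORES = ("hbo2", "hbr", "collagen", "water")

# Wall composition of the healthy control, as volume-fraction-like relative
# concentrations.  Soft tissue is mostly water; the tracheal wall carries a
# collagenous submucosa and a perfused mucosa.
WALL_WATER = 0.65
WALL_COLLAGEN = 0.20
WALL_HBO2 = 0.08

# Vessel inclusions are partial-volume blood: 30% blood volume fraction at
# 75% oxygen saturation (venous-to-capillary mix).
VESSEL_BLOOD_FRACTION = 0.30
VESSEL_SO2 = 0.75
VESSEL_RADIUS_MM = 0.15
#: clearance kept between an inclusion and the lumen / outer wall boundary
VESSEL_MARGIN_MM = 0.02

#: healthy-control mean lumen area, used as the stenosis-rate reference
REFERENCE_CSA_MM2 = 16.28

#: default fractional peak-to-trough CSA modulation over a respiratory cycle
RESPIRATION_DEPTH = 0.15

_TRUNCATION_RETRIES = 100


@dataclass(frozen=True)
class GroupSpec:
    """Morphometry distribution and contrast mechanism of one cohort group."""

    group_label: str
    twt_mean: float  # mm
    twt_sd: float  # mm
    csa_mean: float  # mm^2
    csa_sd: float  # mm^2
    edema_water_boost: float = 1.0
    vessel_density: int = 4
    collagen_boost: float = 1.0

    def __post_init__(self):
        if self.group_label not in {"A", "B", "C", "D"}:
            raise ValueError(f"group_label must be one of A-D, got {self.group_label!r}")
        if self.twt_mean <= 0 or self.csa_mean <= 0:
            raise ValueError("twt_mean and csa_mean must be positive")
        if self.twt_sd < 0 or self.csa_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.edema_water_boost < 1 or self.collagen_boost < 1:
            raise ValueError("contrast multipliers must be >= 1")
        if self.vessel_density < 0:
            raise ValueError("vessel_density must be >= 0")


#: cohort morphometry (mm / mm^2) with the stage-specific contrast mechanisms:
#: B boosts water (edema), C adds vessels (granulation), D boosts collagen (scar)
DEFAULT_GROUP_SPECS = {
    "A": GroupSpec("A", twt_mean=0.82, twt_sd=0.02, csa_mean=16.28, csa_sd=0.33),
    "B": GroupSpec("B", twt_mean=1.14, twt_sd=0.04, csa_mean=12.37, csa_sd=0.30,
                   edema_water_boost=1.5),
    "C": GroupSpec("C", twt_mean=1.50, twt_sd=0.30, csa_mean=8.78, csa_sd=0.92,
                   vessel_density=12),
    "D": GroupSpec("D", twt_mean=1.17, twt_sd=0.11, csa_mean=12.47, csa_sd=0.27,
                   collagen_boost=2.0),
}


@dataclass(frozen=True)
class Inclusion:
    """A circular intramural structure with its own chromophore content."""

    x: float  # mm
    y: float  # mm
    radius: float  # mm
    concentrations: tuple  # ((chromophore, value), ...) — hashable

    def concentration_dict(self) -> dict:
        return dict(self.concentrations)


@dataclass(frozen=True)
class Phantom:
    """One realized trachea cross-section with ground-truth morphometry."""

    lumen_radius: float  # mm
    wall_thickness: float  # mm
    center: tuple = (0.0, 0.0)  # mm
    inclusions: tuple = ()
    group_label: str = "A"
    true_csa: float = 0.0  # mm^2
    true_sr: float = 0.0  # % relative to REFERENCE_CSA_MM2
    water_boost: float = 1.0
    collagen_boost: float = 1.0

    @property
    def outer_radius(self) -> float:
        return self.lumen_radius + self.wall_thickness

    def __post_init__(self):
        if self.lumen_radius <= 0 or self.wall_thickness <= 0:
            raise ValueError("lumen_radius and wall_thickness must be positive")
        if abs(self.true_csa - math.pi * self.lumen_radius**2) > 1e-9:
            raise ValueError("true_csa inconsistent with lumen_radius")


@dataclass
class ChromophoreMap:
    """Per-pixel relative-concentration grids on a physical raster.

    ``origin`` is the (x, y) position in mm of the *center* of pixel
    ``[0, 0]``; arrays are indexed ``[row=y, col=x]``.
    """

    spacing: float  # mm / pixel
    origin: tuple  # (x0, y0) mm
    maps: dict = field(default_factory=dict)  # name -> (ny, nx) float array

    @property
    def shape(self) -> tuple:
        return next(iter(self.maps.values())).shape

    def coordinates(self):
        """Pixel-center coordinate grids (x, y) in mm."""
        ny, nx = self.shape
        x = self.origin[0] + self.spacing * np.arange(nx)
        y = self.origin[1] + self.spacing * np.arange(ny)
        return np.meshgrid(x, y)

    def stack(self) -> np.ndarray:
        """(n_chromophores, ny, nx) array in canonical CHROMOPHORES order."""
        return np.stack([self.maps[c] for c in CHROMOPHORES])

    def save_tiff(self, path):
        """Multi-page float32 TIFF, one page per chromophore."""
        meta = {"spacing_mm": self.spacing, "origin_mm": list(self.origin),
                "pages": list(CHROMOPHORES)}
        tifffile.imwrite(path, self.stack().astype(np.float32),
                         photometric="minisblack",
                     description=json.dumps(meta))

    @classmethod
    def load_tiff(cls, path) -> "ChromophoreMap":
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            meta = json.loads(tf.pages[0].description)
        maps = {name: data[i].astype(float) for i, name in enumerate(meta["pages"])}
        return cls(spacing=float(meta["spacing_mm"]),
                   origin=tuple(meta["origin_mm"]), maps=maps)


def _truncated_positive_normal(rng: np.random.Generator, mean: float, sd: float,
                               what: str) -> float:
    """Draw Normal(mean, sd) truncated to > 0; zero sd returns the mean."""
    if sd == 0:
        if mean <= 0:
            raise DegenerateSpecError(f"{what}: non-positive mean with zero sd")
        return mean
    for _ in range(_TRUNCATION_RETRIES):
        draw = rng.normal(mean, sd)
        if draw > 0:
            return float(draw)
    raise DegenerateSpecError(
        f"{what}: no positive draw in {_TRUNCATION_RETRIES} truncation retries "
        f"(mean={mean}, sd={sd})")


def _vessel_concentrations() -> tuple:
    hbt = VESSEL_BLOOD_FRACTION
    return (("hbo2", hbt * VESSEL_SO2), ("hbr", hbt * (1.0 - VESSEL_SO2)))


def make_phantom(spec: GroupSpec, seed) -> Phantom:
    """Realize one phantom from a group specification.

    The lumen radius is drawn so that the lumen area pi*r^2 follows
    Normal(csa_mean, csa_sd^2) truncated at > 0, and the wall thickness
    follows Normal(twt_mean, twt_sd^2) truncated at > 0.  Vessel inclusions
    are placed uniformly inside the wall annulus, never overlapping the
    lumen.  Identical (spec, seed) pairs yield identical phantoms.
    """
    rng = np.random.default_rng(seed)
    csa = _truncated_positive_normal(rng, spec.csa_mean, spec.csa_sd, "CSA")
    twt = _truncated_positive_normal(rng, spec.twt_mean, spec.twt_sd, "TWT")
    r = math.sqrt(csa / math.pi)

    inclusions = []
    conc = _vessel_concentrations()
    for _ in range(spec.vessel_density):
        # shrink vessels in very thin walls so they always fit the annulus
        vr = min(VESSEL_RADIUS_MM, 0.35 * twt)
        lo = r + vr + VESSEL_MARGIN_MM
        hi = r + twt - vr - VESSEL_MARGIN_MM
        if hi <= lo:
            continue  # wall too thin for any inclusion
        rho = rng.uniform(lo, hi)
        theta = rng.uniform(0.0, 2.0 * math.pi)
        inclusions.append(Inclusion(x=rho * math.cos(theta), y=rho * math.sin(theta),
                                    radius=vr, concentrations=conc))

    return Phantom(
        lumen_radius=r,
        wall_thickness=twt,
        inclusions=tuple(inclusions),
        group_label=spec.group_label,
        true_csa=math.pi * r**2,
        true_sr=(1.0 - csa / REFERENCE_CSA_MM2) * 100.0,
        water_boost=spec.edema_water_boost,
        collagen_boost=spec.collagen_boost,
    )


def sample_cohort(spec: GroupSpec, n: int, seed) -> list:
    """Draw ``n`` independent phantoms, reproducibly per master seed."""
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    children = np.random.SeedSequence(seed).spawn(n)
    return [make_phantom(spec, child) for child in children]


def apply_respiration(phantom: Phantom, phase: float,
                      depth: float = RESPIRATION_DEPTH) -> Phantom:
    """Deform a phantom to a point in the respiratory cycle.

    The lumen radius is scaled by sqrt(1 + depth*(1 - cos(phase))/2) so the
    lumen CSA varies sinusoidally: minimal at phase 0 (end-exhalation) and
    maximal, CSA*(1+depth), at phase pi (end-inhalation).  Wall
    cross-sectional area is conserved: the outer radius is recomputed from
    the deformed lumen, and intramural inclusions track the wall radially.
    """
    if not 0.0 <= phase < 2.0 * math.pi:
        raise ValueError(f"phase must lie in [0, 2*pi), got {phase}")
    if depth < 0 or depth >= 1:
        raise ValueError(f"modulation depth must lie in [0, 1), got {depth}")

    scale = math.sqrt(1.0 + depth * (1.0 - math.cos(phase)) / 2.0)
    r0, t0 = phantom.lumen_radius, phantom.wall_thickness
    outer0 = r0 + t0
    r1 = r0 * scale
    outer1 = math.sqrt(r1**2 + (outer0**2 - r0**2))  # conserve wall area
    t1 = outer1 - r1

    moved = []
    for inc in phantom.inclusions:
        dx, dy = inc.x - phantom.center[0], inc.y - phantom.center[1]
        rho = math.hypot(dx, dy)
        frac = (rho - r0) / t0
        rho1 = r1 + frac * t1
        f = rho1 / rho if rho > 0 else 1.0
        moved.append(dataclasses.replace(
            inc, x=phantom.center[0] + dx * f, y=phantom.center[1] + dy * f))

    csa1 = math.pi * r1**2
    return dataclasses.replace(
        phantom, lumen_radius=r1, wall_thickness=t1, inclusions=tuple(moved),
        true_csa=csa1, true_sr=(1.0 - csa1 / REFERENCE_CSA_MM2) * 100.0)


def rasterize(phantom: Phantom, spacing: float = 0.05,
              fov_mm: float = 12.8) -> ChromophoreMap:
    """Rasterize a phantom onto a square grid centered on the origin.

    Wall pixels carry the water/collagen/HbO2 background (with the group's
    boosts applied), vessel pixels carry their HbO2/HbR pair, and lumen and
    exterior pixels are zero everywhere.  At most three chromophores are
    nonzero at any pixel.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    half = fov_mm / 2.0
    reach = max(math.hypot(*phantom.center) + phantom.outer_radius,
                max((math.hypot(i.x, i.y) + i.radius for i in phantom.inclusions),
                    default=0.0))
    if reach > half:
        raise GeometryError(
            f"phantom extends to {reach:.2f} mm, outside the {half:.2f} mm half-field")

    n = int(round(fov_mm / spacing))
    axis = (np.arange(n) - (n - 1) / 2.0) * spacing
    xx, yy = np.meshgrid(axis, axis)
    rho = np.hypot(xx - phantom.center[0], yy - phantom.center[1])

    maps = {c: np.zeros((n, n)) for c in CHROMOPHORES}
    wall = (rho > phantom.lumen_radius) & (rho <= phantom.outer_radius)
    maps["water"][wall] = WALL_WATER * phantom.water_boost
    maps["collagen"][wall] = WALL_COLLAGEN * phantom.collagen_boost
    maps["hbo2"][wall] = WALL_HBO2

    for inc in phantom.inclusions:
        m = np.hypot(xx - inc.x, yy - inc.y) <= inc.radius
        for c in CHROMOPHORES:
            maps[c][m] = 0.0
        for c, v in inc.concentration_dict().items():
            maps[c][m] = v

    return ChromophoreMap(spacing=spacing, origin=(axis[0], axis[0]), maps=maps)


def lumen_mask(phantom: Phantom, cmap: ChromophoreMap) -> np.ndarray:
    """Boolean mask of lumen pixels (centers inside the lumen disk)."""
    xx, yy = cmap.coordinates()
    return np.hypot(xx - phantom.center[0], yy - phantom.center[1]) < phantom.lumen_radius


def wall_mask(phantom: Phantom, cmap: ChromophoreMap) -> np.ndarray:
    """Boolean mask of wall-annulus pixels (inclusions included)."""
    xx, yy = cmap.coordinates()
    rho = np.hypot(xx - phantom.center[0], yy - phantom.center[1])
    return (rho > phantom.lumen_radius) & (rho <= phantom.outer_radius)


# ---------------------------------------------------------------------------
# serialization

def phantom_to_dict(p: Phantom) -> dict:
    d = dataclasses.asdict(p)
    d["inclusions"] = [
        {"x": i.x, "y": i.y, "radius": i.radius,
         "concentrations": dict(i.concentrations)}
        for i in p.inclusions]
    return d


def phantom_from_dict(d: dict) -> Phantom:
    incs = tuple(
        Inclusion(x=i["x"], y=i["y"], radius=i["radius"],
                  concentrations=tuple(sorted(i["concentrations"].items())))
        for i in d["inclusions"])
    return Phantom(
        lumen_radius=d["lumen_radius"], wall_thickness=d["wall_thickness"],
        center=tuple(d["center"]), inclusions=incs, group_label=d["group_label"],
        true_csa=d["true_csa"], true_sr=d["true_sr"],
        water_boost=d["water_boost"], collagen_boost=d["collagen_boost"])


def save_phantom(p: Phantom, path):
    Path(path).write_text(json.dumps(phantom_to_dict(p), indent=2))


def load_phantom(path) -> Phantom:
    return phantom_from_dict(json.loads(Path(path).read_text()))
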