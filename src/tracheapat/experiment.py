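"""End-to-end experiment orchestration and file-based pipeline stages.

Two layers live here:

* in-memory experiment helpers (``simulate_phantom_images``,
  ``measure_cohort``, ``respiratory_sweep``, ``contrast_experiment``) used
  by the validation suite and by anyone scripting the pipeline, and
* file-based stages (``stage_*``) that read and write the declared formats
  (phantom JSON, chromophore/recon TIFF, sinogram HDF5, morphometry CSV)
  so each step can be rerun in isolation; ``run_experiment`` chains them
  and writes a manifest with the config hash and per-file content
  checksums.

Checksums hash the logical content of each file (arrays + metadata) rather
than raw bytes, so reruns with identical seeds yield identical manifests
even for container formats that embed nondeterministic header details.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from . import morphometry as mm
from . import phantom as ph
from .config import (GROUP_ORDER, STAGE_ACQUIRE, STAGE_OBSERVER, STAGE_PHANTOM,
                     ExperimentConfig, stage_seed)
from .errors import GeometryError, SegmentationError, TracheaPatError
from .forward import Sinogram, acquire_multiwavelength
from .optics import ExtinctionTable, extinction_matrix
from .recon import GridSpec, ReconImage, backproject, load_stack, save_stack
from .unmix import UnmixedMaps, group_contrast, unmix

log = logging.getLogger("tracheapat")


# ---------------------------------------------------------------------------
# in-memory pipeline helpers

def simulate_phantom_images(phantom: ph.Phantom, cfg: ExperimentConfig,
                            noise_seed, table: ExtinctionTable | None = None
                            ) -> list:
    """Rasterize, acquire at all wavelengths and reconstruct one phantom."""
    cmap = ph.rasterize(phantom, spacing=cfg.spacing, fov_mm=cfg.fov_mm)
    sinos = acquire_multiwavelength(
        cmap, cfg.geometry, wavelengths=cfg.wavelengths, table=table,
        relative_noise=cfg.relative_noise, n_averages=cfg.n_averages,
        seed=noise_seed)
    grid = GridSpec.centered(cfg.fov_mm, cfg.spacing)
    return [backproject(s, grid) for s in sinos]


def measure_cohort(group: str, n: int, master_seed: int,
                   cfg: ExperimentConfig | None = None,
                   observer: mm.ObserverParams | None = None) -> pd.DataFrame:
    """Full simulate-reconstruct-segment-measure chain over one cohort.

    Returns one row per phantom with ground truth and estimates; phantoms
    whose segmentation fails are retained with NaN estimates and
    ``ok = False`` (they are excluded from cohort summaries, as an
    unanalyzable animal would be).
    """
    cfg = cfg or ExperimentConfig()
    observer = observer or mm.ObserverParams()
    gi = GROUP_ORDER.index(group)
    spec = cfg.group_spec(group)
    table = ExtinctionTable.default()
    rows = []
    for i in range(n):
        phantom = ph.make_phantom(
            spec, np.random.SeedSequence(stage_seed(master_seed, STAGE_PHANTOM, gi, i)))
        row = {"group": group, "index": i, "true_twt": phantom.wall_thickness,
               "true_csa": phantom.true_csa, "true_sr": phantom.true_sr}
        try:
            images = simulate_phantom_images(
                phantom, cfg, stage_seed(master_seed, STAGE_ACQUIRE, gi, i), table)
            result = mm.measure_image(mm.structural_image(images), observer,
                                      reference_csa=cfg.reference_csa)
            row.update(twt=result.twt_mm, csa=result.csa_mm2, sr=result.sr_pct,
                       ok=True)
        except (SegmentationError, GeometryError) as exc:
            log.warning("phantom %s/%d excluded: %s", group, i, exc)
            row.update(twt=np.nan, csa=np.nan, sr=np.nan, ok=False)
        rows.append(row)
    return pd.DataFrame(rows)


def respiratory_sweep(group: str = "A", n_phases: int = 8, master_seed: int = 0,
                      cfg: ExperimentConfig | None = None) -> tuple:
    """Image one phantom across a respiratory cycle.

    Returns (CsaTrace, phase array, base phantom): frames are simulated at
    ``n_phases`` evenly spaced phases in [0, 2*pi) with the configured
    modulation depth.
    """
    cfg = cfg or ExperimentConfig()
    gi = GROUP_ORDER.index(group)
    base = ph.make_phantom(
        cfg.group_spec(group),
        np.random.SeedSequence(stage_seed(master_seed, STAGE_PHANTOM, gi, 0)))
    phases = np.linspace(0.0, 2.0 * np.pi, n_phases, endpoint=False)
    table = ExtinctionTable.default()
    frames = []
    for j, phase in enumerate(phases):
        deformed = ph.apply_respiration(base, float(phase), cfg.respiration_depth)
        images = simulate_phantom_images(
            deformed, cfg, stage_seed(master_seed, STAGE_ACQUIRE, gi, j), table)
        frames.append(mm.structural_image(images))
    trace = mm.csa_timeseries(frames, phases)
    return trace, phases, base


def boundary_ridge_mask(phantom: ph.Phantom, cmap: ph.ChromophoreMap,
                        band_mm: float = 0.10,
                        vessel_pad_mm: float = 0.35) -> np.ndarray:
    """Region mask hugging the wall boundaries, away from vessels.

    Band-limited reconstructions carry no signal inside homogeneous tissue
    (the flat interior is outside the transducer band); the wall's spectral
    signature is expressed at its boundary envelope ridges, whose amplitude
    is proportional to the local absorption step.  Spectral contrasts are
    therefore evaluated on a band around the inner/outer boundaries,
    excluding the ringing neighborhoods of vessel inclusions.
    """
    xx, yy = cmap.coordinates()
    rho = np.hypot(xx - phantom.center[0], yy - phantom.center[1])
    mask = ((np.abs(rho - phantom.lumen_radius) < band_mm)
            | (np.abs(rho - phantom.outer_radius) < band_mm))
    for inc in phantom.inclusions:
        mask &= np.hypot(xx - inc.x, yy - inc.y) > (inc.radius + vessel_pad_mm)
    return mask


def envelope_stack(images) -> list:
    """Per-wavelength isotropic-envelope images (the unmixing input)."""
    from .recon import isotropic_envelope

    return [ReconImage(pixels=isotropic_envelope(im.pixels), spacing=im.spacing,
                       origin=im.origin, wavelength_nm=im.wavelength_nm)
            for im in images]


def contrast_experiment(n: int = 3, master_seed: int = 0,
                        cfg: ExperimentConfig | None = None) -> pd.DataFrame:
    """Directional chromophore contrasts between the edema and scar stages.

    Pairs group-B (edema, water-boosted) with group-D (scar,
    collagen-boosted) phantoms, runs the full acquisition-reconstruction-
    unmixing chain on envelope stacks and reports per-pair collagen D/B and
    water B/D mean ratios inside each phantom's boundary-ridge region.
    """
    cfg = cfg or ExperimentConfig()
    table = ExtinctionTable.default()
    E = extinction_matrix(table, cfg.wavelengths)
    rows = []
    for i in range(n):
        maps = {}
        masks = {}
        for group in ("B", "D"):
            gi = GROUP_ORDER.index(group)
            phantom = ph.make_phantom(
                cfg.group_spec(group),
                np.random.SeedSequence(stage_seed(master_seed, STAGE_PHANTOM, gi, i)))
            cmap = ph.rasterize(phantom, spacing=cfg.spacing, fov_mm=cfg.fov_mm)
            images = simulate_phantom_images(
                phantom, cfg, stage_seed(master_seed, STAGE_ACQUIRE, gi, i), table)
            maps[group] = unmix(envelope_stack(images), E)
            masks[group] = boundary_ridge_mask(phantom, cmap)
        mean = {g: {c: float(maps[g].maps[c][masks[g]].mean())
                    for c in maps[g].maps} for g in ("B", "D")}
        rows.append({
            "pair": i,
            "collagen_D_over_B": mean["D"]["collagen"] / mean["B"]["collagen"],
            "water_B_over_D": mean["B"]["water"] / mean["D"]["water"],
            "hbo2_B_over_D": mean["B"]["hbo2"] / mean["D"]["hbo2"],
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file-based stages

def _phantom_path(out: Path, g: str, i: int) -> Path:
    return out / "phantoms" / f"phantom_{g}_{i:03d}.json"


def _chromo_path(out: Path, g: str, i: int) -> Path:
    return out / "phantoms" / f"chromo_{g}_{i:03d}.tif"


def _sino_path(out: Path, g: str, i: int, w) -> Path:
    return out / "sinograms" / f"sino_{g}_{i:03d}_w{int(w)}.h5"


def _recon_path(out: Path, g: str, i: int) -> Path:
    return out / "recon" / f"recon_{g}_{i:03d}.tif"


def _unmix_path(out: Path, g: str, i: int) -> Path:
    return out / "unmixed" / f"unmixed_{g}_{i:03d}.tif"


def stage_phantoms(cfg: ExperimentConfig, out: Path):
    out = Path(out)
    (out / "phantoms").mkdir(parents=True, exist_ok=True)
    for gi, g in enumerate(cfg.groups):
        spec = cfg.group_spec(g)
        for i in range(cfg.n):
            phantom = ph.make_phantom(spec, np.random.SeedSequence(
                stage_seed(cfg.master_seed, STAGE_PHANTOM, GROUP_ORDER.index(g), i)))
            ph.save_phantom(phantom, _phantom_path(out, g, i))
            cmap = ph.rasterize(phantom, spacing=cfg.spacing, fov_mm=cfg.fov_mm)
            cmap.save_tiff(_chromo_path(out, g, i))
    log.info("phantom stage: %d groups x %d phantoms", len(cfg.groups), cfg.n)


def stage_simulate(cfg: ExperimentConfig, out: Path):
    out = Path(out)
    (out / "sinograms").mkdir(parents=True, exist_ok=True)
    table = ExtinctionTable.default()
    for g in cfg.groups:
        for i in range(cfg.n):
            src = _chromo_path(out, g, i)
            if not src.exists():
                raise TracheaPatError(f"missing upstream phantom map: {src}")
            cmap = ph.ChromophoreMap.load_tiff(src)
            seed = stage_seed(cfg.master_seed, STAGE_ACQUIRE, GROUP_ORDER.index(g), i)
            log.info("simulate %s/%03d with seed %s", g, i, seed)
            sinos = acquire_multiwavelength(
                cmap, cfg.geometry, wavelengths=cfg.wavelengths, table=table,
                relative_noise=cfg.relative_noise, n_averages=cfg.n_averages,
                seed=seed)
            for s in sinos:
                s.save_h5(_sino_path(out, g, i, s.wavelength_nm))


def stage_reconstruct(cfg: ExperimentConfig, out: Path):
    out = Path(out)
    (out / "recon").mkdir(parents=True, exist_ok=True)
    grid = GridSpec.centered(cfg.fov_mm, cfg.spacing)
    for g in cfg.groups:
        for i in range(cfg.n):
            images = []
            for w in cfg.wavelengths:
                src = _sino_path(out, g, i, w)
                if not src.exists():
                    raise TracheaPatError(f"missing upstream sinogram: {src}")
                images.append(backproject(Sinogram.load_h5(src), grid))
            save_stack(images, _recon_path(out, g, i))


def stage_unmix(cfg: ExperimentConfig, out: Path):
    """Unmix the first phantom of each group (representative maps)."""
    out = Path(out)
    (out / "unmixed").mkdir(parents=True, exist_ok=True)
    table = ExtinctionTable.default()
    E = extinction_matrix(table, cfg.wavelengths)
    for g in cfg.groups:
        src = _recon_path(out, g, 0)
        if not src.exists():
            raise TracheaPatError(f"missing upstream reconstruction: {src}")
        unmix(envelope_stack(load_stack(src)), E).save_tiff(_unmix_path(out, g, 0))


def stage_measure(cfg: ExperimentConfig, out: Path) -> pd.DataFrame:
    out = Path(out)
    base = mm.ObserverParams()
    observers = [
        base.jittered(np.random.SeedSequence(
            stage_seed(cfg.master_seed, STAGE_OBSERVER, 0, 0)),
            cfg.observer_threshold_jitter, cfg.observer_sigma_jitter, "obs_a"),
        base.jittered(np.random.SeedSequence(
            stage_seed(cfg.master_seed, STAGE_OBSERVER, 0, 1)),
            cfg.observer_threshold_jitter, cfg.observer_sigma_jitter, "obs_b"),
    ]
    rows = []
    for g in cfg.groups:
        for i in range(cfg.n):
            src = _recon_path(out, g, i)
            if not src.exists():
                raise TracheaPatError(f"missing upstream reconstruction: {src}")
            structural = mm.structural_image(load_stack(src))
            truth = ph.load_phantom(_phantom_path(out, g, i)) \
                if _phantom_path(out, g, i).exists() else None
            for obs in observers:
                row = {"group": g, "index": i, "observer_id": obs.label}
                try:
                    res = mm.measure_image(structural, obs,
                                           reference_csa=cfg.reference_csa)
                    row.update(twt_mm=res.twt_mm, csa_mm2=res.csa_mm2,
                               sr_pct=res.sr_pct, ok=True)
                except (SegmentationError, GeometryError) as exc:
                    log.warning("measure %s/%03d (%s) failed: %s", g, i,
                                obs.label, exc)
                    row.update(twt_mm=np.nan, csa_mm2=np.nan, sr_pct=np.nan,
                               ok=False)
                if truth is not None:
                    row.update(true_twt=truth.wall_thickness,
                               true_csa=truth.true_csa, true_sr=truth.true_sr)
                rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(out / "morphometry.csv", index=False)
    return df


def stage_stats(cfg: ExperimentConfig, out: Path):
    from . import stats as st

    out = Path(out)
    src = out / "morphometry.csv"
    if not src.exists():
        raise TracheaPatError(f"missing upstream morphometry table: {src}")
    df = pd.read_csv(src)
    df = df[df.ok].copy()
    (out / "stats").mkdir(parents=True, exist_ok=True)

    metrics = ["twt_mm", "csa_mm2", "sr_pct"]
    wide = df.pivot_table(index=["group", "index"], columns="observer_id",
                          values=metrics)
    agreement = {}
    for m in metrics:
        a = wide[(m, "obs_a")].to_numpy(float)
        b = wide[(m, "obs_b")].to_numpy(float)
        keep = np.isfinite(a) & np.isfinite(b)
        if keep.sum() >= 3 and np.std(a[keep]) > 0 and np.std(b[keep]) > 0:
            agr = st.bland_altman(a[keep], b[keep])
            agreement[m] = {k: getattr(agr, k) for k in
                            ("r", "bias", "bias_ci_low", "bias_ci_high",
                             "loa_low", "loa_high", "n")}
    with open(out / "stats" / "agreement.json", "w") as f:
        json.dump(agreement, f, indent=2)

    mean_obs = (df.groupby(["group", "index"])[metrics].mean().reset_index())
    if mean_obs.group.nunique() >= 2 and (mean_obs.groupby("group").size() >= 2).all():
        comp = st.group_table(mean_obs, metrics)
        comp.summary.to_csv(out / "stats" / "group_summary.csv", index=False)
        comp.comparisons.to_csv(out / "stats" / "group_comparisons.csv", index=False)

    _write_plots(df, metrics, out / "stats")


def _write_plots(df, metrics, statdir: Path):
    """Presentation-only PNGs (numbers are tested upstream, plots are not)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from . import stats as st

    wide = df.pivot_table(index=["group", "index"], columns="observer_id",
                          values=metrics)
    for m in metrics:
        try:
            a = wide[(m, "obs_a")].dropna()
            b = wide[(m, "obs_b")].dropna()
            common = a.index.intersection(b.index)
            if len(common) < 3:
                continue
            fig, axes = plt.subplots(1, 2, figsize=(8, 3.2))
            axes[0].scatter(a[common], b[common], s=12)
            axes[0].set_xlabel(f"{m} observer A")
            axes[0].set_ylabel(f"{m} observer B")
            st.bland_altman_plot(a[common].to_numpy(), b[common].to_numpy(),
                                 ax=axes[1], title=m)
            fig.tight_layout()
            fig.savefig(statdir / f"agreement_{m}.png", dpi=110)
            plt.close(fig)
        except Exception as exc:  # plots must never break the pipeline
            log.warning("plot for %s skipped: %s", m, exc)


# ---------------------------------------------------------------------------
# manifest + full run

def content_checksum(path: Path) -> str:
    """Checksum of a file's logical content (stable across reruns)."""
    path = Path(path)
    h = hashlib.sha256()
    if path.suffix == ".h5":
        with h5py.File(path, "r") as f:
            for key in sorted(f.keys()):
                h.update(key.encode())
                h.update(np.ascontiguousarray(f[key][...]).tobytes())
            for key in sorted(f.attrs):
                h.update(key.encode())
                h.update(str(f.attrs[key]).encode())
    elif path.suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            h.update(np.ascontiguousarray(tf.asarray()).tobytes())
            h.update((tf.pages[0].description or "").encode())
    else:
        h.update(path.read_bytes())
    return h.hexdigest()


def run_experiment(cfg: ExperimentConfig, out) -> Path:
    """Run every stage and write ``manifest.json``; deterministic per seed."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    stage_phantoms(cfg, out)
    stage_simulate(cfg, out)
    stage_reconstruct(cfg, out)
    if cfg.unmix_enabled:
        stage_unmix(cfg, out)
    stage_measure(cfg, out)
    stage_stats(cfg, out)

    files = sorted(p for p in out.rglob("*")
                   if p.is_file() and p.name != "manifest.json"
                   and p.suffix != ".png")
    manifest = {
        "config": cfg.to_dict(),
        "config_sha256": cfg.checksum(),
        "seed_scheme": "SeedSequence([master_seed, stage, group_index, item_index])",
        "stage_ids": {"phantom": STAGE_PHANTOM, "acquire": STAGE_ACQUIRE,
                      "observer": STAGE_OBSERVER},
        "checksums": {str(p.relative_to(out)): content_checksum(p) for p in files},
    }
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    return out
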