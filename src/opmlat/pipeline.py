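"""End-to-end run orchestration: simulate -> preprocess -> spectral -> localize -> laterality.

A run is driven by a :class:`RunConfig` (YAML/JSON on disk), validated before
any compute, and writes one directory containing data.h5, clean.h5, spec.h5,
statmap.tsv, laterality.tsv, confidence_volume.json, source_course.tsv,
run.log and resolved-config.yaml.  Every output is traceable to the config
hash and seed recorded in its provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from ._exceptions import ValidationError
from . import beamformer, laterality, preprocess, spectral
from .dataset import TrialDataset, read_dataset, write_dataset
from .forward import compute_leadfields
from .geometry import (
    ROISpec,
    build_source_grid,
    default_sensor_array,
    fit_conductor_sphere,
)
from .simulate import DEFAULT_SOURCE_MM, SimulationTruth, simulate_dataset

CONFIG_SCHEMA_VERSION = 1

_SECTION_KEYS = {
    "schema_version", "seed", "geometry", "simulation", "preprocess",
    "spectral", "localize", "laterality", "confidence",
}


@dataclass
class RunConfig:
    """All pipeline parameters; unknown keys are rejected, every stage is seeded."""

    seed: int = 0
    schema_version: int = CONFIG_SCHEMA_VERSION
    geometry: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    spectral: dict = field(default_factory=dict)
    localize: dict = field(default_factory=dict)
    laterality: dict = field(default_factory=dict)
    confidence: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _SECTION_KEYS
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def resolved(self) -> dict:
        """Config with all defaults filled in (what the run actually uses)."""
        out = asdict(self)
        out["geometry"] = {**_GEOMETRY_DEFAULTS, **self.geometry}
        out["simulation"] = {**_SIMULATION_DEFAULTS, **self.simulation}
        out["preprocess"] = {**_PREPROCESS_DEFAULTS, **self.preprocess}
        out["spectral"] = {**_SPECTRAL_DEFAULTS, **self.spectral}
        out["localize"] = {**_LOCALIZE_DEFAULTS, **self.localize}
        out["laterality"] = {**_LATERALITY_DEFAULTS, **self.laterality}
        out["confidence"] = {**_CONFIDENCE_DEFAULTS, **self.confidence}
        return out

    def hash(self) -> str:
        canon = json.dumps(self.resolved(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def validate(self) -> None:
        r = self.resolved()
        if r["schema_version"] != CONFIG_SCHEMA_VERSION:
            raise ValidationError(f"unsupported config schema version {r['schema_version']}")
        bad = []
        for section, defaults in [
            ("geometry", _GEOMETRY_DEFAULTS), ("simulation", _SIMULATION_DEFAULTS),
            ("preprocess", _PREPROCESS_DEFAULTS), ("spectral", _SPECTRAL_DEFAULTS),
            ("localize", _LOCALIZE_DEFAULTS), ("laterality", _LATERALITY_DEFAULTS),
            ("confidence", _CONFIDENCE_DEFAULTS),
        ]:
            bad += [f"{section}.{k}" for k in getattr(self, section) if k not in defaults]
        if bad:
            raise ValidationError(f"unknown config keys: {bad}")
        sim, loc, spec = r["simulation"], r["localize"], r["spectral"]
        epoch = (-sim["rest_duration_s"], sim["task_duration_s"])
        for name, win in [
            ("localize.baseline_window", loc["baseline_window"]),
            ("localize.active_window", loc["active_window"]),
            ("spectral.rest_window", spec["rest_window"]),
            ("spectral.task_window", spec["task_window"]),
        ]:
            if win[0] < epoch[0] - 1e-9 or win[1] > epoch[1] + 1e-9:
                raise ValidationError(f"{name} {win} lies outside the epoch {epoch}")
        if r["laterality"]["n_boot"] < 2 or r["confidence"]["n_boot"] < 2:
            raise ValidationError("bootstrap counts must be >= 2")


_GEOMETRY_DEFAULTS = {
    "n_scalp": 26,
    "n_reference": 4,
    "sphere_margin_mm": 15.0,
    "grid_spacing_mm": 10.0,
    "grid_margin_mm": 10.0,
    "roi_center_mm": list(DEFAULT_SOURCE_MM),
    "roi_radius_mm": 20.0,
}
_SIMULATION_DEFAULTS = {
    "source_position_mm": list(DEFAULT_SOURCE_MM),
    "source_orientation": None,
    "amplitude_nam": 15.0,
    "desync_depth": 0.4,
    "n_trials": 120,
    "task_duration_s": 3.0,
    "rest_duration_s": 2.0,
    "rest_jitter_s": 0.0,
    "n_interference": 4,
    "interference_amplitude_t": 8e-11,
    "noise_density_ft": 15.0,
    "sampling_rate": 1000.0,
}
_PREPROCESS_DEFAULTS = {
    "target_rate": 200.0,
    "notch_freqs": [50.0],
    "bandstop": [75.0, 79.0],
    "intercept": True,
}
_SPECTRAL_DEFAULTS = {
    "band": [15.0, 30.0],
    "fmin": 5.0,
    "fmax": 45.0,
    "half_bandwidth": 1.5,
    "window_s": 1.0,
    "step_s": 0.1,
    "rest_window": [-2.0, 0.0],
    "task_window": [0.0, 3.0],
    "n_boot": 100,
}
_LOCALIZE_DEFAULTS = {
    "band": [15.0, 30.0],
    "baseline_window": [-1.0, 0.0],
    "active_window": [0.0, 1.0],
    "regularization": 0.05,
    "fdr_q": 0.05,
    "dof_mode": "fixed",
}
_LATERALITY_DEFAULTS = {"thresholds": [1.0, 15.0, 29], "n_boot": 100}
_CONFIDENCE_DEFAULTS = {"n_boot": 50, "roi": "IFG_left"}


def build_geometry(cfg: dict):
    """Sensor array, conductor sphere, ROI-annotated source grid, lead fields."""
    array = default_sensor_array(n_scalp=cfg["n_scalp"], n_reference=cfg["n_reference"])
    sphere = fit_conductor_sphere(
        array.positions[array.scalp_indices], margin=cfg["sphere_margin_mm"]
    )
    roi_left = ROISpec("IFG_left", np.asarray(cfg["roi_center_mm"], float), cfg["roi_radius_mm"])
    grid = build_source_grid(
        sphere,
        spacing=cfg["grid_spacing_mm"],
        margin=cfg["grid_margin_mm"],
        roi_specs=[roi_left, roi_left.mirrored("IFG_right")],
    )
    lf = compute_leadfields(array, grid, sphere)
    return array, sphere, grid, lf


def _truth_from_config(sim: dict, seed: int) -> SimulationTruth:
    ori = sim["source_orientation"]
    return SimulationTruth(
        source_positions=np.atleast_2d(np.asarray(sim["source_position_mm"], float)),
        source_orientations=None if ori is None else np.atleast_2d(np.asarray(ori, float)),
        amplitude_nam=sim["amplitude_nam"],
        desync_depth=sim["desync_depth"],
        n_trials=sim["n_trials"],
        task_duration_s=sim["task_duration_s"],
        rest_duration_s=sim["rest_duration_s"],
        rest_jitter_s=sim["rest_jitter_s"],
        n_interference=sim["n_interference"],
        interference_amplitude_t=sim["interference_amplitude_t"],
        noise_density_ft=sim["noise_density_ft"],
        sampling_rate=sim["sampling_rate"],
        seed=seed,
    )


def _write_spectral_h5(path: Path, course: spectral.PercentChangeCourse) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = 1
        f.create_dataset("times", data=course.times)
        f.create_dataset("percent_change", data=course.values)
        f.create_dataset("se", data=course.se)
        f.create_dataset("significant", data=course.significant.astype(np.uint8))
        f.create_dataset("labels", data=np.array(course.channel_labels, dtype="S"))
        f.attrs["band"] = list(course.band)
        f.attrs["rest_window"] = list(course.rest_window)
        f.attrs["n_boot"] = course.n_boot
        f.attrs["seed"] = course.seed


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute all stages; any failure aborts with the stage name, keeping partial outputs."""
    config.validate()
    r = config.resolved()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()

    log = logging.getLogger("opmlat.pipeline")
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    (outdir / "resolved-config.yaml").write_text(yaml.safe_dump(r, sort_keys=True))
    log.info("run start: config_hash=%s seed=%d", cfg_hash, config.seed)

    stage = "geometry"
    try:
        t0 = time.perf_counter()
        array, sphere, grid, lf = build_geometry(r["geometry"])
        log.info("geometry: %d scalp, %d grid points (%.2fs)",
                 array.n_scalp, grid.n_points, time.perf_counter() - t0)

        stage = "simulate"
        t0 = time.perf_counter()
        truth = _truth_from_config(r["simulation"], config.seed)
        ds = simulate_dataset(truth, array, lf)
        ds.provenance[0]["config_hash"] = cfg_hash
        write_dataset(ds, outdir / "data.h5")
        log.info("simulate: %d trials @ %g Hz (%.2fs)",
                 ds.n_trials, ds.sampling_rate, time.perf_counter() - t0)

        stage = "preprocess"
        t0 = time.perf_counter()
        pp = r["preprocess"]
        ds = preprocess.downsample_and_filter(
            ds, target_rate=pp["target_rate"], notch_freqs=tuple(pp["notch_freqs"]),
            bandstop=tuple(pp["bandstop"]) if pp["bandstop"] else None,
        )
        ds, _ = preprocess.synthetic_gradiometry(ds, intercept=pp["intercept"])
        ds.provenance.append({"config_hash": cfg_hash})
        write_dataset(ds, outdir / "clean.h5")
        log.info("preprocess: -> %g Hz, gradiometry done (%.2fs)",
                 ds.sampling_rate, time.perf_counter() - t0)

        stage = "spectral"
        t0 = time.perf_counter()
        sp = r["spectral"]
        spec = spectral.multitaper_tf(
            ds, sp["fmin"], sp["fmax"], half_bandwidth=sp["half_bandwidth"],
            window_s=sp["window_s"], step_s=sp["step_s"],
        )
        course = spectral.bootstrap_sensor_course(
            spec, band=tuple(sp["band"]), rest_window=tuple(sp["rest_window"]),
            n_boot=sp["n_boot"], seed=config.seed,
        )
        selection = spectral.max_modulated_sensor(course, task_window=tuple(sp["task_window"]))
        _write_spectral_h5(outdir / "spec.h5", course)
        log.info("spectral: max sensor %s (%.1f%%) (%.2fs)",
                 selection.label, selection.value, time.perf_counter() - t0)

        stage = "localize"
        t0 = time.perf_counter()
        lc = r["localize"]
        ds_f = beamformer.band_filter(ds, band=tuple(lc["band"]))
        weights = beamformer.lcmv_weights(ds_f, lf, regularization=lc["regularization"])
        statmap = beamformer.f_map(
            ds_f, weights, baseline_window=tuple(lc["baseline_window"]),
            active_window=tuple(lc["active_window"]), q=lc["fdr_q"],
            band=tuple(lc["band"]), dof_mode=lc["dof_mode"],
        )
        beamformer.statmap_to_tsv(statmap, outdir / "statmap.tsv")
        peak = int(np.argmax(np.abs(np.log(statmap.F))))
        log.info("localize: peak at %s, F=%.3g, %d FDR-passing points (%.2fs)",
                 grid.points[peak].tolist(), statmap.F[peak],
                 int(statmap.fdr_pass.sum()), time.perf_counter() - t0)

        stage = "source_timecourse"
        t0 = time.perf_counter()
        vc = beamformer.source_timecourse(ds, weights, peak)
        vc_spec = spectral.multitaper_tf(
            vc, sp["fmin"], sp["fmax"], half_bandwidth=sp["half_bandwidth"],
            window_s=sp["window_s"], step_s=sp["step_s"],
        )
        vc_course = spectral.bootstrap_sensor_course(
            vc_spec, band=tuple(sp["band"]), rest_window=tuple(sp["rest_window"]),
            n_boot=sp["n_boot"], seed=config.seed,
        )
        import pandas as pd

        pd.DataFrame({
            "time_s": vc_course.times,
            "percent_change": vc_course.values[0],
            "se": vc_course.se[0],
            "significant": vc_course.significant[0].astype(int),
        }).to_csv(outdir / "source_course.tsv", sep="\t", index=False, float_format="%.8g")
        log.info("source_timecourse: at grid point %d (%.2fs)", peak, time.perf_counter() - t0)

        stage = "laterality"
        t0 = time.perf_counter()
        la = r["laterality"]
        lo, hi, n = la["thresholds"]
        curve = laterality.bootstrap_li(
            ds_f, lf, "IFG_left", "IFG_right",
            thresholds=np.linspace(lo, hi, int(n)),
            n_boot=la["n_boot"], seed=config.seed,
            baseline_window=tuple(lc["baseline_window"]),
            active_window=tuple(lc["active_window"]),
            regularization=lc["regularization"],
        )
        curve.to_tsv(outdir / "laterality.tsv")
        log.info("laterality: LI@min-threshold=%.3f (%.2fs)",
                 curve.li[0], time.perf_counter() - t0)

        stage = "confidence"
        t0 = time.perf_counter()
        cv = beamformer.confidence_volume(
            ds_f, lf, grid.mask_for(r["confidence"]["roi"]),
            baseline_window=tuple(lc["baseline_window"]),
            active_window=tuple(lc["active_window"]),
            n_boot=r["confidence"]["n_boot"], seed=config.seed,
            regularization=lc["regularization"], roi_name=r["confidence"]["roi"],
        )
        (outdir / "confidence_volume.json").write_text(json.dumps({
            "roi": cv.roi_name,
            "extents_mm": cv.extents.tolist(),
            "mean_peak_mm": cv.peaks.mean(axis=0).tolist(),
            "n_boot": cv.n_boot,
            "seed": cv.seed,
            "config_hash": cfg_hash,
        }, indent=1))
        log.info("confidence: extents %s mm (%.2fs)",
                 np.round(cv.extents, 2).tolist(), time.perf_counter() - t0)
        log.info("run complete")
    except Exception:
        log.exception("stage %r failed; partial outputs kept in %s", stage, outdir)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return outdir


# -- canonical test fixtures --------------------------------------------------

FIXTURE_MANIFEST = {
    "noiseless": "noiseless.h5",
    "null": "null.h5",
    "mirrored": "mirrored.h5",
    "misspecified": "misspecified.h5",
}


def make_fixtures(seed: int, outdir: str | Path) -> dict[str, Path]:
    """Small canonical datasets for the test suite (each well under 5 MB).

    noiseless: single left source, no interference, no sensor noise;
    null: depth 0; mirrored: source reflected to the right hemisphere;
    misspecified: a 5th interference component outside the reference span.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geo = dict(_GEOMETRY_DEFAULTS)
    geo["grid_spacing_mm"] = 20.0
    array, sphere, grid, lf = build_geometry(geo)
    base = dict(
        n_trials=6, sampling_rate=1000.0, amplitude_nam=15.0,
        rest_duration_s=1.0, task_duration_s=2.0, seed=seed,
    )
    variants = {
        "noiseless": dict(base, interference_amplitude_t=0.0, noise_density_ft=0.0),
        "null": dict(base, desync_depth=0.0),
        "mirrored": dict(
            base,
            source_positions=np.array([DEFAULT_SOURCE_MM]) * np.array([-1.0, 1.0, 1.0]),
        ),
        "misspecified": dict(base, n_interference=5),
    }
    paths = {}
    for name, kwargs in variants.items():
        truth = SimulationTruth(**kwargs)
        ds = simulate_dataset(truth, array, lf)
        path = outdir / FIXTURE_MANIFEST[name]
        write_dataset(ds, path)
        paths[name] = path
    (outdir / "manifest.json").write_text(json.dumps(
        {"seed": seed, "files": FIXTURE_MANIFEST}, indent=1))
    return paths


def load_fixture(outdir: str | Path, name: str) -> TrialDataset:
    return read_dataset(Path(outdir) / FIXTURE_MANIFEST[name])
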