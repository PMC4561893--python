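"""End-to-end reproducible runs: near-field simulation and spectral pipeline.

Every workflow takes a plain-dict configuration (typically loaded from YAML),
runs with fixed seeds, and writes its outputs, the resolved configuration and
a manifest of output hashes into one directory, so that every artifact on
disk is reproducible from (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dipoles, spectra
from .exceptions import ConfigError
from .materials import OpticalConstants

__all__ = [
    "run_field_workflow",
    "run_spectral_workflow",
    "run_treatment_workflow",
    "run_synth_workflow",
    "load_config",
]

log = logging.getLogger("cytosers.workflows")

_FIELD_KEYS = {
    "wavelength", "incidence_angle", "polarization", "evaluation_height",
    "n_particles", "diameter_range", "region", "min_gap", "seed",
    "grid", "vertical_slice", "heights",
}
_SYNTH_KEYS = {"seed", "which", "states", "fractions", "noise_sd", "axis", "baseline"}
_ANALYZE_KEYS = {"spectra", "control", "knot_positions", "knot_half_width", "state"}
_TREATMENT_KEYS = {
    "seed", "f_red_control", "delta_f", "n_replicates", "noise_sd", "which",
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("configuration must be a mapping")
    return cfg


def _check_keys(cfg: dict, allowed: set, mode: str) -> None:
    unknown = set(cfg) - allowed
    if unknown:
        raise ConfigError(f"{mode}: unknown config keys {sorted(unknown)}")


def _write_resolved(cfg: dict, out: Path, name: str = "resolved_config.yaml") -> None:
    (out / name).write_text(yaml.safe_dump(cfg, sort_keys=False))


def _manifest(out: Path, files) -> None:
    entries = {}
    for f in sorted(files):
        p = out / f
        entries[f] = hashlib.sha256(p.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(entries, indent=2) + "\n")


def _write_field_map(grid: dipoles.FieldGrid, path: Path) -> None:
    cols = np.column_stack([
        grid.points,
        grid.field.real[:, 0], grid.field.imag[:, 0],
        grid.field.real[:, 1], grid.field.imag[:, 1],
        grid.field.real[:, 2], grid.field.imag[:, 2],
        grid.intensity,
    ])
    header = "x_nm y_nm z_nm ReEx ImEx ReEy ImEy ReEz ImEz intensity"
    np.savetxt(path, cols, header=header)


def _plane_points(region, height, nx, ny):
    xs = np.linspace(0.0, region[0], nx)
    ys = np.linspace(0.0, region[1], ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    return np.column_stack([X.ravel(), Y.ravel(), np.full(X.size, float(height))])


def run_field_workflow(config: dict, out_dir) -> dict:
    """Near-field comparison: normal vs oblique TM illumination of one ensemble.

    Solves the coupled-dipole system for a random ensemble under both
    illuminations, evaluates the intensity map on a horizontal plane (default
    60 nm above the substrate) and an optional vertical slice, and reports
    mean/max enhancement over the particle-free background field.
    """
    _check_keys(config, _FIELD_KEYS, "simulate-field")
    cfg = {
        "wavelength": 532.0, "incidence_angle": 65.0, "polarization": "TM",
        "evaluation_height": 60.0, "n_particles": 30,
        "diameter_range": [40.0, 50.0], "region": [1000.0, 1000.0],
        "min_gap": 2.0, "seed": 0, "grid": [41, 41], "vertical_slice": False,
        "heights": None,
    }
    cfg.update(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    d_lo, d_hi = cfg["diameter_range"]
    optics = OpticalConstants(wavelength=float(cfg["wavelength"]))
    ens = dipoles.generate_ensemble(
        n=int(cfg["n_particles"]),
        radius_range=(d_lo / 2.0, d_hi / 2.0),
        region=tuple(cfg["region"]),
        min_gap=float(cfg["min_gap"]),
        seed=int(cfg["seed"]),
        optics=optics,
    )
    nx, ny = cfg["grid"]
    pts = _plane_points(cfg["region"], cfg["evaluation_height"], int(nx), int(ny))

    waves = {
        "normal": dipoles.PlaneWave(cfg["wavelength"], 0.0, cfg["polarization"]),
        "oblique": dipoles.PlaneWave(
            cfg["wavelength"], float(cfg["incidence_angle"]), cfg["polarization"]
        ),
    }
    summary = {"config": cfg, "residuals": {}, "enhancement": {}}
    files = []
    for name, wave in waves.items():
        sol = dipoles.solve_dipoles(ens, wave)
        log.info("solve %s: residual %.3e", name, sol.residual_norm)
        summary["residuals"][name] = sol.residual_norm
        grid = dipoles.total_field(ens, sol, pts)
        empty = dipoles.Ensemble(particles=(), optics=optics, region=tuple(cfg["region"]))
        bg = dipoles.total_field(
            empty, dipoles.DipoleSolution(np.zeros((0, 3)), 0.0, wave), pts
        )
        enh = dipoles.enhancement_summary(grid, bg)
        summary["enhancement"][name] = {
            "mean": enh.mean_enhancement, "max": enh.max_enhancement,
            "n_points": enh.n_points,
        }
        fname = f"field_map_{name}.txt"
        _write_field_map(grid, out / fname)
        files.append(fname)
        if cfg["vertical_slice"] and name == "oblique":
            zs = np.linspace(1.0, 3.0 * d_hi, 40)
            xs = np.linspace(0.0, cfg["region"][0], int(nx))
            X, Z = np.meshgrid(xs, zs, indexing="ij")
            vpts = np.column_stack(
                [X.ravel(), np.full(X.size, cfg["region"][1] / 2.0), Z.ravel()]
            )
            vgrid = dipoles.total_field(ens, sol, vpts)
            _write_field_map(vgrid, out / "field_slice_vertical.txt")
            files.append("field_slice_vertical.txt")
        if cfg["heights"] is not None and name == "oblique":
            profile = dipoles.field_vs_height(ens, sol, cfg["heights"])
            profile.to_csv(out / "field_vs_height.csv", index=False)
            files.append("field_vs_height.csv")

    summary["tm_over_normal_mean_enhancement"] = (
        summary["enhancement"]["oblique"]["mean"]
        / summary["enhancement"]["normal"]["mean"]
    )
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    files.append("summary.json")
    _write_resolved(cfg, out)
    files.append("resolved_config.yaml")
    _manifest(out, files)
    return summary


def run_synth_workflow(config: dict, out_dir) -> dict:
    """Write synthetic oxidized/reduced/mixture spectra as two-column ASCII."""
    _check_keys(config, _SYNTH_KEYS, "synth-spectra")
    cfg = {
        "seed": 0, "which": "mitochondria", "states": ["oxidized", "reduced"],
        "fractions": [], "noise_sd": 0.05, "axis": list(spectra.DEFAULT_AXIS),
        "baseline": [list(spectra.DEFAULT_TREATMENT_BASELINE[0]),
                     list(spectra.DEFAULT_TREATMENT_BASELINE[1])],
    }
    cfg.update(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lib = spectra.band_library()
    axis = tuple(cfg["axis"])
    baseline = tuple(map(tuple, cfg["baseline"])) if cfg["baseline"] else None
    rng = np.random.default_rng(int(cfg["seed"]))
    files = []
    for state in cfg["states"]:
        tr = spectra.synthesize_spectrum(
            lib.get(cfg["which"], state), axis, baseline,
            cfg["noise_sd"], int(rng.integers(0, 2**31 - 1)),
            metadata={"state": state, "which": cfg["which"]},
        )
        fname = f"synthetic_{cfg['which']}_{state}.txt"
        spectra.write_spectrum(tr, out / fname)
        files.append(fname)
    for f_red in cfg["fractions"]:
        tr = spectra.mixture_spectrum(
            float(f_red), lib, cfg["which"], axis, baseline,
            cfg["noise_sd"], int(rng.integers(0, 2**31 - 1)),
        )
        fname = f"synthetic_{cfg['which']}_f{float(f_red):.2f}.txt"
        spectra.write_spectrum(tr, out / fname)
        files.append(fname)
    _write_resolved(cfg, out)
    files.append("resolved_config.yaml")
    _manifest(out, files)
    return {"files": files}


def run_spectral_workflow(config: dict, out_dir) -> dict:
    """Baseline-subtract, ratio and classify a set of spectra from disk.

    ``spectra`` maps a label to a file path; ``control`` optionally names the
    label whose ratios define 100% for percent-of-control statistics.
    """
    _check_keys(config, _ANALYZE_KEYS, "analyze-spectra")
    inputs = config.get("spectra") or {}
    if not inputs:
        raise ConfigError("analyze-spectra: empty input set ('spectra' is required)")
    missing = [str(p) for p in inputs.values() if not Path(p).exists()]
    if missing:
        raise ConfigError(f"analyze-spectra: missing spectrum files {missing}")
    state = config.get("state", "oxidized")
    knots = None
    if config.get("knot_positions"):
        knots = spectra.BaselineKnots(
            positions=tuple(config["knot_positions"]),
            half_width=int(config.get("knot_half_width", 2)),
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    reports = {}
    rows = []
    for label, path in inputs.items():
        tr = spectra.read_spectrum(path)
        flat = spectra.subtract_baseline(tr, knots)
        rr = spectra.peak_ratios(flat, state=state)
        call = spectra.classify_redox(flat)
        reports[label] = {
            "ratios": {"r748": rr.r748, "r1170": rr.r1170, "r1371": rr.r1371},
            "centers": rr.centers,
            "redox": {
                "state": call.state,
                "reduced_fraction": call.reduced_fraction_estimate,
                "low_confidence": call.low_confidence,
            },
        }
        rows.append({
            "label": label, "r748": rr.r748, "r1170": rr.r1170, "r1371": rr.r1371,
            "redox_state": call.state,
            "reduced_fraction": call.reduced_fraction_estimate,
        })

    control = config.get("control")
    if control is not None:
        if control not in reports:
            raise ConfigError(f"analyze-spectra: control label {control!r} not in inputs")
        c = reports[control]["ratios"]
        c_rep = spectra.RatioReport(r748=c["r748"], r1170=c["r1170"], r1371=c["r1371"])
        for label in reports:
            t = reports[label]["ratios"]
            t_rep = spectra.RatioReport(r748=t["r748"], r1170=t["r1170"], r1371=t["r1371"])
            pct = spectra.percent_of_control(t_rep, c_rep)
            reports[label]["percent_of_control"] = {
                "r748": pct.r748, "r1170": pct.r1170, "r1371": pct.r1371,
            }

    (out / "report.json").write_text(json.dumps(reports, indent=2) + "\n")
    pd.DataFrame(rows).to_csv(out / "report.csv", index=False)
    resolved = dict(config)
    _write_resolved(resolved, out)
    _manifest(out, ["report.json", "report.csv", "resolved_config.yaml"])
    return reports


def run_treatment_workflow(config: dict, out_dir) -> dict:
    """Synthetic treatment experiment (uncoupler or ATP-synthase inhibitor)."""
    _check_keys(config, _TREATMENT_KEYS, "treatment-sim")
    cfg = {
        "seed": 0, "f_red_control": 0.6, "delta_f": -0.3,
        "n_replicates": 10, "noise_sd": 0.05, "which": "mitochondria",
    }
    cfg.update(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = spectra.treatment_series(
        f_red_control=float(cfg["f_red_control"]), delta_f=float(cfg["delta_f"]),
        n_replicates=int(cfg["n_replicates"]), noise_sd=float(cfg["noise_sd"]),
        seed=int(cfg["seed"]), which=cfg["which"],
    )
    table.to_csv(out / "treatment_table.csv", index=False)
    summary = {
        "config": cfg,
        "mean_pct_r748": float(table["pct_r748"].mean()),
        "mean_pct_r1170": float(table["pct_r1170"].mean()),
        "mean_pct_r1371": float(table["pct_r1371"].mean()),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    _write_resolved(cfg, out)
    _manifest(out, ["treatment_table.csv", "summary.json", "resolved_config.yaml"])
    return summary
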