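"""End-to-end orchestration: config parsing, run provenance, and assembly of
the headline analyses into machine-readable reports.

A pipeline config (YAML or dict) names an output directory, a global seed
and a list of stages. Every stage writes into its own subdirectory together
with a ``manifest.json`` (config snapshot, package version, seed, input
hashes, timestamp) sufficient to reproduce its outputs; stages whose
manifest already matches the requested parameters are skipped, so deleting
one stage's outputs triggers only that stage.

Conventions used throughout the reports: RNA/protein ratios are mg RNA per
mg protein *within the simulation box*; temperatures are reported both raw
(K) and renormalized by the relevant critical temperature, since absolute
temperatures of an implicit-solvent coarse-grained model are only meaningful
relative to each other.
"""

from __future__ import annotations

import hashlib
import json
import time
from importlib import metadata
from pathlib import Path

import numpy as np
import yaml


class ConfigError(ValueError):
    """Pipeline config schema violation, naming the offending field."""


def _version() -> str:
    try:
        return metadata.version("llpsmd")
    except metadata.PackageNotFoundError:
        return "unknown"


def _hash_params(kind: str, params: dict, seed: int) -> str:
    blob = json.dumps({"kind": kind, "params": params, "seed": seed},
                      sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# -- stages -------------------------------------------------------------------

def _stage_sequence_report(outdir: Path, params: dict, seed: int) -> dict:
    from . import sequences as sq
    from .forcefield import default_params

    ff = default_params()
    proteins = sq.load_reference_proteins()
    report = {}
    for name, seq in proteins.items():
        comp = sq.composition(seq)
        entry = {
            "length": len(seq),
            "net_charge_e": sq.net_charge(seq, ff),
            "mass_g_mol": sq.chain_mass(seq, ff),
            "top_composition": dict(sorted(comp.items(),
                                           key=lambda kv: -kv[1])[:5]),
        }
        try:
            entry["electroneutral_mass_ratio"] = sq.electroneutral_mass_ratio(
                seq, sq.make_polyU(250), ff)
        except sq.NoElectroneutralPoint:
            entry["electroneutral_mass_ratio"] = None
        report[name] = entry
    lcd = sq.hnrnpa1_a_lcd(proteins["hnRNPA1"])
    report["hnRNPA1-A-LCD"] = {"length": len(lcd),
                               "segment_lengths": [66, 69]}
    (outdir / "sequences.json").write_text(json.dumps(report, indent=2))
    return report


def _stage_phase_diagram(outdir: Path, params: dict, seed: int) -> dict:
    from .fixtures import FixtureSpec, save_binodal, synthetic_binodal
    from .phase_analysis import fit_critical_point

    gen = dict(tc=params.get("tc", 400.0), rho_c=params.get("rho_c", 0.3),
               n_points=params.get("n_points", 6),
               noise=params.get("noise", 0.01))
    points = synthetic_binodal(seed=seed, **gen)
    spec = FixtureSpec("binodal", gen, seed)
    save_binodal(points, outdir / "binodal.csv", spec)
    diagram = fit_critical_point(points, seed=seed)
    out = {"tc_K": diagram.tc, "tc_err_K": diagram.tc_err,
           "rho_c_g_cm3": diagram.rho_c, "rho_c_err_g_cm3": diagram.rho_c_err,
           "beta": diagram.beta, "generator": gen}
    (outdir / "critical_point.json").write_text(json.dumps(out, indent=2))
    return out


def _stage_interface(outdir: Path, params: dict, seed: int) -> dict:
    from .fixtures import FixtureSpec, save_profile, tanh_profile
    from .phase_analysis import coexisting_densities

    gen = dict(rho_h=params.get("rho_h", 0.30), rho_l=params.get("rho_l", 0.02),
               z0=params.get("z0", 10.0), width=params.get("width", 1.0),
               noise=params.get("noise", 0.01))
    profile = tanh_profile(seed=seed, **gen)
    save_profile(profile, outdir / "profile.csv",
                 FixtureSpec("tanh_profile", gen, seed))
    point = coexisting_densities(profile)
    out = {"rho_low_g_cm3": point.rho_low, "rho_high_g_cm3": point.rho_high,
           "generator": gen}
    (outdir / "coexistence.json").write_text(json.dumps(out, indent=2))
    return out


def _stage_rheology(outdir: Path, params: dict, seed: int) -> dict:
    from .fixtures import FixtureSpec, save_stress, stress_series
    from .transport import fit_maxwell_modes, relaxation_modulus, viscosity

    modes = [tuple(m) for m in params.get("modes", [[0.02, 50.0]])]
    t = params.get("temperature", 300.0)
    v = params.get("volume", 1000.0)
    dt = params.get("dt", 1.0)
    n = params.get("n_steps", 200000)
    series = stress_series(modes, t, v, n, dt, seed=seed)
    save_stress(series[: params.get("save_frames", 2000)],
                outdir / "stress.csv", dt, t, v,
                FixtureSpec("stress_series",
                            {"modes": modes, "dt": dt, "n_steps": n}, seed))
    modulus = relaxation_modulus(series, temperature=t, volume=v, dt=dt)
    fitted = fit_maxwell_modes(modulus, n_modes=params.get("n_modes", 4))
    eta, eta_err = viscosity(fitted)
    out = {"viscosity_mPa_s": eta, "viscosity_err_mPa_s": eta_err,
           "modes": [[m.g, m.tau] for m in fitted.modes],
           "generator_modes": modes}
    (outdir / "viscosity.json").write_text(json.dumps(out, indent=2))
    return out


STAGES = {
    "sequence_report": _stage_sequence_report,
    "phase_diagram": _stage_phase_diagram,
    "interface": _stage_interface,
    "rheology": _stage_rheology,
}


# -- config & driver ----------------------------------------------------------

def load_config(source) -> dict:
    if isinstance(source, dict):
        return source
    with open(source) as fh:
        return yaml.safe_load(fh)


def validate_config(config: dict) -> None:
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    if not isinstance(config.get("seed", 0), int):
        raise ConfigError("field 'seed': must be an integer")
    if "outdir" not in config or not isinstance(config["outdir"], str):
        raise ConfigError("field 'outdir': required string")
    stages = config.get("stages")
    if not isinstance(stages, list) or not stages:
        raise ConfigError("field 'stages': required non-empty list")
    names = set()
    for i, stage in enumerate(stages):
        if not isinstance(stage, dict):
            raise ConfigError(f"stages[{i}]: must be a mapping")
        kind = stage.get("kind")
        if kind not in STAGES:
            raise ConfigError(
                f"stages[{i}].kind: unknown kind {kind!r}; "
                f"expected one of {sorted(STAGES)}")
        name = stage.get("name", kind)
        if name in names:
            raise ConfigError(f"stages[{i}].name: duplicate stage name {name!r}")
        names.add(name)
        if "params" in stage and not isinstance(stage["params"], dict):
            raise ConfigError(f"stages[{i}].params: must be a mapping")


def run_pipeline(source) -> dict:
    """Run (or resume) a pipeline; returns {stage name: stage report}."""
    config = load_config(source)
    validate_config(config)
    base = Path(config["outdir"])
    base.mkdir(parents=True, exist_ok=True)
    global_seed = int(config.get("seed", 0))
    report: dict = {}
    for stage in config["stages"]:
        kind = stage["kind"]
        name = stage.get("name", kind)
        params = stage.get("params", {})
        seed = int(stage.get("seed", global_seed))
        outdir = base / name
        digest = _hash_params(kind, params, seed)
        manifest_path = outdir / "manifest.json"
        if manifest_path.exists():
            manifest = json.loads(manifest_path.read_text())
            if manifest.get("config_hash") == digest and all(
                    (outdir / f).exists() for f in manifest.get("outputs", [])):
                report[name] = manifest.get("report", {})
                continue
        outdir.mkdir(parents=True, exist_ok=True)
        result = STAGES[kind](outdir, params, seed)
        outputs = sorted(p.name for p in outdir.iterdir()
                         if p.name != "manifest.json")
        manifest = {
            "stage": name, "kind": kind, "params": params, "seed": seed,
            "config_hash": digest, "code_version": _version(),
            "outputs": outputs,
            "output_hashes": {f: _hash_file(outdir / f) for f in outputs},
            "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "report": result,
        }
        manifest_path.write_text(json.dumps(manifest, indent=2))
        report[name] = result
    (base / "report.json").write_text(json.dumps(report, indent=2))
    return report
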