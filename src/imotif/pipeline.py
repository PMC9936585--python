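"""Pipeline orchestration: structure in, titration curves + knockout table +
geometry report + transition simulation out.

Configuration is a flat INI-style key-value file with sections; every output
file carries the seed and a hash of the configuration in its header so that
reruns are reproducible bit-for-bit.
"""

from __future__ import annotations

import configparser
import hashlib
import io
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .structure import Structure, parse_structure, write_structure, \
    assign_charges, load_charge_set, default_charge_set
from .synth import BuildSpec, build_imotif
from .electrostatics import EnergyModel
from .titration import (TitrationModel, knockout_scan, default_ph_grid,
                        LOOP_EXCLUSION_DEFAULT, DEFAULT_SITE_INDICES)
from .geometry import describe
from .dynamics import build_cg_model, RatchetSimulation, transition_summary

__all__ = ["RunConfig", "PipelineError", "run_titration_pipeline",
           "run_full_report", "load_config"]

log = logging.getLogger("imotif")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    # input: a PDB path, or a builder spec
    input_pdb: str | None = None
    charge_file: str | None = None
    n_cc_pairs: int = 2
    capping: str = "GCGC"
    topology: str = "3E"
    rise: float = 3.1
    twist: float = 30.0
    noise_sigma: float = 0.0
    # energy model
    eps_in: float = 6.0
    eps_out: float = 80.0
    variant: str = "uniform-screened"
    temperature: float = 298.15
    # titration
    site_indices: tuple = DEFAULT_SITE_INDICES
    ph_start: float = 0.0
    ph_stop: float = 16.0
    ph_step: float = 0.05
    exclude_residues: tuple = LOOP_EXCLUSION_DEFAULT
    knockout_mode: str = "zero-all-charges"
    variants: tuple = ("stack-only", "with-tetrads")
    # transition
    run_transition: bool = False
    scenarios: tuple = ("neutral", "acidic")
    n_trajectories: int = 20
    n_steps: int = 24000
    force_constant: float = 200.0
    threshold: float = 0.7
    # bookkeeping
    output_dir: str = "imotif_out"
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def energy_model(self) -> EnergyModel:
        return EnergyModel(eps_in=self.eps_in, eps_out=self.eps_out,
                           variant=self.variant, temperature=self.temperature)

    def ph_grid(self) -> np.ndarray:
        grid = default_ph_grid(self.ph_start, self.ph_stop, self.ph_step)
        if len(grid) < 2:
            raise PipelineError("config", "pH grid must be increasing")
        return grid


def _parse_tuple(text, cast=int):
    items = [t for t in text.replace(",", " ").split() if t]
    return tuple(cast(t) for t in items)


def load_config(path) -> RunConfig:
    """Read a RunConfig from an INI-style file."""
    cp = configparser.ConfigParser()
    read = cp.read(path)
    if not read:
        raise PipelineError("config", f"cannot read config file {path}")
    cfg = RunConfig()
    mapping = {
        ("input", "pdb"): ("input_pdb", str),
        ("input", "charge_file"): ("charge_file", str),
        ("input", "n_cc_pairs"): ("n_cc_pairs", int),
        ("input", "capping"): ("capping", str),
        ("input", "topology"): ("topology", str),
        ("input", "rise"): ("rise", float),
        ("input", "twist"): ("twist", float),
        ("input", "noise_sigma"): ("noise_sigma", float),
        ("energy", "eps_in"): ("eps_in", float),
        ("energy", "eps_out"): ("eps_out", float),
        ("energy", "variant"): ("variant", str),
        ("energy", "temperature"): ("temperature", float),
        ("titration", "sites"): ("site_indices", lambda t: _parse_tuple(t)),
        ("titration", "ph_start"): ("ph_start", float),
        ("titration", "ph_stop"): ("ph_stop", float),
        ("titration", "ph_step"): ("ph_step", float),
        ("titration", "exclude"): ("exclude_residues", lambda t: _parse_tuple(t)),
        ("titration", "knockout_mode"): ("knockout_mode", str),
        ("titration", "variants"): ("variants", lambda t: _parse_tuple(t, str)),
        ("transition", "run"): ("run_transition", lambda t: t.lower() == "true"),
        ("transition", "scenarios"): ("scenarios", lambda t: _parse_tuple(t, str)),
        ("transition", "n_trajectories"): ("n_trajectories", int),
        ("transition", "n_steps"): ("n_steps", int),
        ("transition", "force_constant"): ("force_constant", float),
        ("transition", "threshold"): ("threshold", float),
        ("output", "dir"): ("output_dir", str),
        ("output", "seed"): ("seed", int),
        ("output", "log_level"): ("log_level", str),
    }
    for (section, key), (attr, cast) in mapping.items():
        if cp.has_option(section, key):
            setattr(cfg, attr, cast(cp.get(section, key)))
    return cfg


def _header(config: RunConfig) -> str:
    return (f"# imotif pipeline output\n"
            f"# seed={config.seed} config_sha256={config.config_hash()}\n")


def _write_csv(path: Path, frame, config: RunConfig):
    with open(path, "w") as fh:
        fh.write(_header(config))
        frame.to_csv(fh, index=False, float_format="%.6g")


def _load_input_structure(config: RunConfig) -> Structure:
    if config.input_pdb:
        try:
            text = Path(config.input_pdb).read_text()
        except OSError as exc:
            raise PipelineError("input", f"{config.input_pdb}: {exc}")
        ens = parse_structure(text, label=Path(config.input_pdb).stem)
        return ens.models[0]
    spec = BuildSpec(n_cc_pairs=config.n_cc_pairs, capping=config.capping,
                     topology=config.topology, rise=config.rise,
                     twist=config.twist, noise_sigma=config.noise_sigma,
                     seed=config.seed)
    return build_imotif(spec)


def _charge_set(config: RunConfig) -> dict:
    if config.charge_file:
        try:
            return load_charge_set(Path(config.charge_file).read_text())
        except OSError as exc:
            raise PipelineError("charges", f"{config.charge_file}: {exc}")
    return default_charge_set()


def _variant_structure(structure: Structure, variant: str,
                       config: RunConfig) -> Structure:
    if variant == "with-tetrads":
        return structure
    if variant == "stack-only":
        keep = set(config.site_indices)
        return structure.subset(lambda r: r.index in keep)
    raise PipelineError("titration", f"unknown variant {variant!r}")


def run_titration_pipeline(config: RunConfig) -> dict:
    """Titration curves, macroscopic pKa table and knockout table.

    Produces the requested variants (stack-only and stack+tetrads) and
    returns a manifest of output paths.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.output_dir)
    charge_set = _charge_set(config)            # fail before creating outputs
    structure = _load_input_structure(config)
    outdir.mkdir(parents=True, exist_ok=True)
    em = config.energy_model()
    grid = config.ph_grid()
    outputs = {"variants": {}}
    import pandas as pd
    pka_rows = []
    for variant in config.variants:
        log.info("titration variant %s", variant)
        sub = _variant_structure(structure, variant, config)
        try:
            charged = assign_charges(sub, charge_set)
            model = TitrationModel.from_structure(
                charged, config.site_indices, em, charge_set,
                exclude_residues=config.exclude_residues)
            result = model.solve(grid)
        except Exception as exc:
            raise PipelineError(f"titration:{variant}", str(exc)) from exc
        path = outdir / f"curves_{variant}.csv"
        _write_csv(path, result.to_frame(), config)
        outputs["variants"][variant] = str(path)
        for lv, ph in result.curve.macroscopic_pkas:
            pka_rows.append({"variant": variant, "level": lv,
                             "pKa": round(ph, 3)})
    pka_frame = pd.DataFrame(pka_rows)
    pka_path = outdir / "macroscopic_pka.csv"
    _write_csv(pka_path, pka_frame, config)
    outputs["pka_table"] = str(pka_path)
    try:
        charged_full = assign_charges(structure, charge_set)
        ko = knockout_scan(charged_full, config.site_indices, em,
                           mode=config.knockout_mode, charge_set=charge_set,
                           exclude_residues=config.exclude_residues,
                           ph_grid=grid)
    except Exception as exc:
        raise PipelineError("knockout", str(exc)) from exc
    ko_path = outdir / "knockout_dpka.csv"
    _write_csv(ko_path, ko, config)
    outputs["knockout_table"] = str(ko_path)
    return outputs


def run_transition_stage(config: RunConfig) -> dict:
    """Coarse-grained rMD surrogate for the configured scenarios."""
    start = build_imotif(BuildSpec(n_cc_pairs=4, capping="GTGT",
                                   topology="3E"))
    target = build_imotif(BuildSpec(n_cc_pairs=2, capping="GCGC",
                                    topology="3E"))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    import pandas as pd
    out = {}
    for scen in config.scenarios:
        model = build_cg_model(start, target, scen)
        sim = RatchetSimulation(model, n_steps=config.n_steps,
                                k_bias=config.force_constant,
                                threshold=config.threshold)
        seeds = [config.seed + 1000 * i for i in range(config.n_trajectories)]
        run = sim.run(seeds)
        frame = pd.DataFrame(run.xi_series.T,
                             columns=[f"traj_{s}" for s in seeds])
        path = outdir / f"transition_{scen}_xi.csv"
        _write_csv(path, frame, config)
        summ = transition_summary(run)
        out[scen] = {"xi_csv": str(path),
                     "successes": int(run.success.sum()),
                     "n_trajectories": len(seeds),
                     "final_median_xi": float(np.median(run.xi_series[:, -1])),
                     "mean_gplane_last":
                         float(np.mean(summ["gplane_distance"][-len(seeds):]))}
    return out


def run_full_report(config: RunConfig) -> dict:
    """Geometry report + titration outputs (+ optional transition run),
    cross-referenced in one manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "config_sha256": config.config_hash(),
                "config": asdict(config)}
    structure = _load_input_structure(config)
    report = describe(structure)
    geo_path = outdir / "geometry_report.json"
    with open(geo_path, "w") as fh:
        json.dump({"seed": config.seed,
                   "config_sha256": config.config_hash(),
                   "report": report.as_dict()}, fh, indent=1, sort_keys=True)
    manifest["geometry_report"] = str(geo_path)
    manifest["titration"] = run_titration_pipeline(config)
    if config.run_transition:
        manifest["transition"] = run_transition_stage(config)
    man_path = outdir / "manifest.json"
    with open(man_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return manifest
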