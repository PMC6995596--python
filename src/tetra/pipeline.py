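"""End-to-end orchestration of the three analysis stages.

A run is described by a flat config (YAML/dict): stage selections, per-stage
parameter blocks, an output directory, and a seed. Stages communicate via
files under the output directory so any intermediate can be inspected and
any stage re-run. The report records the package version, a hash of the
config, and every derived seed.
"""

from __future__ import annotations

import hashlib
import json
import os
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from . import afmdock, itc, itcfit, synthdata, xlinks
from .structio import write_pdb


class ConfigError(ValueError):
    pass


_KNOWN_TOP = {"stages", "outdir", "seed"}
_KNOWN_STAGE = {"xl_eval", "afm_dock", "itc_fit"}


def _config_hash(config: Mapping[str, Any]) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def load_config(path: str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return cfg


def run_pipeline(config: Mapping[str, Any]) -> dict:
    """Execute the requested stages on synthetic inputs; return the report.

    Each stage generates its declared synthetic input (seeded from the run
    seed), writes intermediates to ``outdir``, and contributes a block to the
    JSON-serializable report. A stage failure is recorded with its cause and
    marks the run failed.
    """
    unknown = set(config) - _KNOWN_TOP
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    stages = config.get("stages", {}) or {}
    unknown = set(stages) - _KNOWN_STAGE
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    outdir = str(config.get("outdir", "tetra_run"))
    seed = int(config.get("seed", 0))
    os.makedirs(outdir, exist_ok=True)
    report: dict[str, Any] = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": seed,
        "stages": {},
        "ok": True,
    }
    runners = {"xl_eval": _run_xl, "afm_dock": _run_afm, "itc_fit": _run_itc}
    for name in ("xl_eval", "afm_dock", "itc_fit"):
        if name not in stages:
            continue
        params = stages[name] or {}
        try:
            report["stages"][name] = runners[name](params, outdir, seed)
        except Exception as exc:
            report["stages"][name] = {"error": f"{type(exc).__name__}: {exc}"}
            report["ok"] = False
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report


def _run_xl(params: Mapping[str, Any], outdir: str, seed: int) -> dict:
    n = int(params.get("n_links", 40))
    frac = float(params.get("satisfied_fraction", 0.75))
    model = synthdata.toy_model(
        n_chains=int(params.get("n_chains", 2)),
        residues_per_chain=int(params.get("residues_per_chain", 30)),
        seed=seed,
    )
    links, labels = synthdata.sample_crosslinks(model, n=n, satisfied_fraction=frac, seed=seed + 1)
    write_pdb(model, os.path.join(outdir, "xl_model.pdb"))
    xlinks.write_crosslinks(links, os.path.join(outdir, "xl_links.csv"))
    restraints = xlinks.build_restraints(
        links, {c: [c] for c in model.chains()}
    )
    xlinks.export_restraints(restraints, "haddock_tbl", os.path.join(outdir, "xl_restraints.tbl"))
    report = xlinks.evaluate_restraints(model, restraints)
    report.details.to_csv(os.path.join(outdir, "xl_report.csv"), index=False)
    return {
        "n_links": report.n_total,
        "n_satisfied": report.n_satisfied,
        "n_violated": report.n_violated,
        "satisfaction_fraction": report.satisfaction_fraction,
        "seed": seed + 1,
    }


def _run_afm(params: Mapping[str, Any], outdir: str, seed: int) -> dict:
    model = synthdata.bipartite_model(
        core_radius=float(params.get("core_radius", 2.0)),
        arm_length=float(params.get("arm_length", 6.0)),
        seed=seed,
    )
    pixel = float(params.get("pixel_size", 1.0))
    topo = afmdock.simulate_topograph(model, pixel_size=pixel)
    sd = float(params.get("noise_sd", 0.0))
    if sd > 0:
        topo = synthdata.noisy_topograph(topo, sd, seed=seed + 2)
    topo.save(os.path.join(outdir, "afm_topograph.txt"))
    result = afmdock.dock(
        model,
        topo,
        rotation_step=float(params.get("rotation_step", 90.0)),
        layer_thickness=float(params.get("layer_thickness", 1.0)),
        keep=int(params.get("keep", 100_000)),
    )
    return {
        "max_height_nm": afmdock.max_height(topo),
        "min_energy": result.min_energy,
        "mean_energy_top10": result.mean_energy_top10,
        "rmsd_top3_A": result.rmsd_top3,
        "xy_offset_best_nm": result.xy_offset_best,
        "n_poses": result.n_poses,
    }


def _run_itc(params: Mapping[str, Any], outdir: str, seed: int) -> dict:
    kd = tuple(float(k) for k in params.get("kd", (1.5e-9, 4.3e-6)))
    dh = tuple(float(h) for h in params.get("dh", (-226.25, -360.0)))
    scheme = itc.TitrationScheme(
        cell_conc_M=float(params.get("cell_conc_M", 2.5e-6)),
        syringe_conc_M=float(params.get("syringe_conc_M", 25e-6)),
        temperature_K=float(params.get("temperature_K", 298.15)),
    )
    model = itc.BindingModel.sequential(tuple(zip(kd, dh)))
    iso = itc.simulate_isotherm(scheme, model)
    sd = float(params.get("noise_sd", 0.0))
    if sd > 0:
        iso = synthdata.noisy_isotherm(iso, sd, seed=seed + 3)
    iso.to_csv(os.path.join(outdir, "itc_isotherm.csv"))
    spec = itcfit.FitSpec.for_model(model, seed=seed, multistart=int(params.get("multistart", 8)))
    result = itcfit.fit(iso, scheme, spec)
    with open(os.path.join(outdir, "itc_fit.txt"), "w") as fh:
        fh.write(result.table() + "\n")
    return {
        "params": result.params,
        "rss": result.rss,
        "events": [
            {"kd_M": s.kd, "dG_kJ_mol": s.dG, "dH_kJ_mol": s.dH, "mTdS_kJ_mol": s.mTdS}
            for s in result.thermo
        ],
        "bounded_only": result.diagnostics["bounded_only"],
        "seed": seed,
    }
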