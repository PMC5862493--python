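"""Experiment recipes: configuration, validation, orchestration and I/O.

A recipe bundles everything needed to reproduce a gain-modulation sweep:
morphology source, biophysics overrides, drive settings, the illumination
grid, and a seed.  ``run_recipe`` executes morphology generation ->
opsin decoration -> drive calibration -> modulation sweep and writes a
results table plus a manifest sufficient for an exact re-run.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cable import SimResult
from .gain import DEFAULT_STUDY, StudyConfig, sweep_modulation
from .morphology import MorphologySpec, read_swc

log = logging.getLogger("photogain")

__all__ = [
    "ExperimentRecipe", "ValidationReport", "validate_config",
    "run_recipe", "traces_to_csv", "traces_to_hdf5", "spikes_to_csv",
]

#: defaults that are package assumptions rather than measured quantities
ASSUMED_DEFAULTS = {
    "axial_resistivity": "axial resistivity (Ohm*cm) is a package default, "
                         "not a measured value",
    "spike_threshold": "spike detection threshold 0 mV / refractory 2 ms "
                       "are package conventions",
    "opsin_rates": "photocycle rate constants ship as plausible preset "
                   "defaults, not fitted values",
    "synapse_reversals": "synaptic reversal potentials (0 / -80 mV) are "
                         "package conventions",
}

_RECIPE_KEYS = {
    "name", "morphology", "swc_path", "irradiances", "seed",
    "x_chr2_dominated", "x_nphr_dominated", "rates_hz", "n_sites",
    "n_seeds", "g_ref_um2", "axial_resistivity", "out_dir",
}


@dataclass
class ExperimentRecipe:
    name: str
    morphology: List[Tuple[int, int, int]]    # (n_p, n_b, n_levels) triplets
    irradiances: List[float]
    seed: int = 0
    swc_path: Optional[str] = None
    study: StudyConfig = field(default_factory=lambda: DEFAULT_STUDY)

    @classmethod
    def from_dict(cls, cfg: dict) -> "ExperimentRecipe":
        report = validate_config(cfg)
        if report.errors:
            raise ValueError("invalid recipe: " + "; ".join(report.errors))
        study_kwargs = {}
        for key in ("rates_hz", "n_sites", "n_seeds", "g_ref_um2",
                    "axial_resistivity", "x_chr2_dominated",
                    "x_nphr_dominated"):
            if key in cfg:
                val = cfg[key]
                study_kwargs[key] = tuple(val) if key == "rates_hz" else val
        return cls(
            name=str(cfg["name"]),
            morphology=[tuple(m) for m in cfg.get("morphology", [])],
            irradiances=[float(i) for i in cfg["irradiances"]],
            seed=int(cfg.get("seed", 0)),
            swc_path=cfg.get("swc_path"),
            study=dataclasses.replace(DEFAULT_STUDY, **study_kwargs),
        )

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ExperimentRecipe":
        cfg = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(cfg)

    def config_hash(self) -> str:
        payload = json.dumps(
            {"name": self.name, "morphology": self.morphology,
             "irradiances": self.irradiances, "seed": self.seed,
             "swc_path": self.swc_path,
             "study": dataclasses.asdict(self.study)},
            sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ValidationReport:
    errors: List[str] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)
    assumed_defaults: Dict[str, str] = field(
        default_factory=lambda: dict(ASSUMED_DEFAULTS))

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_config(cfg: dict) -> ValidationReport:
    """Schema and unit checks for a recipe dictionary (report, no raise)."""
    rep = ValidationReport()
    if not isinstance(cfg, dict):
        rep.errors.append("recipe must be a mapping")
        return rep
    for key in cfg:
        if key not in _RECIPE_KEYS:
            hint = difflib.get_close_matches(key, _RECIPE_KEYS, n=1)
            extra = f" (did you mean {hint[0]!r}?)" if hint else ""
            rep.warnings.append(f"unknown key {key!r}{extra}")
    if "name" not in cfg:
        rep.errors.append("missing required key 'name'")
    if not cfg.get("morphology") and not cfg.get("swc_path"):
        rep.errors.append("recipe needs 'morphology' triplets or 'swc_path'")
    if cfg.get("swc_path") and not Path(cfg["swc_path"]).exists():
        rep.errors.append(f"swc_path {cfg['swc_path']!r} does not exist")
    irr = cfg.get("irradiances")
    if not irr:
        rep.errors.append("missing or empty 'irradiances'")
    else:
        if any(float(v) < 0 for v in irr):
            rep.errors.append("irradiances must be >= 0 (mW/mm^2)")
    for m in cfg.get("morphology", []):
        if len(m) != 3 or any(int(v) < 1 for v in m):
            rep.errors.append(f"bad morphology triplet {m!r}")
    if "rates_hz" in cfg and any(float(r) <= 0 for r in cfg["rates_hz"]):
        rep.errors.append("rates_hz must be > 0")
    return rep


def run_recipe(recipe: ExperimentRecipe,
               out_dir: Union[str, Path]) -> pd.DataFrame:
    """Execute a recipe end to end and persist results + manifest.

    Writes ``gain_table.csv`` (one row per morphology x irradiance, each
    carrying seed and config hash) and ``manifest.json``.  On failure a
    ``FAILED`` marker naming the stage is left next to any partial output.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = recipe.config_hash()
    stage = "setup"
    t0 = time.time()
    try:
        stage = "morphology"
        if recipe.swc_path:
            specs = [read_swc(recipe.swc_path)]
        else:
            specs = [MorphologySpec(*m) for m in recipe.morphology]
        log.info("recipe %s: %d morphologies x %d irradiances (hash %s)",
                 recipe.name, len(specs), len(recipe.irradiances), chash)
        stage = "sweep"
        table = sweep_modulation(specs, recipe.irradiances,
                                 seed=recipe.seed, config=recipe.study)
        table["config_hash"] = chash
        stage = "write"
        table.to_csv(out / "gain_table.csv", index=False)
        manifest = {
            "name": recipe.name,
            "version": __version__,
            "seed": recipe.seed,
            "config_hash": chash,
            "study": dataclasses.asdict(recipe.study),
            "morphology": recipe.morphology,
            "irradiances": recipe.irradiances,
            "elapsed_s": round(time.time() - t0, 2),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        log.info("recipe %s finished in %.1f s", recipe.name, time.time() - t0)
        return table
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"recipe {recipe.name!r} failed during "
                           f"{stage}: {exc}") from exc


# ---------------------------------------------------------------------------
# Trace / spike export
# ---------------------------------------------------------------------------

def traces_to_csv(result: SimResult, path: Union[str, Path]) -> None:
    """Long-format CSV: time_ms, site, v_mV."""
    frames = []
    for site, v in result.voltage.items():
        frames.append(pd.DataFrame(
            {"time_ms": result.t, "site": str(site), "v_mV": v}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def traces_to_hdf5(result: SimResult, path: Union[str, Path]) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("time_ms", data=result.t)
        g = f.create_group("voltage")
        for site, v in result.voltage.items():
            g.create_dataset(str(site), data=v)
        p = f.create_group("photocurrent_nA")
        for name, i in result.photocurrent.items():
            p.create_dataset(name, data=i)
        f.create_dataset("spike_times_ms", data=result.spike_times)
        f.attrs["dt_ms"] = result.dt
        for k, v in result.meta.items():
            f.attrs[f"meta_{k}"] = str(v)


def spikes_to_csv(result: SimResult, path: Union[str, Path]) -> None:
    pd.DataFrame({"t_ms": result.spike_times}).to_csv(path, index=False)
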