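"""End-to-end orchestration: simulate -> preprocess -> fit -> overlap -> prioritize.

One YAML config drives the whole analysis. Each stage writes its artifacts
under ``<output_dir>/<stage>/`` together with a manifest recording a hash
of its effective inputs and of every output file; a re-run skips stages
whose input hash is unchanged and whose outputs are intact. All randomness
derives from one master seed through named per-stage substreams.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .ensemble import (EnsembleConfig, fit_ensemble, predict_ensemble,
                       response_curve, variable_contribution)
from .grid import EnvStack
from .marxan import ReserveProblem, repeat_runs, select_key_areas
from .overlap import binarize_suitability, overlap_map
from .preprocess import collinearity_filter, derive_standard_layers
from .synthetic import (LandscapeConfig, OccurrenceSet, TrueNiche,
                        generate_env_stack, sample_presences)
from .units import (DisturbanceScheme, aggregate_feature_amounts,
                    compute_costs, grid_boundary, hex_tessellate,
                    write_bound_dat, write_pu_dat, write_puvspr_dat,
                    write_spec_dat)

STAGES = ("simulate", "preprocess", "fit", "overlap", "prioritize")


def default_species_niches() -> dict[str, TrueNiche]:
    """Four ground-dwelling-bird-like niches with contrasting preferences.

    The focal species avoids roads strongly, prefers dense vegetation and
    east/south-facing slopes; the others differ in their dominant drivers
    (vegetation, dry-season rainfall, elevation/water) so their suitable
    habitats segregate spatially.
    """
    return {
        "focal_pheasant": TrueNiche(),  # defaults: the stringent focal niche
        "silver_pheasant": TrueNiche(
            intercept=-3.0,
            linear={"dem": -2.6, "slope": -3.0, "dist_water": -1.6,
                    "bio3": 1.6},
            evi_opt=0.3, evi_quad=-4.5, road_coef=5.5,
            eastness_coef=0.0, southness_coef=0.0,
        ),
        "grey_laughingthrush": TrueNiche(
            intercept=-2.5,
            linear={"bio14": 5.8, "slope": -2.6, "bio3": 2.9},
            evi_opt=0.0, evi_quad=-2.9, road_coef=3.5,
            eastness_coef=0.0, southness_coef=0.0,
        ),
        "necklaced_laughingthrush": TrueNiche(
            intercept=-2.8,
            linear={"dem": -4.5, "dist_water": -2.2, "slope": -3.0},
            evi_opt=0.2, evi_quad=-4.0, road_coef=2.5,
            eastness_coef=0.8, southness_coef=0.0,
        ),
    }


@dataclass
class PipelineConfig:
    seed: int = 1
    output_dir: str = "outputs"
    grid_shape: tuple[int, int] = (128, 128)
    cell_size: float = 30.0
    species: dict[str, dict] = field(default_factory=dict)  # name -> settings
    n_presences: int = 200
    esdm: dict = field(default_factory=lambda: {
        "n_rounds": 10, "auc_gate": 0.8, "train_fraction": 0.8,
    })
    overlap_threshold: float = 0.7
    marxan: dict = field(default_factory=lambda: {
        "target": 0.5, "spf": 16.74, "blm": 2.11,
        "n_runs": 1000, "n_iterations": 100_000,
        "unit_area_km2": 1.0, "key_threshold": 0.9, "contiguity": True,
        "min_units": 2, "focal_species": None,
    })

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key in ("seed", "output_dir", "n_presences", "cell_size",
                    "overlap_threshold"):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "grid_shape" in raw:
            cfg.grid_shape = tuple(raw["grid_shape"])
        if "species" in raw:
            cfg.species = raw["species"]
        cfg.esdm.update(raw.get("esdm", {}))
        cfg.marxan.update(raw.get("marxan", {}))
        if not isinstance(cfg.seed, int):
            raise ValueError("seed must be an integer")
        return cfg

    def niches(self) -> dict[str, TrueNiche]:
        if not self.species:
            return default_species_niches()
        defaults = default_species_niches()
        out = {}
        for name, settings in self.species.items():
            base = defaults.get(name, TrueNiche())
            for k, v in (settings or {}).get("niche", {}).items():
                setattr(base, k, v)
            out[name] = base
        return out

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)

    def digest(self, stage: str | None = None) -> str:
        """Hash of the config; with ``stage`` given, only the settings that
        stage reads directly (upstream settings reach it through the chained
        stage manifests, so a downstream-only change does not invalidate
        earlier stages)."""
        payload = {
            "seed": self.seed, "grid_shape": list(self.grid_shape),
            "cell_size": self.cell_size, "species": self.species,
            "n_presences": self.n_presences, "esdm": self.esdm,
            "overlap_threshold": self.overlap_threshold, "marxan": self.marxan,
        }
        if stage is not None:
            keys = {
                "simulate": ("seed", "grid_shape", "cell_size", "species",
                             "n_presences"),
                "preprocess": ("seed",),
                "fit": ("seed", "species", "esdm"),
                "overlap": ("seed", "overlap_threshold"),
                "prioritize": ("seed", "marxan"),
            }[stage]
            payload = {k: payload[k] for k in keys}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_dir(cfg: PipelineConfig, stage: str) -> Path:
    d = Path(cfg.output_dir) / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def _manifest_path(cfg: PipelineConfig, stage: str) -> Path:
    return Path(cfg.output_dir) / f"{stage}.manifest.json"


def _stage_fresh(cfg: PipelineConfig, stage: str, inputs_hash: str) -> bool:
    mp = _manifest_path(cfg, stage)
    if not mp.exists():
        return False
    try:
        man = json.loads(mp.read_text())
    except json.JSONDecodeError:
        return False
    if man.get("inputs_hash") != inputs_hash:
        return False
    for rel, digest in man.get("outputs", {}).items():
        f = Path(cfg.output_dir) / rel
        if not f.exists() or _sha256(f) != digest:
            return False
    return True


def _write_manifest(cfg: PipelineConfig, stage: str, inputs_hash: str,
                    outputs: list[Path], elapsed: float) -> dict:
    root = Path(cfg.output_dir)
    man = {
        "stage": stage,
        "inputs_hash": inputs_hash,
        "seed": cfg.stage_seed(stage),
        "elapsed_s": round(elapsed, 3),
        "outputs": {
            str(p.relative_to(root)): _sha256(p) for p in outputs
        },
    }
    _manifest_path(cfg, stage).write_text(json.dumps(man, indent=2))
    return man


def _inputs_hash(cfg: PipelineConfig, stage: str) -> str:
    """Config digest chained with the upstream stage manifests."""
    h = hashlib.sha256(cfg.digest(stage).encode())
    for up in STAGES[: STAGES.index(stage)]:
        mp = _manifest_path(cfg, up)
        if mp.exists():
            h.update(mp.read_bytes())
    return h.hexdigest()


def run_simulate(cfg: PipelineConfig) -> dict:
    stage = "simulate"
    ih = _inputs_hash(cfg, stage)
    if _stage_fresh(cfg, stage, ih):
        return {"stage": stage, "skipped": True}
    t0 = time.time()
    out = _stage_dir(cfg, stage)
    seed = cfg.stage_seed(stage)
    lc = LandscapeConfig(grid_shape=cfg.grid_shape, cell_size=cfg.cell_size,
                         seed=seed)
    stack = generate_env_stack(lc)
    eio.write_stack(out / "stack", stack)
    # sampling needs the derived covariates the niche references
    derived = derive_standard_layers(stack)
    outputs = sorted((out / "stack").glob("*"))
    for i, (name, niche) in enumerate(cfg.niches().items()):
        occ = sample_presences(
            derived, niche, cfg.n_presences, seed=seed + 101 * (i + 1),
            species=name,
        )
        path = out / f"occurrences_{name}.csv"
        occ.to_csv(path)
        outputs.append(path)
        truth = niche.probability(derived)
        tpath = out / f"true_probability_{name}.asc"
        eio.write_ascii_grid(tpath, truth, stack.spec, stack.mask)
        outputs.append(tpath)
    return _write_manifest(cfg, stage, ih, outputs, time.time() - t0)


def run_preprocess(cfg: PipelineConfig) -> dict:
    stage = "preprocess"
    ih = _inputs_hash(cfg, stage)
    if _stage_fresh(cfg, stage, ih):
        return {"stage": stage, "skipped": True}
    t0 = time.time()
    sim = Path(cfg.output_dir) / "simulate"
    out = _stage_dir(cfg, stage)
    stack = eio.read_stack(sim / "stack")
    derived = derive_standard_layers(stack)
    sample = pd.concat(
        [pd.read_csv(p) for p in sorted(sim.glob("occurrences_*.csv"))],
        ignore_index=True,
    )
    reduced, report = collinearity_filter(derived, sample)
    eio.write_stack(out / "stack", reduced)
    report.to_json(out / "collinearity.json")
    (out / "collinearity.txt").write_text(str(report) + "\n")
    outputs = sorted((out / "stack").glob("*")) + [
        out / "collinearity.json", out / "collinearity.txt",
    ]
    return _write_manifest(cfg, stage, ih, outputs, time.time() - t0)


def run_fit(cfg: PipelineConfig, species: list[str] | None = None) -> dict:
    stage = "fit"
    ih = _inputs_hash(cfg, stage)
    if _stage_fresh(cfg, stage, ih):
        return {"stage": stage, "skipped": True}
    t0 = time.time()
    pre = Path(cfg.output_dir) / "preprocess"
    sim = Path(cfg.output_dir) / "simulate"
    out = _stage_dir(cfg, stage)
    stack = eio.read_stack(pre / "stack")
    names = species or list(cfg.niches())
    seed = cfg.stage_seed(stage)
    outputs = []
    metric_rows = []
    for i, name in enumerate(names):
        occ = OccurrenceSet.from_csv(sim / f"occurrences_{name}.csv")
        ecfg = EnsembleConfig(seed=seed + 7 * i, **cfg.esdm)
        fit = fit_ensemble(stack, occ, ecfg)
        smap = predict_ensemble(fit, stack)
        spath = out / f"suitability_{name}.asc"
        eio.write_ascii_grid(spath, smap.values, stack.spec, stack.mask)
        outputs.append(spath)
        m = fit.mean_metrics().as_dict()
        m["species"] = name
        metric_rows.append(m)
        contrib = variable_contribution(fit, stack, n_permutations=3,
                                        seed=seed + 7 * i)
        cpath = out / f"contributions_{name}.csv"
        contrib.rename("contribution_pct").to_csv(cpath)
        outputs.append(cpath)
        for var in ("evi", "dist_road"):
            if var in fit.builder.continuous:
                rc = response_curve(fit, stack, var)
                rpath = out / f"response_{name}_{var}.csv"
                rc.to_csv(rpath, index=False)
                outputs.append(rpath)
    mpath = out / "metrics.csv"
    pd.DataFrame(metric_rows)[
        ["species", "AUC", "TSS", "Omission.rate", "Prop.correct", "Kappa",
         "threshold"]
    ].to_csv(mpath, index=False)
    outputs.append(mpath)
    return _write_manifest(cfg, stage, ih, outputs, time.time() - t0)


def run_overlap(cfg: PipelineConfig) -> dict:
    stage = "overlap"
    ih = _inputs_hash(cfg, stage)
    if _stage_fresh(cfg, stage, ih):
        return {"stage": stage, "skipped": True}
    t0 = time.time()
    fitdir = Path(cfg.output_dir) / "fit"
    out = _stage_dir(cfg, stage)
    from .ensemble import SuitabilityMap

    masks = []
    spec = None
    for p in sorted(fitdir.glob("suitability_*.asc")):
        arr, spec, _ = eio.read_ascii_grid(p)
        name = p.stem.replace("suitability_", "")
        smap = SuitabilityMap(values=arr, spec=spec, species=name)
        masks.append(binarize_suitability(smap, cfg.overlap_threshold))
    counts, table = overlap_map(masks)
    cpath = out / "overlap_count.asc"
    eio.write_ascii_grid(cpath, counts.astype(float), spec)
    tpath = out / "overlap_classes.csv"
    table.to_csv(tpath, index=False)
    return _write_manifest(cfg, stage, ih, [cpath, tpath], time.time() - t0)


def run_prioritize(cfg: PipelineConfig) -> dict:
    stage = "prioritize"
    ih = _inputs_hash(cfg, stage)
    if _stage_fresh(cfg, stage, ih):
        return {"stage": stage, "skipped": True}
    t0 = time.time()
    from .ensemble import SuitabilityMap

    sim = Path(cfg.output_dir) / "simulate"
    fitdir = Path(cfg.output_dir) / "fit"
    out = _stage_dir(cfg, stage)
    mx = cfg.marxan
    focal = mx.get("focal_species") or list(cfg.niches())[0]
    arr, spec, _ = eio.read_ascii_grid(fitdir / f"suitability_{focal}.asc")
    stack = eio.read_stack(sim / "stack")
    boundary = grid_boundary(spec)
    units = hex_tessellate(boundary, mx["unit_area_km2"])
    scheme = DisturbanceScheme.default()
    compute_costs(stack, units, scheme)
    smap = SuitabilityMap(values=arr, spec=spec, species=focal)
    aggregate_feature_amounts(smap, units)

    write_pu_dat(out / "pu.dat", units)
    write_spec_dat(out / "spec.dat", [{
        "id": 1,
        "target": mx["target"] * units.amounts[focal].sum(),
        "spf": mx["spf"], "name": focal,
    }])
    write_puvspr_dat(out / "puvspr.dat", [
        (1, uid, a) for uid, a in zip(units.ids, units.amounts[focal])
        if a > 0
    ])
    write_bound_dat(out / "bound.dat", units)

    problem = ReserveProblem.from_units(
        units, target=mx["target"], spf=mx["spf"], blm=mx["blm"],
        features=[focal],
    )
    seed = cfg.stage_seed(stage)
    freq, best = repeat_runs(
        problem, n_runs=mx["n_runs"], base_seed=seed,
        n_iterations=mx["n_iterations"],
    )
    key = select_key_areas(
        freq, threshold_fraction=mx["key_threshold"],
        contiguity=mx["contiguity"], min_units=mx.get("min_units", 2),
        units=units,
    )
    fpath = out / "selection_frequency.csv"
    pd.DataFrame({
        "id": freq.unit_ids, "count": freq.counts, "n_runs": freq.n_runs,
    }).to_csv(fpath, index=False)
    upath = out / "planning_units.geojson"
    units.to_geojson(upath)
    kpath = out / "key_areas.geojson"
    kidx = [units.ids.index(u) for u in key["ids"]]
    eio.write_geojson(
        kpath,
        [units.polygons[k] for k in kidx],
        [{"id": units.ids[k]} for k in kidx],
    )
    spath = out / "summary.json"
    spath.write_text(json.dumps({
        "focal_species": focal,
        "n_planning_units": len(units),
        "best_objective": best.objective,
        "best_feasible": best.feasible,
        "best_n_selected": int(best.selected.sum()),
        "key_area_n_units": key["n_units"],
        "key_area_km2": key.get("area_km2"),
        "key_area_pct_of_study_area": key.get("pct_of_study_area"),
    }, indent=2))
    outputs = [out / n for n in (
        "pu.dat", "spec.dat", "puvspr.dat", "bound.dat",
    )] + [fpath, upath, kpath, spath]
    return _write_manifest(cfg, stage, ih, outputs, time.time() - t0)


_RUNNERS = {
    "simulate": run_simulate,
    "preprocess": run_preprocess,
    "fit": run_fit,
    "overlap": run_overlap,
    "prioritize": run_prioritize,
}


def run_all(cfg: PipelineConfig) -> dict:
    """Execute every stage in order; returns the combined run manifest."""
    manifest = {}
    for stage in STAGES:
        try:
            manifest[stage] = _RUNNERS[stage](cfg)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return manifest
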