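"""End-to-end orchestration: simulate -> rank -> select -> predict -> report.

A :class:`RunConfig` (plain dict / YAML) drives one reproducible run.  A
single master seed is the only source of randomness; per-stage seeds are
spawned from it deterministically (numpy SeedSequence children in stage
order), so any stage can be re-run in isolation with its recorded seed.
Every run emits a manifest with the config, stage seeds, package version
and SHA-256 checksums of all written artefacts; re-running an identical
config reproduces identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .cohort import encode_cohort, write_cohort
from .panels import BUILTIN_PANELS, builtin_panel
from .prediction import SYSTEMS, fit_system_model, loocv_predict
from .ranking import DEFAULT_CUTOFF, rank_variants, select_top
from .reporting import CallPolicy, enumerate_genotype_space, likelihood_ratio, report
from .simulate import paper_like_config, simulate_cohort

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "rank", "predict", "report", "enumerate", "lr")


@dataclass
class RunConfig:
    outdir: str = "ec11_run"
    seed: int = 0
    stages: tuple = STAGES
    # simulate
    n_discovery: int = 757
    n_model: int = 523
    # rank
    rank_reps: int = 100
    cutoff: float = DEFAULT_CUTOFF
    # predict / report
    panels: tuple = ("ec11", "irisplex6", "rs12913832")
    systems: tuple = SYSTEMS
    two_category_thresholds: tuple = ("pmax", "0.7")
    three_category_thresholds: tuple = ("pmax", "0.5", "0.7")
    lr_rsid: str = "rs12913832"
    lr_smoothing: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        for p in cfg.panels:
            if p not in BUILTIN_PANELS:
                raise ValueError(f"unknown panel {p!r}; available: {BUILTIN_PANELS}")
        for s in cfg.systems:
            if s not in SYSTEMS:
                raise ValueError(f"unknown reporting system {s!r}")
        for s in cfg.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seeds(master: int) -> dict:
    children = np.random.SeedSequence(master).spawn(len(STAGES))
    return {
        stage: int(child.generate_state(1)[0]) for stage, child in zip(STAGES, children)
    }


def run_pipeline(config: "RunConfig | dict") -> dict:
    """Execute the enabled stages in order; returns the run manifest."""
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "artefacts": {},
        "results": {},
    }

    def emit(name: str, path: Path):
        manifest["artefacts"][name] = {
            "path": str(path),
            "sha256": _sha256(path),
        }

    cohorts = {}
    if "simulate" in config.stages:
        for label, n, freq_set in (
            ("discovery", config.n_discovery, "discovery"),
            ("model", config.n_model, "model"),
        ):
            cfg = paper_like_config(n, seed=seeds["simulate"], freq_set=freq_set)
            cohort = simulate_cohort(cfg)
            cohorts[label] = cohort
            gpath = outdir / f"genotypes_{label}.tsv"
            ppath = outdir / f"phenotypes_{label}.tsv"
            write_cohort(cohort, gpath, ppath)
            emit(f"genotypes_{label}", gpath)
            emit(f"phenotypes_{label}", ppath)
        prov = outdir / "simulation_provenance.json"
        prov.write_text(
            json.dumps(
                {"seed": seeds["simulate"], "n_discovery": config.n_discovery,
                 "n_model": config.n_model, "package_version": __version__},
                indent=2,
            )
        )
        emit("simulation_provenance", prov)

    selected = None
    if "rank" in config.stages:
        cohort = cohorts["discovery"]
        panel = builtin_panel("discovery44")
        table = rank_variants(cohort, panel, n_reps=config.rank_reps, seed=seeds["rank"])
        selected = select_top(table, config.cutoff)
        ipath = outdir / "importance.tsv"
        table.to_frame().to_csv(ipath, sep="\t")
        emit("importance", ipath)
        manifest["results"]["selected_variables"] = selected
        manifest["results"]["top_variable"] = table.rank.idxmin()

    loocvs = {}
    if "predict" in config.stages:
        cohort = cohorts["model"]
        summary = {}
        for panel_name in config.panels:
            panel = builtin_panel(panel_name, freq_set="model")
            for system in config.systems:
                res = loocv_predict(cohort, panel, system)
                loocvs[(panel_name, system)] = res
                lpath = outdir / f"loocv_{panel_name}_{system}.tsv"
                res.per_sample.to_csv(lpath, sep="\t")
                emit(f"loocv_{panel_name}_{system}", lpath)
                summary[f"{panel_name}/{system}"] = {"error": res.error, "n": res.n}
        manifest["results"]["prediction_errors"] = summary
        spath = outdir / "loocv_summary.json"
        spath.write_text(json.dumps(summary, indent=2))
        emit("loocv_summary", spath)

    if "report" in config.stages and loocvs:
        reports = {}
        for (panel_name, system), res in loocvs.items():
            if system == "quantitative":
                continue
            thresholds = (
                config.two_category_thresholds
                if system == "two_category"
                else config.three_category_thresholds
            )
            for t in thresholds:
                policy = CallPolicy.parse(t)
                tab = report(res, policy)
                reports[f"{panel_name}/{system}/{policy.label}"] = tab.to_dict()
        rpath = outdir / "report.json"
        rpath.write_text(json.dumps(reports, indent=2))
        emit("report", rpath)
        manifest["results"]["reports"] = list(reports)

    if "enumerate" in config.stages:
        spaces = {}
        for panel_name in config.panels:
            panel = builtin_panel(panel_name, freq_set="model")
            model = None
            if "predict" in config.stages and "three_category" in config.systems:
                coded = encode_cohort(cohorts["model"], panel, on_missing="drop")
                model = fit_system_model(
                    coded.values, cohorts["model"].pie, "three_category", panel_name
                )
            space = enumerate_genotype_space(panel, model)
            spaces[panel_name] = {
                "n_combinations": space.n_combinations,
                "coding": space.coding_note,
                "category_counts": space.category_counts,
                "category_fractions": space.category_fractions,
                "max_probability": space.max_probability,
            }
        epath = outdir / "genotype_space.json"
        epath.write_text(json.dumps(spaces, indent=2))
        emit("genotype_space", epath)
        manifest["results"]["genotype_space"] = {
            k: v["n_combinations"] for k, v in spaces.items()
        }

    if "lr" in config.stages and cohorts:
        cohort = cohorts["model"]
        panel = builtin_panel("rs12913832", freq_set="model")
        variant = panel.variant(config.lr_rsid)
        lrs = {}
        for g in ("".join(sorted((variant.ref_allele,) * 2)),
                  "".join(sorted((variant.ref_allele, variant.var_allele))),
                  "".join(sorted((variant.var_allele,) * 2))):
            try:
                lr = likelihood_ratio(cohort, config.lr_rsid, g, config.lr_smoothing)
                lrs[g] = {"lr": lr.lr, "count_brown": lr.count_brown,
                          "count_blue": lr.count_blue}
            except ValueError as exc:
                lrs[g] = {"error": str(exc)}
        lrpath = outdir / "likelihood_ratios.json"
        lrpath.write_text(json.dumps(lrs, indent=2))
        emit("likelihood_ratios", lrpath)
        manifest["results"]["likelihood_ratios"] = {
            g: v.get("lr") for g, v in lrs.items()
        }

    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return manifest
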