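"""End-to-end analysis pipeline.

Stages: ``simulate`` (synthetic study + covariate tables), ``fit``
(prevalence filter + both hurdle parts), ``vp`` (predictive and
conditional variance partitioning over the grid), ``scenarios``
(counterfactual predictions and diversity surfaces with trends) and
``report`` (tabular summaries). Every stage reads its inputs from the
output directory, so a run can resume from the first stage whose outputs
are missing. Deterministic given the config seeds.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community as comm
from . import scenarios as scen
from . import synthetic, variance
from .design import DesignMatrix, build_design_matrix
from .model import ModelSpec, PosteriorDraws, evaluate, fit_ab, fit_pa, predict

logger = logging.getLogger(__name__)

STAGES = ("simulate", "fit", "vp", "scenarios", "report")


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run."""

    preset: str = "demo"
    seed: int = 0
    study: synthetic.StudyConfig = field(default_factory=synthetic.StudyConfig)
    n_chains: int = 2
    n_iter: int = 2000
    thin: int = 2
    prevalence_threshold: float = 0.10
    kmeans_k: int = 4
    kmeans_restarts: int = 10
    pred_draw_step: int = 5
    scenario_baseline_years: int = 5

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)

    def model_spec(self) -> ModelSpec:
        return ModelSpec(
            n_factors=dict(self.study.n_factors),
            n_chains=self.n_chains,
            n_iter=self.n_iter,
            thin=self.thin,
            seed=self.stage_seed("sampler"),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["study"] = synthetic.config_to_dict(self.study)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["study"] = synthetic.config_from_dict(d.get("study", {}))
        return cls(**d)

    @classmethod
    def preset_config(cls, preset: str = "demo", seed: int = 0):
        if preset == "demo":
            study = synthetic.StudyConfig(
                n_species=10,
                n_sites=40,
                n_years=8,
                grid_rows=15,
                grid_cols=12,
            )
            return cls(
                preset="demo", seed=seed, study=study,
                n_chains=2, n_iter=600, thin=3,
            )
        if preset == "full":
            return cls(preset="full", seed=seed)
        raise ValueError(f"unknown preset {preset!r}")

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


# ---------------------------------------------------------------------------
# stage implementations


def _stage_simulate(cfg: PipelineConfig, out: Path) -> list[Path]:
    d = out / "simulate"
    d.mkdir(parents=True, exist_ok=True)
    study = synthetic.generate_study(cfg.study, seed=cfg.stage_seed("generator"))
    study.community.counts.reset_index().to_csv(
        d / "community.csv", index=False
    )
    study.traits.reset_index().to_csv(d / "traits.csv", index=False)
    study.sampled_covariates.to_csv(d / "sampled_covariates.csv", index=False)
    study.grid_covariates.to_csv(d / "grid_covariates.csv", index=False)
    study.composition.reset_index().to_csv(d / "composition.csv", index=False)
    study.grid.to_csv(d / "grid.csv", index=False)
    with open(d / "standardization.yaml", "w") as fh:
        yaml.safe_dump(
            {k: [float(v[0]), float(v[1])] for k, v in study.X_train.stats.items()},
            fh,
        )
    study.params["PA"].to_netcdf(d / "params_pa.nc")
    study.params["AB"].to_netcdf(d / "params_ab.nc")
    for raster in study.rasters:
        raster.write_tiff(d / f"landscape_{raster.epoch}.tif")
    with open(d / "generator_settings.yaml", "w") as fh:
        yaml.safe_dump(
            {"study": synthetic.config_to_dict(cfg.study),
             "seed": cfg.stage_seed("generator")},
            fh,
        )
    return sorted(d.iterdir())


def _load_study_tables(out: Path):
    d = out / "simulate"
    samp = pd.read_csv(d / "sampled_covariates.csv")
    grid_cov = pd.read_csv(d / "grid_covariates.csv")
    traits = pd.read_csv(d / "traits.csv").set_index("species")
    counts = pd.read_csv(d / "community.csv").set_index(["site", "year"])
    with open(d / "standardization.yaml") as fh:
        stats = {k: (v[0], v[1]) for k, v in yaml.safe_load(fh).items()}
    years = np.sort(grid_cov["year"].unique())
    year_index = {int(y): t for t, y in enumerate(years)}
    X_train = build_design_matrix(
        samp, standardization_stats=stats, unit_columns=("site", "year")
    )
    X_grid = build_design_matrix(
        grid_cov, standardization_stats=stats, unit_columns=("cell", "year")
    )
    levels_train = {
        "site": samp["site"].to_numpy(int),
        "year": samp["year"].map(year_index).to_numpy(int),
        "zone": samp["zone"].to_numpy(int),
    }
    levels_grid = {
        "site": np.full(len(grid_cov), -1, dtype=int),
        "year": grid_cov["year"].map(year_index).to_numpy(int),
        "zone": grid_cov["zone"].to_numpy(int),
    }
    return dict(
        samp=samp, grid_cov=grid_cov, traits=traits, counts=counts,
        stats=stats, X_train=X_train, X_grid=X_grid,
        levels_train=levels_train, levels_grid=levels_grid, years=years,
        year_index=year_index,
    )


def _stage_fit(cfg: PipelineConfig, out: Path) -> list[Path]:
    d = out / "fit"
    d.mkdir(parents=True, exist_ok=True)
    tb = _load_study_tables(out)
    table = comm.CommunityTable(
        counts=tb["counts"],
        effort_days=pd.Series(
            tb["samp"]["effort_days"].to_numpy(), index=tb["counts"].index
        ),
        zone=pd.Series(
            tb["samp"]["zone"].to_numpy(), index=tb["counts"].index
        ),
    )
    kept, report = comm.prevalence_filter(table, cfg.prevalence_threshold)
    if not kept:
        raise RuntimeError("prevalence filter removed every species")
    counts = table.counts[kept].to_numpy(dtype=float)
    traits_kept = tb["traits"].loc[kept]
    T = comm.encode_traits(traits_kept)
    spec = cfg.model_spec()
    pa = fit_pa(
        (counts > 0).astype(float), tb["X_train"], T, spec,
        tb["levels_train"], species=kept,
    )
    ab = fit_ab(
        counts, tb["X_train"], T, spec, tb["levels_train"], species=kept
    )
    pa.to_netcdf(d / "draws_pa.nc")
    ab.to_netcdf(d / "draws_ab.nc")
    pred = predict(pa, ab, tb["X_train"], levels_new=tb["levels_train"])
    metrics = evaluate(pred, counts)
    metrics["species"] = kept
    metrics.to_csv(d / "metrics.csv", index=False)
    with open(d / "prevalence_report.yaml", "w") as fh:
        yaml.safe_dump({**report, "kept": list(map(str, kept))}, fh)
    with open(d / "model_spec.yaml", "w") as fh:
        info = {k: v for k, v in asdict(spec).items() if k != "omega_fixed"}
        yaml.safe_dump(info, fh)
    return sorted(d.iterdir())


def _stage_vp(cfg: PipelineConfig, out: Path) -> list[Path]:
    d = out / "vp"
    d.mkdir(parents=True, exist_ok=True)
    tb = _load_study_tables(out)
    comp = pd.read_csv(out / "simulate" / "composition.csv").set_index("cell")
    results = {}
    for part, fn in (("pa", "draws_pa.nc"), ("ab", "draws_ab.nc")):
        draws = PosteriorDraws.from_netcdf(out / "fit" / fn)
        vp = variance.variance_partition(draws, tb["X_grid"])
        vp.summary().to_csv(d / f"vp_{part}_summary.csv", index=False)
        vp.to_long_frame().to_csv(d / f"vp_{part}_long.csv", index=False)
        dom = variance.dominant_driver_counts(vp)
        results[part] = (draws, vp, dom)

    labels, centers = variance.kmeans_profiles(
        comp, k=cfg.kmeans_k, n_restarts=cfg.kmeans_restarts,
        seed=cfg.stage_seed("kmeans"),
    )
    labels.rename("profile").reset_index().to_csv(
        d / "habitat_profiles.csv", index=False
    )
    centers.to_csv(d / "profile_centers.csv")

    cell_of_unit = tb["grid_cov"]["cell"].to_numpy()
    unit_labels = labels.loc[cell_of_unit].to_numpy()
    ctx_rows, func_rows = [], []
    traits = pd.read_csv(out / "simulate" / "traits.csv").set_index("species")
    for part, (draws, vp, dom) in results.items():
        ctx = variance.conditional_vp_environmental(
            draws, tb["X_grid"], unit_labels
        )
        ws = ctx.within_share().mean()
        bs = ctx.between_share().mean()
        ctx_rows.append(
            {"part": part, "within_share_mean": float(ws),
             "between_share_mean": float(bs)}
        )
        for label, sub in ctx.per_context.items():
            for comp_name in ("habitat", "climate"):
                sh = sub.component_share(comp_name)
                ctx_rows.append(
                    {"part": part, "context": label, "component": comp_name,
                     "share_median": float(np.median(sh))}
                )
        for trait_col in ("host_group", "wing_bin"):
            groups = traits.loc[vp.species, trait_col]
            pooled = variance.conditional_vp_functional(vp, groups)
            for g, info in pooled.items():
                q = info["quantiles"]
                for comp_name in ("habitat", "climate"):
                    func_rows.append(
                        {"part": part, "trait": trait_col, "group": g,
                         "component": comp_name,
                         "share_median": float(q.loc["median", comp_name]),
                         "share_q2.5": float(q.loc["q2.5", comp_name]),
                         "share_q97.5": float(q.loc["q97.5", comp_name])}
                    )
    pd.DataFrame(ctx_rows).to_csv(d / "conditional_vp.csv", index=False)
    pd.DataFrame(func_rows).to_csv(d / "functional_vp.csv", index=False)
    dom_summary = {
        part: {k: (v.tolist() if isinstance(v, np.ndarray) else v)
               for k, v in dom.items() if k != "counts"}
        for part, (_, _, dom) in results.items()
    }
    with open(d / "dominant_driver.yaml", "w") as fh:
        yaml.safe_dump(dom_summary, fh)
    return sorted(d.iterdir())


def _stage_scenarios(cfg: PipelineConfig, out: Path) -> list[Path]:
    d = out / "scenarios"
    d.mkdir(parents=True, exist_ok=True)
    tb = _load_study_tables(out)
    draws_pa = PosteriorDraws.from_netcdf(out / "fit" / "draws_pa.nc")
    draws_ab = PosteriorDraws.from_netcdf(out / "fit" / "draws_ab.nc")
    years = tb["years"]
    trends = {}
    for kind in scen.SCENARIO_KINDS:
        cov = scen.build_scenario(
            tb["grid_cov"], kind, cfg.scenario_baseline_years
        )
        Xs = build_design_matrix(
            cov, standardization_stats=tb["stats"],
            unit_columns=("cell", "year"),
        )
        surfaces = scen.predict_diversity_surfaces(
            draws_pa, draws_ab, Xs, tb["levels_grid"],
            cov["cell"].to_numpy(), years, draw_step=cfg.pred_draw_step,
        )
        for metric, surf in surfaces.items():
            surf.to_frame().to_csv(
                d / f"{kind}_{metric}.csv", index=False
            )
            trends[(kind, metric)] = scen.fit_cell_trends(surf)
            trends[(kind, metric)].to_csv(
                d / f"{kind}_{metric}_trends.csv", index=False
            )
    for metric in ("richness", "evenness"):
        cmp_df = scen.scenario_comparison(
            trends[("full", metric)],
            trends[("climate_only", metric)],
            trends[("habitat_only", metric)],
        )
        cmp_df.to_csv(d / f"comparison_{metric}.csv", index=False)
    return sorted(d.iterdir())


def _stage_report(cfg: PipelineConfig, out: Path) -> list[Path]:
    d = out / "report"
    d.mkdir(parents=True, exist_ok=True)
    needed = [
        out / "fit" / "metrics.csv",
        out / "vp" / "vp_pa_summary.csv",
        out / "vp" / "dominant_driver.yaml",
        out / "scenarios" / "comparison_richness.csv",
    ]
    missing = [str(pth) for pth in needed if not pth.exists()]
    if missing:
        raise FileNotFoundError(f"report inputs missing: {missing}")
    vp_sum = pd.read_csv(out / "vp" / "vp_pa_summary.csv")
    vp_ab = pd.read_csv(out / "vp" / "vp_ab_summary.csv")
    vp_sum["part"] = "pa"
    vp_ab["part"] = "ab"
    pd.concat([vp_sum, vp_ab], ignore_index=True).to_csv(
        d / "species_vp.csv", index=False
    )
    for name in ("conditional_vp.csv", "functional_vp.csv"):
        pd.read_csv(out / "vp" / name).to_csv(d / name, index=False)
    with open(out / "vp" / "dominant_driver.yaml") as fh:
        dom = yaml.safe_load(fh)
    with open(d / "dominant_driver.yaml", "w") as fh:
        yaml.safe_dump(dom, fh)
    pd.read_csv(out / "fit" / "metrics.csv").to_csv(
        d / "fit_metrics.csv", index=False
    )
    rows = []
    for metric in ("richness", "evenness"):
        for kind in scen.SCENARIO_KINDS:
            tr = pd.read_csv(
                out / "scenarios" / f"{kind}_{metric}_trends.csv"
            )
            rows.append(
                {"metric": metric, "scenario": kind,
                 "mean": float(tr["mean"].mean()),
                 "slope_mean": float(tr["slope"].mean()),
                 "variability_mean": float(tr["variability"].mean())}
            )
    pd.DataFrame(rows).to_csv(d / "diversity_summary.csv", index=False)
    return sorted(d.iterdir())


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "fit": _stage_fit,
    "vp": _stage_vp,
    "scenarios": _stage_scenarios,
    "report": _stage_report,
}

_STAGE_MARKER = {
    "simulate": "simulate/community.csv",
    "fit": "fit/draws_pa.nc",
    "vp": "vp/vp_pa_summary.csv",
    "scenarios": "scenarios/comparison_richness.csv",
    "report": "report/species_vp.csv",
}


def run(
    config: PipelineConfig,
    outdir: str | Path,
    stages: list[str] | None = None,
    resume: bool = False,
) -> dict:
    """Run the pipeline, writing a manifest; deterministic given seeds.

    With ``resume=True``, completed stages (marker output present) before
    the first incomplete one are skipped; everything from the first
    missing stage onward is recomputed (stage outputs feed forward).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    todo = list(stages) if stages else list(STAGES)
    unknown = [s for s in todo if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    if resume and stages is None:
        first_missing = next(
            (i for i, s in enumerate(STAGES)
             if not (out / _STAGE_MARKER[s]).exists()),
            len(STAGES),
        )
        todo = list(STAGES[first_missing:])

    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stages": {},
    }
    for stage in STAGES:
        if stage not in todo:
            continue
        t0 = time.perf_counter()
        try:
            outputs = _STAGE_FUNCS[stage](config, out)
        except Exception:
            _write_manifest(out, manifest)
            logger.exception("stage %s failed", stage)
            raise RuntimeError(f"pipeline failed at stage {stage!r}")
        manifest["stages"][stage] = {
            "outputs": [str(p.relative_to(out)) for p in outputs],
            "seconds": round(time.perf_counter() - t0, 3),
        }
    manifest["content_hash"] = _content_hash(out, manifest)
    _write_manifest(out, manifest)
    return manifest


def _content_hash(out: Path, manifest: dict) -> str:
    """Hash of config and every CSV/YAML output (timings excluded)."""
    h = hashlib.sha256(manifest["config_hash"].encode())
    for stage in STAGES:
        info = manifest["stages"].get(stage)
        if not info:
            continue
        for rel in sorted(info["outputs"]):
            pth = out / rel
            if pth.suffix in (".csv", ".yaml"):
                h.update(rel.encode())
                h.update(pth.read_bytes())
    return h.hexdigest()


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
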