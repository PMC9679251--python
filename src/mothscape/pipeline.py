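"""Configuration-driven orchestration of the full landscape-genomics run.

Stages run in the analysis order: simulate (optional) -> qc -> niche ->
distances -> rcm -> dbrda -> scan.  A single global seed expands into
per-stage seeds by hashing the stage name, so toggling one stage does not
shift another's random stream.  Every stage writes its tables under the
output directory and reports record counts to the log; a JSON manifest
captures parameters, file hashes, and versions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._core import MothscapeError, logger, stage_seed
from . import distances as dist_mod
from . import geno_qc, mantel_rcm, niche, ordination, selection_scan, synthdata

__all__ = ["PipelineConfig", "run_pipeline", "main"]

ALL_STAGES = ["simulate", "qc", "niche", "distances", "rcm", "dbrda", "scan"]


@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips through YAML unchanged."""

    outdir: str = "mothscape_run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    vcf: str | None = None
    samples: str | None = None
    simulate: dict = field(default_factory=dict)     # SimulationConfig overrides
    qc: dict = field(default_factory=lambda: {
        "max_ind_missing": 0.25, "min_depth": 5, "min_maf": 0.05,
        "max_locus_missing": 0.05, "min_gap_bp": 10_000,
        "kin_threshold": 0.22, "squared_distance": False})
    niche: dict = field(default_factory=lambda: {
        "n_background": 2000, "reg": 1.0, "folds": 5, "buffer_km": 50.0,
        "floor": 1e-3})
    distances: dict = field(default_factory=lambda: {"connectivity": 8})
    rcm: dict = field(default_factory=lambda: {"n_perm": 999})
    dbrda: dict = field(default_factory=lambda: {"n_perm": 999, "alpha": 0.05})
    scan: dict = field(default_factory=lambda: {
        "K": 2, "runs": 5, "n_perm": 1000, "fdr": 0.05})

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise MothscapeError(f"unknown stages: {sorted(unknown)}")
        needs_geno = {"qc", "rcm", "dbrda", "scan"} & set(self.stages)
        if needs_geno and "simulate" not in self.stages and not self.vcf:
            raise MothscapeError(
                "genotype-consuming stages enabled but no VCF input and "
                "simulate stage disabled")
        if "qc" not in self.stages and ({"rcm", "dbrda", "scan"}
                                        & set(self.stages)):
            if "simulate" not in self.stages:
                raise MothscapeError("rcm/dbrda/scan need qc or simulate")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns the run manifest."""
    import mothscape

    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": mothscape.__version__, "seed": config.seed,
                      "stages": {}, "parameters": dataclasses.asdict(config),
                      "complete": False}
    state: dict = {}

    try:
        if "simulate" in config.stages:
            _stage_simulate(config, outdir, state, manifest)
        else:
            _load_inputs(config, state)
        if "qc" in config.stages:
            _stage_qc(config, outdir, state, manifest)
        if "niche" in config.stages:
            _stage_niche(config, outdir, state, manifest)
        if "distances" in config.stages:
            _stage_distances(config, outdir, state, manifest)
        if "rcm" in config.stages:
            _stage_rcm(config, outdir, state, manifest)
        if "dbrda" in config.stages:
            _stage_dbrda(config, outdir, state, manifest)
        if "scan" in config.stages:
            _stage_scan(config, outdir, state, manifest)
    except Exception as exc:
        manifest["failed_stage"] = state.get("current_stage", "?")
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                         default=str))
        raise

    manifest["complete"] = True
    for p in sorted(outdir.glob("*.csv")):
        manifest.setdefault("outputs", {})[p.name] = _hash_file(p)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     default=str))
    return manifest


# --- stages ---------------------------------------------------------------

def _stage_simulate(config, outdir, state, manifest):
    state["current_stage"] = "simulate"
    params = dict(config.simulate)
    params.setdefault("seed", stage_seed(config.seed, "simulate"))
    sim = synthdata.SimulationConfig(**params)
    rasters, suit, samples, g, truth = synthdata.simulate_dataset(sim)
    synthdata.write_bundle(g, samples, rasters, outdir / "synthetic",
                           suitability=suit, truth=truth)
    state.update(rasters=rasters, suitability=suit, samples=samples,
                 genotypes=g, truth=truth)
    manifest["stages"]["simulate"] = {
        "individuals": g.n_samples, "loci": g.n_loci,
        "sites": int(samples["site"].nunique())}
    logger.info("simulate: %d individuals, %d loci", g.n_samples, g.n_loci)


def _load_inputs(config, state):
    state["current_stage"] = "load"
    if config.vcf:
        state["genotypes"] = geno_qc.read_vcf(config.vcf)
    if config.samples:
        state["samples"] = pd.read_csv(config.samples)


def _stage_qc(config, outdir, state, manifest):
    state["current_stage"] = "qc"
    g = state["genotypes"]
    p = config.qc
    g, report = geno_qc.apply_filters(
        g, max_ind_missing=p["max_ind_missing"], min_depth=p["min_depth"],
        min_maf=p["min_maf"], max_locus_missing=p["max_locus_missing"])
    g = geno_qc.thin_loci(g, min_gap_bp=p["min_gap_bp"])
    kin = geno_qc.kinship_matrix(g)
    g, removed = geno_qc.drop_relatives(g, kin, threshold=p["kin_threshold"])
    gd = geno_qc.genetic_distance(g, squared=p["squared_distance"])
    report.to_frame().to_csv(outdir / "filter_report.csv", index=False)
    kin.to_csv(outdir / "kinship.csv")
    gd.to_csv(outdir / "genetic_distance.csv")
    synthdata.write_vcf(g, outdir / "filtered.vcf")
    if "samples" in state:
        keep = state["samples"]["id"].isin(g.sample_ids)
        state["samples"] = state["samples"][keep].reset_index(drop=True)
    state["genotypes"] = g
    state["genetic_dm"] = gd
    manifest["stages"]["qc"] = {
        "individuals_out": g.n_samples, "loci_out": g.n_loci,
        "siblings_removed": len(removed)}
    logger.info("qc: %d individuals, %d loci survive", g.n_samples, g.n_loci)


def _stage_niche(config, outdir, state, manifest):
    state["current_stage"] = "niche"
    p = config.niche
    samples = state["samples"]
    rasters = state["rasters"]
    seed = stage_seed(config.seed, "niche")
    xs = list(samples["x_km"].to_numpy())
    ys = list(samples["y_km"].to_numpy())
    prov = ["sequenced-sample"] * len(samples)
    if "suitability" in state:
        # emulate external occurrence records: points drawn from the true
        # suitability surface, as GBIF records supplement sequenced samples
        suit = state["suitability"]
        rng = np.random.default_rng(stage_seed(config.seed, "occurrences"))
        flat = np.where(np.isfinite(suit.grid.ravel()), suit.grid.ravel(), 0.0)
        n_extra = int(p.get("n_occurrences", 300))
        cells = rng.choice(flat.size, size=min(n_extra, (flat > 0).sum()),
                           replace=False, p=flat / flat.sum())
        r, c = np.unravel_index(cells, suit.grid.shape)
        xs.extend(suit.x0 + (c + 0.5) * suit.cell_size)
        ys.extend(suit.y0 + (r + 0.5) * suit.cell_size)
        prov.extend(["external-record"] * r.size)
    occ = niche.OccurrenceSet(np.array(xs), np.array(ys), prov)
    mask, masked, occ = niche.make_study_area(
        occ.x, occ.y, rasters, occ, buffer_km=p["buffer_km"])
    cv = niche.cv_auc(occ, masked, folds=p["folds"],
                      n_background=p["n_background"], reg=p["reg"], seed=seed)
    imp = niche.permutation_importance(cv["models"], seed=seed)
    imp.table.to_csv(outdir / "importance.csv", index=False)
    pd.DataFrame({"fold": range(len(cv["fold_auc"])),
                  "auc": cv["fold_auc"]}).to_csv(outdir / "cv_auc.csv",
                                                 index=False)
    state["suitability"] = cv["surface"]
    state["rasters_masked"] = masked
    state["resistance"] = niche.resistance_surface(cv["surface"],
                                                   floor=p["floor"])
    manifest["stages"]["niche"] = {"mean_auc": cv["mean_auc"],
                                   "occurrences": occ.n}
    logger.info("niche: mean AUC %.3f over %d folds", cv["mean_auc"],
                len(cv["fold_auc"]))


def _stage_distances(config, outdir, state, manifest):
    state["current_stage"] = "distances"
    samples = state["samples"]
    dms = [dist_mod.euclidean_dm(samples)]
    if "resistance" in state:
        graph = dist_mod.build_graph(
            state["resistance"], connectivity=config.distances["connectivity"])
        dms.append(dist_mod.least_cost_dm(graph, samples))
        dms.append(dist_mod.resistance_dm(graph, samples))
    dms.extend(dist_mod.env_and_host_dms(samples))
    for dm in dms:
        dm.to_csv(outdir / f"dm_{dm.label}.csv")
    state["predictor_dms"] = dms
    manifest["stages"]["distances"] = {"matrices": len(dms)}
    logger.info("distances: %d predictor matrices", len(dms))


def _stage_rcm(config, outdir, state, manifest):
    state["current_stage"] = "rcm"
    result = mantel_rcm.rcm(state["genetic_dm"], state["predictor_dms"],
                            n_perm=config.rcm["n_perm"],
                            seed=stage_seed(config.seed, "rcm"))
    result.to_csv(outdir / "rcm_index.csv", outdir / "rcm_table.csv")
    state["rcm"] = result
    manifest["stages"]["rcm"] = {"models": result.n_models,
                                 "tests": result.n_tests}
    logger.info("rcm: %d reciprocal models (%d tests)", result.n_models,
                result.n_tests)


def _stage_dbrda(config, outdir, state, manifest):
    state["current_stage"] = "dbrda"
    p = config.dbrda
    seed = stage_seed(config.seed, "dbrda")
    samples = state["samples"]
    gd = state["genetic_dm"]
    basis = ordination.dbmem(samples)
    retained, mem_table = ordination.select_mems(
        basis, gd, alpha=p["alpha"], n_perm=p["n_perm"], seed=seed)
    mem_table.to_csv(outdir / "dbmem_selection.csv", index=False)
    geo = pd.DataFrame(basis.vectors[:, retained],
                       columns=[f"MEM{k + 1}" for k in retained])
    env_src = state.get("rasters_masked", state.get("rasters"))
    envpca = ordination.env_raster_pca(env_src)
    env = envpca.extract(samples)
    host = samples["host"].to_numpy()
    model = ordination.dbrda_fit(gd, geographic=geo if len(geo.columns) else None,
                                 env=env, host=host)
    anova = ordination.permutation_anova(model, n_perm=p["n_perm"], seed=seed)
    anova.to_csv(outdir / "dbrda_anova.csv", index=False)
    model.vif.to_csv(outdir / "dbrda_vif.csv", index=False)
    if len(geo.columns):
        host_dummies = pd.get_dummies(pd.Series(host), drop_first=True,
                                      dtype=float)
        vp = ordination.varpart3(gd, geo, env, host_dummies)
        vp.to_frame().to_csv(outdir / "varpart.csv", index=False)
        state["varpart"] = vp
    state["dbrda"] = model
    manifest["stages"]["dbrda"] = {"r2": model.r2, "adj_r2": model.adj_r2,
                                   "mems_retained": int(len(retained))}
    logger.info("dbrda: R2 %.4f (adj %.4f)", model.r2, model.adj_r2)


def _stage_scan(config, outdir, state, manifest):
    state["current_stage"] = "scan"
    p = config.scan
    seed = stage_seed(config.seed, "scan")
    g = state["genotypes"]
    samples = state["samples"]
    hosts = samples["host"].to_numpy()
    fst_rows = []
    n_out = 0
    for res in selection_scan.pairwise_host_fst(g, hosts):
        scan = selection_scan.fst_outlier_scan(
            g.take_samples(np.nonzero(np.isin(hosts, res.pair.split("-")))[0]),
            hosts[np.isin(hosts, res.pair.split("-"))],
            n_perm=p["n_perm"], fdr=p["fdr"], seed=seed)
        n_out += int(scan.outliers.sum())
        fst_rows.append({"pair": res.pair, "overall_theta": res.overall,
                         "outliers": int(scan.outliers.sum())})
    pd.DataFrame(fst_rows).to_csv(outdir / "fst_pairwise.csv", index=False)
    env_cols = [c for c in samples.columns if c.startswith("env")]
    gea = selection_scan.gea_scan(g, samples[env_cols], K=p["K"],
                                  runs=p["runs"], seed=seed)
    gea.to_frame().to_csv(outdir / "gea.csv", index=False)
    gea.strongest.to_csv(outdir / "gea_strongest.csv", index=False)
    manifest["stages"]["scan"] = {
        "fst_comparisons": len(fst_rows), "fst_outliers": n_out,
        "gea_bonferroni_hits": int(gea.bonferroni.any(axis=1).sum())}
    logger.info("scan: %d FST comparisons, %d GEA Bonferroni hits",
                len(fst_rows), int(gea.bonferroni.any(axis=1).sum()))


# --- CLI ------------------------------------------------------------------

def main() -> None:
    import click

    @click.group()
    @click.option("--verbose", is_flag=True)
    def cli(verbose):
        """Landscape-genomics pipeline for host-associated differentiation."""
        logging.basicConfig(level=logging.INFO if verbose else logging.WARNING,
                            format="%(levelname)s %(name)s: %(message)s")

    def _run(stages, config_path, seed, out):
        if config_path:
            config = PipelineConfig.from_yaml(config_path)
        else:
            config = PipelineConfig()
        if seed is not None:
            config.seed = seed
        if out:
            config.outdir = out
        if stages is not None:
            config.stages = stages
        run_pipeline(config)

    for name in ALL_STAGES + ["all"]:
        def make(stage_name):
            @click.command(name=stage_name)
            @click.option("--config", "config_path", type=click.Path(exists=True))
            @click.option("--seed", type=int, default=None)
            @click.option("--out", type=str, default=None)
            def cmd(config_path, seed, out):
                if stage_name == "all":
                    stages = None
                else:
                    idx = ALL_STAGES.index(stage_name)
                    stages = ALL_STAGES[: idx + 1]
                _run(stages, config_path, seed, out)
            return cmd
        cli.add_command(make(name))

    cli()


if __name__ == "__main__":
    main()
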