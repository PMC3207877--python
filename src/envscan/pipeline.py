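"""End-to-end orchestration: simulate -> annotate -> PLS -> enrichment ->
distances -> partial Mantel -> report.

Every stochastic stage takes an explicit seed derived from the run seed, so
re-running with the same configuration reproduces byte-identical outputs.
The summary JSON carries the headline quantities (significant genes per
category, top-bin enrichments with confidence intervals, drop-one QQ areas);
wall times and record counts go to the log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation, enrichment, io, mantel, pls, simulate
from .containers import EnvironmentTable, FrequencyTable

logger = logging.getLogger(__name__)

PATHOGEN_GROUPS = ("virus", "bacteria", "protozoa", "helminth")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    outdir: str = "envscan_out"
    seed: int = 0
    # input: either a simulation scenario or paths to panel files
    scenario: str | None = "reference"       # reference | null | custom
    simulation: dict = field(default_factory=dict)   # SimulationConfig overrides
    frequency_table: str | None = None
    environment: str | None = None
    categories: str | None = None
    strata: str | None = None
    # stage parameters
    model_specs: tuple[str, ...] = ("full", "pathogen", "subsistence", "climate")
    n_noise: int = pls.DEFAULT_N_NOISE
    bin_width: float = enrichment.DEFAULT_BIN_WIDTH
    block_size: int = enrichment.DEFAULT_BLOCK_SIZE
    n_bootstrap: int = enrichment.DEFAULT_N_BOOTSTRAP
    ci_level: float = enrichment.DEFAULT_CI_LEVEL
    mantel_categories: tuple[str, ...] = mantel.MANTEL_CATEGORIES
    n_perm: int = 2000
    drop_one: bool = True
    q_threshold: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for f in ("model_specs", "mantel_categories"):
            setattr(cfg, f, tuple(getattr(cfg, f)))
        return cfg

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["model_specs"] = list(self.model_specs)
        d["mantel_categories"] = list(self.mantel_categories)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def validate(self) -> None:
        if self.scenario is None and not self.frequency_table:
            raise ValueError("config needs either a simulation scenario or "
                             "a frequency_table path")
        if self.scenario is None and self.n_perm > 0 and not self.strata:
            raise ValueError("strata file is required when n_perm > 0: the "
                             "permutation null is stratified by continent")


def _load_panel(cfg: RunConfig, outdir: Path):
    if cfg.scenario is not None:
        if cfg.scenario == "reference":
            sim = simulate.reference_scenario(cfg.seed, **cfg.simulation)
        elif cfg.scenario == "null":
            sim = simulate.null_scenario(cfg.seed, **cfg.simulation)
        elif cfg.scenario == "custom":
            sim = simulate.SimulationConfig(seed=cfg.seed, **cfg.simulation)
        else:
            raise ValueError(f"unknown scenario {cfg.scenario!r}")
        ft, env, strata, truth = simulate.simulate_panel(sim)
        io.write_frequency_table(ft, outdir / "frequencies.tsv")
        io.write_environment(env, outdir / "environment.csv",
                             outdir / "env_categories.csv")
        io.write_strata(strata, outdir / "strata.tsv")
        io.write_ground_truth(truth, outdir / "ground_truth.json")
        io.write_covariates(ft.annotations[["recomb"]], outdir / "covariates.tsv")
        return ft, env, strata, truth
    ft = io.read_frequency_table(cfg.frequency_table)
    env = io.read_environment(cfg.environment, cfg.categories)
    strata = io.read_strata(cfg.strata) if cfg.strata else None
    return ft, env, strata, None


def _genic_classes(classes: pd.Series) -> pd.Series:
    """Collapse nonsyn into genic for the genic-vs-all contrast."""
    return classes.replace({"nonsyn": "genic"})


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the summary dictionary (also written as JSON)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    summary: dict = {"seed": config.seed}
    t_all = time.perf_counter()

    def stage(name):
        logger.info("stage %s ...", name)
        return time.perf_counter()

    t = stage("panel")
    ft, env, strata, truth = _load_panel(config, outdir)
    logger.info("panel: %d SNPs, %d populations (%.1fs)",
                ft.freqs.shape[0], ft.freqs.shape[1], time.perf_counter() - t)

    t = stage("annotate")
    cov = annotation.annotate_covariates(ft)
    io.write_covariates(cov, outdir / "snp_covariates.tsv")
    logger.info("annotate: done (%.1fs)", time.perf_counter() - t)

    t = stage("pls")
    scans = {}
    for spec in config.model_specs:
        scans[spec] = pls.scan_all_snps(ft, env, spec, n_noise=config.n_noise,
                                        seed=config.seed)
        io.write_table(scans[spec], outdir / f"pls_{spec}.tsv")
    logger.info("pls: %d models x %d SNPs (%.1fs)", len(scans),
                ft.freqs.shape[0], time.perf_counter() - t)

    t = stage("enrichment")
    base = config.model_specs[0]
    edf = pd.DataFrame({
        "chrom": ft.annotations["chrom"],
        "pos": ft.annotations["pos"],
        "q2": scans[base]["q2"],
        "snp_class": _genic_classes(ft.annotations["snp_class"]),
    }).dropna(subset=["q2"])
    curves = {}
    for target in ("genic", "intergenic"):
        curves[target] = enrichment.enrichment_curve(
            edf, target, bin_width=config.bin_width,
            block_size=config.block_size, n_reps=config.n_bootstrap,
            ci_level=config.ci_level, seed=np.random.default_rng(config.seed + 1))
    enr_tab = pd.concat([c.to_frame() for c in curves.values()],
                        ignore_index=True)
    io.write_table(enr_tab, outdir / "enrichment.tsv", index=False)
    gc = curves["genic"]
    summary["top_bin_genic_enrichment"] = float(gc.enrichment[-1])
    summary["top_bin_genic_ci"] = [float(gc.ci_low[-1]), float(gc.ci_high[-1])]
    logger.info("enrichment: %d bins (%.1fs)", len(gc.n_snps),
                time.perf_counter() - t)

    t = stage("distances")
    from .distances import overall_distance_matrix
    Z = overall_distance_matrix(ft)
    io.write_distance_matrix(Z, outdir / "overall_distance.tsv")
    logger.info("distances: Z over %d loci (%.1fs)", ft.freqs.shape[0],
                time.perf_counter() - t)

    results = None
    if config.n_perm > 0:
        t = stage("mantel")
        results = mantel.gene_scan(ft, env, strata,
                                   categories=config.mantel_categories,
                                   n_perm=config.n_perm, seed=config.seed + 2)
        io.write_table(results, outdir / "mantel.tsv", index=False)
        sig = results[results["q_fdr"] < config.q_threshold]
        summary["significant_genes"] = {
            c: int((sig["category"] == c).sum()) for c in config.mantel_categories}
        summary["median_demographic_r2_pct"] = float(
            100.0 * np.median(results["r_yz"] ** 2))
        logger.info("mantel: %d runs (%.1fs)", len(results),
                    time.perf_counter() - t)

        if config.drop_one and "pathogen" in config.mantel_categories:
            t = stage("drop-one")
            full_p = results[results["category"] == "pathogen"]
            qq_areas = {}
            for grp in PATHOGEN_GROUPS:
                dropped = mantel.gene_scan(
                    ft, env, strata, categories=("pathogen",), drop_group=grp,
                    n_perm=config.n_perm, seed=config.seed + 3)
                io.write_table(dropped, outdir / f"mantel_drop_{grp}.tsv",
                               index=False)
                qq = mantel.qq_compare(full_p, dropped)
                qq_areas[grp] = qq["signed_area"]
            summary["qq_signed_area"] = qq_areas
            logger.info("drop-one: %d groups (%.1fs)", len(qq_areas),
                        time.perf_counter() - t)

    if truth is not None and results is not None and truth.selected_gene_ids:
        cat = truth.driving_variable[truth.selected_gene_ids[0]]
        drive_cat = env.categories.get(cat, "pathogen").split(":")[0]
        sub = results[results["category"] == drive_cat]
        summary["selected_gene_auc"] = ranking_auc(
            sub, set(truth.selected_gene_ids))

    logger.info("pipeline finished in %.1fs", time.perf_counter() - t_all)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1,
                                                    sort_keys=True))
    return summary


def ranking_auc(results: pd.DataFrame, positive_genes: set) -> float:
    """AUC of ranking genes by p-value (smaller p = stronger candidate)."""
    from scipy.stats import rankdata
    p = results["p_gpd"].to_numpy(float)
    is_pos = results["gene_id"].isin(positive_genes).to_numpy()
    if is_pos.sum() == 0 or is_pos.sum() == is_pos.size:
        raise ValueError("need both positive and negative genes for AUC")
    ranks = rankdata(-np.log10(p))
    n_pos = is_pos.sum()
    n_neg = is_pos.size - n_pos
    u = ranks[is_pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))
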