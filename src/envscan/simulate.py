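"""Synthetic worldwide genotyping panels with known ground truth.

The generator emulates a worldwide genotyping panel: ~55 populations in ~6
continental strata, allele frequencies shaped by two-level hierarchical
drift (shared continental drift plus population-specific drift, a
Balding-Nichols-style perturbation model), 14 correlated environmental
variables measured per population, and SNPs grouped into genes along
chromosomes as a linkage-block surrogate. A tunable set of "selected" genes
has all its SNP frequencies shifted in proportion to one standardized
environmental variable, mimicking local adaptation to that variable.

Two-level drift: for ancestral frequency p, the continent frequency is
p_c = p + N(0, F_continent * p(1-p)) and the population frequency is
p_cp = p_c + N(0, F_population * p_c(1-p_c)), each truncated to [0, 1].
Selection shifts are applied before truncation and folding, so the emitted
observable is the folded minor allele frequency in [0, 0.5] throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import EnvironmentTable, FrequencyTable, GroundTruth

logger = logging.getLogger(__name__)

# Core 14-variable set: 5 climate, 5 subsistence, 4 pathogen-richness
# variables; two supplemental climate-range variables are optional.
_CORE_VARIABLES = {
    "dist_sea": "climate",
    "temp_mean": "climate",
    "precip_mean": "climate",
    "humidity_mean": "climate",
    "radiation_mean": "climate",
    "agriculture": "subsistence",
    "husbandry": "subsistence",
    "fishing": "subsistence",
    "hunting": "subsistence",
    "gathering": "subsistence",
    "pathogen_virus": "pathogen:virus",
    "pathogen_bacteria": "pathogen:bacteria",
    "pathogen_protozoa": "pathogen:protozoa",
    "pathogen_helminth": "pathogen:helminth",
}
_RANGE_VARIABLES = {
    "temp_range": "climate_range",
    "precip_range": "climate_range",
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic panel.

    Drift coefficients ``F_continent`` and ``F_population`` play the role of
    hierarchical F_ST components; ``effect_size`` is the slope of the
    frequency shift on the standardized driving environmental variable.
    """

    n_continents: int = 6
    pops_per_continent: int | tuple[int, ...] = 9
    n_snps: int = 5000
    snps_per_gene: int = 5
    frac_genic: float = 0.5
    frac_nonsyn_of_genic: float = 0.1
    F_continent: float = 0.1
    F_population: float = 0.05
    n_env_vars: int = 14
    env_corr: float = 0.3
    env_continent_sd: float = 1.0
    env_pop_sd: float = 0.5
    include_climate_range: bool = True
    n_selected_genes: int = 0
    effect_size: float = 0.0
    driving_variables: tuple[str, ...] = ("pathogen_helminth",)
    n_missing_subsistence: int = 0
    n_diploids: int = 20
    n_chroms: int = 4
    seed: int = 0

    def continent_sizes(self) -> list[int]:
        if isinstance(self.pops_per_continent, int):
            return [self.pops_per_continent] * self.n_continents
        sizes = list(self.pops_per_continent)
        if len(sizes) != self.n_continents:
            raise ValueError("pops_per_continent tuple must have n_continents entries")
        return sizes

    def validate(self) -> None:
        if min(self.continent_sizes()) < 2:
            raise ValueError(
                "pops_per_continent must be >= 2: each continental stratum "
                "needs at least two populations to permute"
            )
        if self.n_continents < 2:
            raise ValueError("need at least 2 continents")
        for name in ("frac_genic", "frac_nonsyn_of_genic"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("F_continent", "F_population"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.n_snps < 1 or self.snps_per_gene < 1:
            raise ValueError("n_snps and snps_per_gene must be positive")
        if self.n_env_vars != len(_CORE_VARIABLES):
            raise ValueError(
                f"the core variable set has {len(_CORE_VARIABLES)} members; "
                f"n_env_vars={self.n_env_vars} is not supported"
            )
        n_genes = self._n_genes()
        if self.n_selected_genes > n_genes:
            raise ValueError(
                f"n_selected_genes={self.n_selected_genes} exceeds the "
                f"{n_genes} genic genes implied by n_snps/frac_genic"
            )
        if self.n_missing_subsistence >= sum(self.continent_sizes()):
            raise ValueError("n_missing_subsistence must leave populations intact")

    def _n_genes(self) -> int:
        return int(round(self.frac_genic * self.n_snps)) // self.snps_per_gene


def reference_scenario(seed: int = 0, **overrides) -> SimulationConfig:
    """The default study scenario: 55 populations in 6 continental strata,
    500 genes of which 20 are driven by helminth-species richness with slope
    0.2. Three populations lack subsistence data, mirroring worldwide panels
    where ethnographic coverage is incomplete.
    """
    cfg = SimulationConfig(
        n_continents=6,
        pops_per_continent=(10, 9, 9, 9, 9, 9),
        n_snps=10_000,
        snps_per_gene=10,
        frac_genic=0.5,
        n_selected_genes=20,
        effect_size=0.2,
        n_missing_subsistence=3,
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def null_scenario(seed: int = 0, **overrides) -> SimulationConfig:
    """A no-selection panel used for calibration: 30 populations in 5
    strata, 500 genes, effect_size = 0."""
    cfg = SimulationConfig(
        n_continents=5,
        pops_per_continent=6,
        n_snps=4000,
        snps_per_gene=4,
        frac_genic=0.5,
        n_selected_genes=0,
        effect_size=0.0,
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def _simulate_environment(
    cfg: SimulationConfig, pops: list[str], continent_of: np.ndarray,
    rng: np.random.Generator,
) -> tuple[EnvironmentTable, pd.DataFrame]:
    """Environment values plus the standardized latent matrix (pop x var).

    Continent means are drawn from a multivariate normal with pairwise
    correlation ``env_corr`` (moderate cross-variable correlation, to
    exercise collinearity handling); population values add independent
    noise. Pathogen variables are mapped to non-negative integer species
    richness; other variables get cosmetic affine rescaling only.
    """
    variables = dict(_CORE_VARIABLES)
    if cfg.include_climate_range:
        variables.update(_RANGE_VARIABLES)
    names = list(variables)
    k = len(names)
    n_pops = len(pops)

    corr = np.full((k, k), cfg.env_corr)
    np.fill_diagonal(corr, 1.0)
    chol = np.linalg.cholesky(corr)
    cont_means = (rng.standard_normal((cfg.n_continents, k)) @ chol.T
                  ) * cfg.env_continent_sd
    latent = cont_means[continent_of] + rng.normal(0, cfg.env_pop_sd, (n_pops, k))

    values = pd.DataFrame(index=pd.Index(pops, name="population"), columns=names,
                          dtype=float)
    for j, name in enumerate(names):
        x = latent[:, j]
        if variables[name].startswith("pathogen:"):
            values[name] = np.round(np.clip(60.0 + 18.0 * x, 0.0, None))
        elif variables[name] == "subsistence":
            values[name] = np.clip(20.0 + 15.0 * x, 0.0, 100.0)
        else:
            values[name] = 15.0 + 10.0 * x

    if cfg.n_missing_subsistence:
        drop = rng.choice(n_pops, size=cfg.n_missing_subsistence, replace=False)
        sub_cols = [v for v, c in variables.items() if c == "subsistence"]
        values.iloc[drop, [values.columns.get_loc(c) for c in sub_cols]] = np.nan

    latent_df = pd.DataFrame(latent, index=values.index, columns=names)
    return EnvironmentTable(values, variables), latent_df


def _layout_snps(cfg: SimulationConfig) -> pd.DataFrame:
    """Chromosomal layout: genes as contiguous SNP runs, intergenic runs in
    >100 kb gene-free gaps so the layout is consistent with the genic /
    intergenic classification rules."""
    n_genic = cfg._n_genes() * cfg.snps_per_gene
    n_genes = cfg._n_genes()
    n_inter = cfg.n_snps - n_genic

    chroms, positions, gene_ids, classes = [], [], [], []
    inter_per_gene = np.diff(np.round(np.linspace(0, n_inter, n_genes + 1))).astype(int) \
        if n_genes else np.array([], int)
    genes_per_chrom = np.diff(np.round(np.linspace(0, n_genes, cfg.n_chroms + 1))).astype(int)

    gidx = 0
    leftover = n_inter if n_genes == 0 else 0
    for c in range(cfg.n_chroms):
        pos = 1
        for _ in range(genes_per_chrom[c]):
            gene = f"g{gidx:04d}"
            for _ in range(cfg.snps_per_gene):
                chroms.append(f"chr{c + 1}")
                positions.append(pos)
                gene_ids.append(gene)
                classes.append("genic")
                pos += 2_000
            pos += 120_000
            for _ in range(inter_per_gene[gidx]):
                chroms.append(f"chr{c + 1}")
                positions.append(pos)
                gene_ids.append("")
                classes.append("intergenic")
                pos += 5_000
            pos += 120_000
            gidx += 1
    for _ in range(leftover):
        chroms.append("chr1")
        positions.append(1 + 5_000 * len(positions))
        gene_ids.append("")
        classes.append("intergenic")

    snp_ids = [f"s{i:06d}" for i in range(len(positions))]
    return pd.DataFrame(
        {"chrom": chroms, "pos": positions, "snp_class": classes,
         "gene_id": gene_ids},
        index=pd.Index(snp_ids, name="snp_id"),
    )


def simulate_panel(
    config: SimulationConfig,
) -> tuple[FrequencyTable, EnvironmentTable, pd.Series, GroundTruth]:
    """Generate a panel with known ground truth.

    Returns the frequency table (with a ``recomb`` covariate column in its
    annotations), the environment table, the population -> continent strata
    map, and the ground-truth labels.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    sizes = config.continent_sizes()
    n_pops = sum(sizes)
    continents = [f"C{i + 1}" for i in range(config.n_continents)]
    pops = [f"{continents[i]}p{j + 1}" for i in range(config.n_continents)
            for j in range(sizes[i])]
    continent_of = np.repeat(np.arange(config.n_continents), sizes)
    strata = pd.Series([continents[i] for i in continent_of],
                       index=pd.Index(pops, name="population"), name="continent")

    env, _latent = _simulate_environment(config, pops, continent_of, rng)
    ann = _layout_snps(config)
    n_snps = len(ann)

    # nonsyn labels inside genes
    genic_idx = np.flatnonzero((ann["snp_class"] == "genic").to_numpy())
    n_nonsyn = int(round(config.frac_nonsyn_of_genic * genic_idx.size))
    if n_nonsyn:
        pick = rng.choice(genic_idx, size=n_nonsyn, replace=False)
        col = ann.columns.get_loc("snp_class")
        ann.iloc[pick, col] = "nonsyn"

    # two-level hierarchical drift
    p_anc = rng.uniform(0.05, 0.95, n_snps)
    var_c = config.F_continent * p_anc * (1.0 - p_anc)
    p_cont = p_anc[:, None] + rng.standard_normal(
        (n_snps, config.n_continents)) * np.sqrt(var_c)[:, None]
    np.clip(p_cont, 0.0, 1.0, out=p_cont)
    p_pop = p_cont[:, continent_of]
    var_p = config.F_population * p_pop * (1.0 - p_pop)
    p_pop = p_pop + rng.standard_normal((n_snps, n_pops)) * np.sqrt(var_p)
    np.clip(p_pop, 0.0, 1.0, out=p_pop)

    # selection: shift all SNPs of selected genes along the driving variable
    genes = sorted(g for g in ann["gene_id"].unique() if g)
    selected: list[str] = []
    driving: dict[str, str] = {}
    if config.n_selected_genes:
        selected = sorted(rng.choice(genes, size=config.n_selected_genes,
                                     replace=False).tolist())
        for i, g in enumerate(selected):
            driving[g] = config.driving_variables[i % len(config.driving_variables)]
        gene_col = ann["gene_id"].to_numpy()
        for g in selected:
            var = env.values[driving[g]].to_numpy(float)
            z = (var - np.nanmean(var)) / np.nanstd(var, ddof=1)
            rows = np.flatnonzero(gene_col == g)
            p_pop[rows] = p_pop[rows] + config.effect_size * z[None, :]
        np.clip(p_pop, 0.0, 1.0, out=p_pop)

    # fold to minor allele frequency
    maf = np.minimum(p_pop, 1.0 - p_pop)

    # recombination-rate proxy: smooth positive covariate along chromosomes
    ar = np.empty(n_snps)
    x = 0.0
    for i in range(n_snps):
        x = 0.9 * x + rng.normal(0, 0.25)
        ar[i] = x
    ann = ann.assign(recomb=np.exp(ar))

    freqs = pd.DataFrame(maf, index=ann.index, columns=pops)
    sizes = pd.Series(config.n_diploids, index=freqs.columns)
    ft = FrequencyTable(ann, freqs, sizes)
    truth = GroundTruth(
        selected_gene_ids=selected,
        driving_variable=driving,
        snp_class=ann["snp_class"].to_dict(),
    )
    logger.info("simulated %d SNPs x %d populations (%d genes, %d selected)",
                n_snps, n_pops, len(genes), len(selected))
    return ft, env, strata, truth


def panel_gene_models(ft: FrequencyTable) -> pd.DataFrame:
    """Gene intervals implied by a synthetic panel's SNP layout.

    One interval per gene spanning its SNPs with a 1 kb margin; plus strand.
    Useful for exercising the SNP classifier against the generator's own
    class labels.
    """
    genic = ft.annotations[ft.annotations["gene_id"] != ""]
    rows = []
    for gene, grp in genic.groupby("gene_id", sort=True):
        rows.append({
            "gene_id": gene,
            "chrom": grp["chrom"].iloc[0],
            "start": int(grp["pos"].min()) - 1000,
            "end": int(grp["pos"].max()) + 1000,
            "strand": "+",
        })
    return pd.DataFrame(rows)
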