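"""Core in-memory containers shared across the pipeline.

The pipeline operates on three aligned tables: a SNP x population
minor-allele-frequency matrix with per-SNP annotation, a population x
variable environment matrix with a category label per variable, and a
population -> continent strata map used for restricted permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: SNP classes used throughout. "nonsyn" implies a genic context.
SNP_CLASSES = ("genic", "nonsyn", "intergenic", "other")

#: Environment variable categories. Pathogen categories carry the group name.
ENV_CATEGORIES = (
    "climate",
    "climate_range",
    "subsistence",
    "pathogen:virus",
    "pathogen:bacteria",
    "pathogen:protozoa",
    "pathogen:helminth",
)

#: Annotation columns required in a frequency table, in canonical order.
ANNOTATION_COLS = ("chrom", "pos", "snp_class", "gene_id")


@dataclass
class FrequencyTable:
    """Per-SNP minor allele frequencies over populations.

    Parameters
    ----------
    annotations : DataFrame indexed by snp_id with at least the columns
        ``chrom, pos, snp_class, gene_id`` (extra per-SNP covariate columns
        such as a recombination-rate proxy are allowed and preserved).
    freqs : DataFrame indexed by snp_id, one column per population, values
        folded minor allele frequencies in [0, 0.5].
    sample_sizes : diploid sample size per population (used by the
        Weir-Cockerham F_ST estimator). Defaults to 20 per population.
    """

    annotations: pd.DataFrame
    freqs: pd.DataFrame
    sample_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLS if c not in self.annotations.columns]
        if missing:
            raise ValueError(f"frequency table missing annotation columns: {missing}")
        if not self.annotations.index.equals(self.freqs.index):
            raise ValueError("annotation and frequency rows are not aligned")
        if self.sample_sizes is None:
            self.sample_sizes = pd.Series(20, index=self.freqs.columns)
        vals = self.freqs.to_numpy()
        if vals.size and (np.nanmin(vals) < -1e-9 or np.nanmax(vals) > 0.5 + 1e-9):
            raise ValueError("minor allele frequencies must lie in [0, 0.5]")

    @property
    def populations(self) -> list[str]:
        return list(self.freqs.columns)

    @property
    def snp_ids(self) -> pd.Index:
        return self.freqs.index

    def subset_populations(self, pops: list[str]) -> "FrequencyTable":
        return FrequencyTable(
            self.annotations, self.freqs[pops], self.sample_sizes[pops]
        )

    def gene_snp_ids(self, gene_id: str) -> pd.Index:
        mask = self.annotations["gene_id"] == gene_id
        return self.annotations.index[mask]

    def genes(self) -> list[str]:
        g = self.annotations["gene_id"].dropna()
        g = g[g != ""]
        return sorted(g.unique())


@dataclass
class EnvironmentTable:
    """Population x variable environment matrix with category labels.

    ``values`` is indexed by population; ``categories`` maps each variable
    name to one of :data:`ENV_CATEGORIES`. Missing entries (``NA``) mark
    populations for which a variable could not be assessed; analyses drop
    such populations listwise for the variables they use.
    """

    values: pd.DataFrame
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = [v for v in self.values.columns if v not in self.categories]
        if unknown:
            raise ValueError(f"variables without a category: {unknown}")
        bad = {v: c for v, c in self.categories.items() if c not in ENV_CATEGORIES}
        if bad:
            raise ValueError(f"unknown categories: {bad}")

    @property
    def populations(self) -> list[str]:
        return list(self.values.index)

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    def variables_in(self, category: str) -> list[str]:
        """Variables belonging to ``category``.

        ``"pathogen"`` selects all four pathogen groups; a fully qualified
        name like ``"pathogen:virus"`` selects one group.
        """
        if category == "pathogen":
            return [v for v in self.values.columns
                    if self.categories[v].startswith("pathogen:")]
        return [v for v in self.values.columns if self.categories[v] == category]

    def complete_populations(self, variables: list[str]) -> list[str]:
        """Populations with no missing value among ``variables``."""
        ok = self.values[variables].notna().all(axis=1)
        return list(self.values.index[ok])


def check_strata(strata: pd.Series, populations: list[str]) -> pd.Series:
    """Validate a population -> continent map against an analysis set."""
    missing = [p for p in populations if p not in strata.index]
    if missing:
        raise ValueError(f"populations without a stratum: {missing}")
    return strata.loc[populations]


@dataclass
class GroundTruth:
    """Truth labels emitted by the synthetic panel generator."""

    selected_gene_ids: list[str]
    driving_variable: dict[str, str]
    snp_class: dict[str, str]

    def __post_init__(self) -> None:
        missing = [g for g in self.selected_gene_ids if g not in self.driving_variable]
        if missing:
            raise ValueError(f"selected genes without a driving variable: {missing}")
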