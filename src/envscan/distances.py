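"""Population distance matrices: Reynolds genetic distances (per gene and
genome-wide) and environmental dissimilarities.

The Reynolds coancestry distance between populations A and B over L
biallelic loci is the ratio-of-sums form

    theta = [ sum_l sum_alleles (p_Al - p_Bl)^2 / 2 ] /
            [ sum_l (1 - sum_alleles p_Al * p_Bl) ],

which for biallelic loci reduces to sum (p_A - p_B)^2 over
sum (p_A + p_B - 2 p_A p_B). Loci monomorphic for the same allele in both
populations contribute 0 to both sums (they carry no information); if every
locus is such, the distance is undefined (NaN). No -ln(1-theta)
linearization is applied. Reynolds distance grows linearly with divergence
time under pure drift, which is what makes it the natural "demography"
covariate for the partial Mantel analysis.

Environmental distances: each variable is z-scored over the analyzed
populations; the per-variable distance is |difference of scaled values|;
a category's matrix is the arithmetic mean of its per-variable matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import EnvironmentTable, FrequencyTable

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric population dissimilarity with a role tag."""

    labels: list[str]
    values: np.ndarray
    role: str = ""                       # gene_Y | env_X | overall_Z
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        finite = np.isfinite(v)
        if not np.allclose(v[finite], v.T[finite], atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        self.values = v

    def triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def reorder(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)],
                              self.role, dict(self.provenance))


def reynolds_distance(freqs_a: np.ndarray, freqs_b: np.ndarray) -> float:
    """Reynolds coancestry distance between two populations over loci."""
    pa = np.asarray(freqs_a, float)
    pb = np.asarray(freqs_b, float)
    num = float(((pa - pb) ** 2).sum())
    den = float((pa + pb - 2.0 * pa * pb).sum())
    if den == 0.0:
        return float("nan")
    return num / den


def _pairwise_reynolds(P: np.ndarray) -> np.ndarray:
    """All-pairs Reynolds distances for a population x locus matrix."""
    G = P @ P.T
    q = np.diag(G)
    s = P.sum(axis=1)
    num = q[:, None] + q[None, :] - 2.0 * G
    den = s[:, None] + s[None, :] - 2.0 * G
    with np.errstate(invalid="ignore", divide="ignore"):
        D = num / den
    np.fill_diagonal(D, 0.0)
    return D


def gene_distance_matrix(ft: FrequencyTable, gene_id: str,
                         populations: list[str] | None = None) -> DistanceMatrix:
    """Per-gene Reynolds distance matrix (role gene_Y)."""
    snps = ft.gene_snp_ids(gene_id)
    if len(snps) == 0:
        raise ValueError(f"gene {gene_id!r} has no SNPs in the frequency table")
    pops = populations or ft.populations
    P = ft.freqs.loc[snps, pops].to_numpy(float).T
    return DistanceMatrix(list(pops), _pairwise_reynolds(P), "gene_Y",
                          {"gene_id": gene_id, "n_snps": len(snps)})


def overall_distance_matrix(ft: FrequencyTable,
                            populations: list[str] | None = None,
                            mode: str = "pooled") -> DistanceMatrix:
    """Genome-wide Reynolds distance matrix (role overall_Z).

    ``pooled`` sums numerator and denominator over all loci before dividing
    (default); ``mean_gene`` averages per-gene matrices instead, which suits
    sequencing-style input where per-locus information is heterogeneous.
    """
    pops = populations or ft.populations
    if mode == "pooled":
        P = ft.freqs[pops].to_numpy(float).T
        D = _pairwise_reynolds(P)
    elif mode == "mean_gene":
        genes = ft.genes()
        if not genes:
            raise ValueError("no genes in frequency table")
        acc = np.zeros((len(pops), len(pops)))
        for g in genes:
            acc += gene_distance_matrix(ft, g, pops).values
        D = acc / len(genes)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return DistanceMatrix(list(pops), D, "overall_Z",
                          {"mode": mode, "n_snps": ft.freqs.shape[0]})


def env_distance_matrix(
    env: EnvironmentTable,
    variables: list[str] | None = None,
    category: str | None = None,
    drop_group: str | None = None,
    populations: list[str] | None = None,
) -> DistanceMatrix:
    """Environmental dissimilarity (role env_X).

    Select variables either explicitly or by category (``"pathogen"`` takes
    all four pathogen groups; ``drop_group`` removes one group, e.g.
    ``"helminth"``, before averaging). Variables are z-scored over the
    analyzed populations (sample sd); zero-variance variables are excluded
    with a warning.
    """
    if variables is None:
        if category is None:
            raise ValueError("give either variables or a category")
        variables = env.variables_in(category)
    if drop_group is not None:
        tag = f"pathogen:{drop_group}"
        dropped = [v for v in variables if env.categories[v] == tag]
        variables = [v for v in variables if env.categories[v] != tag]
        if not variables:
            raise ValueError(f"dropping {drop_group!r} leaves no variables")
        logger.debug("drop-one: removed %s", dropped)
    missing = [v for v in variables if v not in env.values.columns]
    if missing:
        raise ValueError(f"unknown variables: {missing}")
    pops = populations or env.complete_populations(variables)
    V = env.values.loc[pops, variables]
    if V.isna().any().any():
        bad = V.columns[V.isna().any()].tolist()
        raise ValueError(f"missing values among analyzed populations: {bad}")

    mats = []
    used = []
    for v in variables:
        x = V[v].to_numpy(float)
        sd = x.std(ddof=1)
        if sd == 0:
            logger.warning("variable %r has zero variance; excluded", v)
            continue
        z = (x - x.mean()) / sd
        mats.append(np.abs(z[:, None] - z[None, :]))
        used.append(v)
    if not mats:
        # every variable constant: the populations are environmentally
        # identical, so every dissimilarity is zero
        logger.warning("all selected variables have zero variance; "
                       "environmental distances are all zero")
        D = np.zeros((len(pops), len(pops)))
    else:
        D = np.mean(mats, axis=0)
    return DistanceMatrix(list(pops), D, "env_X",
                          {"variables": used, "category": category,
                           "drop_group": drop_group})
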