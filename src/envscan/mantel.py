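"""Per-gene partial Mantel tests of environment against allele-frequency
distances, with demography correction and stratified permutations.

For each gene, three aligned population distance matrices enter the test:
Y (the gene's Reynolds distances), X (an environmental dissimilarity) and
Z (the genome-wide Reynolds distances, absorbing shared demographic
history). With Pearson correlations over the strict upper triangles,

    r_XY.Z = (r_XY - r_XZ r_YZ) / sqrt((1 - r_XZ^2)(1 - r_YZ^2))
    R^2    = r_YZ^2 + (1 - r_YZ^2) * r_XY.Z^2
    I(R^2) = R^2 - r_YZ^2,

so I(R^2) is the gain in explained variance of the gene's distances when
the environmental matrix is added on top of demography; it lies in
[0, 1 - r_YZ^2].

Significance: the rows and columns of Y are permuted simultaneously, but
only within continental strata, preserving broad-scale population structure
under the null; p = (1 + #{permuted >= observed}) / (1 + n_perm). Tail
p-values smaller than the permutation resolution are obtained by fitting a
generalized Pareto distribution (GPD) to the largest permuted statistics,
screened by an Anderson-Darling goodness-of-fit test. Multiple testing is
controlled with the Benjamini-Yekutieli step-up, valid under dependence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import EnvironmentTable, FrequencyTable, check_strata
from .distances import (DistanceMatrix, env_distance_matrix,
                        gene_distance_matrix, overall_distance_matrix)

logger = logging.getLogger(__name__)

DEFAULT_N_PERM = 10_000
DEFAULT_N_EXCEED = 250
_PERM_CHUNK = 1024

MANTEL_CATEGORIES = ("pathogen", "subsistence", "climate")


@dataclass
class MantelResult:
    """Partial Mantel summary for one gene under one environmental matrix."""

    gene_id: str
    category: str
    variable: str
    drop_group: str | None
    r_xy: float
    r_xz: float
    r_yz: float
    r_partial: float
    r2: float
    i_r2: float
    p_perm: float
    p_gpd: float
    q_fdr: float = float("nan")
    n_perm: int = 0


# ---------------------------------------------------------------------------
# Mantel statistics

def _tri(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def mantel_r(a: DistanceMatrix, b: DistanceMatrix) -> float:
    """Plain Mantel statistic: Pearson r of the strict upper triangles."""
    if a.labels != b.labels:
        raise ValueError("distance matrices have different population labels")
    x, y = _tri(a.values), _tri(b.values)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("degenerate distance matrix")
    return float(np.corrcoef(x, y)[0, 1])


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def partial_mantel(Y: DistanceMatrix, X: DistanceMatrix, Z: DistanceMatrix
                   ) -> tuple[float, float, float]:
    """Partial Mantel correlation of X and Y given Z.

    Returns (r_XY.Z, R^2, I(R^2)).
    """
    r_xy = mantel_r(X, Y)
    r_xz = mantel_r(X, Z)
    r_yz = mantel_r(Y, Z)
    return _partial_from_r(r_xy, r_xz, r_yz)


def _partial_from_r(r_xy: float, r_xz: float, r_yz: float
                    ) -> tuple[float, float, float]:
    if abs(r_xz) >= 1.0 - 1e-12 or abs(r_yz) >= 1.0 - 1e-12:
        raise ValueError("covariate collinearity: |r_XZ| or |r_YZ| is 1")
    rp = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz ** 2) * (1 - r_yz ** 2))
    r2 = r_yz ** 2 + (1 - r_yz ** 2) * rp ** 2
    return float(rp), float(r2), float(r2 - r_yz ** 2)


# ---------------------------------------------------------------------------
# Stratified permutations

def _strata_codes(strata: pd.Series, labels: list[str]) -> np.ndarray:
    s = check_strata(strata, labels)
    codes, _ = pd.factorize(s.to_numpy())
    return codes


def stratified_permutations(codes: np.ndarray, n_perm: int,
                            rng: np.random.Generator) -> np.ndarray:
    """(n_perm, n) permutation index arrays shuffling only within strata."""
    n = codes.size
    sizes = np.bincount(codes)
    if (sizes[sizes > 0] < 2).all():
        raise ValueError("no permutable structure: all strata are singletons")
    ix = np.tile(np.arange(n), (n_perm, 1))
    for s in np.flatnonzero(sizes >= 2):
        pos = np.flatnonzero(codes == s)
        order = np.argsort(rng.random((n_perm, pos.size)), axis=1)
        ix[:, pos] = pos[order]
    return ix


def _perm_i_r2(Y: np.ndarray, x_tri: np.ndarray, z_tri: np.ndarray,
               perm_ix: np.ndarray) -> np.ndarray:
    """I(R^2) for each row-and-column permutation of Y (vectorized)."""
    n = Y.shape[0]
    iu0, iu1 = np.triu_indices(n, k=1)
    y_flat = Y.ravel()
    xc = x_tri - x_tri.mean()
    zc = z_tri - z_tri.mean()
    xn = np.linalg.norm(xc)
    zn = np.linalg.norm(zc)
    r_xz = float(xc @ zc / (xn * zn))

    out = np.empty(perm_ix.shape[0])
    for lo in range(0, perm_ix.shape[0], _PERM_CHUNK):
        ix = perm_ix[lo:lo + _PERM_CHUNK]
        tri = y_flat[ix[:, iu0] * n + ix[:, iu1]]
        tri_c = tri - tri.mean(axis=1, keepdims=True)
        tn = np.linalg.norm(tri_c, axis=1)
        r_xy = (tri_c @ xc) / (tn * xn)
        r_yz = (tri_c @ zc) / (tn * zn)
        denom = np.sqrt(np.clip((1 - r_xz ** 2) * (1 - r_yz ** 2), 1e-12, None))
        rp = (r_xy - r_xz * r_yz) / denom
        out[lo:lo + ix.shape[0]] = (1 - r_yz ** 2) * rp ** 2
    return out


def stratified_perm_p(
    Y: DistanceMatrix,
    X: DistanceMatrix,
    Z: DistanceMatrix,
    strata: pd.Series,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator = 0,
) -> tuple[float, np.ndarray, float]:
    """Stratified permutation p-value for I(R^2).

    Y's rows and columns are permuted simultaneously within continental
    strata; X and Z are never permuted. Ties count as exceedances, and
    p = (1 + #{permuted >= observed}) / (1 + n_perm).

    Returns (p, permuted statistics, observed statistic).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if not (Y.labels == X.labels == Z.labels):
        raise ValueError("distance matrices have different population labels")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codes = _strata_codes(strata, Y.labels)
    _, _, observed = partial_mantel(Y, X, Z)
    perm_ix = stratified_permutations(codes, n_perm, rng)
    perm_stats = _perm_i_r2(Y.values, _tri(X.values), _tri(Z.values), perm_ix)
    p = (1.0 + np.sum(perm_stats >= observed - 1e-15)) / (1.0 + n_perm)
    return float(p), perm_stats, float(observed)


# ---------------------------------------------------------------------------
# Generalized Pareto tail approximation

# Asymptotic upper-tail critical values of the Anderson-Darling statistic
# for a GPD with both parameters estimated, alpha = 0.05 (Choulakian &
# Stephens 2001; their shape convention k = -xi).
_AD_K = np.array([0.9, 0.5, 0.2, 0.1, 0.0, -0.1, -0.2, -0.3, -0.4, -0.5])
_AD_CRIT_05 = np.array([0.771, 0.830, 0.903, 0.935, 0.974,
                        1.020, 1.074, 1.140, 1.221, 1.321])


def _ad_statistic_gpd(exc: np.ndarray, c: float, scale: float) -> float:
    z = np.sort(stats.genpareto.cdf(exc, c, loc=0.0, scale=scale))
    z = np.clip(z, 1e-12, 1 - 1e-12)
    n = z.size
    i = np.arange(1, n + 1)
    return float(-n - np.mean((2 * i - 1) * (np.log(z) + np.log1p(-z[::-1]))))


def _ad_accepts(exc: np.ndarray, c: float, scale: float) -> bool:
    a2 = _ad_statistic_gpd(exc, c, scale)
    k = np.clip(-c, _AD_K.min(), _AD_K.max())
    crit = float(np.interp(k, _AD_K[::-1], _AD_CRIT_05[::-1]))
    return a2 < crit


def gpd_tail_p(perm_stats: np.ndarray, observed: float,
               n_exceed_init: int = DEFAULT_N_EXCEED) -> float:
    """Permutation p-value with generalized-Pareto tail approximation.

    If at least 10 permuted values reach the observed statistic (or the
    observed value sits below the permutation median) the empirical
    p-value is returned unchanged. Otherwise a GPD is fitted by maximum
    likelihood to the largest ``n_exc`` values in excess of a threshold t
    (the midpoint between the n_exc-th and (n_exc+1)-th largest), with
    n_exc halved while the Anderson-Darling test rejects the fit;
    p = (n_exc / n_perm) * (1 - GPD_cdf(observed - t)). Falls back to the
    empirical p-value if no acceptable fit is found.
    """
    perm = np.asarray(perm_stats, float)
    n = perm.size
    n_over = int(np.sum(perm >= observed))
    p_emp = (1.0 + n_over) / (1.0 + n)
    if n_over >= 10 or observed <= np.median(perm):
        return p_emp

    top = np.sort(perm)[::-1]
    n_exc = min(n_exceed_init, n // 4)
    while n_exc >= 10:
        t = 0.5 * (top[n_exc - 1] + top[n_exc])
        exc = top[:n_exc] - t
        if exc.min() <= 0:          # massive ties at the threshold
            n_exc //= 2
            continue
        try:
            c, _, scale = stats.genpareto.fit(exc, floc=0.0)
        except Exception:           # ML failure counts as a bad fit
            n_exc //= 2
            continue
        if not np.isfinite(c) or not np.isfinite(scale) or scale <= 0:
            n_exc //= 2
            continue
        if _ad_accepts(exc, c, scale):
            sf = stats.genpareto.sf(observed - t, c, loc=0.0, scale=scale)
            p = (n_exc / n) * float(sf)
            return max(p, np.finfo(float).tiny)
        n_exc //= 2
    logger.warning("no acceptable GPD fit; returning empirical p-value")
    return p_emp


# ---------------------------------------------------------------------------
# Multiple testing

def fdr_correct(p_values: np.ndarray, method: str = "dependence") -> np.ndarray:
    """Benjamini-Yekutieli step-up q-values (FDR under dependence)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if method != "dependence":
        raise ValueError("only the dependence-safe (Benjamini-Yekutieli) "
                         "correction is supported")
    _, q, _, _ = multipletests(p, method="fdr_by")
    return q


# ---------------------------------------------------------------------------
# Whole-panel scan

def _zero_variance(tri: np.ndarray) -> bool:
    return not np.isfinite(tri).all() or tri.std() == 0


def _pair_permutations(codes: np.ndarray, n: int, n_perm: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Pair-index permutations induced by within-strata population
    permutations: row r maps triangle slot k to the slot its pair occupies
    after permutation r. Permuting Y's rows and columns permutes its strict
    upper triangle, and the induced pair permutation does not depend on Y,
    so one matrix serves every gene."""
    iu0, iu1 = np.triu_indices(n, k=1)
    pair_id = np.zeros((n, n), dtype=np.int64)
    pair_id[iu0, iu1] = np.arange(iu0.size)
    pair_id[iu1, iu0] = pair_id[iu0, iu1]
    perm_ix = stratified_permutations(codes, n_perm, rng)
    return pair_id[perm_ix[:, iu0], perm_ix[:, iu1]]


def _scatter_permuted(v: np.ndarray, pair_perm: np.ndarray) -> np.ndarray:
    """Vectors w_r with w_r[pair_perm[r, k]] = v[k] (one row per permutation),
    so that tri(Y_perm) . v = tri(Y) . w_r for every Y."""
    out = np.empty(pair_perm.shape, dtype=float)
    out[np.arange(pair_perm.shape[0])[:, None], pair_perm] = v[None, :]
    return out


def _gene_tri_matrix(ft: FrequencyTable, pops: list[str]
                     ) -> tuple[list[str], np.ndarray]:
    """Upper-triangle Reynolds distance vectors for every gene (G x m)."""
    from .distances import _pairwise_reynolds
    genes = ft.genes()
    gene_col = ft.annotations["gene_id"].to_numpy()
    P_all = ft.freqs[pops].to_numpy(float)
    n = len(pops)
    iu = np.triu_indices(n, k=1)
    out = np.empty((len(genes), iu[0].size))
    for g_i, g in enumerate(genes):
        P = P_all[gene_col == g].T
        out[g_i] = _pairwise_reynolds(P)[iu]
    return genes, out


def gene_scan(
    ft: FrequencyTable,
    env: EnvironmentTable,
    strata: pd.Series,
    mode: str = "category",
    categories: tuple[str, ...] = MANTEL_CATEGORIES,
    drop_group: str | None = None,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    z_mode: str = "pooled",
    use_gpd: bool = True,
) -> pd.DataFrame:
    """Partial Mantel scan of every gene against environmental categories.

    ``mode="category"`` tests each category's averaged distance matrix;
    ``mode="per-variable-max"`` tests every variable separately (FDR within
    each variable's scan) and reports, per gene and category, the variable
    with the largest I(R^2). ``drop_group`` removes one pathogen group
    before averaging (pathogen category only) for drop-one comparisons.

    Populations missing any variable used by a run are dropped for that
    run. Genes whose distance triangle has zero variance are skipped.
    """
    genes = ft.genes()
    if not genes:
        raise ValueError("frequency table contains no genes")
    runs: list[tuple[str, str, list[str]]] = []   # (category, variable, vars)
    for cat in categories:
        vs = env.variables_in(cat)
        if not vs:
            raise ValueError(f"no variables for category {cat!r}")
        if mode == "category":
            runs.append((cat, "", vs))
        elif mode == "per-variable-max":
            runs.extend((cat, v, [v]) for v in vs)
        else:
            raise ValueError(f"unknown mode {mode!r}")

    z_cache: dict[tuple[str, ...], DistanceMatrix] = {}
    tri_cache: dict[tuple[str, ...], tuple[list[str], np.ndarray]] = {}
    frames = []
    for run_idx, (cat, variable, vs) in enumerate(runs):
        dg = drop_group if cat == "pathogen" else None
        pops = [p for p in ft.populations
                if p in set(env.complete_populations(vs))]
        X = env_distance_matrix(env, variables=vs, drop_group=dg,
                                populations=pops)
        key = tuple(pops)
        if key not in z_cache:
            z_cache[key] = overall_distance_matrix(ft, pops, mode=z_mode)
            tri_cache[key] = _gene_tri_matrix(ft, pops)
        Z = z_cache[key]
        run_genes, ytri = tri_cache[key]
        codes = _strata_codes(strata, pops)
        x_tri, z_tri = _tri(X.values), _tri(Z.values)

        # one set of within-strata permutations per run, shared by all genes
        rng = np.random.default_rng(np.random.SeedSequence((seed, run_idx)))
        pair_perm = _pair_permutations(codes, len(pops), n_perm, rng)
        xc = x_tri - x_tri.mean()
        zc = z_tri - z_tri.mean()
        xn, zn = np.linalg.norm(xc), np.linalg.norm(zc)
        r_xz = float(xc @ zc / (xn * zn))
        Xp = _scatter_permuted(xc, pair_perm)
        Zp = _scatter_permuted(zc, pair_perm)

        good = np.array([not _zero_variance(t) for t in ytri])
        for gene, ok in zip(run_genes, good):
            if not ok:
                logger.warning("gene %s: zero-variance distances; skipped", gene)
        yc = ytri[good] - ytri[good].mean(axis=1, keepdims=True)
        yn = np.linalg.norm(yc, axis=1)
        r_xy = (yc @ xc) / (yn * xn)
        r_yz = (yc @ zc) / (yn * zn)
        denom = np.sqrt(np.clip((1 - r_xz ** 2) * (1 - r_yz ** 2), 1e-12, None))
        rp = (r_xy - r_xz * r_yz) / denom
        r2_yz = r_yz ** 2
        i_r2 = (1 - r2_yz) * rp ** 2
        # permuted statistics: (genes x permutations)
        RXY = (yc @ Xp.T) / (yn[:, None] * xn)
        RYZ = (yc @ Zp.T) / (yn[:, None] * zn)
        pden = np.sqrt(np.clip((1 - r_xz ** 2) * (1 - RYZ ** 2), 1e-12, None))
        RPP = (RXY - r_xz * RYZ) / pden
        ISTAT = (1 - RYZ ** 2) * RPP ** 2
        exceed = (ISTAT >= i_r2[:, None] - 1e-15).sum(axis=1)
        p_perm = (1.0 + exceed) / (1.0 + n_perm)

        rows = []
        kept = [g for g, ok in zip(run_genes, good) if ok]
        for j, gene in enumerate(kept):
            p_g = gpd_tail_p(ISTAT[j], i_r2[j]) if use_gpd else p_perm[j]
            rows.append((gene, cat, variable, dg, r_xy[j], r_xz, r_yz[j],
                         rp[j], r2_yz[j] + i_r2[j], i_r2[j], p_perm[j], p_g,
                         n_perm))
        run_df = pd.DataFrame(rows, columns=[
            "gene_id", "category", "variable", "drop_group", "r_xy", "r_xz",
            "r_yz", "r_partial", "r2", "i_r2", "p_perm", "p_gpd", "n_perm"])
        run_df["q_fdr"] = fdr_correct(run_df["p_gpd"].to_numpy())
        frames.append(run_df)

    out = pd.concat(frames, ignore_index=True)
    if mode == "per-variable-max":
        best = (out.sort_values("i_r2", ascending=False)
                   .groupby(["gene_id", "category"], as_index=False).first())
        out = best.sort_values(["category", "gene_id"]).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Comparisons

def qq_compare(results_full: pd.DataFrame, results_dropped: pd.DataFrame,
               value_col: str = "i_r2") -> dict:
    """Rank-paired quantiles of a statistic under two runs on the same genes.

    Returns the paired quantile table and the signed area between the QQ
    curve and the diagonal (trapezoidal rule over the full-model quantiles);
    negative area means the dropped run's distribution sits below the full
    model's.
    """
    a = set(results_full["gene_id"])
    b = set(results_dropped["gene_id"])
    if a != b or len(results_full) != len(results_dropped):
        raise ValueError("runs cover different gene sets")
    x = np.sort(results_full[value_col].to_numpy(float))
    y = np.sort(results_dropped[value_col].to_numpy(float))
    area = float(np.trapezoid(y - x, x))
    table = pd.DataFrame({"full": x, "dropped": y})
    return {"table": table, "signed_area": area}


def subset_compare(results: pd.DataFrame, gene_subsets: dict[str, set],
                   p_col: str = "p_gpd") -> dict:
    """Distribution of -log10 p within labeled gene subsets.

    Bins -log10(p) by the quartiles of the full scan and tabulates each
    subset's bin frequencies; also reports one-sided rank-sum p-values for
    every ordered subset pair (alternative: first subset has larger
    -log10 p, i.e. stronger signal). Empty subsets are skipped.
    """
    neglog = -np.log10(results[p_col].to_numpy(float))
    gene_ids = results["gene_id"].to_numpy()
    qs = np.quantile(neglog, [0.25, 0.5, 0.75])
    freqs = {}
    values = {}
    for name, genes in gene_subsets.items():
        mask = np.isin(gene_ids, list(genes))
        if not mask.any():
            logger.warning("subset %r matches no scanned genes; skipped", name)
            continue
        v = neglog[mask]
        values[name] = v
        binned = np.searchsorted(qs, v, side="right")
        freqs[name] = np.bincount(binned, minlength=4) / v.size
    freq_df = pd.DataFrame(freqs, index=["Q1", "Q2", "Q3", "Q4"]).T
    tests = []
    names = list(values)
    for i, na in enumerate(names):
        for nb in names:
            if na == nb:
                continue
            stat = stats.mannwhitneyu(values[na], values[nb],
                                      alternative="greater")
            tests.append((na, nb, float(stat.pvalue)))
    test_df = pd.DataFrame(tests, columns=["subset", "versus", "p_greater"])
    return {"frequencies": freq_df, "rank_sum": test_df, "quartiles": qs}
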