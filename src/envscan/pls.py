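"""Per-SNP UVE-PLS regression of allele frequencies on environment.

For each SNP the population vector of folded minor allele frequencies is
regressed on the environmental predictor matrix with partial least squares
(PLS, projection to latent structures), which tolerates the strong
collinearity among environmental variables. Model quality is the
leave-one-out cross-validated prediction accuracy

    Q^2 = 1 - PRESS / SS,

where PRESS = sum_i (y_i - yhat_{-i})^2 over leave-one-out refits and
SS = sum_i (y_i - ybar)^2. Q^2 is large when populations that differ in
environment also differ in allele frequency; it may be negative.

For the full (all-variable) model an Uninformative Variable Elimination
(UVE) step precedes the regression: standard-normal noise columns are
appended, PLS submodels are fitted over the leave-one-out folds, and a
variable is kept only if the reliability of its coefficient,
c_j = mean(b_j) / sd(b_j), exceeds in magnitude every noise column's
reliability.

The PLS core is a deterministic single-response NIPALS. Coefficients after
k components equal W_k (P_k' W_k)^{-1} q_k; since P'W is upper triangular
the whole component path comes from one factorization, and the leave-one-out
folds are fitted simultaneously (the fold axis is vectorized), so a scan
costs a handful of array operations per SNP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import EnvironmentTable, FrequencyTable

logger = logging.getLogger(__name__)

#: Predictor sets, by environment-variable category.
MODEL_SPECS = ("full", "pathogen", "subsistence", "climate", "climate-range")

DEFAULT_MAX_COMPONENTS = 3
DEFAULT_N_NOISE = 100
_TINY = 1e-30


@dataclass
class PLSResult:
    """Leave-one-out summary for one SNP under one model."""

    snp_id: str
    q2: float
    press: float
    ss: float
    n_components: int
    retained_variables: list[str]
    coefficients: dict[str, float] = field(default_factory=dict)


@dataclass
class PLSModel:
    """A fitted PLS model (predictors z-scored, response centered)."""

    variables: list[str]
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    coef: np.ndarray          # on the standardized-predictor scale
    weights: np.ndarray       # orthonormal weight vectors, one column per comp
    n_components: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, float) - self.x_mean) / self.x_scale
        return self.y_mean + Xs @ self.coef

    def residuals(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        return np.asarray(y, float) - self.predict(X)


def _standardize_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    scale = np.where(scale > 0, scale, 1.0)
    return (X - mean) / scale, mean, scale


def _nipals_path(X: np.ndarray, y: np.ndarray, kmax: int
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Coefficient path of single-response NIPALS on one design.

    Returns (B, W): B[:, a] are regression coefficients (for centered y and
    the given X scale) using a+1 components; W the orthonormal weights.
    Stops early when the residual covariance vanishes.
    """
    n, p = X.shape
    kmax = min(kmax, p, max(n - 1, 1))
    Xd = X.copy()
    yd = y.copy()
    y_norm = max(float(np.linalg.norm(y)), 1.0)
    Ws, Ps, Qs = [], [], []
    for _ in range(kmax):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw <= 1e-13 * y_norm:
            break
        w = w / nw
        t = Xd @ w
        tt = float(t @ t)
        if tt <= _TINY:
            break
        pl = Xd.T @ t / tt
        q = float(yd @ t) / tt
        Xd -= np.outer(t, pl)
        yd = yd - q * t
        Ws.append(w)
        Ps.append(pl)
        Qs.append(q)
    if not Ws:
        return np.zeros((p, 1)), np.zeros((p, 1))
    W = np.column_stack(Ws)
    P = np.column_stack(Ps)
    q_vec = np.asarray(Qs)
    # R = W (P'W)^{-1}; P'W is upper triangular, so the truncated-path
    # coefficients are cumulative sums of R columns scaled by q.
    R = np.linalg.solve((P.T @ W).T, W.T).T
    B = np.cumsum(R * q_vec[None, :], axis=1)
    return B, W


def _nipals_path_batch(X3: np.ndarray, Y2: np.ndarray, kmax: int) -> np.ndarray:
    """Coefficient paths for a batch of designs (fold axis first).

    X3 : (F, m, p) column-standardized designs; Y2 : (F, m) centered
    responses. Returns B of shape (F, p, kmax); folds whose residual
    covariance vanishes keep their last valid coefficients (extra path
    entries repeat them).
    """
    F, m, p = X3.shape
    kmax = min(kmax, p, max(m - 1, 1))
    Xd = X3.copy()
    Yd = Y2.copy()
    W = np.zeros((F, p, kmax))
    P = np.zeros((F, p, kmax))
    Q = np.zeros((F, kmax))
    dead = np.zeros(F, dtype=bool)
    y_norm = np.maximum(np.linalg.norm(Y2, axis=1), 1.0)
    for a in range(kmax):
        w = np.einsum("fmp,fm->fp", Xd, Yd)
        nw = np.linalg.norm(w, axis=1)
        dead |= nw <= 1e-13 * y_norm
        w = np.where(dead[:, None], 0.0, w / np.where(nw > 0, nw, 1.0)[:, None])
        t = np.einsum("fmp,fp->fm", Xd, w)
        tt = np.einsum("fm,fm->f", t, t)
        dead |= tt <= _TINY
        w[dead] = 0.0
        t[dead] = 0.0
        safe_tt = np.where(tt > _TINY, tt, 1.0)
        pl = np.einsum("fmp,fm->fp", Xd, t) / safe_tt[:, None]
        q = np.einsum("fm,fm->f", Yd, t) / safe_tt
        Xd -= t[:, :, None] * pl[:, None, :]
        Yd -= q[:, None] * t
        W[:, :, a] = w
        P[:, :, a] = pl
        Q[:, a] = q
    M = np.einsum("fpa,fpb->fab", P, W)
    # dead components contributed zero columns; unit diagonal keeps M regular
    # and their coefficient contribution exactly zero
    col_dead = np.linalg.norm(W, axis=1) == 0.0
    di = np.arange(kmax)
    M[:, di, di] = np.where(col_dead, 1.0, M[:, di, di])
    R = np.linalg.solve(M.transpose(0, 2, 1), W.transpose(0, 2, 1)
                        ).transpose(0, 2, 1)
    return np.cumsum(R * Q[:, None, :], axis=2)


class _LOODesign:
    """Pre-standardized leave-one-out folds of one predictor matrix.

    Fold i holds the design without row i, z-scored on the remaining rows,
    plus row i standardized with the training statistics. Column subsets of
    a standardized design are the standardized column subsets, so one
    precomputation serves every retained-variable set.
    """

    def __init__(self, X: np.ndarray):
        n, p = X.shape
        self.n, self.p = n, p
        self.fold_rows = np.stack([np.delete(np.arange(n), i) for i in range(n)])
        Xf = X[self.fold_rows]                          # (n, n-1, p)
        mean = Xf.mean(axis=1)
        scale = Xf.std(axis=1, ddof=1)
        scale = np.where(scale > 0, scale, 1.0)
        self.X3 = (Xf - mean[:, None, :]) / scale[:, None, :]
        self.x_test = (X - mean) / scale               # (n, p)

    def press_path(self, y: np.ndarray, kmax: int,
                   cols: np.ndarray | slice = np.s_[:]) -> np.ndarray:
        """PRESS for 1..kmax components (early-stopped folds reuse their
        last prediction)."""
        Y = y[self.fold_rows]
        ym = Y.mean(axis=1)
        B = _nipals_path_batch(self.X3[:, :, cols], Y - ym[:, None], kmax)
        preds = ym[:, None] + np.einsum("fp,fpk->fk", self.x_test[:, cols], B)
        return ((y[:, None] - preds) ** 2).sum(axis=0)

    def coef_folds(self, y: np.ndarray, k: int,
                   cols: np.ndarray | slice = np.s_[:]) -> np.ndarray:
        """Per-fold coefficients (standardized scale) with k components."""
        Y = y[self.fold_rows]
        B = _nipals_path_batch(self.X3[:, :, cols], Y - Y.mean(axis=1)[:, None], k)
        return B[:, :, -1]


def pls_fit(y: np.ndarray, M: pd.DataFrame | np.ndarray,
            n_components: int) -> PLSModel:
    """Fit a single-response PLS model.

    Predictor columns are z-scored, the response is centered. Zero-variance
    predictor columns are dropped with a warning; a zero-variance response
    is an error. With ``n_components`` equal to the column rank the fit
    reproduces ordinary least squares.
    """
    if isinstance(M, pd.DataFrame):
        variables = list(M.columns)
        X = M.to_numpy(float)
    else:
        X = np.asarray(M, float)
        variables = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(y, float)
    if y.std(ddof=1) == 0:
        raise ValueError("constant response")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [v for v, k in zip(variables, keep) if not k]
        logger.warning("dropping zero-variance predictors: %s", dropped)
        X = X[:, keep]
        variables = [v for v, k in zip(variables, keep) if k]
    Xs, x_mean, x_scale = _standardize_columns(X)
    y_mean = float(y.mean())
    B, W = _nipals_path(Xs, y - y_mean, n_components)
    k = B.shape[1]
    return PLSModel(variables, x_mean, x_scale, y_mean, B[:, k - 1], W, k)


def _as_matrix(M) -> tuple[np.ndarray, list[str]]:
    if isinstance(M, pd.DataFrame):
        return M.to_numpy(float), list(M.columns)
    X = np.asarray(M, float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def _pick_k(q2_path: np.ndarray) -> int:
    # first maximum -> ties broken toward fewer components
    return int(np.argmax(np.round(q2_path, 12)))


def q2_loo(
    y: np.ndarray,
    M: pd.DataFrame | np.ndarray,
    n_components: int | None = None,
    snp_id: str = "",
) -> PLSResult:
    """Leave-one-out Q^2 for one response vector.

    If ``n_components`` is None, the count maximizing Q^2 over
    1..min(3, rank) is chosen, with ties broken toward fewer components.
    """
    X, variables = _as_matrix(M)
    y = np.asarray(y, float)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 observations for leave-one-out")
    ss = float(((y - y.mean()) ** 2).sum())
    if ss == 0:
        raise ValueError("constant response")
    kmax = n_components or min(DEFAULT_MAX_COMPONENTS, X.shape[1], n - 2)
    kmax = max(kmax, 1)
    design = _LOODesign(X)
    press = design.press_path(y, kmax)
    q2 = 1.0 - press / ss
    best = kmax - 1 if n_components else _pick_k(q2)
    model = pls_fit(y, M, best + 1)
    coefs = dict(zip(model.variables, model.coef))
    return PLSResult(snp_id, float(q2[best]), float(press[best]), ss,
                     best + 1, variables, coefs)


def _uve_retained(design: _LOODesign, y: np.ndarray, n_real: int,
                  k: int) -> np.ndarray:
    """Indices of real variables whose coefficient reliability beats every
    noise column (design holds real columns then noise columns)."""
    coefs = design.coef_folds(y, k)
    mean = coefs.mean(axis=0)
    sd = np.maximum(coefs.std(axis=0, ddof=1), _TINY)
    c = np.abs(mean / sd)
    cutoff = c[n_real:].max()
    retained = np.flatnonzero(c[:n_real] > cutoff)
    if retained.size == 0:
        logger.info("UVE retained no variables; falling back to all")
        retained = np.arange(n_real)
    return retained


def uve_filter(
    y: np.ndarray,
    M: pd.DataFrame,
    n_components: int | None = None,
    n_noise: int = DEFAULT_N_NOISE,
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """Uninformative Variable Elimination.

    Appends ``n_noise`` standard-normal noise columns, fits a PLS submodel
    on every leave-one-out fold, and computes each column's reliability
    c_j = mean(b_j)/sd(b_j) over folds. Real variables are retained iff
    |c_j| exceeds the largest |c| among the noise columns. If nothing
    survives, all variables are retained (logged).
    """
    X, variables = _as_matrix(M)
    p = len(variables)
    if n_noise < p:
        raise ValueError(f"n_noise ({n_noise}) must be >= n_vars ({p})")
    y = np.asarray(y, float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noise = rng.standard_normal((y.size, n_noise))
    design = _LOODesign(np.hstack([X, noise]))
    k = n_components or min(DEFAULT_MAX_COMPONENTS, y.size - 2)
    idx = _uve_retained(design, y, p, k)
    return [variables[j] for j in idx]


def model_variables(env: EnvironmentTable, model_spec: str) -> list[str]:
    """Predictor set for a model spec."""
    if model_spec == "full":
        out: list[str] = []
        for c in ("climate", "subsistence", "pathogen"):
            out.extend(env.variables_in(c))
        return out
    if model_spec == "pathogen":
        return env.variables_in("pathogen")
    if model_spec == "subsistence":
        return env.variables_in("subsistence")
    if model_spec == "climate":
        return env.variables_in("climate")
    if model_spec == "climate-range":
        return env.variables_in("climate_range")
    raise ValueError(f"unknown model spec {model_spec!r}; choose from {MODEL_SPECS}")


def scan_all_snps(
    ft: FrequencyTable,
    env: EnvironmentTable,
    model_spec: str = "full",
    n_components: int | None = None,
    n_noise: int = DEFAULT_N_NOISE,
    seed: int = 0,
    apply_uve: bool | None = None,
) -> pd.DataFrame:
    """Q^2 scan over all SNPs under one predictor model.

    UVE is applied only for the full model unless ``apply_uve`` overrides;
    the scan draws one noise matrix (seeded) shared by all SNPs, so the
    elimination threshold is comparable across the genome. Populations
    missing any variable of the chosen model are dropped listwise. Returns
    a DataFrame indexed by snp_id with columns ``model_spec, q2, press, ss,
    n_components, retained_variables``.
    """
    variables = model_variables(env, model_spec)
    if not variables:
        raise ValueError(f"no variables available for model {model_spec!r}")
    extra = [p for p in ft.populations if p not in env.populations]
    if extra:
        raise ValueError(f"populations absent from environment table: {extra}")
    pops = [p for p in ft.populations
            if p in set(env.complete_populations(variables))]
    if len(pops) < len(ft.populations):
        logger.info("model %s: dropping %d populations with missing values",
                    model_spec, len(ft.populations) - len(pops))
    X = env.values.loc[pops, variables].to_numpy(float)
    F = ft.freqs[pops].to_numpy(float)
    n, p = X.shape
    use_uve = (model_spec == "full") if apply_uve is None else apply_uve

    design_real = _LOODesign(X)
    design_aug = None
    if use_uve:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal((n, n_noise))
        design_aug = _LOODesign(np.hstack([X, noise]))
    kmax_default = min(DEFAULT_MAX_COMPONENTS, n - 2)

    var_arr = np.asarray(variables)
    rows = []
    for i, snp in enumerate(ft.snp_ids):
        y = F[i]
        ss = float(((y - y.mean()) ** 2).sum())
        if ss == 0:
            rows.append((snp, model_spec, np.nan, np.nan, 0.0, 0, ""))
            continue
        if use_uve:
            cols = _uve_retained(design_aug, y, p, kmax_default)
        else:
            cols = np.arange(p)
        kmax = n_components or max(min(DEFAULT_MAX_COMPONENTS, cols.size, n - 2), 1)
        press = design_real.press_path(y, kmax, cols)
        q2 = 1.0 - press / ss
        best = kmax - 1 if n_components else _pick_k(q2)
        rows.append((snp, model_spec, float(q2[best]), float(press[best]), ss,
                     best + 1, ";".join(var_arr[cols])))
    out = pd.DataFrame(
        rows, columns=["snp_id", "model_spec", "q2", "press", "ss",
                       "n_components", "retained_variables"],
    ).set_index("snp_id")
    return out
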