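"""Source apportionment: correlations, KMO/Bartlett, PCA+varimax, and PMF.

The receptor model factorizes a layer's concentration matrix X (samples x
metals) as X ~ G F with G, F >= 0, minimizing the uncertainty-weighted
objective Q = sum((x_ij - (GF)_ij)^2 / u_ij^2). The solver uses weighted
multiplicative updates (monotone in Q) with multiple random restarts, and
resolves the scaling ambiguity by normalizing each factor's scores to mean 1
so profiles F stay in concentration units. Surface and deep layers are
factorized separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.multivariate.factor_rotation import rotate_factors

from .core_io import METALS, BackgroundValues, DetectionLimits

_EPS = 1e-12


# --------------------------------------------------------------------------
# correlation and sampling adequacy

@dataclass
class CorrelationResult:
    r: pd.DataFrame
    p: pd.DataFrame
    flags: list[str] = field(default_factory=list)


def pearson_matrix(matrix: np.ndarray, columns=METALS) -> CorrelationResult:
    """Pairwise Pearson correlations with p-values (t-test, n-2 df)."""
    x = np.asarray(matrix, dtype=float)
    n, p = x.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    flags = []
    sd = x.std(axis=0)
    for j in np.flatnonzero(sd == 0):
        flags.append(f"constant column {columns[j]}: correlation undefined")
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(x, rowvar=False)
    rc = np.clip(r, -0.9999999999, 0.9999999999)
    t = rc * np.sqrt((n - 2) / (1.0 - rc**2))
    pval = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(pval, 0.0)
    cols = list(columns)
    return CorrelationResult(r=pd.DataFrame(r, index=cols, columns=cols),
                             p=pd.DataFrame(pval, index=cols, columns=cols),
                             flags=flags)


def kmo(correlation: np.ndarray) -> float:
    """Kaiser-Meyer-Olkin sampling adequacy from a correlation matrix.

    KMO = sum r^2 / (sum r^2 + sum a^2) over off-diagonal entries, where a
    are partial correlations obtained from the inverse correlation matrix.
    """
    r = np.asarray(correlation, dtype=float)
    cond = np.linalg.cond(r)
    if cond > 1e12:
        raise ValueError(f"correlation matrix is singular (cond={cond:.3g}); "
                         "KMO undefined")
    inv = np.linalg.inv(r)
    d = np.sqrt(np.outer(np.diag(inv), np.diag(inv)))
    partial = -inv / d
    off = ~np.eye(r.shape[0], dtype=bool)
    r2 = (r[off] ** 2).sum()
    a2 = (partial[off] ** 2).sum()
    return float(r2 / (r2 + a2))


def bartlett(correlation: np.ndarray, n: int) -> tuple[float, float]:
    """Bartlett sphericity test: chi2 = -(n-1-(2p+5)/6) ln det R."""
    r = np.asarray(correlation, dtype=float)
    p = r.shape[0]
    if n <= p:
        raise ValueError("Bartlett test needs n > number of variables")
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise ValueError("correlation matrix must have positive determinant")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) / 2.0
    return float(chi2), float(stats.chi2.sf(chi2, df))


# --------------------------------------------------------------------------
# PCA with varimax rotation

@dataclass
class PcaResult:
    eigenvalues: np.ndarray
    n_retained: int
    loadings: pd.DataFrame            # varimax-rotated retained loadings
    unrotated_loadings: pd.DataFrame
    scores: np.ndarray                # rotated factor scores (regression)
    explained_variance: np.ndarray    # fraction per retained component
    kmo: float
    bartlett_stat: float
    bartlett_p: float


def pca_varimax(matrix: np.ndarray, columns=METALS) -> PcaResult:
    """Correlation-matrix PCA, eigenvalue>1 retention, Kaiser-normalized
    varimax rotation. KMO/Bartlett adequacy gates are reported, not enforced.
    """
    x = np.asarray(matrix, dtype=float)
    n, p = x.shape
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    r = np.corrcoef(x, rowvar=False)
    adequacy = kmo(r)
    chi2, pval = bartlett(r, n)

    eigval, eigvec = np.linalg.eigh(r)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    k = int((eigval > 1.0).sum())
    if k < 1:
        warnings.warn("no eigenvalue exceeds 1; retaining nothing", stacklevel=2)
    load = eigvec[:, :k] * np.sqrt(eigval[:k])

    if k >= 2:
        h = np.sqrt((load**2).sum(axis=1))      # Kaiser normalization
        rot_n, _ = rotate_factors(load / h[:, None], "varimax")
        rot = rot_n * h[:, None]
    else:
        rot = load.copy()
    # deterministic orientation: dominant sign positive, order by variance
    for j in range(rot.shape[1]):
        if rot[:, j].sum() < 0:
            rot[:, j] = -rot[:, j]
    var = (rot**2).sum(axis=0)
    order2 = np.argsort(var)[::-1]
    rot = rot[:, order2]

    scores = np.zeros((n, max(k, 0)))
    if k:
        scores = z @ np.linalg.solve(r, rot)    # regression-method scores
    comp_names = [f"PC{i+1}" for i in range(k)]
    cols = list(columns)
    return PcaResult(
        eigenvalues=eigval, n_retained=k,
        loadings=pd.DataFrame(rot, index=cols, columns=comp_names),
        unrotated_loadings=pd.DataFrame(load, index=cols, columns=comp_names),
        scores=scores,
        explained_variance=(rot**2).sum(axis=0) / p,
        kmo=adequacy, bartlett_stat=chi2, bartlett_p=pval)


# --------------------------------------------------------------------------
# uncertainty matrix and PMF

def build_uncertainty(conc: np.ndarray, mdl: DetectionLimits,
                      error_fraction: float = 0.1) -> np.ndarray:
    """EPA-convention measurement uncertainties, same shape as ``conc``.

    u = sqrt((delta*c)^2 + (MDL/3)^2) above the detection limit, else
    (5/6)*MDL.
    """
    if not 0 < error_fraction <= 1:
        raise ValueError("error_fraction must be in (0, 1]")
    c = np.asarray(conc, dtype=float)
    lim = mdl.vector()[None, :]
    above = np.sqrt((error_fraction * c) ** 2 + (lim / 3.0) ** 2)
    below = np.broadcast_to(5.0 / 6.0 * lim, c.shape)
    return np.where(c > lim, above, below)


def floor_at_mdl(conc: np.ndarray, mdl: DetectionLimits) -> np.ndarray:
    """Replace zero concentrations by MDL/2 (PMF needs positive weighting)."""
    c = np.asarray(conc, dtype=float).copy()
    half = mdl.vector()[None, :] / 2.0
    mask = c <= 0
    c[mask] = np.broadcast_to(half, c.shape)[mask]
    return c


@dataclass
class FactorModel:
    G: np.ndarray                 # (n, k) nonnegative scores, mean 1 per factor
    F: np.ndarray                 # (k, p) nonnegative profiles, mg/kg
    E: np.ndarray                 # residuals X - GF
    Q: float
    k: int
    uncertainty: np.ndarray
    q_history: np.ndarray         # best run's Q per iteration
    restarts: list[dict]          # per-restart {Q, converged, n_iter}
    converged: bool


def _pmf_once(x, w, k, rng, tol, max_iter, warm_iters=300):
    """One solver run: multiplicative-update warm start, then alternating
    weighted nonnegative least squares (each half-sweep is an exact
    minimizer, so Q is nonincreasing throughout)."""
    from scipy.optimize import nnls

    n, p = x.shape
    scale = np.sqrt(x.mean() / k)
    g = rng.uniform(0.1, 1.0, (n, k)) * scale
    f = rng.uniform(0.1, 1.0, (k, p)) * scale
    wx = w * x
    sw = np.sqrt(w)
    q_hist = []
    for _ in range(warm_iters):
        gf = g @ f
        g *= (wx @ f.T) / ((w * gf) @ f.T + _EPS)
        gf = g @ f
        f *= (g.T @ wx) / (g.T @ (w * gf) + _EPS)
        q_hist.append(float((w * (x - g @ f) ** 2).sum()))
    q_prev = q_hist[-1] if q_hist else np.inf
    q_floor = 1e-14 * float((w * x**2).sum())  # exact-fit floor
    converged = False
    for _ in range(max_iter):
        for i in range(n):
            g[i], _ = nnls((f * sw[i]).T, x[i] * sw[i])
        for j in range(p):
            f[:, j], _ = nnls(g * sw[:, j][:, None], x[:, j] * sw[:, j])
        q = float((w * (x - g @ f) ** 2).sum())
        q_hist.append(q)
        if q <= q_floor or q_prev - q <= tol * max(q_prev, 1e-30):
            converged = True
            break
        q_prev = q
    return g, f, np.array(q_hist), converged


def pmf_fit(conc: np.ndarray, u: np.ndarray, k: int = 2,
            n_restarts: int = 20, seed: int = 0,
            tol: float = 1e-12, max_iter: int = 500) -> FactorModel:
    """Best-of-restarts PMF solution minimizing the weighted objective Q.

    Ties across restarts break toward the lowest restart index. Scores are
    normalized to mean 1 per factor so F carries concentration units.
    """
    x = np.asarray(conc, dtype=float)
    u = np.asarray(u, dtype=float)
    if (x < 0).any():
        raise ValueError("concentration matrix must be nonnegative")
    if (u <= 0).any():
        raise ValueError("uncertainties must be strictly positive")
    if u.shape != x.shape:
        raise ValueError("uncertainty matrix must match the data shape")
    if not 1 <= k < min(x.shape):
        raise ValueError("factor count k must satisfy 1 <= k < min(n, p)")
    w = 1.0 / u**2
    best = None
    restarts = []
    ss = np.random.SeedSequence(seed).spawn(n_restarts)
    for i in range(n_restarts):
        g, f, q_hist, conv = _pmf_once(x, w, k, np.random.default_rng(ss[i]),
                                       tol, max_iter)
        q = q_hist[-1]
        restarts.append({"Q": float(q), "converged": bool(conv),
                         "n_iter": len(q_hist)})
        if best is None or q < best[0]:
            best = (q, g, f, q_hist, conv)
    q, g, f, q_hist, conv = best
    col_mean = g.mean(axis=0)
    col_mean[col_mean == 0] = 1.0
    g = g / col_mean[None, :]
    f = f * col_mean[:, None]
    if not any(r["converged"] for r in restarts):
        warnings.warn("no PMF restart converged within max_iter", stacklevel=2)
    e = x - g @ f
    return FactorModel(G=g, F=f, E=e, Q=float(((e / u) ** 2).sum()), k=k,
                       uncertainty=u, q_history=q_hist, restarts=restarts,
                       converged=any(r["converged"] for r in restarts))


# --------------------------------------------------------------------------
# contributions and labelling

@dataclass
class SourceContributions:
    """Per-metal percentage attributed to each factor (rows sum to 100)."""

    percent: pd.DataFrame            # index metals, columns factor labels
    labels: dict[int, str] | None = None
    label_scores: dict[str, float] | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def anthropogenic(self) -> pd.Series:
        return self.percent["anthropogenic"]


def contribution_percent(f: np.ndarray, columns=METALS,
                         factor_names=None) -> pd.DataFrame:
    """Row-normalize factor profiles into per-metal percentages."""
    f = np.asarray(f, dtype=float)
    if (f < 0).any():
        raise ValueError("profiles must be nonnegative")
    tot = f.sum(axis=0)
    if (tot <= 0).any():
        dead = [columns[j] for j in np.flatnonzero(tot <= 0)]
        raise ValueError(f"all-zero profile column(s) for {dead}; "
                         "contribution undefined")
    names = factor_names or [f"factor{i+1}" for i in range(f.shape[0])]
    return pd.DataFrame((f / tot[None, :] * 100.0).T,
                        index=list(columns), columns=names)


def assign_factor_labels(model: FactorModel,
                         background: BackgroundValues | None = None,
                         columns=METALS) -> SourceContributions:
    """Label the two factors natural vs anthropogenic.

    The natural source in this region is dominated by Pb and As (their means
    track the geochemical background), so the factor holding the larger share
    of Pb and As is labelled natural. Scores within 5% relative of each other
    are flagged as ambiguous.
    """
    if model.k != 2:
        raise ValueError("factor labelling requires exactly k=2 factors")
    pct = contribution_percent(model.F, columns=columns)
    marker = [list(columns).index("Pb"), list(columns).index("As")]
    scores = pct.iloc[marker].mean(axis=0)      # mean Pb/As share per factor
    natural_col = scores.idxmax()
    labels = {}
    for i, name in enumerate(pct.columns):
        labels[i] = "natural" if name == natural_col else "anthropogenic"
    renamed = pct.rename(columns={name: labels[i]
                                  for i, name in enumerate(pct.columns)})
    renamed = renamed[["natural", "anthropogenic"]]
    flags = []
    lo, hi = sorted(scores)
    if hi > 0 and (hi - lo) / hi < 0.05:
        flags.append("ambiguous factor labelling: Pb/As shares within 5%")
    return SourceContributions(percent=renamed, labels=labels,
                               label_scores={labels[i]: float(scores.iloc[i])
                                             for i in range(2)},
                               flags=flags)


def compare_layers(surface: SourceContributions,
                   deep: SourceContributions) -> pd.Series:
    """Deep-minus-surface anthropogenic percentage per metal."""
    s, d = surface.anthropogenic, deep.anthropogenic
    if set(s.index) != set(d.index):
        raise ValueError("mismatched metal sets between layers")
    return (d - s.reindex(d.index)).rename("anthropogenic_delta")
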