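"""Inter-kingdom co-abundance networks.

Pipeline order follows the narrative of the analysis it implements:
SparCC compositional correlations -> network deconvolution (removal of
transitively induced correlations) -> random-matrix-theory threshold on
|rho| -> Benjamini-Hochberg FDR filter -> graph construction -> centralities
-> keystone selection (intersection of the top-20 degree and top-20
betweenness lists) -> power-law degree-distribution fit.

SparCC (Friedman & Alm) estimates correlations of the unobserved basis
abundances from the log-ratio variation matrix T_ij = var(log x_i/x_j),
solving the linear system that the sparsity assumption (most correlations
are weak) makes identifiable, and iteratively excluding the strongest pairs
that violate it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "sparcc",
    "permutation_pvalues",
    "network_deconvolution",
    "rmt_threshold",
    "build_network",
    "centralities",
    "keystone_select",
    "PowerLawFit",
    "powerlaw_fit",
    "sample_powerlaw",
]


# ---------------------------------------------------------------------------
# SparCC


def _variation_matrix(logf: np.ndarray) -> np.ndarray:
    v = logf.var(axis=0, ddof=1)
    c = np.cov(logf, rowvar=False)
    return v[:, None] + v[None, :] - 2.0 * c


def _solve_basis(T: np.ndarray, include: np.ndarray) -> np.ndarray:
    n_i = include.sum(axis=1).astype(float)
    M = include.astype(float).copy()
    np.fill_diagonal(M, n_i)
    t = (T * include).sum(axis=1)
    omega = np.linalg.solve(M, t)
    return np.maximum(omega, 1e-12)


def sparcc(counts, n_inner_iter: int = 20, exclusion_threshold: float = 0.1,
           max_exclusion_rounds: int = 10, pseudocount: float = 1.0,
           seed: int | None = None) -> pd.DataFrame:
    """SparCC correlation matrix from a samples x taxa count table.

    By default fractions are the deterministic pseudocount point estimate;
    with a ``seed`` the estimate is averaged over ``n_inner_iter`` Dirichlet
    resamples of the fractions.  Each exclusion round removes the most
    correlated remaining pair above ``exclusion_threshold`` from the basis
    system and re-solves, enforcing the sparsity assumption.
    """
    df = counts if isinstance(counts, pd.DataFrame) else pd.DataFrame(np.asarray(counts))
    X = df.to_numpy(dtype=float)
    n, p = X.shape
    if p < 4:
        raise ValueError("SparCC needs at least 4 taxa (basis system degenerate)")
    if n < 10:
        raise ValueError("SparCC needs at least 10 samples")

    if seed is None:
        logf_list = [np.log((X + pseudocount) / (X + pseudocount).sum(axis=1, keepdims=True))]
    else:
        rng = np.random.default_rng(seed)
        logf_list = []
        for _ in range(n_inner_iter):
            frac = np.vstack([rng.dirichlet(row + pseudocount) for row in X])
            logf_list.append(np.log(frac))

    rhos = []
    for logf in logf_list:
        T = _variation_matrix(logf)
        include = ~np.eye(p, dtype=bool)
        rho = None
        for _round in range(max_exclusion_rounds + 1):
            omega = _solve_basis(T, include)
            denom = 2.0 * np.sqrt(np.outer(omega, omega))
            rho = np.clip((omega[:, None] + omega[None, :] - T) / denom, -1.0, 1.0)
            np.fill_diagonal(rho, 1.0)
            if _round == max_exclusion_rounds:
                break
            masked = np.where(include, np.abs(np.triu(rho, 1)), 0.0)
            i, j = np.unravel_index(np.argmax(masked), masked.shape)
            if masked[i, j] <= exclusion_threshold:
                break
            include[i, j] = include[j, i] = False
            if include.sum(axis=1).min() < 2:
                warnings.warn("SparCC exclusion left a taxon with < 2 partners; "
                              "returning last iterate")
                break
        rhos.append(rho)
    rho = np.mean(rhos, axis=0)
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=df.columns, columns=df.columns)


def permutation_pvalues(counts, observed: pd.DataFrame, n_perm: int = 100,
                        seed: int = 0, **sparcc_kwargs) -> pd.DataFrame:
    """Two-sided permutation p-values for SparCC correlations.

    Each taxon column is permuted independently across samples, SparCC is
    recomputed, and p = (1 + #{|rho_perm| >= |rho_obs|}) / (n_perm + 1).
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    df = counts if isinstance(counts, pd.DataFrame) else pd.DataFrame(np.asarray(counts))
    X = df.to_numpy(dtype=float)
    obs = np.abs(observed.to_numpy(dtype=float))
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(obs)
    for _ in range(n_perm):
        perm = np.column_stack([rng.permutation(X[:, j]) for j in range(X.shape[1])])
        r = sparcc(pd.DataFrame(perm, columns=df.columns), **sparcc_kwargs).to_numpy()
        exceed += (np.abs(r) >= obs)
    pvals = (1.0 + exceed) / (n_perm + 1.0)
    np.fill_diagonal(pvals, 1.0)
    return pd.DataFrame(pvals, index=observed.index, columns=observed.columns)


# ---------------------------------------------------------------------------
# network deconvolution


def network_deconvolution(G_obs, beta: float = 0.99,
                          zero_diagonal: bool = True) -> pd.DataFrame | np.ndarray:
    """Spectral removal of indirect (transitive) effects.

    The observed matrix is linearly scaled so its largest absolute eigenvalue
    is ``beta``, eigendecomposed G = U L U', each eigenvalue is mapped to its
    direct counterpart l_d = l / (1 + l) (the inverse of the geometric series
    that generates indirect paths), and the matrix is reassembled.
    """
    is_df = isinstance(G_obs, pd.DataFrame)
    G = G_obs.to_numpy(dtype=float) if is_df else np.asarray(G_obs, dtype=float)
    if not np.allclose(G, G.T, atol=1e-9):
        raise ValueError("input must be symmetric")
    lam, U = np.linalg.eigh(G)
    max_abs = np.abs(lam).max()
    if max_abs > 0:
        scale = beta / max_abs
        lam = lam * scale
    if np.any(np.abs(lam + 1.0) < 1e-12):
        raise ValueError("eigenvalue -1 after scaling: deconvolution transform singular")
    lam_d = lam / (1.0 + lam)
    D = (U * lam_d) @ U.T
    D = (D + D.T) / 2.0
    if zero_diagonal:
        np.fill_diagonal(D, 0.0)
    if is_df:
        return pd.DataFrame(D, index=G_obs.index, columns=G_obs.columns)
    return D


# ---------------------------------------------------------------------------
# RMT threshold


def _spacing_pvalue(eigvals: np.ndarray, n_bins: int = 20) -> float:
    """Chi-square goodness of fit of unfolded nearest-neighbour eigenvalue
    spacings against the Poisson (exponential) form."""
    ev = np.sort(eigvals)
    m = ev.size
    ranks = np.arange(1, m + 1, dtype=float)
    deg = min(5, m - 2)
    coeff = np.polyfit(ev, ranks, deg)
    unfolded = np.polyval(coeff, ev)
    s = np.diff(unfolded)
    s = s[s >= 0]
    if s.size < n_bins:
        return 1.0
    mean = s.mean()
    if mean <= 0:
        return 1.0
    s = s / mean
    edges = -np.log(1.0 - np.arange(n_bins) / n_bins)
    obs = np.histogram(s, bins=np.append(edges, np.inf))[0]
    exp = np.full(n_bins, s.size / n_bins)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, n_bins - 1))


def rmt_threshold(rho, grid=None, alpha: float = 0.05, n_bins: int = 20,
                  min_eigs: int = 25) -> float:
    """Correlation cutoff where the eigenvalue spacing distribution of the
    thresholded matrix becomes Poisson (random structure removed).

    For each candidate, entries below it are zeroed, taxa left without any
    connection are dropped, and the nearest-neighbour spacing distribution of
    the remaining eigenvalues is tested against the exponential form; a
    candidate with fewer than ``min_eigs`` testable eigenvalues is treated as
    passing (no random-matrix bulk left to test).  Returns the smallest
    threshold that passes and keeps passing for the rest of the grid, or the
    grid maximum with a warning.
    """
    R = rho.to_numpy(dtype=float) if isinstance(rho, pd.DataFrame) else np.asarray(rho, float)
    p = R.shape[0]
    if p < 20:
        raise ValueError("RMT thresholding needs at least 20 taxa")
    if grid is None:
        grid = np.round(np.arange(0.30, 0.95 + 1e-9, 0.01), 2)
    grid = np.asarray(grid, dtype=float)

    passes = []
    for thr in grid:
        A = np.where(np.abs(R) >= thr, R, 0.0)
        np.fill_diagonal(A, 1.0)
        connected = (np.abs(A) > 0).sum(axis=1) > 1  # more than the diagonal
        k = int(connected.sum())
        if k < min_eigs:
            passes.append(True)
            continue
        sub = A[np.ix_(connected, connected)]
        ev = np.linalg.eigvalsh(sub)
        passes.append(_spacing_pvalue(ev, n_bins) > alpha)

    for i, thr in enumerate(grid):
        if all(passes[i:]):
            return float(thr)
    warnings.warn("no threshold passed the Poisson spacing test; returning grid maximum")
    return float(grid[-1])


# ---------------------------------------------------------------------------
# graph construction, centralities, keystones


def build_network(rho, p, rho_min: float = 0.78, fdr_max: float = 0.001,
                  kingdom_map: dict[str, str] | None = None,
                  keep_isolates: bool = False) -> nx.Graph:
    """Keep edges with |rho| >= rho_min AND BH-FDR <= fdr_max.

    BH adjustment is computed jointly over all unique taxon pairs.  Nodes are
    restricted to those with at least one edge unless ``keep_isolates``.
    """
    from statsmodels.stats.multitest import multipletests

    rho_df = rho if isinstance(rho, pd.DataFrame) else pd.DataFrame(np.asarray(rho))
    p_df = p if isinstance(p, pd.DataFrame) else pd.DataFrame(np.asarray(p),
                                                              index=rho_df.index,
                                                              columns=rho_df.columns)
    taxa = list(rho_df.index)
    pairs = [(i, j) for i in range(len(taxa)) for j in range(i + 1, len(taxa))]
    pvec = np.array([p_df.iat[i, j] for i, j in pairs])
    fdr = multipletests(pvec, method="fdr_bh")[1]

    G = nx.Graph()
    if keep_isolates:
        for t in taxa:
            G.add_node(t, kingdom=(kingdom_map or {}).get(t, "unknown"))
    for (idx, (i, j)) in enumerate(pairs):
        r = float(rho_df.iat[i, j])
        if abs(r) >= rho_min and fdr[idx] <= fdr_max:
            for t in (taxa[i], taxa[j]):
                if t not in G:
                    G.add_node(t, kingdom=(kingdom_map or {}).get(t, "unknown"))
            G.add_edge(taxa[i], taxa[j], rho=r, p=float(pvec[idx]),
                       fdr=float(fdr[idx]), sign="+" if r > 0 else "-")
    return G


def centralities(net: nx.Graph) -> pd.DataFrame:
    """Degree, raw (unnormalized) shortest-path betweenness, and closeness
    (n-1)/sum(distances) within each node's component (0 for singletons)."""
    if net.number_of_nodes() == 0:
        raise ValueError("network is empty")
    deg = dict(net.degree())
    btw = nx.betweenness_centrality(net, normalized=False)
    cls = nx.closeness_centrality(net, wf_improved=False)
    rows = [{"node": n, "degree": deg[n], "betweenness": btw[n],
             "closeness": cls[n]} for n in net.nodes]
    return pd.DataFrame(rows).set_index("node")


def keystone_select(table: pd.DataFrame, k: int = 20) -> list[str]:
    """Nodes in both the top-k by degree and the top-k by betweenness; ties
    at rank k are all included.  Ordered by (betweenness, degree, label)."""
    if table.empty:
        raise ValueError("centrality table is empty")

    def top_set(col: str) -> set[str]:
        vals = table[col].sort_values(ascending=False)
        if len(vals) <= k:
            return set(vals.index)
        cutoff = vals.iloc[k - 1]
        return set(vals[vals >= cutoff].index)

    chosen = top_set("degree") & top_set("betweenness")
    return sorted(chosen, key=lambda n: (-table.at[n, "betweenness"],
                                         -table.at[n, "degree"], n))


# ---------------------------------------------------------------------------
# power-law degree distribution


@dataclass
class PowerLawFit:
    alpha: float
    xmin: int
    ks_stat: float
    degenerate: bool = False


def _zeta(alpha: float, xmin: int) -> float:
    return float(special.zeta(alpha, xmin))


def powerlaw_fit(degrees, xmin: int = 1) -> PowerLawFit:
    """Discrete maximum-likelihood power-law fit P(k) ~ k^-alpha for k >= xmin,
    with a KS goodness-of-fit statistic against the fitted law."""
    x = np.asarray([d for d in degrees if d >= xmin], dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 degrees >= xmin")
    degenerate = bool(np.all(x == x[0]))
    mean_log = np.log(x).mean()

    def nll(a: float) -> float:
        return np.log(_zeta(a, xmin)) + a * mean_log

    res = optimize.minimize_scalar(nll, bounds=(1.01, 20.0), method="bounded")
    alpha = float(res.x)

    kmax = int(x.max())
    ks_grid = np.arange(xmin, kmax + 1)
    pmf = ks_grid ** (-alpha) / _zeta(alpha, xmin)
    cdf = np.cumsum(pmf)
    ecdf = np.searchsorted(np.sort(x), ks_grid, side="right") / x.size
    ks = float(np.abs(ecdf - cdf).max())
    return PowerLawFit(alpha=alpha, xmin=xmin, ks_stat=ks, degenerate=degenerate)


def sample_powerlaw(n: int, alpha: float, xmin: int = 1, seed: int = 0,
                    kmax: int = 10_000_000) -> np.ndarray:
    """Draw n integers from the discrete power law P(k) ~ k^-alpha, k >= xmin
    (inverse transform on the truncated pmf; the tail beyond kmax is
    negligible for alpha > 2)."""
    rng = np.random.default_rng(seed)
    ks = np.arange(xmin, kmax + 1, dtype=float)
    pmf = ks ** (-alpha)
    cdf = np.cumsum(pmf)
    cdf /= cdf[-1]
    u = rng.random(n)
    return (np.searchsorted(cdf, u) + xmin).astype(int)
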