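"""Functional connectivity, model fitting, and network characterization.

FC is the pairwise Pearson correlation of ROI time series, optionally
Fisher-z transformed; scan- and subject-level averaging happens in z-space.
Simulated-to-empirical fit is the cosine similarity (uncentered correlation)
between the strict upper triangles of the two FC matrices, maximized over a
(G, sigma) grid; its significance is assessed against surrogate FC networks
generated by sign-aware, degree-preserving rewiring with approximately
preserved strength sequences.  Additional characterizations: PCA of the
simulated time series (dominant covariance networks), nodal-strength
comparison between density-matched simulated and empirical networks, and the
distance dependence of weight agreement via equal-count tract-length bins.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import stats

from macsim.connectome_build import DirectedConnectome, _upper_edges
from macsim.io_formats import logger
from macsim.simulate import DMFParams, simulate_bold, tune_fic

G_RANGE_DEFAULT = (0.1, 5.0, 100)       # min, max, steps of the coupling sweep
SIGMA_RANGE_DEFAULT = (0.01, 0.1, 30)   # min, max, steps of the noise sweep


@dataclasses.dataclass
class FCMatrix:
    """Symmetric FC matrix tagged with its space ('pearson_r' or 'fisher_z')."""

    values: np.ndarray
    space: str = "pearson_r"
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("FC matrix must be symmetric")
        if self.space not in ("pearson_r", "fisher_z"):
            raise ValueError(f"unknown FC space {self.space!r}")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclasses.dataclass
class FitResult:
    """(G, sigma) fit surface and, when computed, the null-fit significance."""

    G_values: np.ndarray
    sigma_values: np.ndarray
    similarity: np.ndarray          # (len(G), len(sigma)); NaN where rejected
    best_G: float
    best_sigma: float
    best_similarity: float
    best_fc: FCMatrix
    n_rejected: int
    null_similarities: np.ndarray | None = None
    p_value: float | None = None


def fisher_z(r: np.ndarray) -> np.ndarray:
    """arctanh with |r| clipped away from 1 for numerical safety."""
    return np.arctanh(np.clip(r, -1 + 1e-7, 1 - 1e-7))


def compute_fc(timeseries: np.ndarray, fisher_z_transform: bool = False,
               provenance: dict | None = None) -> FCMatrix:
    """Pairwise Pearson FC of a region x time array."""
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2 or ts.shape[1] < 2:
        raise ValueError("need a region x time array with >= 2 time points")
    constant = (np.ptp(ts, axis=1) == 0) | (ts.std(axis=1) == 0)
    if np.any(constant):
        bad = np.where(constant)[0]
        raise ValueError(f"constant time series for regions {bad.tolist()}")
    r = np.corrcoef(ts)
    if fisher_z_transform:
        return FCMatrix(fisher_z(r), "fisher_z", provenance or {})
    return FCMatrix(r, "pearson_r", provenance or {})


def average_fc(matrices: list[FCMatrix]) -> FCMatrix:
    """Elementwise mean of Fisher-z FC matrices (one averaging level)."""
    if not matrices:
        raise ValueError("nothing to average")
    spaces = {m.space for m in matrices}
    if spaces != {"fisher_z"}:
        raise ValueError(f"average_fc requires fisher_z matrices, got {sorted(spaces)}")
    if len({m.n for m in matrices}) != 1:
        raise ValueError("matrices differ in size")
    return FCMatrix(np.mean([m.values for m in matrices], axis=0), "fisher_z")


def grand_average_fc(scans_by_subject: list[list[FCMatrix]]) -> FCMatrix:
    """Two-level average: scans -> subject means -> grand mean (all in z)."""
    return average_fc([average_fc(scans) for scans in scans_by_subject])


def cosine_similarity(a, b) -> float:
    """Uncentered correlation between strict upper triangles."""
    va = a.values if isinstance(a, FCMatrix) else np.asarray(a, dtype=float)
    vb = b.values if isinstance(b, FCMatrix) else np.asarray(b, dtype=float)
    if va.shape != vb.shape:
        raise ValueError("FC matrices differ in shape")
    _, _, ua = _upper_edges(va)
    _, _, ub = _upper_edges(vb)
    na, nb = np.linalg.norm(ua), np.linalg.norm(ub)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm upper triangle")
    return float(ua @ ub / (na * nb))


# --------------------------------------------------------------------------
# Grid search
# --------------------------------------------------------------------------

def parameter_grid(G_range=G_RANGE_DEFAULT,
                   sigma_range=SIGMA_RANGE_DEFAULT) -> tuple[np.ndarray, np.ndarray]:
    """The (G, sigma) search lattice: 100 x 30 equally-sized steps by default."""
    g0, g1, ng = G_RANGE_DEFAULT if G_range is None else G_range
    s0, s1, ns = SIGMA_RANGE_DEFAULT if sigma_range is None else sigma_range
    return np.linspace(g0, g1, int(ng)), np.linspace(s0, s1, int(ns))


def grid_search_fit(conn: DirectedConnectome, empirical: FCMatrix,
                    G_values: np.ndarray | None = None,
                    sigma_values: np.ndarray | None = None,
                    seed: int = 0, duration: float = 600.0,
                    **sim_kwargs) -> FitResult:
    """Fit simulated to empirical FC over the (G, sigma) lattice.

    For each grid point: tune FIC, simulate, generate BOLD, compute Fisher-z
    FC, and score the cosine similarity with the empirical FC (itself
    harmonized to z-space).  Rejected simulations (mean rate >= 10 Hz after
    tuning) are excluded from the surface.  Deterministic per seed: each grid
    point uses an independent seed derived from (seed, i, j), so the argmax is
    independent of evaluation order and never aliases another run's noise
    stream.
    """
    if G_values is None or sigma_values is None:
        gv, sv = parameter_grid()
        G_values = gv if G_values is None else np.asarray(G_values, dtype=float)
        sigma_values = sv if sigma_values is None else np.asarray(sigma_values, dtype=float)
    else:
        G_values = np.asarray(G_values, dtype=float)
        sigma_values = np.asarray(sigma_values, dtype=float)
    emp = empirical.values if empirical.space == "fisher_z" else fisher_z(empirical.values)

    sim = np.full((len(G_values), len(sigma_values)), np.nan)
    best = (-np.inf, None, None, None)
    n_rejected = 0
    for i, g in enumerate(G_values):
        for j, s in enumerate(sigma_values):
            point_seed = int(np.random.SeedSequence((seed, i, j)
                                                    ).generate_state(1)[0] % 2**31)
            params = DMFParams(G=float(g), sigma=float(s), duration=duration,
                               rng_seed=point_seed, **sim_kwargs)
            fic = tune_fic(conn, params)
            if fic.rejected:
                n_rejected += 1
                continue
            params.Ji = fic.Ji
            bold, _ = simulate_bold(conn, params)
            fc = compute_fc(bold.values, fisher_z_transform=True)
            sim[i, j] = cosine_similarity(fc.values, emp)
            if sim[i, j] > best[0]:
                best = (sim[i, j], float(g), float(s), fc)
    if best[1] is None:
        raise RuntimeError("all grid points were rejected")
    logger.info("grid search best: G=%.4g sigma=%.4g cs=%.4f (%d rejected)",
                best[1], best[2], best[0], n_rejected)
    return FitResult(G_values, sigma_values, sim, best[1], best[2], best[0],
                     best[3], n_rejected)


# --------------------------------------------------------------------------
# Null networks and significance
# --------------------------------------------------------------------------

def _rewire_skeleton(edges: np.ndarray, occupied: set, rng: np.random.Generator,
                     swaps_per_edge: int = 5) -> np.ndarray:
    """Degree-preserving double-edge swaps on an undirected edge list.

    ``occupied`` holds every pair carrying any edge (either sign class) and is
    updated in place, so swapped edges never collide with the other class.
    """
    edges = edges.copy()
    ne = len(edges)
    if ne < 2:
        return edges
    attempts = swaps_per_edge * ne
    for _ in range(attempts):
        a, b = rng.integers(0, ne, size=2)
        if a == b:
            continue
        i, j = edges[a]
        u, v = edges[b]
        if rng.integers(0, 2):
            u, v = v, u
        # proposed: (i, v), (u, j)
        if len({i, j, u, v}) < 4:
            continue
        e1 = (min(i, v), max(i, v))
        e2 = (min(u, j), max(u, j))
        if e1 in occupied or e2 in occupied:
            continue
        occupied.discard((min(i, j), max(i, j)))
        occupied.discard((min(u, v), max(u, v)))
        occupied.add(e1)
        occupied.add(e2)
        edges[a] = (i, v)
        edges[b] = (u, j)
    return edges


def _assign_weights(edges: np.ndarray, weights: np.ndarray, strengths: np.ndarray,
                    rng: np.random.Generator, wei_freq: float = 0.1) -> np.ndarray:
    """Rank-matched weight reassignment approximating the strength sequence.

    Iteratively assigns the largest remaining weights to the unassigned edges
    with the largest residual expected strength product s_i * s_j, in chunks
    of ``wei_freq`` of the remaining edges, decrementing residual strengths
    after every chunk.
    """
    order = np.argsort(weights)[::-1]
    w_sorted = weights[order]
    res = strengths.astype(float).copy()
    remaining = list(range(len(edges)))
    assigned = np.zeros(len(edges))
    w_pos = 0
    while remaining:
        k = max(1, int(round(wei_freq * len(remaining))))
        scores = np.array([res[edges[e, 0]] * res[edges[e, 1]] for e in remaining])
        top = np.argsort(scores)[::-1][:k]
        chunk = [remaining[t] for t in top]
        for e in chunk:
            w = w_sorted[w_pos]
            w_pos += 1
            assigned[e] = w
            res[edges[e, 0]] = max(res[edges[e, 0]] - w, 0.0)
            res[edges[e, 1]] = max(res[edges[e, 1]] - w, 0.0)
        remaining = [e for e in remaining if e not in set(chunk)]
    return assigned


def null_model_und_sign(w: np.ndarray, seed: int = 0, swaps_per_edge: int = 5,
                        wei_freq: float = 0.02) -> np.ndarray:
    """Sign-aware degree-preserving null of an undirected weighted network.

    Positive and negative edge sets are rewired separately with
    double-edge swaps (degree within each sign class is preserved exactly),
    then the original weight multisets are re-assigned rank-matched to the
    residual-strength products, approximating each node's strength sequence.
    """
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    rng = np.random.default_rng(seed)
    out = np.zeros_like(w)
    iu, ju, vals = _upper_edges(w)
    occupied = {(int(i), int(j)) for i, j, v in zip(iu, ju, vals) if v != 0}
    for sign in (1.0, -1.0):
        mask = (vals * sign) > 0
        if not np.any(mask):
            continue
        edges = np.column_stack([iu[mask], ju[mask]])
        mags = np.abs(vals[mask])
        strengths = np.zeros(n)
        np.add.at(strengths, edges[:, 0], mags)
        np.add.at(strengths, edges[:, 1], mags)
        new_edges = _rewire_skeleton(edges, occupied, rng, swaps_per_edge)
        new_w = _assign_weights(new_edges, mags, strengths, rng, wei_freq)
        out[new_edges[:, 0], new_edges[:, 1]] = sign * new_w
        out[new_edges[:, 1], new_edges[:, 0]] = sign * new_w
    return out


def signed_degrees(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(positive, negative) undirected degree per node."""
    w = np.asarray(w)
    pos = ((w > 0).sum(axis=1))
    neg = ((w < 0).sum(axis=1))
    return pos, neg


def null_fit_pvalue(empirical: FCMatrix, best_sim_fc: FCMatrix,
                    n_nulls: int = 1000, seed: int = 0,
                    wei_freq: float = 0.02) -> tuple[float, np.ndarray]:
    """Significance of the best fit against rewired empirical networks.

    p = proportion of null cosine similarities >= the observed one (so all
    ties give p = 1).  Also returns the null distribution.
    """
    emp = empirical.values.copy()
    np.fill_diagonal(emp, 0.0)
    n = emp.shape[0]
    if n < 4 or np.count_nonzero(emp) == 0:
        raise ValueError("network too small or empty to rewire")
    sim = best_sim_fc.values
    observed = cosine_similarity(emp, sim)
    nulls = np.empty(n_nulls)
    for k in range(n_nulls):
        null = null_model_und_sign(emp, seed=seed + k, wei_freq=wei_freq)
        nulls[k] = cosine_similarity(null, sim)
    p = float(np.mean(nulls >= observed))
    return p, nulls


# --------------------------------------------------------------------------
# Network characterization
# --------------------------------------------------------------------------

def pca_networks(timeseries: np.ndarray, n_components: int = 3,
                 top_k: int = 10) -> dict:
    """Dominant covariance networks of a region x time array.

    Eigendecomposition of the region-space covariance of the demeaned series.
    Returns loadings (region x component), the variance fraction of each of
    the first ``n_components`` (fractions over *all* components sum to 1),
    and the ``top_k`` highest-|loading| nodes per component.
    """
    ts = np.asarray(timeseries, dtype=float)
    n = ts.shape[0]
    if n < n_components:
        raise ValueError("fewer regions than components")
    x = ts - ts.mean(axis=1, keepdims=True)
    cov = x @ x.T / (ts.shape[1] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    total = evals.sum()
    fractions = evals / total
    top = [np.argsort(np.abs(evecs[:, c]))[::-1][:top_k] for c in range(n_components)]
    return {
        "loadings": evecs[:, :n_components],
        "variance_fractions": fractions[:n_components],
        "all_fractions": fractions,
        "top_nodes": top,
    }


def threshold_absolute(w: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    """Keep entries strictly above ``threshold``; zero the rest and diagonal."""
    w = np.asarray(w, dtype=float).copy()
    w[w <= threshold] = 0.0
    np.fill_diagonal(w, 0.0)
    return w


def threshold_proportional_to_count(w: np.ndarray, n_edges: int) -> np.ndarray:
    """Keep the ``n_edges`` strongest undirected edges (stable tie-break)."""
    w = np.asarray(w, dtype=float)
    iu, ju, vals = _upper_edges(w)
    order = np.argsort(vals, kind="stable")[::-1][:n_edges]
    out = np.zeros_like(w)
    out[iu[order], ju[order]] = vals[order]
    return out + out.T


def strength_comparison(sim_fc: FCMatrix, emp_fc: FCMatrix,
                        n_perm: int = 1000, seed: int = 0) -> dict:
    """Nodal strengths of density-matched simulated vs empirical FC networks.

    The empirical network is thresholded to its positive weights; the
    simulated one is proportionally thresholded to the same undirected edge
    count.  Strengths are row sums; agreement is Pearson r with a one-sided
    permutation p-value.
    """
    if sim_fc.n != emp_fc.n:
        raise ValueError("networks differ in size")
    emp = threshold_absolute(emp_fc.values, 0.0)
    _, _, emp_vals = _upper_edges(emp)
    n_edges = int(np.count_nonzero(emp_vals))
    if n_edges == 0:
        raise ValueError("empirical network empty after thresholding")
    simv = sim_fc.values.copy()
    np.fill_diagonal(simv, 0.0)
    sim = threshold_proportional_to_count(simv, n_edges)
    s_sim = sim.sum(axis=1)
    s_emp = emp.sum(axis=1)
    r, p = permutation_corr(s_emp, s_sim, n_perm=n_perm, seed=seed)
    return {"strength_sim": s_sim, "strength_emp": s_emp, "r": r, "p": p,
            "density_edges": n_edges}


def binned_weight_distance(tracer_w: np.ndarray, tract_w: np.ndarray,
                           lengths: np.ndarray, n_bins: int = 8,
                           n_boot: int = 1000, seed: int = 0) -> dict:
    """Distance dependence of tracer-vs-tractography weight agreement.

    Edges are split into ``n_bins`` equal-count tract-length bins (sizes
    differing by at most one); within each bin the Pearson r between log
    weights is computed.  The trend is the Pearson r between bin median
    lengths and bin correlations, with a bootstrap CI over edges.
    """
    tracer_w = np.asarray(tracer_w, dtype=float)
    tract_w = np.asarray(tract_w, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    n_edges = len(lengths)
    if n_edges < 3 * n_bins:
        raise ValueError(f"need at least {3 * n_bins} edges")
    if np.any(tracer_w <= 0) or np.any(tract_w <= 0):
        raise ValueError("weights must be positive (log scale)")

    def trend(idx: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        order = idx[np.argsort(lengths[idx], kind="stable")]
        bins = np.array_split(order, n_bins)
        rs = np.array([stats.pearsonr(np.log(tracer_w[b]), np.log(tract_w[b]))[0]
                       for b in bins])
        med = np.array([np.median(lengths[b]) for b in bins])
        if np.ptp(rs) < 1e-10:   # uniform agreement across bins: no trend
            return 0.0, rs, med
        return float(stats.pearsonr(med, rs)[0]), rs, med

    idx = np.arange(n_edges)
    trend_r, bin_r, bin_len = trend(idx)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    with warnings.catch_warnings():
        # bootstrap resamples can produce constant bins; their r is NaN
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        for k in range(n_boot):
            boot[k] = trend(rng.choice(idx, size=n_edges, replace=True))[0]
    ci = np.nanpercentile(boot, [2.5, 97.5])
    return {"bin_r": bin_r, "bin_median_length": bin_len, "trend_r": trend_r,
            "trend_ci": (float(ci[0]), float(ci[1]))}


def permutation_corr(x: np.ndarray, y: np.ndarray, n_perm: int = 1000,
                     seed: int = 0) -> tuple[float, float]:
    """Pearson r with a one-sided shuffle p: proportion of null r >= observed."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input")
    r = float(stats.pearsonr(x, y)[0])
    rng = np.random.default_rng(seed)
    xc = x - x.mean()
    denom = np.linalg.norm(xc)
    nulls = np.empty(n_perm)
    for k in range(n_perm):
        ys = rng.permutation(y)
        ysc = ys - ys.mean()
        nulls[k] = xc @ ysc / (denom * np.linalg.norm(ysc))
    return r, float(np.mean(nulls >= r))


def ranksum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (thin wrapper for median comparisons)."""
    res = stats.ranksums(x, y)
    return float(res.statistic), float(res.pvalue)


def paired_t_test(x, y) -> tuple[float, float]:
    """Two-sided paired t-test (thin wrapper)."""
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)
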