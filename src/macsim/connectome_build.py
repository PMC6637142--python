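"""Hybrid connectome construction from tracer and tractography data.

The construction follows a two-source design: an axonal tract-tracing matrix
supplies the directed *topology* (which connections exist, and in which
direction), while probabilistic-tractography streamline counts supply the
*weights* (fiber tract capacities) and tract lengths.  Tractography settings
are first optimized per subject by sweeping curvature threshold, distance
correction, and a discard fraction for the weakest edges, scoring each
candidate matrix by the area under the ROC curve (AUC) against a binarized
tracer reference.

Capacity weights are defined as the fraction of streamlines sent from a seed
region that reach a target region.  Tract lengths are recovered from the
ratio of distance-corrected to plain streamline counts per seed voxel (the
distance-corrected mode weights each streamline by its path length, so the
ratio estimates mean path length); the median ratio across seed voxels gives
the length for an ROI pair.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from macsim.io_formats import Parcellation, logger

CURVATURES = (0.2, 0.4, 0.6, 0.8)
DISCARD_FRACTIONS = tuple(np.round(np.arange(0, 20) * 0.05, 2))  # 0.00 .. 0.95


@dataclasses.dataclass(frozen=True)
class TractographyParams:
    """One candidate point of the optimization lattice."""

    curvature: float
    distance_correction: bool
    discard_fraction: float

    def __post_init__(self) -> None:
        if not any(np.isclose(self.discard_fraction, DISCARD_FRACTIONS)):
            raise ValueError(
                f"discard_fraction {self.discard_fraction} not on the 5% lattice")


def threshold_lattice() -> list[TractographyParams]:
    """The full optimization lattice: 4 curvatures x 2 modes x 20 fractions."""
    return [
        TractographyParams(c, dc, f)
        for c, dc, f in itertools.product(CURVATURES, (False, True), DISCARD_FRACTIONS)
    ]


@dataclasses.dataclass
class StreamlineSummary:
    """Streamline counts for one subject under one tracking condition."""

    counts: np.ndarray            # (N, N) nonnegative int, seed row -> target col
    total_sent: np.ndarray        # (N,) streamlines sent per seed ROI, net of rejects
    curvature: float
    distance_correction: bool
    subject_id: str | int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.total_sent = np.asarray(self.total_sent, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be square")
        if np.any(self.counts < 0) or np.any(self.total_sent < 0):
            raise ValueError("streamline counts must be nonnegative")

    @property
    def condition(self) -> tuple[float, bool]:
        return (self.curvature, self.distance_correction)


@dataclasses.dataclass
class SweepResult:
    """AUC of every candidate of the lattice, with the deterministic argmax."""

    auc_by_candidate: dict[TractographyParams, float]
    best: TractographyParams
    max_auc: float


@dataclasses.dataclass
class DirectedConnectome:
    """Directed weights + symmetric tract lengths on a shared parcellation."""

    weights: np.ndarray            # (N, N) nonnegative, directed
    tract_lengths_mm: np.ndarray   # (N, N) symmetric
    parcellation: Parcellation

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.tract_lengths_mm = np.asarray(self.tract_lengths_mm, dtype=float)
        n = self.parcellation.n_rois
        if self.weights.shape != (n, n) or self.tract_lengths_mm.shape != (n, n):
            raise ValueError("matrix shapes must match the parcellation")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if not np.allclose(self.tract_lengths_mm, self.tract_lengths_mm.T):
            raise ValueError("tract lengths must be symmetric")

    @property
    def n_rois(self) -> int:
        return self.parcellation.n_rois

    def n_connections(self) -> int:
        return int(np.count_nonzero(self.weights))


# --------------------------------------------------------------------------
# Elementary operations
# --------------------------------------------------------------------------

def capacity_weights(summary: StreamlineSummary) -> np.ndarray:
    """Fiber tract capacities: counts divided by streamlines sent per seed."""
    counts = summary.counts.astype(float)
    np.fill_diagonal(counts, 0.0)
    sent = summary.total_sent
    has_counts = counts.sum(axis=1) > 0
    if np.any(has_counts & (sent <= 0)):
        bad = np.where(has_counts & (sent <= 0))[0]
        raise ValueError(f"seed ROIs {bad.tolist()} have counts but total_sent == 0")
    out = np.zeros_like(counts)
    nz = sent > 0
    out[nz] = counts[nz] / sent[nz, None]
    return out


def symmetrize_mean(m: np.ndarray) -> np.ndarray:
    """Symmetrize by the mean of the two directions."""
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    return (m + m.T) / 2.0


def _upper_edges(m: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Strict upper-triangle (i, j, value) triples in stable index order."""
    iu, ju = np.triu_indices(m.shape[0], k=1)
    return iu, ju, m[iu, ju]


def discard_weakest(m: np.ndarray, fraction: float) -> np.ndarray:
    """Zero out the lowest ``floor(fraction * E)`` nonzero undirected edges.

    E counts the nonzero strict-upper-triangle entries of the (symmetric)
    input.  Ties at the cutoff weight are resolved by stable edge-index
    order (row-major upper triangle).
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    m = np.asarray(m, dtype=float)
    if fraction == 0:
        return m.copy()
    iu, ju, w = _upper_edges(m)
    nz = np.where(w > 0)[0]
    n_drop = int(np.floor(fraction * len(nz)))
    if n_drop == 0:
        return m.copy()
    order = np.argsort(w[nz], kind="stable")     # ascending weight, stable index
    drop = nz[order[:n_drop]]
    out = m.copy()
    out[iu[drop], ju[drop]] = 0.0
    out[ju[drop], iu[drop]] = 0.0
    return out


def roc_auc(candidate: np.ndarray, reference_binary: np.ndarray) -> float:
    """AUC of candidate edge weights as scores for tracer edge presence.

    Computed over strict-upper-triangle ROI pairs via the rank (Mann-Whitney)
    formulation; tied scores contribute 1/2.
    """
    candidate = np.asarray(candidate, dtype=float)
    reference_binary = np.asarray(reference_binary)
    if candidate.shape != reference_binary.shape:
        raise ValueError("candidate and reference dimensions differ")
    _, _, scores = _upper_edges(candidate)
    _, _, truth = _upper_edges(reference_binary)
    pos = truth > 0
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("reference must contain at least one present and one absent edge")
    ranks = stats.rankdata(scores)               # midranks handle ties as 1/2
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def candidate_matrix(summary: StreamlineSummary, discard_fraction: float) -> np.ndarray:
    """capacity -> symmetrize -> discard for one condition and fraction."""
    return discard_weakest(symmetrize_mean(capacity_weights(summary)), discard_fraction)


def optimize_params(summaries: Iterable[StreamlineSummary],
                    reference_binary: np.ndarray) -> SweepResult:
    """Sweep the full 160-candidate lattice for one subject and return the argmax.

    Tie-break on equal AUC: lower discard fraction, then lower curvature,
    then distance correction off.
    """
    by_condition: dict[tuple[float, bool], StreamlineSummary] = {}
    for s in summaries:
        by_condition[s.condition] = s
    required = set(itertools.product(CURVATURES, (False, True)))
    missing = sorted(required - set(by_condition))
    if missing:
        raise ValueError(f"missing tracking conditions: {missing}")

    auc_by_candidate: dict[TractographyParams, float] = {}
    for (curv, dc), summary in sorted(by_condition.items()):
        sym = symmetrize_mean(capacity_weights(summary))
        for frac in DISCARD_FRACTIONS:
            cand = TractographyParams(curv, dc, frac)
            auc_by_candidate[cand] = roc_auc(discard_weakest(sym, frac), reference_binary)

    max_auc = max(auc_by_candidate.values())
    tied = [c for c, a in auc_by_candidate.items() if a == max_auc]
    best = min(tied, key=lambda c: (c.discard_fraction, c.curvature, c.distance_correction))
    return SweepResult(auc_by_candidate, best, float(max_auc))


def estimate_tract_lengths(dc_counts_per_seed_voxel: Sequence[np.ndarray],
                           plain_counts_per_seed_voxel: Sequence[np.ndarray]) -> np.ndarray:
    """Tract lengths (mm) from the distance-corrected / plain count ratio.

    Inputs are per seed ROI: an (n_voxels, N) array of streamline counts to
    each target ROI, with and without distance correction.  Voxels with zero
    plain counts are excluded; the per-pair length is the median valid ratio.
    Pairs with no valid voxel are marked missing (0) with a warning.
    """
    n = len(dc_counts_per_seed_voxel)
    lengths = np.zeros((n, n))
    missing = []
    for i, (dc, plain) in enumerate(zip(dc_counts_per_seed_voxel,
                                        plain_counts_per_seed_voxel)):
        dc = np.asarray(dc, dtype=float)
        plain = np.asarray(plain, dtype=float)
        if dc.shape != plain.shape:
            raise ValueError(f"seed ROI {i}: paired voxel arrays differ in shape")
        for j in range(n):
            if i == j:
                continue
            valid = plain[:, j] > 0
            if not np.any(valid):
                missing.append((i, j))
                continue
            lengths[i, j] = np.median(dc[valid, j] / plain[valid, j])
    if missing:
        logger.warning("no valid seed voxels for %d ROI pairs; lengths marked missing (0)",
                       len(missing))
    return symmetrize_mean(lengths)


def build_hybrid_connectome(tracer: np.ndarray,
                            subject_weights: Sequence[np.ndarray],
                            subject_lengths: Sequence[np.ndarray],
                            parcellation: Parcellation) -> DirectedConnectome:
    """Average subject estimates and mask them onto the tracer topology.

    ``subject_weights`` are each subject's symmetric capacity matrices already
    thresholded at that subject's optimal discard fraction.  Weights are
    averaged across subjects and kept only at nonzero (directed) tracer
    entries, so directionality is inherited from the tracer.  Lengths are
    averaged, symmetrized, and kept at symmetrized tracer nonzeros.
    """
    tracer = np.asarray(tracer)
    n = parcellation.n_rois
    if tracer.shape != (n, n):
        raise ValueError("tracer matrix does not match the parcellation")
    if not subject_weights:
        raise ValueError("at least one subject required")
    for m in list(subject_weights) + list(subject_lengths):
        if np.shape(m) != (n, n):
            raise ValueError("subject matrix dimension mismatch")

    mean_w = np.mean(np.stack(subject_weights), axis=0)
    weights = np.where(tracer != 0, mean_w, 0.0)
    np.fill_diagonal(weights, 0.0)

    mean_len = symmetrize_mean(np.mean(np.stack(subject_lengths), axis=0))
    tracer_sym = (tracer != 0) | (tracer != 0).T
    lengths = np.where(tracer_sym, mean_len, 0.0)
    np.fill_diagonal(lengths, 0.0)

    unsupported = int(np.count_nonzero((tracer != 0) & (weights == 0)))
    if unsupported:
        logger.warning("%d tracer edges have zero averaged tractography weight", unsupported)
    return DirectedConnectome(weights, lengths, parcellation)


def fit_lognormal(weights: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood lognormal fit: (mu, sigma) of the log-weights."""
    w = np.asarray(weights, dtype=float).ravel()
    if w.size < 3:
        raise ValueError("need at least 3 values")
    if np.any(w <= 0):
        raise ValueError("weights must be positive for a lognormal fit")
    logs = np.log(w)
    sigma = float(np.std(logs))            # ML estimate (ddof=0)
    if sigma == 0:
        warnings.warn("all weights equal; sigma = 0 (degenerate lognormal)")
    return float(np.mean(logs)), sigma


def connectome_stats(conn: DirectedConnectome) -> dict:
    """Summary statistics of a built connectome.

    Reports the directed nonzero connection count; overall, intra- and
    inter-hemispheric median tract lengths over undirected connected pairs;
    the lognormal fit of the nonzero weights; and, when centroids are
    available, the median Euclidean distance and its Pearson correlation with
    tract length over connected pairs.
    """
    parc = conn.parcellation
    iu, ju = np.triu_indices(conn.n_rois, k=1)
    lengths = conn.tract_lengths_mm[iu, ju]
    connected = lengths > 0
    same_hemi = parc.hemisphere[iu] == parc.hemisphere[ju]

    mu, sigma = fit_lognormal(conn.weights[conn.weights > 0])
    out = {
        "n_connections": conn.n_connections(),
        "lognormal_mu": mu,
        "lognormal_sigma": sigma,
        "median_length_mm": float(np.median(lengths[connected])),
        "median_length_intra_mm": float(np.median(lengths[connected & same_hemi])),
        "median_length_inter_mm": float(np.median(lengths[connected & ~same_hemi])),
    }
    if parc.centroid_mm is not None:
        dist = parc.euclidean_distances()[iu, ju]
        ok = connected & np.isfinite(dist)
        r, p = stats.pearsonr(lengths[ok], dist[ok])
        out["median_euclidean_mm"] = float(np.median(dist[ok]))
        out["length_distance_r"] = float(r)
        out["length_distance_p"] = float(p)
    return out
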