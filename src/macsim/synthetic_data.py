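"""Synthetic tracer networks, tractography counts, and surrogate empirical FC.

The generator emulates the statistical structure the construction and fitting
pipeline relies on, so every downstream stage is testable without any
download:

* a directed ground-truth "tracer" network whose weights are lognormal and
  whose nodes sit in two hemispheric clusters, making interhemispheric
  tracts stochastically longer than intrahemispheric ones;
* per-subject, per-condition streamline-count matrices with Poisson counts
  whose intensity is attenuated with distance (the weight-distance confound),
  scaled by a condition-dependent detection sensitivity, contaminated by
  false-positive edges, and accompanied by a distance-corrected twin whose
  counts are scaled by path length so the length-ratio estimator is
  exercised;
* surrogate "empirical" FC produced by running the simulator at a known
  (G, sigma) and adding symmetric noise, for parameter-recovery experiments.

Defaults follow the regime of real macaque data: 82 regions, 3389 directed
connections, lognormal weights with mu = -5.07, sigma = 1.92, and hemisphere
geometry placing the intra-/inter-hemispheric median tract lengths around the
33/51 mm split.  All generators take explicit integer seeds; no global RNG
state is used.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from macsim.connectome_build import (CURVATURES, DirectedConnectome,
                                     StreamlineSummary, symmetrize_mean)
from macsim.io_formats import Parcellation

N_ROIS_DEFAULT = 82
N_EDGES_DEFAULT = 3389          # directed connection count of the real connectome
LOGNORMAL_MU_DEFAULT = -5.07    # lognormal fit of the real capacity weights
LOGNORMAL_SIGMA_DEFAULT = 1.92


@dataclasses.dataclass
class GroundTruthNetwork:
    """Directed tracer-like network with geometry; the synthetic gold standard."""

    adjacency: np.ndarray        # (N, N) binary, directed, zero diagonal
    true_weights: np.ndarray     # (N, N) lognormal where adjacency == 1
    coordinates: np.ndarray      # (N, 3) mm
    hemisphere: np.ndarray       # (N,) 'L'/'R'
    path_lengths_mm: np.ndarray  # (N, N) symmetric tract lengths

    @property
    def n_rois(self) -> int:
        return self.adjacency.shape[0]

    def distances(self) -> np.ndarray:
        d = self.coordinates[:, None, :] - self.coordinates[None, :, :]
        return np.sqrt((d ** 2).sum(-1))

    def parcellation(self) -> Parcellation:
        n = self.n_rois
        ids = np.arange(1, n + 1)
        names = [f"region{ids[i]:03d}_{self.hemisphere[i]}" for i in range(n)]
        abbrs = [f"r{ids[i]:03d}_{self.hemisphere[i]}" for i in range(n)]
        return Parcellation(ids, names, abbrs, self.hemisphere.copy(),
                            centroid_mm=self.coordinates.copy())

    def to_connectome(self) -> DirectedConnectome:
        """The noise-free connectome implied by the truth (for simulation)."""
        mask_sym = (self.adjacency != 0) | (self.adjacency != 0).T
        lengths = np.where(mask_sym, self.path_lengths_mm, 0.0)
        return DirectedConnectome(self.true_weights.copy(), lengths,
                                  self.parcellation())


@dataclasses.dataclass
class SyntheticSubjectSpec:
    """Conditions of the emulated tractography cohort."""

    n_subjects: int = 9
    sensitivity: dict = dataclasses.field(
        default_factory=lambda: {0.2: 0.3, 0.4: 1.0, 0.6: 0.55, 0.8: 0.4})
    false_positive_rate: float = 0.9       # probability a null pair gains counts
    fp_log_mu: float = -7.5                # lognormal intensity of false edges
    fp_log_sigma: float = 1.5
    distance_attenuation: float = 0.05     # mm^-1 multiplicative decay
    seeds_per_voxel_equivalent: int = 5000
    n_voxels_per_roi: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.false_positive_rate <= 1:
            raise ValueError("false_positive_rate must be a probability")
        if any(not 0 < s <= 1 for s in self.sensitivity.values()):
            raise ValueError("sensitivities must lie in (0, 1]")
        if self.distance_attenuation < 0:
            raise ValueError("distance_attenuation must be >= 0")

    @property
    def best_condition(self) -> tuple[float, bool]:
        """The generative condition designed to be best recoverable."""
        curv = max(self.sensitivity, key=self.sensitivity.get)
        return (curv, False)


@dataclasses.dataclass
class SyntheticCohort:
    """All per-subject tracking outputs plus the voxel data for lengths."""

    summaries: list[StreamlineSummary]
    # voxel_counts[(subject, curvature, dc)] = list over seed ROIs of (n_vox, N)
    voxel_counts: dict
    truth: GroundTruthNetwork
    spec: SyntheticSubjectSpec

    def subject_summaries(self, subject: int) -> list[StreamlineSummary]:
        return [s for s in self.summaries if s.subject_id == subject]

    def tract_length_inputs(self, subject: int, curvature: float):
        """(distance-corrected, plain) voxel count lists for one subject."""
        return (self.voxel_counts[(subject, curvature, True)],
                self.voxel_counts[(subject, curvature, False)])


# --------------------------------------------------------------------------
# Ground truth
# --------------------------------------------------------------------------

def make_ground_truth(n_rois: int = N_ROIS_DEFAULT,
                      density: float | None = None,
                      lognormal_mu: float = LOGNORMAL_MU_DEFAULT,
                      lognormal_sigma: float = LOGNORMAL_SIGMA_DEFAULT,
                      interhem_fraction: float = 0.25,
                      rng_seed: int = 0,
                      cluster_separation_mm: float = 40.0,
                      cluster_sd_mm: float = 12.0,
                      edge_distance_scale_mm: float = 30.0,
                      detour_factor: float = 1.235,
                      detour_sigma: float = 0.2) -> GroundTruthNetwork:
    """Sample a directed lognormal-weight network in two hemispheric clusters.

    ``density`` defaults to the real connectome's (3389 directed edges at 82
    ROIs).  Edges are drawn with probability decaying in distance
    (exp(-d / edge_distance_scale)), a fixed fraction interhemispheric.
    Tract lengths are Euclidean distances times a lognormal detour factor
    (fiber paths are longer than straight lines).
    """
    if n_rois < 2:
        raise ValueError("need at least 2 ROIs")
    n_pairs = n_rois * (n_rois - 1)
    if density is None:
        density = min(N_EDGES_DEFAULT / n_pairs, 0.9)
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    n_edges = int(round(density * n_pairs))
    if n_edges < 1:
        raise ValueError(f"density {density} yields no edges at n_rois={n_rois}")
    rng = np.random.default_rng(rng_seed)

    n_left = n_rois // 2
    hemi = np.array(["L"] * n_left + ["R"] * (n_rois - n_left))
    coords = cluster_sd_mm * rng.standard_normal((n_rois, 3))
    coords[:n_left, 0] -= cluster_separation_mm / 2.0
    coords[n_left:, 0] += cluster_separation_mm / 2.0

    net = GroundTruthNetwork(np.zeros((n_rois, n_rois), dtype=np.int8),
                             np.zeros((n_rois, n_rois)), coords, hemi,
                             np.zeros((n_rois, n_rois)))
    dist = net.distances()

    src, dst = np.meshgrid(np.arange(n_rois), np.arange(n_rois), indexing="ij")
    off = src != dst
    inter = (hemi[src] != hemi[dst]) & off
    intra = (hemi[src] == hemi[dst]) & off
    n_inter = min(int(round(interhem_fraction * n_edges)), int(inter.sum()))
    n_intra = min(n_edges - n_inter, int(intra.sum()))
    n_inter = n_edges - n_intra    # re-balance if intra pool was the limit

    adjacency = net.adjacency
    for mask, k in ((intra, n_intra), (inter, n_inter)):
        pool = np.flatnonzero(mask)
        p = np.exp(-dist.ravel()[pool] / edge_distance_scale_mm)
        p /= p.sum()
        chosen = rng.choice(pool, size=k, replace=False, p=p)
        adjacency.ravel()[chosen] = 1

    weights = np.zeros((n_rois, n_rois))
    e = adjacency == 1
    weights[e] = np.exp(rng.normal(lognormal_mu, lognormal_sigma, size=int(e.sum())))
    net.true_weights = weights

    iu, ju = np.triu_indices(n_rois, k=1)
    detour = detour_factor * np.exp(rng.normal(0.0, detour_sigma, size=len(iu)))
    lengths = np.zeros((n_rois, n_rois))
    lengths[iu, ju] = dist[iu, ju] * detour
    net.path_lengths_mm = lengths + lengths.T
    return net


# --------------------------------------------------------------------------
# Tractography emulation
# --------------------------------------------------------------------------

def simulate_tractography_counts(truth: GroundTruthNetwork,
                                 spec: SyntheticSubjectSpec) -> SyntheticCohort:
    """Poisson streamline counts per subject x (curvature, distance-correction).

    Per seed voxel v of ROI i and target j, plain counts are
    Poisson(seeds * sensitivity(curv) * w_ij * exp(-decay * d_ij)) on true
    edges.  A subject-fixed random ``false_positive_rate`` fraction of null
    pairs carries a weak lognormal intensity that does NOT scale with the
    curvature sensitivity (spurious streamlines arise from noise and crossing
    fibers, not from the tract-following ability the curvature threshold
    controls), so conditions with higher sensitivity genuinely separate true
    from false edges better.

    Distance correction reweights detected streamlines by their path length
    rather than detecting new ones: the dc twin of each condition is the
    plain voxel count times L_ij times a small lognormal per-voxel length
    jitter.  The voxelwise dc/plain ratio therefore estimates L_ij, while the
    rank boost that dc gives to long (disproportionately false) connections
    degrades its AUC.  Totals sent per seed ROI are seeds * n_vox, always
    >= the row sums of plain counts.
    """
    n = truth.n_rois
    dist = truth.distances()
    lengths = truth.path_lengths_mm
    decay = spec.distance_attenuation
    n_vox = spec.n_voxels_per_roi
    scale = float(spec.seeds_per_voxel_equivalent)
    summaries: list[StreamlineSummary] = []
    voxel_counts: dict = {}

    for subject in range(spec.n_subjects):
        rng = np.random.default_rng((spec.rng_seed, subject))
        # subject-fixed false-positive support, weak lognormal intensities
        null_pairs = (truth.adjacency == 0) & ~np.eye(n, dtype=bool)
        fp_mask = null_pairs & (rng.uniform(size=(n, n)) < spec.false_positive_rate)
        fp_weight = np.zeros((n, n))
        fp_weight[fp_mask] = np.exp(rng.normal(spec.fp_log_mu, spec.fp_log_sigma,
                                               size=int(fp_mask.sum())))
        attenuation = np.exp(-decay * dist)

        for curv in CURVATURES:
            lam_vox = scale * attenuation * (
                spec.sensitivity[curv] * truth.true_weights + fp_weight)
            np.fill_diagonal(lam_vox, 0.0)
            plain_rois, dc_rois = [], []
            counts_plain = np.zeros((n, n), dtype=np.int64)
            counts_dc = np.zeros((n, n), dtype=np.int64)
            for i in range(n):
                lam = np.tile(lam_vox[i], (n_vox, 1))
                plain = rng.poisson(lam)
                jitter = np.exp(rng.normal(0.0, 0.05, size=plain.shape))
                dc = np.rint(plain * np.maximum(lengths[i], 0.0) * jitter
                             ).astype(np.int64)
                plain_rois.append(plain)
                dc_rois.append(dc)
                counts_plain[i] = plain.sum(axis=0)
                counts_dc[i] = dc.sum(axis=0)
            total_sent = np.full(n, scale * n_vox)
            summaries.append(StreamlineSummary(counts_plain, total_sent.copy(),
                                               curv, False, subject))
            summaries.append(StreamlineSummary(counts_dc, total_sent.copy(),
                                               curv, True, subject))
            voxel_counts[(subject, curv, False)] = plain_rois
            voxel_counts[(subject, curv, True)] = dc_rois
    return SyntheticCohort(summaries, voxel_counts, truth, spec)


# --------------------------------------------------------------------------
# Surrogate empirical FC
# --------------------------------------------------------------------------

def make_surrogate_empirical_fc(connectome: DirectedConnectome, G: float,
                                sigma: float, duration_s: float = 600.0,
                                noise_sd: float = 0.05, rng_seed: int = 0,
                                **sim_kwargs):
    """Fisher-z FC from a reference simulation at a known (G, sigma) + noise.

    Stands in for empirical resting-state FC in recovery experiments; the
    generative parameters are recorded in the returned matrix's provenance.
    Simulator rejection (runaway firing after FIC tuning) propagates as a
    RuntimeError.
    """
    from macsim.fitting import FCMatrix, compute_fc
    from macsim.simulate import DMFParams, simulate_bold, tune_fic

    params = DMFParams(G=G, sigma=sigma, duration=duration_s,
                       rng_seed=rng_seed, **sim_kwargs)
    fic = tune_fic(connectome, params)
    if fic.rejected:
        raise RuntimeError(
            f"reference simulation rejected: mean rate {fic.mean_rates.mean():.1f} Hz")
    params.Ji = fic.Ji
    bold, _ = simulate_bold(connectome, params)
    fc = compute_fc(bold.values, fisher_z_transform=True)
    z = fc.values
    if noise_sd > 0:
        rng = np.random.default_rng((rng_seed, 1))
        noise = noise_sd * rng.standard_normal(z.shape)
        z = z + symmetrize_mean(noise)
        np.fill_diagonal(z, fc.values.diagonal())
    return FCMatrix(z, "fisher_z",
                    provenance={"generative_G": G, "generative_sigma": sigma,
                                "noise_sd": noise_sd, "rng_seed": rng_seed})
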