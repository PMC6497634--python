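"""Dihedral principal component analysis of glycosidic torsions.

Each torsion phi_n enters the dataset as the sine/cosine pair
q_{2n-1} = cos(phi_n), q_{2n} = sin(phi_n), removing the circularity of the
angle coordinate.  The model is the eigendecomposition of the population
covariance sigma_ij = <(q_i - <q_i>)(q_j - <q_j>)> (1/M normalisation, the
angle brackets being time/ensemble averages); projections are the inner
products mu_i = v_i^T (q - <q>).

Density maps over two principal components are labelled deterministically by
grid-density peaks: a mode is a local-maximum bin above a threshold fraction
of the highest bin, and every occupied bin above the threshold is assigned to
a mode by steepest ascent on the bin grid (8-neighbourhood); bins below the
threshold form the noise bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from ._geometry import dihedral
from .io import Trajectory

__all__ = ["DihedralDataset", "PCAModel", "ClusterMap", "extract_dihedrals",
           "transform", "fit", "project", "density_map",
           "conditional_density", "kmeans_modes"]


@dataclass
class DihedralDataset:
    """Sine/cosine-transformed torsions: rows = observations, columns = (cos, sin) pairs."""

    q: np.ndarray               # (n_obs, 2 * n_dihedrals)
    labels: list[str]           # one label per dihedral

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape[1] != 2 * len(self.labels):
            raise ValueError("column count must be 2 x number of dihedrals")
        norms = self.q[:, 0::2] ** 2 + self.q[:, 1::2] ** 2
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("each (cos, sin) pair must lie on the unit circle")

    def angles(self) -> np.ndarray:
        """Back-transform to angles in degrees via atan2, range (-180, 180]."""
        ang = np.degrees(np.arctan2(self.q[:, 1::2], self.q[:, 0::2]))
        return np.where(np.isclose(ang, -180.0), 180.0, ang)


@dataclass
class PCAModel:
    mean: np.ndarray            # <q>
    eigenvalues: np.ndarray     # descending, >= 0
    eigenvectors: np.ndarray    # orthonormal columns v_i

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


@dataclass
class ClusterMap:
    counts: np.ndarray          # (n_bins_a, n_bins_b) histogram
    a_edges: np.ndarray
    b_edges: np.ndarray
    bin_mode: np.ndarray        # mode id per bin, -1 = noise
    point_mode: np.ndarray      # mode id per observation, -1 = noise
    mode_populations: np.ndarray  # fraction of observations per mode

    @property
    def n_modes(self) -> int:
        return len(self.mode_populations)


def extract_dihedrals(traj: Trajectory,
                      dihedral_spec: list[tuple[int, int, int, int]],
                      labels: list[str] | None = None) -> np.ndarray:
    """Raw torsion table (n_frames, n_dihedrals) in degrees, range (-180, 180].

    ``dihedral_spec`` lists atom-index quadruples (a, b, c, d) per linkage;
    collinear triples raise, naming the linkage.
    """
    labels = labels or [f"phi{k + 1}" for k in range(len(dihedral_spec))]
    out = np.empty((traj.n_frames, len(dihedral_spec)))
    for k, quad in enumerate(dihedral_spec):
        if len(set(quad)) != 4:
            raise ValueError(f"linkage {labels[k]}: atoms must be distinct")
        a, b, c, d = (traj.coords[:, i, :] for i in quad)
        for u, v, w in ((a, b, c), (b, c, d)):
            cross = np.cross(v - u, w - v)
            if np.any(np.linalg.norm(cross, axis=-1) < 1e-10):
                raise ValueError(f"linkage {labels[k]}: collinear atoms")
        out[:, k] = dihedral(a, b, c, d)
    return out


def transform(angles: np.ndarray,
              labels: list[str] | None = None) -> DihedralDataset:
    """Sine/cosine transform: columns (cos phi_1, sin phi_1, cos phi_2, ...)."""
    angles = np.asarray(angles, dtype=float)
    if angles.ndim == 1:
        angles = angles[:, None]
    if not np.all(np.isfinite(angles)):
        raise ValueError("non-finite angles")
    rad = np.radians(angles)
    q = np.empty((angles.shape[0], 2 * angles.shape[1]))
    q[:, 0::2] = np.cos(rad)
    q[:, 1::2] = np.sin(rad)
    return DihedralDataset(
        q, labels or [f"phi{k + 1}" for k in range(angles.shape[1])])


def fit(dataset: DihedralDataset | np.ndarray) -> PCAModel:
    """Eigendecomposition of the population covariance of the transformed data.

    Covariance uses 1/M normalisation (ensemble average).  Eigenvalues sort
    descending; each eigenvector's sign is fixed so its largest-magnitude
    component is positive, making projections reproducible across platforms.
    """
    q = dataset.q if isinstance(dataset, DihedralDataset) else np.asarray(dataset, float)
    if q.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    mean = q.mean(axis=0)
    centered = q - mean
    cov = centered.T @ centered / q.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for j in range(evecs.shape[1]):
        k = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]
    return PCAModel(mean=mean, eigenvalues=evals, eigenvectors=evecs)


def project(model: PCAModel,
            dataset: DihedralDataset | np.ndarray) -> np.ndarray:
    """Principal components mu_i = v_i^T (q - <q>) per observation.

    Works for the training set or for an external dataset of matching
    dimension (e.g. new conformers projected onto eigenvectors fitted on a
    reference ensemble).
    """
    q = dataset.q if isinstance(dataset, DihedralDataset) else np.asarray(dataset, float)
    if q.shape[1] != len(model.mean):
        raise ValueError(
            f"dataset has {q.shape[1]} columns, model expects {len(model.mean)}")
    return (q - model.mean) @ model.eigenvectors


def _steepest_ascent_labels(smooth: np.ndarray, occupied: np.ndarray,
                            threshold: float) -> np.ndarray:
    """Mode id per bin: ascend the smoothed density to a peak above threshold.

    A peak is a bin that is its own 8-neighbourhood maximum with smoothed
    density >= threshold.  Every occupied bin follows steepest ascent; bins
    whose ascent ends below the threshold (and empty bins) get -1 (noise).
    """
    na, nb = smooth.shape
    flat_target = np.full((na, nb), -1, dtype=int)
    for i in range(na):
        for j in range(nb):
            best = (smooth[i, j], i, j)
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < na and 0 <= jj < nb:
                        c = (smooth[ii, jj], ii, jj)
                        if c > best:
                            best = c
            flat_target[i, j] = best[1] * nb + best[2]

    modes: dict[int, int] = {}
    labels = np.full((na, nb), -1, dtype=int)
    for i in range(na):
        for j in range(nb):
            if not occupied[i, j]:
                continue
            cur = i * nb + j
            seen = set()
            while flat_target[cur // nb, cur % nb] not in (cur, -1):
                if cur in seen:      # plateau cycle guard
                    break
                seen.add(cur)
                cur = flat_target[cur // nb, cur % nb]
            if smooth[cur // nb, cur % nb] < threshold:
                continue
            if cur not in modes:
                modes[cur] = len(modes)
            labels[i, j] = modes[cur]
    return labels


def density_map(projections: np.ndarray, axes: tuple[int, int] = (0, 1),
                bins: int = 40, threshold: float = 0.1,
                min_count: float = 0.0) -> ClusterMap:
    """2-D occupancy histogram over two principal components with mode labels.

    ``threshold`` is a fraction of the maximum bin count and ``min_count`` an
    absolute floor; bins below either (and their points) go to the noise bin
    (-1).  Mode ids are ordered by first appearance in bin-scan order,
    deterministic for fixed bins and thresholds.
    """
    projections = np.asarray(projections, dtype=float)
    if projections.shape[0] < 1:
        raise ValueError("need at least one observation")
    a = projections[:, axes[0]]
    b = projections[:, axes[1]]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero-width projection axis")
    counts, a_edges, b_edges = np.histogram2d(a, b, bins=bins)
    # peak finding runs on smoothed counts so sampling noise along a density
    # ridge does not split one mode into several; populations and the stored
    # histogram stay raw.  Smoothing scales with resolution so mode counts
    # are stable under bin refinement.
    smooth = gaussian_filter(counts, sigma=max(1.0, bins / 20.0),
                             mode="constant")
    bin_mode = _steepest_ascent_labels(
        smooth, counts > 0, max(threshold * smooth.max(), min_count))
    ia = np.clip(np.searchsorted(a_edges, a, side="right") - 1, 0, bins - 1)
    ib = np.clip(np.searchsorted(b_edges, b, side="right") - 1, 0, bins - 1)
    point_mode = bin_mode[ia, ib]
    n_modes = bin_mode.max() + 1
    pops = np.array([(point_mode == m).mean() for m in range(n_modes)])
    return ClusterMap(counts=counts, a_edges=a_edges, b_edges=b_edges,
                      bin_mode=bin_mode, point_mode=point_mode,
                      mode_populations=pops)


def kmeans_modes(projections: np.ndarray, k: int,
                 axes: tuple[int, int] = (0, 1),
                 seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Alternative mode labeling: seeded k-means on two principal components.

    Returns (labels per observation, population fraction per cluster).
    Deterministic for a fixed seed; a complementary view to the density-peak
    labeling of :func:`density_map`, not a replacement.
    """
    from scipy.cluster.vq import kmeans2

    pts = np.asarray(projections, dtype=float)[:, list(axes)]
    _, labels = kmeans2(pts, k, seed=seed, minit="++")
    pops = np.array([(labels == m).mean() for m in range(k)])
    return labels, pops


def conditional_density(projections: np.ndarray, condition: np.ndarray,
                        axes: tuple[int, int] = (0, 1), bins: int = 40,
                        threshold: float = 0.1) -> tuple[ClusterMap, ClusterMap]:
    """Density maps for all observations and for the condition-true subset.

    Both maps share the full-data bin grid and mode labelling, so per-mode
    populations are directly comparable (e.g. glycan conformer populations
    with and without a bound peptide segment).
    """
    projections = np.asarray(projections, dtype=float)
    condition = np.asarray(condition).astype(bool)
    if len(condition) != projections.shape[0]:
        raise ValueError(
            f"condition length {len(condition)} != observations "
            f"{projections.shape[0]}")
    full = density_map(projections, axes=axes, bins=bins, threshold=threshold)
    sub = projections[condition]
    a = sub[:, axes[0]]
    b = sub[:, axes[1]]
    counts, _, _ = np.histogram2d(a, b, bins=[full.a_edges, full.b_edges])
    nb = full.counts.shape[1]
    ia = np.clip(np.searchsorted(full.a_edges, a, side="right") - 1, 0,
                 full.counts.shape[0] - 1)
    ib = np.clip(np.searchsorted(full.b_edges, b, side="right") - 1, 0, nb - 1)
    point_mode = full.bin_mode[ia, ib]
    n_modes = full.n_modes
    # populations relative to the conditional sample size
    pops = np.array([(point_mode == m).mean() if len(point_mode) else 0.0
                     for m in range(n_modes)])
    cond_map = ClusterMap(counts=counts, a_edges=full.a_edges,
                          b_edges=full.b_edges, bin_mode=full.bin_mode,
                          point_mode=point_mode, mode_populations=pops)
    return full, cond_map
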