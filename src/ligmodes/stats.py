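"""Contact-frequency and distance-distribution statistics.

Frequencies are fractions of frames; their uncertainties come from block
averaging: the trajectory is split into consecutive blocks of equal size
and the sample standard deviation of the per-block means is reported.
Distance distributions are summarized by the mode of a Gaussian-kernel
density estimate (Silverman bandwidth by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .fingerprints import Fingerprint, RingSystem, ring_geometry
from .structio import Trajectory, select_atoms

__all__ = [
    "ContactStats",
    "DensityEstimate",
    "contact_frequency",
    "interaction_share",
    "block_error",
    "contact_stats",
    "distance_series",
    "density_mode",
]


@dataclass
class ContactStats:
    """Per-descriptor contact frequencies with block-averaged errors."""

    labels: list[tuple[str, int, str]]
    frequency: np.ndarray
    block_std: np.ndarray | None
    n_blocks: int
    type_share: dict[str, float]
    type_share_std: dict[str, float]


@dataclass
class DensityEstimate:
    """Gaussian-KDE of a distance sample with the abscissa of its maximum."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    mode: float


def contact_frequency(fp: Fingerprint) -> np.ndarray:
    """Fraction of frames in which each descriptor is set (column means)."""
    if fp.n_frames < 1:
        raise ValueError("fingerprint has no frames")
    return fp.matrix.mean(axis=0)


def interaction_share(fp: Fingerprint, interaction_type: str) -> float:
    """Fraction of frames showing ANY descriptor of the given type
    (e.g. the share of frames with at least one π-stacking contact)."""
    cols = [i for i, (_, _, t) in enumerate(fp.labels) if t == interaction_type]
    if not cols:
        return 0.0
    return float(fp.matrix[:, cols].any(axis=1).mean())


def _block_means(series: np.ndarray, n_blocks: int) -> np.ndarray:
    n = len(series)
    if n < n_blocks:
        raise ValueError(f"series of length {n} cannot be split into {n_blocks} blocks")
    size = n // n_blocks
    means = []
    for b in range(n_blocks):
        start = b * size
        stop = (b + 1) * size if b < n_blocks - 1 else n  # remainder joins the last block
        means.append(float(np.mean(series[start:stop])))
    return np.array(means)


def block_error(series, n_blocks: int = 5) -> float:
    """Block-averaging error: sample standard deviation (n-1 denominator)
    of the means of ``n_blocks`` consecutive blocks."""
    series = np.asarray(series, dtype=float)
    return float(np.std(_block_means(series, n_blocks), ddof=1))


def contact_stats(fp: Fingerprint, n_blocks: int = 5) -> ContactStats:
    """Frequencies, per-descriptor block errors and per-type shares with
    block errors, all from one pooled fingerprint."""
    freq = contact_frequency(fp)
    block_std = np.array([block_error(fp.matrix[:, j].astype(float), n_blocks) for j in range(fp.n_descriptors)])
    types = sorted({t for _, _, t in fp.labels})
    share: dict[str, float] = {}
    share_std: dict[str, float] = {}
    for t in types:
        cols = [i for i, (_, _, tt) in enumerate(fp.labels) if tt == t]
        any_series = fp.matrix[:, cols].any(axis=1).astype(float)
        share[t] = float(any_series.mean())
        share_std[t] = block_error(any_series, n_blocks)
    return ContactStats(
        labels=list(fp.labels),
        frequency=freq,
        block_std=block_std,
        n_blocks=n_blocks,
        type_share=share,
        type_share_std=share_std,
    )


def _resolve_point_spec(traj: Trajectory, spec) -> tuple[str, object]:
    """A point spec is either a selection expression resolving to exactly
    one atom, or a RingSystem / explicit atom-index tuple whose per-frame
    centroid is used."""
    if isinstance(spec, RingSystem):
        return "ring", spec.atom_indices
    if isinstance(spec, (tuple, list, np.ndarray)) and not isinstance(spec, str):
        return "ring", tuple(int(i) for i in spec)
    idx = select_atoms(traj.topology, str(spec))
    if len(idx) != 1:
        matches = [
            f"{traj.topology.chain_id[i]}/{traj.topology.resname[i]}"
            f"{traj.topology.resseq[i]}/{traj.topology.name[i]}"
            for i in idx[:10]
        ]
        raise ValueError(
            f"spec {spec!r} resolves to {len(idx)} atoms (need exactly 1): {matches}"
        )
    return "atom", int(idx[0])


def distance_series(traj: Trajectory, spec_a, spec_b) -> np.ndarray:
    """Per-frame Euclidean distance between two points, each given as a
    single-atom selection expression or a ring (centroid recomputed per
    frame)."""
    kind_a, a = _resolve_point_spec(traj, spec_a)
    kind_b, b = _resolve_point_spec(traj, spec_b)

    def point(coords: np.ndarray, kind: str, ref) -> np.ndarray:
        if kind == "atom":
            return coords[ref]
        centroid, _, _ = ring_geometry(coords, ref)
        return centroid

    return np.array(
        [
            float(np.linalg.norm(point(traj.coords[f], kind_a, a) - point(traj.coords[f], kind_b, b)))
            for f in range(traj.frame_count)
        ]
    )


def density_mode(samples, bandwidth: float | str = "auto", grid_points: int = 512) -> DensityEstimate:
    """Mode of a Gaussian-kernel density estimate.

    The density is evaluated on a grid spanning [min-3h, max+3h] with at
    least 512 points; ``bandwidth='auto'`` uses Silverman's rule.
    """
    samples = np.asarray(samples, dtype=float)
    if len(samples) < 10:
        raise ValueError(f"need at least 10 samples, got {len(samples)}")
    std = float(np.std(samples, ddof=1))
    if bandwidth == "auto":
        kde = gaussian_kde(samples, bw_method="silverman")
        h = float(kde.factor) * std
    else:
        h = float(bandwidth)
        if h <= 0:
            raise ValueError("bandwidth must be positive")
        if std > 0:
            kde = gaussian_kde(samples, bw_method=h / std)
        else:
            kde = None
    grid_points = max(int(grid_points), 512)
    if grid_points % 2 == 0:
        grid_points += 1  # odd count puts the span's midpoint exactly on the grid
    lo, hi = samples.min() - 3 * h, samples.max() + 3 * h
    grid = np.linspace(lo, hi, grid_points)
    if kde is not None and std > 0:
        density = kde(grid)
    else:
        # all samples identical: the KDE is a single Gaussian kernel
        density = np.exp(-0.5 * ((grid - samples[0]) / h) ** 2) / (h * np.sqrt(2 * np.pi))
    mode = float(grid[int(np.argmax(density))])
    return DensityEstimate(grid=grid, density=density, bandwidth=h, mode=mode)
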