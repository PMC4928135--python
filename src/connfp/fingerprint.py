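"""Connectional fingerprints from voxel-level tract-sample counts.

A probabilistic-tractography run seeds every voxel of a region and counts,
for each of the atlas's target regions, how many of the propagated fiber
samples reached it (probtrackx "classification targets" output).  The
connectional fingerprint of a seed region ``i`` is the vector ``w^i`` whose
entry ``j`` is the connection probability to region ``j``::

    w^i_j = (1/n) * sum_q  c_jq / sum_k c_kq

i.e. each voxel's counts are first normalized to the voxel's own total
(so every voxel contributes one probability vector summing to 1) and these
per-voxel probability vectors are then averaged over the seed's voxels.
Because the normalization is nodal, the resulting matrix of fingerprints is
in general asymmetric: ``w_ij != w_ji``.

Voxels from which no sample reached any target have an undefined ratio and
are excluded from the average (with a warning); the denominator counts only
contributing voxels, which preserves the sum-to-1 property.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("connfp")

#: tolerance for fingerprint normalization assertions
NORMALIZATION_TOL = 1e-12


class DegenerateVoxelError(ValueError):
    """A voxel (or a whole seed region) propagated no sample to any target."""


@dataclass(frozen=True)
class RegionAtlas:
    """Ordered brain parcellation defining the canonical node order.

    The file order of the atlas is the canonical node order for every matrix
    in the package; inputs in a different order are an error, never silently
    re-sorted.
    """

    labels: tuple[str, ...]
    hemispheres: tuple[str, ...] = ()

    def __post_init__(self):
        if len(self.labels) < 2:
            raise ValueError("atlas needs at least 2 regions")
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise ValueError(f"duplicate region labels: {dupes}")
        if self.hemispheres and len(self.hemispheres) != len(self.labels):
            raise ValueError("hemispheres must match labels in length")

    @property
    def m(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"region {label!r} not in atlas") from None


@dataclass(frozen=True)
class VoxelCounts:
    """Tract-sample counts for one seed region of one subject.

    ``counts`` is an (n_voxels, m) nonnegative integer array; the column of
    the seed region itself must be all zeros (self-connections are not
    tracked: each of the m seeds targets the other m-1 regions).
    """

    seed: int
    counts: np.ndarray
    samples_per_voxel: int = 5000

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] < 1:
            raise ValueError("counts must be a (n_voxels >= 1, m) matrix")
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        if not (0 <= self.seed < c.shape[1]):
            raise ValueError(f"seed index {self.seed} out of range")
        if np.any(c[:, self.seed] != 0):
            raise ValueError(
                f"seed region {self.seed}: self-connection column must be zero"
            )
        object.__setattr__(self, "counts", c)

    @property
    def n_voxels(self) -> int:
        return self.counts.shape[0]


@dataclass(frozen=True)
class Fingerprint:
    """Connection-probability vector of one seed region (self entry 0)."""

    seed: int
    w: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.w, dtype=float)
        if np.any(w < -NORMALIZATION_TOL) or np.any(w > 1 + NORMALIZATION_TOL):
            raise ValueError("fingerprint entries must lie in [0, 1]")
        object.__setattr__(self, "w", w)


@dataclass(frozen=True)
class FingerprintMatrix:
    """All fingerprints of one subject stacked into an m x m matrix.

    Row ``i`` is the fingerprint of node ``i``; the diagonal is zero.  The
    matrix is *not* symmetric in general (nodal normalization).
    """

    subject: str
    W: np.ndarray
    atlas: RegionAtlas | None = field(default=None, compare=False)

    def __post_init__(self):
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("W must be square")
        if np.any(np.abs(np.diag(W)) > NORMALIZATION_TOL):
            raise ValueError("fingerprint matrix diagonal must be zero")
        object.__setattr__(self, "W", W)


def voxel_probabilities(counts_row: np.ndarray) -> np.ndarray:
    """Connection probabilities of a single voxel.

    Each entry is the number of samples that reached that target divided by
    the total number of samples from the voxel that reached any target.

    Raises
    ------
    DegenerateVoxelError
        If the row is all zero (the ratio is undefined; callers pre-filter).
    """
    row = np.asarray(counts_row, dtype=float)
    if row.ndim != 1:
        raise ValueError("counts_row must be 1-D")
    if np.any(row < 0):
        raise ValueError("counts must be nonnegative")
    total = row.sum()
    if total == 0:
        raise DegenerateVoxelError("voxel propagated no sample to any target")
    return row / total


def compute_fingerprint(vc: VoxelCounts) -> Fingerprint:
    """Average the per-voxel connection probabilities of a seed region.

    Zero-total voxels are excluded from the average (logged); the divisor is
    the number of contributing voxels, so the result sums to 1 whenever at
    least one voxel contributed.
    """
    totals = vc.counts.sum(axis=1)
    keep = totals > 0
    n_kept = int(keep.sum())
    if n_kept == 0:
        raise DegenerateVoxelError(
            f"seed region {vc.seed}: every voxel has zero reached samples"
        )
    if n_kept < vc.n_voxels:
        logger.warning(
            "seed region %d: excluding %d/%d zero-total voxels from the average",
            vc.seed, vc.n_voxels - n_kept, vc.n_voxels,
        )
    probs = vc.counts[keep] / totals[keep, None]
    w = probs.mean(axis=0)
    w[vc.seed] = 0.0
    return Fingerprint(seed=vc.seed, w=w)


def build_fingerprint_matrix(
    all_seeds: list[VoxelCounts], atlas: RegionAtlas, subject: str = ""
) -> FingerprintMatrix:
    """Assemble per-seed fingerprints into the subject-level m x m matrix.

    Requires exactly one :class:`VoxelCounts` per atlas region.
    """
    seeds = [vc.seed for vc in all_seeds]
    missing = sorted(set(range(atlas.m)) - set(seeds))
    dupes = sorted({s for s in seeds if seeds.count(s) > 1})
    if missing or dupes:
        parts = []
        if missing:
            parts.append(f"missing seeds {[atlas.labels[i] for i in missing]}")
        if dupes:
            parts.append(f"duplicate seeds {[atlas.labels[i] for i in dupes]}")
        raise ValueError("; ".join(parts))
    W = np.zeros((atlas.m, atlas.m))
    for vc in all_seeds:
        if vc.counts.shape[1] != atlas.m:
            raise ValueError(
                f"seed {atlas.labels[vc.seed]}: counts have "
                f"{vc.counts.shape[1]} columns, atlas has {atlas.m} regions"
            )
        W[vc.seed] = compute_fingerprint(vc).w
    return FingerprintMatrix(subject=subject, W=W, atlas=atlas)


def fingerprint_from_region_counts(
    C: np.ndarray, atlas: RegionAtlas | None = None, subject: str = ""
) -> FingerprintMatrix:
    """Row-normalize a region x region count matrix into fingerprints.

    Degraded fallback for data where voxel-level counts were not kept: this
    equals the voxel-wise definition only when all voxels of a seed have the
    same total, and is documented as a deviation otherwise.  Zero rows yield
    an all-zero fingerprint with a warning.
    """
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("region-count matrix must be nonnegative")
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("region-count matrix must be square")
    C = C.copy()
    np.fill_diagonal(C, 0.0)
    sums = C.sum(axis=1)
    zero_rows = np.flatnonzero(sums == 0)
    if zero_rows.size:
        names = (
            [atlas.labels[i] for i in zero_rows] if atlas else zero_rows.tolist()
        )
        warnings.warn(f"zero-count seed rows left as all-zero fingerprints: {names}")
    W = np.divide(C, sums[:, None], out=np.zeros_like(C), where=sums[:, None] > 0)
    return FingerprintMatrix(subject=subject, W=W, atlas=atlas)


def fingerprints_to_frame(fm: FingerprintMatrix) -> pd.DataFrame:
    """Subject fingerprint matrix as a labelled DataFrame (seed rows)."""
    labels = (
        list(fm.atlas.labels) if fm.atlas else [str(i) for i in range(fm.W.shape[0])]
    )
    return pd.DataFrame(fm.W, index=labels, columns=labels)
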