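"""Pairwise fingerprint similarity across subjects.

For node ``k`` and subjects ``i, j`` the dissimilarity is the L1 distance
between their fingerprints, ``d^k_ij = |w^k_i - w^k_j|_1``, mapped to a
similarity in (0, 1] by a monotonically decreasing exponential::

    s^k_ij = exp(-d^k_ij / alpha)

``alpha`` is a regularization factor set to half the maximum L1 distance
over all nodes and subject pairs of the pooled cohort.  It is computed once
before testing and is not recomputed inside permutations: relabeling group
membership does not change the pooled set of pairwise distances, so reusing
it is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .fingerprint import Fingerprint, FingerprintMatrix, RegionAtlas


@dataclass(frozen=True)
class CohortFingerprints:
    """Fingerprint matrices of every subject in a (multi-)group cohort."""

    subjects: tuple[str, ...]
    groups: tuple[str, ...]
    W_stack: np.ndarray  # (n_subjects, m, m)
    atlas: RegionAtlas | None = field(default=None, compare=False)

    def __post_init__(self):
        W = np.asarray(self.W_stack, dtype=float)
        if W.ndim != 3 or W.shape[1] != W.shape[2]:
            raise ValueError("W_stack must be (n_subjects, m, m)")
        if len(self.subjects) != W.shape[0] or len(self.groups) != W.shape[0]:
            raise ValueError("subjects/groups must match W_stack's first axis")
        if W.shape[0] < 2:
            raise ValueError("cohort needs at least 2 subjects")
        object.__setattr__(self, "W_stack", W)

    @property
    def n_subjects(self) -> int:
        return self.W_stack.shape[0]

    @property
    def m(self) -> int:
        return self.W_stack.shape[1]

    @classmethod
    def from_matrices(cls, fms: list[FingerprintMatrix], groups) -> "CohortFingerprints":
        return cls(
            subjects=tuple(fm.subject for fm in fms),
            groups=tuple(groups),
            W_stack=np.stack([fm.W for fm in fms]),
            atlas=fms[0].atlas,
        )


@dataclass(frozen=True)
class SimilarityStack:
    """Per-node subject x subject similarity matrices (symmetric, diag 1)."""

    alpha: float
    S: np.ndarray  # (m, n, n)

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        S = np.asarray(self.S, dtype=float)
        if S.ndim != 3 or S.shape[1] != S.shape[2]:
            raise ValueError("S must be (m, n, n)")
        object.__setattr__(self, "S", S)


def l1_distance(w_a: Fingerprint | np.ndarray, w_b: Fingerprint | np.ndarray) -> float:
    """Sum of absolute differences between two fingerprints."""
    a = w_a.w if isinstance(w_a, Fingerprint) else np.asarray(w_a, dtype=float)
    b = w_b.w if isinstance(w_b, Fingerprint) else np.asarray(w_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    return float(np.abs(a - b).sum())


def _distance_stack(cohort: CohortFingerprints) -> np.ndarray:
    """(m, n, n) stack of per-node pairwise L1 distances between subjects."""
    n, m = cohort.n_subjects, cohort.m
    D = np.empty((m, n, n))
    for k in range(m):
        # rows of each subject's matrix at node k: (n, m) observations
        D[k] = squareform(pdist(cohort.W_stack[:, k, :], metric="cityblock"))
    return D


def compute_alpha(cohort: CohortFingerprints) -> float:
    """Half of the maximum pairwise L1 distance over all nodes and subjects."""
    d_max = float(_distance_stack(cohort).max())
    if d_max == 0:
        raise ValueError(
            "all fingerprints are identical across the cohort (alpha = 0); "
            "the similarity transform is undefined"
        )
    return 0.5 * d_max


def similarity_stack(cohort: CohortFingerprints, alpha: float) -> SimilarityStack:
    """Exponential similarity ``exp(-d/alpha)`` for every node and pair."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    S = np.exp(-_distance_stack(cohort) / alpha)
    return SimilarityStack(alpha=alpha, S=S)
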