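"""Edge-level post hoc localization with a pseudo-t statistic.

Once a node's fingerprint is flagged as group-different, each of its m-1
connection probabilities is compared between the two groups with a
two-sample permutation test.  The observed group mean difference
``D = mean(group1) - mean(group2)`` is standardized by the mean and SD of
its permutation distribution::

    pseudo_t = (D_obs - mean_perm(D)) / sd_perm(D)

With group 1 = controls and group 2 = patients, a negative pseudo-t means
the (relative) connection probability is larger in patients.  The test is
two-sided, since both reduced and increased probabilities are of interest.

Because the connection probabilities of one node's fingerprint are
normalized independently of every other node's, multiple-comparison
correction is performed separately within each flagged node (BH-FDR over
its m-1 edges only).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .fingerprint import RegionAtlas
from .grouptest import (
    DEFAULT_N_PERMUTATIONS,
    DEFAULT_Q_THRESHOLD,
    GroupDesign,
    fdr_adjust,
    relabelings,
)
from .similarity import CohortFingerprints

_TIE_TOL = 1e-12


def _perm_mean_diffs(
    V: np.ndarray,
    codes: np.ndarray,
    N: int,
    rng: np.random.Generator,
    exhaustive: bool | str = "auto",
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Observed and permuted group-mean differences for columns of V.

    V is (n_subjects, n_variables); codes are 0 (group 1) / 1 (group 2).
    Returns (D_obs (E,), D_all (R, E), is_exhaustive) where D_all contains
    the full permutation distribution used for the p-value (the observed
    assignment included).
    """
    codes = np.asarray(codes, dtype=np.int64)
    n1 = int((codes == 0).sum())
    n2 = int((codes == 1).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 subjects")
    perms, is_exhaustive = relabelings(codes, N, rng, exhaustive)
    # weight +1/n1 on group-1 positions, -1/n2 on group-2 positions
    L = np.where(perms == 0, 1.0 / n1, -1.0 / n2)
    D_perm = L @ V
    w_obs = np.where(codes == 0, 1.0 / n1, -1.0 / n2)
    D_obs = w_obs @ V
    D_all = D_perm if is_exhaustive else np.vstack([D_obs, D_perm])
    return D_obs, D_all, is_exhaustive


def _pseudo_t_and_p(
    D_obs: np.ndarray, D_all: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    mu = D_all.mean(axis=0)
    sd = D_all.std(axis=0, ddof=1)
    degenerate = sd <= _TIE_TOL
    if np.any(degenerate):
        warnings.warn(
            f"{int(degenerate.sum())} variable(s) have a degenerate permutation "
            "distribution (all pooled values identical); pseudo_t=0, p=1"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(degenerate, 0.0, (D_obs - mu) / sd)
    extreme = np.abs(D_all - mu) >= np.abs(D_obs - mu) - _TIE_TOL
    p = extreme.sum(axis=0) / D_all.shape[0]
    p = np.where(degenerate, 1.0, p)
    return t, p


def edge_permutation_test(
    x: np.ndarray,
    y: np.ndarray,
    N: int = DEFAULT_N_PERMUTATIONS,
    seed: int | np.random.Generator | None = 0,
    exhaustive: bool | str = "auto",
) -> tuple[float, float]:
    """Two-sided two-sample permutation test with pseudo-t for one edge."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    V = np.concatenate([x, y])[:, None]
    codes = np.concatenate([np.zeros(len(x), dtype=int), np.ones(len(y), dtype=int)])
    D_obs, D_all, _ = _perm_mean_diffs(V, codes, N, rng, exhaustive)
    t, p = _pseudo_t_and_p(D_obs, D_all)
    return float(t[0]), float(p[0])


def two_sample_permutation(
    x: np.ndarray,
    y: np.ndarray,
    N: int = DEFAULT_N_PERMUTATIONS,
    seed: int | np.random.Generator | None = 0,
    exhaustive: bool | str = "auto",
) -> float:
    """Two-sided permutation p-value for a difference in group means.

    General-purpose utility (demographic comparisons and the like); the
    same machinery as :func:`edge_permutation_test`, returning p only.
    """
    return edge_permutation_test(x, y, N=N, seed=seed, exhaustive=exhaustive)[1]


def posthoc_node(
    cohort: CohortFingerprints,
    node: int,
    design: GroupDesign,
    N: int = DEFAULT_N_PERMUTATIONS,
    seed: int | np.random.Generator | None = 0,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    exhaustive: bool | str = "auto",
) -> pd.DataFrame:
    """Edge-wise permutation tests for all targets of one flagged node.

    The tested quantity per subject is the node's *relative* connection
    probability to each target, i.e. row ``node`` of the subject's
    fingerprint matrix.  FDR correction is applied within the node only.

    Returns a DataFrame with one row per target (the node itself excluded):
    target, pseudo_t, p, q, reject, per-group means and a direction flag.
    """
    if len(design.group_names) != 2:
        raise ValueError("post hoc edge tests are defined for two groups")
    m = cohort.m
    if not (0 <= node < m):
        raise ValueError(f"node index {node} out of range")
    codes = design.codes
    targets = np.array([j for j in range(m) if j != node])
    V = cohort.W_stack[:, node, targets]  # (n_subjects, m-1)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    D_obs, D_all, _ = _perm_mean_diffs(V, codes, N, rng, exhaustive)
    t, p = _pseudo_t_and_p(D_obs, D_all)
    q, reject = fdr_adjust(p, q_threshold)
    g1, g2 = design.group_names
    mean1 = V[codes == 0].mean(axis=0)
    mean2 = V[codes == 1].mean(axis=0)
    labels = (
        [cohort.atlas.labels[j] for j in targets]
        if cohort.atlas is not None
        else [str(j) for j in targets]
    )
    direction = np.where(t < 0, f"higher in {g2}", f"higher in {g1}")
    table = pd.DataFrame(
        {
            "target": labels,
            "pseudo_t": t,
            "p": p,
            "q": q,
            "reject": reject,
            f"mean_{g1}": mean1,
            f"mean_{g2}": mean2,
            "direction": direction,
        }
    )
    table.attrs.update(node=node, N=N, q_threshold=q_threshold)
    return table
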