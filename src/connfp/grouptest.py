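"""Node-level group test: within- vs between-group fingerprint similarity.

A node whose fingerprint is systematically different between groups makes
same-group subject pairs more similar than different-group pairs.  The test
statistic is therefore::

    T = mean{ s_ij : i<j, same group } - mean{ s_ij : i<j, different group }

and its null distribution is built by permuting the group assignment while
preserving group sizes.  With N-1 random relabelings the significance level
is the fraction of the N values (observed assignment included) that are
equal to or larger than the observed one, so p >= 1/N and the estimator is
valid.  When the number of distinct relabelings is at most N the test
switches to exhaustive enumeration and the p-value is exact.

Across nodes, p-values are corrected with the Benjamini-Hochberg step-up
FDR procedure (threshold q = 0.05 by default).  The test applies unchanged
to more than two groups: within-group pairs are pooled over all groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests
from sympy.utilities.iterables import multiset_permutations

from .similarity import SimilarityStack

DEFAULT_N_PERMUTATIONS = 50_000
DEFAULT_Q_THRESHOLD = 0.05


@dataclass(frozen=True)
class GroupDesign:
    """Group label per subject, in cohort subject order."""

    labels: tuple[str, ...]

    def __post_init__(self):
        if len(self.group_names) < 2:
            raise ValueError("need at least 2 groups")
        small = [g for g, c in zip(self.group_names, self.sizes) if c < 2]
        if small:
            raise ValueError(
                f"groups {small} have fewer than 2 subjects: no within-group pairs"
            )

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def group_names(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for g in self.labels:
            seen.setdefault(g)
        return tuple(seen)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(self.labels.count(g) for g in self.group_names)

    @property
    def codes(self) -> np.ndarray:
        lookup = {g: c for c, g in enumerate(self.group_names)}
        return np.array([lookup[g] for g in self.labels], dtype=np.int64)

    @property
    def n_distinct_relabelings(self) -> int:
        num = math.factorial(self.n)
        for c in self.sizes:
            num //= math.factorial(c)
        return num


def _pair_index(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def _within_mask(codes: np.ndarray, iu, ju) -> np.ndarray:
    return codes[iu] == codes[ju]


def group_statistic(S: np.ndarray, design: GroupDesign) -> float:
    """Average within-group minus average between-group similarity."""
    S = np.asarray(S, dtype=float)
    if S.shape != (design.n, design.n):
        raise ValueError("similarity matrix does not match design size")
    iu, ju = _pair_index(design.n)
    w = _within_mask(design.codes, iu, ju)
    vals = S[iu, ju]
    return float(vals[w].mean() - vals[~w].mean())


def count_distinct_relabelings(codes: np.ndarray) -> int:
    """Number of distinct size-preserving group assignments (multinomial)."""
    n = len(codes)
    num = math.factorial(n)
    for c in np.bincount(np.asarray(codes, dtype=np.int64)):
        num //= math.factorial(int(c))
    return num


def relabelings(codes: np.ndarray, N: int, rng: np.random.Generator,
                exhaustive: bool | str = "auto") -> tuple[np.ndarray, bool]:
    """Permuted group-code arrays: (R, n) plus a flag for exhaustive mode.

    Exhaustive mode enumerates every distinct size-preserving assignment
    (observed one included) and yields exact p-values; it is entered
    whenever the number of distinct assignments is at most N.  Monte-Carlo
    mode draws N-1 uniform relabelings without enforcing uniqueness.
    """
    codes = np.asarray(codes, dtype=np.int64)
    if exhaustive == "auto":
        exhaustive = count_distinct_relabelings(codes) <= N
    if exhaustive:
        perms = np.array(list(multiset_permutations(codes.tolist())), dtype=np.int64)
        return perms, True
    n = len(codes)
    order = rng.permuted(
        np.broadcast_to(np.arange(n), (N - 1, n)).copy(), axis=1
    )
    return codes[order], False


def permutation_pvalue(
    S: np.ndarray,
    design: GroupDesign,
    N: int = DEFAULT_N_PERMUTATIONS,
    seed: int | np.random.Generator | None = 0,
    exhaustive: bool | str = "auto",
) -> tuple[float, float]:
    """One-sided permutation p-value for one node's similarity matrix."""
    table = test_all_nodes(
        SimilarityStack(alpha=1.0, S=np.asarray(S, dtype=float)[None]),
        design, N=N, seed=seed, exhaustive=exhaustive,
    )
    return float(table["T"].iloc[0]), float(table["p"].iloc[0])


def test_all_nodes(
    sim: SimilarityStack,
    design: GroupDesign,
    N: int = DEFAULT_N_PERMUTATIONS,
    seed: int | np.random.Generator | None = 0,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    exhaustive: bool | str = "auto",
    node_labels: list[str] | None = None,
) -> pd.DataFrame:
    """Per-node permutation test with BH-FDR across nodes.

    The same set of relabelings is applied to every node (the nodes share
    one subject cohort, so this is the natural coupling and is much faster
    than redrawing per node).

    Returns a DataFrame with columns node, T, p, q, reject and attrs
    recording N, seed, q_threshold and whether enumeration was exhaustive.
    """
    if N < 2:
        raise ValueError("N must be at least 2")
    S = sim.S
    m, n = S.shape[0], S.shape[1]
    if n != design.n:
        raise ValueError("similarity stack does not match design size")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    iu, ju = _pair_index(n)
    vals = S[:, iu, ju]  # (m, n_pairs)
    w_obs = _within_mask(design.codes, iu, ju)
    n_within = int(w_obs.sum())
    n_between = w_obs.size - n_within
    tot = vals.sum(axis=1)
    scale = 1.0 / n_within + 1.0 / n_between

    # T = within_sum*(1/nw + 1/nb) - total_sum/nb, since between = total - within
    T_obs = vals @ w_obs.astype(float) * scale - tot / n_between

    perms, is_exhaustive = relabelings(design.codes, N, rng, exhaustive)
    masks = (perms[:, iu] == perms[:, ju]).astype(float)  # (R, n_pairs)
    T_perm = vals @ masks.T * scale - tot[:, None] / n_between  # (m, R)

    ge = (T_perm >= T_obs[:, None] - 1e-12).sum(axis=1)
    if is_exhaustive:
        p = ge / perms.shape[0]  # identity assignment is among the perms
    else:
        p = (1 + ge) / N  # observed assignment counts itself

    q, reject = fdr_adjust(p, q_threshold)
    labels = node_labels if node_labels is not None else [str(k) for k in range(m)]
    table = pd.DataFrame(
        {"node": labels, "T": T_obs, "p": p, "q": q, "reject": reject}
    )
    table.attrs.update(
        N=N, q_threshold=q_threshold, exhaustive=is_exhaustive,
        n_relabelings=perms.shape[0] + (0 if is_exhaustive else 1),
        group_sizes=design.sizes,
    )
    return table


def fdr_adjust(
    pvals: np.ndarray, q_threshold: float = DEFAULT_Q_THRESHOLD, method: str = "bh"
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and rejection flags.

    ``method='by'`` selects the Benjamini-Yekutieli variant (valid under
    arbitrary dependence) as a config option; BH is the default.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    mt_method = {"bh": "fdr_bh", "by": "fdr_by"}[method]
    reject, q, _, _ = multipletests(p, alpha=q_threshold, method=mt_method)
    return q, reject
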