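"""Radial fingerprint diagrams and bar graphs of group mean profiles.

The radial ("fingerprint") diagram shows one node's connection
probabilities to a selected subset of targets: angular position encodes
the target, radial distance the probability, with one polyline plus a
confidence band per group and asterisks at targets flagged by the post hoc
tests.  Target selection is the top-K strongest mean probabilities with
flagged targets force-included first, so the figure is a pure function of
the cohort and the plot spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .grouptest import GroupDesign
from .similarity import CohortFingerprints

DEFAULT_RINGS = (0.05, 0.1, 0.15, 0.2, 0.25, 0.3)


@dataclass(frozen=True)
class RadialPlotSpec:
    """Layout parameters for a fingerprint diagram."""

    top_k: int = 12
    ci: float = 0.95
    scale: str = "linear"  # or "log"
    rings: tuple[float, ...] = DEFAULT_RINGS
    group_colors: tuple[str, ...] = ("tab:blue", "tab:red")

    def __post_init__(self):
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if not (0 < self.ci < 1):
            raise ValueError("CI level must lie in (0, 1)")
        if self.scale not in ("linear", "log"):
            raise ValueError("scale must be 'linear' or 'log'")


def select_targets(
    cohort: CohortFingerprints,
    node: int,
    spec: RadialPlotSpec,
    flagged: list[int] | None = None,
) -> list[int]:
    """Top-K strongest mean-probability targets, flagged ones included first.

    Deterministic: ties in mean probability are broken by target index.
    """
    m = cohort.m
    mean_w = cohort.W_stack[:, node, :].mean(axis=0)
    order = [j for j in np.argsort(-mean_w, kind="stable") if j != node]
    chosen: list[int] = list(dict.fromkeys(flagged or []))
    for j in order:
        if len(chosen) >= spec.top_k:
            break
        if j not in chosen:
            chosen.append(int(j))
    if not chosen:
        raise ValueError("empty target selection")
    return chosen[: max(spec.top_k, len(dict.fromkeys(flagged or [])))]


def _group_mean_ci(values: np.ndarray, ci: float) -> tuple[np.ndarray, np.ndarray]:
    """Mean and t-based CI half-width per column of (subjects, targets)."""
    n = values.shape[0]
    mean = values.mean(axis=0)
    if n < 2:
        return mean, np.zeros_like(mean)
    se = values.std(axis=0, ddof=1) / np.sqrt(n)
    half = stats.t.ppf(0.5 + ci / 2, df=n - 1) * se
    return mean, half


def radial_plot(
    cohort: CohortFingerprints,
    node: int,
    design: GroupDesign | None,
    spec: RadialPlotSpec = RadialPlotSpec(),
    edge_table=None,
    out: str | Path | None = None,
):
    """Render the fingerprint diagram of one node; returns the Figure.

    ``edge_table`` is an optional post hoc result for this node; its
    rejected targets are force-included in the selection and marked with
    asterisks.  With no design (or a single group) one polyline is drawn.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = (
        list(cohort.atlas.labels)
        if cohort.atlas
        else [str(i) for i in range(cohort.m)]
    )
    flagged: list[int] = []
    if edge_table is not None:
        flagged = [
            labels.index(t) for t in edge_table.loc[edge_table["reject"], "target"]
        ]
    targets = select_targets(cohort, node, spec, flagged)
    theta = np.linspace(0, 2 * np.pi, len(targets), endpoint=False)

    def transform(r: np.ndarray) -> np.ndarray:
        if spec.scale == "log":
            floor = min(spec.rings) / 10
            return np.log10(np.maximum(r, floor) / floor)
        return r

    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
    groups = design.group_names if design is not None else ("all",)
    member = (
        {g: [i for i, l in enumerate(design.labels) if l == g] for g in groups}
        if design is not None
        else {"all": list(range(cohort.n_subjects))}
    )
    closed = np.r_[theta, theta[:1]]
    for g, color in zip(groups, spec.group_colors):
        vals = cohort.W_stack[member[g]][:, node, targets]
        mean, half = _group_mean_ci(vals, spec.ci)
        lo, hi = transform(np.maximum(mean - half, 0)), transform(mean + half)
        ax.plot(closed, np.r_[transform(mean), transform(mean)[:1]],
                color=color, label=str(g))
        ax.fill_between(closed, np.r_[lo, lo[:1]], np.r_[hi, hi[:1]],
                        color=color, alpha=0.2)
    for j, ang in zip(targets, theta):
        if j in flagged:
            ax.annotate("*", (ang, ax.get_rmax() * 0.97), color="black",
                        ha="center", fontsize=14)
    ax.set_xticks(theta)
    ax.set_xticklabels([labels[j] for j in targets], fontsize=7)
    ring_pos = transform(np.asarray(spec.rings))
    ax.set_rgrids(ring_pos, labels=[f"{r:g}" for r in spec.rings], fontsize=6)
    ax.set_title(f"Connectional fingerprint: {labels[node]}", fontsize=10)
    if len(groups) > 1:
        ax.legend(loc="lower right", bbox_to_anchor=(1.1, -0.1), fontsize=8)
    if out is not None:
        fig.savefig(out, bbox_inches="tight", dpi=150)
        plt.close(fig)
    return fig
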