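"""Pearson correlation of flagged connection probabilities with clinical scores.

For each flagged (seed, target) connection probability and each clinical
score column (e.g. PANSS items or factor sums), the sample Pearson r and
its two-sided t-based p-value (n-2 df) are reported.  Missing scores are
dropped pairwise.  The output is explicitly *not* corrected for multiple
comparisons; it is an exploratory companion to the main tests.

By default correlations are computed in the second group only (the patient
group in a case-control design), since symptom scores are typically defined
for patients; a subset flag overrides this.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .grouptest import GroupDesign
from .similarity import CohortFingerprints

MIN_COMPLETE_PAIRS = 3


def correlate_edges(
    edges: list[tuple[int, int]],
    cohort: CohortFingerprints,
    clinical: pd.DataFrame,
    design: GroupDesign | None = None,
    subset: str | list[str] | None = "second",
) -> pd.DataFrame:
    """Correlate connection probabilities with clinical score columns.

    Parameters
    ----------
    edges
        (seed node, target) index pairs, typically the rejected rows of the
        post hoc tables.
    clinical
        DataFrame indexed by subject id with numeric score columns; NaN
        allowed (pairwise-dropped).
    subset
        ``"second"`` (default) restricts to the design's second group;
        ``None`` uses every cohort subject; a list of subject ids selects
        those explicitly.

    Returns
    -------
    DataFrame with columns seed, target, score, r, p, n and attrs noting
    that the p-values are uncorrected.  Zero-variance pairs produce NaN
    rows with a warning.
    """
    if subset == "second":
        if design is None:
            raise ValueError("subset='second' requires the group design")
        second = design.group_names[1]
        keep = [s for s, g in zip(cohort.subjects, design.labels) if g == second]
    elif subset is None:
        keep = list(cohort.subjects)
    else:
        unknown = set(subset) - set(cohort.subjects)
        if unknown:
            raise ValueError(f"unknown subjects in subset: {sorted(unknown)}")
        keep = list(subset)

    idx = [cohort.subjects.index(s) for s in keep]
    labels = cohort.atlas.labels if cohort.atlas else None
    rows = []
    for seed, target in edges:
        probs = pd.Series(cohort.W_stack[idx, seed, target], index=keep)
        for score in clinical.columns:
            y = clinical[score].reindex(keep)
            pair = pd.concat([probs, y], axis=1, keys=["x", "y"]).dropna()
            n = len(pair)
            name_s = labels[seed] if labels else str(seed)
            name_t = labels[target] if labels else str(target)
            if n < MIN_COMPLETE_PAIRS:
                raise ValueError(
                    f"edge ({name_s}, {name_t}) x {score}: only {n} complete "
                    f"pairs (need >= {MIN_COMPLETE_PAIRS})"
                )
            if pair["x"].nunique() == 1 or pair["y"].nunique() == 1:
                warnings.warn(
                    f"zero variance for edge ({name_s}, {name_t}) x {score}; "
                    "correlation undefined"
                )
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(pair["x"], pair["y"])
            rows.append((name_s, name_t, score, float(r), float(p), n))
    out = pd.DataFrame(rows, columns=["seed", "target", "score", "r", "p", "n"])
    out.attrs["multiplicity_corrected"] = False
    return out
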