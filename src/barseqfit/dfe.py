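"""Distribution-of-fitness-effects classification.

The isogenic barcoded control collection calibrates the noise floor of the
pooled assay: in the study design, 98.2% of control strains fell within
±10% fitness, motivating a ±0.10 cutoff for calling a strain beneficial or
deleterious.  Classification is strict — a strain is beneficial only if its
mean fitness exceeds +cutoff, deleterious only below -cutoff; values on the
boundary are neutral.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

__all__ = [
    "control_window_fraction",
    "classify_fitness",
    "dfe_summary",
    "DfeSummary",
]

CLASSES = ("deleterious", "neutral", "beneficial")


def control_window_fraction(control_fitness, halfwidth: float = 0.10) -> float:
    """Fraction of control fitness values inside [-halfwidth, +halfwidth]."""
    v = np.asarray(control_fitness, dtype=float)
    if v.size == 0:
        raise ValueError("empty control fitness vector")
    return float(((v >= -halfwidth) & (v <= halfwidth)).mean())


def classify_fitness(mean_fitness, cutoff: float = 0.10):
    """beneficial iff fitness > +cutoff, deleterious iff < -cutoff, else neutral.

    Accepts a scalar (returns a label) or an array-like (returns an array of
    labels).  Boundary values are neutral (strict inequalities).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    v = np.asarray(mean_fitness, dtype=float)
    labels = np.where(v > cutoff, "beneficial", np.where(v < -cutoff, "deleterious", "neutral"))
    return labels.item() if np.isscalar(mean_fitness) else labels


@dataclass
class DfeSummary:
    """Class counts, per-condition beneficial sets, overlaps, and enrichment
    tests, per cutoff.

    ``class_counts``: cutoff -> {class: count of strain×condition events}.
    ``class_counts_dedup``: cutoff -> {class: count of distinct strains,
    taking each strain's most extreme call across conditions}.
    ``beneficial_by_condition``: cutoff -> {condition: set of strain ids}.
    ``overlap``: cutoff -> number of strains beneficial in >1 condition.
    ``control_fraction``: fraction of control calls inside the ±cutoff
    window at the primary cutoff.
    ``enrichment``: cutoff -> {direction: (chi2, p)} test-vs-control 2×2.
    """

    cutoffs: list
    class_counts: dict = field(default_factory=dict)
    class_counts_dedup: dict = field(default_factory=dict)
    beneficial_by_condition: dict = field(default_factory=dict)
    overlap: dict = field(default_factory=dict)
    control_fraction: float = float("nan")
    enrichment: dict = field(default_factory=dict)


def _enrichment_test(
    n_hit_test: int, n_test: int, n_hit_ctrl: int, n_ctrl: int, correction: bool
) -> tuple[float, float]:
    """2×2 chi-square: classified-vs-not × test-vs-control."""
    table = np.array(
        [[n_hit_test, n_test - n_hit_test], [n_hit_ctrl, n_ctrl - n_hit_ctrl]]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return float("nan"), 1.0
    stat, p, *_ = chi2_contingency(table, correction=correction)
    return float(stat), float(p)


def dfe_summary(
    fitness: pd.DataFrame,
    control_ids,
    cutoffs=(0.10, 0.05),
    correction: bool = False,
) -> DfeSummary:
    """Summarize the DFE of a tidy fitness table against control strains.

    ``fitness`` is the tidy output of the fitness stage (index strain_id,
    columns including ``condition`` and ``mean_fitness``).  ``control_ids``
    are the strains of the neutral control collection; every other strain is
    a test strain.  Per cutoff the summary counts strain×condition events in
    each class (and a per-strain deduplicated variant), collects
    per-condition beneficial sets and their cross-condition overlap, and
    tests beneficial/deleterious enrichment of test vs control strains with
    a 2×2 chi-square (uncorrected by default).
    """
    control_ids = set(control_ids)
    is_ctrl = fitness.index.isin(list(control_ids))
    test, ctrl = fitness[~is_ctrl], fitness[is_ctrl]
    summary = DfeSummary(cutoffs=list(cutoffs))

    if len(ctrl):
        summary.control_fraction = control_window_fraction(
            ctrl["mean_fitness"], halfwidth=cutoffs[0]
        )

    for cutoff in cutoffs:
        labels = pd.Series(
            classify_fitness(test["mean_fitness"].to_numpy(), cutoff),
            index=test.index,
        )
        summary.class_counts[cutoff] = {
            c: int((labels == c).sum()) for c in CLASSES
        }
        # dedup: a strain counts once, by its most extreme value across conditions
        extreme = test.groupby(level=0)["mean_fitness"].agg(
            lambda v: v.iloc[int(np.argmax(np.abs(v.to_numpy())))]
        )
        best = pd.Series(classify_fitness(extreme.to_numpy(), cutoff), index=extreme.index)
        summary.class_counts_dedup[cutoff] = {
            c: int((best == c).sum()) for c in CLASSES
        }
        by_cond = {}
        for cond, grp in test.groupby("condition"):
            lab = classify_fitness(grp["mean_fitness"].to_numpy(), cutoff)
            by_cond[cond] = set(grp.index[lab == "beneficial"])
        summary.beneficial_by_condition[cutoff] = by_cond
        counts = pd.Series(
            [sid for s in by_cond.values() for sid in s]
        ).value_counts() if by_cond else pd.Series(dtype=int)
        summary.overlap[cutoff] = int((counts > 1).sum())

        if len(ctrl) == 0:
            warnings.warn("no control strains; skipping enrichment tests")
            continue
        ctrl_labels = classify_fitness(ctrl["mean_fitness"].to_numpy(), cutoff)
        tests = {}
        for direction in ("beneficial", "deleterious"):
            tests[direction] = _enrichment_test(
                int((labels == direction).sum()),
                len(labels),
                int((ctrl_labels == direction).sum()),
                len(ctrl_labels),
                correction,
            )
        summary.enrichment[cutoff] = tests
    return summary
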