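"""Relative fitness from barcode counts by log-linear regression.

Per sample, each barcode count is increased by a pseudocount (default 10, to
avoid division by zero for strains that drop out) and normalized to a
frequency.  Fitness is the ordinary-least-squares slope of
log2(f_i(t)/f_i(0)) on generation t, restricted to the steady-state window
(generations 6–20 inclusive), in units of log2 per generation.  Replicate
screens are fitted independently and averaged.

Because every strain shares the same per-sample normalizing denominator and
the same population-mean growth term, pairwise slope differences satisfy
slope_i - slope_j = log2((1+s_i)/(1+s_j)) exactly in the absence of
sampling noise.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "normalize_counts",
    "log_ratio_matrix",
    "estimate_fitness",
    "average_replicates",
    "counts_to_fitness",
    "fitness_oracle",
]

DEFAULT_WINDOW = (6, 20)


def normalize_counts(counts, pseudocount: float = 10) -> np.ndarray:
    """(c_i + pseudocount) / sum_j (c_j + pseudocount); sums to 1."""
    c = np.asarray(counts, dtype=float)
    if c.size == 0:
        raise ValueError("empty count vector")
    if (c < 0).any():
        raise ValueError("counts must be >= 0")
    shifted = c + pseudocount
    return shifted / shifted.sum(axis=0, keepdims=c.ndim > 1)


def log_ratio_matrix(freqs: pd.DataFrame, t0: int = 0) -> pd.DataFrame:
    """log2(f_i(t) / f_i(t0)) for a strains × timepoint frequency table.

    Columns are generation numbers; the t0 column comes out all zeros.
    Zero frequencies are rejected — apply the pseudocount upstream.
    """
    if t0 not in freqs.columns:
        raise ValueError(f"reference timepoint {t0} not among columns {list(freqs.columns)}")
    vals = freqs.to_numpy(dtype=float)
    if (vals <= 0).any():
        raise ValueError(
            "zero or negative frequency encountered; counts must be "
            "pseudocount-normalized before taking log ratios"
        )
    ref = freqs[t0].to_numpy(dtype=float)[:, None]
    return pd.DataFrame(
        np.log2(vals / ref), index=freqs.index, columns=freqs.columns
    )


def estimate_fitness(
    log_ratios: pd.DataFrame,
    window: tuple[int, int] = DEFAULT_WINDOW,
    include_t0: bool = False,
) -> pd.Series:
    """Per-strain OLS slope of log ratio on generation within the window.

    Only timepoints t with window[0] <= t <= window[1] enter the fit (the
    generation-0 reference point is excluded unless ``include_t0``).  The
    intercept is free.  Units: log2 per generation.
    """
    lo, hi = window
    ts = [t for t in log_ratios.columns if lo <= t <= hi]
    if include_t0 and 0 in log_ratios.columns and 0 not in ts:
        ts = [0] + ts
    if len(ts) < 2:
        raise ValueError(
            f"need >= 2 timepoints in window [{lo}, {hi}], have {ts}"
        )
    t = np.asarray(ts, dtype=float)
    y = log_ratios[ts].to_numpy(dtype=float).T  # timepoints × strains
    x = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    return pd.Series(coef[1], index=log_ratios.index, name="fitness")


def average_replicates(per_replicate: pd.DataFrame) -> pd.DataFrame:
    """Average replicate fitness values per strain.

    ``per_replicate`` has one column per replicate (NaN where a strain was
    not measured in that screen).  Returns columns ``mean_fitness`` (mean of
    available replicates) and ``n_replicates``.
    """
    out = pd.DataFrame(index=per_replicate.index)
    out["mean_fitness"] = per_replicate.mean(axis=1, skipna=True)
    out["n_replicates"] = per_replicate.notna().sum(axis=1)
    return out[out["n_replicates"] >= 1]


def counts_to_fitness(
    counts: pd.DataFrame,
    pseudocount: float = 10,
    window: tuple[int, int] = DEFAULT_WINDOW,
    min_total: int = 20,
    include_t0: bool = False,
) -> pd.DataFrame:
    """Full counts → fitness pipeline for a multi-screen counts table.

    ``counts`` carries a (condition, replicate, timepoint) column MultiIndex.
    Per screen (condition × replicate): strains with fewer than ``min_total``
    reads summed over the screen's samples are dropped from that screen, the
    remaining counts are pseudocount-normalized per sample, log2 ratios to
    generation 0 are regressed on generation over the window, and replicate
    slopes are averaged.

    Returns a tidy frame: strain_id (index), condition, per-replicate
    columns ``rep<k>``, ``mean_fitness``, ``n_replicates``.
    """
    results = []
    for cond in counts.columns.get_level_values("condition").unique():
        sub = counts[cond]
        reps = sub.columns.get_level_values("replicate").unique()
        slopes = {}
        for rep in reps:
            screen = sub[rep]  # strains × timepoints
            screen = screen.loc[screen.sum(axis=1) >= min_total]
            # normalize per sample: strains are axis 0, one column per timepoint
            freqs = pd.DataFrame(
                normalize_counts(screen.to_numpy(), pseudocount),
                index=screen.index,
                columns=screen.columns,
            )
            ratios = log_ratio_matrix(freqs, t0=0)
            slopes[f"rep{rep}"] = estimate_fitness(ratios, window, include_t0)
        per_rep = pd.DataFrame(slopes)
        avg = average_replicates(per_rep)
        block = per_rep.join(avg, how="right")
        block.insert(0, "condition", cond)
        results.append(block)
    return pd.concat(results)


def fitness_oracle(s: np.ndarray, weights: Sequence[float] | None = None) -> np.ndarray:
    """Expected regression fitness for true selection coefficients ``s``.

    The common population term shifts all slopes equally; relative to the
    (initial-frequency-weighted) pool mean the expected slope is
    log2((1+s_i)/(1+s̄)).  Exact for pairwise differences; the small
    time-varying part of the population term cancels there.
    """
    s = np.asarray(s, dtype=float)
    w = np.full_like(s, 1.0 / s.size) if weights is None else np.asarray(weights)
    sbar = float(np.sum(w * s) / np.sum(w))
    return np.log2((1.0 + s) / (1.0 + sbar))
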