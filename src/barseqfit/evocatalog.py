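"""Analyses of a mutation catalog compiled from evolve-and-resequence studies.

The catalog ("E set") holds one record per (gene, sample) mutation event
observed in sequenced evolved clones or populations, annotated with the
condition, ploidy of the background, sample type, and a SNPeff-style
mutation class.  This module computes:

* impact classes (high / moderate / low / modifier) from mutation classes;
* gene-level recurrence across samples;
* per-class mutation-spectrum contingency between haploids and diploids
  (2×2 chi-square with Yates correction, Fisher by flag) plus an overall
  class × ploidy heterogeneity test (Monte-Carlo Fisher);
* gene-length bias of recurrently mutated genes (Wilcoxon rank-sum);
* driver prediction by joining mutated genes to the single-gene
  amplification/deletion fitness screen in the same condition; and
* fitness comparison of screen-beneficial genes found vs not found among
  the evolved mutations (Wilcoxon rank-sum).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2_contingency, fisher_exact, mannwhitneyu, random_table

__all__ = [
    "MCLASSES",
    "IMPACT_OF",
    "ContingencyResult",
    "impact_of",
    "validate_catalog",
    "recurrence_counts",
    "ploidy_contingency",
    "heterogeneity_test",
    "length_bias",
    "predict_drivers",
    "per_sample_driver_stats",
    "found_vs_notfound",
]

# class -> predicted functional impact (SNPeff convention)
IMPACT_OF = {
    "stop_gained": "high",
    "start_lost": "high",
    "stop_lost": "high",
    "frameshift": "high",
    "nonsynonymous": "moderate",
    "codon_indel": "moderate",
    "synonymous": "low",
    "upstream": "modifier",
    "intron": "modifier",
    "intergenic": "modifier",
}
MCLASSES = tuple(IMPACT_OF)

CATALOG_COLUMNS = ("gene", "sample_id", "condition", "ploidy", "sample_type", "mclass")


@dataclass(frozen=True)
class ContingencyResult:
    table: np.ndarray
    statistic: float
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


def impact_of(mclass: str) -> str:
    """Map a mutation class to its impact (high/moderate/low/modifier)."""
    try:
        return IMPACT_OF[mclass]
    except KeyError:
        raise ValueError(
            f"unknown mutation class {mclass!r}; expected one of {MCLASSES}"
        ) from None


def validate_catalog(catalog: pd.DataFrame) -> pd.DataFrame:
    """Check required columns and the class vocabulary; adds an ``impact``
    column. One row = one (gene, sample) mutation event."""
    missing = [c for c in CATALOG_COLUMNS if c not in catalog.columns]
    if missing:
        raise ValueError(f"catalog missing columns: {missing}")
    bad = set(catalog["mclass"]) - set(MCLASSES)
    if bad:
        raise ValueError(f"unknown mutation classes: {sorted(bad)}")
    bad_pl = set(catalog["ploidy"]) - {"haploid", "diploid"}
    if bad_pl:
        raise ValueError(f"ploidy must be haploid/diploid, got {sorted(bad_pl)}")
    out = catalog.copy()
    out["impact"] = out["mclass"].map(IMPACT_OF)
    return out


def recurrence_counts(
    catalog: pd.DataFrame, condition: str | None = None
) -> tuple[pd.Series, dict]:
    """Per-gene number of distinct samples mutated, with recurrence summary.

    A gene mutated several times within the same sample counts once.
    Returns (counts, {"n_genes", "recurrent" (>1 sample), "highly_recurrent"
    (>5 samples)}).
    """
    sub = catalog if condition is None else catalog[catalog["condition"] == condition]
    if sub.empty:
        return pd.Series(dtype=int, name="n_samples"), {
            "n_genes": 0, "recurrent": 0, "highly_recurrent": 0,
        }
    counts = (
        sub.drop_duplicates(["gene", "sample_id"]).groupby("gene").size()
        .rename("n_samples").sort_values(ascending=False)
    )
    return counts, {
        "n_genes": int(len(counts)),
        "recurrent": int((counts > 1).sum()),
        "highly_recurrent": int((counts > 5).sum()),
    }


def ploidy_contingency(
    catalog: pd.DataFrame, mclass: str, method: str = "chi2_yates"
) -> ContingencyResult:
    """2×2 test of one mutation class vs all others across ploidies.

    Table rows are [mclass, other classes], columns [haploid, diploid],
    filled with mutation-event counts.  Default is chi-square with Yates
    continuity correction; ``method="fisher"`` gives the two-sided exact
    test and ``"chi2"`` the uncorrected statistic.
    """
    impact_of(mclass)  # vocabulary check
    ploidies = catalog["ploidy"].to_numpy()
    if not ({"haploid", "diploid"} <= set(ploidies)):
        raise ValueError("both ploidies must be present in the catalog")
    is_cls = (catalog["mclass"] == mclass).to_numpy()
    table = np.array(
        [
            [int((is_cls & (ploidies == "haploid")).sum()),
             int((is_cls & (ploidies == "diploid")).sum())],
            [int((~is_cls & (ploidies == "haploid")).sum()),
             int((~is_cls & (ploidies == "diploid")).sum())],
        ]
    )
    return contingency_2x2(table, method)


def contingency_2x2(table: np.ndarray, method: str = "chi2_yates") -> ContingencyResult:
    """Run a 2×2 test on an explicit table (counts >= 0, nonzero margins)."""
    table = np.asarray(table, dtype=int)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError(f"zero margin in contingency table:\n{table}")
    if method == "fisher":
        stat, p = fisher_exact(table, alternative="two-sided")
        return ContingencyResult(table, float(stat), float(p), "fisher_exact")
    if method not in ("chi2", "chi2_yates"):
        raise ValueError(f"unknown method {method!r}")
    stat, p, *_ = chi2_contingency(table, correction=(method == "chi2_yates"))
    return ContingencyResult(table, float(stat), float(p), method)


def _log_table_prob(table: np.ndarray) -> float:
    """Log probability of a contingency table under fixed margins
    (multivariate hypergeometric); the margin-dependent constant is shared
    by all tables with the same margins and may be ignored for comparisons."""
    t = np.asarray(table)
    return (
        gammaln(t.sum(axis=1) + 1).sum()
        + gammaln(t.sum(axis=0) + 1).sum()
        - gammaln(t.sum() + 1)
        - gammaln(t + 1).sum()
    )


def heterogeneity_test(
    catalog: pd.DataFrame,
    n_mc: int = 20000,
    seed: int = 0,
    by: str = "mclass",
) -> ContingencyResult:
    """Overall class × ploidy heterogeneity, Monte-Carlo Fisher exact.

    Builds the full k×2 table of mutation classes (or impacts, ``by=
    "impact"``) by ploidy and estimates the two-sided Fisher p-value by
    sampling tables with the observed margins: p = P(prob(table) <=
    prob(observed)), with the +1 correction so p is never exactly 0.
    """
    col = catalog[by] if by in catalog.columns else catalog["mclass"].map(IMPACT_OF)
    table = pd.crosstab(col, catalog["ploidy"]).to_numpy()
    table = table[table.sum(axis=1) > 0][:, ::-1] if table.shape[1] == 2 else table
    if table.shape[1] < 2:
        raise ValueError("both ploidies must be present")
    obs_lp = _log_table_prob(table)
    rng = np.random.default_rng(seed)
    draws = random_table(table.sum(axis=1), table.sum(axis=0)).rvs(
        n_mc, random_state=rng
    )
    lps = (
        -gammaln(draws + 1).sum(axis=(1, 2))
    )  # margin terms are constant across draws
    obs = -gammaln(np.asarray(table) + 1).sum()
    p = (np.count_nonzero(lps <= obs + 1e-9) + 1) / (n_mc + 1)
    return ContingencyResult(table, float("nan"), float(p), f"fisher_mc[{n_mc}]")


def length_bias(
    catalog: pd.DataFrame, annotations: pd.DataFrame
) -> tuple[float, float, pd.DataFrame]:
    """Are recurrently mutated genes longer than singletons?

    ``annotations`` maps gene -> length (bp).  Splits catalog genes into
    recurrent (mutated in >1 sample) and singleton groups and compares their
    lengths with a two-sided Wilcoxon rank-sum test (exact for small
    groups).  Genes without a length are dropped with a warning.  Returns
    (statistic, p_value, per-group summary frame).
    """
    counts, _ = recurrence_counts(catalog)
    lengths = annotations.set_index("gene")["length"] if "gene" in annotations else annotations["length"]
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    missing = counts.index.difference(lengths.index)
    if len(missing):
        warnings.warn(f"dropping {len(missing)} genes without length annotation")
        counts = counts.drop(missing)
    recurrent = lengths[counts.index[counts > 1]]
    singleton = lengths[counts.index[counts == 1]]
    if recurrent.empty or singleton.empty:
        raise ValueError("need non-empty recurrent and singleton groups")
    stat, p = mannwhitneyu(recurrent, singleton, alternative="two-sided", method="auto")
    summary = pd.DataFrame(
        {
            "n": [len(recurrent), len(singleton)],
            "median_length": [recurrent.median(), singleton.median()],
        },
        index=["recurrent", "singleton"],
    )
    return float(stat), float(p), summary


DRIVER_LABELS = (
    "predicted_beneficial",
    "intermediate",
    "not_predicted",
    "absent_from_screen",
)


def predict_drivers(
    catalog: pd.DataFrame,
    fitness: pd.DataFrame,
    cutoff: float = 0.10,
    secondary: float = 0.05,
    gene_column: str = "gene",
    strict: bool = False,
    agg: str = "max",
) -> pd.DataFrame:
    """Label each catalog mutation by the screen fitness of its gene.

    For every mutation, take the best (maximum, or mean with ``agg="mean"``)
    replicate-averaged fitness of its gene over all screened collections in
    the SAME condition:

    * ``predicted_beneficial``: best fitness >= cutoff;
    * ``intermediate``: secondary <= best fitness < cutoff;
    * ``not_predicted``: measured but below secondary;
    * ``absent_from_screen``: the gene/condition pair was not measured.

    ``fitness`` is the tidy fitness table (index strain_id, columns
    condition, mean_fitness and a gene column).  With ``strict=True``,
    mutation mechanism must match collection mechanism: high/moderate-impact
    (LOF-like) mutations only join deletion collections, modifiers
    (expression-changing) only plasmid-amplification collections; low-impact
    mutations join any collection.
    """
    if not secondary <= cutoff:
        raise ValueError("secondary threshold must be <= cutoff")
    if agg not in ("max", "mean"):
        raise ValueError("agg must be 'max' or 'mean'")
    fit = fitness.reset_index()
    if gene_column not in fit.columns:
        raise ValueError(f"fitness table lacks a {gene_column!r} column")
    out = catalog.copy()
    if strict:
        if "collection" not in fit.columns:
            raise ValueError("strict matching needs a 'collection' column")
        deletion = {"haploid_deletion", "het_diploid_deletion"}
        plasmid = {"low_copy_plasmid", "high_copy_plasmid"}
        allowed = {
            "high": deletion, "moderate": deletion,
            "modifier": plasmid,
            "low": deletion | plasmid | {"control"},
        }
        impacts = out["mclass"].map(IMPACT_OF)
        vals = []
        grouped = fit.groupby([gene_column, "condition"])
        for gene, cond, imp in zip(out["gene"], out["condition"], impacts):
            try:
                grp = grouped.get_group((gene, cond))
            except KeyError:
                vals.append(np.nan)
                continue
            grp = grp[grp["collection"].isin(allowed[imp])]
            vals.append(
                (grp["mean_fitness"].max() if agg == "max" else grp["mean_fitness"].mean())
                if len(grp) else np.nan
            )
        out["best_fitness"] = vals
    else:
        best = (
            fit.groupby([gene_column, "condition"])["mean_fitness"]
            .agg(agg)
            .rename("best_fitness")
        )
        keys = list(zip(out["gene"], out["condition"]))
        out["best_fitness"] = [best.get(k, np.nan) for k in keys]
    unmatched = out["condition"][~out["condition"].isin(fit["condition"].unique())].unique()
    if len(unmatched):
        warnings.warn(f"conditions absent from the screen: {sorted(unmatched)}")
    bf = out["best_fitness"]
    out["driver_label"] = np.select(
        [bf.isna(), bf >= cutoff, bf >= secondary],
        ["absent_from_screen", "predicted_beneficial", "intermediate"],
        default="not_predicted",
    )
    return out


def per_sample_driver_stats(annotated: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-sample driver counts and clone vs population comparison.

    From a ``predict_drivers`` output: per sample, the number of predicted
    beneficial mutations, the total mutations, and their ratio; group means
    for clones and populations; and a two-sided Wilcoxon rank-sum test of
    the per-sample ratios between the two sample types (run when both are
    present).
    """
    is_driver = annotated["driver_label"] == "predicted_beneficial"
    per = (
        annotated.assign(driver=is_driver)
        .groupby(["sample_id", "sample_type"], as_index=False)
        .agg(n_drivers=("driver", "sum"), n_total=("driver", "size"))
    )
    per["ratio"] = per["n_drivers"] / per["n_total"]
    groups = {
        st: grp for st, grp in per.groupby("sample_type")
    }
    stats = {
        "mean_drivers_per_sample": float(per["n_drivers"].mean()),
        "mean_driver_ratio": float(per["ratio"].mean()),
        "overall_driver_fraction": float(is_driver.sum() / len(annotated)),
        "mean_drivers_by_type": {
            st: float(g["n_drivers"].mean()) for st, g in groups.items()
        },
    }
    if {"clone", "population"} <= set(groups):
        stat, p = mannwhitneyu(
            groups["clone"]["ratio"],
            groups["population"]["ratio"],
            alternative="two-sided",
        )
        stats["clone_vs_population"] = {"statistic": float(stat), "p_value": float(p)}
    return per.set_index("sample_id"), stats


def found_vs_notfound(
    fitness: pd.DataFrame,
    catalog: pd.DataFrame,
    condition: str,
    cutoff: float = 0.10,
    exclude_genes=(),
    gene_column: str = "gene",
) -> dict:
    """Compare screen fitness of beneficial genes found vs not found evolved.

    Restricts the fitness table to ``condition`` and to beneficial entries
    (mean fitness > cutoff), then splits them by whether the gene carries a
    catalog mutation in the same condition.  ``exclude_genes`` removes named
    genes (e.g. a dominant driver) from both groups before testing.  Returns
    group values, medians, and the two-sided Wilcoxon rank-sum p-value
    (None with a warning if a group is empty).
    """
    fit = fitness.reset_index()
    sub = fit[(fit["condition"] == condition) & (fit["mean_fitness"] > cutoff)]
    sub = sub[~sub[gene_column].isin(set(exclude_genes))]
    if condition not in set(catalog["condition"]):
        raise ValueError(f"condition {condition!r} absent from the catalog")
    mutated = set(catalog.loc[catalog["condition"] == condition, "gene"])
    found = sub[sub[gene_column].isin(mutated)]["mean_fitness"]
    notfound = sub[~sub[gene_column].isin(mutated)]["mean_fitness"]
    result = {
        "found": found.to_numpy(),
        "not_found": notfound.to_numpy(),
        "median_found": float(found.median()) if len(found) else float("nan"),
        "median_not_found": float(notfound.median()) if len(notfound) else float("nan"),
        "p_value": None,
    }
    if found.empty or notfound.empty:
        warnings.warn("one group is empty; rank-sum test not run")
        return result
    stat, p = mannwhitneyu(found, notfound, alternative="two-sided", method="auto")
    result.update(statistic=float(stat), p_value=float(p))
    return result
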