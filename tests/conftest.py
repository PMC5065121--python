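import numpy as np
import pandas as pd
import pytest

from barseqfit.pool import (
    CompetitionDesign,
    DfeMixture,
    build_pool,
    simulate_counts,
)


@pytest.fixture(scope="session")
def small_pool():
    """50-strain mixed pool with 10 controls, fixed seed."""
    catalog, s = build_pool(50, DfeMixture(), n_control=10, seed=42)
    return catalog, s


@pytest.fixture(scope="session")
def small_run(small_pool):
    """Noisy simulated screen on the small pool (2 replicates)."""
    catalog, s = small_pool
    design = CompetitionDesign(condition="sulfate", seed=43)
    counts, truth = simulate_counts(catalog, design)
    return catalog, counts, truth


@pytest.fixture()
def toy_eset():
    """Hand-built mutation catalog: 8 mutations, 4 samples, 2 ploidies."""
    rows = [
        # gene, sample, condition, ploidy, sample_type, mclass
        ("SUL1", "s1", "sulfate", "haploid", "population", "nonsynonymous"),
        ("SUL1", "s2", "sulfate", "haploid", "clone", "nonsynonymous"),
        ("SGF73", "s1", "sulfate", "haploid", "population", "stop_gained"),
        ("WHI2", "s3", "glucose", "diploid", "population", "upstream"),
        ("MTH1", "s3", "glucose", "diploid", "population", "stop_gained"),
        ("MTH1", "s4", "glucose", "haploid", "clone", "frameshift"),
        ("ACT1", "s4", "glucose", "haploid", "clone", "synonymous"),
        ("RPL5", "s2", "sulfate", "haploid", "clone", "intergenic"),
    ]
    return pd.DataFrame(
        rows,
        columns=["gene", "sample_id", "condition", "ploidy", "sample_type", "mclass"],
    )


@pytest.fixture()
def toy_fitness():
    """Tidy screen-fitness table matching the toy catalog's gene space."""
    rows = [
        # strain, gene, collection, condition, mean_fitness
        ("st1", "SUL1", "high_copy_plasmid", "sulfate", 0.428),
        ("st2", "SUL1", "low_copy_plasmid", "sulfate", 0.15),
        ("st3", "SGF73", "haploid_deletion", "sulfate", 0.12),
        ("st4", "WHI2", "haploid_deletion", "glucose", 0.07),
        ("st5", "MTH1", "haploid_deletion", "glucose", 0.22),
        ("st6", "ACT1", "haploid_deletion", "glucose", -0.30),
        ("st7", "BSD2", "low_copy_plasmid", "sulfate", 0.05),
    ]
    frame = pd.DataFrame(
        rows, columns=["strain_id", "gene", "collection", "condition", "mean_fitness"]
    ).set_index("strain_id")
    frame["n_replicates"] = 2
    return frame


def rank_sum_exact_two_sided(x, y):
    """Brute-force two-sided rank-sum p-value by full enumeration.

    Enumerates all ways the pooled observations could split into groups of
    the observed sizes and sums the probability of U statistics at least as
    extreme (two-sided, doubling the smaller tail) — independent of scipy.
    """
    from itertools import combinations

    pooled = np.concatenate([x, y])
    n = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj) + 0.5 * sum(
        1 for xi in x for yj in y if xi == yj
    )
    us = []
    for idx in combinations(range(len(pooled)), n):
        grp = pooled[list(idx)]
        rest = np.delete(pooled, list(idx))
        u = sum(1 for a in grp for b in rest if a > b) + 0.5 * sum(
            1 for a in grp for b in rest if a == b
        )
        us.append(u)
    us = np.array(us)
    p_low = np.mean(us <= u_obs)
    p_high = np.mean(us >= u_obs)
    return min(1.0, 2 * min(p_low, p_high))
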