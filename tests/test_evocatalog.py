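"""Mutation-catalog analyses: impact, recurrence, contingency, drivers."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from conftest import rank_sum_exact_two_sided
from barseqfit.evocatalog import (
    IMPACT_OF,
    MCLASSES,
    contingency_2x2,
    found_vs_notfound,
    heterogeneity_test,
    impact_of,
    length_bias,
    per_sample_driver_stats,
    ploidy_contingency,
    predict_drivers,
    recurrence_counts,
    validate_catalog,
)

# Published haploid/diploid mutation-event counts per class in the compiled
# evolve-and-resequence catalog (1017 haploid, 150 diploid events total).
ESET_SPECTRUM = {
    "stop_gained": (118, 5),
    "start_lost": (7, 1),
    "stop_lost": (2, 0),
    "frameshift": (6, 0),
    "nonsynonymous": (720, 97),
    "codon_indel": (3, 0),
    "synonymous": (127, 15),
    "upstream": (6, 7),
    "intron": (4, 1),
    "intergenic": (24, 24),
}


def spectrum_catalog():
    """Expand the published class × ploidy totals into one row per event."""
    rows = []
    i = 0
    for mclass, (n_hap, n_dip) in ESET_SPECTRUM.items():
        for ploidy, n in (("haploid", n_hap), ("diploid", n_dip)):
            for _ in range(n):
                rows.append(
                    (f"g{i}", f"s{i}", "glucose", ploidy, "clone", mclass)
                )
                i += 1
    return pd.DataFrame(
        rows,
        columns=["gene", "sample_id", "condition", "ploidy", "sample_type", "mclass"],
    )


class TestImpact:
    @pytest.mark.parametrize(
        "mclass,impact",
        [
            ("stop_gained", "high"),
            ("start_lost", "high"),
            ("stop_lost", "high"),
            ("frameshift", "high"),
            ("nonsynonymous", "moderate"),
            ("codon_indel", "moderate"),
            ("synonymous", "low"),
            ("upstream", "modifier"),
            ("intron", "modifier"),
            ("intergenic", "modifier"),
        ],
    )
    def test_published_mapping(self, mclass, impact):
        assert impact_of(mclass) == impact

    def test_total_on_vocabulary(self):
        assert set(IMPACT_OF) == set(MCLASSES)
        for m in MCLASSES:
            assert impact_of(m) in {"high", "moderate", "low", "modifier"}

    def test_unknown_rejected(self):
        with pytest.raises(ValueError, match="unknown mutation class"):
            impact_of("missense")


class TestValidate:
    def test_adds_impact_column(self, toy_eset):
        out = validate_catalog(toy_eset)
        assert out.loc[out["mclass"] == "stop_gained", "impact"].eq("high").all()

    def test_bad_class_rejected(self, toy_eset):
        bad = toy_eset.copy()
        bad.loc[0, "mclass"] = "nonsense"
        with pytest.raises(ValueError, match="unknown mutation classes"):
            validate_catalog(bad)


class TestRecurrence:
    def test_toy_enumeration(self, toy_eset):
        counts, summary = recurrence_counts(toy_eset)
        assert counts["SUL1"] == 2 and counts["MTH1"] == 2 and counts["WHI2"] == 1
        assert summary["recurrent"] == 2  # SUL1, MTH1
        assert summary["highly_recurrent"] == 0

    def test_same_sample_counts_once(self):
        cat = pd.DataFrame(
            [("G", "s1", "glucose", "haploid", "clone", "nonsynonymous"),
             ("G", "s1", "glucose", "haploid", "clone", "stop_gained")],
            columns=["gene", "sample_id", "condition", "ploidy", "sample_type", "mclass"],
        )
        counts, summary = recurrence_counts(cat)
        assert counts["G"] == 1 and summary["recurrent"] == 0

    def test_empty_catalog(self):
        counts, summary = recurrence_counts(spectrum_catalog().iloc[:0])
        assert summary == {"n_genes": 0, "recurrent": 0, "highly_recurrent": 0}

    def test_condition_restriction(self, toy_eset):
        _, summary = recurrence_counts(toy_eset, condition="sulfate")
        assert summary["n_genes"] == 3  # SUL1, SGF73, RPL5


class TestPloidyContingency:
    def test_stop_gained_published_p(self):
        """Stop-codon gains are haploid-biased: 118/1017 vs 5/150 gives
        p ≈ 0.003 under a Yates-corrected chi-square."""
        res = ploidy_contingency(spectrum_catalog(), "stop_gained")
        assert res.table.tolist() == [[118, 5], [899, 145]]
        assert res.p_value == pytest.approx(0.003, abs=5e-4)

    def test_proportional_table_statistic_zero(self):
        res = contingency_2x2([[10, 1], [100, 10]], method="chi2")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_fisher_matches_hypergeometric_enumeration(self):
        # table [[3,1],[1,3]]: margins 4/4, p = sum of P over tables with
        # probability <= observed = (16+16+1+1)/70
        res = contingency_2x2([[3, 1], [1, 3]], method="fisher")
        assert res.p_value == pytest.approx(34 / 70, abs=1e-12)

    def test_yates_equals_textbook_formula(self):
        table = np.array([[30, 10], [20, 40]])
        total, rows, cols = table.sum(), table.sum(1), table.sum(0)
        expected = np.outer(rows, cols) / total
        stat = ((np.abs(table - expected) - 0.5) ** 2 / expected).sum()
        res = contingency_2x2(table, method="chi2_yates")
        assert res.statistic == pytest.approx(stat, abs=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            contingency_2x2([[0, 0], [1, 2]])

    def test_single_ploidy_rejected(self, toy_eset):
        hap = toy_eset[toy_eset["ploidy"] == "haploid"]
        with pytest.raises(ValueError, match="both ploidies"):
            ploidy_contingency(hap, "stop_gained")


class TestHeterogeneity:
    def test_published_spectrum_is_heterogeneous(self):
        """The full class × ploidy table is strongly non-homogeneous."""
        res = heterogeneity_test(spectrum_catalog(), n_mc=2000, seed=1)
        assert res.p_value < 0.001

    def test_homogeneous_table_p_near_one(self):
        rows = []
        for i, ploidy in enumerate(["haploid"] * 50 + ["diploid"] * 50):
            mclass = "nonsynonymous" if i % 2 else "synonymous"
            rows.append((f"g{i}", f"s{i}", "glucose", ploidy, "clone", mclass))
        cat = pd.DataFrame(
            rows,
            columns=["gene", "sample_id", "condition", "ploidy", "sample_type", "mclass"],
        )
        res = heterogeneity_test(cat, n_mc=2000, seed=2)
        assert res.p_value > 0.5


class TestLengthBias:
    def test_exact_small_sample(self):
        cat = pd.DataFrame(
            [("A", "s1", "g", "haploid", "clone", "nonsynonymous"),
             ("A", "s2", "g", "haploid", "clone", "nonsynonymous"),
             ("B", "s1", "g", "haploid", "clone", "nonsynonymous"),
             ("B", "s3", "g", "haploid", "clone", "nonsynonymous"),
             ("C", "s1", "g", "haploid", "clone", "nonsynonymous"),
             ("D", "s2", "g", "haploid", "clone", "nonsynonymous"),
             ("E", "s3", "g", "haploid", "clone", "nonsynonymous")],
            columns=["gene", "sample_id", "condition", "ploidy", "sample_type", "mclass"],
        )
        ann = pd.DataFrame(
            {"gene": list("ABCDE"), "length": [5000, 6000, 1000, 1100, 1200]}
        )
        stat, p, summary = length_bias(cat, ann)
        assert summary.loc["recurrent", "median_length"] > summary.loc["singleton", "median_length"]
        expected = rank_sum_exact_two_sided(
            np.array([5000, 6000]), np.array([1000, 1100, 1200])
        )
        assert p == pytest.approx(expected, abs=1e-12)

    def test_identical_multisets_p_one(self):
        cat = pd.DataFrame(
            [("A", "s1", "g", "haploid", "clone", "nonsynonymous"),
             ("A", "s2", "g", "haploid", "clone", "nonsynonymous"),
             ("B", "s1", "g", "haploid", "clone", "nonsynonymous")],
            columns=["gene", "sample_id", "condition", "ploidy", "sample_type", "mclass"],
        )
        ann = pd.DataFrame({"gene": ["A", "B"], "length": [1000, 1000]})
        _, p, _ = length_bias(cat, ann)
        assert p == pytest.approx(1.0)

    def test_missing_lengths_warn_and_empty_group_rejected(self, toy_eset):
        ann = pd.DataFrame({"gene": ["SUL1", "MTH1"], "length": [2400, 1300]})
        with pytest.warns(UserWarning, match="without length"):
            with pytest.raises(ValueError, match="non-empty"):
                length_bias(toy_eset, ann)


class TestDrivers:
    def test_label_rules(self, toy_eset, toy_fitness):
        out = predict_drivers(toy_eset, toy_fitness)
        by = out.set_index(["gene", "sample_id"])["driver_label"]
        assert by[("SUL1", "s1")] == "predicted_beneficial"  # 0.428 sulfate
        assert by[("SGF73", "s1")] == "predicted_beneficial"  # 0.12 >= 0.10
        assert by[("WHI2", "s3")] == "intermediate"  # 0.07 in [0.05, 0.10)
        assert by[("ACT1", "s4")] == "not_predicted"  # -0.30 measured
        assert by[("RPL5", "s2")] == "absent_from_screen"

    def test_monotone_in_cutoff(self, toy_eset, toy_fitness):
        hi = predict_drivers(toy_eset, toy_fitness, cutoff=0.10)
        lo = predict_drivers(toy_eset, toy_fitness, cutoff=0.05, secondary=0.05)
        hi_set = set(hi.index[hi["driver_label"] == "predicted_beneficial"])
        lo_set = set(lo.index[lo["driver_label"] == "predicted_beneficial"])
        assert hi_set <= lo_set

    def test_strict_mode_matches_mechanism(self, toy_eset, toy_fitness):
        # MTH1 stop_gained (high impact) matches the deletion-collection
        # fitness 0.22; SUL1 nonsynonymous is moderate -> deletion
        # collections only, and SUL1 was measured on plasmids -> absent
        out = predict_drivers(toy_eset, toy_fitness, strict=True)
        by = out.set_index(["gene", "sample_id"])["driver_label"]
        assert by[("MTH1", "s3")] == "predicted_beneficial"
        assert by[("SUL1", "s1")] == "absent_from_screen"

    def test_per_sample_stats(self, toy_eset, toy_fitness):
        out = predict_drivers(toy_eset, toy_fitness)
        per, stats = per_sample_driver_stats(out)
        # s1 carries SUL1 + SGF73, both predicted beneficial
        assert per.loc["s1", "n_drivers"] == 2
        assert per.loc["s1", "n_total"] == 2
        assert per.loc["s1", "ratio"] == pytest.approx(1.0)
        # s3 carries MTH1 (predicted) and WHI2 (intermediate)
        assert per.loc["s3", "ratio"] == pytest.approx(0.5)
        assert "clone_vs_population" in stats
        # permuting rows changes nothing
        _, stats2 = per_sample_driver_stats(out.sample(frac=1, random_state=0))
        assert stats2["mean_drivers_per_sample"] == stats["mean_drivers_per_sample"]

    def test_half_ratio(self, toy_fitness):
        cat = pd.DataFrame(
            [("SUL1", "x", "sulfate", "haploid", "clone", "nonsynonymous"),
             ("SGF73", "x", "sulfate", "haploid", "clone", "stop_gained"),
             ("RPL5", "x", "sulfate", "haploid", "clone", "synonymous"),
             ("UNK9", "x", "sulfate", "haploid", "clone", "intergenic")],
            columns=["gene", "sample_id", "condition", "ploidy", "sample_type", "mclass"],
        )
        per, _ = per_sample_driver_stats(predict_drivers(cat, toy_fitness))
        assert per.loc["x", "ratio"] == pytest.approx(0.5)


class TestFoundVsNotFound:
    def _fitness(self):
        rows = [
            ("s1", "SUL1", "sulfate", 0.30),
            ("s2", "SGF73", "sulfate", 0.40),
            ("s3", "MAC1", "sulfate", 0.12),
            ("s4", "PHO3", "sulfate", 0.11),
        ]
        return pd.DataFrame(
            rows, columns=["strain_id", "gene", "condition", "mean_fitness"]
        ).set_index("strain_id")

    def _catalog(self):
        return pd.DataFrame(
            [("SUL1", "e1", "sulfate", "haploid", "population", "nonsynonymous"),
             ("SGF73", "e2", "sulfate", "haploid", "population", "stop_gained")],
            columns=["gene", "sample_id", "condition", "ploidy", "sample_type", "mclass"],
        )

    def test_split_and_exact_p(self):
        res = found_vs_notfound(self._fitness(), self._catalog(), "sulfate")
        assert sorted(res["found"]) == [0.30, 0.40]
        assert sorted(res["not_found"]) == [0.11, 0.12]
        assert res["median_found"] > res["median_not_found"]
        expected = rank_sum_exact_two_sided(
            np.array([0.30, 0.40]), np.array([0.11, 0.12])
        )
        assert res["p_value"] == pytest.approx(expected, abs=1e-12)

    def test_identical_groups_p_one(self):
        fit = self._fitness()
        fit["mean_fitness"] = 0.2
        res = found_vs_notfound(fit, self._catalog(), "sulfate")
        assert res["p_value"] == pytest.approx(1.0)

    def test_excluding_gene_removes_its_entries(self):
        res = found_vs_notfound(
            self._fitness(), self._catalog(), "sulfate", exclude_genes={"SUL1"}
        )
        assert list(res["found"]) == [0.40]

    def test_empty_group_warns(self):
        cat = self._catalog()
        fit = self._fitness().query("gene in ['SUL1', 'SGF73']")
        with pytest.warns(UserWarning, match="empty"):
            res = found_vs_notfound(fit, cat, "sulfate")
        assert res["p_value"] is None
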