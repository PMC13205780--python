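"""Read counting, depth normalisation and NB differential abundance."""

import numpy as np
import pandas as pd
import pytest

from cmcpminer.abundance import (
    count_reads,
    diff_abundance,
    relative_abundance,
    size_factors,
)
from cmcpminer.seq_io import SequenceRecord, reverse_complement
from cmcpminer.synthetic_data import SimScenario, simulate_cohorts


def _dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestCountReads:
    def _contigs(self, rng):
        a = SequenceRecord("cA", _dna(rng, 300), alphabet="dna")
        b = SequenceRecord("cB", _dna(rng, 300), alphabet="dna")
        return a, b

    def test_exact_substring_counted_once(self, rng):
        a, b = self._contigs(rng)
        read = SequenceRecord("r1", a.residues[100:150], alphabet="dna")
        counts = count_reads([read], [a, b], {"cA": "featA", "cB": "featB"})
        assert counts["featA"] == 1 and counts["featB"] == 0

    def test_reverse_strand_read_counted(self, rng):
        a, b = self._contigs(rng)
        read = SequenceRecord("r1", reverse_complement(a.residues[100:150]),
                              alphabet="dna")
        counts = count_reads([read], [a, b], {"cA": "featA", "cB": "featB"})
        assert counts["featA"] == 1

    def test_unmatched_read_unassigned(self, rng):
        a, b = self._contigs(rng)
        read = SequenceRecord("r1", _dna(rng, 50), alphabet="dna")
        counts = count_reads([read], [a, b], {"cA": "featA", "cB": "featB"})
        assert counts.sum() == 0

    def test_tied_read_discarded(self, rng):
        shared = _dna(rng, 80)
        a = SequenceRecord("cA", shared + _dna(rng, 100), alphabet="dna")
        b = SequenceRecord("cB", shared + _dna(rng, 100), alphabet="dna")
        read = SequenceRecord("r1", shared[10:60], alphabet="dna")
        counts = count_reads([read], [a, b], {"cA": "featA", "cB": "featB"})
        assert counts.sum() == 0


class TestRelativeAbundance:
    def test_single_feature_all_ones(self):
        m = pd.DataFrame({"s1": [4], "s2": [9]}, index=["f1"])
        props = relative_abundance(m)
        assert (props.loc["f1"] == 1.0).all()

    def test_column_normalisation(self):
        m = pd.DataFrame({"s1": [2, 2], "s2": [1, 3]}, index=["f1", "f2"])
        props = relative_abundance(m)
        assert props["s1"].tolist() == [0.5, 0.5]
        assert np.allclose(props.sum(axis=0), 1.0, atol=1e-12)

    def test_zero_total_sample_dropped_with_warning(self):
        m = pd.DataFrame({"s1": [2, 2], "s2": [0, 0]}, index=["f1", "f2"])
        with pytest.warns(UserWarning, match="zero-total"):
            props = relative_abundance(m)
        assert list(props.columns) == ["s1"]


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self, rng):
        col = rng.integers(1, 100, size=20)
        m = pd.DataFrame({f"s{j}": col for j in range(5)})
        assert np.allclose(size_factors(m), 1.0)

    def test_doubled_column_doubles_factor(self, rng):
        col = rng.integers(1, 100, size=30)
        m = pd.DataFrame({"a": col, "b": 2 * col})
        sf = size_factors(m)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_scale_equivariance_of_factor_ratios(self, rng):
        # size factors are defined up to a common scale; scaling one
        # sample by c multiplies its factor relative to every other by c
        m = pd.DataFrame(rng.integers(1, 200, size=(25, 6)),
                         columns=[f"s{j}" for j in range(6)])
        sf = size_factors(m)
        m2 = m.copy()
        m2["s3"] = m2["s3"] * 5
        sf2 = size_factors(m2)
        for s in ("s0", "s1", "s2", "s4", "s5"):
            assert sf2["s3"] / sf2[s] == pytest.approx(5 * sf["s3"] / sf[s])
        assert sf2["s0"] / sf2["s1"] == pytest.approx(sf["s0"] / sf["s1"])

    def test_feature_order_invariance(self, rng):
        m = pd.DataFrame(rng.integers(1, 200, size=(25, 4)),
                         columns=list("abcd"))
        perm = rng.permutation(25)
        assert np.allclose(size_factors(m), size_factors(m.iloc[perm]))

    def test_zero_rich_matrix_falls_back_with_warning(self):
        m = pd.DataFrame([[0, 5, 5], [5, 0, 5], [5, 5, 0]],
                         columns=list("abc"))
        with pytest.warns(UserWarning, match="positive counts only"):
            sf = size_factors(m)
        assert (sf > 0).all()


@pytest.fixture(scope="module")
def cohort_data():
    eff = {f"feat{i:04d}": 2.0 for i in range(5)}
    scenario = SimScenario(seed=42, n_cohorts=1, n_case=15, n_control=15,
                           n_features=40, dispersion=0.2,
                           planted_effects=eff)
    counts, meta, effects = simulate_cohorts(scenario)
    return counts, meta, effects


class TestDiffAbundance:
    def test_planted_features_significant_with_correct_sign(self, cohort_data):
        counts, meta, effects = cohort_data
        stats = diff_abundance(counts, meta, "cohort1")
        planted = [f for f, v in effects.items() if v > 0]
        tab = stats.table.loc[planted]
        assert (tab["padj"] < 0.05).all()
        assert (tab["direction"] == 1).all()

    def test_direction_matches_normalised_group_means(self, cohort_data):
        counts, meta, effects = cohort_data
        stats = diff_abundance(counts, meta, "cohort1")
        sf = size_factors(counts)
        q = counts / sf
        case = meta.index[meta["condition"] == "case"]
        ctrl = meta.index[meta["condition"] == "control"]
        for feat, row in stats.table.iterrows():
            if row["flagged"] or row["direction"] == 0:
                continue
            diff = q.loc[feat, case].mean() - q.loc[feat, ctrl].mean()
            assert np.sign(diff) == row["direction"]

    def test_bh_adjustment_properties(self, cohort_data):
        counts, meta, _ = cohort_data
        stats = diff_abundance(counts, meta, "cohort1")
        tab = stats.table.sort_values("pvalue")
        assert (tab["padj"] >= tab["pvalue"] - 1e-15).all()
        assert tab["padj"].is_monotonic_increasing

    def test_highlight_rule(self, cohort_data):
        counts, meta, _ = cohort_data
        stats = diff_abundance(counts, meta, "cohort1")
        t = stats.table
        assert (t["highlight"] == ((t["lfc"].abs() > 2) & (t["padj"] < 0.05))).all()

    def test_all_zero_feature_flagged(self):
        scenario = SimScenario(seed=3, n_cohorts=1, n_case=5, n_control=5,
                               n_features=10)
        counts, meta, _ = simulate_cohorts(scenario)
        counts.loc["feat0000"] = 0
        stats = diff_abundance(counts, meta, "cohort1")
        row = stats.table.loc["feat0000"]
        assert row["flagged"] and row["pvalue"] == 1.0

    def test_undersized_cohort_rejected(self):
        scenario = SimScenario(seed=3, n_cohorts=1, n_case=1, n_control=5,
                               n_features=10)
        counts, meta, _ = simulate_cohorts(scenario)
        with pytest.raises(ValueError, match="2 samples per condition"):
            diff_abundance(counts, meta, "cohort1")
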