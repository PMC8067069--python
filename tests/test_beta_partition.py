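"""Sørensen/Jaccard partitioning, resampling, and the vegan cross-check."""

import math
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beltdiv import (
    FormatError,
    beta_resample,
    multisite_partition,
    nestedness_ratio,
    pairwise_partition,
)

from oracles import brute_bootstrap_multisite_mean, random_incidence

species_sets = st.sets(st.sampled_from([f"sp{i}" for i in range(8)]),
                       max_size=8)


class TestPairwise:
    def test_fixture_a_vs_b_has_zero_nestedness(self, table3):
        matrix, _ = table3
        part = pairwise_partition(matrix.species_set("A"),
                                  matrix.species_set("B"), "sorensen")
        assert part.total == pytest.approx(0.5)
        assert part.turnover == pytest.approx(0.5)
        assert part.nestedness == pytest.approx(0.0, abs=1e-15)

    def test_fixture_b_vs_c_ratio_is_half(self, table3):
        matrix, _ = table3
        part = pairwise_partition(matrix.species_set("B"),
                                  matrix.species_set("C"), "sorensen")
        assert part.total == pytest.approx(1 / 3)
        assert part.turnover == pytest.approx(1 / 6)
        assert part.nestedness == pytest.approx(1 / 6)
        assert nestedness_ratio(part) == pytest.approx(0.5)

    def test_identical_units_are_fully_similar(self):
        part = pairwise_partition({"a", "b"}, {"a", "b"}, "sorensen")
        assert (part.total, part.turnover, part.nestedness) == (0.0, 0.0, 0.0)
        assert nestedness_ratio(part) is None

    def test_nested_pair_has_zero_turnover(self):
        for family in ("sorensen", "jaccard"):
            part = pairwise_partition({"a", "b", "c", "d"}, {"a", "b"}, family)
            assert part.turnover == 0.0
            assert part.nestedness == pytest.approx(part.total)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(species_sets, species_sets)
    def test_additivity_and_bounds(self, s1, s2):
        sor = pairwise_partition(s1, s2, "sorensen")
        jac = pairwise_partition(s1, s2, "jaccard")
        for part in (sor, jac):
            assert part.total == pytest.approx(
                part.turnover + part.nestedness, abs=1e-12)
            assert -1e-12 <= part.turnover <= part.total + 1e-12
            assert part.total <= 1 + 1e-12
        assert jac.total >= sor.total - 1e-12
        if 0 < sor.total < 1:
            assert jac.total > sor.total


class TestMultisite:
    def test_fixture_values(self, table3):
        matrix, _ = table3
        part = multisite_partition(matrix, "sorensen")
        assert part.turnover == pytest.approx(7 / 15)
        assert part.total == pytest.approx(5 / 9)
        assert part.nestedness == pytest.approx(4 / 45)
        assert part.ratio == pytest.approx(0.16)

    def test_identical_units_all_zero(self):
        sets = [frozenset({"a", "b"})] * 4
        part = multisite_partition(sets, "sorensen")
        assert (part.total, part.turnover, part.nestedness) == (0.0, 0.0, 0.0)
        assert not part.degenerate  # denominators stay positive here

    def test_all_empty_units_are_degenerate_zero(self):
        sets = [frozenset()] * 3
        part = multisite_partition(sets, "jaccard")
        assert (part.total, part.turnover, part.nestedness) == (0.0, 0.0, 0.0)
        assert part.ratio is None
        assert part.degenerate

    def test_two_units_reduce_to_pairwise(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            matrix = random_incidence(rng, 2, 8, p=0.5)
            sets = matrix.species_sets()
            for family in ("sorensen", "jaccard"):
                multi = multisite_partition(matrix, family)
                pair = pairwise_partition(sets[0], sets[1], family)
                assert multi.total == pytest.approx(pair.total, abs=1e-12)
                assert multi.turnover == pytest.approx(pair.turnover,
                                                       abs=1e-12)

    def test_single_unit_rejected(self):
        with pytest.raises(FormatError, match="2 units"):
            multisite_partition([frozenset({"a"})], "sorensen")

    def test_nested_chain_is_pure_nestedness(self):
        sets = [frozenset(f"sp{i}" for i in range(k)) for k in (2, 4, 6, 8)]
        for family in ("sorensen", "jaccard"):
            part = multisite_partition(sets, family)
            assert part.turnover == pytest.approx(0.0, abs=1e-15)
            assert part.nestedness == pytest.approx(part.total)

    def test_additivity_on_random_matrices(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            matrix = random_incidence(rng, int(rng.integers(2, 8)),
                                      int(rng.integers(2, 10)), p=0.5)
            for family in ("sorensen", "jaccard"):
                part = multisite_partition(matrix, family)
                assert part.total == pytest.approx(
                    part.turnover + part.nestedness, abs=1e-12)


class TestResampling:
    def test_identical_units_give_degenerate_zero(self, rng):
        import pandas as pd

        from beltdiv import IncidenceMatrix

        frame = pd.DataFrame([[1, 1, 0]] * 4, index=list("wxyz"),
                             columns=["a", "b", "c"])
        matrix = IncidenceMatrix(frame, level="site")
        result = beta_resample(matrix, "sorensen", n_replicates=20, seed=3)
        assert result.mean == {"total": 0.0, "turnover": 0.0,
                               "nestedness": 0.0}
        assert result.sd == {"total": 0.0, "turnover": 0.0, "nestedness": 0.0}

    def test_same_seed_reproduces_replicates(self, table3):
        matrix, _ = table3
        a = beta_resample(matrix, "sorensen", n_replicates=50, seed=9)
        b = beta_resample(matrix, "sorensen", n_replicates=50, seed=9)
        assert [r.total for r in a.replicates] == \
            [r.total for r in b.replicates]

    def test_bootstrap_mean_matches_enumeration_oracle(self, table3):
        matrix, _ = table3
        n_reps = 1000
        result = beta_resample(matrix, "sorensen", n_replicates=n_reps,
                               subset_size=3, replace=True, seed=42)
        oracle = brute_bootstrap_multisite_mean(matrix.species_sets(), 3,
                                                "sorensen")
        se = result.sd["total"] / math.sqrt(n_reps)
        assert abs(result.mean["total"] - oracle) <= 3 * se

    def test_replicate_count_validated(self, table3):
        matrix, _ = table3
        with pytest.raises(FormatError, match="n_replicates"):
            beta_resample(matrix, "sorensen", n_replicates=0)


def test_multisite_sorensen_matches_vegan(table3):
    """Independent oracle: vegan::nestedbetasor on the packaged fixture."""
    matrix, _ = table3
    rows = ";".join(
        ",".join(str(int(v)) for v in matrix.data.loc[u])
        for u in matrix.unit_ids
    )
    script = (
        "suppressMessages(library(vegan));"
        f"m <- do.call(rbind, lapply(strsplit(strsplit('{rows}', ';')[[1]], ','),"
        "as.numeric));"
        "r <- nestedbetasor(m);"
        "cat(sprintf('%.12f %.12f %.12f', r[['turnover']],"
        "r[['nestedness']], r[['sorensen']]))"
    )
    proc = subprocess.run(["Rscript", "-e", script], capture_output=True,
                          text=True, timeout=300)
    assert proc.returncode == 0, proc.stderr
    turnover, nestedness, total = map(float, proc.stdout.split())
    part = multisite_partition(matrix, "sorensen")
    assert part.turnover == pytest.approx(turnover, abs=1e-10)
    assert part.nestedness == pytest.approx(nestedness, abs=1e-10)
    assert part.total == pytest.approx(total, abs=1e-10)
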