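import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agreechart import (
    DegenerateTableError,
    b_statistic,
    cohen_kappa,
    interpret,
    observed_expected,
    partial_band_areas,
    summarize,
    validate,
    weighted_b,
)

from _oracle import kappa as oracle_kappa
from _oracle import weighted_b as oracle_weighted_b
from conftest import random_table


# strategy: small random non-degenerate square count matrices
@st.composite
def tables(draw, min_k=2, max_k=6):
    k = draw(st.integers(min_k, max_k))
    cells = draw(
        st.lists(
            st.lists(st.integers(0, 25), min_size=k, max_size=k),
            min_size=k, max_size=k,
        )
    )
    m = np.array(cells)
    row, col = m.sum(axis=1), m.sum(axis=0)
    total = m.sum()
    if total == 0 or row @ col >= total**2:  # empty or Pe = 1
        m[0, 1] += 1
        m[1, 0] += 1
    return validate(m)


class TestObservedExpected:
    def test_winnipeg_hand_sums(self, fixture_tables):
        # diagonal 38+11+5+10 = 64; marginal products sum to 6211
        po, pe = observed_expected(fixture_tables["westlund_winnipeg"])
        assert po == pytest.approx(64 / 149, abs=1e-15)
        assert pe == pytest.approx(6211 / 22201, abs=1e-15)

    def test_diagonal_only_table_has_po_one(self):
        po, _ = observed_expected(np.diag([3, 7, 2]))
        assert po == 1.0

    def test_single_cell_mass_gives_pe_one_and_kappa_undefined(self):
        t = [[9, 0], [0, 0]]
        _, pe = observed_expected(t)
        assert pe == 1.0
        with pytest.raises(DegenerateTableError):
            cohen_kappa(t)


class TestPartialBandAreas:
    def test_band_zero_is_dark_square(self, fixture_tables):
        t = fixture_tables["boyd"]
        for i in range(t.k):
            assert partial_band_areas(t, i, 0) == t.diagonal[i] ** 2

    def test_bands_telescope_to_marginal_rectangle(self, fixture_tables):
        for t in fixture_tables.values():
            for i in range(t.k):
                total = sum(partial_band_areas(t, i, b) for b in range(t.k))
                assert total == pytest.approx(
                    t.row_totals[i] * t.col_totals[i], abs=1e-9
                )

    def test_lrc_elderly_first_band(self, fixture_tables):
        # CVD rectangle: 183*207 minus the 172^2 dark square
        t = fixture_tables["lrc_elderly"]
        assert partial_band_areas(t, 0, 1) == 183 * 207 - 172**2 == 8297

    def test_index_out_of_range(self, fixture_tables):
        t = fixture_tables["lrc_elderly"]
        with pytest.raises(IndexError):
            partial_band_areas(t, 0, 2)
        with pytest.raises(IndexError):
            partial_band_areas(t, 5, 0)


class TestPerfectAgreement:
    def test_all_statistics_one_on_diagonal_table(self):
        t = validate(np.diag([4, 9, 1]))
        s = summarize(t, "quadratic")
        assert s.kappa == s.kappa_weighted == s.b == s.b_weighted == 1.0

    @pytest.mark.parametrize("scheme", ["unweighted", "linear", "quadratic"])
    def test_kappa_one_any_scheme(self, scheme):
        assert cohen_kappa(np.diag([2, 5]), scheme) == 1.0


class TestProperties:
    @settings(max_examples=60, derandomize=True)
    @given(tables())
    def test_rater_symmetry(self, t):
        tt = t.transpose()
        for scheme in ("unweighted", "quadratic"):
            assert cohen_kappa(t, scheme) == pytest.approx(
                cohen_kappa(tt, scheme), abs=1e-12
            )
        assert b_statistic(t) == pytest.approx(b_statistic(tt), abs=1e-12)
        assert weighted_b(t, "quadratic") == pytest.approx(
            weighted_b(tt, "quadratic"), abs=1e-12
        )

    @settings(max_examples=60, derandomize=True)
    @given(tables(), st.integers(2, 9))
    def test_scale_invariance(self, t, c):
        tc = t.scaled(c)
        assert cohen_kappa(t, "quadratic") == pytest.approx(
            cohen_kappa(tc, "quadratic"), abs=1e-12
        )
        assert b_statistic(t) == pytest.approx(b_statistic(tc), abs=1e-12)
        assert weighted_b(t) == pytest.approx(weighted_b(tc), abs=1e-12)

    @settings(max_examples=60, derandomize=True)
    @given(tables(min_k=3))
    def test_unweighted_stats_invariant_under_category_permutation(self, t):
        rng = np.random.default_rng(t.n)
        perm = rng.permutation(t.k)
        tp = validate(t.counts[np.ix_(perm, perm)])
        assert cohen_kappa(tp) == pytest.approx(cohen_kappa(t), abs=1e-12)
        assert b_statistic(tp) == pytest.approx(b_statistic(t), abs=1e-12)

    def test_weighted_stats_depend_on_category_order(self, fixture_tables):
        t = fixture_tables["westlund_winnipeg"]
        perm = [0, 2, 1, 3]  # swap two middle ordinal categories
        tp = validate(t.counts[np.ix_(perm, perm)])
        assert weighted_b(tp, "quadratic") != pytest.approx(
            weighted_b(t, "quadratic"), abs=1e-9
        )
        assert cohen_kappa(tp, "quadratic") != pytest.approx(
            cohen_kappa(t, "quadratic"), abs=1e-9
        )

    @settings(max_examples=80, derandomize=True)
    @given(tables())
    def test_b_bounds_and_unweighted_reduction(self, t):
        b = b_statistic(t)
        bw = weighted_b(t, "quadratic")
        assert 0.0 <= b <= bw <= 1.0 + 1e-12
        assert weighted_b(t, "unweighted") == pytest.approx(b, abs=1e-12)

    @settings(max_examples=60, derandomize=True)
    @given(tables())
    def test_matches_brute_force_oracle(self, t):
        cells = t.counts.tolist()
        for scheme in ("unweighted", "linear", "quadratic"):
            assert cohen_kappa(t, scheme) == pytest.approx(
                oracle_kappa(cells, scheme), abs=1e-12
            )
            assert weighted_b(t, scheme) == pytest.approx(
                oracle_weighted_b(cells, scheme), abs=1e-12
            )


class TestStatsmodelsCrossCheck:
    """statsmodels' independent kappa implementation as an external oracle."""

    @pytest.mark.parametrize("name", ["westlund_winnipeg", "boyd", "lrc_elderly"])
    def test_kappa_agrees_with_statsmodels(self, fixture_tables, name):
        from statsmodels.stats.inter_rater import cohens_kappa

        t = fixture_tables[name]
        sm_plain = cohens_kappa(t.counts, return_results=False)
        assert cohen_kappa(t) == pytest.approx(sm_plain, abs=1e-12)
        sm_quad = cohens_kappa(t.counts, wt="quadratic").kappa
        assert cohen_kappa(t, "quadratic") == pytest.approx(sm_quad, abs=1e-12)


class TestInterpret:
    @pytest.mark.parametrize("value, label", [
        (-0.1, "poor"), (0.0, "poor"), (0.1, "slight"), (0.35, "fair"),
        (0.65, "substantial"), (0.85, "almost perfect"), (1.0, "almost perfect"),
    ])
    def test_default_bands(self, value, label):
        assert interpret(value) == label

    def test_custom_bands_and_range_check(self):
        bands = ((0.5, "low"), (1.0, "high"))
        assert interpret(0.4, bands) == "low"
        assert interpret(0.9, bands) == "high"
        with pytest.raises(ValueError):
            interpret(1.5)


class TestSummarize:
    def test_bundles_all_statistics_with_labels(self, fixture_tables):
        s = summarize(fixture_tables["lrc_nonelderly"], "quadratic")
        d = s.to_dict()
        assert set(d) >= {"po", "pe", "kappa", "kappa_weighted", "b",
                          "b_weighted", "scheme", "labels"}
        assert d["labels"]["kappa"] == "substantial"
        import json

        json.dumps(d)  # must be serializable

    def test_degenerate_table_flagged_not_nan(self):
        s = summarize([[7, 0], [0, 0]], "quadratic")
        assert s.degenerate and s.kappa is None and s.b == 1.0
        assert "undefined" in s.to_text()

    def test_random_tables_match_oracle_summary(self, rng):
        for _ in range(25):
            t = random_table(rng)
            s = summarize(t, "quadratic")
            cells = t.counts.tolist()
            assert s.kappa == pytest.approx(oracle_kappa(cells, "unweighted"), abs=1e-12)
            assert s.b_weighted == pytest.approx(
                oracle_weighted_b(cells, "quadratic"), abs=1e-12
            )
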