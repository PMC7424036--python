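import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pedpv import disproportionality as dis
from pedpv.disproportionality import ContingencyTable

from conftest import make_case
from oracle import naive_screen, naive_table


class TestBuildContingency:
    def test_single_case_with_pair(self):
        cases = [make_case("C1", ["X"], ["E"])]
        t = dis.build_contingency(cases, "X", "E")
        assert (t.a, t.b, t.c, t.d) == (1, 0, 0, 0)

    def test_case_level_counting_ignores_repeats(self):
        case = make_case("C1", ["X"], ["E"])
        case.drugs.append(case.drugs[0])  # same drug listed twice
        t = dis.build_contingency([case], "X", "E")
        assert t.a == 1 and t.n_total == 1

    def test_matches_brute_force_on_hand_fixture(self, ten_cases):
        for drug in ("VANCOMYCIN", "OXACILLIN", "LARONIDASE"):
            for event in ("RASH", "FEVER", "COUGH"):
                t = dis.build_contingency(ten_cases, drug, event)
                assert (t.a, t.b, t.c, t.d) == naive_table(ten_cases, drug, event)
                assert t.n_total == len(ten_cases)

    def test_enumerate_pair_tables_agrees_with_direct_build(self, ten_cases):
        tables = dis.enumerate_pair_tables(ten_cases, min_a=1)
        for (drug, event), t in tables.items():
            assert t == dis.build_contingency(ten_cases, drug, event)


class TestComputeRor:
    def test_balanced_table_is_one(self):
        assert dis.compute_ror(ContingencyTable(1, 1, 1, 1)) == (1.0, False)

    def test_hand_evaluated_ratio(self):
        ror, sentinel = dis.compute_ror(ContingencyTable(5, 95, 10, 1890))
        assert not sentinel
        assert ror == pytest.approx(9.947368, abs=1e-6)

    def test_c_zero_gives_sentinel(self):
        ror, sentinel = dis.compute_ror(ContingencyTable(3, 40, 0, 1934))
        assert sentinel and ror == 99.9

    def test_a_zero_is_undefined(self):
        with pytest.raises(dis.UndefinedPairError):
            dis.compute_ror(ContingencyTable(0, 5, 5, 100))

    def test_zero_b_or_d_uses_haldane_correction(self):
        ror, sentinel = dis.compute_ror(ContingencyTable(3, 0, 10, 200))
        assert not sentinel
        assert ror == pytest.approx((3.5 * 200.5) / (10.5 * 0.5))
        res = dis.score_pair("X", "E", ContingencyTable(3, 0, 10, 200))
        assert res.haldane_corrected


class TestComputeCi:
    def test_hand_evaluated_woolf_interval(self):
        lo, hi = dis.compute_ci(ContingencyTable(5, 95, 10, 1890))
        assert lo == pytest.approx(3.334, abs=2e-3)
        assert hi == pytest.approx(29.68, abs=2e-2)

    def test_balanced_table_interval_contains_one_symmetric_in_log(self):
        t = ContingencyTable(100, 100, 100, 100)
        lo, hi = dis.compute_ci(t)
        assert lo < 1 < hi
        assert math.log(lo) == pytest.approx(-math.log(hi), abs=1e-12)

    def test_scaling_cells_narrows_interval_same_point(self):
        small = ContingencyTable(5, 95, 10, 1890)
        big = ContingencyTable(50, 950, 100, 18900)
        assert dis.compute_ror(big)[0] == pytest.approx(dis.compute_ror(small)[0])
        lo_s, hi_s = dis.compute_ci(small)
        lo_b, hi_b = dis.compute_ci(big)
        assert lo_s < lo_b and hi_b < hi_s

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            dis.compute_ci(ContingencyTable(5, 5, 5, 5), level=1.2)


cells = st.integers(1, 500)


@given(a=cells, b=cells, c=cells, d=cells)
def test_ror_invariant_under_bc_swap_and_reciprocal_under_row_swap(a, b, c, d):
    ror, _ = dis.compute_ror(ContingencyTable(a, b, c, d))
    swapped, _ = dis.compute_ror(ContingencyTable(a, c, b, d))
    assert swapped == pytest.approx(ror)
    recip, _ = dis.compute_ror(ContingencyTable(c, d, a, b))
    assert recip == pytest.approx(1 / ror)


@given(a=st.integers(1, 100), b=cells, c=cells, d=cells)
def test_increasing_a_strictly_increases_ror_and_lower_bound(a, b, c, d):
    t0, t1 = ContingencyTable(a, b, c, d), ContingencyTable(a + 1, b, c, d)
    assert dis.compute_ror(t1)[0] > dis.compute_ror(t0)[0]
    assert dis.compute_ci(t1)[0] > dis.compute_ci(t0)[0]


@given(a=cells, b=cells, c=cells, d=cells)
def test_conservation_and_ci_brackets_estimate(a, b, c, d):
    t = ContingencyTable(a, b, c, d)
    assert t.n_total == a + b + c + d
    res = dis.score_pair("X", "E", t)
    assert res.ci_lower < res.ror < res.ci_upper


class TestDetectSdr:
    def _result(self, a, c=10, ci_lower=None):
        t = ContingencyTable(a, 40, c, 1000)
        res = dis.score_pair("DRUG", "EVENT", t)
        if ci_lower is not None:
            res.ci_lower = ci_lower
        return res

    def test_monitored_drug_qualifies_at_a_3(self):
        out = dis.detect_sdr([self._result(3, ci_lower=1.4)], {"DRUG"}, {"EVENT"})[0]
        assert out.is_sdr and out.stratum == dis.STRATUM_A_3_TO_4

    def test_unmonitored_drug_needs_a_5(self):
        out = dis.detect_sdr([self._result(4, ci_lower=5.0)], set(), {"EVENT"})[0]
        assert not out.is_sdr and out.stratum == dis.STRATUM_A_3_TO_4

    def test_lower_bound_below_one_is_not_a_signal(self):
        out = dis.detect_sdr([self._result(8, ci_lower=0.9)], set(), {"EVENT"})[0]
        assert not out.is_sdr

    def test_non_ime_event_never_signals(self):
        out = dis.detect_sdr([self._result(8, ci_lower=3.0)], set(), set())[0]
        assert not out.is_sdr

    def test_below_threshold_stratum_for_small_a(self):
        out = dis.detect_sdr([self._result(2, ci_lower=9.0)], {"DRUG"}, {"EVENT"})[0]
        assert out.stratum == dis.STRATUM_BELOW and not out.is_sdr

    def test_sentinel_table_qualifies_without_ci(self):
        t = ContingencyTable(5, 40, 0, 1000)
        res = dis.score_pair("DRUG", "EVENT", t)
        out = dis.detect_sdr([res], set(), {"EVENT"})[0]
        assert out.sentinel and out.is_sdr and out.ci_lower is None


def test_screen_matches_naive_reference_on_random_fixtures():
    rng = np.random.default_rng(2024)
    drug_vocab = [f"D{i}" for i in range(6)]
    event_vocab = [f"E{i}" for i in range(5)]
    monitoring, ime = {"D0", "D1"}, {"E0", "E1", "E2"}
    from oracle import random_fixture

    for _ in range(25):
        cases = random_fixture(rng, int(rng.integers(5, 51)), drug_vocab, event_vocab)
        expected = naive_screen(cases, monitoring, ime)
        got = {
            (r.drug_name, r.event_term): r
            for r in dis.screen(cases, monitoring, ime)
        }
        assert set(got) == set(expected)
        for key, (a, b, c, d, ror, lo, sentinel, is_sdr) in expected.items():
            r = got[key]
            assert (r.table.a, r.table.b, r.table.c, r.table.d) == (a, b, c, d)
            assert r.ror == pytest.approx(ror)
            assert r.sentinel == sentinel
            if not sentinel:
                assert r.ci_lower == pytest.approx(lo)
            assert r.is_sdr == is_sdr


def test_term_list_round_trip(tmp_path):
    path = tmp_path / "terms.txt"
    path.write_text("# comment line\npneumonia  \nApnoea # inline\n\nRASH\n")
    assert dis.read_term_list(path) == {"PNEUMONIA", "APNOEA", "RASH"}


def test_signals_csv_empty_when_nothing_scored(tmp_path):
    path = dis.write_signals([], tmp_path / "signals.csv")
    assert path.read_text().strip() == ",".join(dis.SIGNALS_COLUMNS)
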