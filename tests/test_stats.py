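from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pvsignal.simulate import SyntheticTruth, simulate_store
from pvsignal.stats import (
    ContingencyTable,
    build_table,
    evaluate_signal,
    ic,
    is_signal,
    ror,
    signal_table,
)

cells = st.integers(min_value=1, max_value=10_000)


class TestContingencyTable:
    def test_rejects_negative_and_empty(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)
        with pytest.raises(ValueError):
            ContingencyTable(0, 0, 0, 0)

    def test_expected_count(self):
        table = ContingencyTable(100, 900, 9900, 989100)
        assert table.expected == pytest.approx(10.0)


class TestRor:
    def test_null_table(self):
        est = ror(ContingencyTable(10, 90, 100, 900))
        assert est.ror == pytest.approx(1.0)
        assert est.low == pytest.approx(0.50398, abs=1e-4)
        assert est.high == pytest.approx(1.98421, abs=1e-4)
        assert not est.haldane_applied

    def test_strong_signal_table(self):
        est = ror(ContingencyTable(100, 900, 9900, 989100))
        assert est.ror == pytest.approx(11.1010101, rel=1e-8)
        assert est.low == pytest.approx(9.0204, abs=1e-3)
        assert est.high == pytest.approx(13.6615, abs=1e-3)

    def test_zero_cell_requires_haldane(self):
        table = ContingencyTable(0, 10, 5, 100)
        with pytest.raises(ValueError, match="correction"):
            ror(table, haldane=False)
        est = ror(table)  # default auto-corrects
        assert est.haldane_applied
        assert est.ror == pytest.approx((0.5 * 100.5) / (10.5 * 5.5))

    @given(a=cells, b=cells, c=cells, d=cells)
    def test_reciprocal_symmetry(self, a, b, c, d):
        fwd = ror(ContingencyTable(a, b, c, d))
        rev = ror(ContingencyTable(c, d, a, b))
        assert fwd.ror * rev.ror == pytest.approx(1.0, rel=1e-9)
        assert fwd.low == pytest.approx(1.0 / rev.high, rel=1e-9)

    @given(a=st.integers(1, 500), b=cells, c=cells, d=cells)
    def test_monotone_in_a(self, a, b, c, d):
        lower = ror(ContingencyTable(a, b, c, d)).ror
        higher = ror(ContingencyTable(a + 1, b, c, d)).ror
        assert higher > lower


class TestIc:
    def test_zero_at_independence(self):
        # a equals its expected count: (a+b)(a+c)/N = 10
        table = ContingencyTable(10, 90, 10, 90)
        assert table.expected == pytest.approx(10.0)
        assert ic(table).ic == pytest.approx(0.0)

    def test_shrunk_observed_to_expected(self):
        est = ic(ContingencyTable(100, 900, 9900, 989100))
        assert est.ic == pytest.approx(3.25873, abs=1e-4)
        assert est.low == pytest.approx(2.92757, abs=1e-4)
        assert est.high == pytest.approx(3.49764, abs=1e-4)

    def test_zero_count_is_negative_not_an_error(self):
        table = ContingencyTable(0, 40, 50, 910)  # E = 2
        assert ic(table).ic == pytest.approx(math.log2(0.5 / 2.5))

    def test_bate_variance_agrees_at_large_counts(self):
        table = ContingencyTable(500, 99_500, 5_000, 995_000)
        noren = ic(table)
        bate = ic(table, method="bate_variance")
        assert bate.ic == pytest.approx(noren.ic, abs=0.05)
        assert bate.low < bate.ic < bate.high

    @given(a=cells, b=cells, c=cells, d=st.integers(1, 500))
    def test_monotone_in_d(self, a, b, c, d):
        # enlarging the unexposed non-case cell lowers the expected count,
        # so the shrunk observed-to-expected ratio strictly increases
        lower = ic(ContingencyTable(a, b, c, d))
        higher = ic(ContingencyTable(a, b, c, d + 1))
        assert higher.ic > lower.ic

    @pytest.mark.parametrize("rate", [1.0, 1.5, 2.0])
    def test_large_count_consistency_with_planted_rate(self, rate):
        """At expected counts with all cells >= 1e4 and a small exposed
        share, both ROR and 2**IC estimate the planted relative rate
        within 5%."""
        p = 0.02
        n1, n0 = 500_000, 20_000_000
        a = int(round(rate * p * n1))
        b = n1 - a
        c = int(round(p * n0))
        d = n0 - c
        assert min(a, b, c, d) >= 10_000
        table = ContingencyTable(a, b, c, d)
        assert ror(table).ror == pytest.approx(rate, rel=0.05)
        assert 2 ** ic(table).ic == pytest.approx(rate, rel=0.05)


class TestSignalRule:
    @pytest.mark.parametrize(
        ("n", "ror_low", "ic_low", "expected"),
        [
            (3, 1.2, 0.1, True),
            (2, 5.0, 2.0, False),   # below the case threshold
            (50, 0.9, 0.2, False),  # ROR lower bound not above 1
            (50, 1.0, 0.2, False),  # boundary: ROR025 must exceed 1
            (50, 1.5, 0.0, False),  # boundary: IC025 must exceed 0
            (50, 1.5, 0.3, True),
        ],
    )
    def test_joint_rule(self, n, ror_low, ic_low, expected):
        assert is_signal(n, ror_low, ic_low) is expected

    def test_evaluate_signal_echoes_components(self):
        table = ContingencyTable(100, 900, 9900, 989100)
        res = evaluate_signal(table)
        assert res.n_cases == 100
        assert res.expected == pytest.approx(10.0)
        assert res.is_signal  # ror_low ~ 9.0, ic_low ~ 2.9


class TestBuildTable:
    @staticmethod
    def _store(counts):
        rows = []
        for group, (n_case, n_ctrl) in counts.items():
            rows += [{"group": group, "is_case": True}] * n_case
            rows += [{"group": group, "is_case": False}] * n_ctrl
        return pd.DataFrame(rows)

    def test_rest_of_store_counts(self):
        store = self._store({"statin:x": (10, 90), "other": (100, 900)})
        table = build_table(store, "statin:x")
        assert table.cells() == (10, 90, 100, 900)

    def test_explicit_background(self):
        store = self._store({"colchicine": (348, 18046)})
        table = build_table(store, "colchicine", comparator="explicit_background",
                            background=(18847, 992746))
        assert table.cells() == (348, 18046, 18847, 992746)

    def test_zero_case_group_is_not_an_error(self):
        store = self._store({"statin:x": (0, 50), "other": (10, 100)})
        assert build_table(store, "statin:x").a == 0

    def test_empty_group_raises(self):
        store = self._store({"other": (10, 100)})
        with pytest.raises(ValueError, match="no exposed reports"):
            build_table(store, "colchicine")

    def test_aggregate_groups(self):
        store = self._store({"statin:x": (5, 45), "statin:y": (5, 45),
                             "other": (10, 90)})
        table = build_table(store, ["statin:x", "statin:y"])
        assert table.cells() == (10, 90, 10, 90)

    def test_signal_table_skips_absent_groups(self):
        store = self._store({"statin:x": (10, 90), "other": (10, 890)})
        frame = signal_table(store, ["statin:x", "colchicine"])
        assert list(frame["group"]) == ["statin:x"]


class TestOracleEquivalence:
    def test_ror_matches_statsmodels(self):
        """The hand-rolled odds ratio and Woolf interval must agree with an
        independent implementation to floating-point accuracy."""
        from statsmodels.stats.contingency_tables import Table2x2

        rng = np.random.default_rng(42)
        for _ in range(25):
            a, b, c, d = rng.integers(1, 2000, size=4)
            table = ContingencyTable(int(a), int(b), int(c), int(d))
            est = ror(table)
            sm = Table2x2([[a, b], [c, d]], shift_zeros=False)
            assert est.ror == pytest.approx(sm.oddsratio, rel=1e-12)
            low, high = sm.oddsratio_confint(0.05)
            # statsmodels uses the exact normal quantile; z=1.96 is the
            # conventional rounding, so agreement is to ~1e-4 relative.
            assert est.low == pytest.approx(low, rel=1e-3)
            assert est.high == pytest.approx(high, rel=1e-3)

    def test_counts_match_brute_force_recount(self):
        """Cells built by the vectorised path equal a plain-Python recount
        over raw labeled records, and the statistics recompute exactly."""
        truth = SyntheticTruth(
            n_reports=10_000,
            exposure_weights={"colchicine": 0.2, "statin:simvastatin": 0.3,
                              "other": 0.5},
            background_event_prob={"rhabdomyolysis": 0.03, "myopathy": 0.02},
            planted=[{"group": "colchicine", "pt": "rhabdomyolysis", "rate": 3.0}],
            duplicate_rate=0, deleted_rate=0, preexisting_indication_rate=0,
        )
        store, _ = simulate_store(truth, seed=9)
        for group in ("colchicine", "statin:simvastatin"):
            for pt in ("rhabdomyolysis", "myopathy"):
                col = f"pt:{pt}"
                a = b = c = d = 0
                for row_group, flag in zip(store["group"], store[col]):
                    if row_group == group:
                        a, b = (a + 1, b) if flag else (a, b + 1)
                    else:
                        c, d = (c + 1, d) if flag else (c, d + 1)
                table = build_table(store, group, case_col=col)
                assert table.cells() == (a, b, c, d)
                est = ror(table)
                assert est.ror == (a * d) / (b * c)
                n = a + b + c + d
                expected = (a + b) * (a + c) / n
                assert abs(ic(table).ic - math.log2((a + 0.5) / (expected + 0.5))) < 1e-12
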