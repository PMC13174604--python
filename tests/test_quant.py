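import numpy as np
import pandas as pd
import pytest

from iresmpra.quant import (
    CountMatrix,
    combine_replicates,
    compute_rpm,
    compute_te,
    filter_low_input,
    normalize_luciferase,
    replicate_correlation,
    te_pipeline,
)


def make_cm(count_rows, sample_rows):
    counts = pd.DataFrame(count_rows, columns=["construct_id", "cap_class", "sample_id", "count"])
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "role", "condition", "bio_rep", "tech_rep"]
    )
    return CountMatrix(counts, samples)


SAMPLES_2TECH = [
    ("in_t1", "input", "control", "1", "1"),
    ("in_t2", "input", "control", "1", "2"),
]


class TestCombineReplicates:
    def test_technical_sum(self):
        cm = make_cm(
            [("X", "a_cap", "in_t1", 3), ("X", "a_cap", "in_t2", 7)], SAMPLES_2TECH
        )
        out = combine_replicates(cm, "technical")
        assert out.counts["count"].tolist() == [10]
        assert out.samples["sample_id"].tolist() == ["input_control_b1"]

    def test_single_replicate_identity(self):
        cm = make_cm([("X", "a_cap", "in_t1", 5)], SAMPLES_2TECH[:1])
        assert combine_replicates(cm, "technical").counts["count"].tolist() == [5]

    def test_biological_sum_with_zero(self):
        rows = [
            ("in_b1", "input", "control", "1", "1"),
            ("in_b2", "input", "control", "2", "1"),
            ("in_b3", "input", "control", "3", "1"),
        ]
        cm = make_cm(
            [("X", "g_cap", "in_b1", 1), ("X", "g_cap", "in_b2", 0), ("X", "g_cap", "in_b3", 4)],
            rows,
        )
        assert combine_replicates(cm, "biological").counts["count"].tolist() == [5]


class TestFilterLowInput:
    def _cm(self, c1, c2):
        rows = [
            ("in_a", "input", "control", "1", "1"),
            ("in_b", "input", "stress", "1", "1"),
        ]
        return make_cm(
            [("X", "a_cap", "in_a", c1), ("X", "a_cap", "in_b", c2)], rows
        )

    def test_below_threshold_in_any_library_removes(self):
        flags = filter_low_input(self._cm(9, 1000))
        assert flags["filtered_low_input"].tolist() == [True]

    def test_exactly_ten_everywhere_retained(self):
        flags = filter_low_input(self._cm(10, 10))
        assert flags["filtered_low_input"].tolist() == [False]

    def test_zero_removed(self):
        flags = filter_low_input(self._cm(0, 50))
        assert flags["filtered_low_input"].tolist() == [True]

    def test_monotone_in_min_input(self):
        rng = np.random.default_rng(1)
        rows = [("in_a", "input", "control", "1", "1")]
        counts = [
            (f"c{i}", "a_cap", "in_a", int(rng.integers(0, 40))) for i in range(30)
        ]
        cm = make_cm(counts, rows)
        prev_removed = set()
        for thr in (0, 5, 10, 20, 50):
            flags = filter_low_input(cm, thr)
            removed = set(flags.loc[flags["filtered_low_input"], "construct_id"])
            assert prev_removed <= removed
            prev_removed = removed


class TestComputeRpm:
    def _setup(self, ip_zero=False):
        rows = [
            ("inp", "input", "control", "1", "1"),
            ("ip", "IP", "control", "1", "1"),
        ]
        counts = [
            ("X", "a_cap", "inp", 10),
            ("Y", "a_cap", "inp", 990),
            ("X", "a_cap", "ip", 0 if ip_zero else 500),
            ("Y", "a_cap", "ip", 500),
        ]
        cm = make_cm(counts, rows)
        flags = filter_low_input(cm)
        return cm, flags

    def test_rpm_arithmetic(self):
        cm, flags = self._setup()
        rpm = compute_rpm(cm, flags)
        x = rpm[(rpm.construct_id == "X") & (rpm.sample_id == "inp")]["rpm"].iloc[0]
        assert x == pytest.approx(10_000.0)

    def test_ip_zero_gets_pseudocount_flag(self):
        cm, flags = self._setup(ip_zero=True)
        rpm = compute_rpm(cm, flags)
        row = rpm[(rpm.construct_id == "X") & (rpm.sample_id == "ip")].iloc[0]
        assert row["ip_pseudocounted"]
        assert 0 < row["rpm"] < 1  # 1e-6 scaled by ~2e6/500
        # input zeros are never pseudocounted
        assert not rpm[rpm.sample_id == "inp"]["ip_pseudocounted"].any()

    def test_rpm_totals_conserved(self):
        cm, flags = self._setup(ip_zero=True)
        rpm = compute_rpm(cm, flags)
        for sid, sub in rpm.groupby("sample_id"):
            assert abs(sub["rpm"].sum() - 1e6) < 1.0


class TestComputeTe:
    def _te(self, input_counts, ip_counts):
        rows = [
            ("inp", "input", "control", "1", "1"),
            ("ip", "IP", "control", "1", "1"),
        ]
        counts = [("A", "a_cap", "inp", input_counts[0]), ("B", "a_cap", "inp", input_counts[1]),
                  ("A", "a_cap", "ip", ip_counts[0]), ("B", "a_cap", "ip", ip_counts[1])]
        cm = make_cm(counts, rows)
        flags = filter_low_input(cm)
        rpm = compute_rpm(cm, flags)
        return compute_te(rpm, cm.samples, flags)

    def test_log2_ratio(self):
        te = self._te((100, 100), (50, 150)).set_index("construct_id")
        # input RPM equal; A takes 25% of IP
        assert te.loc["A", "te_linear"] == pytest.approx(0.5)
        assert te.loc["A", "log2_te"] == pytest.approx(-1.0)

    def test_equal_rpm_gives_zero_log2(self):
        te = self._te((100, 100), (300, 300)).set_index("construct_id")
        assert te.loc["A", "log2_te"] == pytest.approx(0.0)

    def test_log2_consistency(self):
        te = self._te((100, 37), (50, 403))
        ok = ~te["filtered_low_input"]
        assert np.allclose(te.loc[ok, "log2_te"], np.log2(te.loc[ok, "te_linear"]))

    def test_filtered_rows_carry_no_te(self):
        rows = [("inp", "input", "control", "1", "1"), ("ip", "IP", "control", "1", "1")]
        cm = make_cm(
            [("A", "a_cap", "inp", 5), ("B", "a_cap", "inp", 100),
             ("A", "a_cap", "ip", 50), ("B", "a_cap", "ip", 50)],
            rows,
        )
        flags = filter_low_input(cm)
        te = compute_te(compute_rpm(cm, flags), cm.samples, flags).set_index("construct_id")
        assert te.loc["A", "filtered_low_input"]
        assert np.isnan(te.loc["A", "te_linear"])

    def test_depth_invariance(self, toy_countmatrix):
        # raise all counts above the input filter first: uniform scaling can
        # only be TE-neutral when it does not move constructs across the
        # min-input boundary
        cm = toy_countmatrix.copy()
        cm.counts["count"] += 10
        te1 = te_pipeline(cm)
        scaled = cm.copy()
        scaled.counts["count"] *= 7
        te2 = te_pipeline(scaled)
        m = te1.merge(te2, on=["construct_id", "cap_class"], suffixes=("_1", "_7"))
        ok = ~m["filtered_low_input_1"] & ~m["ip_pseudocounted_1"] & ~m["ip_pseudocounted_7"]
        assert ok.any()
        assert np.allclose(m.loc[ok, "te_linear_1"], m.loc[ok, "te_linear_7"])


class TestReplicateCorrelation:
    def _table(self, log2, ip_counts):
        n = len(log2)
        return pd.DataFrame(
            {
                "construct_id": [f"c{i}" for i in range(n)],
                "cap_class": ["a_cap"] * n,
                "log2_te": log2,
                "ip_count": ip_counts,
                "filtered_low_input": [False] * n,
            }
        )

    def test_self_correlation_is_one(self):
        t = self._table([0.5, 1.0, -2.0, 3.0], [5, 5, 5, 5])
        out = replicate_correlation({"a": t, "b": t.copy()})
        assert out["pearson_r"].iloc[0] == pytest.approx(1.0)

    def test_zero_ip_construct_excluded(self):
        a = self._table([0.5, 1.0, -2.0, 3.0], [5, 5, 5, 0])
        b = self._table([0.4, 1.1, -1.9, 9.9], [5, 5, 5, 5])
        out = replicate_correlation({"a": a, "b": b})
        assert out["n_constructs"].iloc[0] == 3

    def test_too_few_shared_constructs(self):
        a = self._table([1.0, 2.0], [0, 5])
        b = self._table([1.0, 2.0], [5, 5])
        with pytest.raises(ValueError):
            replicate_correlation({"a": a, "b": b})

    def test_independent_resimulations_correlate(self, toy_library, toy_truth):
        from conftest import simulate_sample
        from iresmpra.readproc import process_pairs

        tables = {}
        for tag in ("r1", "r2"):
            frames = []
            for role, sid in (("input", f"in_{tag}"), ("IP", f"ip_{tag}")):
                reads, _ = simulate_sample(toy_truth, toy_library, role, sid)
                frames.append(process_pairs(iter(reads), toy_library, sid).counts)
            samples = pd.DataFrame(
                {
                    "sample_id": [f"in_{tag}", f"ip_{tag}"],
                    "role": ["input", "IP"],
                    "condition": ["control"] * 2,
                    "bio_rep": ["1"] * 2,
                    "tech_rep": ["1"] * 2,
                }
            )
            tables[tag] = te_pipeline(CountMatrix(pd.concat(frames), samples))
        out = replicate_correlation(tables)
        assert out["pearson_r"].iloc[0] > 0.9


class TestLuciferase:
    def test_ratio_arithmetic(self):
        assert normalize_luciferase(1100, 600, 100, 100) == pytest.approx(2.0)

    def test_zero_signal(self):
        assert normalize_luciferase(100, 600, 100, 100) == pytest.approx(0.0)

    def test_background_denominator_error(self):
        with pytest.raises(ValueError):
            normalize_luciferase(1100, 100, 100, 100)
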