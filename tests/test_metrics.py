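"""Base counts, error-rate filters, detection limits, tracking, concordance."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from uidseq.consensus import ConsensusRead, collapse_reads
from uidseq.metrics import (
    base_counts,
    call_variants_naive,
    concordance,
    detection_limit,
    error_rate,
    format_detection_limit,
    recurrence_filter,
    required_coverage,
    track_mutations,
)


def _cons(pos, seq, strand="+", size=3, chrom="chr1"):
    return ConsensusRead(chrom, pos, strand, "AAAAAA", seq, size)


REF = "ACGTACGTACGTACGTACGT"  # 20 bp


class TestBaseCounts:
    def test_all_ref_reads(self):
        reads = [_cons(0, REF[:10]) for _ in range(3)]
        table = base_counts(reads, [(0, 20)], REF)
        row = table.set_index("pos").loc[0]
        assert row["A"] == 3 and row["unique_depth"] == 3

    def test_one_alt_in_ten(self):
        reads = [_cons(0, REF[:8]) for _ in range(9)]
        alt = "T" + REF[1:8]
        reads.append(_cons(0, alt))
        table = base_counts(reads, [(0, 20)], REF).set_index("pos")
        assert table.loc[0, "T"] == 1
        assert table.loc[0, "A"] == 9
        assert table.loc[0, "T"] / table.loc[0, "unique_depth"] == pytest.approx(0.1)

    def test_n_excluded_from_unique_depth(self):
        reads = [_cons(0, "NCGT"), _cons(0, "ACGT"), _cons(0, "ACGT")]
        table = base_counts(reads, [(0, 20)], REF).set_index("pos")
        assert table.loc[0, "N"] == 1
        assert table.loc[0, "unique_depth"] == 2

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        reads = [
            _cons(int(p), REF[int(p) : int(p) + 6])
            for p in rng.integers(0, 14, 50)
        ]
        t1 = base_counts(reads, [(0, 20)], REF)
        shuffled = [reads[i] for i in rng.permutation(len(reads))]
        t2 = base_counts(shuffled, [(0, 20)], REF)
        pd.testing.assert_frame_equal(t1, t2)

    def test_off_target_reads_tallied(self):
        reads = [_cons(0, "ACGT"), _cons(15, "CGT")]
        table = base_counts(reads, [(0, 8)], REF)
        assert table.attrs["off_target"] == 1

    def test_minus_strand_read_placement(self):
        # '-' read with 5' coordinate 9 covering [6, 10)
        read = _cons(9, REF[6:10], strand="-")
        table = base_counts([read], [(0, 20)], REF).set_index("pos")
        for p in range(6, 10):
            assert table.loc[p, REF[p]] == 1
        assert table.loc[5, "unique_depth"] == 0

    def test_raw_depth_interval_coverage(self, clean_run, clean_config):
        reads, _, _ = clean_run
        _, cons = collapse_reads(reads)
        ref = __import__("uidseq.simulate", fromlist=["reference_sequence"]).reference_sequence(clean_config)
        table = base_counts(cons, clean_config.panel_regions, ref, raw_reads=reads)
        # cross-check one position by brute force
        pos = int(table.loc[table["raw_depth"].idxmax(), "pos"])
        brute = sum(
            1 for r in reads if r.leftmost <= pos < r.leftmost + len(r.sequence)
        )
        assert table.set_index("pos").loc[pos, "raw_depth"] == brute


def _table(rows):
    df = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "A", "C", "G", "T", "N", "raw_depth"],
    )
    df["unique_depth"] = df[["A", "C", "G", "T"]].sum(axis=1)
    return df


class TestErrorRate:
    def test_basic_rate(self):
        """99 ref + 1 alt at depth 100 -> rate 0.01."""
        t = _table([("chr1", 5, "A", 99, 1, 0, 0, 0, 1000)])
        res = error_rate(t)
        assert res.sample_rate == pytest.approx(0.01)

    def test_filters_each_exclude(self):
        rows = [
            ("chr1", 1, "A", 99, 1, 0, 0, 0, 1000),   # retained, rate 0.01
            ("chr1", 2, "A", 19, 0, 0, 0, 0, 1000),   # unique depth 19 < 20
            ("chr1", 3, "A", 100, 0, 0, 0, 0, 199),   # raw depth 199 < 200
            ("chr1", 4, "A", 100, 0, 0, 0, 0, 1000),  # dbSNP-masked
            ("chr1", 5, "A", 85, 15, 0, 0, 0, 1000),  # 15% error > 10%
            ("chr1", 6, "C", 2, 98, 0, 0, 0, 1000),   # retained, rate 0.02
        ]
        res = error_rate(_table(rows), known_snp_positions=[4])
        assert sorted(res.positions["pos"]) == [1, 6]
        assert res.sample_rate == pytest.approx((0.01 + 0.02) / 2)
        assert res.exclusions["snp"] == 1
        assert res.exclusions["low_unique_depth"] == 1
        assert res.exclusions["low_raw_depth"] == 1
        assert res.exclusions["high_error"] == 1

    def test_filter_order_invariance(self):
        """Position-local filters: any application order retains the same set."""
        rows = [
            ("chr1", p, "A", 100 - p, p, 0, 0, 0, 1000 if p < 8 else 150)
            for p in range(12)
        ]
        t = _table(rows)
        res = error_rate(t, known_snp_positions=[2, 9])
        keep = set(res.positions["pos"])
        # manual recomputation in a different order: depth, rate, snp
        manual = []
        for _, row in t.iterrows():
            if row["raw_depth"] < 200 or row["unique_depth"] < 20:
                continue
            rate = (row["unique_depth"] - row["A"]) / row["unique_depth"]
            if rate > 0.10:
                continue
            if row["pos"] in (2, 9):
                continue
            manual.append(row["pos"])
        assert keep == set(manual)

    def test_no_retained_positions_raises(self):
        t = _table([("chr1", 1, "A", 5, 0, 0, 0, 0, 10)])
        with pytest.raises(ValueError):
            error_rate(t)

    def test_consensus_below_raw_on_simulation(self, small_config):
        """Collapse suppresses errors: consensus rate < raw rate."""
        import dataclasses

        from uidseq.simulate import reference_sequence, simulate_reads

        cfg = dataclasses.replace(small_config, seq_error_rate=0.005, seed=13)
        reads, _, _ = simulate_reads(cfg)
        _, cons = collapse_reads(reads)
        ref = reference_sequence(cfg)
        t_cons = base_counts(cons, cfg.panel_regions, ref, raw_reads=reads)
        t_raw = base_counts(reads, cfg.panel_regions, ref, raw_reads=reads)
        r_cons = error_rate(t_cons, min_raw_depth=0, min_unique_depth=10)
        r_raw = error_rate(t_raw, min_raw_depth=0, min_unique_depth=10)
        assert r_cons.sample_rate < r_raw.sample_rate


class TestDetectionLimit:
    def test_values_and_formatting(self):
        assert detection_limit(249) == pytest.approx(1 / 249)
        assert format_detection_limit(249) == "0.4%"
        assert format_detection_limit(551) == "0.18%"
        assert format_detection_limit(1) == "100%"

    def test_zero_coverage_undefined(self):
        with pytest.raises(ValueError):
            detection_limit(0)

    def test_required_coverage(self):
        assert required_coverage(0.001) == 1000
        assert required_coverage(1.0) == 1
        assert required_coverage(0.0033) == 304

    def test_required_coverage_invalid(self):
        for af in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                required_coverage(af)


class TestTrackMutations:
    def test_zero_alt_not_detected(self):
        t = _table([("chr1", 3, "G", 0, 0, 400, 0, 0, 5000)])
        out = track_mutations(t, [("chr1", 3, "G", "A")])
        row = out.iloc[0]
        assert not row["detected"] and row["vaf"] == 0.0
        assert row["detection_limit"] == pytest.approx(1 / 400)

    def test_vaf_and_limit_definitions(self):
        t = _table([("chr1", 3, "G", 20, 0, 380, 0, 0, 5000)])
        row = track_mutations(t, [("chr1", 3, "G", "A")]).iloc[0]
        assert row["vaf"] == pytest.approx(0.05)
        assert row["detected"]
        assert row["vaf"] >= row["detection_limit"]  # holds for any detection

    def test_site_outside_panel_reported_missing(self):
        t = _table([("chr1", 3, "G", 0, 0, 400, 0, 0, 5000)])
        row = track_mutations(t, [("chr1", 99, "G", "A")]).iloc[0]
        assert np.isnan(row["unique_depth"]) and not row["detected"]

    def test_spiked_vaf_within_binomial_interval(self, small_config):
        """A 5% spike at ~400x comes back inside the binomial 95% CI."""
        import dataclasses

        from uidseq.simulate import (
            SpikedMutation,
            reference_sequence,
            simulate_reads,
        )
        from scipy import stats as sps

        cfg = dataclasses.replace(
            small_config,
            spiked_mutations=(SpikedMutation(6_000, "N", "X", 0.05),),
            seed=17,
        )
        ref = reference_sequence(cfg)
        refbase = ref[6_000]
        alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[refbase]
        cfg = dataclasses.replace(
            cfg, spiked_mutations=(SpikedMutation(6_000, refbase, alt, 0.05),)
        )
        reads, _, _ = simulate_reads(cfg)
        _, cons = collapse_reads(reads)
        table = base_counts(cons, cfg.panel_regions, ref)
        row = track_mutations(table, [(cfg.chrom, 6_000, refbase, alt)]).iloc[0]
        depth = int(row["unique_depth"])
        lo, hi = sps.binom.interval(0.95, depth, 0.05)
        assert lo <= row["alt_count"] <= hi


class TestRecurrenceFilter:
    def _calls(self, detected_in):
        return {
            s: pd.DataFrame(
                [{"chrom": "chr1", "pos": 10, "ref": "A", "alt": "T"}]
                if s in detected_in
                else [],
                columns=["chrom", "pos", "ref", "alt"],
            )
            for s in "abcdefghij"
        }

    def test_variant_in_four_of_ten_removed(self):
        filtered, removed = recurrence_filter(self._calls("abcd"))
        assert len(removed) == 1
        assert all(df.empty for df in filtered.values())

    def test_variant_in_three_retained(self):
        filtered, removed = recurrence_filter(self._calls("abc"))
        assert removed.empty
        assert sum(len(df) for df in filtered.values()) == 3

    def test_empty_input(self):
        calls = {"s1": pd.DataFrame(columns=["chrom", "pos", "ref", "alt"])}
        filtered, removed = recurrence_filter(calls)
        assert filtered["s1"].empty and removed.empty


class TestConcordance:
    def _tables(self, n_truth=38, n_detected=24):
        rng = np.random.default_rng(5)
        truth = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.arange(n_truth),
                "detected": True,
                "af": rng.uniform(0.001, 0.2, n_truth),
            }
        )
        ngs = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.arange(n_truth),
                "detected": [i < n_detected for i in range(n_truth)],
                "vaf": truth["af"] * 1.1,
                "unique_depth": 500,
            }
        )
        return ngs, truth

    def test_24_of_38_is_63_2_percent(self):
        ngs, truth = self._tables()
        res = concordance(ngs, truth)
        assert res.sensitivity_pct == 63.2
        assert res.n_truth_detected == 38 and res.n_both_detected == 24

    def test_identical_afs_correlate_perfectly(self):
        ngs, truth = self._tables()
        ngs["vaf"] = truth["af"]
        res = concordance(ngs, truth)
        assert res.af_pearson_r == pytest.approx(1.0)

    def test_zero_truth_detections_flagged(self):
        ngs, truth = self._tables()
        truth["detected"] = False
        res = concordance(ngs, truth)
        assert not res.sensitivity_defined
        assert np.isnan(res.sensitivity_pct)

    def test_coverage_sufficiency_flags(self):
        ngs, truth = self._tables(n_truth=2, n_detected=2)
        truth.loc[0, "af"] = 0.01   # needs 100x, depth 500 -> sufficient
        truth.loc[1, "af"] = 0.001  # needs 1000x, depth 500 -> insufficient
        res = concordance(ngs, truth)
        flags = list(res.per_mutation["coverage_sufficient"])
        assert flags == [True, False]


class TestNaiveCaller:
    def test_detects_clear_variant_and_skips_singletons(self):
        t = _table(
            [
                ("chr1", 1, "A", 95, 5, 0, 0, 0, 1000),   # 5 alt reads, VAF 5%
                ("chr1", 2, "A", 99, 1, 0, 0, 0, 1000),   # singleton -> skipped
            ]
        )
        calls = call_variants_naive(t, min_alt=2)
        assert len(calls) == 1
        assert calls.iloc[0]["pos"] == 1 and calls.iloc[0]["alt"] == "C"
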