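import numpy as np
import pandas as pd
import pytest

from bovarch.core import MISSING
from bovarch.roh import (
    ROHParams,
    annotate_islands,
    call_roh,
    call_roh_panel,
    find_islands,
    island_length,
    read_gene_intervals,
    roh_length_summary,
    window_scan,
)

from conftest import make_panel

SMALL = ROHParams(window_snp=10, window_het_max=1, window_missing_max=2,
                  window_hit_threshold=0.05, min_length_kb=100, min_snp=15,
                  max_gap_kb=500)


def brute_window_scores(d, params):
    """All-windows enumerator: the independent oracle for window_scan."""
    m = len(d)
    w = min(params.window_snp, m)
    hom = []
    for s in range(m - w + 1):
        win = d[s:s + w]
        hom.append(
            (win == 1).sum() <= params.window_het_max
            and (win == MISSING).sum() <= params.window_missing_max
        )
    scores = np.zeros(m)
    for i in range(m):
        cover = [hom[s] for s in range(max(0, i - w + 1), min(i, m - w) + 1)]
        scores[i] = np.mean(cover)
    return scores


class TestWindowScan:
    def test_all_homozygous_scores_one(self):
        d = np.zeros(100, dtype=np.int8)
        assert (window_scan(d, SMALL) == 1.0).all()

    def test_all_heterozygous_scores_zero(self):
        d = np.ones(100, dtype=np.int8)
        assert (window_scan(d, SMALL) == 0.0).all()

    def test_two_adjacent_hets_dip_matches_bruteforce(self):
        d = np.zeros(200, dtype=np.int8)
        d[100] = d[101] = 1
        params = ROHParams(window_snp=50)
        np.testing.assert_allclose(window_scan(d, params), brute_window_scores(d, params))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.choice([0, 0, 0, 0, 2, 2, 1, MISSING], size=300).astype(np.int8)
        np.testing.assert_allclose(window_scan(d, SMALL), brute_window_scores(d, SMALL))

    def test_chromosome_shorter_than_window_uses_truncated_window(self):
        d = np.zeros(5, dtype=np.int8)
        assert (window_scan(d, SMALL) == 1.0).all()
        d[2] = d[3] = 1  # 2 hets > budget in the single truncated window
        assert (window_scan(d, SMALL) == 0.0).all()


class TestCallRoh:
    def test_implanted_run_bounds_snap_to_markers(self):
        # 300 hom markers inside a het background; 10 kb spacing
        d = np.ones(500, dtype=np.int8)
        d[100:400] = 0
        pos = np.arange(1, 501) * 10_000
        scores = window_scan(d, SMALL)
        segs = call_roh(scores, d, pos, SMALL)
        assert len(segs) == 1
        a, b, n_snp, n_het, n_miss = segs[0]
        # bounds within one marker of the implant edges
        assert abs(a - 100) <= 1 and abs(b - 399) <= 1
        assert n_het <= 2 and n_miss == 0

    def test_gap_rule_splits_runs(self):
        # homozygous markers with a 600 kb gap in the middle (> 500 kb max)
        pos = np.concatenate([np.arange(1, 31) * 10_000,
                              np.arange(31, 61) * 10_000 + 600_000])
        d = np.zeros(60, dtype=np.int8)
        scores = window_scan(d, SMALL)
        segs = call_roh(scores, d, pos, SMALL)
        assert len(segs) == 2
        (a1, b1, *_), (a2, b2, *_) = segs
        assert (a1, b1) == (0, 29) and (a2, b2) == (30, 59)

    def test_short_run_below_min_length_dropped(self):
        params = ROHParams(window_snp=10, min_length_kb=1000, min_snp=10,
                           max_gap_kb=1000)
        d = np.zeros(50, dtype=np.int8)
        pos = np.arange(1, 51) * 10_000  # total span 490 kb < 1000 kb
        segs = call_roh(window_scan(d, params), d, pos, params)
        assert segs == []

    def test_min_snp_threshold(self):
        params = ROHParams(window_snp=10, min_length_kb=100, min_snp=60,
                           max_gap_kb=1000)
        d = np.zeros(50, dtype=np.int8)
        pos = np.arange(1, 51) * 10_000
        assert call_roh(window_scan(d, params), d, pos, params) == []

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(1)
        d = rng.choice([0, 2, 1], p=[0.6, 0.35, 0.05], size=(20, 400)).astype(np.int8)
        d[:10, 100:300] = 0
        g = make_panel(d, positions=np.arange(1, 401) * 10_000)
        segs = call_roh_panel(g, SMALL)
        perm = rng.permutation(20)
        gp = g.subset(sample_idx=perm)
        segs_p = call_roh_panel(gp, SMALL)
        pd.testing.assert_frame_equal(
            segs.reset_index(drop=True), segs_p.reset_index(drop=True)
        )


class TestLengthSummary:
    def _segs(self, lengths_mb, sample="s0", breed="POP"):
        return pd.DataFrame({
            "sample_id": sample, "breed": breed, "chrom": "1",
            "start_bp": 1_000_000,
            "end_bp": [int(1_000_000 + l * 1e6) for l in lengths_mb],
            "length_bp": [int(l * 1e6) for l in lengths_mb],
            "n_snp": 100, "n_het": 0, "n_missing": 0,
        })

    def test_single_short_segment(self):
        _, pop = roh_length_summary(self._segs([4]))
        assert pop["<5Mb"].iloc[0] == pytest.approx(100.0)

    def test_mixed_lengths_arithmetic(self):
        _, pop = roh_length_summary(self._segs([2, 6, 40]))
        row = pop.iloc[0]
        assert row["<5Mb"] == pytest.approx(100 * 2 / 48)
        assert row["<=10Mb"] == pytest.approx(100 * 6 / 48)
        assert row[">31Mb"] == pytest.approx(100 * 40 / 48)

    def test_empty_segment_list(self):
        per_sample, pop = roh_length_summary(pd.DataFrame(
            columns=["sample_id", "breed", "chrom", "start_bp", "end_bp",
                     "length_bp", "n_snp", "n_het", "n_missing"]))
        assert per_sample.empty and pop.empty


class TestIslandLength:
    @pytest.mark.parametrize("start,end,expected", [
        (42_096_163, 43_741_249, 1_645_086),
        (54_590_248, 60_271_069, 5_680_821),
        (7, 8, 1),
    ])
    def test_end_minus_start(self, start, end, expected):
        assert island_length(start, end) == expected

    def test_reversed_bounds_rejected(self):
        with pytest.raises(ValueError):
            island_length(10, 10)


class TestFindIslands:
    def _seg_table(self, spans):
        # spans: list of (sample, start, end)
        return pd.DataFrame([
            {"sample_id": s, "breed": "POP", "chrom": "1", "start_bp": a,
             "end_bp": b, "length_bp": b - a, "n_snp": 0, "n_het": 0,
             "n_missing": 0}
            for s, a, b in spans
        ])

    def _markers(self, n=50, spacing=100_000):
        return make_panel(np.zeros((1, n), dtype=np.int8),
                          positions=np.arange(1, n + 1) * spacing).markers

    def test_shared_segment_above_majority(self):
        mk = self._markers()
        segs = self._seg_table([(f"s{i}", 1_000_000, 3_000_000) for i in range(6)])
        isl = find_islands(segs, mk, n_samples=10)
        assert len(isl) == 1
        assert isl["carrier_fraction"].iloc[0] == pytest.approx(0.6)
        assert isl["start_bp"].iloc[0] == 1_000_000
        assert isl["end_bp"].iloc[0] == 3_000_000

    def test_exactly_half_is_not_an_island(self):
        mk = self._markers()
        segs = self._seg_table([(f"s{i}", 1_000_000, 3_000_000) for i in range(5)])
        assert find_islands(segs, mk, n_samples=10).empty

    def test_staggered_segments_match_per_marker_counting(self):
        mk = self._markers()
        spans = ([(f"s{i}", 1_000_000, 3_000_000) for i in range(6)]
                 + [(f"s{i}", 2_000_000, 4_000_000) for i in range(4, 10)])
        segs = self._seg_table(spans)
        isl = find_islands(segs, mk, n_samples=10)
        # brute-force per-marker incidence
        pos = mk["pos_bp"].to_numpy()
        inc = np.zeros(pos.size)
        for sid in {s for s, *_ in spans}:
            cover = np.zeros(pos.size, dtype=bool)
            for s, a, b in spans:
                if s == sid:
                    cover |= (pos >= a) & (pos <= b)
            inc += cover
        inc /= 10
        expected_mask = inc > 0.5
        got_mask = np.zeros(pos.size, dtype=bool)
        for _, r in isl.iterrows():
            got_mask |= (pos >= r["start_bp"]) & (pos <= r["end_bp"])
        np.testing.assert_array_equal(got_mask, expected_mask)

    def test_segment_order_invariance(self):
        mk = self._markers()
        spans = [(f"s{i}", 1_000_000, 3_000_000) for i in range(7)]
        segs = self._seg_table(spans)
        a = find_islands(segs, mk, n_samples=10)
        b = find_islands(segs.iloc[::-1].reset_index(drop=True), mk, n_samples=10)
        pd.testing.assert_frame_equal(a, b)

    def test_extra_heterozygous_sample_cannot_enlarge_islands(self):
        mk = self._markers()
        segs = self._seg_table([(f"s{i}", 1_000_000, 3_000_000) for i in range(6)])
        before = find_islands(segs, mk, n_samples=10)
        after = find_islands(segs, mk, n_samples=11)  # extra sample, no ROH
        if after.empty:
            return
        assert len(after) <= len(before)
        assert (after["length_bp"] <= before["length_bp"]).all()


class TestAnnotation:
    def _islands(self):
        return pd.DataFrame([
            {"population": "POP", "chrom": "1", "start_bp": 100, "end_bp": 200,
             "length_bp": 100, "n_snp": 5, "carrier_fraction": 0.7, "genes": ""},
        ])

    def test_overlap_and_adjacency(self):
        genes = pd.DataFrame({
            "chrom": ["1", "1"], "start_bp": [150, 201], "end_bp": [250, 300],
            "gene_id": ["OVER", "ADJ"],
        })
        out = annotate_islands(self._islands(), genes)
        assert out["genes"].iloc[0] == "OVER"

    def test_unknown_chromosome_warns_and_skips(self):
        genes = pd.DataFrame({"chrom": ["99"], "start_bp": [1], "end_bp": [2],
                              "gene_id": ["X"]})
        with pytest.warns(UserWarning, match="99"):
            out = annotate_islands(self._islands(), genes)
        assert out["genes"].iloc[0] == ""

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(0)
        islands = pd.DataFrame([
            {"population": "POP", "chrom": "1", "start_bp": int(a),
             "end_bp": int(a + 500), "length_bp": 500, "n_snp": 5,
             "carrier_fraction": 0.6, "genes": ""}
            for a in rng.integers(0, 5000, 3)
        ])
        genes = pd.DataFrame({
            "chrom": "1",
            "start_bp": rng.integers(0, 5000, 10),
        }).assign(end_bp=lambda x: x["start_bp"] + rng.integers(10, 800, 10),
                  gene_id=[f"g{i}" for i in range(10)])
        out = annotate_islands(islands, genes)
        for _, isl in out.iterrows():
            expected = sorted(
                (g["gene_id"] for _, g in genes.iterrows()
                 if g["start_bp"] <= isl["end_bp"] and g["end_bp"] >= isl["start_bp"]),
                key=lambda gid: int(genes.set_index("gene_id").loc[gid, "start_bp"]),
            )
            got = isl["genes"].split(",") if isl["genes"] else []
            assert sorted(got) == sorted(expected)

    def test_bed_and_gff3_round(self, tmp_path):
        bed = tmp_path / "g.bed"
        bed.write_text("1\t99\t200\tGENE1\n")
        g = read_gene_intervals(bed)
        assert g.iloc[0].tolist() == ["1", 100, 200, "GENE1"]
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "1\tsrc\tgene\t100\t200\t.\t+\t.\tID=GENE1;Name=foo\n"
            "1\tsrc\texon\t100\t150\t.\t+\t.\tID=exon1\n"
        )
        g2 = read_gene_intervals(gff)
        assert len(g2) == 1
        assert g2.iloc[0].tolist() == ["1", 100, 200, "GENE1"]


class TestEmittedSegmentsRespectThresholds:
    def test_post_hoc_threshold_audit(self):
        rng = np.random.default_rng(5)
        d = rng.choice([0, 2, 1, MISSING], p=[0.5, 0.35, 0.1, 0.05],
                       size=(15, 600)).astype(np.int8)
        d[:8, 150:450] = 0
        g = make_panel(d, positions=np.arange(1, 601) * 10_000)
        segs = call_roh_panel(g, SMALL)
        assert not segs.empty
        assert (segs["length_bp"] >= SMALL.min_length_kb * 1000).all()
        assert (segs["n_snp"] >= SMALL.min_snp).all()
        assert (segs["length_bp"] == segs["end_bp"] - segs["start_bp"]).all()
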