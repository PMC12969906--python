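"""Coverage windows, DOC ratios and duplication calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from acescan import cnv
from acescan import simulate as sim


def frame(contig, pos, depth):
    return pd.DataFrame({"contig": contig, "pos": pos, "depth": depth})


def constant_depth(contig, length, depth):
    return frame(contig, np.arange(1, length + 1), depth)


class TestProfile:
    def test_constant_depth(self):
        p = cnv.profile_from_depth(constant_depth("c", 1000, 10), "c")
        assert len(p.mean_depth) == 10
        assert np.allclose(p.mean_depth, 10)
        assert p.normalizer == 10
        assert p.starts[0] == 1 and p.ends[-1] == 1000

    def test_elevated_block(self):
        df = constant_depth("c", 1000, 10)
        df.loc[df["pos"].between(101, 200), "depth"] = 20
        p = cnv.profile_from_depth(df, "c")
        assert p.mean_depth[1] == 20
        assert np.allclose(np.delete(p.mean_depth, 1), 10)

    def test_sparse_table_implicit_zeros(self):
        # only odd positions listed at depth 8: window means are 4
        df = frame("c", np.arange(1, 1001, 2), 8)
        p = cnv.profile_from_depth(df, "c", contig_lengths={"c": 1000})
        assert np.allclose(p.mean_depth, 4)

    def test_partial_final_window_dropped(self):
        p = cnv.profile_from_depth(constant_depth("c", 250, 5), "c")
        assert len(p.mean_depth) == 2

    def test_unknown_contig(self):
        with pytest.raises(ValueError):
            cnv.profile_from_depth(constant_depth("c", 100, 5), "nope")

    def test_bad_window(self):
        with pytest.raises(ValueError):
            cnv.profile_from_depth(constant_depth("c", 100, 5), "c", window_size=0)

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 2**20), frac=st.floats(0.2, 1.0), size=st.integers(7, 60))
    def test_window_means_match_brute_force(self, seed, frac, size):
        rng = np.random.default_rng(seed)
        length = 500
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=int(frac * length), replace=False))
        depth = rng.integers(0, 50, size=pos.size)
        df = frame("c", pos, depth)
        p = cnv.profile_from_depth(df, "c", window_size=size, window_step=size,
                                   contig_lengths={"c": length})
        dense = np.zeros(length)
        dense[pos - 1] = depth
        for i, (s, e) in enumerate(zip(p.starts, p.ends)):
            assert p.mean_depth[i] == pytest.approx(dense[s - 1 : e].mean())


class TestRatio:
    def test_identical_profiles_give_unit_ratio(self):
        df = constant_depth("c", 1000, 12)
        p = cnv.profile_from_depth(df, "c")
        t = cnv.doc_ratio(p, p)
        assert np.allclose(t.ratio, 1.0)
        assert t.masked_fraction == 0.0

    def test_global_doubling_normalizes_away(self):
        """A genome-wide 2x library-size difference vanishes under median
        normalization; only a local duplication shifts ratios."""
        sen = constant_depth("c", 10_000, 10)
        res = constant_depth("c", 10_000, 20)
        t = cnv.doc_ratio(cnv.profile_from_depth(res, "c"), cnv.profile_from_depth(sen, "c"))
        assert np.allclose(t.ratio, 1.0)
        # unnormalized oracle: raw window ratio is 2 everywhere
        raw = cnv.profile_from_depth(res, "c").mean_depth / cnv.profile_from_depth(sen, "c").mean_depth
        assert np.allclose(raw, 2.0)

    def test_local_duplication_shifts_span_only(self):
        # span small relative to the contig, so it cannot move the median
        sen = constant_depth("c", 10_000, 10)
        res = constant_depth("c", 10_000, 10)
        res.loc[res["pos"].between(3001, 4000), "depth"] = 20
        t = cnv.doc_ratio(cnv.profile_from_depth(res, "c"), cnv.profile_from_depth(sen, "c"))
        inside = slice(30, 40)
        assert np.allclose(t.ratio[inside], 2.0)
        assert np.allclose(np.concatenate([t.ratio[:30], t.ratio[40:]]), 1.0)

    def test_zero_denominator_masked(self):
        sen = constant_depth("c", 300, 10)
        sen.loc[sen["pos"].between(101, 200), "depth"] = 0
        res = constant_depth("c", 300, 10)
        t = cnv.doc_ratio(cnv.profile_from_depth(res, "c"), cnv.profile_from_depth(sen, "c"))
        assert np.isnan(t.ratio[1])
        assert t.masked_fraction == pytest.approx(1 / 3)

    def test_windowing_mismatch_rejected(self):
        a = cnv.profile_from_depth(constant_depth("c", 1000, 10), "c", window_size=100)
        b = cnv.profile_from_depth(constant_depth("c", 1000, 10), "c", window_size=50)
        with pytest.raises(ValueError):
            cnv.doc_ratio(a, b)


class TestCall:
    def make_track(self, contig, n_windows, value):
        starts = np.arange(n_windows) * 100 + 1
        return cnv.RatioTrack(contig, starts, starts + 99, np.full(n_windows, value, dtype=float))

    def test_duplicated_locus_called(self):
        t = self.make_track("tgt", 100, 2.0)
        c = self.make_track("ctl", 100, 1.0)
        call = cnv.call_duplication(
            t, cnv.Span("tgt", 2000, 4000), c, cnv.Span("ctl", 0, 2000)
        )
        assert call.is_duplicated and call.control_ok
        assert call.copy_estimate == pytest.approx(2.0)

    def test_single_copy_not_called(self):
        t = self.make_track("tgt", 100, 1.0)
        c = self.make_track("ctl", 100, 1.0)
        call = cnv.call_duplication(t, cnv.Span("tgt", 0, 1000), c, cnv.Span("ctl", 0, 1000))
        assert not call.is_duplicated

    def test_bad_control_vetoes_call(self):
        t = self.make_track("tgt", 100, 2.0)
        c = self.make_track("ctl", 100, 1.6)
        call = cnv.call_duplication(t, cnv.Span("tgt", 0, 1000), c, cnv.Span("ctl", 0, 1000))
        assert not call.control_ok and not call.is_duplicated

    def test_all_masked_span_errors(self):
        t = self.make_track("tgt", 10, np.nan)
        c = self.make_track("ctl", 10, 1.0)
        with pytest.raises(ValueError):
            cnv.call_duplication(t, cnv.Span("tgt", 0, 500), c, cnv.Span("ctl", 0, 500))


class TestSimulationRecovery:
    L = {"KE524393-like": 41_288, "vgsc_contig": 35_000}

    def run_once(self, seed, copy_number):
        cov = sim.CoverageSpec(copy_number=copy_number)
        res = sim.gen_depth(cov, seed=seed, resistant=True)
        sen = sim.gen_depth(cov, seed=seed + 1_000_000, resistant=False)
        t = cnv.doc_ratio(
            cnv.profile_from_depth(res, cov.target_contig, contig_lengths=self.L),
            cnv.profile_from_depth(sen, cov.target_contig, contig_lengths=self.L),
        )
        c = cnv.doc_ratio(
            cnv.profile_from_depth(res, cov.control_contig, contig_lengths=self.L),
            cnv.profile_from_depth(sen, cov.control_contig, contig_lengths=self.L),
        )
        return cnv.call_duplication(
            t, cnv.Span(cov.target_contig, cov.dup_start, cov.dup_end),
            c, cnv.Span(cov.control_contig, 5_000, 9_000), locus_name="ace1",
        )

    def test_copy2_recovered(self):
        """Poisson 30x, 4 kb copy-2 span: duplication called with a copy
        estimate inside 2 +/- 0.2 in >= 95% of 20 seeded replicates."""
        good = sum(
            (c.is_duplicated and abs(c.copy_estimate - 2.0) <= 0.2 and c.control_ok)
            for c in (self.run_once(s, 2.0) for s in range(20))
        )
        assert good >= 19

    def test_copy1_not_called(self):
        calls = [self.run_once(100 + s, 1.0) for s in range(20)]
        assert sum(not c.is_duplicated for c in calls) >= 19

    def test_deletion_halves_ratio(self):
        call = self.run_once(7, 0.5)
        assert call.mean_ratio == pytest.approx(0.5, abs=0.1)
        assert not call.is_duplicated


class TestIO:
    def test_depth_tsv_roundtrip(self, tmp_path):
        df = constant_depth("c", 120, 9)
        path = tmp_path / "d.tsv"
        sim.write_depth_tsv(df, path)
        back = cnv.read_depth_tsv(path)
        pd.testing.assert_frame_equal(back, df)

    def test_bed_spans_and_bedgraph(self, tmp_path):
        bed = tmp_path / "loci.bed"
        bed.write_text("ctg\t100\t300\tace1\nctl\t0\t50\tvgsc\n")
        spans = cnv.read_bed_spans(bed)
        assert spans["ace1"] == cnv.Span("ctg", 100, 300)
        track = cnv.RatioTrack("ctg", np.array([1, 101]), np.array([100, 200]),
                               np.array([1.0, np.nan]))
        out = tmp_path / "t.bedgraph"
        cnv.write_bedgraph(track, out)
        lines = out.read_text().strip().splitlines()
        assert lines[1] == "ctg\t0\t100\t1"
        assert len(lines) == 2  # masked window skipped
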