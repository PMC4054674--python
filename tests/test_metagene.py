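"""Metagene profiles, point profiles, the length-ordered matrix and bins."""

import numpy as np
import pytest

from nucvar.io import GeneModel, ProbeTrack
from nucvar.metagene import (bin_by_expression, grouped_profiles,
                             metagene_profile, point_profile, tss_tts_matrix)


def _gene(gid, start, end, strand="+", chrom="chr1", expression=()):
    tss, tts = (start, end) if strand == "+" else (end, start)
    return GeneModel(id=gid, chromosome=chrom, strand=strand, tss=tss,
                     tts=tts, expression=np.asarray(expression, dtype=float))


def _dense_track(length, fn, chrom="chr1", spacing=5):
    pos = np.arange(0, length, spacing)
    return {chrom: ProbeTrack(chrom, pos, fn(pos))}


class TestMetageneProfile:
    def test_constant_track_gives_constant_profile(self):
        tracks = _dense_track(30_000, lambda p: np.full(len(p), 3.5))
        genes = [_gene("g1", 8_000, 12_000), _gene("g2", 18_000, 23_000, "-")]
        prof = metagene_profile(tracks, genes, flank=3000, bin_size=50,
                                n_body_bins=100)
        np.testing.assert_allclose(prof.concat(), 3.5)
        assert prof.n_genes == 2

    def test_minus_strand_profile_mirrors_plus_strand(self):
        # signal symmetric about the genome midpoint; a minus-strand gene
        # mirrored through it must produce the same profile
        L = 40_000
        rng = np.random.default_rng(0)
        half = rng.normal(size=L // 10)
        sig = np.concatenate([half, half[::-1]])
        pos = np.arange(0, L, 5)
        tracks = {"chr1": ProbeTrack("chr1", pos, sig[:len(pos)])}
        # mirror of [8000,12000)+ is (L-12000, L-8000] on the minus strand
        gp = _gene("gp", 8_000, 12_000, "+")
        gm = _gene("gm", L - 12_000, L - 8_000, "-")
        pp = metagene_profile(tracks, [gp], flank=2000, bin_size=100,
                              n_body_bins=40)
        pm = metagene_profile(tracks, [gm], flank=2000, bin_size=100,
                              n_body_bins=40)
        # mirrored track sampling differs by at most the probe phase
        np.testing.assert_allclose(pp.concat(), pm.concat(), atol=0.35)

    def test_matches_brute_force_averaging_oracle(self):
        rng = np.random.default_rng(7)
        L = 120_000
        pos = np.arange(0, L, 5)
        vals = rng.normal(size=len(pos))
        tracks = {"chr1": ProbeTrack("chr1", pos, vals)}
        genes = []
        start = 5_000
        for i in range(10):
            end = start + int(rng.integers(1500, 6000))
            genes.append(_gene(f"g{i}", start, end,
                               "+" if rng.random() < 0.5 else "-"))
            start = end + 4_000
        flank, bs, nb = 3000, 50, 100
        prof = metagene_profile(tracks, genes, flank=flank, bin_size=bs,
                                n_body_bins=nb)
        # oracle: per-gene, per-bin direct averaging, then mean over genes
        n_flank = flank // bs
        acc = [[[] for _ in range(n_flank)], [[] for _ in range(nb)],
               [[] for _ in range(n_flank)]]
        for g in genes:
            s = 1 if g.strand == "+" else -1
            glen = abs(g.tts - g.tss)
            for b in range(n_flank):
                lo, hi = -flank + b * bs, -flank + (b + 1) * bs
                w = _window_vals(pos, vals, g.tss, lo, hi, s)
                if len(w):
                    acc[0][b].append(w.mean())
                w = _window_vals(pos, vals, g.tts, b * bs, (b + 1) * bs, s)
                if len(w):
                    acc[2][b].append(w.mean())
            for b in range(nb):
                lo, hi = glen * b / nb, glen * (b + 1) / nb
                w = _window_vals(pos, vals, g.tss, lo, hi, s)
                if len(w):
                    acc[1][b].append(w.mean())
        expect = np.concatenate([[np.mean(c) for c in part] for part in acc])
        np.testing.assert_allclose(prof.concat(), expect, atol=1e-12)

    def test_affine_equivariance(self):
        rng = np.random.default_rng(8)
        tracks = _dense_track(30_000, lambda p: rng.normal(size=len(p)))
        genes = [_gene("g1", 8_000, 13_000)]
        base = metagene_profile(tracks, genes, flank=2000, n_body_bins=50)
        t2 = {"chr1": ProbeTrack("chr1", tracks["chr1"].positions,
                                 2.0 * tracks["chr1"].values + 1.0)}
        scaled = metagene_profile(t2, genes, flank=2000, n_body_bins=50)
        np.testing.assert_allclose(scaled.concat(), 2.0 * base.concat() + 1.0,
                                   atol=1e-12)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(9)
        tracks = _dense_track(50_000, lambda p: rng.normal(size=len(p)))
        genes = [_gene(f"g{i}", 5_000 + 9_000 * i, 10_000 + 9_000 * i)
                 for i in range(5)]
        a = metagene_profile(tracks, genes, flank=2000, n_body_bins=50)
        b = metagene_profile(tracks, genes[::-1], flank=2000, n_body_bins=50)
        # equal up to float summation order
        np.testing.assert_allclose(a.concat(), b.concat(), rtol=1e-12)

    def test_short_gene_skipped_with_warning(self):
        tracks = _dense_track(10_000, lambda p: np.zeros(len(p)))
        genes = [_gene("tiny", 5_000, 5_050), _gene("ok", 6_000, 8_000)]
        with pytest.warns(UserWarning, match="tiny"):
            prof = metagene_profile(tracks, genes, n_body_bins=100)
        assert prof.n_genes == 1


class TestGroupedProfiles:
    def test_single_group_equals_plain_profile(self):
        rng = np.random.default_rng(10)
        tracks = _dense_track(40_000, lambda p: rng.normal(size=len(p)))
        genes = [_gene(f"g{i}", 5_000 + 9_000 * i, 10_000 + 9_000 * i)
                 for i in range(4)]
        grouping = {g.id: "all" for g in genes}
        grouped = grouped_profiles(tracks, genes, grouping, flank=2000,
                                   n_body_bins=50)
        plain = metagene_profile(tracks, genes, flank=2000, n_body_bins=50)
        np.testing.assert_array_equal(grouped["all"].concat(), plain.concat())

    def test_planted_tts_signal_orders_expression_bins(self, small_config,
                                                       small_truth,
                                                       small_tracks):
        """Variant signal at the TTS is planted preferentially at
        high-expression genes, so the top expression bin's downstream
        profile must exceed the bottom bin's near the TTS."""
        genes = [g for g in small_truth.genes
                 if g.feature_type == "protein_coding" and g.expression.sum() > 0]
        ebins = bin_by_expression(genes, n_bins=4)
        grouped = grouped_profiles(small_tracks["variant"], genes,
                                   ebins.assignment, flank=1000, bin_size=100,
                                   n_body_bins=20)
        top, bottom = grouped[4], grouped[1]
        # compare mean signal in the first 500 bp downstream of the TTS
        t = np.nanmean(top.downstream_bins[:5])
        b = np.nanmean(bottom.downstream_bins[:5])
        assert t > b

    def test_gene_order_within_groups_irrelevant(self):
        rng = np.random.default_rng(11)
        tracks = _dense_track(60_000, lambda p: rng.normal(size=len(p)))
        genes = [_gene(f"g{i}", 4_000 + 9_000 * i, 9_000 + 9_000 * i)
                 for i in range(6)]
        grouping = {g.id: i % 2 for i, g in enumerate(genes)}
        a = grouped_profiles(tracks, genes, grouping, flank=1000,
                             n_body_bins=20)
        b = grouped_profiles(tracks, genes[::-1], grouping, flank=1000,
                             n_body_bins=20)
        for key in a:
            np.testing.assert_allclose(a[key].concat(), b[key].concat(),
                                       rtol=1e-12)


class TestPointProfile:
    def test_constant_track_flat_profile_zero_band(self):
        tracks = _dense_track(20_000, lambda p: np.full(len(p), 2.0))
        points = [("chr1", 5_000.0), ("chr1", 9_000.0)]
        df = point_profile(tracks, points, half_width=600, bin_size=50)
        np.testing.assert_allclose(df["mean"], 2.0)
        np.testing.assert_allclose(df["ci_high"] - df["ci_low"], 0.0,
                                   atol=1e-12)

    def test_single_point_equals_local_signal(self):
        rng = np.random.default_rng(12)
        tracks = _dense_track(10_000, lambda p: rng.normal(size=len(p)))
        df = point_profile(tracks, [("chr1", 5_000.0)], half_width=200,
                           bin_size=50)
        track = tracks["chr1"]
        for off, m in zip(df["offset"], df["mean"]):
            lo = 5_000 + off - 25
            sel = (track.positions >= lo) & (track.positions < lo + 50)
            assert m == pytest.approx(track.values[sel].mean())

    def test_matches_stacking_oracle(self):
        rng = np.random.default_rng(13)
        tracks = _dense_track(50_000, lambda p: rng.normal(size=len(p)))
        points = [("chr1", float(c)) for c in rng.integers(2_000, 48_000, 30)]
        df = point_profile(tracks, points, half_width=600, bin_size=100)
        track = tracks["chr1"]
        stacks = []
        for _chrom, c in points:
            row = []
            for b in range(12):
                lo = c - 600 + b * 100
                sel = (track.positions >= lo) & (track.positions < lo + 100)
                row.append(track.values[sel].mean())
            stacks.append(row)
        np.testing.assert_allclose(df["mean"], np.nanmean(stacks, axis=0),
                                   atol=1e-12)

    def test_empty_points_rejected(self):
        with pytest.raises(ValueError):
            point_profile({}, [], half_width=600)


class TestTssTtsMatrix:
    def test_constant_track_constant_matrix(self):
        tracks = _dense_track(60_000, lambda p: np.full(len(p), 1.5))
        genes = [_gene(f"g{i}", 5_000 + 11_000 * i, 9_000 + 11_000 * i)
                 for i in range(5)]
        mat = tss_tts_matrix(tracks, genes, max_body=5000, downstream=1000,
                             bin_size=100)
        vals = mat.to_numpy()
        np.testing.assert_allclose(vals[np.isfinite(vals)], 1.5)

    def test_rows_ordered_by_gene_length(self):
        rng = np.random.default_rng(14)
        tracks = _dense_track(200_000, lambda p: np.zeros(len(p)))
        genes = []
        start = 2_000
        for i in range(12):
            end = start + int(rng.integers(1_000, 9_000))
            genes.append(_gene(f"g{i}", start, end))
            start = end + 3_000
        mat = tss_tts_matrix(tracks, genes)
        lengths = [next(g.length for g in genes if g.id == gid)
                   for gid in mat.index]
        assert lengths == sorted(lengths)

    def test_cells_match_direct_window_means(self):
        rng = np.random.default_rng(15)
        tracks = _dense_track(30_000, lambda p: rng.normal(size=len(p)))
        g = _gene("g0", 4_000, 10_500, "-")
        mat = tss_tts_matrix(tracks, [g], max_body=5000, downstream=1000,
                             bin_size=100)
        track = tracks["chr1"]
        # minus strand: TSS = 10,500; body bin b covers [tss-(b+1)*100, tss-b*100)
        for b in (0, 17, 49):
            lo, hi = 10_500 - (b + 1) * 100, 10_500 - b * 100
            sel = (track.positions >= lo) & (track.positions < hi)
            assert mat.iloc[0, b] == pytest.approx(track.values[sel].mean())


class TestBinByExpression:
    def test_eight_genes_four_even_bins(self):
        genes = [_gene(f"g{i}", 1_000 * i + 100, 1_000 * i + 600,
                       expression=[float(i + 1)] * 2) for i in range(8)]
        ebins = bin_by_expression(genes, n_bins=4)
        sizes = [sum(1 for b in ebins.assignment.values() if b == k)
                 for k in (1, 2, 3, 4)]
        assert sizes == [2, 2, 2, 2]
        assert ebins.assignment["g0"] == 1 and ebins.assignment["g7"] == 4

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(16)
        vals = rng.lognormal(size=20)
        genes = [_gene(f"g{i}", 1_000 * i + 100, 1_000 * i + 600,
                       expression=[v, v]) for i, v in enumerate(vals)]
        warped = [_gene(f"g{i}", 1_000 * i + 100, 1_000 * i + 600,
                        expression=[np.exp(v), np.exp(v)])
                  for i, v in enumerate(vals)]
        assert bin_by_expression(genes).assignment == \
               bin_by_expression(warped).assignment

    def test_matches_sorting_oracle(self):
        rng = np.random.default_rng(17)
        vals = rng.normal(10, 2, size=23)
        genes = [_gene(f"g{i:02d}", 1_000 * i + 100, 1_000 * i + 600,
                       expression=[v, v]) for i, v in enumerate(vals)]
        ebins = bin_by_expression(genes, n_bins=4)
        order = [g.id for _, g in sorted(zip(vals, genes),
                                         key=lambda t: (t[0], t[1].id))]
        expect = {}
        for b, chunk in enumerate(np.array_split(order, 4), start=1):
            for gid in chunk:
                expect[gid] = b
        assert ebins.assignment == expect

    def test_all_equal_expression_rejected(self):
        genes = [_gene(f"g{i}", 1_000 * i + 100, 1_000 * i + 600,
                       expression=[1.0, 1.0]) for i in range(8)]
        with pytest.raises(ValueError):
            bin_by_expression(genes)


def _window_vals(pos, vals, anchor, off_lo, off_hi, sign):
    if sign > 0:
        lo, hi = anchor + off_lo, anchor + off_hi
    else:
        lo, hi = anchor - off_hi, anchor - off_lo
    sel = (pos >= lo) & (pos < hi)
    return vals[sel]
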