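"""Allele-frequency mapping: VCF filtering, windowing, region detection."""

import numpy as np
import pysam
import pytest

from poolmap import afmap, popsim
from poolmap.popsim import PooledVariant

from conftest import simulate_variants


def make_variant(chrom="ch01", pos=100, wt=(10, 10), mut=(10, 10), ref="A", alt="G",
                 known=False):
    return PooledVariant(chrom, pos, ref, alt, wt[0], wt[1], mut[0], mut[1], known)


def constant_af_variants(n, wt_af, mut_af, chrom="ch01", depth=30, start_pos=100):
    out = []
    for i in range(n):
        wt_alt = round(depth * wt_af)
        mut_alt = round(depth * mut_af)
        out.append(
            make_variant(chrom, start_pos + 10 * i, (depth - wt_alt, wt_alt),
                         (depth - mut_alt, mut_alt))
        )
    return out


def write_vcf(path, records):
    """records: (chrom, pos, alleles, wt_ad, mut_ad)."""
    header = pysam.VariantHeader()
    header.add_line("##contig=<ID=ch01,length=1000000>")
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="AD">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="DP">')
    header.add_sample("wt_pool")
    header.add_sample("mut_pool")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for chrom, pos, alleles, wt_ad, mut_ad in records:
            rec = vcf.new_record(contig=chrom, start=pos - 1, alleles=alleles)
            rec.samples["wt_pool"]["AD"] = wt_ad
            rec.samples["mut_pool"]["AD"] = mut_ad
            vcf.write(rec)


class TestReadPooledVcf:
    def test_depth_filter_boundary(self, tmp_path):
        path = tmp_path / "t.vcf"
        write_vcf(path, [
            ("ch01", 100, ("A", "G"), (4, 5), (20, 20)),   # wt depth 9 -> drop
            ("ch01", 200, ("A", "G"), (5, 5), (5, 5)),     # both exactly 10 -> keep
            ("ch01", 300, ("A", "G"), (20, 20), (4, 5)),   # mut depth 9 -> drop
        ])
        kept = afmap.read_pooled_vcf(str(path), min_depth=10)
        assert [v.pos for v in kept] == [200]

    def test_multiallelic_and_indel_records_dropped(self, tmp_path):
        path = tmp_path / "t.vcf"
        write_vcf(path, [
            ("ch01", 100, ("A", "G", "T"), (10, 5, 5), (10, 5, 5)),  # multiallelic
            ("ch01", 200, ("AT", "A"), (10, 10), (10, 10)),          # indel
            ("ch01", 300, ("A", "G"), (10, 10), (10, 10)),
        ])
        kept = afmap.read_pooled_vcf(str(path), min_depth=10)
        assert [v.pos for v in kept] == [300]

    def test_unknown_sample_errors(self, tmp_path):
        path = tmp_path / "t.vcf"
        write_vcf(path, [("ch01", 100, ("A", "G"), (10, 10), (10, 10))])
        with pytest.raises(ValueError, match="nope"):
            afmap.read_pooled_vcf(str(path), wt_sample="nope")


class TestAlleleFrequency:
    def test_values(self):
        assert afmap.allele_frequency(make_variant(wt=(10, 10)), "wt") == 0.5
        assert afmap.allele_frequency(make_variant(wt=(25, 0)), "wt") == 0.0
        assert afmap.allele_frequency(make_variant(mut=(0, 7)), "mut") == 1.0

    def test_zero_depth_errors(self):
        with pytest.raises(ValueError, match="zero depth"):
            afmap.allele_frequency(make_variant(wt=(0, 0)), "wt")


class TestWindowProfile:
    def test_2000_variants_default_windows(self):
        vs = constant_af_variants(2000, 0.5, 0.5)
        (prof,) = afmap.window_profile(vs, 1000, 100)
        assert len(prof.windows) == 11
        assert [w.start_index for w in prof.windows] == list(range(1, 1002, 100))
        assert all(w.n_variants == 1000 and not w.partial for w in prof.windows)
        assert all(w.mean_af_wt == 0.5 == w.mean_af_mut for w in prof.windows)

    def test_short_chromosome_yields_single_partial_window(self):
        vs = constant_af_variants(3, 0.5, 0.0)
        (prof,) = afmap.window_profile(vs, 5, 2)
        (w,) = prof.windows
        assert w.partial and w.n_variants == 3
        assert (w.start_bp, w.end_bp) == (vs[0].pos, vs[-1].pos)

    def test_window_mean_matches_brute_force(self):
        """Oracle equivalence on random small instances (window 5, step 2)."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = rng.integers(5, 51)
            vs = []
            for i in range(n):
                wt = (int(rng.integers(0, 30)), int(rng.integers(0, 30)))
                mut = (int(rng.integers(0, 30)), int(rng.integers(0, 30)))
                if sum(wt) == 0 or sum(mut) == 0:
                    wt, mut = (5, 5), (5, 5)
                vs.append(make_variant(pos=100 + i, wt=wt, mut=mut))
            (prof,) = afmap.window_profile(vs, 5, 2)
            afs_wt = [v.wt_alt / (v.wt_ref + v.wt_alt) for v in vs]
            afs_mut = [v.mut_alt / (v.mut_ref + v.mut_alt) for v in vs]
            expected = []
            s = 0
            while s + 5 <= n:
                expected.append(
                    (sum(afs_wt[s:s + 5]) / 5, sum(afs_mut[s:s + 5]) / 5)
                )
                s += 2
            assert len(prof.windows) == len(expected)
            for w, (ewt, emut) in zip(prof.windows, expected):
                assert w.mean_af_wt == pytest.approx(ewt, abs=1e-12)
                assert w.mean_af_mut == pytest.approx(emut, abs=1e-12)

    def test_profile_invariant_to_bp_coordinates(self):
        vs1 = constant_af_variants(20, 0.3, 0.1)
        vs2 = [
            PooledVariant(v.chrom, 10_000 + 997 * i, v.ref, v.alt,
                          v.wt_ref, v.wt_alt, v.mut_ref, v.mut_alt)
            for i, v in enumerate(vs1)
        ]
        p1 = afmap.window_profile(vs1, 5, 2)[0]
        p2 = afmap.window_profile(vs2, 5, 2)[0]
        assert [(w.mean_af_wt, w.mean_af_mut, w.start_index) for w in p1.windows] == \
               [(w.mean_af_wt, w.mean_af_mut, w.start_index) for w in p2.windows]

    def test_window_mean_bounded_by_member_afs(self):
        rng = np.random.default_rng(7)
        vs = []
        for i in range(60):
            alt = int(rng.integers(0, 21))
            vs.append(make_variant(pos=100 + i, wt=(20 - alt, alt), mut=(10, 10)))
        (prof,) = afmap.window_profile(vs, 10, 3)
        afs = [v.wt_alt / 20 for v in vs]
        for w in prof.windows:
            members = afs[w.start_index - 1:w.end_index]
            assert min(members) <= w.mean_af_wt <= max(members)

    def test_invalid_window_step(self):
        with pytest.raises(ValueError):
            afmap.window_profile([], window_size=2, step=5)


class TestDetectCandidateRegion:
    def test_flat_half_profiles_give_no_region(self):
        vs = constant_af_variants(30, 0.5, 0.5)
        profiles = afmap.window_profile(vs, 5, 2)
        assert afmap.detect_candidate_region(profiles) == []

    def test_depleted_chromosome_merges_into_one_region(self):
        vs = constant_af_variants(30, 2 / 3, 0.0, chrom="ch01") + \
             constant_af_variants(30, 0.5, 0.5, chrom="ch02")
        profiles = afmap.window_profile(vs, 5, 2)
        regions = afmap.detect_candidate_region(profiles, variants=vs)
        assert len(regions) == 1
        r = regions[0]
        n_windows = len(profiles[0].windows)
        assert (r.chrom, r.n_windows) == ("ch01", n_windows)
        # last full window ends at rank 29; the trailing variant gets no
        # extra partial window by design
        assert r.start_bp == vs[0].pos and r.end_bp == vs[28].pos
        assert len(r.variant_ids) == 29
        assert r.min_mut_af == 0.0
        assert r.mean_delta == pytest.approx(2 / 3)

    def test_causal_locus_recovered_on_simulated_cross(self, small_genome):
        cfg, _, vs = simulate_variants(small_genome, seed=0)
        vs = [v for v in vs if v.wt_ref + v.wt_alt >= 10 and v.mut_ref + v.mut_alt >= 10]
        profiles = afmap.window_profile(vs, 50, 10)
        regions = afmap.detect_candidate_region(profiles)
        assert regions and regions[0].contains(cfg.causal_chrom, cfg.causal_pos)


class TestExportProfile:
    def test_rows_and_means_match_profile(self, tmp_path):
        vs = constant_af_variants(30, 0.6, 0.2)
        profiles = afmap.window_profile(vs, 5, 2)
        tsv = tmp_path / "profile.tsv"
        df = afmap.export_profile(profiles, tsv_path=str(tsv))
        assert len(df) == len(profiles[0].windows)
        assert df.mean_af_wt.tolist() == [w.mean_af_wt for w in profiles[0].windows]
        assert tsv.exists()

    def test_plot_smoke(self, tmp_path):
        vs = constant_af_variants(30, 0.6, 0.2, chrom="ch01") + \
             constant_af_variants(30, 0.5, 0.5, chrom="ch02")
        profiles = afmap.window_profile(vs, 5, 2)
        png = tmp_path / "profile.png"
        afmap.export_profile(profiles, plot_path=str(png))
        assert png.exists() and png.stat().st_size > 0

    def test_empty_profiles_error(self):
        with pytest.raises(ValueError):
            afmap.export_profile([])
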