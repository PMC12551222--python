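"""Local-ancestry painting, donor frequencies, and region calling."""

import numpy as np
import pandas as pd
import pytest

import hapintro as hi
from hapintro.ancestry import AncestryPaint, DonorFrequencyTrack
from hapintro.intervals import GenomicInterval
from hapintro.vcfio import HaplotypeMatrix, VariantTable


def tiny_hm(alleles, pos=None, chrom="1"):
    alleles = np.asarray(alleles, dtype=np.int8)
    m = alleles.shape[1]
    pos = pos if pos is not None else np.arange(1, m + 1) * 100
    vt = VariantTable(
        pd.DataFrame(
            {
                "chrom": chrom,
                "pos": pos,
                "id": [f"{chrom}:{p}" for p in pos],
                "ref": "A",
                "alt": "T",
            }
        )
    )
    n = alleles.shape[0] // 2
    return HaplotypeMatrix(vt, alleles, [f"S{i}" for i in range(n)])


class TestClassifier:
    def test_identical_to_donor_block_wins(self):
        target_block = [1, 0, 1, 1, 0]
        target = tiny_hm([target_block, target_block])
        donor1 = tiny_hm([target_block] * 4)
        far = [0, 1, 0, 0, 1]  # Hamming 5 from the target block
        eur = tiny_hm([far] * 4)
        donor2 = tiny_hm([[1, 1, 0, 0, 1]] * 4)  # Hamming 3
        paint = hi.classify_local_ancestry(
            target, {"EUR": eur, "DONOR1": donor1, "DONOR2": donor2}, context_blocks=1
        )
        assert (paint.codes == 1).all()

    def test_equidistant_block_falls_back_to_recipient(self):
        hapl = [1, 0, 1, 1, 0]
        target = tiny_hm([hapl, hapl])
        same = tiny_hm([hapl] * 4)
        paint = hi.classify_local_ancestry(
            target, {"EUR": same, "DONOR1": same, "DONOR2": same}, context_blocks=1
        )
        assert (paint.codes == 0).all()  # no panel exceeds 0.5

    def test_block_accuracy_on_simulated_cohort(self, admix_bundle):
        paint = admix_bundle["paint"]
        truth = admix_bundle["truth_blocks"]
        assert (paint.codes == truth).mean() >= 0.9

    def test_accuracy_monotone_in_panel_divergence(self):
        accs = []
        for fst in (0.1, 0.3, 0.5):
            cfg = hi.SimulationConfig(seed=31, m_snps=2000, n_per_panel=30,
                                      panel_fst=fst, admix_fraction=0.2)
            panels = hi.simulate_panels(cfg)
            cohort, truth = hi.simulate_admixed_cohort(
                cfg, panels["EUR"],
                {"DONOR1": panels["DONOR1"], "DONOR2": panels["DONOR2"]},
                n_samples=60,
            )
            paint = hi.classify_local_ancestry(cohort, panels)
            accs.append((paint.codes == hi.truth_block_labels(truth)).mean())
        assert accs[0] < accs[1] < accs[2]

    def test_zero_reference_panel_rejected(self):
        t = tiny_hm([[0, 1, 0, 1, 0]] * 2)
        empty = HaplotypeMatrix(t.variants, np.empty((0, 5), np.int8), [])
        with pytest.raises(ValueError):
            hi.classify_local_ancestry(t, {"EUR": t, "DONOR1": empty})


class TestReadPaint:
    def make_cohort(self):
        # 10 SNPs at 1-based 100..1000 -> two 5-SNP blocks [99,500), [599,1000)
        return tiny_hm(np.zeros((4, 10), np.int8))

    def test_full_cover_segments_inherit_code(self, tmp_path):
        hm = self.make_cohort()
        df = pd.DataFrame(
            {
                "chrom": ["1"],
                "start": [0],
                "end": [2000],
                "S0.0": [1],
                "S0.1": [0],
                "S1.0": [2],
                "S1.1": [0],
            }
        )
        p = tmp_path / "msp.tsv"
        df.to_csv(p, sep="\t", index=False)
        paint = hi.read_ancestry_paint(str(p), hm)
        np.testing.assert_array_equal(paint.codes, [[1, 1], [0, 0], [2, 2], [0, 0]])

    def test_mid_block_boundary_uses_majority_bp(self, tmp_path):
        hm = self.make_cohort()
        # first block spans [99, 500); boundary at 200 gives 101 bp of code 1
        # and 300 bp of code 2 -> majority 2
        df = pd.DataFrame(
            {
                "chrom": ["1", "1"],
                "start": [0, 200],
                "end": [200, 2000],
                "S0.0": [1, 2],
                "S0.1": [1, 1],
                "S1.0": [0, 0],
                "S1.1": [0, 2],
            }
        )
        p = tmp_path / "msp.tsv"
        df.to_csv(p, sep="\t", index=False)
        paint = hi.read_ancestry_paint(str(p), hm)
        assert paint.codes[0, 0] == 2  # majority of overlap bp
        assert paint.codes[1, 0] == 1

    def test_empty_file_rejected(self, tmp_path):
        hm = self.make_cohort()
        p = tmp_path / "empty.tsv"
        p.write_text("chrom\tstart\tend\tS0.0\tS0.1\tS1.0\tS1.1\n")
        with pytest.raises(ValueError):
            hi.read_ancestry_paint(str(p), hm)

    def test_haplotype_count_mismatch_rejected(self, tmp_path):
        hm = self.make_cohort()
        df = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [2000], "S0.0": [1]})
        p = tmp_path / "bad.tsv"
        df.to_csv(p, sep="\t", index=False)
        with pytest.raises(ValueError, match="mismatch"):
            hi.read_ancestry_paint(str(p), hm)


def paint_from_codes(codes):
    codes = np.asarray(codes, dtype=np.int8)
    n_hap, n_blocks = codes.shape
    blocks = [GenomicInterval("1", i * 100, (i + 1) * 100) for i in range(n_blocks)]
    return AncestryPaint(
        blocks, codes, ("EUR", "DONOR1", "DONOR2"),
        [f"S{i}" for i in range(n_hap // 2)],
    )


class TestDonorFrequency:
    def test_counting(self):
        paint = paint_from_codes([[1], [1], [0], [2]])
        track = hi.donor_frequency(paint)
        assert track.frequency("DONOR1")[0] == 0.5
        assert track.frequency("DONOR2")[0] == 0.25
        assert track.frequency("DONOR_ALL")[0] == 0.75

    def test_all_recipient_gives_zero_everywhere(self):
        paint = paint_from_codes(np.zeros((6, 4)))
        track = hi.donor_frequency(paint)
        assert (track.frequency("DONOR_ALL") == 0).all()

    def test_frequencies_sum_to_one_per_block(self, admix_bundle):
        track = hi.donor_frequency(admix_bundle["paint"])
        tot = sum(
            track.frequency(k) for k in ("EUR", "DONOR1", "DONOR2")
        )
        np.testing.assert_allclose(tot, 1.0, atol=1e-12)

    def test_unknown_sample_rejected(self):
        paint = paint_from_codes([[1], [0]])
        with pytest.raises(KeyError):
            hi.donor_frequency(paint, cohort=["nope"])

    def test_recovers_simulated_alpha(self, admix_bundle):
        track = hi.donor_frequency(admix_bundle["paint"])
        assert abs(track.frequency("DONOR_ALL").mean() - 0.2) < 0.03


def track_from_freqs(freqs):
    freqs = np.asarray(freqs, dtype=float)
    blocks = [GenomicInterval("1", i * 100, (i + 1) * 100) for i in range(len(freqs))]
    df = pd.DataFrame(
        {"EUR": 1 - freqs, "DONOR1": freqs, "DONOR2": 0.0, "DONOR_ALL": freqs}
    )
    return DonorFrequencyTrack(blocks, df)


class TestIntrogressedRegions:
    def test_run_detection(self):
        track = track_from_freqs([0.6, 0.7, 0.4, 0.8])
        regions = hi.call_introgressed_regions(track)
        assert [(r.start, r.end) for r in regions] == [(0, 200), (300, 400)]

    def test_no_block_above_threshold_gives_empty(self):
        track = track_from_freqs([0.1, 0.5, 0.3])
        assert hi.call_introgressed_regions(track) == []

    def test_matches_linear_scan_oracle(self):
        rng = np.random.default_rng(7)
        freqs = rng.random(200)
        track = track_from_freqs(freqs)
        regions = hi.call_introgressed_regions(track, threshold=0.5)
        # brute-force scan over blocks
        expected = []
        i = 0
        while i < len(freqs):
            if freqs[i] > 0.5:
                j = i
                while j + 1 < len(freqs) and freqs[j + 1] > 0.5:
                    j += 1
                expected.append((i * 100, (j + 1) * 100))
                i = j + 1
            else:
                i += 1
        assert [(r.start, r.end) for r in regions] == expected

    def test_threshold_nesting(self):
        rng = np.random.default_rng(8)
        track = track_from_freqs(rng.random(100))
        strict = hi.call_introgressed_regions(track, threshold=0.9)
        loose = hi.call_introgressed_regions(track, threshold=0.1)

        def covered(r, regions):
            return any(
                s.chrom == r.chrom and s.start <= r.start and r.end <= s.end
                for s in regions
            )

        assert all(covered(r, loose) for r in strict)


class TestProfileComparison:
    def test_identity_profile(self):
        t = track_from_freqs([0.1, 0.5, 0.9, 0.3])
        r, kld = hi.compare_frequency_profiles(t, t)
        assert r == pytest.approx(1.0)
        assert kld == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_kld(self):
        a = track_from_freqs([0.2, 0.8])
        b = track_from_freqs([0.5, 0.5])
        _, kld = hi.compare_frequency_profiles(a, b)
        expected = 0.2 * np.log(0.4) + 0.8 * np.log(1.6)
        assert kld == pytest.approx(expected, abs=1e-6)

    def test_kld_nonnegative_on_random_pairs(self):
        rng = np.random.default_rng(9)
        for _ in range(1000):
            a = track_from_freqs(rng.random(10))
            b = track_from_freqs(rng.random(10))
            _, kld = hi.compare_frequency_profiles(a, b)
            assert kld >= -1e-12

    def test_zero_variance_flags_pearson_missing(self):
        a = track_from_freqs([0.5, 0.5, 0.5])
        b = track_from_freqs([0.1, 0.2, 0.3])
        r, _ = hi.compare_frequency_profiles(a, b)
        assert np.isnan(r)
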