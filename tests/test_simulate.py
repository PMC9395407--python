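"""Synthetic-cohort generator: frequency model, truth implantation, signals."""

import numpy as np
import pytest

import ovinecnv as oc
from ovinecnv import simulate


class TestBaldingNichols:
    def test_zero_differentiation_returns_ancestral(self):
        rng = np.random.default_rng(0)
        out = simulate.draw_allele_frequencies(0.3, 0.0, 3, rng)
        assert out.shape == (3,)
        assert np.all(out == 0.3)

    def test_beta_mean_matches_ancestral(self):
        rng = np.random.default_rng(1)
        draws = simulate.draw_allele_frequencies(np.full(10_000, 0.5), 0.1, 2, rng)
        assert abs(draws.mean() - 0.5) < 0.01

    def test_beta_variance_is_F_p_q(self):
        rng = np.random.default_rng(2)
        draws = simulate.draw_allele_frequencies(np.full(10_000, 0.5), 0.1, 1, rng)
        expected = 0.1 * 0.25
        assert abs(draws.var() - expected) < 0.15 * expected

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_degenerate_ancestral_rejected(self, p):
        with pytest.raises(ValueError):
            simulate.draw_allele_frequencies(p, 0.1, 2, np.random.default_rng(0))

    def test_bad_fst_rejected(self):
        with pytest.raises(ValueError):
            simulate.draw_allele_frequencies(0.5, 1.0, 2, np.random.default_rng(0))


class TestImplantCnvs:
    def test_zero_mean_gives_empty_truth(self, tiny_config, tiny_cohort):
        cfg = oc.SimConfig(**{**_asdict(tiny_config), "cnvs_per_individual_mean": 0.0})
        truth = simulate.implant_cnvs(cfg, tiny_cohort.marker_map, np.random.default_rng(0))
        assert truth == []

    def test_fixed_seed_reproduces_truth(self, tiny_config, tiny_cohort):
        t1 = simulate.implant_cnvs(tiny_config, tiny_cohort.marker_map, np.random.default_rng(5))
        t2 = simulate.implant_cnvs(tiny_config, tiny_cohort.marker_map, np.random.default_rng(5))
        assert t1 == t2

    def test_total_count_within_poisson_bound(self, desk_cohort):
        # 30 samples x mean 2 -> 60 expected, 3 SD ~ 23
        n = len(desk_cohort.truth)
        assert abs(n - 60) <= 3 * np.sqrt(60)

    def test_no_overlap_within_sample_and_spans_marker(self, desk_cohort):
        chrom = desk_cohort.marker_map["chrom"].to_numpy()
        pos = desk_cohort.marker_map["pos"].to_numpy()
        by_sample = {}
        for ev in desk_cohort.truth:
            assert ev.start_bp <= ev.end_bp
            assert ev.copy_number in (0, 1, 3, 4)
            covered = ((chrom == ev.chromosome) & (pos >= ev.start_bp) & (pos <= ev.end_bp)).sum()
            assert covered >= 1
            for other in by_sample.get((ev.sample_id, ev.chromosome), []):
                assert ev.end_bp < other.start_bp or other.end_bp < ev.start_bp
            by_sample.setdefault((ev.sample_id, ev.chromosome), []).append(ev)

    def test_impossible_length_range_rejected(self):
        with pytest.raises(ValueError):
            oc.SimConfig(chrom_length_bp=1_000_000, cnv_length_range_bp=(20_000, 2_000_000))


class TestSynthesizeIntensities:
    def _noise_free(self, tiny_config):
        return oc.SimConfig(**{**_asdict(tiny_config), "lrr_noise_sd": 0.0, "baf_noise_sd": 0.0})

    def test_noise_free_heterozygote_diploid(self, tiny_config, tiny_cohort):
        """c=2, k=1 without noise lands exactly on the AB cluster: BAF 0.5, LRR 0."""
        cfg = self._noise_free(tiny_config)
        mm = tiny_cohort.marker_map
        dosage = np.ones((1, len(mm)), dtype=np.int8)
        x, y = simulate.synthesize_intensities(dosage, [], mm, cfg, np.random.default_rng(0), sample_ids=["s"])
        clusters = simulate._true_clusters(len(mm))
        sig = oc.signal.transform_sample("s", "b", x[0], y[0], clusters)
        np.testing.assert_allclose(sig.theta, simulate.TRUE_THETA[1], atol=1e-12)
        np.testing.assert_allclose(sig.baf, 0.5, atol=1e-12)
        np.testing.assert_allclose(sig.lrr, 0.0, atol=1e-12)

    def test_noise_free_hemizygous_deletion(self, tiny_config, tiny_cohort):
        """c=1, k=0 without noise: BAF 0 and LRR at the single-copy state mean."""
        cfg = self._noise_free(tiny_config)
        mm = tiny_cohort.marker_map
        chrom = mm["chrom"].iloc[0]
        span = (int(mm["pos"].iloc[0]), int(mm["pos"].iloc[49]))
        truth = [oc.TruthCnv("s", chrom, span[0], span[1], 1)]
        dosage = np.zeros((1, len(mm)), dtype=np.int8)  # all-AA so k=0 inside too
        freqs = np.full((1, len(mm)), 0.01)
        x, y = simulate.synthesize_intensities(
            dosage, truth, mm, cfg, np.random.default_rng(0), sample_ids=["s"], breed_freq_per_sample=freqs
        )
        clusters = simulate._true_clusters(len(mm))
        sig = oc.signal.transform_sample("s", "b", x[0], y[0], clusters)
        inside = (mm["chrom"] == chrom).to_numpy() & (mm["pos"].to_numpy() >= span[0]) & (mm["pos"].to_numpy() <= span[1])
        cn1_mean = oc.hmm.DEFAULT_PARAMS.lrr_mean[1]
        # binomial(1, 0.01) dosage draw can yield k=1; check the k=0 markers
        k0 = inside & (sig.baf < 0.5)
        assert k0.sum() > 0
        np.testing.assert_allclose(sig.baf[k0], 0.0, atol=1e-9)
        np.testing.assert_allclose(sig.lrr[k0], cn1_mean, atol=1e-9)
        np.testing.assert_allclose(sig.lrr[~inside], 0.0, atol=1e-9)

    def test_intensities_non_negative(self, tiny_cohort):
        assert np.all(tiny_cohort.x >= 0)
        assert np.all(tiny_cohort.y >= 0)


class TestCohortInvariants:
    def test_seed_determinism_byte_for_byte(self, tiny_config, tmp_path):
        c1 = oc.simulate_cohort(tiny_config)
        c2 = oc.simulate_cohort(tiny_config)
        np.testing.assert_array_equal(c1.x, c2.x)
        np.testing.assert_array_equal(c1.dosage, c2.dosage)
        assert c1.truth == c2.truth
        simulate.write_cohort(c1, tmp_path / "a")
        simulate.write_cohort(c2, tmp_path / "b")
        for rel in ["cohort.pfb", "cohort.ped", "cohort.map", "truth_cnvs.tsv"]:
            assert (tmp_path / "a" / rel).read_bytes() == (tmp_path / "b" / rel).read_bytes()

    def test_hardy_weinberg_at_zero_differentiation(self):
        """F=0, no CNVs: per-breed genotype frequencies match HWE within
        binomial sampling error."""
        cfg = oc.SimConfig(
            n_breeds=2, n_per_breed=200, n_chromosomes=1, snps_per_chromosome=300,
            chrom_length_bp=30_000_000, fst_target=0.0, cnvs_per_individual_mean=0.0, seed=5,
        )
        coh = oc.simulate_cohort(cfg)
        p = coh.ancestral_freq
        het = (coh.dosage == 1).mean(axis=0)
        expected = 2 * p * (1 - p)
        se = np.sqrt(expected * (1 - expected) / coh.n_samples)
        assert (np.abs(het - expected) < 4 * se + 1e-9).mean() > 0.95

    def test_written_files_roundtrip(self, tiny_cohort, tmp_path):
        from ovinecnv import io as oio

        paths = simulate.write_cohort(tiny_cohort, tmp_path)
        mm, samples, dosage = oio.read_plink(paths["ped"], paths["map"])
        np.testing.assert_array_equal(dosage, tiny_cohort.dosage)
        assert list(samples["breed"]) == list(tiny_cohort.samples["breed"])
        sig = oio.read_signal_file(paths["signals"][0])
        assert {"X", "Y", "B Allele Freq", "Log R Ratio"}.issubset(sig.columns)
        assert len(sig) == tiny_cohort.n_snps


def _asdict(cfg: oc.SimConfig) -> dict:
    from dataclasses import asdict

    return asdict(cfg)
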