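"""Copy-number HMM: transitions, emissions, Viterbi decoding, call segmentation."""

import numpy as np
import pytest
from scipy import stats

import ovinecnv as oc
from ovinecnv import hmm

N_STATES = len(hmm.STATES)


def brute_force_paths(n_markers: int) -> np.ndarray:
    """All state paths of length n as an (S^n, n) array (exhaustive oracle)."""
    return np.indices((N_STATES,) * n_markers).reshape(n_markers, -1).T


def brute_force_viterbi(positions, emissions, params) -> np.ndarray:
    """Score every possible path explicitly and return the best one.

    Ties resolved toward the lexicographically smallest path, matching the
    decoder's lower-state-index preference.
    """
    paths = brute_force_paths(len(positions))
    scores = np.log(np.asarray(params.pi))[paths[:, 0]].astype(float)
    for t in range(len(positions)):
        scores += emissions[paths[:, t], t]
        if t > 0:
            log_a = np.log(hmm.transition_matrix(positions[t] - positions[t - 1], params))
            scores += log_a[paths[:, t - 1], paths[:, t]]
    best = np.flatnonzero(scores == scores.max())
    return paths[best[0]]  # paths are generated in lexicographic order


class TestTransitionMatrix:
    def test_zero_distance_is_identity(self):
        np.testing.assert_allclose(hmm.transition_matrix(0.0), np.eye(N_STATES))

    def test_large_distance_rows_tend_to_stationary(self):
        a = hmm.transition_matrix(1e12)
        for row in a:
            np.testing.assert_allclose(row, hmm.DEFAULT_PARAMS.pi, rtol=1e-9)

    @pytest.mark.parametrize("d", [0.0, 1.0, 5_000.0, 100_000.0, 2e6])
    def test_rows_are_stochastic(self, d):
        np.testing.assert_allclose(hmm.transition_matrix(d).sum(axis=1), 1.0, atol=1e-12)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            hmm.transition_matrix(-1.0)


class TestEmissions:
    def test_binomial_mixture_weights_for_cn3(self):
        # c=3, pfb=0.3 -> (0.343, 0.441, 0.189, 0.027)
        w = stats.binom.pmf(np.arange(4), 3, 0.3)
        np.testing.assert_allclose(w, [0.343, 0.441, 0.189, 0.027], atol=1e-12)

    def test_diploid_mode_scores_highest_lrr(self):
        em = hmm.emission_loglik(np.array([0.0]), np.array([0.5]), np.array([0.5]))
        cn2 = hmm.STATES.index("CN2")
        assert em[cn2, 0] == em[:, 0].max()

    def test_loh_penalises_heterozygous_baf(self):
        em = hmm.emission_loglik(np.array([np.nan]), np.array([0.5]), np.array([0.5]))
        cn2 = hmm.STATES.index("CN2")
        loh = hmm.STATES.index("CN2-LOH")
        assert em[loh, 0] < em[cn2, 0] - 10.0

    def test_missing_marker_contributes_zero(self):
        em = hmm.emission_loglik(np.array([np.nan]), np.array([np.nan]), np.array([0.5]))
        np.testing.assert_allclose(em[:, 0], 0.0)

    def test_homozygous_deletion_prefers_low_lrr(self):
        em = hmm.emission_loglik(np.array([-3.5]), np.array([0.77]), np.array([0.5]))
        assert int(np.argmax(em[:, 0])) == hmm.STATES.index("CN0")


class TestViterbi:
    def test_empty_track(self):
        path = hmm.viterbi(np.array([]), np.array([]), np.array([]), np.array([]))
        assert path.size == 0

    def test_single_uninformative_marker_takes_prior(self):
        path = hmm.viterbi(np.array([100.0]), np.array([np.nan]), np.array([np.nan]), np.array([0.5]))
        assert hmm.STATES[path[0]] == "CN2"

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_enumeration(self, seed):
        """Decoded path equals explicit search over all 6^6 paths."""
        rng = np.random.default_rng(seed)
        n = 6
        positions = np.sort(rng.integers(1, 500_000, size=n)).astype(float)
        em = rng.normal(0.0, 3.0, size=(N_STATES, n))
        got = hmm.viterbi(positions, None, None, None, emissions=em)
        want = brute_force_viterbi(positions, em, hmm.DEFAULT_PARAMS)
        np.testing.assert_array_equal(got, want)

    def test_translation_invariance(self):
        rng = np.random.default_rng(42)
        n = 40
        positions = np.sort(rng.integers(1, 5_000_000, size=n)).astype(float)
        em = rng.normal(0.0, 2.0, size=(N_STATES, n))
        p1 = hmm.viterbi(positions, None, None, None, emissions=em)
        p2 = hmm.viterbi(positions + 7_777_777.0, None, None, None, emissions=em)
        np.testing.assert_array_equal(p1, p2)

    def test_implanted_deletion_recovered(self):
        """A 50-marker deletion in a 200-marker track decodes as a CN1 run."""
        rng = np.random.default_rng(3)
        n = 200
        positions = np.arange(1, n + 1) * 50_000.0
        cn1 = hmm.STATES.index("CN1")
        lrr = rng.normal(0.0, 0.2, size=n)
        lrr[80:130] += hmm.DEFAULT_PARAMS.lrr_mean[cn1]
        baf = np.clip(rng.choice([0.0, 0.5, 1.0], size=n) + rng.normal(0, 0.03, n), 0, 1)
        baf[80:130] = np.clip(rng.choice([0.0, 1.0], size=50) + rng.normal(0, 0.03, 50), 0, 1)
        pfb = np.full(n, 0.5)
        path = hmm.viterbi(positions, lrr, baf, pfb)
        assert (path[80:130] == cn1).sum() >= 45
        assert (path[:70] == hmm.STATES.index("CN2")).all()


class TestPathToCalls:
    PARAMS = hmm.DEFAULT_PARAMS

    def test_all_diploid_no_calls(self):
        path = np.full(20, hmm.STATES.index("CN2"))
        calls, loh = hmm.path_to_calls(path, np.arange(20) * 1000.0, self.PARAMS)
        assert calls == [] and loh == []

    def test_short_run_filtered(self):
        path = np.full(10, hmm.STATES.index("CN2"))
        path[4:6] = hmm.STATES.index("CN3")
        calls, _ = hmm.path_to_calls(path, np.arange(10) * 1000.0, self.PARAMS)
        assert calls == []

    def test_run_becomes_one_call_with_span_and_count(self):
        positions = np.arange(1, 21) * 10_000.0
        path = np.full(20, hmm.STATES.index("CN2"))
        path[5:15] = hmm.STATES.index("CN1")
        calls, _ = hmm.path_to_calls(path, positions, self.PARAMS, "s1", "3")
        assert len(calls) == 1
        c = calls[0]
        assert (c.start_bp, c.end_bp, c.n_snps) == (60_000, 150_000, 10)
        assert c.copy_number == 1 and c.chromosome == "3"

    def test_loh_runs_reported_separately_not_as_cnv(self):
        path = np.full(12, hmm.STATES.index("CN2"))
        path[2:9] = hmm.STATES.index("CN2-LOH")
        calls, loh = hmm.path_to_calls(path, np.arange(12) * 1000.0, self.PARAMS)
        assert calls == []
        assert len(loh) == 1 and loh[0].copy_number == 2

    def test_confidence_is_llr_against_diploid(self):
        em = np.zeros((N_STATES, 6))
        em[hmm.STATES.index("CN3")] = 2.0
        path = np.full(6, hmm.STATES.index("CN3"))
        calls, _ = hmm.path_to_calls(path, np.arange(6) * 1000.0, self.PARAMS, emissions=em)
        assert calls[0].confidence == pytest.approx(12.0)


class TestGapMerge:
    def test_small_gap_bridged_same_state_only(self):
        mk = lambda s, e, state, cn: hmm.CnvCall("s", "1", s, e, state, cn, 5, 1.0)
        a = mk(100_000, 200_000, "CN3", 3)
        b = mk(210_000, 300_000, "CN3", 3)
        c = mk(800_000, 900_000, "CN1", 1)
        merged = hmm.merge_adjacent_calls([a, b, c], max_gap_fraction=0.2)
        assert len(merged) == 2
        assert merged[0].start_bp == 100_000 and merged[0].end_bp == 300_000
        assert merged[0].n_snps == 10

    def test_large_gap_kept_separate(self):
        mk = lambda s, e: hmm.CnvCall("s", "1", s, e, "CN3", 3, 5, 1.0)
        merged = hmm.merge_adjacent_calls([mk(100_000, 150_000), mk(400_000, 450_000)])
        assert len(merged) == 2


class TestRecoveryDegradation:
    def test_f1_non_increasing_in_noise(self):
        """Recovery quality must not improve as LRR noise grows."""
        f1s = []
        for noise in (0.1, 0.2, 0.35):
            cfg = oc.SimConfig(
                n_breeds=1, n_per_breed=8, n_chromosomes=1, snps_per_chromosome=1200,
                chrom_length_bp=60_000_000, cnvs_per_individual_mean=2.0,
                cnv_length_range_bp=(500_000, 2_000_000), lrr_noise_sd=noise, seed=17,
            )
            coh = oc.simulate_cohort(cfg)
            f1s.append(_recovery_f1(coh))
        assert f1s[0] >= f1s[1] - 0.05 >= f1s[2] - 0.10
        assert f1s[0] > 0.8

    def test_noise_free_recovery_has_exact_marker_spans(self):
        cfg = oc.SimConfig(
            n_breeds=1, n_per_breed=4, n_chromosomes=1, snps_per_chromosome=800,
            chrom_length_bp=40_000_000, cnvs_per_individual_mean=1.5,
            cnv_length_range_bp=(500_000, 2_000_000), lrr_noise_sd=0.0, baf_noise_sd=0.0,
            seed=23,
        )
        coh = oc.simulate_cohort(cfg)
        # the generator's own cluster geometry and allele-frequency PFB:
        # with zero noise the signal round-trip is then exact by construction
        pfb = np.clip(coh.breed_freqs.mean(axis=0), 0.01, 0.99)
        calls = _call_all(coh, clusters=coh.clusters, pfb=pfb)
        chrom = coh.marker_map["chrom"].to_numpy()
        pos = coh.marker_map["pos"].to_numpy()
        for ev in coh.truth:
            inside = (chrom == ev.chromosome) & (pos >= ev.start_bp) & (pos <= ev.end_bp)
            if inside.sum() < hmm.DEFAULT_PARAMS.min_snps_per_call:
                continue
            span = (int(pos[inside][0]), int(pos[inside][-1]))
            match = [
                c
                for c in calls
                if c.sample_id == ev.sample_id
                and c.chromosome == ev.chromosome
                and (c.start_bp, c.end_bp) == span
            ]
            assert match, f"event {ev} not recovered with exact span {span}"


def _call_all(coh, clusters=None, pfb=None):
    theta = oc.signal.compute_theta(coh.x, coh.y)
    if clusters is None:
        clusters = oc.signal.estimate_clusters(theta, coh.x + coh.y, coh.dosage)
    sigs = [
        oc.signal.transform_sample(row.sample_id, row.breed, coh.x[i], coh.y[i], clusters)
        for i, row in coh.samples.iterrows()
    ]
    if pfb is None:
        pfb, _ = oc.signal.compile_pfb(np.vstack([s.baf for s in sigs]))
    chrom = coh.marker_map["chrom"].to_numpy()
    pos = coh.marker_map["pos"].to_numpy()
    calls = []
    for s in sigs:
        for c in np.unique(chrom):
            sel = (chrom == c) & clusters.usable
            got, _ = hmm.call_chromosome(pos[sel], s.lrr[sel], s.baf[sel], pfb[sel], hmm.DEFAULT_PARAMS, s.sample_id, str(c))
            calls.extend(got)
    return calls


def _recovery_f1(coh) -> float:
    calls = _call_all(coh)
    chrom = coh.marker_map["chrom"].to_numpy()
    pos = coh.marker_map["pos"].to_numpy()

    def reciprocal(c, ev):
        ov = min(c.end_bp, ev.end_bp) - max(c.start_bp, ev.start_bp) + 1
        if ov < 1:
            return 0.0
        return min(ov / (c.end_bp - c.start_bp + 1), ov / (ev.end_bp - ev.start_bp + 1))

    callable_events = [
        ev
        for ev in coh.truth
        if ((chrom == ev.chromosome) & (pos >= ev.start_bp) & (pos <= ev.end_bp)).sum()
        >= hmm.DEFAULT_PARAMS.min_snps_per_call
    ]
    if not callable_events or not calls:
        return 0.0
    tp = sum(
        any(c.sample_id == ev.sample_id and c.chromosome == ev.chromosome and reciprocal(c, ev) >= 0.5 for c in calls)
        for ev in callable_events
    )
    recall = tp / len(callable_events)
    matched_calls = sum(
        any(c.sample_id == ev.sample_id and c.chromosome == ev.chromosome and reciprocal(c, ev) >= 0.5 for ev in coh.truth)
        for c in calls
    )
    precision = matched_calls / len(calls)
    if recall + precision == 0:
        return 0.0
    return 2 * recall * precision / (recall + precision)
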