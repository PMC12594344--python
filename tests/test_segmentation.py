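import itertools

import numpy as np
import pandas as pd
import pytest

from hfrmap.segmentation import (
    BinarySeries,
    ChangepointParams,
    Fragment,
    HmmParams,
    changepoint_segment,
    compare_methods,
    downsample_robustness,
    flag_unresolved,
    fragment_stats,
    hmm_posterior,
    hmm_segment,
    pelt_changepoints,
    viterbi_path,
)

from _oracles import (
    all_paths_log_likelihood,
    dp_optimal_partition,
    partition_total_cost,
    random_piecewise_series,
)

PARAMS = HmmParams()


# ---------------------------------------------------------------------------
# HMM
# ---------------------------------------------------------------------------

class TestHmmSegment:
    def test_all_donor_labels_single_fragment(self):
        s = BinarySeries(positions=np.arange(0, 1000, 10), labels=np.ones(100))
        frags = hmm_segment(s, PARAMS)
        assert len(frags) == 1
        assert (frags[0].start, frags[0].end) == (0, 991)
        assert frags[0].n_obs == 100

    def test_all_recipient_labels_no_fragment(self):
        s = BinarySeries(positions=np.arange(0, 1000, 10), labels=np.zeros(100))
        assert hmm_segment(s, PARAMS) == []

    def test_empty_series(self):
        s = BinarySeries(positions=np.empty(0), labels=np.empty(0))
        assert hmm_segment(s, PARAMS) == []

    def test_viterbi_equals_exhaustive_enumeration(self):
        """Viterbi path attains the maximum over all 2^n state paths
        (random series, n <= 12, 100 seeds)."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(1, 13))
            y = rng.integers(0, 2, size=n)
            params = HmmParams(
                e_d=float(rng.uniform(0.55, 0.99)),
                e_r=float(rng.uniform(0.01, 0.45)),
                t=float(rng.uniform(1e-4, 0.3)),
                pi_d=float(rng.uniform(0.1, 0.9)),
            )
            paths, ll = all_paths_log_likelihood(y, params)
            vit = viterbi_path(y, params)
            i_vit = int(np.dot(vit, 2 ** np.arange(n - 1, -1, -1)))
            assert ll[i_vit] == pytest.approx(ll.max(), abs=1e-9)
            if np.sum(ll >= ll.max() - 1e-12) == 1:
                assert np.array_equal(vit, paths[int(np.argmax(ll))])

    def test_matches_hmmlearn_decoding(self):
        """Cross-check against an independent HMM implementation."""
        from hmmlearn.hmm import CategoricalHMM

        rng = np.random.default_rng(3)
        y = (rng.random(500) < np.where(np.arange(500) % 200 < 100, 0.9, 0.1)).astype(int)
        m = CategoricalHMM(n_components=2, init_params="", params="")
        m.startprob_ = np.array([1 - PARAMS.pi_d, PARAMS.pi_d])
        m.transmat_ = np.array([[1 - PARAMS.t, PARAMS.t], [PARAMS.t, 1 - PARAMS.t]])
        m.emissionprob_ = np.array(
            [[1 - PARAMS.e_r, PARAMS.e_r], [1 - PARAMS.e_d, PARAMS.e_d]]
        )
        _, ref_states = m.decode(y.reshape(-1, 1), algorithm="viterbi")
        assert np.array_equal(viterbi_path(y, PARAMS), ref_states)
        post = hmm_posterior(y, PARAMS)
        ref_post = m.predict_proba(y.reshape(-1, 1))[:, 1]
        assert np.allclose(post, ref_post, atol=1e-8)

    def test_posterior_flags_unresolved_series(self):
        rng = np.random.default_rng(4)
        ambiguous = rng.integers(0, 2, size=400)
        soft = HmmParams(e_d=0.6, e_r=0.4, t=0.01)
        assert flag_unresolved(hmm_posterior(ambiguous, soft))
        clean = np.concatenate([np.zeros(200, int), np.ones(200, int)])
        assert not flag_unresolved(hmm_posterior(clean, PARAMS))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            HmmParams(e_d=0.1, e_r=0.5)
        with pytest.raises(ValueError):
            HmmParams(t=0.0)


# ---------------------------------------------------------------------------
# changepoint
# ---------------------------------------------------------------------------

def freq_frame(positions, values):
    return pd.DataFrame(
        {
            "recipient_pos": positions,
            "donor_frequency": values,
            "donor_count": 1,
            "recipient_count": 1,
            "covered": True,
        }
    )


class TestChangepointSegment:
    def test_constant_zero_no_donor_fragment(self):
        f = freq_frame(np.arange(0, 500, 10), np.zeros(50))
        assert changepoint_segment(f) == []

    def test_noiseless_step_exact_boundaries(self):
        pos = np.arange(0, 300, 10)
        val = np.zeros(30)
        val[10:20] = 1.0
        frags = changepoint_segment(freq_frame(pos, val))
        assert len(frags) == 1
        assert (frags[0].start, frags[0].end) == (100, 191)
        assert frags[0].n_obs == 10

    def test_single_site_series(self):
        frags = changepoint_segment(freq_frame([5], [1.0]))
        assert len(frags) == 1
        assert (frags[0].start, frags[0].end) == (5, 6)

    def test_zero_coverage_sites_dropped(self):
        f = freq_frame(np.arange(5), [0.0, np.nan, 1.0, 1.0, np.nan])
        frags = changepoint_segment(f, ChangepointParams(penalty=0.1, min_segment_sites=1))
        assert len(frags) == 1
        assert frags[0].start == 2

    def test_pelt_equals_exhaustive_dynamic_program(self):
        """PELT segmentation equals the unpruned optimal partition
        (random series, n <= 30, 100 seeds)."""
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            n = int(rng.integers(4, 31))
            v = random_piecewise_series(rng, n)
            penalty = float(rng.uniform(0.05, 3.0))
            minseg = int(rng.integers(1, 3))
            cps = pelt_changepoints(v, penalty, minseg)
            oracle_cps, oracle_cost = dp_optimal_partition(v, penalty, minseg)
            assert partition_total_cost(v, cps, penalty) == pytest.approx(oracle_cost, abs=1e-9)
            assert cps == oracle_cps

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ChangepointParams(penalty=-1)
        with pytest.raises(ValueError):
            ChangepointParams(min_segment_sites=0)


# ---------------------------------------------------------------------------
# comparison & statistics
# ---------------------------------------------------------------------------

class TestCompareMethods:
    def test_identical_lists(self):
        frags = [Fragment(100, 200), Fragment(500, 900)]
        rep = compare_methods(frags, list(frags))
        assert rep["jaccard"] == 1.0
        assert rep["unique_hmm"] == rep["unique_freq"] == []
        assert len(rep["matched_pairs"]) == 2

    def test_disjoint_territories(self):
        rep = compare_methods([Fragment(0, 100)], [Fragment(200, 300)])
        assert rep["jaccard"] == 0.0
        assert rep["unique_hmm"] == [0] and rep["unique_freq"] == [0]

    def test_partial_overlap_interval_arithmetic(self):
        rep = compare_methods([Fragment(100, 200)], [Fragment(150, 250)])
        assert rep["jaccard"] == pytest.approx(50 / 150)


class TestFragmentStats:
    def test_single_fragment(self):
        out = fragment_stats({"c": [Fragment(0, 100)]})
        assert out["median_length"] == 100
        assert out["per_clone"].loc["c", "total_length"] == 100
        assert out["per_clone"].loc["c", "n_fragments"] == 1

    def test_median_of_three(self):
        frags = [Fragment(0, 10), Fragment(20, 40), Fragment(50, 80)]
        assert fragment_stats({"c": frags})["median_length"] == 20

    def test_ranksum_matches_exact_enumeration(self):
        """Two-sided rank-sum p-value equals exhaustive enumeration of all
        rank assignments for a 6 vs 6 table."""
        marker = [Fragment(0, int(l)) for l in (310, 420, 150, 600, 580, 330)]
        other = [
            Fragment(1000, 1000 + int(l)) for l in (90, 210, 130, 300, 80, 120)
        ]
        for f in marker:
            f.contains_marker = True
        out = fragment_stats({"c": marker + other})
        lengths = [f.length for f in marker + other]
        ranks = pd.Series(lengths).rank().to_numpy()
        w_obs = ranks[:6].sum()
        # exact two-sided p by enumerating all C(12,6) assignments
        sums = np.array(
            [ranks[list(idx)].sum() for idx in itertools.combinations(range(12), 6)]
        )
        mean_w = sums.mean()
        p_exact = np.mean(np.abs(sums - mean_w) >= abs(w_obs - mean_w) - 1e-9)
        assert out["ranksum_pvalue"] == pytest.approx(p_exact, abs=1e-9)
        # U statistic consistent with the rank sum
        assert out["ranksum_statistic"] == pytest.approx(w_obs - 6 * 7 / 2)


@pytest.fixture(scope="module")
def clean_clone():
    from hfrmap.classify import classify_builtin
    from hfrmap.distributions import FragmentLengthDistribution
    from hfrmap.synthetic import (
        GenomePairConfig,
        generate_genome_pair,
        simulate_reads,
        simulate_recombinant,
    )

    pair = generate_genome_pair(
        GenomePairConfig(genome_length=200_000, divergence=0.01, seed=60)
    )
    clone = simulate_recombinant(
        pair,
        100_000,
        FragmentLengthDistribution("fixed", length=30_000),
        extra_count=2,
        extra_dist=FragmentLengthDistribution("fixed", length=8_000),
        placement_window=80_000,
        seed=61,
    )
    reads = simulate_reads(clone, depth=20.0, error_rate=0.0, seed=62)
    return clone, classify_builtin(reads, pair)


class TestDownsampleRobustness:

    def test_full_fraction_identical_to_full_run(self, clean_clone):
        clone, cl = clean_clone
        out = downsample_robustness(cl, fractions=(1.0,), seed=0)
        assert out.loc[0, "n_fragments_hmm"] == len(clone.truth.fragments)
        assert out.loc[0, "n_fragments_cp"] == len(clone.truth.fragments)

    def test_subsampling_never_adds_fragments_on_clean_data(self, clean_clone):
        clone, cl = clean_clone
        out = downsample_robustness(cl, fractions=(1.0, 0.5, 0.25, 0.1), seed=1)
        full = out.loc[0, "n_fragments_hmm"]
        assert (out["n_fragments_hmm"] <= full).all()
        assert (out["n_fragments_cp"] <= out.loc[0, "n_fragments_cp"]).all()

    def test_all_fragments_retained_at_half_coverage(self, clean_clone):
        clone, cl = clean_clone
        out = downsample_robustness(cl, fractions=(0.5,), seed=2)
        assert out.loc[0, "n_fragments_hmm"] == len(clone.truth.fragments)

    def test_invalid_fraction_rejected(self, clean_clone):
        _clone, cl = clean_clone
        with pytest.raises(ValueError):
            downsample_robustness(cl, fractions=(0.0,))
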