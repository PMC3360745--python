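"""Gibbs sampler: priors, indicators, conditionals, bookkeeping, recovery."""

import numpy as np
import pytest
from scipy.stats import chisquare
from scipy.stats import t as student_t

from motifstream import (SamplerConfig, average_likelihood_ratio, demo_pswm,
                         encode_sequence, fit_markov_background, position_prior,
                         run_sampler, uniform_background, update_pswm)
from motifstream.background import window_log_prob
from motifstream.denovo import GibbsMotifSampler


class TestPositionPrior:
    def test_single_valid_start(self):
        prior = position_prior(8, w=8, df=4.0, scale=5.0)
        assert prior.probs.tolist() == [1.0]

    def test_symmetric_about_midpoint(self):
        prior = position_prior(21, w=6, df=4.0, scale=4.0)
        assert np.allclose(prior.probs, prior.probs[::-1], atol=1e-12)

    def test_matches_direct_density_evaluation(self):
        L, w, df, scale, center = 20, 8, 4.0, 5.0, 10.5
        prior = position_prior(L, w, df, scale, center)
        starts = np.arange(1, L - w + 2)
        dens = student_t.pdf((starts + (w - 1) / 2 - center) / scale, df)
        assert np.abs(prior.probs - dens / dens.sum()).max() <= 1e-12

    def test_too_short_sequence(self):
        with pytest.raises(ValueError):
            position_prior(5, w=8, df=4.0, scale=5.0)


class TestAverageLikelihoodRatio:
    def test_background_matching_model_averages_exactly_one(self, rng):
        seqs = [encode_sequence("".join(rng.choice(list("ACGT"), 80)), "a")]
        bg = fit_markov_background(seqs, order=0, pseudocount=1.0)
        theta = np.tile(bg.marg0, (8, 1))
        # analytic identity: every window ratio is exactly 1
        assert average_likelihood_ratio(seqs[0], theta, bg) == 1.0

    def test_hand_computed_average(self):
        # 4 starts: ratios 16, 0, 0, 0 -> average 4
        bg = uniform_background(0)
        seq = encode_sequence("ACGTA")
        theta = np.array([[1.0, 0, 0, 0], [0, 1.0, 0, 0]])  # consensus AC
        # windows: AC(16·...), CG(0), GT(0), TA(0); ratio AC = (1/0.0625)=16
        assert average_likelihood_ratio(seq, theta, bg) == pytest.approx(4.0)

    def test_matches_naive_loop(self, rng):
        seqs = [encode_sequence("".join(rng.choice(list("ACGT"), 40)), "n")]
        bg = fit_markov_background(seqs, order=3, pseudocount=1.0)
        theta = rng.dirichlet(np.ones(4), size=6)
        got = average_likelihood_ratio(seqs[0], theta, bg)
        seq = seqs[0]
        total = 0.0
        for a in range(1, len(seq) - 6 + 2):
            num = np.prod([theta[i, seq.codes[a - 1 + i] - 1]
                           for i in range(6)])
            total += num / 2.0 ** window_log_prob(bg, seq, a, 6)
        expected = total / (len(seq) - 6 + 1)
        assert got == pytest.approx(expected, rel=1e-9)
        assert got >= 0


class TestIndicator:
    @pytest.fixture
    def sampler(self, rng):
        seqs = [encode_sequence("".join(rng.choice(list("ACGT"), 60)), f"i{k}")
                for k in range(4)]
        bg = fit_markov_background(seqs, order=0, pseudocount=1.0)
        cfg = SamplerConfig(w=8, iterations=5, burn_in=1, seed=0,
                            both_strands=False)
        return GibbsMotifSampler(seqs, cfg, bg)

    def test_average_exactly_one_excludes(self, sampler):
        theta = np.tile(sampler.bg.marg0, (8, 1))
        for j in range(sampler.n):
            # background-matching theta gives average exactly 1: strict rule
            assert sampler.update_indicator(j, theta) == 0

    def test_average_just_above_one_includes(self, sampler, monkeypatch):
        monkeypatch.setattr(GibbsMotifSampler, "_average_ratio",
                            lambda self, j, th, reverse: 1.0 + 1e-9)
        assert sampler.update_indicator(0, np.full((8, 4), 0.25)) == 1

    def test_planted_vs_background_sequence(self):
        pswm = demo_pswm(8, dominant=0.97)
        planted = encode_sequence("ACGT" * 5 + pswm.consensus() + "ACGT" * 5,
                                  "planted")
        null = encode_sequence("ACGTGTCAAGTCGTACGTAGCTAGCTAGCATG", "null")
        bg = uniform_background(0)
        cfg = SamplerConfig(w=8, iterations=5, burn_in=1, seed=0)
        sampler = GibbsMotifSampler([planted, null], cfg, bg)
        assert sampler.update_indicator(0, pswm.theta) == 1
        assert sampler.update_indicator(1, pswm.theta) == 0
        # exclusion removed the null sequence's counts
        assert sampler.state.counts.sum() == sampler.config.w * \
            sampler.state.n_assigned


class TestUpdatePswm:
    def test_posterior_mean_hand_arithmetic(self):
        counts = np.zeros((1, 4))
        counts[0, 0] = 10
        theta = update_pswm(counts, (0.5, 0.5, 0.5, 0.5), n_included=10)
        assert np.allclose(theta, [[10.5 / 12, 0.5 / 12, 0.5 / 12, 0.5 / 12]])

    def test_zero_counts_gives_prior_mean(self):
        theta = update_pswm(np.zeros((3, 4)), (1, 1, 1, 1), n_included=0)
        assert np.allclose(theta, 0.25)

    def test_rows_sum_to_one(self, rng):
        counts = rng.integers(0, 30, (6, 4)).astype(float)
        n1 = int(counts[0].sum())
        counts[1:] = counts[0]  # consistent columns
        theta = update_pswm(counts, (0.5,) * 4, n_included=n1)
        assert np.allclose(theta.sum(axis=1), 1.0, atol=1e-12)


class TestAlignmentConditional:
    def _toy_sampler(self, both_strands=True, seed=3):
        seqs = [encode_sequence("ACGTACGTACGTACG", f"t{i}") for i in range(4)]
        bg = fit_markov_background(seqs, order=2, pseudocount=1.0)
        cfg = SamplerConfig(w=5, iterations=10, burn_in=2, seed=seed,
                            both_strands=both_strands)
        return GibbsMotifSampler(seqs, cfg, bg)

    def test_matches_enumeration_oracle(self):
        sampler = self._toy_sampler()
        probs = sampler.alignment_conditional(0)
        # independent brute-force enumeration of the full conditional
        st = sampler.state
        seq = sampler.sequences[0]
        w, L = 5, len(seq)
        beta = np.asarray(sampler.config.beta)
        counts = np.zeros((w, 4))
        n = 0
        for k in range(1, 4):
            if st.Z[k] != 1 or st.A[k] < 1:
                continue
            a, strand = int(st.A[k]), int(st.strand[k])
            win = sampler.sequences[k].codes[a - 1:a - 1 + w].astype(int) - 1
            if strand:
                win = (3 - win)[::-1]
            for i, b in enumerate(win):
                counts[i, b] += 1
            n += 1
        tt = (counts + beta) / (n + beta.sum())
        prior = position_prior(seq, w, sampler.config.t_df,
                               sampler.config.t_scale_factor * L).probs
        table = np.zeros((2, L - w + 1))
        for strand in (0, 1):
            for a in range(1, L - w + 2):
                win = seq.codes[a - 1:a - 1 + w].astype(int) - 1
                if strand:
                    win = (3 - win)[::-1]
                num = np.prod([tt[i, b] for i, b in enumerate(win)])
                den = 2.0 ** window_log_prob(sampler.bg, seq, a, w)
                table[strand, a - 1] = prior[a - 1] * num / den
        table /= table.sum()
        assert np.abs(table - probs).max() <= 1e-12

    def test_state_unchanged_by_conditional_query(self):
        sampler = self._toy_sampler()
        before = (sampler.state.A.copy(), sampler.state.counts.copy(),
                  sampler.state.n_assigned)
        sampler.alignment_conditional(1)
        assert np.array_equal(before[0], sampler.state.A)
        assert np.array_equal(before[1], sampler.state.counts)
        assert before[2] == sampler.state.n_assigned

    def test_flat_posterior_samples_uniformly(self):
        seqs = [encode_sequence("ACGTACGTACGTACG", f"u{i}") for i in range(2)]
        bg = uniform_background(0)
        cfg = SamplerConfig(w=5, iterations=5, burn_in=1, seed=11,
                            both_strands=False, use_position_prior=False)
        sampler = GibbsMotifSampler(seqs, cfg, bg)
        sampler.state.Z[:] = 1
        sampler.state.A[:] = -1
        sampler.state.counts[:] = 0
        sampler.state.n_assigned = 0
        n_starts = 11
        draws = np.zeros(n_starts)
        for _ in range(20000):
            a = sampler.sample_alignment(0)
            draws[a - 1] += 1
            sampler._remove_site(0)
        assert chisquare(draws).pvalue > 0.01

    def test_dominant_site_always_selected(self):
        # near-deterministic predictive: one window gets ~all the mass
        consensus = "TGACT"
        seqs = [encode_sequence("AAAA" + consensus + "AAAA", f"d{i}")
                for i in range(30)]
        bg = uniform_background(0)
        cfg = SamplerConfig(w=5, iterations=5, burn_in=1, seed=13,
                            both_strands=False, use_position_prior=False)
        sampler = GibbsMotifSampler(seqs, cfg, bg)
        # a huge consensus-aligned count mass makes theta-tilde
        # near-deterministic for every other sequence's conditional
        sampler.state.Z[:] = 1
        sampler.state.A[:] = 5
        sampler.state.strand[:] = 0
        site = sampler.sequences[0].codes[4:9].astype(int) - 1
        counts = np.zeros((5, 4), dtype=np.int64)
        counts[np.arange(5), site] = 10**6
        sampler.state.counts = counts
        sampler.state.n_assigned = 10**6
        sampler.state.A[0] = -1  # nothing to remove for sequence 0
        probs = sampler.alignment_conditional(0)
        assert probs[0, 4] > 1 - 1e-12
        hits = 0
        for _ in range(10000):
            hits += sampler.sample_alignment(0) == 5
            sampler._remove_site(0)
        assert hits >= 9990


class TestRunSampler:
    def test_count_bookkeeping_matches_rebuild(self, rng):
        seqs = [encode_sequence("".join(rng.choice(list("ACGT"), 50)), f"b{k}")
                for k in range(10)]
        bg = fit_markov_background(seqs, order=3)
        cfg = SamplerConfig(w=6, iterations=20, burn_in=5, seed=2)
        sampler = GibbsMotifSampler(seqs, cfg, bg)
        for _ in range(20):
            for j in range(sampler.n):
                if sampler.state.Z[j] == 1:
                    sampler.sample_alignment(j)
            theta = sampler.current_theta_hat()
            for j in range(sampler.n):
                sampler.update_indicator(j, theta)
            assert np.array_equal(sampler.state.counts,
                                  sampler.rebuild_counts())

    def test_reproducible_given_seed(self, rng):
        seqs = [encode_sequence("".join(rng.choice(list("ACGT"), 60)), f"r{k}")
                for k in range(12)]
        bg = fit_markov_background(seqs, order=3)
        cfg = SamplerConfig(w=6, iterations=30, burn_in=10, seed=42)
        r1 = run_sampler(seqs, cfg, bg)
        r2 = run_sampler(seqs, cfg, bg)
        assert np.array_equal(r1.pswm.theta, r2.pswm.theta)
        assert r1.sites == r2.sites
        assert r1.trace.equals(r2.trace)

    def test_perfectly_conserved_sequences_condense(self):
        seqs = [encode_sequence("GGGGACGTACGTGGGG", f"c{k}")
                for k in range(20)]
        bg = fit_markov_background(seqs, order=3)
        cfg = SamplerConfig(w=8, iterations=200, burn_in=50, seed=1)
        res = run_sampler(seqs, cfg, bg)
        # all sequences align to one position with a sharp motif
        starts = {(a, s) for _, a, s in res.sites}
        assert len(starts) == 1
        assert (res.pswm.information_content() >= 1.5).all()
        text = "GGGGACGTACGTGGGG"
        rc = encode_sequence(text).reverse_complement().decode()
        assert res.pswm.consensus() in text or res.pswm.consensus() in rc

    def test_null_input_terminates_and_reports(self, rng):
        seqs = [encode_sequence("".join(rng.choice(list("ACGT"), 80)), f"z{k}")
                for k in range(15)]
        bg = fit_markov_background(seqs, order=3)
        cfg = SamplerConfig(w=8, iterations=40, burn_in=10, seed=5)
        res = run_sampler(seqs, cfg, bg)
        frac_included = sum(res.Z.values()) / len(res.Z)
        assert 0.0 <= frac_included <= 1.0
        assert len(res.trace) >= 1
        assert np.isfinite(res.trace.log_post).all()

    def test_stronger_planting_never_loses_included_planted(self):
        from motifstream import SyntheticSpec, generate_dataset

        included_planted = []
        for dominant in (0.75, 0.95):
            spec = SyntheticSpec(n_sequences=60, length=80,
                                 true_pswm=demo_pswm(dominant=dominant),
                                 planting_probability=0.9, seed=21)
            seqs, truth = generate_dataset(spec)
            bg = fit_markov_background(seqs, order=3)
            cfg = SamplerConfig(w=8, iterations=250, burn_in=80, seed=11)
            res = run_sampler(seqs, cfg, bg)
            planted_ids = set(
                truth[truth.planted.astype(bool)].sequence_id)
            included_planted.append(
                sum(res.Z[sid] for sid in planted_ids if sid in res.Z))
        assert included_planted[1] >= included_planted[0]
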