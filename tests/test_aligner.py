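import itertools

import numpy as np
import pytest

from gazealign.aligner import (
    AlignedModels,
    AlignerConfig,
    AlignmentLink,
    HmmParams,
    TranslationTable,
    align_image,
    combine_posteriors,
    decode,
    hmm_lattice,
    hmm_posteriors,
    model1_posteriors,
    pair_posteriors,
    train_hmm,
    train_joint,
    train_model1,
)
from gazealign.corpus import ParallelPair


def pair(v, l):
    return ParallelPair(v.split(), l.split())


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def m1_posteriors_bruteforce(src, tgt, table):
    """Enumerate all alignment functions a: targets -> sources+NULL and
    accumulate P(a_j = i) from the joint weights prod_j t(f_j | e_{a_j})."""
    I, J = len(src), len(tgt)
    options = list(range(I)) + [I]  # I encodes NULL
    post = np.zeros((J, I + 1))
    total = 0.0
    for a in itertools.product(options, repeat=J):
        wgt = 1.0
        for j, i in enumerate(a):
            s = table.src_index[src[i]] if i < I else 0
            wgt *= table.t[s, table.tgt_index[tgt[j]]]
        total += wgt
        for j, i in enumerate(a):
            post[j, i] += wgt
    return post / total


def hmm_posteriors_bruteforce(init, trans, emit):
    """Path-sum over every hidden state sequence of the per-pair chain."""
    n_states, J = emit.shape
    post = np.zeros((J, n_states))
    total = 0.0
    for path in itertools.product(range(n_states), repeat=J):
        w = init[path[0]] * emit[path[0], 0]
        for j in range(1, J):
            w *= trans[path[j - 1], path[j]] * emit[path[j], j]
        total += w
        for j, s in enumerate(path):
            post[j, s] += w
    return post / total


def random_table(rng, src, tgt):
    table = TranslationTable(src, tgt)
    t = rng.uniform(0.05, 1.0, size=table.t.shape)
    table.t = t / t.sum(axis=1, keepdims=True)
    return table


# ---------------------------------------------------------------------------
# Model 1
# ---------------------------------------------------------------------------


class TestModel1:
    def test_posteriors_match_bruteforce(self, rng):
        for _ in range(10):
            I, J = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            src = [f"r{i}" for i in range(I)]
            tgt = [f"w{j}" for j in range(J)]
            table = random_table(rng, src, tgt)
            got = model1_posteriors(ParallelPair(src, tgt), table)
            want = m1_posteriors_bruteforce(src, tgt, table)
            assert np.max(np.abs(got - want)) <= 1e-10

    def test_rows_sum_to_one(self, rng):
        table = random_table(rng, ["r1", "r2"], ["w1", "w2", "w3"])
        post = model1_posteriors(pair("r1 r2", "w1 w3"), table)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_cooccurrence_pins_translation(self):
        # the classic pigeonhole: a shared word across pairs resolves both
        corpus = [pair("ghar", "house"), pair("chhota ghar", "small house")]
        model = train_model1(corpus, "forward", iters=10)
        assert model.table.argmax_target("ghar") == "house"
        assert model.table.argmax_target("chhota") == "small"

    def test_disambiguation_at_convergence(self):
        corpus = [pair("r1 r2", "bear log"), pair("r1", "bear")]
        model = train_model1(corpus, "forward", iters=60)
        t = model.table
        assert t.prob("r1", "bear") > t.prob("r1", "log")
        assert t.prob("r2", "log") > t.prob("r2", "bear")

    def test_loglik_nondecreasing(self, rng):
        for _ in range(5):
            corpus = random_corpus(rng)
            model = train_model1(corpus, "forward", iters=6)
            diffs = np.diff(model.loglik_history)
            assert (diffs >= -1e-9).all()

    def test_empty_corpus_errors(self):
        with pytest.raises(ValueError):
            train_model1([], "forward")

    def test_oov_target_goes_to_null(self):
        table = TranslationTable(["r1"], ["w1"])
        post = model1_posteriors(pair("r1", "unseen"), table)
        assert post[0, -1] == 1.0


def random_corpus(rng, n_pairs=6, v_vocab=4, l_vocab=4, max_len=4):
    corpus = []
    for _ in range(n_pairs):
        nv = int(rng.integers(1, max_len + 1))
        nl = int(rng.integers(1, max_len + 1))
        corpus.append(
            ParallelPair(
                [f"r{rng.integers(1, v_vocab + 1)}" for _ in range(nv)],
                [f"w{rng.integers(1, l_vocab + 1)}" for _ in range(nl)],
            )
        )
    return corpus


# ---------------------------------------------------------------------------
# HMM
# ---------------------------------------------------------------------------


class TestHmm:
    def test_posteriors_match_path_enumeration(self, rng):
        for _ in range(6):
            I, J = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            src = [f"r{i}" for i in range(I)]
            tgt = [f"w{j}" for j in range(J)]
            table = random_table(rng, src, tgt)
            jump = rng.uniform(0.1, 1.0, size=11)
            params = HmmParams(jump / jump.sum(), p_null=0.2, max_jump=5, jump_smooth=0.0)
            got = hmm_posteriors(ParallelPair(src, tgt), table, params)
            si = np.array([table.src_index[w] for w in src])
            ti = np.array([table.tgt_index[w] for w in tgt])
            init, trans, emit = hmm_lattice(si, ti, table, params)
            full = hmm_posteriors_bruteforce(init, trans, emit)
            want = np.column_stack([full[:, :I], full[:, I:].sum(axis=1)])
            assert np.max(np.abs(got - want)) <= 1e-8

    def test_five_by_five_with_null(self, rng):
        src = [f"r{i}" for i in range(5)]
        tgt = [f"w{j}" for j in range(5)]
        table = random_table(rng, src, tgt)
        params = HmmParams(np.full(11, 1 / 11), p_null=0.3, max_jump=5, jump_smooth=0.0)
        got = hmm_posteriors(ParallelPair(src, tgt), table, params)
        si = np.array([table.src_index[w] for w in src])
        ti = np.array([table.tgt_index[w] for w in tgt])
        init, trans, emit = hmm_lattice(si, ti, table, params)
        full = hmm_posteriors_bruteforce(init, trans, emit)
        want = np.column_stack([full[:, :5], full[:, 5:].sum(axis=1)])
        assert np.max(np.abs(got - want)) <= 1e-8

    def test_degenerate_1x1_matches_model1_at_balanced_null(self, rng):
        # with p_null = 0.5 the chain's NULL prior equals Model 1's uniform
        # source+NULL prior, so the single-position posteriors coincide
        corpus = [pair("r1", "bear"), pair("r2", "log")]
        table = random_table(rng, ["r1", "r2"], ["bear", "log"])
        params = HmmParams(np.full(11, 1 / 11), p_null=0.5, max_jump=5, jump_smooth=0.0)
        for p in corpus:
            hm = hmm_posteriors(p, table, params)
            m1 = model1_posteriors(p, table)
            assert np.allclose(hm, m1, atol=1e-12)

    def test_monotone_corpus_concentrates_forward_jumps(self, rng):
        # monotone slices of a one-to-one lexicon: varying windows make the
        # lexicon identifiable, after which every jump in the data is +1
        corpus = []
        for _ in range(40):
            k = int(rng.integers(0, 5))
            n = int(rng.integers(3, 5))
            corpus.append(
                ParallelPair(
                    [f"r{i}" for i in range(k, k + n)],
                    [f"w{i}" for i in range(k, k + n)],
                )
            )
        m1 = train_model1(corpus, "forward", iters=5)
        model = train_hmm(corpus, "forward", m1, iters=5)
        jump = model.hmm.jump
        assert int(np.argmax(jump)) == 5 + 1  # bucket for +1

    def test_baum_welch_loglik_nondecreasing(self, rng):
        for _ in range(5):
            corpus = random_corpus(rng)
            m1 = train_model1(corpus, "forward", iters=2)
            model = train_hmm(corpus, "forward", m1, iters=5)
            diffs = np.diff(model.loglik_history)
            assert (diffs >= -1e-9).all()


# ---------------------------------------------------------------------------
# Agreement training and decoding
# ---------------------------------------------------------------------------


class TestAgreement:
    def test_product_rule_before_renormalisation(self):
        p_fwd = np.array([[0.6, 0.4]])  # one word, one region + NULL
        p_rev = np.array([[0.4, 0.6]])  # one region, one word + NULL
        comb = combine_posteriors(p_fwd, p_rev)
        # raw products: lexical 0.6*0.4 = 0.24, NULL keeps 0.4
        assert comb[0, 0] == pytest.approx(0.24 / (0.24 + 0.4))

    def test_agreeing_directions_are_a_fixed_point(self):
        p_fwd = np.array([[1.0, 0.0]])
        p_rev = np.array([[1.0, 0.0]])
        comb = combine_posteriors(p_fwd, p_rev)
        assert np.allclose(comb, p_fwd)

    def test_joint_training_deterministic(self, rng):
        corpus = random_corpus(rng, n_pairs=8)
        cfg = AlignerConfig()
        m1 = train_joint(corpus, cfg)
        m2 = train_joint(corpus, cfg)
        assert np.array_equal(m1.forward.table.t, m2.forward.table.t)
        assert np.array_equal(m1.reverse.table.t, m2.reverse.table.t)
        assert np.array_equal(m1.forward.hmm.jump, m2.forward.hmm.jump)

    def test_tables_row_normalised_after_training(self, rng):
        corpus = random_corpus(rng, n_pairs=8)
        models = train_joint(corpus, AlignerConfig())
        for m in (models.forward, models.reverse):
            assert np.allclose(m.table.t.sum(axis=1), 1.0, atol=1e-9)

    def test_one_to_one_lexicon_recovered(self, rng):
        # known lexicon r_k <-> w_k with mild token noise
        lexicon = {f"r{k}": f"w{k}" for k in range(1, 6)}
        corpus = []
        for _ in range(60):
            ks = rng.choice(5, size=3, replace=False) + 1
            v = [f"r{k}" for k in ks]
            l = [lexicon[x] for x in v]
            if rng.random() < 0.3:
                l.append(f"w{rng.integers(1, 6)}")  # stray word
            corpus.append(ParallelPair(v, l))
        models = train_joint(corpus, AlignerConfig())
        hits = sum(models.forward.table.argmax_target(r) == w for r, w in lexicon.items())
        assert hits >= 0.9 * len(lexicon)


class TestDecode:
    def _models(self, rng):
        corpus = [pair("r1 r2", "bear log"), pair("r1", "bear"), pair("r2", "log")]
        return train_joint(corpus * 4, AlignerConfig())

    def test_threshold_keeps_only_clearing_links(self, rng):
        models = self._models(rng)
        links = decode(pair("r1 r2", "bear log"), models, delta=0.1)
        keys = {(l.word, l.region) for l in links}
        assert ("bear", "r1") in keys and ("log", "r2") in keys

    def test_monotone_in_delta(self, rng):
        models = self._models(rng)
        p = pair("r1 r2", "bear log")
        for d1, d2 in [(0.0, 0.1), (0.1, 0.5), (0.5, 0.9)]:
            l1 = {(l.word, l.region) for l in decode(p, models, d1)}
            l2 = {(l.word, l.region) for l in decode(p, models, d2)}
            assert l2 <= l1

    def test_delta_zero_links_every_cell(self, rng):
        models = self._models(rng)
        p = pair("r1 r2", "bear log")
        links = decode(p, models, delta=0.0)
        assert len(links) == 4  # every (word, region) cell, NULL excluded

    def test_posterior_rows_sum_to_one(self, rng):
        models = self._models(rng)
        post = pair_posteriors(pair("r1 r2", "bear log"), models)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_oov_tokens_dropped_not_fatal(self, rng):
        models = self._models(rng)
        links = decode(pair("r1 rX", "bear wX"), models, delta=0.0)
        assert {(l.word, l.region) for l in links} == {("bear", "r1")}

    def test_align_image_keeps_max_posterior(self, rng):
        models = self._models(rng)
        pairs = [pair("r1", "bear"), pair("r1 r2", "bear log")]
        A = align_image(pairs, models, delta=0.0)
        assert ("bear", "r1") in A
        singles = decode(pairs[0], models, 0.0)
        doubles = decode(pairs[1], models, 0.0)
        p1 = max(l.posterior for l in singles if (l.word, l.region) == ("bear", "r1"))
        p2 = max(l.posterior for l in doubles if (l.word, l.region) == ("bear", "r1"))
        assert A[("bear", "r1")] == pytest.approx(max(p1, p2))
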