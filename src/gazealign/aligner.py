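"""Unsupervised bitext word alignment for visual/linguistic unit sequences.

Two directional generative models are trained on the parallel corpus of
one image: IBM Model 1 (bag-of-words translation table, EM) as a warm
start, then an HMM aligner (first-order dependence on the jump width
between consecutive source positions, Baum-Welch).  The two directions —
regions-as-source and words-as-source — are coupled by agreement training:
at every E-step the directional link posteriors are multiplied elementwise
and renormalised before expected counts are collected, discouraging links
only one direction believes in.  Decoding keeps every link whose combined
posterior clears a threshold, so one-to-many links are allowed.

Source sentences implicitly contain a NULL token so that unaligned target
tokens need not be forced onto a lexical source.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from gazealign.corpus import ParallelPair

logger = logging.getLogger(__name__)

NULL_TOKEN = "<NULL>"
EPS = 1e-12  # add-eps smoothing on expected counts


@dataclass
class AlignerConfig:
    m1_iters: int = 2
    hmm_iters: int = 2
    joint: bool = True
    delta: float = 0.1  # posterior decoding threshold
    max_jump: int = 5
    p_null: float = 0.2
    jump_smooth: float = 0.5  # decode-time uniform interpolation of transitions
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m1_iters < 1 or self.hmm_iters < 0:
            raise ValueError("iteration counts must be >= 1 (hmm may be 0)")
        if not (0 <= self.delta <= 1):
            raise ValueError("delta must lie in [0, 1]")
        if not (0 <= self.p_null < 1):
            raise ValueError("p_null must lie in [0, 1)")
        if not (0 <= self.jump_smooth <= 1):
            raise ValueError("jump_smooth must lie in [0, 1]")


class TranslationTable:
    """P(target token | source token), source vocab includes NULL (row 0)."""

    def __init__(self, src_tokens: list[str], tgt_tokens: list[str]):
        self.src_tokens = [NULL_TOKEN] + sorted(set(src_tokens))
        self.tgt_tokens = sorted(set(tgt_tokens))
        self.src_index = {w: i for i, w in enumerate(self.src_tokens)}
        self.tgt_index = {w: i for i, w in enumerate(self.tgt_tokens)}
        n_src, n_tgt = len(self.src_tokens), len(self.tgt_tokens)
        self.t = np.full((n_src, n_tgt), 1.0 / n_tgt)

    def prob(self, src: str, tgt: str) -> float:
        return float(self.t[self.src_index[src], self.tgt_index[tgt]])

    def argmax_target(self, src: str) -> str:
        """Most probable target token for a source token (lexicon read-out)."""
        return self.tgt_tokens[int(np.argmax(self.t[self.src_index[src]]))]

    def m_step(self, counts: np.ndarray) -> None:
        counts = counts + EPS
        self.t = counts / counts.sum(axis=1, keepdims=True)

    def to_dict(self) -> dict:
        return {
            "src_tokens": self.src_tokens,
            "tgt_tokens": self.tgt_tokens,
            "t": self.t.tolist(),
        }


@dataclass
class HmmParams:
    """Jump-width distribution (bucketed at +/-max_jump) and NULL rate.

    ``jump_smooth`` interpolates the learned jump law with a uniform one
    when *posteriors are read out* (decoding).  Training uses the pure
    learned law, so Baum-Welch stays an exact EM.  Gaze-speech sequences
    have far weaker order correspondence than bilingual text (regions are
    revisited and often left unnamed), so the lexical signal should
    dominate the positional one at decode time.
    """

    jump: np.ndarray  # length 2*max_jump+1, sums to 1
    p_null: float
    max_jump: int
    jump_smooth: float = 0.5

    def jump_prob(self, d: int) -> float:
        d = max(-self.max_jump, min(self.max_jump, d))
        return float(self.jump[d + self.max_jump])


@dataclass
class DirectionalModel:
    """One translation direction: table, optional HMM stage, likelihoods."""

    table: TranslationTable
    hmm: HmmParams | None = None
    loglik_history: list[float] = field(default_factory=list)


@dataclass
class AlignedModels:
    """Both directions; forward = visual side as source."""

    forward: DirectionalModel
    reverse: DirectionalModel
    config: AlignerConfig

    def to_json(self) -> str:
        def enc(m: DirectionalModel) -> dict:
            d = {"table": m.table.to_dict(), "loglik": m.loglik_history}
            if m.hmm is not None:
                d["hmm"] = {
                    "jump": m.hmm.jump.tolist(),
                    "p_null": m.hmm.p_null,
                    "max_jump": m.hmm.max_jump,
                    "jump_smooth": m.hmm.jump_smooth,
                }
            return d

        return json.dumps(
            {
                "forward": enc(self.forward),
                "reverse": enc(self.reverse),
                "config": vars(self.config),
            }
        )


@dataclass(frozen=True)
class AlignmentLink:
    word: str
    region: str
    posterior: float
    j: int  # target (word) position
    i: int  # source (region) position


def _sides(pair: ParallelPair, direction: str) -> tuple[list[str], list[str]]:
    """(source tokens, target tokens) for a direction."""
    if direction == "forward":
        return pair.visual, pair.linguistic
    if direction == "reverse":
        return pair.linguistic, pair.visual
    raise ValueError(f"unknown direction: {direction!r}")


def _new_table(corpus: list[ParallelPair], direction: str) -> TranslationTable:
    src, tgt = [], []
    for p in corpus:
        s, t = _sides(p, direction)
        src.extend(s)
        tgt.extend(t)
    return TranslationTable(src, tgt)


def _pair_indices(pair, direction, table) -> tuple[np.ndarray, np.ndarray]:
    s, t = _sides(pair, direction)
    si = np.array([table.src_index[w] for w in s], dtype=int)
    ti = np.array([table.tgt_index[w] for w in t], dtype=int)
    return si, ti


# ---------------------------------------------------------------------------
# IBM Model 1
# ---------------------------------------------------------------------------


def _m1_posterior_matrix(si, ti, table) -> np.ndarray:
    """Shape (J, I+1); column I is NULL.  Rows sum to 1."""
    rows = np.concatenate([si, [0]])  # lexical sources then NULL
    P = table.t[np.ix_(rows, ti)].T  # (J, I+1)
    return P / P.sum(axis=1, keepdims=True)


def model1_posteriors(pair: ParallelPair, table: TranslationTable,
                      direction: str = "forward") -> np.ndarray:
    """Model 1 link posteriors p[j, i] (last column = NULL).

    An out-of-vocabulary target token gets all its mass on NULL (logged).
    """
    s, t = _sides(pair, direction)
    J, I = len(t), len(s)
    P = np.zeros((J, I + 1))
    for j, w in enumerate(t):
        if w not in table.tgt_index:
            logger.info("OOV target token %r; aligned to NULL", w)
            P[j, I] = 1.0
            continue
        ti = table.tgt_index[w]
        row = np.array(
            [table.t[table.src_index[x], ti] for x in s]
            + [table.t[0, ti]]
        )
        P[j] = row / row.sum()
    return P


def _m1_loglik(corpus, direction, table) -> float:
    ll = 0.0
    for pair in corpus:
        si, ti = _pair_indices(pair, direction, table)
        rows = np.concatenate([si, [0]])
        P = table.t[np.ix_(rows, ti)]  # (I+1, J)
        ll += float(np.log(P.sum(axis=0)).sum()) - len(ti) * np.log(len(si) + 1)
    return ll


def train_model1(
    corpus: list[ParallelPair], direction: str = "forward", iters: int = 2
) -> DirectionalModel:
    """Standard Model 1 EM from a uniform table.

    The per-iteration corpus log-likelihood (evaluated before each M-step)
    is recorded in ``loglik_history`` and is non-decreasing.
    """
    if not corpus:
        raise ValueError("empty corpus")
    table = _new_table(corpus, direction)
    model = DirectionalModel(table=table)
    indexed = [_pair_indices(p, direction, table) for p in corpus]
    for _ in range(iters):
        model.loglik_history.append(_m1_loglik(corpus, direction, table))
        counts = np.zeros_like(table.t)
        for si, ti in indexed:
            post = _m1_posterior_matrix(si, ti, table)  # (J, I+1)
            for col, row in enumerate(np.concatenate([si, [0]])):
                np.add.at(counts[row], ti, post[:, col])
        table.m_step(counts)
    model.loglik_history.append(_m1_loglik(corpus, direction, table))
    return model


# ---------------------------------------------------------------------------
# HMM aligner
# ---------------------------------------------------------------------------


def hmm_lattice(
    si: np.ndarray,
    ti: np.ndarray,
    table: TranslationTable,
    params: HmmParams,
    smooth: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Initial, transition, and emission matrices of the per-pair chain.

    States 0..I-1 are the lexical source positions; states I..2I-1 are NULL
    states remembering the last lexical position.  A NULL state emits from
    the NULL row of the table and transitions as its remembered position.
    ``smooth`` interpolates the jump law with a uniform distribution over
    the reachable lexical states.

    Transition rows are deliberately left unnormalised (a *deficient*
    parameterisation, as in the IBM fertility models): jumps that would
    leave the sentence keep their probability mass.  This makes
    normalised-count updates the exact M-step for the tied jump buckets,
    so Baum-Welch likelihood is guaranteed non-decreasing; posteriors are
    unaffected because forward-backward conditions on the observed pair.
    """
    I, J = len(si), len(ti)
    jumps = np.array(
        [[params.jump_prob(i2 - i1) for i2 in range(I)] for i1 in range(I)]
    )
    if smooth:
        jumps = (1 - smooth) * jumps + smooth * jumps.sum(axis=1, keepdims=True) / I
    trans = np.zeros((2 * I, 2 * I))
    for i1 in range(I):
        trans[i1, :I] = (1 - params.p_null) * jumps[i1]
        trans[i1, I + i1] = params.p_null
        trans[I + i1, :I] = (1 - params.p_null) * jumps[i1]
        trans[I + i1, I + i1] = params.p_null
    init = np.empty(2 * I)
    init[:I] = (1 - params.p_null) / I
    init[I:] = params.p_null / I
    emit = np.empty((2 * I, J))
    emit[:I] = table.t[np.ix_(si, ti)]
    emit[I:] = table.t[0, ti][None, :]
    return init, trans, emit


def _forward_backward(init, trans, emit):
    """Scaled forward-backward; returns (gamma, xi_sum, loglik)."""
    n_states, J = emit.shape
    alpha = np.zeros((J, n_states))
    scale = np.zeros(J)
    alpha[0] = init * emit[:, 0]
    scale[0] = alpha[0].sum()
    alpha[0] /= scale[0]
    for j in range(1, J):
        alpha[j] = (alpha[j - 1] @ trans) * emit[:, j]
        scale[j] = alpha[j].sum()
        alpha[j] /= scale[j]
    beta = np.zeros((J, n_states))
    beta[-1] = 1.0
    for j in range(J - 2, -1, -1):
        beta[j] = (trans @ (emit[:, j + 1] * beta[j + 1])) / scale[j + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi_sum = np.zeros((n_states, n_states))
    for j in range(J - 1):
        xi = (
            alpha[j][:, None]
            * trans
            * (emit[:, j + 1] * beta[j + 1])[None, :]
            / scale[j + 1]
        )
        xi_sum += xi
    return gamma, xi_sum, float(np.log(scale).sum())


def hmm_posteriors(
    pair: ParallelPair,
    table: TranslationTable,
    params: HmmParams,
    direction: str = "forward",
) -> np.ndarray:
    """HMM link posteriors p[j, i] (last column = aggregate NULL mass).

    The read-out applies the decode-time transition smoothing configured in
    ``params.jump_smooth``.
    """
    si, ti = _pair_indices(pair, direction, table)
    I = len(si)
    init, trans, emit = hmm_lattice(si, ti, table, params, smooth=params.jump_smooth)
    gamma, _, _ = _forward_backward(init, trans, emit)
    post = np.empty((len(ti), I + 1))
    post[:, :I] = gamma[:, :I]
    post[:, I] = gamma[:, I:].sum(axis=1)
    return post


def train_hmm(
    corpus: list[ParallelPair],
    direction: str,
    init_model: DirectionalModel,
    iters: int = 2,
    max_jump: int = 5,
    p_null: float = 0.2,
    jump_smooth: float = 0.5,
) -> DirectionalModel:
    """Baum-Welch over source positions, emissions seeded from Model 1."""
    if not corpus:
        raise ValueError("empty corpus")
    table = init_model.table
    n_buckets = 2 * max_jump + 1
    params = HmmParams(np.full(n_buckets, 1.0 / n_buckets), p_null, max_jump,
                       jump_smooth=jump_smooth)
    model = DirectionalModel(table=table, hmm=params)
    indexed = [_pair_indices(p, direction, table) for p in corpus]
    for _ in range(iters):
        t_counts = np.zeros_like(table.t)
        j_counts = np.zeros(n_buckets)
        ll = 0.0
        for si, ti in indexed:
            I = len(si)
            init, trans, emit = hmm_lattice(si, ti, table, params)
            gamma, xi_sum, pair_ll = _forward_backward(init, trans, emit)
            ll += pair_ll
            _collect_hmm_counts(si, ti, gamma, t_counts)
            # jump counts: transitions landing on a lexical state, from the
            # (possibly remembered) lexical position of the origin state
            for a in range(2 * I):
                i1 = a if a < I else a - I
                for i2 in range(I):
                    d = max(-max_jump, min(max_jump, i2 - i1))
                    j_counts[d + max_jump] += xi_sum[a, i2]
        model.loglik_history.append(ll)
        table.m_step(t_counts)
        j_counts += EPS
        params.jump = j_counts / j_counts.sum()
    return model


def _collect_hmm_counts(si, ti, gamma, t_counts) -> None:
    I = len(si)
    for col in range(I):
        np.add.at(t_counts[si[col]], ti, gamma[:, col])
    np.add.at(t_counts[0], ti, gamma[:, I:].sum(axis=1))


# ---------------------------------------------------------------------------
# Agreement (joint) training
# ---------------------------------------------------------------------------


def combine_posteriors(p_fwd: np.ndarray, p_rev: np.ndarray) -> np.ndarray:
    """Agreement product of two directional posterior matrices.

    ``p_fwd`` is (J, I+1) over words x regions+NULL; ``p_rev`` is (I, J+1)
    over regions x words+NULL.  Lexical cells multiply elementwise with the
    transposed reverse matrix; the NULL column keeps the forward mass; each
    row is renormalised.
    """
    J, I = p_fwd.shape[0], p_fwd.shape[1] - 1
    comb = np.empty_like(p_fwd)
    comb[:, :I] = p_fwd[:, :I] * p_rev[:, :J].T
    comb[:, I] = p_fwd[:, I]
    comb /= comb.sum(axis=1, keepdims=True)
    return comb


def _posteriors(pair, model: DirectionalModel, direction: str) -> np.ndarray:
    if model.hmm is not None:
        return hmm_posteriors(pair, model.table, model.hmm, direction)
    return model1_posteriors(pair, model.table, direction)


def pair_posteriors(pair: ParallelPair, models: AlignedModels) -> np.ndarray:
    """Combined (word x region+NULL) posterior matrix for one pair."""
    p_fwd = _posteriors(pair, models.forward, "forward")
    p_rev = _posteriors(pair, models.reverse, "reverse")
    return combine_posteriors(p_fwd, p_rev)


def train_joint(corpus: list[ParallelPair], config: AlignerConfig | None = None) -> AlignedModels:
    """Train both directions with the staged Model 1 -> HMM schedule.

    With ``config.joint`` on, every E-step uses agreement-combined
    posteriors for the translation-table counts of both directions (jump
    counts stay directional).  With it off, directions train independently.
    """
    config = config or AlignerConfig()
    if not corpus:
        raise ValueError("empty corpus")
    if not config.joint:
        fwd = train_model1(corpus, "forward", config.m1_iters)
        rev = train_model1(corpus, "reverse", config.m1_iters)
        if config.hmm_iters:
            fwd = train_hmm(corpus, "forward", fwd, config.hmm_iters,
                            config.max_jump, config.p_null, config.jump_smooth)
            rev = train_hmm(corpus, "reverse", rev, config.hmm_iters,
                            config.max_jump, config.p_null, config.jump_smooth)
        return AlignedModels(fwd, rev, config)

    fwd = DirectionalModel(table=_new_table(corpus, "forward"))
    rev = DirectionalModel(table=_new_table(corpus, "reverse"))
    idx_f = [_pair_indices(p, "forward", fwd.table) for p in corpus]
    idx_r = [_pair_indices(p, "reverse", rev.table) for p in corpus]

    # --- Model 1 stage with agreement -------------------------------------
    for _ in range(config.m1_iters):
        fwd.loglik_history.append(_m1_loglik(corpus, "forward", fwd.table))
        rev.loglik_history.append(_m1_loglik(corpus, "reverse", rev.table))
        cf = np.zeros_like(fwd.table.t)
        cr = np.zeros_like(rev.table.t)
        for (sf, tf), (sr, tr) in zip(idx_f, idx_r):
            pf = _m1_posterior_matrix(sf, tf, fwd.table)
            pr = _m1_posterior_matrix(sr, tr, rev.table)
            comb_f = combine_posteriors(pf, pr)
            comb_r = combine_posteriors(pr, pf)
            for col, row in enumerate(np.concatenate([sf, [0]])):
                np.add.at(cf[row], tf, comb_f[:, col])
            for col, row in enumerate(np.concatenate([sr, [0]])):
                np.add.at(cr[row], tr, comb_r[:, col])
        fwd.table.m_step(cf)
        rev.table.m_step(cr)

    if not config.hmm_iters:
        return AlignedModels(fwd, rev, config)

    # --- HMM stage with agreement ------------------------------------------
    n_buckets = 2 * config.max_jump + 1
    for m in (fwd, rev):
        m.hmm = HmmParams(
            np.full(n_buckets, 1.0 / n_buckets), config.p_null, config.max_jump,
            jump_smooth=config.jump_smooth,
        )
    for _ in range(config.hmm_iters):
        cf = np.zeros_like(fwd.table.t)
        cr = np.zeros_like(rev.table.t)
        jf = np.zeros(n_buckets)
        jr = np.zeros(n_buckets)
        llf = llr = 0.0
        for (sf, tf), (sr, tr) in zip(idx_f, idx_r):
            gf, xif, lf = _forward_backward(*hmm_lattice(sf, tf, fwd.table, fwd.hmm))
            gr, xir, lr = _forward_backward(*hmm_lattice(sr, tr, rev.table, rev.hmm))
            llf += lf
            llr += lr
            If, Ir = len(sf), len(sr)
            pf = np.column_stack([gf[:, :If], gf[:, If:].sum(axis=1)])
            pr = np.column_stack([gr[:, :Ir], gr[:, Ir:].sum(axis=1)])
            comb_f = combine_posteriors(pf, pr)
            comb_r = combine_posteriors(pr, pf)
            for col in range(If):
                np.add.at(cf[sf[col]], tf, comb_f[:, col])
            np.add.at(cf[0], tf, comb_f[:, If])
            for col in range(Ir):
                np.add.at(cr[sr[col]], tr, comb_r[:, col])
            np.add.at(cr[0], tr, comb_r[:, Ir])
            _accumulate_jump_counts(xif, If, config.max_jump, jf)
            _accumulate_jump_counts(xir, Ir, config.max_jump, jr)
        fwd.loglik_history.append(llf)
        rev.loglik_history.append(llr)
        fwd.table.m_step(cf)
        rev.table.m_step(cr)
        fwd.hmm.jump = (jf + EPS) / (jf + EPS).sum()
        rev.hmm.jump = (jr + EPS) / (jr + EPS).sum()
    return AlignedModels(fwd, rev, config)


def _accumulate_jump_counts(xi_sum, I, max_jump, out) -> None:
    for a in range(2 * I):
        i1 = a if a < I else a - I
        for i2 in range(I):
            d = max(-max_jump, min(max_jump, i2 - i1))
            out[d + max_jump] += xi_sum[a, i2]


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------


def decode(pair: ParallelPair, models: AlignedModels, delta: float | None = None) -> list[AlignmentLink]:
    """Posterior decoding: keep every non-NULL link with posterior >= delta."""
    delta = models.config.delta if delta is None else delta
    known_v = models.forward.table.src_index
    known_l = models.forward.table.tgt_index
    if any(v not in known_v for v in pair.visual) or any(
        w not in known_l for w in pair.linguistic
    ):
        kept_v = [v for v in pair.visual if v in known_v]
        kept_l = [w for w in pair.linguistic if w in known_l]
        logger.info(
            "dropping %d out-of-vocabulary token(s) at decode",
            len(pair.visual) + len(pair.linguistic) - len(kept_v) - len(kept_l),
        )
        if not kept_v or not kept_l:
            return []
        pair = ParallelPair(kept_v, kept_l, pair.observer_id, pair.origin)
    post = pair_posteriors(pair, models)
    I = len(pair.visual)
    links = []
    for j, word in enumerate(pair.linguistic):
        for i in range(I):
            if post[j, i] >= delta:
                links.append(AlignmentLink(word, pair.visual[i], float(post[j, i]), j, i))
    return links


def align_image(
    full_pairs: list[ParallelPair], models: AlignedModels, delta: float | None = None
) -> dict[tuple[str, str], float]:
    """Image-level alignment set: decode each observer's full pair and pool.

    Returns the set of distinct (word surface, region label) links, keeping
    the maximum posterior seen for each.
    """
    A: dict[tuple[str, str], float] = {}
    for pair in full_pairs:
        for link in decode(pair, models, delta):
            key = (link.word, link.region)
            A[key] = max(A.get(key, 0.0), link.posterior)
    return A


def write_pharaoh(pairs_links: list[list[AlignmentLink]], path) -> None:
    """Pharaoh convention: one line per pair, space-separated j-i tokens."""
    with open(path, "w") as fh:
        for links in pairs_links:
            fh.write(" ".join(f"{l.j}-{l.i}" for l in links) + "\n")
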