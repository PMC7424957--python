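"""Parallel-corpus construction from visual and linguistic unit sequences.

Each observer's trial yields one bitext "sentence" pair per nonempty
sliding window, plus one full-sequence pair.  Visual sides are shortened
by merging contiguous identical region labels and then selecting units
(by longest fixation duration, by default) until the visual/linguistic
length ratio matches beta.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from gazealign.gaze import VisualUnit
from gazealign.narrative import LinguisticUnit

logger = logging.getLogger(__name__)


@dataclass
class CorpusConfig:
    """Knobs of the corpus expansion.

    T: sliding-window length in seconds.  stride: window step.  alpha:
    visual-unit selection method when a window holds more visual than
    linguistic units.  beta: target ratio |visual| / |linguistic| per pair.
    full_pair_balance: whether the full-sequence pair is beta-balanced like
    the windows (it is always merged).  Off by default: the full pair is
    the decoding input, and truncating it discards alignment candidates;
    leaving it intact also lets the HMM see full-sequence jump geometry
    during training.
    """

    T: float = 5.0
    stride: float = 0.5
    alpha: str = "longest"  # longest | earliest | random
    beta: float = 1.0
    full_pair_balance: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("T must be positive")
        if not (0 < self.stride <= self.T):
            raise ValueError("stride must satisfy 0 < stride <= T")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.alpha not in ("longest", "earliest", "random"):
            raise ValueError(f"unknown alpha: {self.alpha!r}")


@dataclass
class ParallelPair:
    """One bitext sentence pair: region-label tokens vs word tokens."""

    visual: list[str]
    linguistic: list[str]
    observer_id: str = ""
    origin: str = "full"  # "full" or "window@<start>"

    def __post_init__(self) -> None:
        if not self.visual or not self.linguistic:
            raise ValueError("both sides of a parallel pair must be nonempty")


def slide_windows(
    vunits: list[VisualUnit],
    lunits: list[LinguisticUnit],
    config: CorpusConfig,
) -> list[tuple[list[VisualUnit], list[LinguisticUnit], float]]:
    """Extract unit subsequences for windows [w, w+T), w = 0, stride, ...

    A unit belongs to a window iff its onset lies in the half-open
    interval.  Windows are generated while w < D, D being the latest unit
    end time; windows with an empty side are dropped.
    """
    ends = [v.t_on + v.dur for v in vunits] + [l.t_on for l in lunits]
    if not ends:
        return []
    D = max(ends)
    out = []
    k = 0
    while True:
        w = k * config.stride
        if w >= D:
            break
        vsub = [v for v in vunits if w <= v.t_on < w + config.T]
        lsub = [l for l in lunits if w <= l.t_on < w + config.T]
        if vsub and lsub:
            out.append((vsub, lsub, w))
        k += 1
    return out


def merge_contiguous(vsub: list[VisualUnit]) -> list[VisualUnit]:
    """Collapse maximal runs of identical region labels into one unit.

    The merged unit keeps the run's first onset and the summed duration,
    so total duration is conserved; no two adjacent output labels are equal.
    """
    merged: list[VisualUnit] = []
    for v in vsub:
        if merged and merged[-1].label == v.label:
            prev = merged[-1]
            merged[-1] = VisualUnit(prev.label, prev.t_on, prev.dur + v.dur)
        else:
            merged.append(v)
    return merged


def select_units(
    vmerged: list[VisualUnit],
    n_target: int,
    alpha: str = "longest",
    seed: int = 0,
) -> list[VisualUnit]:
    """Keep ``n_target`` visual units, preserving linear order.

    alpha = longest keeps the longest-duration units (ties broken toward
    the earlier onset); earliest keeps the first n_target; random samples
    without replacement with the given seed.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    if len(vmerged) <= n_target:
        return list(vmerged)
    if alpha == "longest":
        ranked = sorted(range(len(vmerged)), key=lambda i: (-vmerged[i].dur, i))
        keep = sorted(ranked[:n_target])
    elif alpha == "earliest":
        keep = list(range(n_target))
    elif alpha == "random":
        rng = np.random.default_rng(seed)
        keep = sorted(rng.choice(len(vmerged), size=n_target, replace=False))
    else:
        raise ValueError(f"unknown alpha: {alpha!r}")
    return [vmerged[i] for i in keep]


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def balance_pair(
    vmerged: list[VisualUnit],
    lsub: list[LinguisticUnit],
    beta: float = 1.0,
    alpha: str = "longest",
    seed: int = 0,
    observer_id: str = "",
    origin: str = "full",
) -> ParallelPair | None:
    """Build a pair whose visual length is ~beta times its linguistic length.

    n_target = max(1, round(beta * |linguistic|)); when fewer visual units
    are available they are all kept.  Returns None (logged) when the merged
    visual side is empty.
    """
    if not lsub:
        raise ValueError("linguistic side must be nonempty")
    if not vmerged:
        logger.info("empty visual side after merging; pair dropped (%s)", observer_id)
        return None
    n_target = max(1, _round_half_away(beta * len(lsub)))
    selected = select_units(vmerged, n_target, alpha, seed)
    return ParallelPair(
        visual=[v.label for v in selected],
        linguistic=[l.surface for l in lsub],
        observer_id=observer_id,
        origin=origin,
    )


def build_corpus(
    trials: list[tuple[str, list[VisualUnit], list[LinguisticUnit]]],
    config: CorpusConfig | None = None,
) -> list[ParallelPair]:
    """Expanded parallel corpus for one image.

    ``trials`` holds (observer_id, visual units, linguistic units) per
    observer.  Every nonempty window contributes a merged, beta-balanced
    pair, and the full trial contributes one more pair.  Observers with an
    empty side contribute nothing.
    """
    config = config or CorpusConfig()
    corpus: list[ParallelPair] = []
    for obs, vunits, lunits in trials:
        if not lunits or not vunits:
            logger.info("observer %s has an empty unit sequence; skipped", obs)
            continue
        for vsub, lsub, w in slide_windows(vunits, lunits, config):
            pair = balance_pair(
                merge_contiguous(vsub),
                lsub,
                config.beta,
                config.alpha,
                config.seed,
                observer_id=obs,
                origin=f"window@{w:g}",
            )
            if pair is not None:
                corpus.append(pair)
        vfull = merge_contiguous(vunits) if config.full_pair_balance else list(vunits)
        if config.full_pair_balance:
            pair = balance_pair(
                vfull, lunits, config.beta, config.alpha, config.seed,
                observer_id=obs, origin="full",
            )
        else:
            pair = ParallelPair(
                visual=[v.label for v in vfull],
                linguistic=[l.surface for l in lunits],
                observer_id=obs,
                origin="full",
            )
        if pair is not None:
            corpus.append(pair)
    return corpus


def full_pairs(corpus: list[ParallelPair]) -> list[ParallelPair]:
    """The per-observer full-sequence pairs of a corpus."""
    return [p for p in corpus if p.origin == "full"]


def decode_pairs(
    trials: list[tuple[str, list[VisualUnit], list[LinguisticUnit]]],
) -> list[ParallelPair]:
    """Merged but *unbalanced* full-sequence pairs, used as decoding inputs.

    Balancing is a training-time device to equalise sentence lengths; at
    decoding time every region the observer fixated must stay available as
    an alignment candidate, otherwise words whose region was truncated away
    get forced onto a neighbour.
    """
    pairs = []
    for obs, vunits, lunits in trials:
        if not vunits or not lunits:
            continue
        vmerged = merge_contiguous(vunits)
        pairs.append(
            ParallelPair(
                visual=[v.label for v in vmerged],
                linguistic=[l.surface for l in lunits],
                observer_id=obs,
                origin="full",
            )
        )
    return pairs


def write_bitext(corpus: list[ParallelPair], visual_path, linguistic_path, manifest_path):
    """Serialise a corpus in the standard two-file bitext convention."""
    with open(visual_path, "w") as fv, open(linguistic_path, "w") as fl, open(
        manifest_path, "w"
    ) as fm:
        fm.write("line\tobserver\torigin\n")
        for i, p in enumerate(corpus):
            fv.write(" ".join(p.visual) + "\n")
            fl.write(" ".join(p.linguistic) + "\n")
            fm.write(f"{i}\t{p.observer_id}\t{p.origin}\n")


def read_bitext(visual_path, linguistic_path, manifest_path=None) -> list[ParallelPair]:
    with open(visual_path) as fv:
        vlines = [ln.split() for ln in fv.read().splitlines()]
    with open(linguistic_path) as fl:
        llines = [ln.split() for ln in fl.read().splitlines()]
    if len(vlines) != len(llines):
        raise ValueError("bitext files have different line counts")
    meta = []
    if manifest_path is not None:
        with open(manifest_path) as fm:
            rows = fm.read().splitlines()[1:]
        meta = [r.split("\t") for r in rows]
    pairs = []
    for i, (v, l) in enumerate(zip(vlines, llines)):
        obs, origin = (meta[i][1], meta[i][2]) if meta else ("", "full")
        pairs.append(ParallelPair(v, l, observer_id=obs, origin=origin))
    return pairs
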