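"""Linguistic-unit extraction from time-stamped, POS-tagged transcripts.

Content words — adjectives, common/proper nouns, gerunds, and foreign
words — are kept; stopwords and task-instruction words are removed; word
forms uttered only once for a given image are dropped (they tend to be
transcription errors or idiosyncratic word choices).  The linear order and
onset times of the surviving tokens are preserved throughout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources

import pandas as pd

logger = logging.getLogger(__name__)

#: adjectives, nouns, proper nouns, gerunds, foreign words (Penn tagset)
DEFAULT_POS_WHITELIST = frozenset(
    {"JJ", "JJR", "JJS", "NN", "NNS", "NNP", "NNPS", "VBG", "FW"}
)
#: words tied to the task instructions rather than the image content
DEFAULT_TASK_WORDS = frozenset({"next"})


@dataclass(frozen=True)
class WordToken:
    """A transcribed word with utterance interval and Penn POS tag."""

    surface: str
    pos: str
    t_on: float
    t_off: float

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("token surface must be nonempty")
        if not (0 <= self.t_on <= self.t_off):
            raise ValueError("token times must satisfy 0 <= t_on <= t_off")


@dataclass
class Narrative:
    """One observer's spoken description of one image."""

    observer_id: str
    image_id: str
    tokens: list[WordToken]

    def __post_init__(self) -> None:
        onsets = [t.t_on for t in self.tokens]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("token onsets must be non-decreasing")


@dataclass(frozen=True)
class LinguisticUnit:
    """A content word that survived all filters, anchored at its onset."""

    surface: str
    t_on: float


@dataclass(frozen=True)
class NarrativeStats:
    n_tokens: int
    n_types: int
    ttr: float | None


def load_default_stopwords() -> frozenset[str]:
    text = resources.files("gazealign.data").joinpath("stopwords.txt").read_text()
    return frozenset(w.strip().lower() for w in text.splitlines() if w.strip())


def read_transcript(
    stream, observer_id: str = "obs0", image_id: str = "img0", fmt: str = "jsonl"
) -> Narrative:
    """Read a word-level transcript (JSON lines or TSV with columns
    word, t_on, t_off, pos) into a Narrative."""
    if fmt == "jsonl":
        if isinstance(stream, str):
            lines = stream.splitlines()
        else:
            lines = stream.read().splitlines()
        rows = [json.loads(ln) for ln in lines if ln.strip()]
        df = pd.DataFrame(rows)
    elif fmt == "tsv":
        df = pd.read_csv(stream, sep="\t")
    else:
        raise ValueError(f"unknown transcript format: {fmt!r}")
    tokens = [
        WordToken(str(r["word"]).lower(), str(r["pos"]), float(r["t_on"]), float(r["t_off"]))
        for r in df.to_dict("records")
    ]
    return Narrative(observer_id, image_id, tokens)


def extract_candidate_tokens(
    narrative: Narrative, pos_whitelist: frozenset[str] | None = None
) -> list[WordToken]:
    """Keep tokens whose POS tag is in the whitelist, in original order."""
    whitelist = pos_whitelist if pos_whitelist is not None else DEFAULT_POS_WHITELIST
    for tok in narrative.tokens:
        if not tok.pos:
            raise ValueError(f"untagged token: {tok.surface!r} at t={tok.t_on}")
    return [t for t in narrative.tokens if t.pos in whitelist]


def remove_stopwords(
    tokens: list[WordToken],
    stopword_list: frozenset[str] | None = None,
    task_word_list: frozenset[str] | None = None,
) -> list[WordToken]:
    """Drop tokens whose surface is a stopword or a task-instruction word."""
    stop = stopword_list if stopword_list is not None else load_default_stopwords()
    task = task_word_list if task_word_list is not None else DEFAULT_TASK_WORDS
    return [t for t in tokens if t.surface not in stop and t.surface not in task]


def remove_singletons(
    per_image_narratives: list[list[WordToken]],
) -> list[list[WordToken]]:
    """Remove word forms uttered only once across all narratives of an image.

    A surface whose total count over the image's narratives is exactly 1 is
    removed everywhere; order is otherwise preserved.
    """
    counts: dict[str, int] = {}
    for toks in per_image_narratives:
        for t in toks:
            counts[t.surface] = counts.get(t.surface, 0) + 1
    return [[t for t in toks if counts[t.surface] > 1] for toks in per_image_narratives]


def narrative_stats(tokens: list[WordToken]) -> NarrativeStats:
    """Token count, type count, and type-token ratio of a narrative."""
    n = len(tokens)
    types = len({t.surface for t in tokens})
    return NarrativeStats(n, types, (types / n) if n else None)


def extract_linguistic_units(
    narratives: list[Narrative],
    pos_whitelist: frozenset[str] | None = None,
    stopword_list: frozenset[str] | None = None,
    task_word_list: frozenset[str] | None = None,
    drop_singletons: bool = True,
) -> list[list[LinguisticUnit]]:
    """Full linguistic pipeline for all narratives of a single image.

    POS filtering and stopword removal run per narrative; singleton removal
    counts surfaces across the whole image *after* those filters.  Returns
    one ordered unit list per input narrative.
    """
    filtered = [
        remove_stopwords(
            extract_candidate_tokens(n, pos_whitelist), stopword_list, task_word_list
        )
        for n in narratives
    ]
    if drop_singletons:
        filtered = remove_singletons(filtered)
    out = [[LinguisticUnit(t.surface, t.t_on) for t in toks] for toks in filtered]
    for narrative, units in zip(narratives, out):
        if not units:
            logger.info(
                "no linguistic units survive filtering for (%s, %s)",
                narrative.observer_id,
                narrative.image_id,
            )
    return out
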