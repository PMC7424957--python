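"""Co-registered scanpath + narrative simulator with known ground truth.

The generator emulates the behavioural regularities of image-description
studies: fixations of ~250 ms mean duration grouped into region visits,
narratives of ~22 s spoken at ~2.5 words/s, a silent preview before speech
begins, and a variable, sub-second eye-voice lag between fixating a region
and uttering its name.  Every non-filler word has exactly one generating
region, so sure/possible reference alignments are known by construction:
a region's dominant name is a sure link, its synonyms possible links.

Scenes are abstract: regions are Gaussian fixation sources with a name
lexicon; no raster is synthesised (mean-shift clustering of fixations
does not need one).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gazealign.evaluation import ReferenceAlignment, ReferenceRegion, project_reference
from gazealign.gaze import (
    Fixation,
    RegionModel,
    ScanpathTrial,
    discard_offimage_clusters,
    mean_shift_cluster,
)
from gazealign.narrative import Narrative, WordToken

_NOUN_BANK = [
    "bear", "log", "giraffe", "woman", "man", "child", "dog", "cat", "horse",
    "table", "chair", "bench", "car", "truck", "bus", "bicycle", "boat",
    "train", "plane", "kite", "ball", "bat", "glove", "racket", "umbrella",
    "backpack", "handbag", "suitcase", "bottle", "cup", "plate", "bowl",
    "banana", "apple", "sandwich", "pizza", "cake", "donut", "carrot",
    "couch", "bed", "desk", "toilet", "television", "laptop", "keyboard",
    "phone", "microwave", "oven", "toaster", "sink", "fridge", "book",
    "clock", "vase", "scissors", "teddy", "hairdryer", "toothbrush", "tie",
    "tree", "bush", "rock", "river", "fence", "sign", "lamp", "window",
    "door", "roof", "tower", "bridge", "field", "road", "hill", "cloud",
]

_SYNONYM_MAP = {
    "woman": ["lady", "female"],
    "man": ["guy", "gentleman"],
    "child": ["kid"],
    "dog": ["puppy"],
    "cat": ["kitten"],
    "car": ["vehicle"],
    "couch": ["sofa"],
    "television": ["tv"],
    "phone": ["cellphone"],
    "fridge": ["refrigerator"],
    "plane": ["airplane"],
    "bicycle": ["bike"],
    "rock": ["boulder"],
    "road": ["street"],
    "bear": ["animal"],
    "giraffe": ["animal"],
    "horse": ["animal"],
}

_FILLER_WORDS = ["okay", "like", "so", "well", "just", "um", "uh", "really", "some", "kind"]
_FILLER_TAGS = {"okay": "UH", "like": "UH", "so": "UH", "well": "UH", "just": "UH",
                "um": "UH", "uh": "UH", "really": "UH", "some": "DT", "kind": "UH"}


@dataclass
class SceneRegion:
    region_id: str
    cx: float
    cy: float
    sigma: float
    names: list[str]  # names[0] is the dominant name
    name_probs: list[float]
    salience: float = 1.0

    def __post_init__(self) -> None:
        if abs(sum(self.name_probs) - 1.0) > 1e-9:
            raise ValueError("lexicon probabilities must sum to 1")


@dataclass
class SceneSpec:
    image_id: str
    image_w: int
    image_h: int
    regions: list[SceneRegion]

    def __post_init__(self) -> None:
        if not self.regions:
            raise ValueError("a scene needs at least one region")


@dataclass
class ObserverParams:
    """Behavioural parameters of a simulated observer.

    Defaults reproduce the descriptive statistics of free image
    description: 250 ms mean fixation duration, 2.5 words/s, ~22 s
    narratives, ~0.58 s silent preview, and a positive, variable,
    sub-second eye-voice lag.
    """

    fix_dur_mean: float = 0.25  # s, lognormal mean
    fix_dur_sigma: float = 0.4  # lognormal shape (log-space sd)
    speech_rate: float = 2.5  # words per second
    narrative_len: float = 22.0  # s
    lag_mean: float = 0.9  # s, word onset minus fixation-visit onset
    lag_sd: float = 0.3  # s
    preview: float = 0.58  # s of silent viewing before any filler speech
    filler_rate: float = 0.5  # probability a free speech slot emits a filler
    synonym_use: float = 0.2  # probability a naming uses a synonym
    fixations_per_visit: float = 4.0  # mean fixations per region visit
    saccade_gap: float = 0.03  # s between consecutive fixations
    rename_prob: float = 0.25  # probability a revisited region is named again
    attention_sd: float = 0.6  # log-sd of per-observer salience idiosyncrasy

    def __post_init__(self) -> None:
        if min(self.fix_dur_mean, self.speech_rate, self.narrative_len) <= 0:
            raise ValueError("rates and durations must be positive")
        if self.lag_sd < 0 or not (0 <= self.filler_rate <= 1):
            raise ValueError("invalid noise parameters")
        if not (0 <= self.synonym_use <= 1):
            raise ValueError("synonym_use must lie in [0, 1]")


@dataclass
class SimulatedTrial:
    """One observer's scanpath + narrative with per-token ground truth."""

    trial: ScanpathTrial
    narrative: Narrative
    token_regions: list[str | None]  # generating region id per token
    sure_pairs: set[tuple[str, str]]  # (dominant name, region id)
    possible_pairs: set[tuple[str, str]]  # (synonym, region id)


@dataclass
class SimulatedImage:
    """All observers of one image plus pipeline-ready references.

    The reference alignment is expressed in the labels of ``region_model``
    (mean-shift clustering of the pooled simulated fixations), so simulated
    references and pipeline outputs share a label space.
    ``region_to_label`` maps each generating scene region to the cluster
    holding the majority of its fixations (for lexicon-recovery checks).
    """

    image_id: str
    scene: SceneSpec
    trials: list[SimulatedTrial]
    reference_regions: list[ReferenceRegion]
    region_model: RegionModel
    reference: ReferenceAlignment
    region_to_label: dict[str, str]


def random_scene(
    image_id: str,
    rng: np.random.Generator,
    n_regions: int = 10,
    image_w: int = 1680,
    image_h: int = 1050,
    sigma: float = 40.0,
) -> SceneSpec:
    """A scene with well-separated Gaussian regions and a name lexicon.

    Region centroids sit on a jittered grid with a wide margin so that the
    fixation clouds (sd ``sigma``) of different regions stay separable.
    Dominant names are drawn without replacement from a noun bank; regions
    whose noun has common synonyms carry them in the lexicon.
    """
    margin = 180.0
    n_cols = int(np.ceil(np.sqrt(n_regions * image_w / image_h)))
    n_rows = int(np.ceil(n_regions / n_cols))
    xs = np.linspace(margin, image_w - margin, n_cols)
    ys = np.linspace(margin, image_h - margin, n_rows)
    slots = [(x, y) for y in ys for x in xs]
    chosen = [slots[i] for i in rng.choice(len(slots), size=n_regions, replace=False)]
    nouns = [
        _NOUN_BANK[i] for i in rng.choice(len(_NOUN_BANK), size=n_regions, replace=False)
    ]
    regions = []
    for k, ((cx, cy), noun) in enumerate(zip(chosen, nouns)):
        syns = [s for s in _SYNONYM_MAP.get(noun, []) if s not in nouns]
        if syns:
            probs = [0.8] + [0.2 / len(syns)] * len(syns)
        else:
            probs = [1.0]
        regions.append(
            SceneRegion(
                region_id=f"region{k + 1}",
                cx=float(cx + rng.uniform(-40, 40)),
                cy=float(cy + rng.uniform(-40, 40)),
                sigma=sigma,
                names=[noun] + syns,
                name_probs=probs,
                # heavy-tailed salience: a few primary objects draw most
                # visits, background regions are inspected (and named) rarely
                salience=float(rng.lognormal(0.0, 0.9)),
            )
        )
    return SceneSpec(image_id, image_w, image_h, regions)


def _sample_name(region: SceneRegion, params: ObserverParams, rng) -> str:
    if len(region.names) == 1 or rng.random() >= params.synonym_use:
        return region.names[0]
    rel = np.asarray(region.name_probs[1:], dtype=float)
    return region.names[1 + rng.choice(len(rel), p=rel / rel.sum())]


def simulate_trial(
    scene: SceneSpec,
    params: ObserverParams,
    seed: int,
    observer_id: str = "obs0",
) -> SimulatedTrial:
    """Generate one observer's trial on a scene.

    The observer visits regions in a salience-weighted chain without
    immediate self-transitions (revisits allowed), emitting a burst of
    fixations around each region's centroid.  A region is named (``lag``
    seconds after the visit onset) on its first visit and only occasionally
    on revisits, matching the observation that speakers fixate an object
    around the moment of first mention rather than re-naming it on every
    glance.  Observers differ in what draws their attention: each trial
    perturbs the scene's salience weights by a per-observer lognormal
    factor.  Filler words (drawn from the stopword vocabulary, so the
    linguistic filter is exercised) fill free speech slots at the speech
    rate.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    sal = np.array([r.salience for r in scene.regions], dtype=float)
    sal = sal * rng.lognormal(0.0, params.attention_sd, size=len(sal))
    mu_log = np.log(params.fix_dur_mean) - params.fix_dur_sigma**2 / 2

    fixations: list[Fixation] = []
    name_events: list[tuple[float, str, str]] = []
    t = 0.0
    prev = -1
    named: set[int] = set()
    while t < params.narrative_len:
        w = sal.copy()
        if prev >= 0 and len(scene.regions) > 1:
            w[prev] = 0.0
        idx = int(rng.choice(len(scene.regions), p=w / w.sum()))
        region = scene.regions[idx]
        visit_onset = t
        n_fix = 1 + rng.poisson(max(params.fixations_per_visit - 1, 0))
        for _ in range(n_fix):
            dur = float(rng.lognormal(mu_log, params.fix_dur_sigma))
            x = float(np.clip(rng.normal(region.cx, region.sigma), 0, scene.image_w - 1))
            y = float(np.clip(rng.normal(region.cy, region.sigma), 0, scene.image_h - 1))
            fixations.append(Fixation(observer_id, scene.image_id, x, y, t, dur))
            t += dur + params.saccade_gap
        if idx not in named or rng.random() < params.rename_prob:
            lag = max(0.0, float(rng.normal(params.lag_mean, params.lag_sd)))
            name_events.append(
                (visit_onset + lag, _sample_name(region, params, rng), region.region_id)
            )
            named.add(idx)
        prev = idx

    tokens, token_regions = _build_tokens(name_events, params, rng, t)
    narrative = Narrative(observer_id, scene.image_id, tokens)
    trial = ScanpathTrial(
        observer_id, scene.image_id, fixations, scene.image_w, scene.image_h
    )
    sure = {(r.names[0], r.region_id) for r in scene.regions}
    possible = {(s, r.region_id) for r in scene.regions for s in r.names[1:]}
    return SimulatedTrial(trial, narrative, token_regions, sure, possible)


def _build_tokens(name_events, params: ObserverParams, rng, t_end):
    """Interleave name utterances with fillers at the speech rate."""
    slot = 1.0 / params.speech_rate
    word_dur = min(0.3, slot)
    events = sorted(name_events, key=lambda e: e[0])
    # enforce the speech rate between consecutive names
    spaced = []
    prev_t = None
    for t, name, rid in events:
        if prev_t is not None and t < prev_t + slot:
            t = prev_t + slot
        spaced.append((t, name, rid))
        prev_t = t
    tokens: list[WordToken] = []
    token_regions: list[str | None] = []

    def add_fillers(start, stop):
        s = max(start, params.preview)
        while s + word_dur <= stop:
            if rng.random() < params.filler_rate:
                w = _FILLER_WORDS[rng.choice(len(_FILLER_WORDS))]
                tokens.append(WordToken(w, _FILLER_TAGS[w], s, s + word_dur))
                token_regions.append(None)
            s += slot

    cursor = 0.0
    for t, name, rid in spaced:
        add_fillers(cursor, t - word_dur / 2)
        tokens.append(WordToken(name, "NN", t, t + word_dur))
        token_regions.append(rid)
        cursor = t + slot
    add_fillers(cursor, t_end)
    tokens.append(WordToken("next", "UH", max(cursor, t_end) + slot,
                            max(cursor, t_end) + slot + word_dur))
    token_regions.append(None)
    return tokens, token_regions


def scene_reference_regions(scene: SceneSpec, radius_sigmas: float = 3.0) -> list[ReferenceRegion]:
    """Pixel-space references: a disc of ``radius_sigmas`` sd per region."""
    regions = []
    for r in scene.regions:
        rad = radius_sigmas * r.sigma
        poly = [
            (r.cx + rad * np.cos(a), r.cy + rad * np.sin(a))
            for a in np.linspace(0, 2 * np.pi, 33)[:-1]
        ]
        regions.append(
            ReferenceRegion(
                region_id=r.region_id,
                sure_words=[r.names[0]],
                possible_words=r.names[1:],
                polygon=poly,
            )
        )
    return regions


def simulate_dataset(
    n_images: int,
    n_observers: int,
    params: ObserverParams | None = None,
    seed: int = 0,
    n_regions: int = 10,
    bandwidth: float | None = None,
) -> list[SimulatedImage]:
    """Simulate a study: per image, a scene, ``n_observers`` trials, and a
    reference alignment projected into the mean-shift label space."""
    if n_images < 1 or n_observers < 1:
        raise ValueError("counts must be >= 1")
    params = params or ObserverParams()
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n_images):
        image_id = f"img{k + 1}"
        scene = random_scene(image_id, rng, n_regions=n_regions)
        trials = [
            simulate_trial(
                scene,
                params,
                seed=int(rng.integers(0, 2**31 - 1)),
                observer_id=f"obs{o + 1}",
            )
            for o in range(n_observers)
        ]
        scanpaths = [st.trial for st in trials]
        model = mean_shift_cluster(scanpaths, bandwidth=bandwidth)
        model = discard_offimage_clusters(model, scanpaths, scene.image_w, scene.image_h)
        ref_regions = scene_reference_regions(scene)
        reference = project_reference(ref_regions, model, scanpaths)
        region_to_label = _region_to_label_by_centroid(scene, model)
        out.append(
            SimulatedImage(
                image_id=image_id,
                scene=scene,
                trials=trials,
                reference_regions=ref_regions,
                region_model=model,
                reference=reference,
                region_to_label=region_to_label,
            )
        )
    return out


def _region_to_label_by_centroid(scene: SceneSpec, model: RegionModel) -> dict[str, str]:
    """Map each scene region to the nearest cluster centroid's label."""
    out = {}
    for r in scene.regions:
        best, best_d = None, np.inf
        for lab, (cx, cy) in model.centroids.items():
            d = (cx - r.cx) ** 2 + (cy - r.cy) ** 2
            if d < best_d:
                best, best_d = lab, d
        if best is not None and best_d <= (3 * r.sigma) ** 2:
            out[r.region_id] = best
    return out


# ---------------------------------------------------------------------------
# Serialisation in the production input formats (round-trip tested)
# ---------------------------------------------------------------------------


def fixation_log_text(trials: list[ScanpathTrial]) -> str:
    """Render trials in the tab-separated tracker-export dialect the
    production reader consumes (timestamps in microseconds; a saccade row
    separates consecutive fixations so runs never merge)."""
    lines = ["\t".join(
        ["Time", "L_x", "L_y", "R_x", "R_y", "L_event", "R_event", "observer", "image"]
    )]
    for trial in trials:
        def row(t, x, y, ev):
            us = int(round(t * 1e6))
            return f"{us}\t{x:.2f}\t{y:.2f}\t{x:.2f}\t{y:.2f}\t{ev}\t{ev}\t{trial.observer_id}\t{trial.image_id}"

        lines.append(row(0.0, 0.0, 0.0, "Saccade"))
        for f in trial.fixations:
            lines.append(row(f.t_on, f.x_px, f.y_px, "Fixation"))
            lines.append(row(f.t_on + f.dur, f.x_px, f.y_px, "Fixation"))
            lines.append(row(f.t_on + f.dur + 1e-6, 0.0, 0.0, "Saccade"))
    return "\n".join(lines) + "\n"


def transcript_jsonl(narrative: Narrative) -> str:
    import json

    return "\n".join(
        json.dumps(
            {"word": t.surface, "pos": t.pos, "t_on": round(t.t_on, 6),
             "t_off": round(t.t_off, 6)}
        )
        for t in narrative.tokens
    ) + "\n"
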