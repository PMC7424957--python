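"""Reference projection, temporal baselines, and alignment scoring.

Alignments are scored against human references containing *sure* links S
(unambiguous word-region correspondences) and *possible* links P
(plausible but uncertain ones).  Following the Och-Ney convention the
evaluation set is P* = S u P, so a sure link always also counts as
possible.  For an output alignment set A:

    precision = |A n P*| / |A|
    recall    = |A n S|  / |S|
    AER       = 1 - (|A n S| + |A n P*|) / (|A| + |S|)

The two temporal baselines link each word to the region fixated at the
word's onset (simultaneous) or one second earlier (fixed eye-voice delay).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from matplotlib.path import Path as _MplPath

from gazealign.gaze import RegionModel, ScanpathTrial, VisualUnit
from gazealign.narrative import LinguisticUnit

logger = logging.getLogger(__name__)

Link = tuple[str, str]  # (word surface, region label)


@dataclass
class ReferenceRegion:
    """A hand-drawn image region with its sure/possible word lists.

    The pixel support may be given either as a polygon (list of (x, y)
    vertices, 0-based pixel coordinates) or as an explicit pixel set.
    """

    region_id: str
    sure_words: list[str]
    possible_words: list[str] = field(default_factory=list)
    polygon: list[tuple[float, float]] | None = None
    pixels: set[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.polygon is None and not self.pixels:
            raise ValueError("reference region needs a polygon or pixel set")
        self.sure_words = [w.lower() for w in self.sure_words]
        self.possible_words = [w.lower() for w in self.possible_words]

    def contains(self, x: float, y: float) -> bool:
        if self.pixels is not None:
            return (int(x), int(y)) in self.pixels
        return bool(_MplPath(np.asarray(self.polygon)).contains_point((x, y)))

    def pixel_mask(self, image_w: int, image_h: int) -> np.ndarray:
        """Boolean (h, w) mask of the region's pixel support."""
        if self.pixels is not None:
            mask = np.zeros((image_h, image_w), dtype=bool)
            for x, y in self.pixels:
                if 0 <= x < image_w and 0 <= y < image_h:
                    mask[y, x] = True
            return mask
        ys, xs = np.mgrid[0:image_h, 0:image_w]
        pts = np.column_stack([xs.ravel(), ys.ravel()])
        inside = _MplPath(np.asarray(self.polygon)).contains_points(pts)
        return inside.reshape(image_h, image_w)


@dataclass
class ReferenceAlignment:
    """Sure set S and possible set P of (word, region-label) links.

    ``p_star`` (= S u P) is the evaluation set used for precision and AER.
    ``uncovered`` lists reference regions no model label mapped onto;
    their sure words bound the attainable recall.
    """

    S: set[Link]
    P: set[Link]
    uncovered: list[str] = field(default_factory=list)

    @property
    def p_star(self) -> set[Link]:
        return self.S | self.P


@dataclass(frozen=True)
class Metrics:
    precision: float
    recall: float | None
    aer: float
    n_a: int
    n_a_sure: int
    n_a_pstar: int
    n_s: int


def project_reference(
    regions: list[ReferenceRegion],
    model: RegionModel,
    trials: list[ScanpathTrial] | None = None,
) -> ReferenceAlignment:
    """Express pixel-level reference regions in the model's label space.

    MSFC models: a cluster maps to the reference region containing a strict
    majority (> 50%) of the cluster's fixations.  Label-map models: a
    segment maps to the reference region with the largest pixel overlap,
    provided that overlap covers a strict majority of the segment.  Regions
    onto which no label maps are reported as uncovered.
    """
    label_to_region: dict[str, str] = {}
    if model.method == "msfc":
        if trials is None:
            raise ValueError("msfc projection needs the clustered trials")
        fix_by_label: dict[str, list[tuple[float, float]]] = {l: [] for l in model.labels}
        for trial in trials:
            for i, f in enumerate(trial.fixations):
                lab = (model.fixation_assignment or {}).get(
                    (trial.observer_id, trial.image_id, i)
                )
                if lab is not None:
                    fix_by_label[lab].append((f.x_px, f.y_px))
        for lab, pts in fix_by_label.items():
            if not pts:
                continue
            best, best_n = None, 0
            for reg in regions:
                n_in = sum(reg.contains(x, y) for x, y in pts)
                if n_in > best_n:
                    best, best_n = reg, n_in
            if best is not None and best_n * 2 > len(pts):
                label_to_region[lab] = best.region_id
    else:
        if model.label_map is None:
            raise ValueError("label-map model has no label_map")
        h, w = model.label_map.shape
        masks = {r.region_id: r.pixel_mask(w, h) for r in regions}
        for idx, lab in enumerate(model.labels):
            seg = model.label_map == idx
            seg_n = int(seg.sum())
            if seg_n == 0:
                continue
            overlaps = {rid: int((seg & m).sum()) for rid, m in masks.items()}
            rid, best_n = max(overlaps.items(), key=lambda kv: kv[1])
            if best_n * 2 > seg_n:
                label_to_region[lab] = rid

    S: set[Link] = set()
    P: set[Link] = set()
    covered = set(label_to_region.values())
    for lab, rid in label_to_region.items():
        reg = next(r for r in regions if r.region_id == rid)
        S.update((w, lab) for w in reg.sure_words)
        P.update((w, lab) for w in reg.possible_words)
    uncovered = [r.region_id for r in regions if r.region_id not in covered]
    if uncovered:
        logger.info("uncovered reference regions: %s", uncovered)
    return ReferenceAlignment(S=S, P=S | P, uncovered=uncovered)


def _active_label(
    vunits: list[VisualUnit], t: float, gap_rule: str = "previous"
) -> str | None:
    """Label of the visual unit active at time t, else the gap rule's pick."""
    for v in vunits:
        if v.t_on <= t < v.t_on + v.dur:
            return v.label
    if gap_rule == "previous":
        past = [v for v in vunits if v.t_on + v.dur <= t]
        if past:
            return max(past, key=lambda v: v.t_on + v.dur).label
    return None


def baseline_simultaneous(
    vunits: list[VisualUnit],
    lunits: list[LinguisticUnit],
    gap_rule: str = "previous",
) -> set[Link]:
    """Assume words are uttered at the moment their region is fixated."""
    return baseline_delayed(vunits, lunits, delay=0.0, gap_rule=gap_rule)


def baseline_delayed(
    vunits: list[VisualUnit],
    lunits: list[LinguisticUnit],
    delay: float = 1.0,
    gap_rule: str = "previous",
) -> set[Link]:
    """Assume a fixed eye-voice delay: a word at time t names the region
    fixated at t - delay.  Words before the first fixation stay unaligned;
    in fixation gaps the most recent preceding fixation is used (or none,
    with gap_rule="strict")."""
    if delay < 0:
        raise ValueError("delay must be >= 0")
    A: set[Link] = set()
    for l in lunits:
        lab = _active_label(vunits, l.t_on - delay, gap_rule)
        if lab is not None:
            A.add((l.surface, lab))
    return A


def compute_metrics(A: set[Link], reference: ReferenceAlignment) -> Metrics:
    """Precision, recall, and AER of an alignment set against a reference."""
    p_star = reference.p_star
    n_a = len(A)
    n_a_sure = len(A & reference.S)
    n_a_pstar = len(A & p_star)
    n_s = len(reference.S)
    precision = (n_a_pstar / n_a) if n_a else 1.0
    if n_s:
        recall = n_a_sure / n_s
    else:
        logger.warning("empty sure set; recall undefined")
        recall = None
    aer = 1.0 - (n_a_sure + n_a_pstar) / (n_a + n_s) if (n_a + n_s) else 1.0
    return Metrics(precision, recall, aer, n_a, n_a_sure, n_a_pstar, n_s)


def summarize(per_image: dict[str, dict[str, Metrics]]) -> pd.DataFrame:
    """Macro-averages and improvement counts over a set of images.

    ``per_image`` maps image id -> method name -> Metrics, where methods
    include ``framework`` plus any baselines.  Returns a tidy frame with
    one row per method carrying mean precision/recall/AER and, for each
    baseline, the number of images where the framework strictly improves
    each metric, plus the mean absolute improvement in points.
    """
    if not per_image:
        raise ValueError("empty image set")
    methods = sorted({m for d in per_image.values() for m in d})
    rows = []
    for method in methods:
        ms = [per_image[img][method] for img in per_image if method in per_image[img]]
        recs = [m.recall for m in ms if m.recall is not None]
        row = {
            "method": method,
            "n_images": len(ms),
            "precision": float(np.mean([m.precision for m in ms])),
            "recall": float(np.mean(recs)) if recs else None,
            "aer": float(np.mean([m.aer for m in ms])),
        }
        rows.append(row)
    df = pd.DataFrame(rows).set_index("method")
    if "framework" in methods:
        for base in methods:
            if base == "framework":
                continue
            imgs = [i for i in per_image if base in per_image[i] and "framework" in per_image[i]]
            fw = [per_image[i]["framework"] for i in imgs]
            bl = [per_image[i][base] for i in imgs]
            df.loc[base, "n_fw_better_precision"] = sum(
                f.precision > b.precision for f, b in zip(fw, bl)
            )
            df.loc[base, "n_fw_better_recall"] = sum(
                (f.recall or 0) > (b.recall or 0) for f, b in zip(fw, bl)
            )
            df.loc[base, "n_fw_better_aer"] = sum(f.aer < b.aer for f, b in zip(fw, bl))
    return df


def read_reference_json(stream) -> list[ReferenceRegion]:
    """Reference file: JSON list of regions with polygon/pixels and words."""
    data = json.load(stream) if hasattr(stream, "read") else json.loads(stream)
    regions = []
    for rec in data["regions"]:
        regions.append(
            ReferenceRegion(
                region_id=rec["id"],
                sure_words=rec.get("sure_words", []),
                possible_words=rec.get("possible_words", []),
                polygon=[tuple(p) for p in rec["polygon"]] if "polygon" in rec else None,
                pixels={tuple(p) for p in rec["pixels"]} if "pixels" in rec else None,
            )
        )
    return regions


def write_reference_json(regions: list[ReferenceRegion], path) -> None:
    recs = []
    for r in regions:
        rec = {
            "id": r.region_id,
            "sure_words": r.sure_words,
            "possible_words": r.possible_words,
        }
        if r.polygon is not None:
            rec["polygon"] = [list(p) for p in r.polygon]
        else:
            rec["pixels"] = sorted([list(p) for p in r.pixels])
        recs.append(rec)
    with open(path, "w") as fh:
        json.dump({"regions": recs}, fh, indent=1, sort_keys=True)
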