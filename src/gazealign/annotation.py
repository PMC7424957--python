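"""Aggregate alignment links into ranked word labels per image region."""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from gazealign.gaze import RegionModel


@dataclass
class RegionAnnotation:
    """Ranked word labels for one region.

    ``words`` holds (word, utterance count, max posterior) tuples sorted by
    utterance frequency (descending by default; the ascending order used by
    some plotting conventions is available via ``ascending=True`` in
    :func:`aggregate_labels`), ties broken by max posterior then
    lexicographically.  ``W`` is the display cutoff.
    """

    region: str
    words: list[tuple[str, int, float]]
    W: int = 3

    def top(self) -> list[str]:
        return [w for w, _, _ in self.words[: self.W]]


def aggregate_labels(
    links: dict[tuple[str, str], float],
    word_freq: dict[str, int],
    W: int = 3,
    ascending: bool = False,
) -> dict[str, RegionAnnotation]:
    """Group pooled (word, region) links by region and rank the words.

    ``word_freq`` is the per-image utterance count of each linguistic unit;
    words missing from it count 0.  Regions with no links are absent here
    and should be added by the exporter from the region model.
    """
    if W < 1:
        raise ValueError("W must be >= 1")
    by_region: dict[str, list[tuple[str, int, float]]] = {}
    for (word, region), post in links.items():
        by_region.setdefault(region, []).append(
            (word, word_freq.get(word, 0), float(post))
        )
    out = {}
    for region, items in by_region.items():
        sign = 1 if ascending else -1
        items.sort(key=lambda t: (sign * t[1], -t[2], t[0]))
        out[region] = RegionAnnotation(region, items, W)
    return out


def export_annotations(
    annotations: dict[str, RegionAnnotation],
    model: RegionModel,
    tsv_path,
    overlay_path=None,
) -> pd.DataFrame:
    """Write the annotation table (TSV) and label-placement overlay (JSON).

    Every model label appears in the output; regions without links get no
    rows in the TSV but an empty entry in the overlay.  The overlay places
    each region's labels at its centroid.
    """
    unknown = set(annotations) - set(model.labels)
    if unknown:
        raise ValueError(f"unknown region label(s): {sorted(unknown)}")
    rows = []
    for region in model.labels:
        ann = annotations.get(region)
        if ann is None:
            continue
        for rank, (word, count, post) in enumerate(ann.words, start=1):
            rows.append(
                {"region": region, "rank": rank, "word": word,
                 "count": count, "posterior": post}
            )
    df = pd.DataFrame(rows, columns=["region", "rank", "word", "count", "posterior"])
    df.to_csv(tsv_path, sep="\t", index=False)
    if overlay_path is not None:
        overlay = {}
        for region in model.labels:
            cx, cy = model.centroids.get(region, (np.nan, np.nan))
            ann = annotations.get(region)
            overlay[region] = {
                "centroid": [float(cx), float(cy)],
                "labels": ann.top() if ann else [],
            }
        with open(overlay_path, "w") as fh:
            json.dump(overlay, fh, indent=1, sort_keys=True)
    return df
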