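"""Fixation-log parsing, observer quality control, and visual-unit encoding.

A scanpath is reduced to a sequence of *visual units*: each fixation is
replaced by the label of the image region it falls in.  Regions come from
one of three sources: mean-shift clustering of the pooled fixation
coordinates themselves (MSFC), k-means segmentation of the image raster on
RGB + spatial features, or an externally supplied per-pixel label map.
"""

from __future__ import annotations

import io
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans, MeanShift

logger = logging.getLogger(__name__)

# Display geometry of a 1680x1050 monitor subtending 38x22 deg at ~68 cm:
# 1680/38 ~ 44 px per degree of visual angle.
DEFAULT_PX_PER_DEG = 44.0
#: default mean-shift bandwidth: 2 deg of visual angle, foveal-scale grouping
DEFAULT_BANDWIDTH_DEG = 2.0


class FixationLogFormatError(ValueError):
    """Raised when a fixation log violates its declared dialect."""


@dataclass(frozen=True)
class Fixation:
    """A single stabilised gaze event, in image pixel coordinates."""

    observer_id: str
    image_id: str
    x_px: float
    y_px: float
    t_on: float  # onset, seconds from trial start
    dur: float  # seconds

    def __post_init__(self) -> None:
        if not (self.dur > 0):
            raise ValueError(f"fixation duration must be positive, got {self.dur}")
        if self.t_on < 0:
            raise ValueError(f"fixation onset must be >= 0, got {self.t_on}")
        if not (np.isfinite(self.x_px) and np.isfinite(self.y_px)):
            raise ValueError("fixation coordinates must be finite")


@dataclass
class ScanpathTrial:
    """Ordered fixations of one observer on one image."""

    observer_id: str
    image_id: str
    fixations: list[Fixation]
    image_w: int = 1680
    image_h: int = 1050

    def __post_init__(self) -> None:
        onsets = [f.t_on for f in self.fixations]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("fixation onsets must be non-decreasing")


@dataclass(frozen=True)
class CalibrationRecord:
    """Per-observer mean calibration error in degrees of visual angle."""

    observer_id: str
    err_x_deg: float
    err_y_deg: float

    def __post_init__(self) -> None:
        if self.err_x_deg < 0 or self.err_y_deg < 0:
            raise ValueError("calibration errors must be >= 0")


@dataclass
class RegionModel:
    """Labelled image regions used to encode fixations as visual units.

    ``method`` is one of ``msfc`` (fixation clustering; per-fixation
    assignment keyed by ``(observer_id, image_id, fixation_index)``),
    ``kmeans`` or ``external`` (per-pixel ``label_map`` of shape
    ``image_h x image_w`` holding indices into ``labels``).
    """

    method: str
    labels: list[str]
    fixation_assignment: dict[tuple[str, str, int], str] | None = None
    label_map: np.ndarray | None = None
    centroids: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "labels": self.labels,
                "centroids": {k: list(v) for k, v in self.centroids.items()},
            },
            sort_keys=True,
        )


@dataclass(frozen=True)
class VisualUnit:
    """A fixation encoded by the label of the region it falls in."""

    label: str
    t_on: float
    dur: float

    def __post_init__(self) -> None:
        if not (self.dur > 0):
            raise ValueError("visual unit duration must be positive")


@dataclass
class LogDialect:
    """Column layout of a delimited eye-tracker export.

    ``time_unit`` is one of ``us``, ``ms``, ``s``.  ``sample_period`` is the
    duration assigned to a fixation supported by a single sample row (a
    250 Hz tracker emits one row every 4 ms).
    """

    time_col: str = "Time"
    lx_col: str = "L_x"
    ly_col: str = "L_y"
    rx_col: str = "R_x"
    ry_col: str = "R_y"
    levent_col: str = "L_event"
    revent_col: str = "R_event"
    observer_col: str | None = "observer"
    image_col: str | None = "image"
    delimiter: str = "\t"
    time_unit: str = "us"
    fixation_label: str = "Fixation"
    sample_period: float = 0.004
    position_tol_px: float = 1.0

    @property
    def time_scale(self) -> float:
        return {"us": 1e-6, "ms": 1e-3, "s": 1.0}[self.time_unit]


def _required_columns(dialect: LogDialect) -> list[str]:
    cols = [
        dialect.time_col,
        dialect.lx_col,
        dialect.ly_col,
        dialect.rx_col,
        dialect.ry_col,
        dialect.levent_col,
        dialect.revent_col,
    ]
    for extra in (dialect.observer_col, dialect.image_col):
        if extra is not None:
            cols.append(extra)
    return cols


def read_fixation_log(
    stream,
    dialect: LogDialect | None = None,
    observer_id: str = "obs0",
    image_id: str = "img0",
    image_w: int = 1680,
    image_h: int = 1050,
) -> list[ScanpathTrial]:
    """Parse a delimited eye-tracker export into scanpath trials.

    Rows whose event field equals the dialect's fixation label are grouped;
    consecutive rows at the same position (within ``position_tol_px``)
    collapse into one fixation whose duration is the spanned time.
    Timestamps are rebased to zero at each trial's first row and converted
    to seconds.  When the dialect declares no observer/image columns, the
    whole file is one trial with the ids given as arguments.
    """
    dialect = dialect or LogDialect()
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    df = pd.read_csv(stream, sep=dialect.delimiter)
    if df.empty:
        return []
    for col in _required_columns(dialect):
        if col not in df.columns:
            raise FixationLogFormatError(f"missing required column: {col!r}")

    if dialect.observer_col is not None and dialect.image_col is not None:
        groups = df.groupby([dialect.observer_col, dialect.image_col], sort=False)
        keyed = [((str(o), str(i)), g) for (o, i), g in groups]
    else:
        keyed = [((observer_id, image_id), df)]

    trials = []
    for (obs, img), g in keyed:
        g = g.reset_index(drop=True)
        ts = g[dialect.time_col].to_numpy(dtype=float)
        if np.any(np.diff(ts) < 0):
            bad = int(np.argmax(np.diff(ts) < 0)) + 1
            raise FixationLogFormatError(
                f"non-monotone timestamps in trial ({obs}, {img}) at row {bad}"
            )
        t0 = ts[0]
        t_sec = (ts - t0) * dialect.time_scale
        fixations = _collapse_fixation_rows(g, t_sec, dialect, obs, img)
        trials.append(
            ScanpathTrial(obs, img, fixations, image_w=image_w, image_h=image_h)
        )
    return trials


def _row_position(row, dialect: LogDialect) -> tuple[float, float] | None:
    """Average the eyes whose event is a fixation; None if neither fixating."""
    pts = []
    if row[dialect.levent_col] == dialect.fixation_label:
        x, y = float(row[dialect.lx_col]), float(row[dialect.ly_col])
        if np.isfinite(x) and np.isfinite(y):
            pts.append((x, y))
    if row[dialect.revent_col] == dialect.fixation_label:
        x, y = float(row[dialect.rx_col]), float(row[dialect.ry_col])
        if np.isfinite(x) and np.isfinite(y):
            pts.append((x, y))
    if not pts:
        return None
    return float(np.mean([p[0] for p in pts])), float(np.mean([p[1] for p in pts]))


def _collapse_fixation_rows(g, t_sec, dialect, obs, img) -> list[Fixation]:
    fixations: list[Fixation] = []
    run_pos: tuple[float, float] | None = None
    run_start = run_end = 0.0

    def flush():
        if run_pos is None:
            return
        dur = run_end - run_start
        if dur <= 0:
            dur = dialect.sample_period
        fixations.append(Fixation(obs, img, run_pos[0], run_pos[1], run_start, dur))

    for idx in range(len(g)):
        pos = _row_position(g.iloc[idx], dialect)
        t = float(t_sec[idx])
        if pos is None:
            flush()
            run_pos = None
            continue
        if run_pos is not None and (
            abs(pos[0] - run_pos[0]) <= dialect.position_tol_px
            and abs(pos[1] - run_pos[1]) <= dialect.position_tol_px
        ):
            run_end = t
        else:
            flush()
            run_pos, run_start, run_end = pos, t, t
    flush()
    return fixations


def qc_filter_observers(
    records: list[CalibrationRecord], k_sd: float = 2.0
) -> set[str]:
    """Observers whose calibration error lies within ``k_sd`` sample SDs
    of the group mean in *both* the horizontal and vertical directions.

    With zero spread every deviation is 0 <= 0, so all observers pass.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 calibration records to estimate an SD")
    ex = np.array([r.err_x_deg for r in records])
    ey = np.array([r.err_y_deg for r in records])
    mx, sx = ex.mean(), ex.std(ddof=1)
    my, sy = ey.mean(), ey.std(ddof=1)
    return {
        r.observer_id
        for r in records
        if abs(r.err_x_deg - mx) <= k_sd * sx and abs(r.err_y_deg - my) <= k_sd * sy
    }


def mean_shift_cluster(
    trials: list[ScanpathTrial], bandwidth: float | None = None
) -> RegionModel:
    """Mean-shift fixation clustering (MSFC) on pooled (x, y) coordinates.

    The number of clusters is data-driven, not preset.  Fixations from all
    trials (typically all observers of one image) are pooled; each fixation
    is assigned to the mode of its basin of attraction.  Labels are
    ``cluster1..clusterN`` ordered by cluster size (sklearn convention).
    """
    if bandwidth is None:
        bandwidth = DEFAULT_BANDWIDTH_DEG * DEFAULT_PX_PER_DEG
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    keys, coords = [], []
    for trial in trials:
        for i, f in enumerate(trial.fixations):
            keys.append((trial.observer_id, trial.image_id, i))
            coords.append((f.x_px, f.y_px))
    if not coords:
        raise ValueError("no fixations to cluster")
    X = np.asarray(coords, dtype=float)
    ms = MeanShift(bandwidth=bandwidth, cluster_all=True)
    assign = ms.fit_predict(X)
    labels = [f"cluster{i + 1}" for i in range(len(ms.cluster_centers_))]
    centroids = {
        labels[i]: (float(c[0]), float(c[1]))
        for i, c in enumerate(ms.cluster_centers_)
    }
    return RegionModel(
        method="msfc",
        labels=labels,
        fixation_assignment={k: labels[a] for k, a in zip(keys, assign)},
        centroids=centroids,
    )


def discard_offimage_clusters(
    model: RegionModel, trials: list[ScanpathTrial], image_w: int, image_h: int
) -> RegionModel:
    """Drop MSFC clusters whose centroid lies outside the image.

    Off-image clusters arise from blinks and track losses; their fixations
    are removed from all downstream unit sequences.
    """
    if model.method != "msfc":
        raise ValueError("discard_offimage_clusters applies to msfc models only")
    keep = [
        lab
        for lab in model.labels
        if 0 <= model.centroids[lab][0] < image_w
        and 0 <= model.centroids[lab][1] < image_h
    ]
    dropped = set(model.labels) - set(keep)
    if dropped:
        logger.info("discarding %d off-image cluster(s): %s", len(dropped), sorted(dropped))
    if not keep:
        logger.warning("all clusters off-image; returning empty region model")
    assignment = {
        k: v for k, v in (model.fixation_assignment or {}).items() if v in keep
    }
    return RegionModel(
        method="msfc",
        labels=keep,
        fixation_assignment=assignment,
        centroids={lab: model.centroids[lab] for lab in keep},
    )


def kmeans_segment(
    image: np.ndarray,
    k: int,
    spatial_weight: float = 1.0,
    seed: int = 0,
) -> RegionModel:
    """Segment an RGB raster with Lloyd's k-means on colour + position.

    Per-pixel features are (R, G, B, w*x, w*y), each channel standardised
    to zero mean / unit variance before the spatial weight is applied, so
    ``spatial_weight`` trades off colour homogeneity against compactness.
    ``k`` is typically taken from the MSFC cluster count for the same image.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        img = img[:, :, None].repeat(3, axis=2)
    h, w = img.shape[:2]
    ys, xs = np.mgrid[0:h, 0:w]
    feats = np.column_stack(
        [img[..., c].ravel() for c in range(3)] + [xs.ravel(), ys.ravel()]
    ).astype(float)
    std = feats.std(axis=0)
    std[std == 0] = 1.0
    feats = (feats - feats.mean(axis=0)) / std
    feats[:, 3:] *= spatial_weight

    n_distinct = len(np.unique(feats, axis=0))
    k_eff = min(k, n_distinct)
    if k_eff < k:
        warnings.warn(
            f"requested k={k} but only {n_distinct} distinct feature vectors; "
            f"using k={k_eff}",
            stacklevel=2,
        )
    km = KMeans(n_clusters=k_eff, n_init=1, max_iter=300, tol=1e-4, random_state=seed)
    assign = km.fit_predict(feats)
    # drop empty segments (possible under degenerate inputs), renumber densely
    used = np.unique(assign)
    remap = {old: new for new, old in enumerate(used)}
    label_map = np.vectorize(remap.get)(assign).reshape(h, w)
    labels = [f"segment{i + 1}" for i in range(len(used))]
    centroids = {}
    for i, lab in enumerate(labels):
        mask = label_map == i
        centroids[lab] = (float(xs[mask].mean()), float(ys[mask].mean()))
    return RegionModel(
        method="kmeans", labels=labels, label_map=label_map, centroids=centroids
    )


def encode_visual_units(
    trial: ScanpathTrial, model: RegionModel
) -> list[VisualUnit]:
    """Encode each retained fixation by its region label, preserving order.

    MSFC models carry an explicit per-fixation assignment (fixations whose
    cluster was discarded are skipped); label-map models look the fixation
    pixel up in the map, dropping out-of-bounds fixations.
    """
    units: list[VisualUnit] = []
    dropped = 0
    for i, f in enumerate(trial.fixations):
        if model.method == "msfc":
            lab = (model.fixation_assignment or {}).get(
                (trial.observer_id, trial.image_id, i)
            )
            if lab is None:
                dropped += 1
                continue
        else:
            if model.label_map is None:
                raise ValueError("label-map model has no label_map")
            h, w = model.label_map.shape
            xi, yi = int(f.x_px), int(f.y_px)
            if not (0 <= xi < w and 0 <= yi < h):
                dropped += 1
                continue
            lab = model.labels[int(model.label_map[yi, xi])]
        units.append(VisualUnit(lab, f.t_on, f.dur))
    if dropped:
        logger.info(
            "dropped %d fixation(s) outside the region model for trial (%s, %s)",
            dropped,
            trial.observer_id,
            trial.image_id,
        )
    return units
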