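"""Sliding-window scene classification, detection extraction and matching.

A trained patch pipeline is slid across a full trap scene at a fixed
stride; every window is classified exactly like a training patch, giving a
category map of predicted classes and decision scores.  Non-background
local maxima become detections after greedy per-class non-maximum
suppression; detections are matched one-to-one against ground-truth markers
within a pixel tolerance to score localization recall and precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotations import MARKER_COLUMNS, PATCH_SIZE, PoolingScheme
from .pipeline import BovwPipeline

logger = logging.getLogger(__name__)

BACKGROUND_LABEL = "BKGRND"


@dataclass(frozen=True)
class CategoryMap:
    """Grid of window-centre predictions over a scene.

    ``xs``/``ys`` are the window-centre coordinates of the grid columns and
    rows; ``labels`` (rows x cols, object dtype) the predicted classes;
    ``scores`` the winning decision margin; ``all_scores`` the full
    per-class score stack in ``classes`` order.
    """

    xs: np.ndarray
    ys: np.ndarray
    labels: np.ndarray
    scores: np.ndarray
    all_scores: np.ndarray
    classes: tuple[str, ...]
    window: int
    stride: int

    def cells(self) -> pd.DataFrame:
        yy, xx = np.meshgrid(self.ys, self.xs, indexing="ij")
        return pd.DataFrame(
            {
                "x": xx.ravel(),
                "y": yy.ravel(),
                "label": self.labels.ravel(),
                "score": self.scores.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.cells().to_csv(path, sep="\t", index=False)


def scan_scene(
    scene: np.ndarray,
    pipeline: BovwPipeline,
    window: int = PATCH_SIZE,
    stride: int = 25,
) -> CategoryMap:
    """Classify every window position of a scene through the patch pipeline.

    The grid covers all positions where a full window fits:
    ``floor((W - window) / stride) + 1`` columns and the analogous number of
    rows.  Scenes smaller than the window are rejected.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    h, w = scene.shape[:2]
    if h < window or w < window:
        raise ValueError(
            f"scene {w}x{h} smaller than the {window}-px window"
        )
    if pipeline.model is None:
        raise ValueError("pipeline has no trained model attached")
    half = window // 2
    x0s = np.arange(0, w - window + 1, stride)
    y0s = np.arange(0, h - window + 1, stride)
    classes = pipeline.model.classes
    labels = np.empty((len(y0s), len(x0s)), dtype=object)
    scores = np.empty((len(y0s), len(x0s)))
    all_scores = np.empty((len(y0s), len(x0s), len(classes)))
    for i, y0 in enumerate(y0s):
        for j, x0 in enumerate(x0s):
            patch = scene[y0 : y0 + window, x0 : x0 + window]
            result = pipeline.predict(patch)
            labels[i, j] = result.label
            scores[i, j] = float(np.max(result.scores))
            all_scores[i, j] = result.scores
    return CategoryMap(
        xs=x0s + half,
        ys=y0s + half,
        labels=labels,
        scores=scores,
        all_scores=all_scores,
        classes=classes,
        window=window,
        stride=stride,
    )


def _mean_shift(
    x: float,
    y: float,
    pts: np.ndarray,
    weights: np.ndarray,
    radius: float,
    iters: int = 4,
) -> tuple[float, float]:
    """Drift a detection to the score-weighted centroid of nearby cells.

    Windows containing an insect anywhere inside them score similarly, so
    the raw argmax cell can sit well off-centre; the positive plateau is
    roughly symmetric about the insect and scores sag toward its rim, so a
    few weighted mean-shift steps over it recover the centre.
    """
    for _ in range(iters):
        d2 = (pts[:, 0] - x) ** 2 + (pts[:, 1] - y) ** 2
        near = d2 <= radius**2
        if not near.any():
            break
        w = weights[near]
        x = float(np.average(pts[near, 0], weights=w))
        y = float(np.average(pts[near, 1], weights=w))
    return x, y


def _connected_component(
    pts: np.ndarray, x: float, y: float, link: float
) -> np.ndarray:
    """Boolean mask of the points chained to (x, y) by steps <= ``link``.

    Restricting position refinement to the peak's own connected cluster
    keeps a neighbouring object's cells (same class, further away) from
    dragging the centroid.
    """
    n = len(pts)
    mask = np.zeros(n, dtype=bool)
    if n == 0:
        return mask
    d0 = (pts[:, 0] - x) ** 2 + (pts[:, 1] - y) ** 2
    frontier = [int(np.argmin(d0))]
    mask[frontier[0]] = True
    while frontier:
        i = frontier.pop()
        d = (pts[:, 0] - pts[i, 0]) ** 2 + (pts[:, 1] - pts[i, 1]) ** 2
        new = (d <= link**2) & ~mask
        for j in np.nonzero(new)[0]:
            mask[j] = True
            frontier.append(int(j))
    return mask


def extract_detections(
    cmap: CategoryMap,
    min_score: float = 0.0,
    suppression_radius: float = 50.0,
    background_label: str = BACKGROUND_LABEL,
    refine: bool = False,
    refine_radius: float | None = None,
    class_agnostic: bool = False,
) -> pd.DataFrame:
    """Greedy per-class non-maximum suppression of a category map.

    Cells predicted as a non-background class with score >= ``min_score``
    are visited in (score descending, y, x) order; a cell is kept unless a
    kept detection of the same class lies within ``suppression_radius``.
    ``class_agnostic=True`` suppresses across classes as well, which removes
    the wrong-class detections that windows catching only part of an insect
    tend to produce.  With ``refine=True`` kept detections are additionally
    re-centred by weighted mean-shift over the same-class candidate cells
    (positions then no longer coincide with grid cells).
    """
    cells = cmap.cells()
    cand = cells[(cells["label"] != background_label) & (cells["score"] >= min_score)]
    cand = cand.sort_values(
        by=["score", "y", "x"], ascending=[False, True, True], kind="mergesort"
    )
    kept: list[dict] = []
    for row in cand.itertuples(index=False):
        ok = True
        for k in kept:
            if not class_agnostic and k["label"] != row.label:
                continue
            if (k["cell_x"] - row.x) ** 2 + (k["cell_y"] - row.y) ** 2 < suppression_radius**2:
                ok = False
                break
        if ok:
            kept.append(
                {
                    "x": float(row.x),
                    "y": float(row.y),
                    "cell_x": float(row.x),
                    "cell_y": float(row.y),
                    "label": row.label,
                    "score": float(row.score),
                }
            )
    if refine:
        for k in kept:
            sub = cand[cand["label"] == k["label"]]
            pts = sub[["x", "y"]].to_numpy(dtype=float)
            scores = sub["score"].to_numpy(dtype=float)
            comp = _connected_component(
                pts, k["cell_x"], k["cell_y"], link=2.5 * cmap.stride
            )
            weights = scores[comp] - min_score + 1e-6
            k["x"], k["y"] = _mean_shift(
                k["x"],
                k["y"],
                pts[comp],
                weights,
                radius=refine_radius or suppression_radius,
            )
        # Refinement can collapse distinct cells onto one object; dedup on
        # the refined positions, keeping the higher-scoring detection.
        deduped: list[dict] = []
        for k in kept:  # kept is already in (score desc, y, x) order
            dup = False
            for d in deduped:
                if not class_agnostic and d["label"] != k["label"]:
                    continue
                if (d["x"] - k["x"]) ** 2 + (d["y"] - k["y"]) ** 2 < suppression_radius**2:
                    dup = True
                    break
            if not dup:
                deduped.append(k)
        kept = deduped
    out = pd.DataFrame(kept, columns=["x", "y", "cell_x", "cell_y", "label", "score"])
    return out[["x", "y", "label", "score"]]


@dataclass(frozen=True)
class MatchResult:
    """Detection-vs-marker scoring at a pixel tolerance."""

    tp: int
    fp: int
    fn: int
    per_class: dict
    pairs: list  # (detection index, marker index) of matched pairs

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0


def match_detections(
    detections: pd.DataFrame,
    markers: pd.DataFrame,
    tolerance_px: float = 30.0,
    pooling: PoolingScheme | None = None,
) -> MatchResult:
    """One-to-one greedy nearest matching of detections to markers.

    Candidate pairs share a class (after optional pooling of both sides) and
    lie within ``tolerance_px``; pairs are accepted closest-first, each
    detection and marker at most once.  Unmatched detections count as false
    positives, unmatched markers as false negatives.
    """
    if tolerance_px <= 0:
        raise ValueError("tolerance_px must be > 0")
    det_labels = [
        pooling.map_label(l) if pooling else l for l in detections["label"]
    ]
    mark_labels = [
        pooling.map_label(l) if pooling else l for l in markers["label"]
    ]
    dx = detections["x"].to_numpy(dtype=float)
    dy = detections["y"].to_numpy(dtype=float)
    mx = markers["x"].to_numpy(dtype=float)
    my = markers["y"].to_numpy(dtype=float)
    pairs = []
    for i in range(len(detections)):
        for j in range(len(markers)):
            if det_labels[i] != mark_labels[j]:
                continue
            d = float(np.hypot(dx[i] - mx[j], dy[i] - my[j]))
            if d <= tolerance_px:
                pairs.append((d, i, j))
    pairs.sort(key=lambda t: (t[0], t[1], t[2]))
    used_d: set[int] = set()
    used_m: set[int] = set()
    matched = []
    for d, i, j in pairs:
        if i in used_d or j in used_m:
            continue
        used_d.add(i)
        used_m.add(j)
        matched.append((i, j))
    per_class: dict[str, dict] = {}
    for lbl in sorted(set(det_labels) | set(mark_labels)):
        per_class[lbl] = {"tp": 0, "fp": 0, "fn": 0}
    for i, j in matched:
        per_class[mark_labels[j]]["tp"] += 1
    for i in range(len(detections)):
        if i not in used_d:
            per_class[det_labels[i]]["fp"] += 1
    for j in range(len(markers)):
        if j not in used_m:
            per_class[mark_labels[j]]["fn"] += 1
    tp = len(matched)
    return MatchResult(
        tp=tp,
        fp=len(detections) - tp,
        fn=len(markers) - tp,
        per_class=per_class,
        pairs=matched,
    )


def detections_as_markers(
    detections: pd.DataFrame, image_id: str, dataset_tag: str = "detections"
) -> pd.DataFrame:
    """Convert a detection list to marker-table format (round-trippable)."""
    return pd.DataFrame(
        {
            "image_id": image_id,
            "x": np.round(detections["x"]).astype(int),
            "y": np.round(detections["y"]).astype(int),
            "label": detections["label"],
            "dataset_tag": dataset_tag,
        },
        columns=list(MARKER_COLUMNS),
    )


def overlay_png(
    scene: np.ndarray,
    detections: pd.DataFrame,
    path,
    palette: dict | None = None,
    radius: int = 12,
) -> None:
    """Write the scene with colour-coded detection circles as a PNG."""
    from PIL import Image, ImageDraw

    default_palette = {
        "BEMITA": (220, 40, 40),
        "TRIAVA": (40, 40, 220),
        "BEM-TRI": (160, 20, 160),
        "ENCAFO": (20, 120, 20),
        "MACRPY": (230, 140, 20),
    }
    palette = palette or default_palette
    img = Image.fromarray(scene)
    draw = ImageDraw.Draw(img)
    for row in detections.itertuples(index=False):
        colour = palette.get(row.label, (0, 0, 0))
        draw.ellipse(
            [row.x - radius, row.y - radius, row.x + radius, row.y + radius],
            outline=colour,
            width=3,
        )
    img.save(path, format="PNG")
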