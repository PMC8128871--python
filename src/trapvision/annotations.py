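"""Point-marker annotation tables, sub-image cropping, splits and pooling.

Trap photographs are annotated by digitizing one point near the middle of
each trapped individual.  A marker table holds those points together with a
class label and a dataset tag (e.g. ``Lab0d`` for freshly trapped catches,
``Lab7d`` for catches aged seven days on the trap).  Sub-images of
201 x 201 px are cropped around the markers and become the classifier's
training and test records.

Coordinate convention, used throughout the package: 0-based, ``x`` is the
column, ``y`` the row, origin at the top-left corner of the image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The five-class taxonomy: two whitefly pests, two natural enemies, and the
#: trap-background ("garbage") class that absorbs every non-target object.
DEFAULT_TAXONOMY: tuple[str, ...] = ("BEMITA", "TRIAVA", "ENCAFO", "MACRPY", "BKGRND")

#: Label of the pooled whitefly class (BEMITA and TRIAVA merged).
POOLED_WHITEFLY_LABEL = "BEM-TRI"

#: Default sub-image edge length in pixels (odd, so the marker is the centre).
PATCH_SIZE = 201

MARKER_COLUMNS = ("image_id", "x", "y", "label", "dataset_tag")


class MarkerParseError(ValueError):
    """A marker file line could not be parsed."""


class MarkerValidationError(ValueError):
    """A marker carries an unknown label or lies outside its image."""


@dataclass(frozen=True)
class SubImageRecord:
    """A labelled 201x201 patch with provenance.

    ``patch`` may be in any colour space; ``source`` records the originating
    image id and marker position; ``decay`` is the ageing fraction used when
    the patch is synthetic (``None`` for patches cropped from real images).
    """

    patch: np.ndarray
    label: str
    source: tuple[str, int, int]
    dataset_tag: str
    decay: float | None = None

    def __post_init__(self) -> None:
        if self.patch.shape[:2] != (PATCH_SIZE, PATCH_SIZE):
            raise ValueError(
                f"patch must be {PATCH_SIZE}x{PATCH_SIZE}, got {self.patch.shape[:2]}"
            )


@dataclass(frozen=True)
class PoolingScheme:
    """Temporal and/or categorical pooling of records.

    temporal
        Merge the ``Lab0d`` and ``Lab7d`` dataset tags into one tag, emulating
        training/testing irrespective of how long catches aged on the trap.
    categorical
        A total label map over the taxonomy.  The standard scheme merges the
        two whitefly classes into ``BEM-TRI`` and fixes every other label.
    """

    temporal: bool = False
    categorical: dict[str, str] = field(default_factory=dict)
    temporal_tags: tuple[str, str] = ("Lab0d", "Lab7d")
    merged_tag: str = "Lab0d-7d"

    def map_label(self, label: str) -> str:
        if self.categorical:
            if label not in self.categorical:
                raise MarkerValidationError(
                    f"label {label!r} outside the pooling scheme domain"
                )
            return self.categorical[label]
        return label

    def map_tag(self, tag: str) -> str:
        if self.temporal and tag in self.temporal_tags:
            return self.merged_tag
        return tag

    @property
    def pooled_taxonomy(self) -> tuple[str, ...]:
        if not self.categorical:
            return DEFAULT_TAXONOMY
        seen: list[str] = []
        for lab in self.categorical.values():
            if lab not in seen:
                seen.append(lab)
        return tuple(seen)


def whitefly_pooling(
    taxonomy: Sequence[str] = DEFAULT_TAXONOMY, temporal: bool = False
) -> PoolingScheme:
    """The standard categorical scheme: BEMITA and TRIAVA -> BEM-TRI."""
    mapping = {
        lab: POOLED_WHITEFLY_LABEL if lab in ("BEMITA", "TRIAVA") else lab
        for lab in taxonomy
    }
    return PoolingScheme(temporal=temporal, categorical=mapping)


# ---------------------------------------------------------------------------
# Marker-table I/O
# ---------------------------------------------------------------------------

def empty_marker_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "image_id": pd.Series(dtype=str),
            "x": pd.Series(dtype=int),
            "y": pd.Series(dtype=int),
            "label": pd.Series(dtype=str),
            "dataset_tag": pd.Series(dtype=str),
        }
    )


def read_markers(
    path,
    taxonomy: Sequence[str] | None = DEFAULT_TAXONOMY,
    image_shape: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Read a tab-delimited marker table.

    The format is UTF-8 text with a header row ``image_id\tx\ty\tlabel\t
    dataset_tag`` and one marker per line.  ``taxonomy`` restricts admissible
    labels (pass ``None`` to accept any label); ``image_shape`` as
    ``(height, width)`` additionally validates that markers fall inside the
    referenced image.

    Raises :class:`MarkerParseError` with the offending line number on
    malformed rows and :class:`MarkerValidationError` on unknown labels or
    out-of-bounds coordinates.
    """
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header.split("\t") != list(MARKER_COLUMNS):
            raise MarkerParseError(f"{path}: line 1: bad header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(MARKER_COLUMNS):
                raise MarkerParseError(
                    f"{path}: line {lineno}: expected {len(MARKER_COLUMNS)} "
                    f"fields, got {len(parts)}"
                )
            image_id, xs, ys, label, tag = parts
            try:
                x, y = int(xs), int(ys)
            except ValueError as exc:
                raise MarkerParseError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            if taxonomy is not None and label not in taxonomy:
                raise MarkerValidationError(
                    f"{path}: line {lineno}: label {label!r} not in taxonomy "
                    f"{tuple(taxonomy)}"
                )
            if image_shape is not None:
                h, w = image_shape
                if not (0 <= x < w and 0 <= y < h):
                    raise MarkerValidationError(
                        f"{path}: line {lineno}: marker ({x}, {y}) outside "
                        f"image of size {w}x{h}"
                    )
            rows.append((image_id, x, y, label, tag))
    if not rows:
        return empty_marker_table()
    return pd.DataFrame(rows, columns=list(MARKER_COLUMNS))


def write_markers(table: pd.DataFrame, path) -> None:
    """Write a marker table as tab-delimited UTF-8 text with a header row."""
    out = table.loc[:, list(MARKER_COLUMNS)] if len(table) else empty_marker_table()
    out.to_csv(path, sep="\t", index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# Cropping
# ---------------------------------------------------------------------------

def crop_subimages(
    image: np.ndarray,
    markers: pd.DataFrame,
    size: int = PATCH_SIZE,
    edge_policy: str = "reflect",
) -> list[SubImageRecord]:
    """Crop one ``size x size`` patch around each marker.

    ``size`` must be odd so the marker is the centre pixel: for an interior
    marker at ``(x, y)``, ``patch[i, j] == image[y - size//2 + i,
    x - size//2 + j]``.

    Markers within ``size // 2`` px of a border are handled per
    ``edge_policy``:

    ``"reflect"`` (default)
        The image is reflect-padded, preserving the dataset count.
    ``"skip"``
        The marker is dropped and a warning is logged.
    """
    if size % 2 == 0:
        raise ValueError(f"patch size must be odd, got {size}")
    if edge_policy not in ("reflect", "skip"):
        raise ValueError(f"unknown edge_policy {edge_policy!r}")
    half = size // 2
    h, w = image.shape[:2]
    records: list[SubImageRecord] = []
    padded = None
    for row in markers.itertuples(index=False):
        x, y = int(row.x), int(row.y)
        if not (0 <= x < w and 0 <= y < h):
            raise MarkerValidationError(
                f"marker ({x}, {y}) outside image of size {w}x{h}"
            )
        interior = half <= x < w - half and half <= y < h - half
        if interior:
            patch = image[y - half : y + half + 1, x - half : x + half + 1].copy()
        elif edge_policy == "skip":
            logger.warning(
                "skipping border marker (%d, %d) on image %s", x, y, row.image_id
            )
            continue
        else:
            if padded is None:
                pad = [(half, half), (half, half)] + [(0, 0)] * (image.ndim - 2)
                padded = np.pad(image, pad, mode="reflect")
            patch = padded[y : y + size, x : x + size].copy()
        records.append(
            SubImageRecord(
                patch=patch,
                label=row.label,
                source=(row.image_id, x, y),
                dataset_tag=row.dataset_tag,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Splitting and pooling
# ---------------------------------------------------------------------------

def split_train_opt(
    records: Sequence[SubImageRecord],
    fraction: float = 0.75,
    rng_seed: int = 0,
) -> tuple[list[SubImageRecord], list[SubImageRecord]]:
    """Stratified random split into a model-fitting and an optimization set.

    Per class, ``floor(n * fraction)`` records (at least 1, and at least one
    held out when ``n >= 2``) go to the fitting set.  Classes with fewer than
    two records stay whole in the fitting set and a warning is logged.  The
    split is deterministic for a fixed ``rng_seed``.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(rng_seed)
    by_class: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        by_class.setdefault(rec.label, []).append(i)
    fit_idx: list[int] = []
    opt_idx: list[int] = []
    for label in sorted(by_class):
        idx = np.asarray(by_class[label])
        n = len(idx)
        if n < 2:
            logger.warning(
                "class %s has %d record(s); kept whole in the fitting set",
                label,
                n,
            )
            fit_idx.extend(idx.tolist())
            continue
        n_fit = min(max(int(np.floor(n * fraction)), 1), n - 1)
        perm = rng.permutation(n)
        fit_idx.extend(idx[perm[:n_fit]].tolist())
        opt_idx.extend(idx[perm[n_fit:]].tolist())
    fit_idx.sort()
    opt_idx.sort()
    return [records[i] for i in fit_idx], [records[i] for i in opt_idx]


def apply_pooling(
    records: Iterable[SubImageRecord] | Sequence[str],
    scheme: PoolingScheme,
) -> list:
    """Relabel records (or a plain label sequence) under a pooling scheme.

    Record count is always preserved; only labels and dataset tags change.
    """
    items = list(records)
    if items and isinstance(items[0], str):
        return [scheme.map_label(lab) for lab in items]
    out = []
    for rec in items:
        out.append(
            replace(
                rec,
                label=scheme.map_label(rec.label),
                dataset_tag=scheme.map_tag(rec.dataset_tag),
            )
        )
    return out
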