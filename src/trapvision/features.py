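"""Colour-space conversion and SIFT local-descriptor extraction.

Sub-images enter the pipeline as 8-bit RGB.  Models can be trained on
greyscale, RGB or HSV versions of the patches; SIFT itself is defined on a
scalar image, so multi-channel inputs are handled by running the detector
independently per channel and pooling the resulting descriptors into one
set, each tagged with its source channel.  Keypoints need not co-occur
across channels, which is why descriptors are pooled rather than
concatenated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2hsv
from skimage.feature import SIFT

logger = logging.getLogger(__name__)

#: ITU-R BT.601 luma weights used for greyscale conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

COLOUR_SPACES = ("greyscale", "RGB", "HSV")


@dataclass(frozen=True)
class SiftParams:
    """Detector/descriptor settings.

    ``peak_threshold`` is the difference-of-Gaussians contrast threshold
    (lower finds more, weaker blobs); ``edge_threshold`` rejects elongated
    responses.  ``upsampling`` of 1 skips the initial 2x image upsampling --
    the default here, since 201-px patches already resolve the relevant
    blobs and upsampling quadruples the cost.  With ``low_contrast_fallback``
    a patch yielding zero keypoints is retried once at a tenth of the peak
    threshold; patches that still yield nothing produce an empty set (their
    bag-of-words vector is all zero).
    """

    peak_threshold: float = 0.004
    edge_threshold: float = 10.0
    upsampling: int = 1
    n_octaves: int = 8
    low_contrast_fallback: bool = True


@dataclass(frozen=True)
class DescriptorSet:
    """SIFT descriptors plus keypoint geometry from one image.

    ``descriptors`` is an ``n x 128`` float array of non-negative gradient
    orientation histograms; ``keypoints`` holds one ``(x, y, scale,
    orientation)`` row per descriptor; ``channel_ids`` tags the source
    channel (0 for scalar images).
    """

    descriptors: np.ndarray
    keypoints: np.ndarray
    channel_ids: np.ndarray
    source_space: str = "greyscale"

    def __post_init__(self) -> None:
        if self.descriptors.ndim != 2 or self.descriptors.shape[1] != 128:
            raise ValueError(
                f"descriptors must be n x 128, got {self.descriptors.shape}"
            )

    def __len__(self) -> int:
        return self.descriptors.shape[0]

    @staticmethod
    def empty(source_space: str = "greyscale") -> "DescriptorSet":
        return DescriptorSet(
            descriptors=np.empty((0, 128)),
            keypoints=np.empty((0, 4)),
            channel_ids=np.empty((0,), dtype=int),
            source_space=source_space,
        )


def convert_colour(image: np.ndarray, space: str) -> np.ndarray:
    """Convert an 8-bit RGB image to the requested working colour space.

    ``greyscale`` applies the BT.601 luma weights and rounds to 8 bit,
    returning a single-channel image; ``RGB`` is the identity; ``HSV`` maps
    hue, saturation and value each onto [0, 255].
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an RGB image, got shape {image.shape}")
    if image.dtype != np.uint8:
        raise ValueError(f"expected 8-bit input, got dtype {image.dtype}")
    if space == "RGB":
        return image.copy()
    if space == "greyscale":
        w = np.asarray(LUMA_WEIGHTS)
        return np.clip(np.round(image.astype(float) @ w), 0, 255).astype(np.uint8)
    if space == "HSV":
        hsv = rgb2hsv(image)
        return np.clip(np.round(hsv * 255.0), 0, 255).astype(np.uint8)
    raise ValueError(f"unknown colour space {space!r}; choose from {COLOUR_SPACES}")


def _sift_single_channel(channel: np.ndarray, params: SiftParams):
    """Run SIFT on one scalar channel; returns (descriptors, keypoints)."""
    img = channel.astype(float) / 255.0
    for peak in ([params.peak_threshold, params.peak_threshold / 10.0]
                 if params.low_contrast_fallback else [params.peak_threshold]):
        det = SIFT(
            upsampling=params.upsampling,
            n_octaves=params.n_octaves,
            c_dog=peak,
            c_edge=params.edge_threshold,
        )
        try:
            det.detect_and_extract(img)
        except RuntimeError:
            continue
        if len(det.keypoints):
            kp = np.column_stack(
                [
                    det.keypoints[:, 1].astype(float),  # x = column
                    det.keypoints[:, 0].astype(float),  # y = row
                    det.scales.astype(float),
                    det.orientations.astype(float),
                ]
            )
            return det.descriptors.astype(float), kp
    return np.empty((0, 128)), np.empty((0, 4))


def extract_descriptors(
    image: np.ndarray,
    params: SiftParams | None = None,
    source_space: str = "greyscale",
) -> DescriptorSet:
    """Extract SIFT descriptors from a scalar or multi-channel image.

    Multi-channel images are processed per channel and the descriptors are
    pooled; an empty set is a valid result for low-contrast patches.
    """
    params = params or SiftParams()
    if image.ndim == 2:
        channels = [image]
    elif image.ndim == 3:
        channels = [image[..., c] for c in range(image.shape[2])]
    else:
        raise ValueError(f"unsupported image shape {image.shape}")
    desc_parts, kp_parts, chan_parts = [], [], []
    for c, channel in enumerate(channels):
        d, k = _sift_single_channel(channel, params)
        if len(d):
            desc_parts.append(d)
            kp_parts.append(k)
            chan_parts.append(np.full(len(d), c, dtype=int))
    if not desc_parts:
        return DescriptorSet.empty(source_space)
    return DescriptorSet(
        descriptors=np.vstack(desc_parts),
        keypoints=np.vstack(kp_parts),
        channel_ids=np.concatenate(chan_parts),
        source_space=source_space,
    )
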