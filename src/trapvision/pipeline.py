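"""The shared patch-classification path used everywhere a patch is scored.

Training, held-out evaluation and sliding-window scene scanning must all
push a patch through the *identical* sequence — colour conversion, SIFT
extraction, quantization against the dictionary, BoVW encoding, linear-SVM
scoring — or window predictions would not reproduce patch-level
predictions.  :class:`BovwPipeline` bundles that sequence with its fitted
artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifier import LinearSvmModel, PredictionResult, predict_label
from .features import SiftParams, convert_colour, extract_descriptors
from .vocabulary import (
    BoVWVector,
    VisualDictionary,
    encode_bovw,
    quantize_kdtree,
    quantize_vq,
)


@dataclass(frozen=True)
class BovwPipeline:
    """Colour space + SIFT + dictionary + quantizer + normalization (+ SVM)."""

    dictionary: VisualDictionary
    colour_space: str = "greyscale"
    quantizer: str = "kdtree"
    normalization: str = "hellinger"
    sift_params: SiftParams = SiftParams()
    kdtree_max_comparisons: int | None = None
    model: LinearSvmModel | None = None

    def __post_init__(self) -> None:
        if self.quantizer not in ("vq", "kdtree"):
            raise ValueError(f"unknown quantizer {self.quantizer!r}")

    def descriptors(self, patch_rgb: np.ndarray):
        converted = convert_colour(patch_rgb, self.colour_space)
        return extract_descriptors(
            converted, self.sift_params, source_space=self.colour_space
        )

    def quantize(self, descriptor_set) -> np.ndarray:
        if self.quantizer == "vq":
            return quantize_vq(descriptor_set, self.dictionary)
        return quantize_kdtree(
            descriptor_set, self.dictionary, max_comparisons=self.kdtree_max_comparisons
        )

    def encode(self, patch_rgb: np.ndarray) -> BoVWVector:
        """8-bit RGB patch -> BoVW frequency vector."""
        descriptor_set = self.descriptors(patch_rgb)
        assignments = self.quantize(descriptor_set)
        return encode_bovw(assignments, self.dictionary.vocsize, self.normalization)

    def predict(self, patch_rgb: np.ndarray) -> PredictionResult:
        """8-bit RGB patch -> (label, per-class scores, low-confidence flag)."""
        if self.model is None:
            raise ValueError("pipeline has no trained model attached")
        return predict_label(self.model, self.encode(patch_rgb))

    def with_model(self, model: LinearSvmModel) -> "BovwPipeline":
        from dataclasses import replace

        return replace(self, model=model)
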