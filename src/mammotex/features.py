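"""ROI -> feature-vector stage: per-orientation code histograms.

For each orientation theta in a descriptor's orientation set, the code
image of the ROI is histogrammed over its valid interior pixels and the
block is L1-normalised; blocks are concatenated in ascending-theta order.
LBP and LDP are single-orientation, so their vectors are one block long
(256 bins); the elliptical families default to eight orientations
(8 x 256 = 2048 values, or 8 x 59 for the uniform mapping).

Normalising each block to unit mass makes feature vectors comparable
across ROI sizes, which matters when sweeping the ROI side length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .descriptors import DescriptorConfig, code_image, uniform_bin_map

__all__ = [
    "FeatureVector",
    "descriptor_histogram",
    "extract_features",
    "feature_names",
    "extract_feature_matrix",
    "features_frame",
    "save_features",
    "load_features",
    "frame_to_xy",
]


@dataclass
class FeatureVector:
    """Concatenated per-orientation L1-normalised histograms for one ROI."""

    values: np.ndarray
    family: str
    orientations: tuple[float, ...]
    bins_per_orientation: int

    def __post_init__(self) -> None:
        expected = len(self.orientations) * self.bins_per_orientation
        if self.values.shape != (expected,):
            raise ValueError("feature length inconsistent with layout")

    def __len__(self) -> int:
        return self.values.shape[0]


def descriptor_histogram(
    roi: np.ndarray, cfg: DescriptorConfig, theta: float = 0.0
) -> np.ndarray:
    """L1-normalised code histogram of one ROI at one orientation."""
    ci = code_image(roi, cfg, theta)
    codes = ci.valid_codes()
    if cfg.family == "uelbp":
        codes = uniform_bin_map(cfg.p)[codes]
    h = np.bincount(codes, minlength=cfg.n_bins).astype(float)
    return h / h.sum()


def extract_features(roi: np.ndarray, cfg: DescriptorConfig) -> FeatureVector:
    """Concatenate histograms over the descriptor's orientation set."""
    thetas = cfg.orientation_set
    blocks = [descriptor_histogram(roi, cfg, t) for t in thetas]
    return FeatureVector(
        values=np.concatenate(blocks),
        family=cfg.family,
        orientations=thetas,
        bins_per_orientation=cfg.n_bins,
    )


def feature_names(cfg: DescriptorConfig) -> list[str]:
    """Stable column labels: ``t{theta}_b{bin}`` in (orientation, bin) order."""
    return [
        f"t{int(round(t)):03d}_b{b:04d}"
        for t in cfg.orientation_set
        for b in range(cfg.n_bins)
    ]


def extract_feature_matrix(
    rois: Sequence[np.ndarray], cfg: DescriptorConfig
) -> np.ndarray:
    """Stack feature vectors of several ROIs into an (n, d) matrix."""
    return np.stack([extract_features(r, cfg).values for r in rois])


def features_frame(
    ids: Sequence[str],
    labels: Sequence[str],
    rois: Sequence[np.ndarray],
    cfg: DescriptorConfig,
) -> pd.DataFrame:
    """Feature table: index = image_id, 'class' column, then features."""
    X = extract_feature_matrix(rois, cfg)
    df = pd.DataFrame(X, index=pd.Index(ids, name="image_id"), columns=feature_names(cfg))
    df.insert(0, "class", list(labels))
    return df


def save_features(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, float_format="%.12g")


def load_features(path: str) -> pd.DataFrame:
    return pd.read_csv(path, index_col="image_id")


def frame_to_xy(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Split a feature table into (X, y)."""
    y = df["class"].to_numpy(dtype=str)
    X = df.drop(columns="class").to_numpy(dtype=float)
    return X, y
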