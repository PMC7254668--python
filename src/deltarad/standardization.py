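"""Landmark-based MRI histogram standardization.

MRI signal intensities have no physical unit and drift between scans, so
intensity-based radiomics features are only comparable after the histograms
are harmonized.  This module implements the classic two-stage landmark
method: a *standard scale* is learned by averaging percentile landmarks of
the training volumes mapped to a fixed range, and each volume is then
transformed by the monotone piecewise-linear map that sends its own
landmarks onto the standard ones.

Defaults: decile landmarks between the 1st and 99th percentile, standard
scale [0, 4095], foreground defined by Otsu thresholding of the
pre-contrast phase (the map is learned on foreground voxels so air/fat does
not dominate the histogram).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu


@dataclass
class StandardizationConfig:
    """Landmark percentiles and the target standard scale."""

    lower_percentile: float = 1.0
    upper_percentile: float = 99.0
    n_landmarks: int = 9            #: interior landmarks (deciles by default)
    standard_range: tuple[float, float] = (0.0, 4095.0)

    @property
    def percentiles(self) -> np.ndarray:
        """All landmark percentiles, endpoints included."""
        inner = np.linspace(
            self.lower_percentile, self.upper_percentile, self.n_landmarks + 2
        )[1:-1]
        return np.concatenate(
            [[self.lower_percentile], inner, [self.upper_percentile]]
        )


@dataclass
class StandardizationMap:
    """Learned standard-scale landmarks plus the percentiles defining them."""

    percentiles: np.ndarray
    standard_landmarks: np.ndarray
    standard_range: tuple[float, float]

    def __post_init__(self) -> None:
        self.percentiles = np.asarray(self.percentiles, dtype=float)
        self.standard_landmarks = np.asarray(self.standard_landmarks, dtype=float)
        if np.any(np.diff(self.standard_landmarks) <= 0):
            raise ValueError("standard landmarks must be strictly increasing")

    def to_json(self) -> str:
        return json.dumps(
            {
                "percentiles": self.percentiles.tolist(),
                "standard_landmarks": self.standard_landmarks.tolist(),
                "standard_range": list(self.standard_range),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "StandardizationMap":
        d = json.loads(text)
        return cls(
            percentiles=np.array(d["percentiles"]),
            standard_landmarks=np.array(d["standard_landmarks"]),
            standard_range=tuple(d["standard_range"]),
        )


def otsu_foreground(volume: np.ndarray) -> np.ndarray:
    """Foreground voxels: intensities above the Otsu threshold."""
    v = np.asarray(volume)
    if v.max() == v.min():
        raise ValueError("constant volume: histogram is degenerate")
    return v > threshold_otsu(v)


def _volume_landmarks(
    volume: np.ndarray,
    percentiles: np.ndarray,
    foreground: np.ndarray | None,
) -> np.ndarray:
    v = np.asarray(volume, dtype=float)
    if foreground is not None:
        v = v[foreground]
    v = v.ravel()
    if v.size == 0:
        raise ValueError("empty foreground")
    lm = np.percentile(v, percentiles)
    if lm[-1] - lm[0] <= 0:
        raise ValueError("constant volume: histogram is degenerate")
    # enforce strict monotonicity in flat histogram stretches
    eps = 1e-9 * (lm[-1] - lm[0])
    for i in range(1, len(lm)):
        if lm[i] <= lm[i - 1]:
            lm[i] = lm[i - 1] + eps
    return lm


def learn_standard_scale(
    volumes,
    config: StandardizationConfig | None = None,
    foregrounds=None,
) -> StandardizationMap:
    """Learn standard-scale landmarks from a collection of training volumes.

    Each volume's landmark intensities are mapped affinely onto the
    standard range (by its own 1st/99th percentile) and the mapped
    positions are averaged across volumes.

    Parameters
    ----------
    volumes : iterable of ndarray
    foregrounds : iterable of boolean ndarray, optional
        Foreground mask per volume; defaults to Otsu thresholding.
    """
    config = config or StandardizationConfig()
    volumes = list(volumes)
    if not volumes:
        raise ValueError("need at least one training volume")
    if foregrounds is None:
        foregrounds = [otsu_foreground(v) for v in volumes]
    lo, hi = config.standard_range
    mapped = []
    for vol, fg in zip(volumes, foregrounds):
        lm = _volume_landmarks(vol, config.percentiles, fg)
        mapped.append(lo + (lm - lm[0]) / (lm[-1] - lm[0]) * (hi - lo))
    standard = np.mean(mapped, axis=0)
    return StandardizationMap(
        percentiles=config.percentiles,
        standard_landmarks=standard,
        standard_range=config.standard_range,
    )


def apply_standardization(
    volume: np.ndarray,
    smap: StandardizationMap,
    foreground: np.ndarray | None = None,
) -> np.ndarray:
    """Apply the monotone piecewise-linear landmark transform to a volume.

    The volume's own landmark intensities (computed on its foreground) are
    mapped exactly onto the standard landmarks; intensities between
    landmarks are interpolated linearly and values outside the landmark
    range are clamped to the standard range.
    """
    if foreground is None:
        foreground = otsu_foreground(volume)
    lm = _volume_landmarks(volume, smap.percentiles, foreground)
    v = np.asarray(volume, dtype=float)
    out = np.interp(v, lm, smap.standard_landmarks)
    return np.clip(out, *smap.standard_range)
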