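"""Core data containers shared by every pipeline stage.

A dynamic contrast-enhanced (DCE) breast-MRI exam is a co-registered stack of
four T1-weighted volumes: one pre-contrast acquisition followed by three
post-contrast acquisitions.  One exam exists per treatment timing: ``bef``
(before neoadjuvant chemotherapy) and ``af`` (after).  Arrays are indexed
``(x, y, z)`` with the axial plane spanned by the first two axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical phase names in acquisition order; index 0 is pre-contrast.
PHASE_NAMES: tuple[str, ...] = ("pre", "post1", "post2", "post3")

#: Exam timings: before / after neoadjuvant chemotherapy.
TIMING_BEFORE = "bef"
TIMING_AFTER = "af"
TIMINGS = (TIMING_BEFORE, TIMING_AFTER)

#: Molecular subtype levels (hormone receptor / HER2 status).
SUBTYPES = ("HR+HER2-", "HR+HER2+", "HR-HER2+", "TN")

#: Response labels.  pCR = pathologic complete response.
LABEL_PCR = "pCR"
LABEL_NO_PCR = "no-pCR"
LABELS = (LABEL_PCR, LABEL_NO_PCR)


@dataclass
class DCESeries:
    """One exam's four co-registered phase volumes plus geometry metadata.

    Parameters
    ----------
    phases : ndarray, shape (4, nx, ny, nz)
        Stacked phase volumes in acquisition order (pre, post1, post2, post3).
    spacing : tuple of float
        Voxel spacing in millimetres per axis.
    exam_timing : {"bef", "af"}
        Whether the exam was acquired before or after chemotherapy.
    """

    phases: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    exam_timing: str = TIMING_BEFORE

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases)
        if self.phases.ndim != 4 or self.phases.shape[0] != 4:
            raise ValueError(
                f"expected 4 stacked phase volumes, got array of shape "
                f"{self.phases.shape}"
            )
        if self.exam_timing not in TIMINGS:
            raise ValueError(f"exam_timing must be one of {TIMINGS}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths (mm)")

    @property
    def shape(self) -> tuple[int, int, int]:
        """Spatial shape shared by the four phases."""
        return self.phases.shape[1:]

    def phase(self, index_or_name) -> np.ndarray:
        """Return a single phase volume by index or canonical name."""
        if isinstance(index_or_name, str):
            index_or_name = PHASE_NAMES.index(index_or_name)
        return self.phases[index_or_name]


@dataclass
class TumorMask:
    """Binary tumor mask aligned to a :class:`DCESeries`.

    ``provenance`` records how the mask arose: a radiologist-style single
    slice ``seed``, an automatically ``grown`` volume, a manually
    ``corrected`` volume, or simulation ground ``truth``.
    """

    mask: np.ndarray
    provenance: str = "seed"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be a 3-D volume")
        if self.provenance not in ("seed", "grown", "corrected", "truth"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def bounding_box(self) -> tuple[slice, slice, slice]:
        """Tight bounding box of the mask as a tuple of slices."""
        if not self.mask.any():
            raise ValueError("mask is empty")
        coords = np.nonzero(self.mask)
        return tuple(
            slice(int(c.min()), int(c.max()) + 1) for c in coords
        )


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap coefficient between two binary volumes."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
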