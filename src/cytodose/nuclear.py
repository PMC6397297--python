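"""Nucleus-referenced intensity statistics.

Implements the nuclear-to-cytosolic ratio of a stained protein (mean stain
intensity in the nucleus divided by that in an equal-area cytosolic
annulus immediately adjacent to it), the mean stain intensity colocalized
to previously segmented fibres, and planar nuclear size/shape descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .morphometrics import _ellipse_axes


@dataclass
class AnnulusSpec:
    """Nucleus mask plus an equal-size adjacent cytosolic annulus."""

    nucleus_mask: np.ndarray
    annulus_mask: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.nucleus_mask & self.annulus_mask):
            raise ValueError("annulus overlaps the nucleus")
        if abs(int(self.annulus_mask.sum()) - int(self.nucleus_mask.sum())) > 1:
            raise ValueError("annulus and nucleus pixel counts differ by >1")


def build_annulus(nucleus_mask: np.ndarray, cell_mask: np.ndarray
                  ) -> AnnulusSpec:
    """Grow an equal-area cytosolic annulus around the nucleus.

    The nucleus is dilated ring by ring (1-px 8-connected dilations); new
    pixels inside the cell and outside the nucleus are collected until
    their count reaches the nucleus pixel count, and the final ring is
    truncated deterministically in row-major order to make the counts
    equal.  Raises ``ValueError`` if the cell cannot host an equal-area
    annulus.
    """
    n_target = int(nucleus_mask.sum())
    if n_target == 0:
        raise ValueError("empty nucleus mask")
    if np.any(nucleus_mask & ~cell_mask):
        raise ValueError("nucleus extends outside the cell")
    available = cell_mask & ~nucleus_mask
    if int(available.sum()) < n_target:
        raise ValueError(
            f"cell too small for an equal-area annulus "
            f"({int(available.sum())} < {n_target} px available)")

    structure = np.ones((3, 3), dtype=bool)
    annulus = np.zeros_like(nucleus_mask, dtype=bool)
    grown = nucleus_mask.copy()
    collected = 0
    while collected < n_target:
        dilated = ndimage.binary_dilation(grown, structure=structure)
        ring = dilated & available & ~annulus
        n_ring = int(ring.sum())
        if n_ring == 0:
            raise ValueError("annulus growth stalled before reaching "
                             "the nucleus pixel count")
        if collected + n_ring > n_target:
            need = n_target - collected
            rr, cc = np.nonzero(ring)  # row-major order
            ring = np.zeros_like(ring)
            ring[rr[:need], cc[:need]] = True
            n_ring = need
        annulus |= ring
        collected += n_ring
        grown = dilated
    return AnnulusSpec(nucleus_mask=nucleus_mask, annulus_mask=annulus)


def nuc_cyto_ratio(stain: np.ndarray, spec: AnnulusSpec) -> float:
    """Mean nuclear stain intensity over mean annulus intensity."""
    if not spec.nucleus_mask.any() or not spec.annulus_mask.any():
        raise ValueError("empty nucleus or annulus mask")
    cyto = float(stain[spec.annulus_mask].mean())
    if cyto == 0:
        raise ValueError("degenerate cytosolic signal (zero annulus mean)")
    return float(stain[spec.nucleus_mask].mean()) / cyto


def fibre_colocalized_intensity(stain: np.ndarray, fibre_mask: np.ndarray,
                                background: Optional[float] = None,
                                cell_mask: Optional[np.ndarray] = None
                                ) -> float:
    """Mean background-subtracted stain intensity on fibre pixels.

    Quantifies how strongly a protein decorates previously segmented
    fibres.  ``background`` defaults to the median stain intensity outside
    ``cell_mask`` (or outside ``fibre_mask`` if no cell mask is given).
    Returns NaN (missing, not zero) for an empty fibre mask.
    """
    if not fibre_mask.any():
        return float("nan")
    if background is None:
        outside = ~cell_mask if cell_mask is not None else ~fibre_mask
        vals = stain[outside]
        background = float(np.median(vals)) if vals.size else 0.0
    return float(np.mean(stain[fibre_mask] - background))


def nucleus_descriptors(dapi: np.ndarray, nucleus_mask: np.ndarray,
                        pixel_size: float) -> dict:
    """Planar nuclear size and shape: projected area (um^2) and the
    best-fit-ellipse axes (um)."""
    if not nucleus_mask.any():
        raise ValueError("empty nucleus mask")
    major, minor = _ellipse_axes(nucleus_mask)
    return {
        "nucleus_area": float(nucleus_mask.sum()) * pixel_size ** 2,
        "nucleus_major_axis": major * pixel_size,
        "nucleus_minor_axis": minor * pixel_size,
    }
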