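"""Slide-level quality control and patient-level score aggregation.

Whole-slide images are tiled into non-overlapping 256 x 256 px tiles at a
resolution of 0.5 microns per pixel, so each tile covers a 128 um square
and 100 tiles correspond to about 1.63 mm^2 of tissue. Slides with fewer
than 100 tissue tiles are excluded; a patient's score is the arithmetic
mean of the image scores of their retained slides.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._common import ConfigError, DataError

__all__ = [
    "TileGeometry",
    "tissue_area_mm2",
    "format_area_mm2",
    "apply_slide_qc",
    "aggregate_patient_scores",
    "MIN_TILES_DEFAULT",
]

logger = logging.getLogger(__name__)

#: Minimum tissue tiles per slide; slides below this are excluded.
MIN_TILES_DEFAULT = 100


@dataclass(frozen=True)
class TileGeometry:
    """Physical tile geometry: edge length in pixels and microns per pixel."""

    tile_px: int = 256
    mpp: float = 0.5

    def __post_init__(self) -> None:
        if not (self.tile_px > 0 and self.mpp > 0):
            raise ConfigError("tile_px and mpp must both be strictly positive")


def tissue_area_mm2(n_tiles: int, geom: TileGeometry = TileGeometry()) -> float:
    """Tissue area in mm^2 covered by ``n_tiles`` tiles.

    Each tile spans ``tile_px * mpp`` microns per edge, so the area is
    ``n_tiles * (tile_px * mpp / 1000) ** 2`` mm^2. 100 default tiles give
    1.6384 mm^2.
    """
    if n_tiles < 0:
        raise DataError(f"n_tiles must be non-negative, got {n_tiles}")
    edge_mm = geom.tile_px * geom.mpp / 1000.0
    return n_tiles * edge_mm * edge_mm


def format_area_mm2(area: float, decimals: int = 2) -> str:
    """Format an area truncating (not rounding) to ``decimals`` places,
    the convention used when quoting the 100-tile bound as 1.63 mm^2."""
    scale = 10 ** decimals
    return f"{math.floor(area * scale) / scale:.{decimals}f}"


def apply_slide_qc(slides: pd.DataFrame,
                   min_tiles: int = MIN_TILES_DEFAULT
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition slides into (included, excluded) by the strict
    ``n_tissue_tiles < min_tiles`` exclusion rule."""
    if "n_tissue_tiles" not in slides.columns:
        raise DataError("slides table needs an 'n_tissue_tiles' column")
    fail = slides["n_tissue_tiles"] < min_tiles
    return slides.loc[~fail].copy(), slides.loc[fail].copy()


def aggregate_patient_scores(slides: pd.DataFrame,
                             all_patient_ids=None) -> pd.Series:
    """Patient-level scores: the arithmetic mean of each patient's slide
    ``image_score`` values.

    When ``all_patient_ids`` is given, patients with no post-QC slide are
    reported as missing (NaN) — never as zero — and a warning is logged.
    """
    needed = {"patient_id", "image_score"}
    if not needed <= set(slides.columns):
        raise DataError(f"slides table needs columns {sorted(needed)}")
    scores = slides.groupby("patient_id")["image_score"].mean()
    scores.name = "patient_score"
    if all_patient_ids is not None:
        scores = scores.reindex(pd.Index(all_patient_ids, name="patient_id"))
        n_missing = int(scores.isna().sum())
        if n_missing:
            logger.warning("%d patient(s) lost all slides to QC and are "
                           "reported as missing", n_missing)
    return scores
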