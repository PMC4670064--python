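"""Invasion-stage classification from paired regional and global predictions.

Comparing a regional model (trained on invaded-range occurrences only)
with a global model (native + invaded occurrences) places each occurrence
or map cell in one of four quadrants of the (p_regional, p_global) plane:

* stabilizing — both models predict high suitability (quasi-equilibrium);
* colonization — regional low but global high (suitable climate the
  regional population has not yet equilibrated into);
* adaptation — regional high but global low (persistence beyond the
  species-wide envelope, suggesting local adaptation);
* sink — both low (occurrences likely not self-sustaining).

"High" means probability >= tau (default 0.5; configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import RasterGrid

STAGES = ("stabilizing", "colonization", "adaptation", "sink")
STAGE_CODES = {"stabilizing": 1, "colonization": 2, "adaptation": 3, "sink": 4}


def classify_stage(p_regional, p_global, tau: float = 0.5):
    """Quadrant classification; scalar in -> str out, arrays in -> str array."""
    pr = np.asarray(p_regional, dtype=float)
    pg = np.asarray(p_global, dtype=float)
    if np.any((pr < 0) | (pr > 1) | (pg < 0) | (pg > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    hi_r = pr >= tau
    hi_g = pg >= tau
    out = np.where(hi_r & hi_g, "stabilizing",
          np.where(~hi_r & hi_g, "colonization",
          np.where(hi_r & ~hi_g, "adaptation", "sink")))
    if out.ndim == 0:
        return str(out)
    return out


@dataclass
class StageRaster:
    """Cellwise stage map (integer-coded) with category counts and legend."""

    raster: RasterGrid              # codes 1..4, nan on nodata
    counts: dict[str, int]
    tau: float
    legend: dict[str, int]


def classify_stage_raster(regional: RasterGrid, global_: RasterGrid,
                          tau: float = 0.5) -> StageRaster:
    """Cellwise quadrant classification of two aligned prediction rasters."""
    if not regional.same_frame(global_):
        raise ValueError("regional and global rasters are on different grids")
    mask = regional.nodata_mask | global_.nodata_mask
    pr = regional.values[~mask]
    pg = global_.values[~mask]
    stages = classify_stage(pr, pg, tau=tau)
    codes = np.full(regional.shape, np.nan)
    codes[~mask] = np.vectorize(STAGE_CODES.get)(stages)
    counts = {s: int(np.sum(stages == s)) for s in STAGES}
    return StageRaster(
        raster=regional.copy_with(codes, mask.copy()),
        counts=counts, tau=tau, legend=dict(STAGE_CODES),
    )
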