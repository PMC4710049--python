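"""CellProfiler-style image quantification.

Segments nuclei by a global two-class Otsu threshold, defines cell territories
by a fixed Euclidean expansion from the nucleus border (20 px by default),
detects rolling-circle-amplification spots by white top-hat filtering followed
by a manual intensity threshold, and assigns each spot to the cell it falls in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import disk, white_tophat

from .errors import ParameterError, SpotBoundsError

logger = logging.getLogger(__name__)

#: Sentinel for spots that fall outside every cell territory.
UNASSIGNED = -1

SPOT_COLUMNS = ["row", "col", "gene", "cell_id"]


@dataclass
class CellMap:
    """Paired nucleus / expanded-cell label images sharing one label space."""

    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    expansion_distance: float

    @property
    def labels(self) -> np.ndarray:
        """Sorted nonzero labels present in the map."""
        labs = np.unique(self.nucleus_labels)
        return labs[labs > 0]


def empty_spot_table() -> pd.DataFrame:
    return pd.DataFrame({"row": pd.Series(dtype=int), "col": pd.Series(dtype=int),
                         "gene": pd.Series(dtype=object), "cell_id": pd.Series(dtype=int)})


def segment_nuclei(
    image: np.ndarray, min_area: float = 20.0, log_otsu: bool = False
) -> np.ndarray:
    """Segment nuclei by global Otsu thresholding.

    Connected components (8-connectivity) of the above-threshold mask with at
    least ``min_area`` pixels become labels 1..K in raster order of their first
    pixel. ``log_otsu`` applies the threshold in log intensity space instead
    of on raw intensities. A constant image yields zero nuclei with a warning.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ParameterError("nuclei image must be a non-empty 2-D array")
    if not np.isfinite(image).all():
        raise ParameterError("nuclei image contains non-finite values")
    if np.ptp(image) == 0:
        logger.warning("constant nuclei image: no threshold exists, returning zero nuclei")
        return np.zeros(image.shape, dtype=np.int32)
    if log_otsu:
        shifted = image - image.min() + 1.0
        thr = np.exp(threshold_otsu(np.log(shifted)))
        mask = shifted > thr
    else:
        mask = image > threshold_otsu(image)
    labels = cc_label(mask, connectivity=2)
    if labels.max() == 0:
        return labels.astype(np.int32)
    areas = np.bincount(labels.ravel())
    keep = np.nonzero(areas >= min_area)[0]
    keep = keep[keep > 0]
    # skimage labels components in raster order of first pixel, so compressing
    # the kept ids in ascending order preserves that ordering
    remap = np.zeros(labels.max() + 1, dtype=np.int32)
    remap[keep] = np.arange(1, len(keep) + 1, dtype=np.int32)
    return remap[labels]


def expand_cells(nucleus_labels: np.ndarray, distance: float = 20.0) -> CellMap:
    """Expand each nucleus by a fixed Euclidean distance to define its cell.

    Every background pixel within ``distance`` of a nucleus pixel set receives
    the label of the nearest nucleus; exact ties go to the lowest label.
    Implemented as an ascending-label sweep of local distance transforms, which
    makes the tie-break explicit (a strictly smaller distance is required to
    overwrite an earlier label).
    """
    if distance < 0:
        raise ParameterError("expansion distance must be >= 0")
    nucleus_labels = np.asarray(nucleus_labels)
    if nucleus_labels.ndim != 2:
        raise ParameterError("nucleus label image must be 2-D")
    cell = nucleus_labels.astype(np.int32).copy()
    best = np.where(nucleus_labels > 0, 0.0, np.inf)
    pad = int(np.ceil(distance)) + 1
    h, w = nucleus_labels.shape
    for lab, sl in enumerate(ndi.find_objects(nucleus_labels), start=1):
        if sl is None:
            continue
        win = (
            slice(max(0, sl[0].start - pad), min(h, sl[0].stop + pad)),
            slice(max(0, sl[1].start - pad), min(w, sl[1].stop + pad)),
        )
        local = nucleus_labels[win] == lab
        d = ndi.distance_transform_edt(~local)
        sel = (d <= distance) & (d < best[win])
        cell[win][sel] = lab
        best[win][sel] = d[sel]
    return CellMap(
        nucleus_labels=nucleus_labels.astype(np.int32),
        cell_labels=cell,
        expansion_distance=float(distance),
    )


def detect_spots(
    image: np.ndarray, tophat_radius: float, threshold: float, gene: str
) -> pd.DataFrame:
    """Detect spots by white top-hat filtering and manual thresholding.

    Pixels of the top-hat response above ``threshold`` form 8-connected
    components; each component becomes one spot at its intensity-weighted
    centroid (weighted by the top-hat response), rounded to the nearest pixel.
    Returned spots are unassigned (``cell_id == UNASSIGNED``).
    """
    if tophat_radius < 1:
        raise ParameterError("tophat_radius must be >= 1 pixel")
    if threshold <= 0:
        raise ParameterError("spot threshold must be > 0 (0 would call every pixel)")
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ParameterError("spot channel must be a non-empty 2-D array")
    response = white_tophat(image, footprint=disk(int(round(tophat_radius))))
    mask = response > threshold
    labels = cc_label(mask, connectivity=2)
    rows, cols = [], []
    for prop in regionprops(labels, intensity_image=response):
        r, c = prop.centroid_weighted
        rows.append(int(np.rint(r)))
        cols.append(int(np.rint(c)))
    out = pd.DataFrame({
        "row": pd.Series(rows, dtype=int),
        "col": pd.Series(cols, dtype=int),
        "gene": pd.Series([gene] * len(rows), dtype=object),
        "cell_id": pd.Series([UNASSIGNED] * len(rows), dtype=int),
    })
    logger.info("detect_spots(%s): %d spots (radius=%s, threshold=%s)",
                gene, len(out), tophat_radius, threshold)
    return out


def assign_spots(spots: pd.DataFrame, cells: CellMap) -> pd.DataFrame:
    """Assign each spot the cell label at its pixel (0 becomes UNASSIGNED).

    Input order is preserved; out-of-bounds coordinates raise SpotBoundsError
    listing the offending record indices.
    """
    h, w = cells.cell_labels.shape
    spots = spots.reset_index(drop=True)
    r = spots["row"].to_numpy()
    c = spots["col"].to_numpy()
    bad = np.nonzero((r < 0) | (r >= h) | (c < 0) | (c >= w))[0]
    if len(bad):
        raise SpotBoundsError(bad.tolist())
    out = spots.copy()
    labs = cells.cell_labels[r, c] if len(spots) else np.zeros(0, dtype=int)
    out["cell_id"] = np.where(labs > 0, labs, UNASSIGNED).astype(int)
    return out
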