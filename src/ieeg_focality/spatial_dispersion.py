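"""Spatial dispersion statistics for electrode contact clouds.

Two statistics summarize where a patient's intracranial electrodes sit and
where their interictal abnormalities live:

* **standard distance (SD, "implant distance")** — the 3D standard deviation
  of the contact cloud: the square root of the summed per-axis *population*
  variances about the mean centre. A compact, targeted implant yields a small
  SD; broad bilateral coverage yields a large one.

* **weighted standard distance (WSD, "abnormality distance")** — the same
  statistic with each contact weighted by a non-negative abnormality value,
  taken about the weighted mean centre. Tightly clustered abnormality gives a
  small WSD even when the implant itself is broad.

Both are in millimetres when coordinates are in millimetres, are invariant to
rigid motion (the summed per-axis variance is the trace of the covariance),
and scale linearly with the coordinates. WSD is invariant to rescaling all
weights by a positive constant and reduces exactly to SD for equal weights.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "standard_distance",
    "weighted_standard_distance",
    "assemble_feature_vector",
]


def _as_cloud(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[None, :]
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected an (n, 3) coordinate array, got shape {pts.shape}")
    if pts.shape[0] == 0:
        raise ValueError("empty contact cloud")
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite coordinates in contact cloud")
    return pts


def standard_distance(points) -> float:
    """3D standard distance of a point cloud, in the units of ``points``.

    ``sqrt(var_x + var_y + var_z)`` with population (1/n) variances about the
    unweighted mean centre. A single point gives 0.
    """
    pts = _as_cloud(points)
    centre = pts.mean(axis=0)
    return float(np.sqrt(((pts - centre) ** 2).mean(axis=0).sum()))


def weighted_standard_distance(points, weights) -> float:
    """Weighted 3D standard distance about the weighted mean centre.

    Weights must be finite, non-negative, and not all zero. Equal weights
    reproduce :func:`standard_distance` exactly; concentrating all mass on one
    point gives 0.
    """
    pts = _as_cloud(points)
    w = np.asarray(weights, dtype=float)
    if w.shape != (pts.shape[0],):
        raise ValueError(f"weights shape {w.shape} does not match {pts.shape[0]} points")
    if not np.all(np.isfinite(w)):
        raise ValueError("non-finite weights")
    if np.any(w < 0):
        raise ValueError("negative weights")
    total = w.sum()
    if total <= 0:
        raise ValueError("all weights are zero; weighted centre undefined")
    centre = (w[:, None] * pts).sum(axis=0) / total
    var = (w[:, None] * (pts - centre) ** 2).sum(axis=0) / total
    return float(np.sqrt(var.sum()))


def assemble_feature_vector(
    positions: np.ndarray,
    channel_names: Sequence[str],
    weight_maps: pd.DataFrame,
    five_sense: float,
    labels: Mapping[str, object] | None = None,
    patient_id: str | None = None,
) -> pd.Series:
    """Assemble one patient's feature row: 5-SENSE, SD, and 12 WSDs.

    Parameters
    ----------
    positions
        (n, 3) mm coordinates of the patient's scorable grey-matter bipolar
        channel midpoints.
    channel_names
        Names aligned with ``positions``.
    weight_maps
        Long-format abnormality weights with columns
        ``channel, band, measure, weight`` (NaN weight = unscorable channel,
        excluded from that map's WSD but not from SD).
    five_sense
        Pre-implant focality score, passed through.
    labels
        Optional clinical labels appended verbatim.

    Returns
    -------
    pandas.Series with ``five_sense``, ``implant_distance_mm`` and one
    ``wsd_<band>_<measure>_mm`` entry per weight map.
    """
    positions = _as_cloud(positions)
    if len(channel_names) != positions.shape[0]:
        raise ValueError("channel_names does not match positions")
    row: dict[str, object] = {}
    if patient_id is not None:
        row["patient_id"] = patient_id
    row["five_sense"] = float(five_sense)
    row["implant_distance_mm"] = standard_distance(positions)

    index = {name: i for i, name in enumerate(channel_names)}
    n_maps = 0
    for (band, measure), grp in weight_maps.groupby(["band", "measure"], sort=False):
        grp = grp.dropna(subset=["weight"])
        key = f"wsd_{band}_{measure}_mm"
        idx = [index[c] for c in grp["channel"] if c in index]
        w = grp.loc[grp["channel"].isin(index), "weight"].to_numpy(dtype=float)
        if len(idx) == 0 or w.sum() <= 0:
            # all channels unscorable (or zero abnormality everywhere): flag
            row[key] = np.nan
            logger.warning("patient %s: weight map %s/%s empty; WSD missing", patient_id, band, measure)
            continue
        row[key] = weighted_standard_distance(positions[idx], w)
        n_maps += 1
    if n_maps == 0 and len(weight_maps):
        logger.warning("patient %s: no usable weight maps", patient_id)
    if labels:
        for k, v in labels.items():
            row[k] = v
    return pd.Series(row)
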