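"""Normative iEEG atlas: ROI-level feature distributions and Z-score maps.

Because intracranial electrodes are essentially never implanted in healthy
brains, "normal" interictal iEEG is approximated by pooling channels that sit
outside epileptogenic tissue across many patients. The atlas stores, for each
parcellated region of interest (ROI) and frequency band, the mean and
standard deviation of relative band power across those normal channel-clips,
and for each unordered ROI pair and band the same for magnitude-squared
coherence.

A patient's channel is scored as ``Z = (value − atlas mean) / atlas sd``
against its own ROI (or ROI pair for connections). Over 20 interictal clips
this yields a Z distribution per channel, which is collapsed to a single
non-negative abnormality weight:

* power weight   = median over clips of |Z|;
* coherence weight (per channel) = median over clips of the mean |Z| across
  that channel's scored connections (edge → node collapse).

Both hypo- and hyper-normal values count as abnormal, and weights feed the
weighted-standard-distance statistic, which requires non-negative weights.
Absolute broadband power is log10-transformed before atlas statistics and
scoring to tame its heavy right skew; all other features are scored on their
native scale.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .signal_processing import BAND_NAMES, ClipFeatureTensor

logger = logging.getLogger(__name__)

_BROADBAND_IDX = BAND_NAMES.index("broadband")

ATLAS_FORMAT_VERSION = 1


def _transform_power(values: np.ndarray, band_idx: int) -> np.ndarray:
    """Feature transform applied before atlas stats and scoring."""
    if band_idx == _BROADBAND_IDX:
        with np.errstate(divide="ignore"):
            return np.log10(values)
    return values


@dataclass
class NormativeAtlas:
    """ROI-level normative statistics for power and coherence features.

    ``power_stats`` maps ``(roi, band) -> (mean, sd, n)``;
    ``coherence_stats`` maps ``(roi_a, roi_b, band) -> (mean, sd, n)`` with
    ``roi_a <= roi_b``. Entries with fewer than ``min_n`` samples or zero
    variance are never stored. ``source_subjects`` records provenance for the
    no-leakage check.
    """

    power_stats: dict[tuple, tuple[float, float, int]]
    coherence_stats: dict[tuple, tuple[float, float, int]]
    min_n: int = 5
    source_subjects: frozenset = field(default_factory=frozenset)

    def power_entry(self, roi, band: str):
        return self.power_stats.get((roi, band))

    def coherence_entry(self, roi_a, roi_b, band: str):
        key = (roi_a, roi_b, band) if str(roi_a) <= str(roi_b) else (roi_b, roi_a, band)
        return self.coherence_stats.get(key)

    # -- serialization ------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"roi_a": r, "roi_b": "", "band": b, "measure": "power", "mean": m, "sd": s, "n": n}
            for (r, b), (m, s, n) in sorted(self.power_stats.items(), key=str)
        ] + [
            {"roi_a": ra, "roi_b": rb, "band": b, "measure": "coherence", "mean": m, "sd": s, "n": n}
            for (ra, rb, b), (m, s, n) in sorted(self.coherence_stats.items(), key=str)
        ]
        return pd.DataFrame(rows, columns=["roi_a", "roi_b", "band", "measure", "mean", "sd", "n"])

    def save(self, path) -> None:
        payload = {
            "format_version": ATLAS_FORMAT_VERSION,
            "min_n": self.min_n,
            "source_subjects": sorted(str(s) for s in self.source_subjects),
            "entries": self.to_frame().to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "NormativeAtlas":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format_version") != ATLAS_FORMAT_VERSION:
            raise ValueError("unrecognized atlas format version")
        power, coh = {}, {}
        for row in payload["entries"]:
            stat = (float(row["mean"]), float(row["sd"]), int(row["n"]))
            if row["measure"] == "power":
                power[(row["roi_a"], row["band"])] = stat
            else:
                coh[(row["roi_a"], row["roi_b"], row["band"])] = stat
        return cls(
            power_stats=power,
            coherence_stats=coh,
            min_n=int(payload["min_n"]),
            source_subjects=frozenset(payload["source_subjects"]),
        )


def build_atlas(
    population: Mapping[str, ClipFeatureTensor],
    min_n: int = 5,
) -> NormativeAtlas:
    """Pool normal channel-clips into ROI-level normative statistics.

    ``population`` maps subject id → that subject's feature tensor (computed
    by :mod:`ieeg_focality.signal_processing`), with ROI labels attached to
    every channel. Power values pool over all channels in an ROI and all
    clips; coherence values pool over all connections between an ROI pair.
    Entries with ``n < min_n`` or zero variance are excluded (warned).
    """
    power_vals: dict[tuple, list] = {}
    coh_vals: dict[tuple, list] = {}
    for sid, feats in population.items():
        rois = feats.rois
        for b_idx, band in enumerate(BAND_NAMES):
            vals = _transform_power(feats.rel_power[:, :, b_idx], b_idx)
            for c_idx, roi in enumerate(rois):
                power_vals.setdefault((roi, band), []).extend(vals[:, c_idx].tolist())
            for p_idx in range(feats.pairs.shape[0]):
                ra, rb = rois[feats.pairs[p_idx, 0]], rois[feats.pairs[p_idx, 1]]
                if str(ra) > str(rb):
                    ra, rb = rb, ra
                coh_vals.setdefault((ra, rb, band), []).extend(
                    feats.coherence[:, p_idx, b_idx].tolist()
                )

    def summarize(values: dict[tuple, list], what: str) -> dict:
        out = {}
        for key, vals in values.items():
            arr = np.asarray(vals, dtype=float)
            arr = arr[np.isfinite(arr)]
            if arr.size < min_n:
                logger.warning("atlas: %s entry %s has n=%d < %d; excluded", what, key, arr.size, min_n)
                continue
            sd = float(arr.std(ddof=1))
            if sd <= 0:
                logger.warning("atlas: %s entry %s has zero variance; excluded", what, key)
                continue
            out[key] = (float(arr.mean()), sd, int(arr.size))
        return out

    subjects = frozenset(str(s) for s in population)
    return NormativeAtlas(
        power_stats=summarize(power_vals, "power"),
        coherence_stats=summarize(coh_vals, "coherence"),
        min_n=min_n,
        source_subjects=subjects,
    )


def _check_leakage(atlas: NormativeAtlas, subject_id, allow_self: bool) -> None:
    if subject_id is None:
        return
    if str(subject_id) in atlas.source_subjects and not allow_self:
        raise ValueError(
            f"subject {subject_id!r} contributed to this atlas; scoring it against "
            "its own atlas leaks information (pass allow_self=True for calibration checks)"
        )


def zscore_power(
    feats: ClipFeatureTensor,
    atlas: NormativeAtlas,
    subject_id=None,
    allow_self: bool = False,
) -> np.ndarray:
    """Z-score each channel's band power per clip against its ROI's atlas entry.

    Returns (n_clips, n_channels, 6); NaN where the channel's ROI (or band)
    has no atlas entry (unscorable — excluded downstream, never silently 0).
    """
    _check_leakage(atlas, subject_id, allow_self)
    z = np.full_like(feats.rel_power, np.nan)
    n_unscorable = 0
    for b_idx, band in enumerate(BAND_NAMES):
        vals = _transform_power(feats.rel_power[:, :, b_idx], b_idx)
        for c_idx, roi in enumerate(feats.rois):
            entry = atlas.power_entry(roi, band)
            if entry is None:
                n_unscorable += 1
                continue
            mean, sd, _ = entry
            z[:, c_idx, b_idx] = (vals[:, c_idx] - mean) / sd
    if n_unscorable:
        logger.info("zscore_power: %d channel×band entries unscorable (ROI not in atlas)", n_unscorable)
    return z


def zscore_coherence(
    feats: ClipFeatureTensor,
    atlas: NormativeAtlas,
    subject_id=None,
    allow_self: bool = False,
) -> np.ndarray:
    """Z-score each connection's coherence per clip against its ROI-pair entry.

    Returns (n_clips, n_pairs, 6); lookup is unordered in the ROI pair.
    """
    _check_leakage(atlas, subject_id, allow_self)
    z = np.full_like(feats.coherence, np.nan)
    n_unscorable = 0
    for b_idx, band in enumerate(BAND_NAMES):
        for p_idx in range(feats.pairs.shape[0]):
            ra = feats.rois[feats.pairs[p_idx, 0]]
            rb = feats.rois[feats.pairs[p_idx, 1]]
            entry = atlas.coherence_entry(ra, rb, band)
            if entry is None:
                n_unscorable += 1
                continue
            mean, sd, _ = entry
            z[:, p_idx, b_idx] = (feats.coherence[:, p_idx, b_idx] - mean) / sd
    if n_unscorable:
        logger.info("zscore_coherence: %d pair×band entries unscorable", n_unscorable)
    return z


def aggregate_to_weights(
    z_power: np.ndarray,
    z_coherence: np.ndarray,
    feats: ClipFeatureTensor,
    reduction: str = "median",
) -> pd.DataFrame:
    """Collapse per-clip Z tensors to one non-negative weight per channel.

    Power: ``reduction`` (median by default, mean available) over clips of
    |Z|. Coherence: per clip, each channel takes the mean |Z| over its scored
    incident connections; then the same reduction over clips. Channels
    unscorable in every clip keep a NaN weight (missing flag).

    Returns a long DataFrame: channel, band, measure, weight, n_clips.
    """
    if z_power.shape[0] < 1:
        raise ValueError("need at least one scored clip")
    if reduction not in {"median", "mean"}:
        raise ValueError("reduction must be 'median' or 'mean'")
    reduce = np.nanmedian if reduction == "median" else np.nanmean
    n_clips, n_ch, n_bands = z_power.shape
    rows = []
    with warnings.catch_warnings():
        # all-NaN slices (fully unscorable channels) legitimately reduce to NaN
        warnings.simplefilter("ignore", RuntimeWarning)
        power_w = reduce(np.abs(z_power), axis=0)  # (n_ch, 6)

        # edge → node collapse: mean |Z| over incident scored pairs, per clip
        incid_sum = np.zeros((n_clips, n_ch, n_bands))
        incid_cnt = np.zeros((n_clips, n_ch, n_bands))
        absz = np.abs(z_coherence)
        scored = np.isfinite(absz)
        for p_idx in range(feats.pairs.shape[0]):
            i, j = feats.pairs[p_idx]
            contrib = np.where(scored[:, p_idx, :], absz[:, p_idx, :], 0.0)
            cnt = scored[:, p_idx, :].astype(float)
            incid_sum[:, i, :] += contrib
            incid_sum[:, j, :] += contrib
            incid_cnt[:, i, :] += cnt
            incid_cnt[:, j, :] += cnt
        node_clip = np.where(incid_cnt > 0, incid_sum / np.maximum(incid_cnt, 1), np.nan)
        coh_w = reduce(node_clip, axis=0)

    for c_idx, ch in enumerate(feats.channels):
        for b_idx, band in enumerate(BAND_NAMES):
            rows.append((ch, band, "power", power_w[c_idx, b_idx], n_clips))
            rows.append((ch, band, "coherence", coh_w[c_idx, b_idx], n_clips))
    df = pd.DataFrame(rows, columns=["channel", "band", "measure", "weight", "n_clips"])
    n_missing = int(df["weight"].isna().sum())
    if n_missing:
        logger.info("aggregate_to_weights: %d channel×band×measure weights missing", n_missing)
    return df


def score_patient(
    feats: ClipFeatureTensor,
    atlas: NormativeAtlas,
    subject_id=None,
    allow_self: bool = False,
    reduction: str = "median",
) -> pd.DataFrame:
    """Convenience: Z-score a patient and collapse to abnormality weights."""
    zp = zscore_power(feats, atlas, subject_id=subject_id, allow_self=allow_self)
    zc = zscore_coherence(feats, atlas, subject_id=subject_id, allow_self=allow_self)
    return aggregate_to_weights(zp, zc, feats, reduction=reduction)
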