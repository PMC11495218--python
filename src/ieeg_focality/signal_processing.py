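"""From raw interictal iEEG clips to band power and coherence features.

The processing chain mirrors standard interictal iEEG practice: bipolar
re-referencing along each electrode shank, a zero-phase third-order
Butterworth band-pass between 0.5 and 80 Hz plus a 60 Hz notch, polyphase
resampling to 200 Hz, then Welch spectral estimates with 2 s Hamming windows
and 1 s overlap. Features per clip are

* relative band power in the five canonical bands (delta 0.5-4, theta 4-8,
  alpha 8-12, beta 12-30, gamma 30-80 Hz), each band's integrated PSD divided
  by total power over 0.5-80 Hz, plus *absolute* broadband (0.5-80 Hz) power
  (relative broadband power is identically 1, so the broadband feature is
  kept on an absolute scale);
* magnitude-squared coherence (MSC) between every channel pair, averaged over
  the frequency bins of each band.

Band edges are half-open ``[lo, hi)`` and bin membership is decided by bin
centre, so each Welch bin is counted in exactly one canonical band.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)


class Band(NamedTuple):
    name: str
    lo: float
    hi: float


#: Canonical five bands partitioning [0.5, 80) Hz.
CANONICAL_BANDS: tuple[Band, ...] = (
    Band("delta", 0.5, 4.0),
    Band("theta", 4.0, 8.0),
    Band("alpha", 8.0, 12.0),
    Band("beta", 12.0, 30.0),
    Band("gamma", 30.0, 80.0),
)
BROADBAND = Band("broadband", 0.5, 80.0)
#: Feature order used throughout: five canonical bands then broadband.
BANDS: tuple[Band, ...] = CANONICAL_BANDS + (BROADBAND,)
BAND_NAMES: tuple[str, ...] = tuple(b.name for b in BANDS)

FS_TARGET = 200.0
NPERSEG = 400  # 2 s at 200 Hz
NOVERLAP = 200  # 1 s overlap


# ---------------------------------------------------------------------------
# Bipolar montage
# ---------------------------------------------------------------------------

def make_bipolar_montage(electrodes: pd.DataFrame) -> pd.DataFrame:
    """Build the bipolar montage from a contact table.

    ``electrodes`` needs columns ``contact, shank, index, x_mm, y_mm, z_mm,
    tissue, roi``. Adjacent contacts (i, i+1) on each shank form a bipolar
    channel located at their midpoint. A channel whose midpoint is not in
    grey matter (either member contact white matter / outside the brain) is
    excluded. The midpoint ROI is the anode's ROI when the two contacts
    disagree (midpoint is equidistant; the tie goes to the lower-index
    contact).

    Returns a DataFrame with columns ``channel, anode, cathode, shank,
    x_mm, y_mm, z_mm, roi, tissue``, grey-matter channels only.
    """
    required = {"contact", "shank", "index", "x_mm", "y_mm", "z_mm", "tissue", "roi"}
    missing = required - set(electrodes.columns)
    if missing:
        raise ValueError(f"electrode table missing columns: {sorted(missing)}")
    rows = []
    n_excluded = 0
    for shank, grp in electrodes.groupby("shank", sort=False):
        grp = grp.sort_values("index")
        if len(grp) < 2:
            logger.warning("shank %s has a single contact; no bipolar pair formed", shank)
            continue
        a = grp.iloc[:-1]
        c = grp.iloc[1:]
        for (_, anode), (_, cathode) in zip(a.iterrows(), c.iterrows()):
            tissues = {anode["tissue"], cathode["tissue"]}
            if "outside" in tissues:
                tissue = "outside"
            elif "white" in tissues:
                tissue = "white"
            else:
                tissue = "gray"
            if tissue != "gray":
                n_excluded += 1
                continue
            rows.append(
                {
                    "channel": f"{anode['contact']}-{cathode['contact']}",
                    "anode": anode["contact"],
                    "cathode": cathode["contact"],
                    "shank": shank,
                    "x_mm": (anode["x_mm"] + cathode["x_mm"]) / 2.0,
                    "y_mm": (anode["y_mm"] + cathode["y_mm"]) / 2.0,
                    "z_mm": (anode["z_mm"] + cathode["z_mm"]) / 2.0,
                    # midpoint is equidistant from both contacts; tie → anode's ROI
                    "roi": anode["roi"],
                    "tissue": tissue,
                }
            )
    if n_excluded:
        logger.debug("bipolar montage: %d channels excluded (non-grey midpoint)", n_excluded)
    if not rows:
        logger.warning("bipolar montage is empty")
        return pd.DataFrame(
            columns=["channel", "anode", "cathode", "shank", "x_mm", "y_mm", "z_mm", "roi", "tissue"]
        )
    return pd.DataFrame(rows)


def apply_bipolar(raw: np.ndarray, contact_order: Sequence[str], montage: pd.DataFrame) -> np.ndarray:
    """Re-reference a (..., n_contacts, n_samples) clip to the bipolar montage."""
    index = {c: i for i, c in enumerate(contact_order)}
    missing = [c for c in montage["anode"] if c not in index] + [
        c for c in montage["cathode"] if c not in index
    ]
    if missing:
        raise ValueError(f"clip is missing contacts referenced by the montage: {sorted(set(missing))}")
    ai = [index[c] for c in montage["anode"]]
    ci = [index[c] for c in montage["cathode"]]
    return raw[..., ai, :] - raw[..., ci, :]


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _bandpass_sos(order: int, band: tuple[float, float], fs: float) -> np.ndarray:
    return signal.butter(order, band, btype="bandpass", fs=fs, output="sos")


@lru_cache(maxsize=32)
def _notch_ba(freq: float, q: float, fs: float) -> tuple[np.ndarray, np.ndarray]:
    return signal.iirnotch(freq, q, fs=fs)


def preprocess_clip(
    raw: np.ndarray,
    fs_raw: float,
    *,
    band: tuple[float, float] = (0.5, 80.0),
    filter_order: int = 3,
    notch_hz: float = 60.0,
    notch_q: float = 30.0,
    fs_out: float = FS_TARGET,
) -> np.ndarray:
    """Band-pass, notch and resample a (n_channels, n_samples) clip to 200 Hz.

    Zero-phase (forward-backward) third-order Butterworth band-pass, a 60 Hz
    IIR notch (Q=30, also zero-phase), then polyphase resampling to exactly
    ``fs_out``. Output length is ``round(n_samples * fs_out / fs_raw)``.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    if fs_raw < 2 * fs_out:
        raise ValueError(f"fs_raw must be ≥ {2 * fs_out:g} Hz for a true decimation, got {fs_raw:g}")
    bad = np.argwhere(~np.isfinite(raw).all(axis=-1))
    if bad.size:
        raise ValueError(f"NaN/inf samples in channel(s) {bad.squeeze(-1).tolist()}; clip rejected")
    sos = _bandpass_sos(filter_order, band, fs_raw)
    x = signal.sosfiltfilt(sos, raw, axis=-1)
    if band[0] < notch_hz < band[1]:
        b, a = _notch_ba(notch_hz, notch_q, fs_raw)
        x = signal.filtfilt(b, a, x, axis=-1)
    ratio = Fraction(fs_out / fs_raw).limit_denominator(10000)
    x = signal.resample_poly(x, ratio.numerator, ratio.denominator, axis=-1)
    n_out = int(round(raw.shape[-1] * fs_out / fs_raw))
    return x[..., :n_out]


# ---------------------------------------------------------------------------
# Wake detection and clip selection
# ---------------------------------------------------------------------------

def detect_wake_epochs(
    alpha_power: np.ndarray,
    delta_power: np.ndarray,
    threshold: float = -0.40,
) -> np.ndarray:
    """Flag awake windows from an alpha/delta power ratio timeline.

    ``alpha_power`` and ``delta_power`` are (n_windows,) or
    (n_windows, n_channels). Per window the ratio is the channel-median of
    log10(alpha/delta); ratios are z-normalized across the recording and a
    window is awake when its normalized ratio is at or above ``threshold``
    (wakefulness shows relatively more alpha than delta). Windows with
    non-positive delta power on all channels are skipped (flagged not awake).
    """
    a = np.atleast_2d(np.asarray(alpha_power, dtype=float).T).T
    d = np.atleast_2d(np.asarray(delta_power, dtype=float).T).T
    if a.shape != d.shape:
        raise ValueError("alpha and delta power timelines differ in shape")
    if a.shape[0] < 10:
        raise ValueError("need ≥ 10 windows to normalize the alpha/delta ratio")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where((a > 0) & (d > 0), np.log10(a / d), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows reduce to NaN
        per_window = np.nanmedian(ratio, axis=1)
    valid = np.isfinite(per_window)
    if (~valid).any():
        logger.warning("wake detector: %d window(s) skipped (non-positive band power)", int((~valid).sum()))
    z = np.zeros_like(per_window)
    sd = np.nanstd(per_window[valid]) if valid.any() else 0.0
    if sd > 0:
        z[valid] = (per_window[valid] - np.nanmean(per_window[valid])) / sd
    awake = np.zeros(per_window.shape, dtype=bool)
    awake[valid] = z[valid] >= threshold
    return awake


def select_interictal_clips(
    awake_mask: np.ndarray,
    window_s: float,
    seizure_times_s: Sequence[float],
    rng: np.random.Generator,
    *,
    n_clips: int = 20,
    clip_duration_s: float = 60.0,
    post_implant_blackout_s: float = 72 * 3600.0,
    seizure_pad_s: float = 2 * 3600.0,
) -> np.ndarray:
    """Pick interictal clip start times (seconds from implant).

    The recording timeline starts at implantation and is described by
    ``awake_mask``, one flag per ``window_s``-second window. Candidate starts
    lie on a ``clip_duration_s`` grid (so chosen clips cannot overlap); a
    start is eligible when the clip lies at least ``post_implant_blackout_s``
    after implant, at least ``seizure_pad_s`` from every seizure annotation
    (both sides), and every awake window it touches is flagged awake.
    ``n_clips`` starts are drawn uniformly without replacement; a shortfall
    returns every eligible start with a warning.
    """
    awake_mask = np.asarray(awake_mask, dtype=bool)
    total_s = awake_mask.size * window_s
    starts = np.arange(0.0, total_s - clip_duration_s + 1e-9, clip_duration_s)
    eligible = []
    seizures = np.asarray(list(seizure_times_s), dtype=float)
    for t0 in starts:
        t1 = t0 + clip_duration_s
        if t0 < post_implant_blackout_s:
            continue
        if seizures.size and np.any((seizures > t0 - seizure_pad_s) & (seizures < t1 + seizure_pad_s)):
            continue
        w0 = int(np.floor(t0 / window_s))
        w1 = int(np.ceil(t1 / window_s))
        if not awake_mask[w0:w1].all():
            continue
        eligible.append(t0)
    eligible = np.asarray(eligible)
    if eligible.size < n_clips:
        logger.warning(
            "only %d eligible interictal windows (requested %d); returning all", eligible.size, n_clips
        )
        return np.sort(eligible)
    chosen = rng.choice(eligible, size=n_clips, replace=False)
    return np.sort(chosen)


# ---------------------------------------------------------------------------
# Spectral features
# ---------------------------------------------------------------------------

def _band_masks(freqs: np.ndarray) -> dict[str, np.ndarray]:
    return {b.name: (freqs >= b.lo) & (freqs < b.hi) for b in BANDS}


def relative_band_power(clip: np.ndarray, fs: float = FS_TARGET) -> np.ndarray:
    """Per-channel band power features for one 200 Hz clip.

    Returns an (n_channels, 6) array ordered as :data:`BAND_NAMES`: relative
    power (fraction of total 0.5-80 Hz power) for the five canonical bands,
    then absolute broadband power (signal units squared). Canonical fractions
    sum to 1 per channel. Flat (zero-variance) channels yield NaN fractions.
    """
    clip = np.atleast_2d(np.asarray(clip, dtype=float))
    if clip.shape[-1] < 2 * NPERSEG:
        raise ValueError("clip shorter than 4 s at 200 Hz; Welch estimate unreliable")
    freqs, psd = signal.welch(
        clip, fs=fs, window="hamming", nperseg=NPERSEG, noverlap=NOVERLAP, axis=-1
    )
    df = freqs[1] - freqs[0]
    masks = _band_masks(freqs)
    total = psd[:, masks["broadband"]].sum(axis=-1) * df
    out = np.empty((clip.shape[0], len(BANDS)))
    flat = total <= 0
    if flat.any():
        logger.warning("flat channel(s) %s: relative power undefined", np.flatnonzero(flat).tolist())
    with np.errstate(divide="ignore", invalid="ignore"):
        for j, b in enumerate(CANONICAL_BANDS):
            out[:, j] = np.where(flat, np.nan, psd[:, masks[b.name]].sum(axis=-1) * df / total)
    out[:, len(CANONICAL_BANDS)] = total  # absolute broadband power
    return out


def _windowed_fft(clips: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hamming-windowed, per-segment demeaned rFFTs: (..., K, F) and freqs."""
    n = clips.shape[-1]
    step = NPERSEG - NOVERLAP
    k = 1 + (n - NPERSEG) // step
    idx = np.arange(NPERSEG)[None, :] + step * np.arange(k)[:, None]
    segs = clips[..., idx]  # (..., K, nperseg)
    segs = segs - segs.mean(axis=-1, keepdims=True)
    win = signal.get_window("hamming", NPERSEG)
    spec = np.fft.rfft(segs * win, axis=-1)
    freqs = np.fft.rfftfreq(NPERSEG, d=1.0 / FS_TARGET)
    return spec, freqs


def _msc_batch(clips: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Band-averaged MSC for a (n_clips, n_ch, n_samples) stack.

    Cross-spectra via per-clip batched matrix products (BLAS) rather than an
    explicit pair loop. Returns pairs (i < j) and (n_clips, n_pairs, 6).
    """
    n_clips, n_ch, _ = clips.shape
    spec, freqs = _windowed_fft(clips)  # (n_clips, n_ch, K, F)
    k = spec.shape[-2]
    auto = (spec.real**2 + spec.imag**2).mean(axis=-2)  # (n_clips, n_ch, F)
    ii, jj = np.triu_indices(n_ch, k=1)
    masks = _band_masks(freqs)
    out = np.empty((n_clips, ii.size, len(BANDS)))
    for c in range(n_clips):
        s = spec[c].transpose(2, 0, 1)  # (F, n_ch, K)
        cross = s @ s.conj().transpose(0, 2, 1) / k  # (F, n_ch, n_ch)
        with np.errstate(divide="ignore", invalid="ignore"):
            msc_f = np.abs(cross[:, ii, jj]) ** 2 / (auto[c, ii].T * auto[c, jj].T)
        msc_f = msc_f.T  # (n_pairs, F)
        for b_idx, b in enumerate(BANDS):
            out[c, :, b_idx] = np.nanmean(msc_f[:, masks[b.name]], axis=-1)
    pairs = np.column_stack([ii, jj])
    return pairs, np.clip(out, 0.0, 1.0)


def magnitude_squared_coherence(
    clip: np.ndarray, fs: float = FS_TARGET
) -> tuple[np.ndarray, np.ndarray]:
    """Band-averaged magnitude-squared coherence for every channel pair.

    Welch cross-spectra with the same 2 s Hamming / 1 s overlap windowing as
    the power features. Returns ``(pairs, msc)`` where ``pairs`` is an
    (n_pairs, 2) array of channel indices (i < j) and ``msc`` is
    (n_pairs, 6): per band, the mean MSC over that band's frequency bins.
    Values lie in [0, 1]; the estimate is invariant to per-channel scaling
    and to pure delays.
    """
    clip = np.atleast_2d(np.asarray(clip, dtype=float))
    if clip.shape[0] < 2:
        raise ValueError("coherence needs at least two channels")
    if clip.shape[-1] < 2 * NPERSEG:
        raise ValueError("clip shorter than 4 s at 200 Hz")
    if fs != FS_TARGET:
        raise ValueError("coherence features are defined on 200 Hz clips")
    pairs, msc = _msc_batch(clip[None])
    return pairs, msc[0]


# ---------------------------------------------------------------------------
# Clip feature container
# ---------------------------------------------------------------------------

@dataclass
class ClipFeatureTensor:
    """Per-patient feature stack over clips.

    ``rel_power`` is (n_clips, n_channels, 6) ordered as :data:`BAND_NAMES`
    (broadband column = absolute power); ``coherence`` is
    (n_clips, n_pairs, 6) with ``pairs`` indexing into ``channels``.
    """

    channels: list[str]
    rois: list
    rel_power: np.ndarray
    coherence: np.ndarray
    pairs: np.ndarray
    fs: float = FS_TARGET

    def __post_init__(self) -> None:
        if self.rel_power.shape[1] != len(self.channels):
            raise ValueError("rel_power channel axis mismatch")
        if self.coherence.shape[1] != self.pairs.shape[0]:
            raise ValueError("coherence pair axis mismatch")

    @property
    def n_clips(self) -> int:
        return self.rel_power.shape[0]

    def to_frame(self, patient_id: str = "") -> pd.DataFrame:
        """Long-format view: (patient, clip, channel|pair, band, measure, value)."""
        rows = []
        for k in range(self.n_clips):
            for c, ch in enumerate(self.channels):
                for b, band in enumerate(BAND_NAMES):
                    rows.append((patient_id, k, ch, band, "power", self.rel_power[k, c, b]))
            for p in range(self.pairs.shape[0]):
                name = f"{self.channels[self.pairs[p, 0]]}|{self.channels[self.pairs[p, 1]]}"
                for b, band in enumerate(BAND_NAMES):
                    rows.append((patient_id, k, name, band, "coherence", self.coherence[k, p, b]))
        return pd.DataFrame(rows, columns=["patient", "clip", "channel", "band", "measure", "value"])


def compute_clip_features(
    clips: Sequence[np.ndarray],
    channels: Sequence[str],
    rois: Sequence,
) -> ClipFeatureTensor:
    """Stack power and coherence features for a list of 200 Hz bipolar clips.

    Clips are processed as one batch (identical channel sets assumed); the
    result for clip k depends only on clip k.
    """
    if isinstance(clips, np.ndarray) and clips.ndim == 3:
        stack = clips.astype(float, copy=False)
    else:
        stack = np.stack([np.atleast_2d(np.asarray(c, dtype=float)) for c in clips])
    rel = np.stack([relative_band_power(stack[k]) for k in range(stack.shape[0])])
    pairs, coh = _msc_batch(stack)
    return ClipFeatureTensor(
        channels=list(channels),
        rois=list(rois),
        rel_power=rel,
        coherence=coh,
        pairs=pairs,
    )
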