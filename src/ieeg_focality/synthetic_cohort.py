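"""Synthetic iEEG cohorts with known ground truth.

Real pre-surgical iEEG cohorts cannot ship with a software package, so this
module generates cohorts that exhibit the statistical structure the analysis
assumes and nothing it does not:

* **Geometry** — linear shanks of equally spaced contacts inside a spherical
  head volume. Patients with a focal epileptic network get shanks clustered
  around one seed point; non-focal patients (bifocal / multi-focal / broad /
  non-localized subtypes) get broader, multi-cluster or scattered coverage,
  emulating how clinicians target implants from the pre-implant hypothesis.
  Contacts are assigned to regions of interest (ROIs) by nearest of a fixed
  set of deterministic ROI centres, and a configurable fraction is flagged
  white matter purely to exercise the exclusion rule.

* **Signals** — stationary colored-noise background (1/f-shaped via spectral
  shaping of white noise, plus an alpha-band component) per contact.
  Epileptic contacts additionally receive independent band-limited noise
  (raising relative band power) and a shared band-limited source (raising
  pairwise coherence). The shared source enters adjacent contacts with
  alternating sign along the shank so bipolar differencing preserves it.
  Injection amplitudes are calibrated against numerically estimated null
  statistics of the generator itself so that ``power_effect`` and
  ``coherence_effect`` are approximately Z-shifts in the downstream
  normative-atlas scores.

* **Clinical covariates** — a pre-implant focality score ("5-SENSE"-like)
  drawn class-conditionally and weakly anti-correlated with implant
  dispersion; therapy and outcome sampled with class-dependent rates
  mirroring a 101-patient surgical cohort (65 focal / 36 non-focal;
  52/65 vs 11/36 surgical).

All randomness flows from a single integer seed; each patient uses an
independent substream keyed by (seed, patient index), so cohorts are
byte-reproducible and stable under cohort-size changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .signal_processing import (
    BAND_NAMES,
    CANONICAL_BANDS,
    apply_bipolar,
    compute_clip_features,
    make_bipolar_montage,
    preprocess_clip,
)
from .spatial_dispersion import standard_distance

logger = logging.getLogger(__name__)

NONFOCAL_SUBTYPES = ("bifocal", "multifocal", "broad", "nonlocalized")
FOCALITY_LABELS = ("focal",) + NONFOCAL_SUBTYPES

#: default bands receiving injected power (slowing + high-frequency elevation)
POWER_EFFECT_BANDS = ("delta", "gamma")
#: default band carrying the shared coherent source
COHERENCE_EFFECT_BANDS = ("beta",)

_BAND_RANGES = {b.name: (b.lo, b.hi) for b in CANONICAL_BANDS}


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults emulate the cohort structure of a 101-patient single-centre
    surgical series (65 focal / 36 non-focal) with SEEG-like implants.
    """

    n_patients: int = 101
    focal_fraction: float = 65 / 101
    n_shanks_range: tuple[int, int] = (4, 7)
    contacts_per_shank: int = 8
    contact_spacing_mm: float = 3.5
    focal_cluster_radius_mm: float = 16.0
    nonfocal_spread_mm: float = 64.0  # diameter of the non-focal scatter volume
    # log-normal sigma of the per-patient multiplier on the scatter radius:
    # implant extent varies between patients, so the class-conditional
    # dispersion distributions overlap instead of separating perfectly
    dispersion_jitter_sigma: float = 0.45
    n_rois: int = 10
    head_radius_mm: float = 70.0
    white_matter_rate: float = 0.15
    fs_raw: float = 512.0
    clip_duration_s: float = 60.0
    n_clips: int = 20
    power_effect: float | Mapping[str, float] = 2.0
    coherence_effect: float | Mapping[str, float] = 2.0
    five_sense_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"focal": (0.61, 0.15), "nonfocal": (0.50, 0.15)}
    )
    implant_score_corr: float = -0.15  # within-class coupling; cohort-level r lands near -0.2
    surgery_rate: Mapping[str, float] = field(
        default_factory=lambda: {"focal": 52 / 65, "nonfocal": 11 / 36}
    )
    seizure_free_rate: Mapping[str, float] = field(
        default_factory=lambda: {"focal": 0.65, "nonfocal": 0.35}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_rois < 1 or self.n_clips < 1:
            raise ValueError("counts must be ≥ 1")
        if not 0.0 <= self.focal_fraction <= 1.0:
            raise ValueError("focal_fraction must lie in [0, 1]")
        lo, hi = self.n_shanks_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid n_shanks_range")
        if self.contacts_per_shank < 1 or self.contact_spacing_mm <= 0:
            raise ValueError("contacts_per_shank ≥ 1 and spacing > 0 required")
        if self.fs_raw < 400.0:
            raise ValueError("fs_raw must be ≥ 400 Hz so downsampling to 200 Hz is a true decimation")
        if self.clip_duration_s < 10.0:
            raise ValueError("clip_duration_s must be ≥ 10 s")
        shank_len = (self.contacts_per_shank - 1) * self.contact_spacing_mm
        if shank_len > 2 * self.head_radius_mm:
            raise ValueError("impossible geometry: shank longer than the head volume")
        if shank_len > self.nonfocal_spread_mm + 2 * self.focal_cluster_radius_mm:
            raise ValueError("impossible geometry: spacing × contacts exceeds the scatter volume")
        if not 0.0 <= self.white_matter_rate < 1.0:
            raise ValueError("white_matter_rate must lie in [0, 1)")
        if self.dispersion_jitter_sigma < 0:
            raise ValueError("dispersion_jitter_sigma must be ≥ 0")

    @classmethod
    def scaled_down(cls, seed: int = 0, **overrides) -> "CohortConfig":
        """Reduced problem size for fast end-to-end runs.

        Same cohort structure (101 patients, 65 focal, 20 clips each) with
        10 s clips at 400 Hz and 3-5 shanks per patient, so a full study
        completes in well under a minute on one CPU.
        """
        params = dict(fs_raw=400.0, clip_duration_s=10.0, n_shanks_range=(3, 5), seed=seed)
        params.update(overrides)
        return cls(**params)

    def power_effect_by_band(self) -> dict[str, float]:
        if isinstance(self.power_effect, Mapping):
            return {b: float(v) for b, v in self.power_effect.items() if v}
        return {b: float(self.power_effect) for b in POWER_EFFECT_BANDS if self.power_effect}

    def coherence_effect_by_band(self) -> dict[str, float]:
        if isinstance(self.coherence_effect, Mapping):
            return {b: float(v) for b, v in self.coherence_effect.items() if v}
        return {b: float(self.coherence_effect) for b in COHERENCE_EFFECT_BANDS if self.coherence_effect}


@dataclass
class GroundTruth:
    patient_id: str
    focality_label: str  # focal | bifocal | multifocal | broad | nonlocalized
    epileptic_contacts: frozenset
    therapy: str = "none"  # resection | ablation | neurostimulation
    outcome: str = "none"  # ILAE 1-2 | ILAE 3-6 | none
    implant_type: str = "SEEG"  # SEEG | ECOG

    @property
    def is_focal(self) -> bool:
        return self.focality_label == "focal"


@dataclass
class ElectrodeSet:
    patient_id: str
    table: pd.DataFrame  # contact, shank, index, x_mm, y_mm, z_mm, tissue, roi

    @property
    def contacts(self) -> list[str]:
        return self.table["contact"].tolist()

    def positions(self) -> np.ndarray:
        return self.table[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# ROI parcellation (deterministic spatial binning)
# ---------------------------------------------------------------------------

def roi_centres(n_rois: int, head_radius_mm: float) -> np.ndarray:
    """Fixed ROI centres inside the head volume, deterministic in n_rois."""
    rng = np.random.default_rng(1234567)  # parcellation constant, not cohort randomness
    pts = []
    while len(pts) < n_rois:
        p = rng.uniform(-1, 1, size=3)
        if np.linalg.norm(p) <= 0.85:
            pts.append(p * head_radius_mm)
    return np.asarray(pts)


def assign_rois(xyz: np.ndarray, centres: np.ndarray) -> np.ndarray:
    d = np.linalg.norm(xyz[:, None, :] - centres[None, :, :], axis=-1)
    return d.argmin(axis=1)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _point_in_ball(rng: np.random.Generator, radius: float, centre=None) -> np.ndarray:
    while True:
        p = rng.uniform(-radius, radius, size=3)
        if np.linalg.norm(p) <= radius:
            return p if centre is None else centre + p


def _shank(target: np.ndarray, direction: np.ndarray, n: int, spacing: float) -> np.ndarray:
    offs = (np.arange(n) - (n - 1) / 2.0)[:, None] * spacing * direction[None, :]
    return target[None, :] + offs


def generate_electrode_geometry(
    config: CohortConfig,
    label: str,
    rng: np.random.Generator,
    patient_id: str = "pt",
    shank_targets: Sequence[np.ndarray] | None = None,
) -> tuple[ElectrodeSet, GroundTruth]:
    """Generate one patient's electrode geometry and ground-truth focality.

    Focal patients get shank targets within ``focal_cluster_radius_mm`` of a
    seed point and epileptic contacts within that radius. Non-focal subtypes:
    bifocal = two mirrored clusters, multifocal = three clusters, broad = one
    wide cluster, nonlocalized = scattered contacts with a diffuse random
    epileptic subset. ``shank_targets`` overrides target placement (used by
    the atlas population builder to guarantee ROI coverage).
    """
    if label not in FOCALITY_LABELS:
        raise ValueError(f"unknown focality label {label!r}")
    centres = roi_centres(config.n_rois, config.head_radius_mm)
    n_shanks = int(rng.integers(config.n_shanks_range[0], config.n_shanks_range[1] + 1))
    r_focal = config.focal_cluster_radius_mm
    r_spread = config.nonfocal_spread_mm / 2.0
    inner = 0.6 * config.head_radius_mm

    cluster_centres: list[np.ndarray]
    if label == "focal":
        cluster_centres = [_point_in_ball(rng, inner)]
        target_radius = r_focal
    elif label == "bifocal":
        c = _point_in_ball(rng, inner)
        cluster_centres = [c, c * np.array([-1.0, 1.0, 1.0])]  # mirrored across midline
        target_radius = r_focal
    elif label == "multifocal":
        cluster_centres = [_point_in_ball(rng, inner) for _ in range(3)]
        target_radius = r_focal
    else:  # broad, nonlocalized
        cluster_centres = [_point_in_ball(rng, 0.3 * config.head_radius_mm)]
        target_radius = r_spread

    jitter = float(np.exp(rng.normal(0.0, config.dispersion_jitter_sigma)))
    target_radius = target_radius * jitter

    rows = []
    for s in range(n_shanks):
        if shank_targets is not None:
            target = np.asarray(shank_targets[s % len(shank_targets)], dtype=float)
        else:
            centre = cluster_centres[s % len(cluster_centres)]
            target = _point_in_ball(rng, target_radius, centre)
        direction = _random_unit(rng)
        pts = _shank(target, direction, config.contacts_per_shank, config.contact_spacing_mm)
        for k, p in enumerate(pts):
            rows.append(
                {
                    "contact": f"{patient_id}_S{s:02d}C{k:02d}",
                    "shank": f"S{s:02d}",
                    "index": k,
                    "x_mm": p[0],
                    "y_mm": p[1],
                    "z_mm": p[2],
                }
            )
    table = pd.DataFrame(rows)
    xyz = table[["x_mm", "y_mm", "z_mm"]].to_numpy()
    table["roi"] = [f"roi{r:02d}" for r in assign_rois(xyz, centres)]
    white = rng.random(len(table)) < config.white_matter_rate
    table["tissue"] = np.where(white, "white", "gray")
    table = table[["contact", "shank", "index", "x_mm", "y_mm", "z_mm", "tissue", "roi"]]

    # ground-truth epileptic contacts
    if label == "nonlocalized":
        mask = rng.random(len(table)) < 0.3
        if not mask.any():
            mask[rng.integers(len(table))] = True
    elif label == "broad":
        c = cluster_centres[0]
        mask = np.linalg.norm(xyz - c, axis=1) <= r_spread
    else:
        mask = np.zeros(len(table), dtype=bool)
        for c in cluster_centres:
            mask |= np.linalg.norm(xyz - c, axis=1) <= r_focal
        if label == "focal" and not mask.any():
            # guarantee one spatial cluster: claim the shank nearest the seed
            d = np.linalg.norm(xyz - cluster_centres[0], axis=1)
            mask = table["shank"] == table["shank"].iloc[int(d.argmin())]
    epileptic = frozenset(table.loc[mask, "contact"])

    truth = GroundTruth(patient_id=patient_id, focality_label=label, epileptic_contacts=epileptic)
    return ElectrodeSet(patient_id=patient_id, table=table), truth


# ---------------------------------------------------------------------------
# Null calibration of the signal model
# ---------------------------------------------------------------------------

@dataclass
class _NullStats:
    rel_mean: dict[str, float]
    rel_sd: dict[str, float]
    band_power: dict[str, float]  # absolute band power of bipolar channels
    total_power: float
    coh_mean: dict[str, float]
    coh_sd: dict[str, float]


_NULL_CACHE: dict[tuple, _NullStats] = {}


def _null_stats(config: CohortConfig) -> _NullStats:
    """Numerically estimated null feature statistics of the generator.

    Simulates a handful of background-only bipolar clips through the exact
    feature pipeline and summarizes band relative power and coherence. Used
    to convert the configured Z-shift effects into injection amplitudes.
    Cached per (fs_raw, clip_duration) — geometry does not enter.
    """
    key = (round(config.fs_raw, 3), round(config.clip_duration_s, 3))
    if key in _NULL_CACHE:
        return _NULL_CACHE[key]
    rng = np.random.default_rng(987654321)  # calibration constant
    n_contacts = 16
    n_samples = int(round(config.clip_duration_s * config.fs_raw))
    rels, cohs, totals, bands_abs = [], [], [], []
    for _ in range(6):
        raw = _background(n_contacts, n_samples, config.fs_raw, rng)
        bipolar = raw[:-1] - raw[1:]
        clip = preprocess_clip(bipolar, config.fs_raw)
        f, psd = sp_signal.welch(clip, fs=200.0, window="hamming", nperseg=400, noverlap=200, axis=-1)
        df = f[1] - f[0]
        tot = psd[:, (f >= 0.5) & (f < 80.0)].sum(-1) * df
        totals.extend(tot.tolist())
        rel_rows, abs_rows = {}, {}
        for b in CANONICAL_BANDS:
            bp = psd[:, (f >= b.lo) & (f < b.hi)].sum(-1) * df
            rel_rows[b.name] = bp / tot
            abs_rows[b.name] = bp
        rels.append(rel_rows)
        bands_abs.append(abs_rows)
        from .signal_processing import magnitude_squared_coherence

        _, msc = magnitude_squared_coherence(clip)
        cohs.append(msc)
    rel_mean, rel_sd, band_power = {}, {}, {}
    for b in CANONICAL_BANDS:
        vals = np.concatenate([r[b.name] for r in rels])
        rel_mean[b.name] = float(vals.mean())
        rel_sd[b.name] = float(vals.std(ddof=1))
        band_power[b.name] = float(np.concatenate([r[b.name] for r in bands_abs]).mean())
    coh_all = np.concatenate(cohs, axis=0)
    coh_mean = {name: float(coh_all[:, i].mean()) for i, name in enumerate(BAND_NAMES)}
    coh_sd = {name: float(coh_all[:, i].std(ddof=1)) for i, name in enumerate(BAND_NAMES)}
    stats = _NullStats(
        rel_mean=rel_mean,
        rel_sd=rel_sd,
        band_power=band_power,
        total_power=float(np.mean(totals)),
        coh_mean=coh_mean,
        coh_sd=coh_sd,
    )
    _NULL_CACHE[key] = stats
    return stats


def _spectral_noise(
    shape: tuple[int, ...],
    n_samples: int,
    fs: float,
    rng: np.random.Generator,
    envelope: np.ndarray,
) -> np.ndarray:
    """Gaussian noise with amplitude spectrum ∝ ``envelope``, unit variance.

    Generated directly in the frequency domain (complex Gaussian bins on the
    envelope's support, single inverse rFFT) — equivalent in law to filtering
    white noise, at half the transform cost. The envelope is scaled so the
    time-domain variance is 1 in expectation; draws are float32 (synthesis
    precision is far below the feature estimators' statistical noise).
    """
    n_freqs = n_samples // 2 + 1
    support = np.flatnonzero(envelope)
    # E[var] = (4 / n²) Σ env² for interior bins → rescale to unit variance
    scale = n_samples / (2.0 * np.sqrt(np.sum(envelope[support] ** 2)))
    vals = rng.standard_normal(shape + (support.size, 2), dtype=np.float32)
    spec = np.zeros(shape + (n_freqs,), dtype=np.complex64)
    env = (scale * envelope[support]).astype(np.float32)
    spec[..., support] = (vals[..., 0] + 1j * vals[..., 1]) * env
    return np.fft.irfft(spec, n=n_samples, axis=-1)


def _band_envelope(n_samples: int, fs: float, band: tuple[float, float]) -> np.ndarray:
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    lo = max(band[0], 0.1)
    hi = min(band[1], 0.49 * fs)
    return ((freqs >= lo) & (freqs < hi)).astype(float)


def _band_limited_noise(
    n_ch: int, n_samples: int, band: tuple[float, float], fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance (in expectation) noise confined to ``band``."""
    return _spectral_noise((n_ch,), n_samples, fs, rng, _band_envelope(n_samples, fs, band))


#: background spectral support stops here — the analysis band-passes at 80 Hz,
#: so content far above it would be discarded by the pipeline anyway
_BACKGROUND_F_MAX = 95.0


def _background(n_ch: int, n_samples: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """1/f-shaped background plus an alpha-band component, ~unit variance."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    nz = (freqs > 0) & (freqs <= _BACKGROUND_F_MAX)
    shape[nz] = 1.0 / np.sqrt(np.maximum(freqs[nz], 1.0))  # flat below 1 Hz, 1/f above
    pink = _spectral_noise((n_ch,), n_samples, fs, rng, shape)
    alpha = _band_limited_noise(n_ch, n_samples, (8.0, 12.0), fs, rng)
    out = pink
    out += np.float32(0.35) * alpha
    out /= np.float32(np.sqrt(1.0 + 0.35**2))
    return out


def synthesize_clip_batch(
    electrodes: ElectrodeSet,
    truth: GroundTruth,
    config: CohortConfig,
    rng: np.random.Generator,
    n_clips: int,
) -> np.ndarray:
    """Raw clips for one patient: (n_clips, n_contacts, clip_duration_s × fs_raw).

    Every contact carries the colored-noise background scaled by a random
    per-channel gain (log-normal, emulating electrode impedance variation).
    Epileptic contacts additionally receive, per configured band, independent
    band-limited noise sized so the *bipolar* relative band power shifts by
    about ``power_effect`` null SDs, and a shared band-limited source entering
    with alternating sign along the shank sized so epileptic bipolar pairs
    reach a coherence about ``coherence_effect`` null SDs above the null mean.
    """
    table = electrodes.table
    n_contacts = len(table)
    if n_contacts < 2:
        raise ValueError("need at least two contacts to synthesize a clip")
    n_samples = int(round(config.clip_duration_s * config.fs_raw))
    fs = config.fs_raw
    base_scale = 50.0  # µV-like overall scale; features are scale-invariant
    gains = np.exp(rng.normal(0.0, 0.2, size=(n_clips, n_contacts, 1))).astype(np.float32)
    bg = _background(n_clips * n_contacts, n_samples, fs, rng).reshape(
        n_clips, n_contacts, n_samples
    )
    x = np.float32(base_scale) * gains * bg

    epileptic = np.fromiter((c in truth.epileptic_contacts for c in table["contact"]), bool, n_contacts)
    if not epileptic.any():
        return x

    stats = _null_stats(config)
    scale2 = base_scale**2  # null stats are computed at unit background scale
    n_ep = int(epileptic.sum())

    # coherent-source powers first: they also add band power, which the
    # relative-power solve must account for
    coh_fx = config.coherence_effect_by_band()
    source_var: dict[str, float] = {}
    for band, eff in coh_fx.items():
        target = float(np.clip(stats.coh_mean[band] + eff * stats.coh_sd[band], 0.0, 0.95))
        root = np.sqrt(target)
        # MSC between two channels sharing power A over background P: (A/(P+A))²
        source_var[band] = stats.band_power[band] * root / (1.0 - root)
    a_tot = sum(source_var.values())

    power_fx = config.power_effect_by_band()
    if power_fx:
        # joint solve: injected absolute powers Δ_k (bipolar scale) giving
        # target relative powers t_k, given total power T + ΣΔ + Σsource
        t = {
            band: float(np.clip(stats.rel_mean[band] + eff * stats.rel_sd[band], 0.0, 0.95))
            for band, eff in power_fx.items()
        }
        sum_t = sum(t.values())
        if sum_t >= 0.98:
            raise ValueError("power_effect targets infeasible: relative powers would exceed 1")
        T = stats.total_power
        sum_ba = sum(stats.band_power[b] + source_var.get(b, 0.0) for b in t)
        S = max((sum_t * (T + a_tot) - sum_ba) / (1.0 - sum_t), 0.0)
        for band, target in t.items():
            delta = target * (T + a_tot + S) - stats.band_power[band] - source_var.get(band, 0.0)
            # bipolar channel = difference of two contacts with independent
            # injections → per-contact variance is half the bipolar target
            contact_var = scale2 * max(delta, 0.0) / 2.0
            if contact_var <= 0:
                continue
            noise = _spectral_noise(
                (n_clips, n_ep), n_samples, fs, rng, _band_envelope(n_samples, fs, _BAND_RANGES[band])
            )
            x[:, epileptic] += np.float32(np.sqrt(contact_var)) * noise

    if source_var:
        # alternating sign along each shank → adjacent bipolar pairs keep ±s
        sign = np.where(table["index"].to_numpy() % 2 == 0, 1.0, -1.0)
        for band, var in source_var.items():
            if var <= 0:
                continue
            s = _spectral_noise(
                (n_clips,), n_samples, fs, rng, _band_envelope(n_samples, fs, _BAND_RANGES[band])
            )
            amp = np.float32(0.5 * np.sqrt(scale2 * var)) * sign[epileptic].astype(np.float32)
            x[:, epileptic] += amp[None, :, None] * s[:, None, :]
    return x


def synthesize_clip(
    electrodes: ElectrodeSet,
    truth: GroundTruth,
    config: CohortConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One raw multichannel clip: (n_contacts, clip_duration_s × fs_raw)."""
    return synthesize_clip_batch(electrodes, truth, config, rng, 1)[0]


def synthesize_clips(
    electrodes: ElectrodeSet,
    truth: GroundTruth,
    config: CohortConfig,
    rng: np.random.Generator,
) -> Iterator[np.ndarray]:
    yield from synthesize_clip_batch(electrodes, truth, config, rng, config.n_clips)


# ---------------------------------------------------------------------------
# Atlas population
# ---------------------------------------------------------------------------

def generate_atlas_population(
    config: CohortConfig,
    n_subjects: int,
    rng: np.random.Generator,
    min_channels_per_roi: int = 5,
    n_clips: int | None = None,
) -> list[tuple[ElectrodeSet, GroundTruth]]:
    """Generate the normal (atlas) population: no injected abnormality.

    Shank targets cycle deterministically through the ROI centres so that
    every ROI accrues bipolar channels; raises if any ROI ends up with fewer
    than ``min_channels_per_roi`` grey-matter bipolar channels across the
    population.
    """
    centres = roi_centres(config.n_rois, config.head_radius_mm)
    null_cfg = replace(
        config,
        power_effect=0.0,
        coherence_effect=0.0,
        n_clips=n_clips if n_clips is not None else config.n_clips,
    )
    subjects = []
    roi_counts: dict[str, int] = {f"roi{r:02d}": 0 for r in range(config.n_rois)}
    offset = 0
    for s in range(n_subjects):
        n_shanks = int(rng.integers(config.n_shanks_range[0], config.n_shanks_range[1] + 1))
        targets = [
            centres[(offset + j) % len(centres)] + _point_in_ball(rng, 8.0) for j in range(n_shanks)
        ]
        offset += n_shanks
        es, truth = generate_electrode_geometry(
            null_cfg, "broad", rng, patient_id=f"atlas{s:03d}", shank_targets=targets
        )
        # atlas subjects are "normal": no epileptic contacts
        truth = GroundTruth(
            patient_id=truth.patient_id, focality_label="broad", epileptic_contacts=frozenset()
        )
        montage = make_bipolar_montage(es.table)
        for roi, cnt in montage["roi"].value_counts().items():
            roi_counts[roi] = roi_counts.get(roi, 0) + int(cnt)
        subjects.append((es, truth))
    uncovered = sorted(r for r, c in roi_counts.items() if c < min_channels_per_roi)
    if uncovered:
        raise ValueError(
            f"atlas population leaves ROIs under-covered (<{min_channels_per_roi} "
            f"grey bipolar channels): {uncovered}"
        )
    return subjects


# ---------------------------------------------------------------------------
# Clinical covariates
# ---------------------------------------------------------------------------

def assign_clinical_covariates(
    truth: GroundTruth,
    config: CohortConfig,
    rng: np.random.Generator,
    implant_sd_z: float = 0.0,
) -> GroundTruth:
    """Fill therapy, outcome and implant type on a ground-truth record.

    ``implant_sd_z`` is the patient's implant dispersion standardized within
    class; it is consumed by :func:`draw_five_sense`, not here, but kept in
    the signature order for symmetry of the covariate stage.
    """
    cls = "focal" if truth.is_focal else "nonfocal"
    if rng.random() < config.surgery_rate[cls]:
        therapy = "resection" if rng.random() < 0.55 else "ablation"
        outcome = "ILAE 1-2" if rng.random() < config.seizure_free_rate[cls] else "ILAE 3-6"
    else:
        therapy, outcome = "neurostimulation", "none"
    implant_type = "ECOG" if rng.random() < (0.40 if cls == "focal" else 0.22) else "SEEG"
    return GroundTruth(
        patient_id=truth.patient_id,
        focality_label=truth.focality_label,
        epileptic_contacts=truth.epileptic_contacts,
        therapy=therapy,
        outcome=outcome,
        implant_type=implant_type,
    )


def draw_five_sense(
    truth: GroundTruth,
    config: CohortConfig,
    rng: np.random.Generator,
    implant_sd_z: float = 0.0,
) -> float:
    """Class-conditional pre-implant focality score, coupled to dispersion.

    score = class mean + ρ·σ·(−z_SD) + sqrt(1−ρ²)·σ·ε, clipped to [0, 1]:
    patients with more dispersed implants tend to have lower pre-implant
    probability of focality (weak negative correlation).
    """
    cls = "focal" if truth.is_focal else "nonfocal"
    mu, sd = config.five_sense_params[cls]
    rho = abs(config.implant_score_corr)
    eps = rng.normal()
    score = mu + rho * sd * (-implant_sd_z) + np.sqrt(max(1 - rho**2, 0.0)) * sd * eps
    return float(np.clip(score, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class SyntheticPatient:
    electrodes: ElectrodeSet
    truth: GroundTruth
    five_sense: float
    signal_seed: tuple  # substream key for deterministic clip regeneration


@dataclass
class SyntheticCohort:
    config: CohortConfig
    patients: list[SyntheticPatient]

    def cohort_table(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            t = p.truth
            rows.append(
                {
                    "patient_id": t.patient_id,
                    "five_sense": p.five_sense,
                    "focality_label": "focal" if t.is_focal else "nonfocal",
                    "subtype": t.focality_label,
                    "therapy": t.therapy,
                    "outcome": t.outcome,
                    "implant_type": t.implant_type,
                }
            )
        return pd.DataFrame(rows)

    def clips(self, patient: SyntheticPatient) -> Iterator[np.ndarray]:
        """Deterministically (re)generate a patient's raw clips."""
        yield from self.clip_batch(patient)

    def clip_batch(self, patient: SyntheticPatient) -> np.ndarray:
        """All of a patient's raw clips as one (n_clips, n_contacts, n) array."""
        rng = np.random.default_rng(patient.signal_seed)
        return synthesize_clip_batch(
            patient.electrodes, patient.truth, self.config, rng, self.config.n_clips
        )


def patient_rng(seed: int, index: int, stream: int = 0) -> np.random.Generator:
    """Independent substream for patient ``index`` (stable under cohort size)."""
    return np.random.default_rng((seed, index, stream))


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate geometry, covariates and clip substream keys for a cohort.

    Clips themselves are not materialized (20 one-minute multichannel clips
    per patient are large); :meth:`SyntheticCohort.clips` regenerates them
    deterministically from the per-patient substream.
    """
    n_focal = int(round(config.n_patients * config.focal_fraction))
    subtype_rng = np.random.default_rng((config.seed, 10**6))
    labels = ["focal"] * n_focal + [
        str(subtype_rng.choice(NONFOCAL_SUBTYPES, p=[0.35, 0.30, 0.20, 0.15]))
        for _ in range(config.n_patients - n_focal)
    ]

    prelim = []
    for i, label in enumerate(labels):
        rng = patient_rng(config.seed, i, 0)
        es, truth = generate_electrode_geometry(config, label, rng, patient_id=f"pt{i:03d}")
        gray = es.table[es.table["tissue"] == "gray"]
        sd = standard_distance(gray[["x_mm", "y_mm", "z_mm"]].to_numpy())
        prelim.append((i, es, truth, sd))

    # standardize implant SD within class for the score coupling
    sds = np.array([p[3] for p in prelim])
    is_focal = np.array([p[2].is_focal for p in prelim])
    z = np.zeros(len(prelim))
    for mask in (is_focal, ~is_focal):
        if mask.sum() >= 2 and sds[mask].std() > 0:
            z[mask] = (sds[mask] - sds[mask].mean()) / sds[mask].std()

    patients = []
    for (i, es, truth, _sd), sd_z in zip(prelim, z):
        rng_cov = patient_rng(config.seed, i, 1)
        truth = assign_clinical_covariates(truth, config, rng_cov, implant_sd_z=sd_z)
        score = draw_five_sense(truth, config, rng_cov, implant_sd_z=sd_z)
        patients.append(
            SyntheticPatient(
                electrodes=es,
                truth=truth,
                five_sense=score,
                signal_seed=(config.seed, i, 2),
            )
        )
    return SyntheticCohort(config=config, patients=patients)


def atlas_feature_population(
    config: CohortConfig,
    n_subjects: int,
    rng: np.random.Generator,
    n_clips: int | None = None,
) -> dict:
    """Generate and featurize the atlas population (no abnormality injected)."""
    null_cfg = replace(
        config,
        power_effect=0.0,
        coherence_effect=0.0,
        n_clips=n_clips if n_clips is not None else config.n_clips,
    )
    population = {}
    for es, truth in generate_atlas_population(config, n_subjects, rng, n_clips=null_cfg.n_clips):
        montage = make_bipolar_montage(es.table)
        if len(montage) < 2:
            continue
        raw = synthesize_clip_batch(es, truth, null_cfg, rng, null_cfg.n_clips)
        clips = preprocess_clip(apply_bipolar(raw, es.contacts, montage), null_cfg.fs_raw)
        population[es.patient_id] = compute_clip_features(
            clips, montage["channel"], montage["roi"]
        )
    return population
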