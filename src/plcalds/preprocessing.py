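"""Sliding-window feature extraction, peak-flow binarisation and episode annotation.

Raw subdaily sensor streams are turned into a nonnegative feature tensor
``V[f, t]`` with one frame per 8-day sliding window (1-day step by default).
Per channel, a frame carries either the plain window average
(``feature_set="average_only"``) or a rich set of statistical and spectral
features, the spectral ones computed on the band energies of a Daubechies
discrete wavelet decomposition of the window.

Daily peak expiratory flow is binarised at the personal median ("worsening of
peak flow": 1 below the median, 0 at or above). Binary daily symptom series are
segmented into episodes with onset (first day), transient (interior days) and
offset (last day) temporal states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pywt
from scipy import stats as _stats
from statsmodels.tsa.stattools import acf as _acf

from .synthetic_cohort import (
    POLLUTANT_CHANNELS,
    ConfigurationError,
    ParticipantRecord,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: temporal states of a symptom episode, in mask-axis order
STATE_NAMES = ("onset", "transient", "offset")

RICH_FEATURES = (
    "average", "median", "variance", "maximum", "minimum",
    "kurtosis", "skewness",
    "spectral_flux", "spectral_centroid", "spectral_energy", "spectral_entropy",
)

#: channels used by the "pollutants_only" sensor subset
POLLUTANTS_ONLY = POLLUTANT_CHANNELS + ("RH",)


@dataclass
class WindowSpec:
    """Sliding-window geometry: 8-day windows advanced by 1 day by default."""

    window_days: int = 8
    step_days: int = 1

    def __post_init__(self) -> None:
        if self.window_days < 1 or self.step_days < 1:
            raise ConfigurationError("window_days and step_days must be >= 1")


@dataclass
class EpisodeAnnotation:
    """One contiguous symptom episode on an integer day axis."""

    symptom: int
    onset_day: int
    transient_days: list[int]
    offset_day: int


@dataclass
class FeatureTensor:
    """Nonnegative spectral-feature frames V[f, t] with frame energies P(t)."""

    values: np.ndarray  # F x T, >= 0
    feature_names: list[str]
    frame_dates: list  # date of each frame's end day
    frame_end_days: np.ndarray  # integer index of each frame's end day
    dropped_dates: list = field(default_factory=list)

    @property
    def frame_energy(self) -> np.ndarray:
        return self.values.sum(axis=0)

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_names,
                            columns=[str(d) for d in self.frame_dates])


# ---------------------------------------------------------------------------
# Daily biomarkers and episode annotation
# ---------------------------------------------------------------------------

def binarise_peak_flow(series: pd.Series | np.ndarray) -> pd.Series:
    """Binarise daily peak flow at the personal median.

    1 where the value is strictly below the personal median, 0 at or above;
    missing days stay missing.
    """
    s = pd.Series(series, dtype=float, copy=True)
    if s.notna().sum() == 0:
        raise ValidationError("peak-flow series has no observed values")
    median = s.median(skipna=True)
    out = (s < median).astype(float)
    out[s.isna()] = np.nan
    return out


def annotate_temporal_states(binary: Sequence[float] | np.ndarray,
                             symptom: int = 0) -> list[EpisodeAnnotation]:
    """Segment a binary daily series into episodes.

    Each maximal run of ones becomes one episode with onset = first day,
    offset = last day and transients = strictly interior days. Missing values
    are treated as zeros (no symptom reported).
    """
    arr = np.nan_to_num(np.asarray(binary, dtype=float), nan=0.0).astype(bool)
    episodes: list[EpisodeAnnotation] = []
    t = 0
    n = len(arr)
    while t < n:
        if arr[t]:
            start = t
            while t < n and arr[t]:
                t += 1
            end = t - 1
            episodes.append(EpisodeAnnotation(
                symptom=symptom,
                onset_day=start,
                transient_days=list(range(start + 1, end)),
                offset_day=end,
            ))
        else:
            t += 1
    return episodes


def expand_annotation_masks(annotations: Sequence[EpisodeAnnotation],
                            n_symptoms: int, n_days: int) -> np.ndarray:
    """Expand episode annotations into an S x 3 x T binary mask tensor.

    Mask axis order is (onset, transient, offset); a single-day episode sets
    both its onset and offset cells.
    """
    masks = np.zeros((n_symptoms, len(STATE_NAMES), n_days), dtype=int)
    for ep in annotations:
        if not (0 <= ep.onset_day <= ep.offset_day < n_days):
            raise ValidationError("episode annotation outside the day axis")
        if ep.symptom < 0 or ep.symptom >= n_symptoms:
            raise ValidationError("symptom index outside the symptom axis")
        masks[ep.symptom, 0, ep.onset_day] = 1
        for d in ep.transient_days:
            masks[ep.symptom, 1, d] = 1
        masks[ep.symptom, 2, ep.offset_day] = 1
    return masks


# ---------------------------------------------------------------------------
# Window-size estimation from peak-flow autocorrelation
# ---------------------------------------------------------------------------

def estimate_window_lag(series_by_participant: Mapping[str, Sequence[float]],
                        max_lag: int = 30) -> tuple[dict[str, int], int, float]:
    """Estimate the sliding-window size from peak-flow autocorrelations.

    Per participant the lag is the smallest positive lag at which the sample
    autocorrelation first drops inside the 95% significance band
    (|r| < 1.96/sqrt(N)); the cohort window is the rounded median of the
    per-participant lags, with the mean also returned.
    """
    lags: dict[str, int] = {}
    for pid, series in series_by_participant.items():
        x = np.asarray(pd.Series(series).dropna(), dtype=float)
        if len(x) < 2 * max_lag:
            logger.warning("participant %s series too short for lag estimation; skipped", pid)
            continue
        band = 1.96 / np.sqrt(len(x))
        r = _acf(x, nlags=max_lag, fft=True)
        inside = np.abs(r[1:]) < band
        lags[pid] = int(np.argmax(inside) + 1) if inside.any() else max_lag
    if not lags:
        raise ValidationError("no participant had a usable series")
    values = np.array(list(lags.values()), dtype=float)
    return lags, int(round(float(np.median(values)))), float(values.mean())


# ---------------------------------------------------------------------------
# Wavelet decomposition and window features
# ---------------------------------------------------------------------------

def dwt_decompose(samples: Sequence[float] | np.ndarray,
                  wavelet_order: int = 2, levels: int = 3) -> list[np.ndarray]:
    """Multilevel Daubechies DWT of a window, coarse band first.

    Uses periodization padding so the transform is orthogonal (energy
    preserving, perfectly invertible) on padding-free lengths. If the window is
    too short for the requested depth the level count falls back with a logged
    warning.
    """
    x = np.asarray(samples, dtype=float)
    wavelet = pywt.Wavelet(f"db{wavelet_order}")
    max_level = pywt.dwt_max_level(len(x), wavelet.dec_len)
    use = min(levels, max(max_level, 1))
    if use < levels and (len(x), levels) not in _short_window_warned:
        _short_window_warned.add((len(x), levels))
        logger.warning("window of %d samples supports only %d DWT level(s) (requested %d)",
                       len(x), use, levels)
    return pywt.wavedec(x, wavelet, mode="periodization", level=use)


_short_window_warned: set[tuple[int, int]] = set()


def _band_energies(samples: np.ndarray, wavelet_order: int, levels: int) -> np.ndarray:
    # mean-removed: spectral features describe fluctuation across scales,
    # the window level is already carried by the average/median features
    coeffs = dwt_decompose(samples - samples.mean(), wavelet_order, levels)
    return np.array([float(np.sum(c ** 2)) for c in coeffs])


def extract_window_features(window_by_channel: Mapping[str, np.ndarray],
                            feature_set: str = "rich",
                            prev_band_energies: Mapping[str, np.ndarray] | None = None,
                            wavelet_order: int = 2, levels: int = 3,
                            ) -> tuple[np.ndarray, list[str], dict[str, np.ndarray]]:
    """Compute the raw (unshifted) feature vector of one window.

    ``window_by_channel`` maps channel name to its non-missing samples inside
    the window (empty array for an invalid channel, whose features become 0).
    Spectral features are computed on DWT band energies, bands ordered coarse
    to fine; spectral flux compares the square-root band energies against the
    previous frame of the same channel. Returns the feature vector, its stable
    (channel, feature) names, and this frame's band energies for flux chaining.
    """
    if feature_set not in ("rich", "average_only"):
        raise ConfigurationError(f"unknown feature_set {feature_set!r}")
    values: list[float] = []
    names: list[str] = []
    band_energies: dict[str, np.ndarray] = {}
    for ch, samples in window_by_channel.items():
        x = np.asarray(samples, dtype=float)
        x = x[np.isfinite(x)]
        if feature_set == "average_only":
            values.append(float(x.mean()) if x.size else 0.0)
            names.append(f"{ch}:average")
            continue
        if x.size == 0:
            values.extend([0.0] * len(RICH_FEATURES))
            names.extend(f"{ch}:{f}" for f in RICH_FEATURES)
            band_energies[ch] = np.zeros(levels + 1)
            continue
        var = float(np.var(x))
        if var > 0:
            skew = float(_stats.skew(x))
            kurt = float(_stats.kurtosis(x))
        else:  # constant window: moments defined as 0 by convention
            skew, kurt = 0.0, 0.0
        eb = _band_energies(x, wavelet_order, levels)
        total = eb.sum()
        if prev_band_energies is not None and ch in prev_band_energies:
            prev = np.asarray(prev_band_energies[ch], dtype=float)
            m = min(len(prev), len(eb))
            flux = float(np.sum((np.sqrt(eb[:m]) - np.sqrt(prev[:m])) ** 2))
        else:
            flux = 0.0
        if total > 0:
            p = eb / total
            centroid = float(np.sum(np.arange(len(eb)) * p))
            entropy = float(-np.sum(p[p > 0] * np.log(p[p > 0])))
        else:
            centroid, entropy = 0.0, 0.0
        values.extend([
            float(x.mean()), float(np.median(x)), var, float(x.max()), float(x.min()),
            kurt, skew, flux, centroid, float(total), entropy,
        ])
        names.extend(f"{ch}:{f}" for f in RICH_FEATURES)
        band_energies[ch] = eb
    return np.asarray(values), names, band_energies


@dataclass
class NonnegativeScaler:
    """Rectified on/off deviation coding of the raw features.

    Each raw feature row is standardised against its training-split median and
    standard deviation and split into two nonnegative rows: the rectified
    positive deviation (``:+``, the feature is unusually high) and the
    rectified negative deviation (``:-``, unusually low). This serves two
    purposes at once. First, the decomposition requires a nonnegative tensor
    while half of the raw features are signed. Second — and more importantly —
    an energy-based decomposition can only key on the *presence* of mass, so a
    biomarker that expresses itself by dropping (peak flow during an episode)
    would otherwise be invisible; the off-row turns that deficit into positive
    energy. Standardising per row also stops large-unit channels (pollutant
    energies) from dominating the divergence that the decomposition minimises.
    """

    median: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, raw: np.ndarray, feature_names: list[str],
            train_mask: np.ndarray) -> "NonnegativeScaler":
        train = raw[:, train_mask] if train_mask.any() else raw
        sd = train.std(axis=1)
        return cls(median=np.median(train, axis=1), scale=np.where(sd > 0, sd, 1.0))

    def transform(self, raw: np.ndarray) -> np.ndarray:
        dev = (raw - self.median[:, None]) / self.scale[:, None]
        return np.vstack([np.clip(dev, 0.0, None), np.clip(-dev, 0.0, None)])

    @staticmethod
    def output_names(feature_names: list[str]) -> list[str]:
        return [f"{n}:+" for n in feature_names] + [f"{n}:-" for n in feature_names]


def _window_samples(record: ParticipantRecord, channels: Sequence[str],
                    start_day: int, end_day: int) -> dict[str, np.ndarray]:
    spd = record.samples_per_day
    out = {}
    for ch in channels:
        if ch == "peak_flow":
            vals = record.peak_flow.iloc[start_day:end_day + 1].to_numpy(dtype=float)
        else:
            vals = record.sensor_streams[ch].iloc[start_day * spd:(end_day + 1) * spd].to_numpy()
        out[ch] = vals[np.isfinite(vals)]
    return out


def build_feature_tensor(record: ParticipantRecord,
                         spec: WindowSpec | None = None,
                         feature_set: str = "rich",
                         sensors_subset: str = "all",
                         train_days: np.ndarray | None = None,
                         wavelet_order: int = 2, levels: int = 3,
                         min_valid_frac: float = 0.5) -> FeatureTensor:
    """Build the nonnegative feature tensor of one participant.

    One frame per window end-day. Sensor subsets: ``"all"`` uses every sensor
    channel plus the daily peak-flow series as an extra channel,
    ``"pollutants_only"`` restricts to {NO, CO, PM1, PM2.5, PM10, RH}, and
    ``"peakflow_only"`` uses the daily peak-flow series as the sole channel.
    A channel is valid in a frame when at least ``min_valid_frac`` of its
    expected samples are present; frames where every channel is invalid are
    dropped (their dates recorded in ``dropped_dates``). ``train_days`` (bool
    per day) selects the frames used to fit the nonnegativity scaling; by
    default all frames are used.
    """
    spec = spec or WindowSpec()
    if record.n_days < spec.window_days:
        raise ValidationError("record shorter than one window")
    if sensors_subset == "all":
        channels = list(record.sensor_streams.columns)
        if record.peak_flow is not None:
            channels.append("peak_flow")
    elif sensors_subset == "pollutants_only":
        channels = [c for c in record.sensor_streams.columns if c in POLLUTANTS_ONLY]
    elif sensors_subset == "peakflow_only":
        if record.peak_flow is None:
            raise ConfigurationError("record has no peak-flow series")
        channels = ["peak_flow"]
    else:
        raise ConfigurationError(f"unknown sensors_subset {sensors_subset!r}")
    if not channels:
        raise ConfigurationError("empty channel subset")

    spd = record.samples_per_day
    expected = {ch: spec.window_days * (1 if ch == "peak_flow" else spd) for ch in channels}

    frames, names, end_days, dropped = [], None, [], []
    prev_bands: dict[str, np.ndarray] | None = None
    for end in range(spec.window_days - 1, record.n_days, spec.step_days):
        start = end - spec.window_days + 1
        windows = _window_samples(record, channels, start, end)
        valid = {ch: len(w) >= min_valid_frac * expected[ch] for ch, w in windows.items()}
        if not any(valid.values()):
            dropped.append(record.dates[end].date())
            prev_bands = None  # flux chain broken across a gap
            continue
        windows = {ch: (w if valid[ch] else np.empty(0)) for ch, w in windows.items()}
        vec, names, bands = extract_window_features(
            windows, feature_set, prev_bands, wavelet_order, levels)
        prev_bands = bands
        frames.append(vec)
        end_days.append(end)

    if not frames:
        raise ValidationError("no valid frames for this participant")
    raw = np.column_stack(frames)
    end_days = np.asarray(end_days)
    if train_days is None:
        train_mask = np.ones(len(end_days), dtype=bool)
    else:
        train_mask = np.asarray(train_days, dtype=bool)[end_days]
    scaler = NonnegativeScaler.fit(raw, names, train_mask)
    values = scaler.transform(raw)
    return FeatureTensor(
        values=values,
        feature_names=NonnegativeScaler.output_names(list(names)),
        frame_dates=[record.dates[d].date() for d in end_days],
        frame_end_days=end_days,
        dropped_dates=dropped,
    )
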