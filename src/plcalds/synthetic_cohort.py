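"""Synthetic cohorts of personal-exposure sensor streams, peak flow and symptom diaries.

The study data behind this framework (106 COPD patients carrying portable
air-quality monitors for up to six months) is not public, so this module
generates cohorts with the statistical structure the method assumes:

* multichannel subdaily sensor streams (pollutants as log-normal AR(1)
  processes, meteorology and activity as Gaussian channels) with whole-day
  contiguous coverage gaps, mimicking participants leaving the device at home;
* episodic symptom diaries in which the probability of an episode starting on
  day *t* increases with the recent pollutant average (lagged coupling);
* daily peak expiratory flow that dips below the personal baseline during
  episodes of the lung-capacity symptom class, so that binarisation at the
  personal median flags those episodes.

It also provides exact model-sampled feature tensors (``sample_from_plca_model``)
for parameter-recovery tests of the decomposition itself.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Channels treated as air pollutants (always nonnegative, right-skewed).
POLLUTANT_CHANNELS = ("NO", "CO", "PM1", "PM2.5", "PM10")

#: Default sensor suite of the personal air monitor.
DEFAULT_CHANNELS = (
    "NO", "CO", "PM1", "PM2.5", "PM10",
    "RH", "temperature", "noise", "accelerometer",
)

#: log-space mean and daily AR(1) parameters per pollutant channel.
_POLLUTANT_PARAMS = {
    "NO": (2.8, 0.5),
    "CO": (-1.0, 0.4),
    "PM1": (1.6, 0.5),
    "PM2.5": (2.1, 0.5),
    "PM10": (2.6, 0.5),
}

SEASONS = ("spring", "summer", "autumn", "winter")

DEFAULT_SYMPTOMS = ("lung_capacity", "exacerbation", "cough", "wheeze")


class ConfigurationError(ValueError):
    """Raised when a cohort configuration is inconsistent."""


class ValidationError(ValueError):
    """Raised when numeric inputs violate their contracts."""


@dataclass
class CohortConfig:
    """Configuration of a synthetic monitoring cohort.

    Parameters
    ----------
    n_participants
        Number of participants to simulate.
    n_days
        Monitoring length in days (16..182; the study monitored up to 182 days
        and the half-month train/test split needs at least one full month).
    channels
        Sensor channel names; must be a subset of :data:`DEFAULT_CHANNELS`.
    samples_per_day
        Subdaily sampling rate of the sensor node.
    coverage_fracs
        Per-participant fraction of days with valid sensor data. ``None``
        spreads coverages evenly over [0.55, 1.0] to emulate the wide coverage
        distribution seen in free-living cohorts.
    episode_rate
        Expected number of symptom onsets per month per symptom class when the
        pollutant level is at its average.
    transient_mean_days
        Mean number of interior (transient) days of an episode.
    coupling_lag_days
        Lag of the pollutant window that drives episode starts.
    coupling_strength
        Log-odds increase of an episode start per standard deviation of the
        lagged pollutant average; 0 decouples symptoms from exposure.
    """

    n_participants: int = 10
    n_days: int = 120
    channels: Sequence[str] = DEFAULT_CHANNELS
    samples_per_day: int = 24
    coverage_fracs: Sequence[float] | None = None
    episode_rate: float = 2.0
    transient_mean_days: float = 3.0
    coupling_lag_days: int = 1
    coupling_strength: float = 1.0
    seed: int = 0
    symptom_names: Sequence[str] = DEFAULT_SYMPTOMS
    start_date: _dt.date = _dt.date(2021, 3, 1)
    peak_flow_baseline_mean: float = 350.0
    peak_flow_baseline_sd: float = 40.0
    peak_flow_drift_sd: float = 15.0
    peak_flow_noise_sd: float = 4.0
    peak_flow_drop_frac: float = 0.15

    def __post_init__(self) -> None:
        if self.n_days < 16 or self.n_days > 182:
            raise ConfigurationError("n_days must be in [16, 182]")
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        unknown = set(self.channels) - set(DEFAULT_CHANNELS)
        if unknown:
            raise ConfigurationError(f"unknown channel name(s): {sorted(unknown)}")
        if self.coverage_fracs is not None:
            fr = np.asarray(self.coverage_fracs, dtype=float)
            if fr.shape != (self.n_participants,):
                raise ConfigurationError("coverage_fracs must have one entry per participant")
            if np.any((fr < 0) | (fr > 1)):
                raise ConfigurationError("coverage fractions must lie in [0, 1]")
        if self.coupling_lag_days < 0:
            raise ConfigurationError("coupling_lag_days must be >= 0")
        if self.coupling_strength < 0:
            raise ConfigurationError("coupling_strength must be >= 0")
        if self.transient_mean_days <= 0:
            raise ConfigurationError("transient_mean_days must be positive")
        if self.samples_per_day < 1:
            raise ConfigurationError("samples_per_day must be >= 1")

    def coverage_for(self, participant_index: int) -> float:
        if self.coverage_fracs is not None:
            return float(self.coverage_fracs[participant_index])
        if self.n_participants == 1:
            return 1.0
        return float(0.55 + 0.45 * participant_index / (self.n_participants - 1))


@dataclass
class ParticipantRecord:
    """All raw data of one participant on a shared day axis."""

    participant_id: str
    dates: pd.DatetimeIndex
    sensor_streams: pd.DataFrame  # (n_days*samples_per_day) x channels, NaN = missing
    samples_per_day: int
    day_valid: np.ndarray  # bool per day: sensors present that day
    season_of_day: np.ndarray  # str per day
    peak_flow: pd.Series | None = None  # daily, positive
    diary: pd.DataFrame | None = None  # n_days x symptom classes, 0/1

    @property
    def n_days(self) -> int:
        return len(self.dates)

    @property
    def coverage(self) -> float:
        return float(np.mean(self.day_valid))


def _rng_for(cfg: CohortConfig, participant_id: str, stream: str) -> np.random.Generator:
    # participant and stream tags keep draws independent and reproducible
    tag = [ord(c) for c in f"{participant_id}/{stream}"]
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, *tag]))


def _season_labels(n_days: int) -> np.ndarray:
    idx = (np.arange(n_days) // 91) % 4
    return np.asarray(SEASONS, dtype=object)[idx]


def _missing_day_mask(n_days: int, coverage: float, rng: np.random.Generator) -> np.ndarray:
    """Whole-day contiguous gaps hitting the requested coverage exactly."""
    n_missing = int(round((1.0 - coverage) * n_days))
    mask = np.zeros(n_days, dtype=bool)
    remaining = n_missing
    while remaining > 0:
        runs = _false_runs(mask)
        start, length = max(runs, key=lambda r: r[1])
        block = min(remaining, int(rng.integers(3, 15)), length)
        offset = int(rng.integers(0, length - block + 1))
        mask[start + offset:start + offset + block] = True
        remaining -= block
    return mask


def _false_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    runs, start = [], None
    for i, m in enumerate(mask):
        if not m and start is None:
            start = i
        elif m and start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, len(mask) - start))
    return runs


def generate_sensor_streams(cfg: CohortConfig, participant_id: str,
                            participant_index: int = 0) -> ParticipantRecord:
    """Simulate the sensor streams of one participant (no diary yet).

    Pollutants are log-normal with a shared plus channel-specific daily AR(1)
    level; meteorology/activity channels are Gaussian. Missing days form
    contiguous gaps reaching the configured coverage within rounding.
    """
    n_days, spd = cfg.n_days, cfg.samples_per_day
    rng = _rng_for(cfg, participant_id, "sensors")
    coverage = cfg.coverage_for(participant_index)
    missing = _missing_day_mask(n_days, coverage, _rng_for(cfg, participant_id, "gaps"))

    # shared daily pollution factor (AR(1)) so pollutant channels co-vary
    phi = 0.8
    common = np.empty(n_days)
    common[0] = rng.normal()
    for t in range(1, n_days):
        common[t] = phi * common[t - 1] + np.sqrt(1 - phi ** 2) * rng.normal()

    dates = pd.date_range(cfg.start_date, periods=n_days, freq="D")
    ts = pd.date_range(cfg.start_date, periods=n_days * spd,
                       freq=pd.Timedelta(days=1) / spd)
    day_of_sample = np.repeat(np.arange(n_days), spd)

    data: dict[str, np.ndarray] = {}
    for ch in cfg.channels:
        own = np.empty(n_days)
        own[0] = rng.normal()
        for t in range(1, n_days):
            own[t] = phi * own[t - 1] + np.sqrt(1 - phi ** 2) * rng.normal()
        if ch in _POLLUTANT_PARAMS:
            mu, sd = _POLLUTANT_PARAMS[ch]
            daily = mu + sd * (0.7 * common + 0.3 * own)
            samples = np.exp(daily[day_of_sample] + 0.25 * rng.normal(size=n_days * spd))
        elif ch == "RH":
            daily = 70.0 + 8.0 * own
            samples = np.clip(daily[day_of_sample] + 3.0 * rng.normal(size=n_days * spd), 1.0, 100.0)
        elif ch == "temperature":
            seasonal = 12.0 + 8.0 * np.sin(2 * np.pi * (np.arange(n_days) - 30) / 365.0)
            daily = seasonal + 2.5 * own
            samples = daily[day_of_sample] + 1.0 * rng.normal(size=n_days * spd)
        elif ch == "noise":
            daily = 55.0 + 5.0 * own
            samples = np.clip(daily[day_of_sample] + 4.0 * rng.normal(size=n_days * spd), 20.0, 110.0)
        elif ch == "accelerometer":
            daily = 1.0 + 0.2 * own
            samples = np.abs(daily[day_of_sample] + 0.3 * rng.normal(size=n_days * spd))
        else:  # pragma: no cover - guarded by config validation
            raise ConfigurationError(f"unknown channel {ch}")
        samples[missing[day_of_sample]] = np.nan
        data[ch] = samples

    streams = pd.DataFrame(data, index=ts)
    return ParticipantRecord(
        participant_id=participant_id,
        dates=dates,
        sensor_streams=streams,
        samples_per_day=spd,
        day_valid=~missing,
        season_of_day=_season_labels(n_days),
    )


def _daily_pollutant_zscore(record: ParticipantRecord) -> np.ndarray:
    """Per-day pollutant average (over pollutant channels), z-scored, 0 on gaps."""
    cols = [c for c in record.sensor_streams.columns if c in POLLUTANT_CHANNELS]
    if not cols:
        return np.zeros(record.n_days)
    sub = record.sensor_streams[cols]
    daily = sub.groupby(np.repeat(np.arange(record.n_days), record.samples_per_day)).mean()
    # average of per-channel z-scores so channels with large scales do not dominate
    z = (daily - daily.mean()) / daily.std().replace(0.0, 1.0)
    out = z.mean(axis=1).to_numpy()
    return np.nan_to_num(out, nan=0.0)


def generate_symptom_diary(record: ParticipantRecord, cfg: CohortConfig) -> ParticipantRecord:
    """Add a symptom diary and peak-flow series to a sensor record.

    Episode starts follow a per-day Bernoulli hazard whose log-odds increase by
    ``coupling_strength`` per standard deviation of the pollutant average over
    the window ``[t - coupling_lag_days, t]``. Episode length is
    ``1 + Poisson(transient_mean_days + 1)`` days, so the mean interior
    (transient) duration is approximately ``transient_mean_days``. Peak flow is
    an AR-free noisy constant depressed by ``peak_flow_drop_frac`` of the
    personal baseline during lung-capacity episodes.
    """
    n_days = record.n_days
    zpoll = _daily_pollutant_zscore(record)
    lag = cfg.coupling_lag_days
    lagged = np.array([zpoll[max(0, t - lag):t + 1].mean() for t in range(n_days)])

    p0 = min(max(cfg.episode_rate / 30.44, 1e-6), 0.5)
    logit0 = np.log(p0 / (1 - p0))
    hazard = 1.0 / (1.0 + np.exp(-(logit0 + cfg.coupling_strength * lagged)))

    diary = np.zeros((n_days, len(cfg.symptom_names)), dtype=int)
    for j, name in enumerate(cfg.symptom_names):
        rng = _rng_for(cfg, record.participant_id, f"diary/{name}")
        t = 0
        while t < n_days:
            if rng.random() < hazard[t]:
                dur = 1 + int(rng.poisson(cfg.transient_mean_days + 1.0))
                diary[t:t + dur, j] = 1
                t += dur + 1  # at least one healthy day between episodes
            else:
                t += 1
    diary_df = pd.DataFrame(diary, index=record.dates, columns=list(cfg.symptom_names))

    rng = _rng_for(cfg, record.participant_id, "peakflow")
    baseline = max(cfg.peak_flow_baseline_mean
                   + cfg.peak_flow_baseline_sd * rng.normal(), 100.0)
    # lung function drifts slowly (airway state persists for days), on top of
    # which sits small day-to-day measurement noise
    phi = 0.9
    drift = np.empty(n_days)
    drift[0] = rng.normal()
    for t in range(1, n_days):
        drift[t] = phi * drift[t - 1] + np.sqrt(1 - phi ** 2) * rng.normal()
    pf = (baseline + cfg.peak_flow_drift_sd * drift
          + cfg.peak_flow_noise_sd * rng.normal(size=n_days))
    if "lung_capacity" in diary_df.columns:
        active = diary_df["lung_capacity"].to_numpy(bool)
        pf[active] -= cfg.peak_flow_drop_frac * baseline
    pf = np.maximum(pf, 50.0)
    peak_flow = pd.Series(pf, index=record.dates, name="peak_flow")

    return dataclasses.replace(record, diary=diary_df, peak_flow=peak_flow)


def generate_cohort(cfg: CohortConfig) -> list[ParticipantRecord]:
    """Generate the full cohort (streams + diaries), deterministic in cfg.seed."""
    cohort = []
    for i in range(cfg.n_participants):
        pid = f"P{i:03d}"
        rec = generate_sensor_streams(cfg, pid, participant_index=i)
        cohort.append(generate_symptom_diary(rec, cfg))
    return cohort


# ---------------------------------------------------------------------------
# Exact sampling from the decomposition model (for recovery tests)
# ---------------------------------------------------------------------------

def sample_from_plca_model(templates: np.ndarray,
                           p_s_given_t: np.ndarray,
                           p_a_given_st: np.ndarray,
                           energies: np.ndarray,
                           n_draws: int = 0,
                           seed: int = 0,
                           p_m_given_st: np.ndarray | None = None) -> np.ndarray:
    """Draw a feature tensor V[f, t] from the latent-component mixture.

    Each frame *t* mixes the dictionary templates with weights
    P(s|t)·P(a|s,t) (and P(m|s,t) for the seasonal model) and is scaled by the
    frame energy P(t). With ``n_draws == 0`` the exact expectation is returned;
    otherwise each frame is ``n_draws`` multinomial draws from the mixture,
    rescaled so the column sum equals P(t).
    """
    templates = np.asarray(templates, float)
    p_s_given_t = np.asarray(p_s_given_t, float)
    p_a_given_st = np.asarray(p_a_given_st, float)
    energies = np.asarray(energies, float)
    if np.any(energies < 0):
        raise ValidationError("frame energies must be nonnegative")

    if p_m_given_st is None:
        _check_norm(templates, axis=0, name="P(f|s,a)")
        _check_norm(p_s_given_t, axis=0, name="P(s|t)")
        _check_norm(p_a_given_st, axis=0, name="P(a|s,t)")
        weights = np.einsum("st,ast->sat", p_s_given_t, p_a_given_st)
        mix = np.einsum("fsa,sat->ft", templates, weights)
    else:
        p_m_given_st = np.asarray(p_m_given_st, float)
        _check_norm(templates, axis=0, name="P(f|m,s,a)")
        _check_norm(p_s_given_t, axis=0, name="P(s|t)")
        _check_norm(p_a_given_st, axis=0, name="P(a|s,t)")
        _check_norm(p_m_given_st, axis=0, name="P(m|s,t)")
        weights = np.einsum("st,ast,mst->msat", p_s_given_t, p_a_given_st, p_m_given_st)
        mix = np.einsum("fmsa,msat->ft", templates, weights)

    if n_draws == 0:
        return mix * energies[None, :]
    rng = np.random.default_rng(seed)
    F, T = mix.shape
    V = np.empty((F, T))
    for t in range(T):
        p = mix[:, t]
        p = p / p.sum() if p.sum() > 0 else np.full(F, 1.0 / F)
        V[:, t] = rng.multinomial(n_draws, p) * (energies[t] / n_draws)
    return V


def _check_norm(arr: np.ndarray, axis: int, name: str, tol: float = 1e-6) -> None:
    sums = arr.sum(axis=axis)
    if np.any(arr < -1e-12) or not np.allclose(sums, 1.0, atol=tol):
        raise ValidationError(f"{name} is not a normalised distribution over axis {axis}")


# ---------------------------------------------------------------------------
# Cohort serialisation (CSV per participant + JSON manifest)
# ---------------------------------------------------------------------------

def write_cohort(cohort: list[ParticipantRecord], cfg: CohortConfig, out_dir: str | Path) -> None:
    """Write sensors_<id>.csv, diary_<id>.csv and a cohort manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in cohort:
        sensors = rec.sensor_streams.copy()
        sensors.index.name = "timestamp"
        sensors.to_csv(out / f"sensors_{rec.participant_id}.csv",
                       float_format="%.6g", na_rep="")
        diary = rec.diary.copy()
        diary["peak_flow"] = rec.peak_flow
        diary.index.name = "date"
        diary.to_csv(out / f"diary_{rec.participant_id}.csv", float_format="%.6g")
    manifest = {
        "participants": [rec.participant_id for rec in cohort],
        "n_days": cfg.n_days,
        "channels": list(cfg.channels),
        "samples_per_day": cfg.samples_per_day,
        "symptoms": list(cfg.symptom_names),
        "seed": cfg.seed,
        "start_date": cfg.start_date.isoformat(),
    }
    (out / "cohort.json").write_text(json.dumps(manifest, indent=2))


def read_cohort(in_dir: str | Path) -> list[ParticipantRecord]:
    """Read a cohort previously written by :func:`write_cohort`."""
    src = Path(in_dir)
    manifest = json.loads((src / "cohort.json").read_text())
    spd = manifest["samples_per_day"]
    n_days = manifest["n_days"]
    cohort = []
    for pid in manifest["participants"]:
        sensors = pd.read_csv(src / f"sensors_{pid}.csv",
                              index_col="timestamp", parse_dates=True)
        diary_all = pd.read_csv(src / f"diary_{pid}.csv", index_col="date", parse_dates=True)
        peak_flow = diary_all.pop("peak_flow")
        dates = pd.DatetimeIndex(diary_all.index)
        day_valid = sensors.notna().any(axis=1).to_numpy().reshape(n_days, spd).any(axis=1)
        cohort.append(ParticipantRecord(
            participant_id=pid,
            dates=dates,
            sensor_streams=sensors,
            samples_per_day=spd,
            day_valid=day_valid,
            season_of_day=_season_labels(n_days),
            peak_flow=peak_flow,
            diary=diary_all.astype(int),
        ))
    return cohort
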