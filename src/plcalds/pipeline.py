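"""End-to-end experiment orchestration.

Runs the full detection/forecasting pipeline on a cohort: coverage filtering,
half-month train/test splitting, per-participant (personalised) or shared
(population) dictionary building, EM decomposition, optional LDS tracking,
train-side threshold selection and test-side F-measure evaluation, with
one-day-ahead label alignment by default.

Stage order per participant:

1. derive the label matrix (diary classes plus the worsening-of-peak-flow
   biomarker binarised at the personal median) and its episode masks;
2. build the nonnegative feature tensor for the chosen sensor subset and
   feature set;
3. align frame labels to the forecast horizon (frame ending at day t is
   supervised by day t + horizon) and split frames by the calendar half-month
   of the supervised day;
4. build the template dictionary on training frames, fit the decomposition on
   train and test frames, and — for the LDS variants — learn the tracker from
   ground-truth-initialised training activations and smooth both splits;
5. select thresholds on training scores and evaluate on test frames.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dictionary as _dictionary
from . import lds_tracker as _lds
from . import plca_core as _plca
from . import postprocess_eval as _eval
from . import preprocessing as _prep
from .synthetic_cohort import ConfigurationError, ParticipantRecord, ValidationError

logger = logging.getLogger(__name__)

MODELS = ("PLCA-3D", "PLCA-LDS-3D", "PLCA-4D", "PLCA-LDS-4D")

#: label name of the biomarker derived from peak-flow binarisation
PEAK_FLOW_LABEL = "worsening_peak_flow"


@dataclass
class ExperimentConfig:
    """Configuration of one experiment run."""

    model: str = "PLCA-LDS-3D"
    regime: str = "personalised"
    sensors: str = "all"
    features: str = "rich"
    coverage_threshold: float | None = None
    forecast_horizon_days: int = 1
    kappa: float = 1.1
    alpha: float = 0.2
    beta: float = 0.1
    n_iter: int = 40
    seed: int = 0
    window_days: int = 8
    step_days: int = 1
    nmf_rank: int = 1
    # dedicated template for symptom-free frames: without it the class whose
    # episodes are most widespread becomes the default winner on healthy
    # frames, inverting its scores
    background_class: bool = True

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ConfigurationError(f"model must be one of {MODELS}")
        if self.regime not in ("personalised", "population"):
            raise ConfigurationError("regime must be 'personalised' or 'population'")
        if self.sensors not in ("all", "pollutants_only", "peakflow_only"):
            raise ConfigurationError("unknown sensor subset")
        if self.features not in ("rich", "average_only"):
            raise ConfigurationError("unknown feature set")
        if self.forecast_horizon_days < 0:
            raise ConfigurationError("forecast horizon must be >= 0")

    @property
    def uses_lds(self) -> bool:
        return "LDS" in self.model

    @property
    def is_seasonal(self) -> bool:
        return self.model.endswith("4D")


# ---------------------------------------------------------------------------
# Cohort-level helpers
# ---------------------------------------------------------------------------

def filter_by_coverage(cohort: list[ParticipantRecord],
                       threshold: float | None) -> list[ParticipantRecord]:
    """Keep participants whose sensor-day coverage reaches the threshold."""
    if threshold is None:
        return list(cohort)
    kept = [rec for rec in cohort if rec.coverage >= threshold]
    logger.info("coverage filter %.0f%%: kept %d of %d participants",
                100 * threshold, len(kept), len(cohort))
    return kept


def split_train_test(dates: pd.DatetimeIndex) -> np.ndarray:
    """Half-month split: calendar days 1-15 are training, the rest testing.

    Returns a boolean array, True = training day.
    """
    return np.asarray(pd.DatetimeIndex(dates).day <= 15)


def align_forecast(day_labels: np.ndarray, frame_end_days: np.ndarray,
                   horizon: int) -> tuple[np.ndarray, np.ndarray]:
    """Map frames to the day they supervise (end day + horizon).

    ``day_labels`` has its last axis on the day grid. Returns the supervised
    day index per retained frame and the boolean retention mask over frames
    (trailing frames without a future label are dropped).
    """
    n_days = day_labels.shape[-1]
    target = np.asarray(frame_end_days) + horizon
    keep = target < n_days
    return target[keep], keep


def derive_labels(record: ParticipantRecord) -> tuple[np.ndarray, list[str]]:
    """Daily 0/1 label matrix: diary classes plus the peak-flow biomarker.

    Lung capacity is a *measured* biomarker, not a diary entry: when a
    peak-flow series is present, the derived worsening-of-peak-flow label
    replaces any diary column named ``lung_capacity`` (keeping both would
    duplicate one episode process as two competing label classes).
    """
    if record.diary is None:
        raise ValidationError("record has no diary")
    names = list(record.diary.columns)
    if record.peak_flow is not None and "lung_capacity" in names:
        names.remove("lung_capacity")
    rows = [record.diary[c].to_numpy(dtype=float) for c in names]
    if record.peak_flow is not None:
        rows.append(np.nan_to_num(
            _prep.binarise_peak_flow(record.peak_flow).to_numpy(), nan=0.0))
        names.append(PEAK_FLOW_LABEL)
    return np.vstack(rows), names


def day_masks(labels: np.ndarray) -> np.ndarray:
    """Episode-state masks (S x 3 x n_days) from the daily label matrix."""
    S, n_days = labels.shape
    annotations = []
    for s in range(S):
        annotations.extend(_prep.annotate_temporal_states(labels[s], symptom=s))
    return _prep.expand_annotation_masks(annotations, S, n_days)


def filter_trainable_symptoms(frame_masks: np.ndarray, train_frames: np.ndarray,
                              regime: str) -> np.ndarray:
    """Boolean selector over symptom classes usable for supervised evaluation.

    Personalised regime: a symptom is retained only if each temporal state
    (onset/transient/offset) occurs at least once among the training frames
    AND at least once among the testing frames. Population regime: any
    occurrence retains the symptom.
    """
    S = frame_masks.shape[0]
    keep = np.zeros(S, dtype=bool)
    test_frames = ~train_frames
    for s in range(S):
        if regime == "personalised":
            keep[s] = all(frame_masks[s, a, train_frames].any()
                          and frame_masks[s, a, test_frames].any()
                          for a in range(frame_masks.shape[1]))
        else:
            keep[s] = frame_masks[s].any()
    return keep


# ---------------------------------------------------------------------------
# Per-participant preparation
# ---------------------------------------------------------------------------

@dataclass
class _Prepared:
    """Frame-level supervised data of one participant."""

    record: ParticipantRecord
    features: _prep.FeatureTensor
    label_names: list[str]
    frame_labels: np.ndarray  # S x n_frames (aligned to horizon)
    frame_masks: np.ndarray  # S x 3 x n_frames
    train_frames: np.ndarray  # bool per frame
    season_of_frame: np.ndarray


def _prepare(record: ParticipantRecord, cfg: ExperimentConfig) -> _Prepared:
    labels, names = derive_labels(record)
    masks = day_masks(labels)
    train_days = split_train_test(record.dates)
    spec = _prep.WindowSpec(cfg.window_days, cfg.step_days)
    features = _prep.build_feature_tensor(
        record, spec, feature_set=cfg.features, sensors_subset=cfg.sensors,
        train_days=train_days)
    target_days, keep = align_forecast(labels, features.frame_end_days, cfg.forecast_horizon_days)
    features = dataclasses.replace(
        features,
        values=features.values[:, keep],
        frame_dates=[d for d, k in zip(features.frame_dates, keep) if k],
        frame_end_days=features.frame_end_days[keep])
    return _Prepared(
        record=record,
        features=features,
        label_names=names,
        frame_labels=labels[:, target_days],
        frame_masks=masks[:, :, target_days],
        train_frames=train_days[target_days],
        season_of_frame=record.season_of_day[target_days],
    )


def _masked_init(frame_masks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth binary-mask initialisers for P(s|t) and P(a|s,t).

    Zeros survive the multiplicative EM updates, so the resulting activations
    stay confined to annotated symptoms/states; frames with no active symptom
    normalise to a uniform column (with a background class present, the
    background row claims those frames instead).
    """
    any_state = frame_masks.max(axis=1).astype(float)  # S x T
    per_state = frame_masks.transpose(1, 0, 2).astype(float)  # A x S x T
    return any_state, per_state


BACKGROUND_NAME = "__background__"


def _augment_with_background(masks: np.ndarray, names: list[str]
                             ) -> tuple[np.ndarray, list[str]]:
    """Append a background pseudo-symptom active (all states) on label-free frames."""
    healthy = masks.max(axis=(0, 1)) == 0  # no symptom, no state anywhere
    bg = np.repeat(healthy[None, None, :].astype(int), masks.shape[1], axis=1)
    return np.concatenate([masks, bg], axis=0), names + [BACKGROUND_NAME]


@dataclass
class _Scores:
    """Continuous decision scores per split for one participant."""

    overall_train: np.ndarray  # S x T_train
    overall_test: np.ndarray
    state_train: np.ndarray  # A x S x T_train
    state_test: np.ndarray


def _participant_seed(base: int, participant_id: str) -> int:
    # crc32 keeps per-participant streams distinct yet reproducible across runs
    return (base + zlib.crc32(participant_id.encode())) % (2 ** 31)


def _decompose_and_track(prep: _Prepared, dic: _dictionary.DictionaryTensor,
                         cfg: ExperimentConfig,
                         shared_lds: _lds.LDSParams | None = None) -> _Scores:
    model = "4D" if cfg.is_seasonal else "3D"
    V, tr = prep.features, prep.train_frames
    V_train, V_test = V.values[:, tr], V.values[:, ~tr]
    e_train, e_test = V_train.sum(axis=0), V_test.sum(axis=0)
    seed = _participant_seed(cfg.seed, prep.record.participant_id)
    S_real = len(prep.label_names)  # dictionary may carry an extra background row

    # deterministic symmetric init: with highly collinear templates a random
    # init decides the symptom attribution more than the data does
    acts_train = _plca.fit_plca(V_train, dic, model=model, kappa=cfg.kappa,
                                n_iter=cfg.n_iter, seed=seed, init="uniform")
    acts_test = _plca.fit_plca(V_test, dic, model=model, kappa=cfg.kappa,
                               n_iter=cfg.n_iter, seed=seed + 1, init="uniform")
    p_st_train = acts_train.p_s_given_t[:S_real] * e_train[None, :]
    p_st_test = acts_test.p_s_given_t[:S_real] * e_test[None, :]
    state_train = acts_train.p_a_given_st[:, :S_real] * p_st_train[None, :, :]
    state_test = acts_test.p_a_given_st[:, :S_real] * p_st_test[None, :, :]

    if cfg.uses_lds:
        params = shared_lds
        if params is None:
            params = _learn_participant_lds(prep, dic, cfg, seed)
        tracked_train = _lds.track_symptoms(p_st_train, params)
        tracked_test = _lds.track_symptoms(p_st_test, params)
        # per-state scores inherit the smoothing through the tracked level
        state_train = acts_train.p_a_given_st[:, :S_real] * tracked_train[None, :, :]
        state_test = acts_test.p_a_given_st[:, :S_real] * tracked_test[None, :, :]
        p_st_train, p_st_test = tracked_train, tracked_test
    return _Scores(p_st_train, p_st_test, state_train, state_test)


def _learn_participant_lds(prep: _Prepared, dic: _dictionary.DictionaryTensor,
                           cfg: ExperimentConfig, seed: int) -> _lds.LDSParams:
    states, obs = _lds_training_sequences(prep, dic, cfg, seed)
    return _lds.learn_lds_parameters(states, obs, alpha=cfg.alpha, beta=cfg.beta)


def _lds_training_sequences(prep: _Prepared, dic: _dictionary.DictionaryTensor,
                            cfg: ExperimentConfig, seed: int
                            ) -> tuple[_lds.StateSequence, np.ndarray]:
    """Clean/noisy training pair for LDS learning on the training split.

    The clean states come from an EM run whose P(s|t) and P(a|s,t) are
    initialised with the ground-truth binary masks; the noisy observations are
    the ordinary randomly initialised EM activations of the same frames.
    """
    model = "4D" if cfg.is_seasonal else "3D"
    tr = prep.train_frames
    V_train = prep.features.values[:, tr]
    energy = V_train.sum(axis=0)
    S_real = len(prep.label_names)
    masks = prep.frame_masks[:, :, tr]
    if cfg.background_class:
        masks, _ = _augment_with_background(masks, list(prep.label_names))
    init_s, init_a = _masked_init(masks)
    acts_masked = _plca.fit_plca(V_train, dic, model=model, kappa=cfg.kappa,
                                 n_iter=cfg.n_iter, seed=seed + 2,
                                 init_p_s_given_t=init_s, init_p_a_given_st=init_a)
    acts_plain = _plca.fit_plca(V_train, dic, model=model, kappa=cfg.kappa,
                                n_iter=cfg.n_iter, seed=seed, init="uniform")
    clean = acts_masked.p_s_given_t[:S_real] * energy[None, :]
    noisy = acts_plain.p_s_given_t[:S_real] * energy[None, :]
    return _lds.build_state_sequence(clean), noisy


# ---------------------------------------------------------------------------
# Experiment driver
# ---------------------------------------------------------------------------

def run_experiment(cfg: ExperimentConfig,
                   cohort: list[ParticipantRecord]) -> _eval.EvalReport:
    """Execute a full experiment and return the evaluation report.

    Deterministic given ``cfg.seed``. Raises a stage-tagged error if any
    participant fails a pipeline stage.
    """
    cohort = filter_by_coverage(cohort, cfg.coverage_threshold)
    if not cohort:
        raise ValidationError("no participants left after coverage filtering")

    prepared: list[_Prepared] = []
    for rec in cohort:
        try:
            prepared.append(_prepare(rec, cfg))
        except (ValidationError, ConfigurationError) as exc:
            raise type(exc)(f"[prepare:{rec.participant_id}] {exc}") from exc

    if cfg.regime == "personalised":
        return _run_personalised(cfg, prepared)
    return _run_population(cfg, prepared)


def _retained(prep: _Prepared, cfg: ExperimentConfig) -> np.ndarray:
    keep = filter_trainable_symptoms(prep.frame_masks, prep.train_frames, cfg.regime)
    if not keep.any():
        logger.info("participant %s has no trainable symptom; skipped",
                    prep.record.participant_id)
    return keep


def _restrict(prep: _Prepared, keep: np.ndarray) -> _Prepared:
    return dataclasses.replace(
        prep,
        frame_labels=prep.frame_labels[keep],
        frame_masks=prep.frame_masks[keep],
        label_names=[n for n, k in zip(prep.label_names, keep) if k],
    )


def _build_dictionary(cfg: ExperimentConfig, V: np.ndarray, masks: np.ndarray,
                      seasons: np.ndarray, names: list[str]) -> _dictionary.DictionaryTensor:
    if cfg.background_class:
        masks, names = _augment_with_background(masks, list(names))
    if cfg.is_seasonal:
        return _dictionary.build_dictionary_4d(V, masks, seasons, symptom_names=names,
                                               rank=cfg.nmf_rank, seed=cfg.seed)
    return _dictionary.build_dictionary_3d(V, masks, symptom_names=names,
                                           rank=cfg.nmf_rank, seed=cfg.seed)


def _score_maps(prep: _Prepared, scores: _Scores, split: str
                ) -> tuple[dict, dict]:
    """(scores, labels) maps keyed by (symptom, target) for one split."""
    tr = prep.train_frames
    sel = tr if split == "train" else ~tr
    overall = scores.overall_train if split == "train" else scores.overall_test
    state = scores.state_train if split == "train" else scores.state_test
    smap, lmap = {}, {}
    for i, name in enumerate(prep.label_names):
        smap[(name, "overall")] = overall[i]
        lmap[(name, "overall")] = prep.frame_labels[i, sel].astype(int)
        for a, st in enumerate(_prep.STATE_NAMES):
            smap[(name, st)] = state[a, i]
            lmap[(name, st)] = prep.frame_masks[i, a, sel].astype(int)
    return smap, lmap


def _decide(prep: _Prepared, scores: _Scores,
            thresholds: _eval.ThresholdSet) -> dict[tuple[str, str], np.ndarray]:
    return _eval.binarise_activations(scores.overall_test, thresholds,
                                      prep.label_names, state_scores=scores.state_test)


def _personalised_decisions(cfg: ExperimentConfig, prepared: list[_Prepared]
                            ) -> tuple[dict, dict]:
    decisions, truths = {}, {}
    for prep in prepared:
        keep = _retained(prep, cfg)
        if not keep.any():
            continue
        prep = _restrict(prep, keep)
        tr = prep.train_frames
        dic = _build_dictionary(cfg, prep.features.values[:, tr],
                                prep.frame_masks[:, :, tr],
                                prep.season_of_frame[tr], prep.label_names)
        scores = _decompose_and_track(prep, dic, cfg)
        train_scores, train_labels = _score_maps(prep, scores, "train")
        thresholds = _eval.select_thresholds(train_scores, train_labels)
        decisions[prep.record.participant_id] = _decide(prep, scores, thresholds)
        _, test_labels = _score_maps(prep, scores, "test")
        truths[prep.record.participant_id] = test_labels
    if not decisions:
        raise ValidationError("[evaluate] no participant had trainable symptoms")
    return decisions, truths


def _run_personalised(cfg: ExperimentConfig, prepared: list[_Prepared]) -> _eval.EvalReport:
    decisions, truths = _personalised_decisions(cfg, prepared)
    return _eval.evaluate_cohort(decisions, truths, grouping="personalised")


def _run_population(cfg: ExperimentConfig, prepared: list[_Prepared]) -> _eval.EvalReport:
    # keep the union of symptoms with any occurrence anywhere in the cohort
    S = prepared[0].frame_masks.shape[0]
    keep = np.zeros(S, dtype=bool)
    for prep in prepared:
        keep |= filter_trainable_symptoms(prep.frame_masks, prep.train_frames, "population")
    if not keep.any():
        raise ValidationError("[dictionary] no symptom occurs anywhere in the cohort")
    prepared = [_restrict(p, keep) for p in prepared]

    V_train = np.hstack([p.features.values[:, p.train_frames] for p in prepared])
    masks_train = np.concatenate([p.frame_masks[:, :, p.train_frames] for p in prepared], axis=2)
    seasons_train = np.concatenate([p.season_of_frame[p.train_frames] for p in prepared])
    dic = _build_dictionary(cfg, V_train, masks_train, seasons_train,
                            prepared[0].label_names)

    shared_lds = None
    if cfg.uses_lds:
        pairs = [_lds_training_sequences(p, dic, cfg,
                                         _participant_seed(cfg.seed, p.record.participant_id))
                 for p in prepared]
        shared_lds = _lds.learn_lds_parameters([s for s, _ in pairs], [o for _, o in pairs],
                                               alpha=cfg.alpha, beta=cfg.beta)

    per_scores = {p.record.participant_id: _decompose_and_track(p, dic, cfg, shared_lds)
                  for p in prepared}

    # thresholds fitted on training frames pooled across the cohort
    pooled_scores: dict[tuple[str, str], list[np.ndarray]] = {}
    pooled_labels: dict[tuple[str, str], list[np.ndarray]] = {}
    for prep in prepared:
        smap, lmap = _score_maps(prep, per_scores[prep.record.participant_id], "train")
        for key in smap:
            pooled_scores.setdefault(key, []).append(smap[key])
            pooled_labels.setdefault(key, []).append(lmap[key])
    thresholds = _eval.select_thresholds(
        {k: np.concatenate(v) for k, v in pooled_scores.items()},
        {k: np.concatenate(v) for k, v in pooled_labels.items()})

    decisions, truths = {}, {}
    for prep in prepared:
        scores = per_scores[prep.record.participant_id]
        decisions[prep.record.participant_id] = _decide(prep, scores, thresholds)
        _, test_labels = _score_maps(prep, scores, "test")
        truths[prep.record.participant_id] = test_labels
    return _eval.evaluate_cohort(decisions, truths, grouping="population")


# ---------------------------------------------------------------------------
# Permutation-null baseline
# ---------------------------------------------------------------------------

def permutation_win_fraction(decisions: dict[str, dict[tuple[str, str], np.ndarray]],
                             truths: dict[str, dict[tuple[str, str], np.ndarray]],
                             seed: int = 0, n_permutations: int = 20,
                             target: str = "overall", level: str = "symptom") -> float:
    """Fraction of retained symptoms whose F1 beats a label-shuffle null.

    The null for each (participant, symptom) pair is the mean F1 over
    ``n_permutations`` random shuffles of the test-frame truth labels with the
    predictions held fixed. ``level="symptom"`` compares, per symptom class,
    the mean F1 across participants against the matching mean null F1 (the
    study reports per-symptom averages); ``level="pair"`` scores every
    (participant, symptom) pair separately.
    """
    if level not in ("symptom", "pair"):
        raise ValidationError(f"unknown aggregation level {level!r}")
    rng = np.random.default_rng(seed)
    per_symptom: dict[str, list[tuple[float, float]]] = {}
    for pid, dec in decisions.items():
        for (symptom, tgt), pred in dec.items():
            if tgt != target:
                continue
            truth = truths[pid][(symptom, tgt)]
            if truth.sum() == 0:
                continue
            _, _, actual = _eval.event_f_measure(pred, truth)
            null = float(np.mean([
                _eval.event_f_measure(pred, rng.permutation(truth))[2]
                for _ in range(n_permutations)]))
            per_symptom.setdefault(symptom, []).append((actual, null))
    if not per_symptom:
        raise ValidationError("no evaluable (participant, symptom) pairs")
    if level == "pair":
        pairs = [a > n for vals in per_symptom.values() for a, n in vals]
        return float(np.mean(pairs))
    wins = [float(np.mean([a for a, _ in vals])) > float(np.mean([n for _, n in vals]))
            for vals in per_symptom.values()]
    return float(np.mean(wins))


def run_experiment_with_null(cfg: ExperimentConfig, cohort: list[ParticipantRecord],
                             n_permutations: int = 20
                             ) -> tuple[_eval.EvalReport, float]:
    """Run an experiment and also report the permutation-null win fraction."""
    if cfg.regime != "personalised":
        raise ConfigurationError("null comparison is defined for the personalised regime")
    cohort = filter_by_coverage(cohort, cfg.coverage_threshold)
    prepared = [_prepare(rec, cfg) for rec in cohort]
    decisions, truths = _personalised_decisions(cfg, prepared)
    report = _eval.evaluate_cohort(decisions, truths, grouping="personalised")
    win = permutation_win_fraction(decisions, truths, seed=cfg.seed,
                                   n_permutations=n_permutations)
    return report, win
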