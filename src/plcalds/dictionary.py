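"""Spectral template dictionaries P(f|s,a) and P(f|m,s,a) built by KL-NMF.

For every (symptom, temporal state) cell — optionally further partitioned by
season — the training frames labelled with that cell are collected and a
KL-divergence nonnegative matrix factorisation (multiplicative updates) is run
on them. The default rank-1 basis column, normalised to sum to one over the
feature axis, becomes the cell's template. Cells with no labelled frames are
imputed with the mean template of their symptom, falling back to the global
mean template. Templates are fixed after the build; the decomposition never
updates them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

from .preprocessing import STATE_NAMES, FeatureTensor
from .synthetic_cohort import SEASONS, ValidationError

logger = logging.getLogger(__name__)

_NORM_TOL = 1e-9


@dataclass
class DictionaryTensor:
    """Per-template-normalised dictionary: F x S x A, or F x M x S x A with seasons."""

    templates: np.ndarray
    symptom_names: list[str]
    state_names: tuple[str, ...] = STATE_NAMES
    season_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.templates.ndim not in (3, 4):
            raise ValidationError("templates must be 3- or 4-dimensional")
        if self.templates.ndim == 4 and self.season_names is None:
            raise ValidationError("4D dictionary needs season names")
        if np.any(self.templates < 0):
            raise ValidationError("dictionary templates must be nonnegative")
        sums = self.templates.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=_NORM_TOL):
            raise ValidationError("each template must sum to 1 over the feature axis")

    @property
    def is_seasonal(self) -> bool:
        return self.templates.ndim == 4


def kl_nmf_basis(U: np.ndarray, rank: int = 1, seed: int = 0) -> np.ndarray:
    """Rank-``rank`` KL-NMF basis of the frame matrix U (F x n), columns normalised."""
    U = np.asarray(U, dtype=float)
    if U.ndim == 1:
        U = U[:, None]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model = NMF(n_components=rank, solver="mu", beta_loss="kullback-leibler",
                    init="random", max_iter=500, tol=1e-6, random_state=seed)
        W = model.fit_transform(U)
    sums = W.sum(axis=0)
    sums[sums == 0] = 1.0
    return W / sums


def _collect_templates(V: np.ndarray, frame_masks: np.ndarray,
                       rank: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Raw per-cell templates (F x S x A x rank) and a filled-cell indicator."""
    F = V.shape[0]
    S, A, T = frame_masks.shape
    templates = np.zeros((F, S, A, rank))
    filled = np.zeros((S, A), dtype=bool)
    for s in range(S):
        for a in range(A):
            cols = frame_masks[s, a].astype(bool)
            if not cols.any():
                continue
            basis = kl_nmf_basis(V[:, cols], rank=rank, seed=seed + 7919 * s + 104729 * a)
            templates[:, s, a, :] = basis
            filled[s, a] = True
    return templates, filled


def _impute_empty_cells(templates: np.ndarray, filled: np.ndarray) -> np.ndarray:
    """Mean-template fill for unlabelled cells (per symptom, else global)."""
    F, S, A, rank = templates.shape
    if not filled.any():
        raise ValidationError("no labelled frames for any (symptom, state) cell")
    global_mean = templates[:, filled, :].mean(axis=1)  # F x rank
    out = templates.copy()
    for s in range(S):
        cells = filled[s]
        symptom_mean = templates[:, s, cells, :].mean(axis=1) if cells.any() else global_mean
        for a in range(A):
            if not filled[s, a]:
                logger.info("imputing dictionary cell (s=%d, a=%d) with mean template", s, a)
                out[:, s, a, :] = symptom_mean
    return out


def _stack_rank(templates: np.ndarray, state_names: tuple[str, ...]) -> tuple[np.ndarray, tuple[str, ...]]:
    """Fold extra NMF components into pseudo temporal states (rank>1 only)."""
    F, S, A, rank = templates.shape
    if rank == 1:
        return templates[..., 0], state_names
    stacked = templates.transpose(0, 1, 2, 3).reshape(F, S, A * rank)
    names = tuple(f"{st}#{k}" for st in state_names for k in range(rank))
    return stacked, names


def build_dictionary_3d(train_features: FeatureTensor | np.ndarray,
                        frame_masks: np.ndarray,
                        symptom_names: list[str] | None = None,
                        rank: int = 1, seed: int = 0) -> DictionaryTensor:
    """Build the 3D dictionary P(f|s,a) from labelled training frames.

    ``frame_masks`` is the S x A x T ground-truth indicator on the frame axis
    of ``train_features``.
    """
    if rank < 1:
        raise ValidationError("rank must be >= 1")
    V = train_features.values if isinstance(train_features, FeatureTensor) else np.asarray(train_features, float)
    if V.shape[1] != frame_masks.shape[2]:
        raise ValidationError("frame mask and feature tensor disagree on frame count")
    templates, filled = _collect_templates(V, frame_masks, rank, seed)
    templates = _impute_empty_cells(templates, filled)
    stacked, state_names = _stack_rank(templates, STATE_NAMES)
    S = frame_masks.shape[0]
    names = symptom_names or [f"symptom_{i}" for i in range(S)]
    return DictionaryTensor(templates=stacked, symptom_names=list(names),
                            state_names=state_names)


def build_dictionary_4d(train_features: FeatureTensor | np.ndarray,
                        frame_masks: np.ndarray,
                        season_of_frame: np.ndarray,
                        symptom_names: list[str] | None = None,
                        rank: int = 1, seed: int = 0) -> DictionaryTensor:
    """Build the seasonal 4D dictionary P(f|m,s,a).

    Frames are first partitioned by their season label; each partition is
    factorised as in the 3D build. Season cells without labelled frames are
    imputed from the other seasons of the same (s, a) cell, falling back to the
    symptom/global mean-template rule.
    """
    if rank < 1:
        raise ValidationError("rank must be >= 1")
    V = train_features.values if isinstance(train_features, FeatureTensor) else np.asarray(train_features, float)
    season_of_frame = np.asarray(season_of_frame)
    if V.shape[1] != frame_masks.shape[2] or len(season_of_frame) != V.shape[1]:
        raise ValidationError("feature tensor, masks and season labels disagree on frame count")
    F = V.shape[0]
    S, A, _ = frame_masks.shape
    per_season, filled = [], []
    for m, season in enumerate(SEASONS):
        sel = season_of_frame == season
        if sel.any():
            t, f = _collect_templates(V[:, sel], frame_masks[:, :, sel], rank,
                                      seed + 31 * m)
        else:
            t = np.zeros((F, S, A, rank))
            f = np.zeros((S, A), dtype=bool)
        per_season.append(t)
        filled.append(f)
    templates = np.stack(per_season, axis=1)  # F x M x S x A x rank
    filled = np.stack(filled, axis=0)  # M x S x A

    # first impute across seasons within a filled (s, a) cell
    for s in range(S):
        for a in range(A):
            have = filled[:, s, a]
            if have.any() and not have.all():
                mean_t = templates[:, have, s, a, :].mean(axis=1)
                for m in range(len(SEASONS)):
                    if not have[m]:
                        logger.info("imputing seasonal cell (m=%d, s=%d, a=%d) across seasons", m, s, a)
                        templates[:, m, s, a, :] = mean_t
                filled[:, s, a] = True
    # remaining empty (s, a) cells: mean-template rule applied per season slice
    for m in range(len(SEASONS)):
        templates[:, m] = _impute_empty_cells(templates[:, m], filled[m])

    stacked_list = []
    for m in range(len(SEASONS)):
        st, state_names = _stack_rank(templates[:, m], STATE_NAMES)
        stacked_list.append(st)
    stacked = np.stack(stacked_list, axis=1)
    names = symptom_names or [f"symptom_{i}" for i in range(S)]
    return DictionaryTensor(templates=stacked, symptom_names=list(names),
                            state_names=state_names, season_names=SEASONS)


def save_dictionary(dictionary: DictionaryTensor, path: str | Path) -> None:
    """Serialise a dictionary to a compressed .npz container with named axes."""
    payload = {
        "templates": dictionary.templates,
        "symptom_names": np.asarray(dictionary.symptom_names),
        "state_names": np.asarray(dictionary.state_names),
    }
    if dictionary.season_names is not None:
        payload["season_names"] = np.asarray(dictionary.season_names)
    np.savez_compressed(path, **payload)


def load_dictionary(path: str | Path) -> DictionaryTensor:
    with np.load(path, allow_pickle=False) as data:
        return DictionaryTensor(
            templates=data["templates"],
            symptom_names=[str(s) for s in data["symptom_names"]],
            state_names=tuple(str(s) for s in data["state_names"]),
            season_names=(tuple(str(s) for s in data["season_names"])
                          if "season_names" in data else None),
        )
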