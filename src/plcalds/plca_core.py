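"""EM inference of symptom activations under the 3D and 4D latent-component models.

The nonnegative feature tensor V[f, t] is treated, frame by frame, as repeated
draws from a mixture of fixed dictionary templates:

    3D:  P(f, t) = P(t) * sum_{s,a}   P(f|s,a)   P(s|t) P(a|s,t)
    4D:  P(f, t) = P(t) * sum_{m,s,a} P(f|m,s,a) P(s|t) P(a|s,t) P(m|s,t)

with s the symptom class, a the temporal state (onset/transient/offset), m the
season and P(t) = sum_f V[f, t] the known frame energy. The dictionary is
fixed; EM estimates the activations P(s|t), P(a|s,t) (and P(m|s,t)). A
sparsity exponent kappa > 1 is applied to the unnormalised symptom masses in
the M-step to lower the entropy of P(s|t) (kappa = 1 recovers plain EM). The
detector output is the energy-scaled activation P(s,t) = P(t) P(s|t).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dictionary import DictionaryTensor
from .preprocessing import FeatureTensor
from .synthetic_cohort import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

_NORM_TOL = 1e-9


@dataclass
class ActivationSet:
    """Conditional activation distributions estimated by EM."""

    p_s_given_t: np.ndarray  # S x T
    p_a_given_st: np.ndarray  # A x S x T
    p_m_given_st: np.ndarray | None = None  # M x S x T (4D model only)
    kappa: float = 1.1
    n_iter: int = 40
    kl_history: list[float] = field(default_factory=list)

    def validate(self) -> None:
        for name, arr in (("P(s|t)", self.p_s_given_t), ("P(a|s,t)", self.p_a_given_st),
                          ("P(m|s,t)", self.p_m_given_st)):
            if arr is None:
                continue
            if np.any(arr < -1e-12):
                raise ValidationError(f"{name} has negative entries")
            if not np.allclose(arr.sum(axis=0), 1.0, atol=_NORM_TOL):
                raise ValidationError(f"{name} does not normalise over its first axis")


@dataclass
class SymptomActivation:
    """Energy-scaled symptom activation P(s,t) = P(t) P(s|t)."""

    p_st: np.ndarray  # S x T
    symptom_names: list[str] | None = None


def _as_matrix(V: FeatureTensor | np.ndarray) -> np.ndarray:
    return V.values if isinstance(V, FeatureTensor) else np.asarray(V, dtype=float)


# ---------------------------------------------------------------------------
# 3D model
# ---------------------------------------------------------------------------

def e_step_3d(V: FeatureTensor | np.ndarray, dictionary: DictionaryTensor,
              acts: ActivationSet) -> np.ndarray:
    """Posterior P(s,a|f,t), shape S x A x F x T.

    Frames where the mixture assigns zero mass to every (s, a) get a uniform
    posterior (logged) so silent frames do not propagate NaNs.
    """
    V = _as_matrix(V)
    templates = dictionary.templates  # F x S x A
    if templates.ndim != 3:
        raise ValidationError("e_step_3d needs a 3D dictionary")
    F, S, A = templates.shape
    if V.shape[0] != F or acts.p_s_given_t.shape != (S, V.shape[1]) \
            or acts.p_a_given_st.shape != (A, S, V.shape[1]):
        raise ValidationError("shape mismatch between V, dictionary and activations")
    weights = np.einsum("st,ast->sat", acts.p_s_given_t, acts.p_a_given_st)
    num = np.einsum("fsa,sat->saft", templates, weights)
    denom = num.sum(axis=(0, 1))  # F x T
    zero = denom <= 0
    if zero.any():
        logger.info("uniform posterior on %d zero-denominator cells", int(zero.sum()))
    denom = np.where(zero, 1.0, denom)
    post = num / denom
    post[:, :, zero] = 1.0 / (S * A)
    return post


def m_step_3d(posterior: np.ndarray, V: FeatureTensor | np.ndarray,
              kappa: float = 1.1) -> tuple[np.ndarray, np.ndarray]:
    """Updated (P(s|t), P(a|s,t)) from the 3D posterior.

    The symptom masses are raised to the power kappa before renormalisation;
    kappa = 1 is the plain EM update.
    """
    if kappa <= 0:
        raise ConfigurationError("kappa must be positive")
    V = _as_matrix(V)
    pv = posterior * V[None, None]  # S x A x F x T
    raw_s = pv.sum(axis=(1, 2))  # S x T
    p_s = _normalise_power(raw_s, kappa)
    raw_a = pv.sum(axis=2)  # S x A x T
    p_a = _normalise(raw_a.transpose(1, 0, 2))  # A x S x T
    return p_s, p_a


# ---------------------------------------------------------------------------
# 4D model
# ---------------------------------------------------------------------------

def e_step_4d(V: FeatureTensor | np.ndarray, dictionary: DictionaryTensor,
              acts: ActivationSet) -> np.ndarray:
    """Posterior P(m,s,a|f,t), shape M x S x A x F x T."""
    V = _as_matrix(V)
    templates = dictionary.templates  # F x M x S x A
    if templates.ndim != 4:
        raise ValidationError("e_step_4d needs a 4D (seasonal) dictionary")
    F, M, S, A = templates.shape
    if acts.p_m_given_st is None:
        raise ValidationError("4D E-step needs P(m|s,t)")
    if V.shape[0] != F or acts.p_m_given_st.shape != (M, S, V.shape[1]):
        raise ValidationError("shape mismatch between V, dictionary and activations")
    weights = np.einsum("st,ast,mst->msat", acts.p_s_given_t, acts.p_a_given_st,
                        acts.p_m_given_st)
    num = np.einsum("fmsa,msat->msaft", templates, weights)
    denom = num.sum(axis=(0, 1, 2))  # F x T
    zero = denom <= 0
    if zero.any():
        logger.info("uniform posterior on %d zero-denominator cells", int(zero.sum()))
    denom = np.where(zero, 1.0, denom)
    post = num / denom
    post[:, :, :, zero] = 1.0 / (M * S * A)
    return post


def m_step_4d(posterior: np.ndarray, V: FeatureTensor | np.ndarray,
              kappa: float = 1.1) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Updated (P(s|t), P(a|s,t), P(m|s,t)) from the 4D posterior."""
    if kappa <= 0:
        raise ConfigurationError("kappa must be positive")
    V = _as_matrix(V)
    pv = posterior * V[None, None, None]  # M x S x A x F x T
    raw_s = pv.sum(axis=(0, 2, 3))  # S x T
    p_s = _normalise_power(raw_s, kappa)
    raw_a = pv.sum(axis=(0, 3))  # S x A x T
    p_a = _normalise(raw_a.transpose(1, 0, 2))  # A x S x T
    raw_m = pv.sum(axis=(2, 3))  # M x S x T
    p_m = _normalise(raw_m)
    return p_s, p_a, p_m


def _normalise(arr: np.ndarray) -> np.ndarray:
    sums = arr.sum(axis=0, keepdims=True)
    out = np.divide(arr, sums, out=np.zeros_like(arr), where=sums > 0)
    uniform = (sums[0] <= 0)
    if uniform.any():
        out[:, uniform] = 1.0 / arr.shape[0]
    return out


def _normalise_power(raw: np.ndarray, kappa: float) -> np.ndarray:
    powered = raw ** kappa if kappa != 1.0 else raw
    return _normalise(powered)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def reconstruct(dictionary: DictionaryTensor, acts: ActivationSet,
                frame_energy: np.ndarray | None = None) -> np.ndarray:
    """Model reconstruction: the mixture P(f|t), scaled by P(t) when given."""
    if dictionary.is_seasonal:
        weights = np.einsum("st,ast,mst->msat", acts.p_s_given_t, acts.p_a_given_st,
                            acts.p_m_given_st)
        mix = np.einsum("fmsa,msat->ft", dictionary.templates, weights)
    else:
        weights = np.einsum("st,ast->sat", acts.p_s_given_t, acts.p_a_given_st)
        mix = np.einsum("fsa,sat->ft", dictionary.templates, weights)
    if frame_energy is not None:
        mix = mix * np.asarray(frame_energy)[None, :]
    return mix


def kl_divergence(V: FeatureTensor | np.ndarray, dictionary: DictionaryTensor,
                  acts: ActivationSet) -> float:
    """Energy-weighted KL divergence between column-normalised V and the mixture.

    D = sum_t P(t) * KL(Vbar_t || Q_t); this is the quantity plain EM (kappa=1)
    monotonically decreases.
    """
    V = _as_matrix(V)
    energy = V.sum(axis=0)
    vbar = np.divide(V, energy[None, :], out=np.zeros_like(V), where=energy > 0)
    q = reconstruct(dictionary, acts)
    mask = vbar > 0
    ratio = np.log(vbar[mask] / np.maximum(q[mask], 1e-300))
    weights = np.broadcast_to(energy[None, :], V.shape)[mask]
    return float(np.sum(weights * vbar[mask] * ratio))


def fit_plca(V: FeatureTensor | np.ndarray, dictionary: DictionaryTensor,
             model: str = "3D", kappa: float = 1.1, n_iter: int = 40,
             seed: int = 0, init: str = "random",
             init_p_s_given_t: np.ndarray | None = None,
             init_p_a_given_st: np.ndarray | None = None,
             early_stop_tol: float | None = None) -> ActivationSet:
    """Fit the activations by EM with the dictionary fixed.

    By default activations start from uniform random values in (0, 1),
    normalised. ``init="uniform"`` starts every distribution flat instead,
    which makes the fit deterministic and lets the data alone break the
    symmetry — preferable when dictionary templates are highly collinear, as
    the random draw then decides the symptom attribution more than the data
    does. Explicit initialisers (e.g. a ground-truth binary mask, whose zeros
    are preserved by the multiplicative updates) override either choice. Runs
    ``n_iter`` iterations (the study found 40 sufficient); the per-iteration
    energy-weighted KL divergence is recorded in ``kl_history``. With
    ``early_stop_tol`` set, iteration stops once the relative KL improvement
    drops below it.
    """
    V = _as_matrix(V)
    model = model.upper()
    if model not in ("3D", "4D"):
        raise ConfigurationError("model must be '3D' or '4D'")
    if (model == "4D") != dictionary.is_seasonal:
        raise ValidationError("model choice and dictionary dimensionality disagree")
    T = V.shape[1]
    if dictionary.is_seasonal:
        _, M, S, A = dictionary.templates.shape
    else:
        _, S, A = dictionary.templates.shape
        M = None
    if init not in ("random", "uniform"):
        raise ConfigurationError("init must be 'random' or 'uniform'")
    rng = np.random.default_rng(seed)
    draw = (lambda shape: rng.random(shape)) if init == "random" \
        else (lambda shape: np.ones(shape))

    p_s = _normalise(init_p_s_given_t.astype(float).copy()
                     if init_p_s_given_t is not None else draw((S, T)))
    p_a = _normalise(init_p_a_given_st.astype(float).copy()
                     if init_p_a_given_st is not None else draw((A, S, T)))
    p_m = _normalise(draw((M, S, T))) if M else None

    acts = ActivationSet(p_s, p_a, p_m, kappa=kappa, n_iter=n_iter)
    history: list[float] = []
    for _ in range(n_iter):
        if model == "3D":
            post = e_step_3d(V, dictionary, acts)
            p_s, p_a = m_step_3d(post, V, kappa)
            acts = ActivationSet(p_s, p_a, None, kappa=kappa, n_iter=n_iter)
        else:
            post = e_step_4d(V, dictionary, acts)
            p_s, p_a, p_m = m_step_4d(post, V, kappa)
            acts = ActivationSet(p_s, p_a, p_m, kappa=kappa, n_iter=n_iter)
        history.append(kl_divergence(V, dictionary, acts))
        if early_stop_tol is not None and len(history) > 1:
            prev, cur = history[-2], history[-1]
            if prev > 0 and abs(prev - cur) / abs(prev) < early_stop_tol:
                break
    acts.kl_history = history
    acts.validate()
    return acts


def symptom_activation(acts: ActivationSet, frame_energy: np.ndarray,
                       symptom_names: list[str] | None = None) -> SymptomActivation:
    """Energy-scaled detector output P(s,t) = P(t) P(s|t)."""
    frame_energy = np.asarray(frame_energy, dtype=float)
    if acts.p_s_given_t.shape[1] != frame_energy.shape[0]:
        raise ValidationError("frame energy length does not match activations")
    return SymptomActivation(p_st=acts.p_s_given_t * frame_energy[None, :],
                             symptom_names=symptom_names)
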