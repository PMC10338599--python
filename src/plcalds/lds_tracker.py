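"""Linear dynamic system tracking of symptom activations via Kalman filtering.

The energy-scaled symptom activation P(s,t) produced by the decomposition is
treated as a noisy observation y_t of a latent state z_t that stacks, per
symptom class, the clean activation level and its "velocity" (first difference
across adjacent frames):

    z_{t+1} = A z_t + eps_t,      eps_t ~ N(0, Q),  Q = alpha * I
    y_t     = H z_t + delta_t,  delta_t ~ N(0, R),  R = beta * I

The transition matrix A and observation matrix H are learned from fully
observed training sequences by least squares (z_{t-1} -> z_t and z_t -> y_t);
the noise scales default to alpha = 0.2 and beta = 0.1. Filtering forward with
the standard Kalman recursion yields the posterior mean, whose first S rows
(clipped at zero) are the temporally smoothed symptom tracks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .plca_core import SymptomActivation
from .synthetic_cohort import ValidationError

logger = logging.getLogger(__name__)


class NumericalError(RuntimeError):
    """Raised when a filter covariance loses positive semidefiniteness."""


@dataclass
class LDSParams:
    """Learned transition/observation models and fixed isotropic noise."""

    A: np.ndarray  # 2S x 2S
    H: np.ndarray  # S x 2S
    alpha: float = 0.2
    beta: float = 0.1
    z0: np.ndarray | None = None
    Sigma0: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValidationError("noise scales alpha and beta must be positive")
        n = self.A.shape[0]
        if self.A.shape != (n, n) or self.H.shape[1] != n:
            raise ValidationError("A must be square and H conformable with it")
        if self.z0 is None:
            self.z0 = np.zeros(n)
        if self.Sigma0 is None:
            self.Sigma0 = np.eye(n)

    @property
    def Q(self) -> np.ndarray:
        return self.alpha * np.eye(self.A.shape[0])

    @property
    def R(self) -> np.ndarray:
        return self.beta * np.eye(self.H.shape[0])


@dataclass
class StateSequence:
    """Latent training states: activation levels stacked over their velocities."""

    z: np.ndarray  # 2S x T

    @property
    def n_symptoms(self) -> int:
        return self.z.shape[0] // 2


@dataclass
class KalmanResult:
    """Filter output: posterior means/covariances plus per-step diagnostics."""

    means: np.ndarray  # n x T
    covariances: np.ndarray  # T x n x n
    gains: list[np.ndarray]
    predicted_covariances: np.ndarray  # T x n x n


def build_state_sequence(p_st: SymptomActivation | np.ndarray) -> StateSequence:
    """Stack activation levels and their first differences into LDS states.

    The velocity of the first frame is 0 by convention.
    """
    x = p_st.p_st if isinstance(p_st, SymptomActivation) else np.asarray(p_st, float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValidationError("state sequence needs an S x T activation with T >= 2")
    vel = np.diff(x, axis=1, prepend=x[:, :1])
    return StateSequence(z=np.vstack([x, vel]))


def _ridge_lstsq(X: np.ndarray, Y: np.ndarray, ridge: float = 1e-8) -> np.ndarray:
    """argmin_B ||Y - B X||_F^2 via normal equations with a small ridge."""
    G = X @ X.T + ridge * np.eye(X.shape[0])
    return np.linalg.solve(G, X @ Y.T).T


def learn_lds_parameters(train_states: StateSequence | list[StateSequence],
                         train_obs: np.ndarray | list[np.ndarray],
                         alpha: float = 0.2, beta: float = 0.1) -> LDSParams:
    """Least-squares estimates of A (z_{t-1} -> z_t) and H (z_t -> y_t).

    Accepts a single training sequence or a list of sequences (transition
    pairs never straddle sequence boundaries). Observations are S x T with the
    same frame count as the states.
    """
    seqs = train_states if isinstance(train_states, list) else [train_states]
    obs = train_obs if isinstance(train_obs, list) else [train_obs]
    if len(seqs) != len(obs):
        raise ValidationError("need one observation matrix per state sequence")
    Zprev, Znext, Zall, Yall = [], [], [], []
    for seq, y in zip(seqs, obs):
        z = seq.z
        y = np.asarray(y, float)
        if y.shape[1] != z.shape[1]:
            raise ValidationError("observation and state frame counts differ")
        Zprev.append(z[:, :-1])
        Znext.append(z[:, 1:])
        Zall.append(z)
        Yall.append(y)
    Zprev, Znext = np.hstack(Zprev), np.hstack(Znext)
    Zall, Yall = np.hstack(Zall), np.hstack(Yall)
    if not np.any(Zall):
        raise ValidationError("training states are identically zero")
    A = _ridge_lstsq(Zprev, Znext)
    H = _ridge_lstsq(Zall, Yall)
    return LDSParams(A=A, H=H, alpha=alpha, beta=beta)


def kalman_filter(obs: np.ndarray, params: LDSParams) -> KalmanResult:
    """Forward Kalman filter over an S x T observation sequence.

    Frames containing NaN are treated as missing and handled with a
    prediction-only step (zero gain). Covariances are symmetrised each step; a
    negative eigenvalue below -1e-8 raises :class:`NumericalError`.
    """
    y = np.asarray(obs, dtype=float)
    A, H, Q, R = params.A, params.H, params.Q, params.R
    n = A.shape[0]
    S_obs, T = y.shape
    if H.shape[0] != S_obs:
        raise ValidationError("observation dimensionality does not match H")
    mu = params.z0.copy()
    Sigma = params.Sigma0.copy()
    means = np.empty((n, T))
    covs = np.empty((T, n, n))
    pred_covs = np.empty((T, n, n))
    gains: list[np.ndarray] = []
    eye = np.eye(n)
    for t in range(T):
        # predict
        mu_pred = A @ mu
        Sigma_pred = A @ Sigma @ A.T + Q
        Sigma_pred = 0.5 * (Sigma_pred + Sigma_pred.T)
        pred_covs[t] = Sigma_pred
        if np.any(~np.isfinite(y[:, t])):
            mu, Sigma = mu_pred, Sigma_pred
            gains.append(np.zeros((n, S_obs)))
        else:
            innov_cov = H @ Sigma_pred @ H.T + R
            K = Sigma_pred @ H.T @ np.linalg.inv(innov_cov)
            resid = y[:, t] - H @ mu_pred
            mu = mu_pred + K @ resid
            Sigma = (eye - K @ H) @ Sigma_pred
            Sigma = 0.5 * (Sigma + Sigma.T)
            gains.append(K)
        if np.linalg.eigvalsh(Sigma).min() < -1e-8:
            raise NumericalError(f"filter covariance lost PSD at frame {t}")
        means[:, t] = mu
        covs[t] = Sigma
    return KalmanResult(means=means, covariances=covs, gains=gains,
                        predicted_covariances=pred_covs)


def track_symptoms(p_st: SymptomActivation | np.ndarray,
                   params: LDSParams) -> np.ndarray:
    """Temporally smoothed S x T activation: filtered posterior mean, clipped at 0."""
    x = p_st.p_st if isinstance(p_st, SymptomActivation) else np.asarray(p_st, float)
    result = kalman_filter(x, params)
    S = params.H.shape[0]
    return np.clip(result.means[:S], 0.0, None)
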