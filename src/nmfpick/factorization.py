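"""Rank-2 non-negative matrix factorization and channel reconstruction.

The scale-space feature matrix M (R x mn) is factorized as M ~= S H with
S, H >= 0 by multiplicative updates under a selectable divergence
(Frobenius, Kullback-Leibler, or the scale-invariant Itakura-Saito). With
rank 2 the two rank-1 slices reconstruct a structure channel W1 (particles)
and a background channel W2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InvalidInputError
from .scale_space import FeatureMatrix

_EPS = 1e-12

DIVERGENCES = ("frobenius", "kullback_leibler", "itakura_saito")
_BETA = {"frobenius": 2.0, "kullback_leibler": 1.0, "itakura_saito": 0.0}


@dataclass
class NNMFConfig:
    rank: int = 2
    divergence: str = "frobenius"
    max_iter: int = 500
    tol: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ConfigurationError("rank must be >= 1")
        if self.divergence not in DIVERGENCES:
            raise ConfigurationError(
                f"divergence must be one of {DIVERGENCES}, got {self.divergence!r}"
            )
        if self.max_iter < 1:
            raise ConfigurationError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ConfigurationError("tol must be positive")


@dataclass
class FactorPair:
    """NNMF factors with the per-iteration objective trace."""

    S: np.ndarray
    H: np.ndarray
    objective_trace: list[float]
    divergence: str = "frobenius"
    converged: bool = False


@dataclass
class ChannelPair:
    """Structure channel W1 and background channel W2 (both m x n, >= 0)."""

    W1: np.ndarray
    W2: np.ndarray
    assignment_score: float = field(default=1.0)


def _objective(V: np.ndarray, W_hat: np.ndarray, beta: float) -> float:
    if beta == 2.0:
        return 0.5 * float(np.sum((V - W_hat) ** 2))
    Wh = np.maximum(W_hat, _EPS)
    if beta == 1.0:
        return float(np.sum(V * np.log(V / Wh) - V + Wh))
    # Itakura-Saito
    ratio = V / Wh
    return float(np.sum(ratio - np.log(ratio) - 1.0))


def nnmf(feature_matrix: FeatureMatrix | np.ndarray, config: NNMFConfig) -> FactorPair:
    """Multiplicative-update NNMF of a nonnegative matrix.

    Initialization is seeded uniform in (0, 1]; iterations stop at
    ``max_iter`` or when the relative objective change drops below ``tol``.
    The update exponent follows the beta-divergence scheme that guarantees
    a non-increasing objective (exponent 1 for beta in [1, 2], 1/(2 - beta)
    below), so the recorded trace is monotone to numerical precision.
    """
    V = feature_matrix.values if isinstance(feature_matrix, FeatureMatrix) else feature_matrix
    V = np.asarray(V, dtype=np.float64)
    if V.ndim != 2:
        raise InvalidInputError("feature matrix must be 2D")
    if V.min() < 0:
        raise InvalidInputError("feature matrix must be nonnegative")
    R, N = V.shape
    if config.rank >= min(R, N):
        raise ConfigurationError(
            f"rank {config.rank} must be < min(R, mn) = {min(R, N)}"
        )
    beta = _BETA[config.divergence]
    if beta < 2.0:
        V = np.maximum(V, _EPS)  # KL/IS need strict positivity
    gamma = 1.0 if beta >= 1.0 else 1.0 / (2.0 - beta)

    rng = np.random.default_rng(config.seed)
    S = 1.0 - rng.random((R, config.rank))
    H = 1.0 - rng.random((config.rank, N))

    if beta == 2.0:
        v_sq = float(np.sum(V * V))  # reused by the Gram-form objective

        def _frob_obj(S: np.ndarray, H: np.ndarray) -> float:
            # 0.5||V - SH||^2 without forming SH explicitly
            StV = S.T @ V
            cross = float(np.sum(StV * H))
            gram = float(np.sum((S.T @ S) * (H @ H.T)))
            return 0.5 * (v_sq - 2.0 * cross + gram)

        trace = [_frob_obj(S, H)]
    else:
        trace = [_objective(V, S @ H, beta)]
    converged = False
    for _ in range(config.max_iter):
        if beta == 2.0:
            H *= (S.T @ V) / np.maximum(S.T @ S @ H, _EPS)
            S *= (V @ H.T) / np.maximum(S @ (H @ H.T), _EPS)
            obj = _frob_obj(S, H)
        else:
            Wh = np.maximum(S @ H, _EPS)
            num = S.T @ (Wh ** (beta - 2.0) * V)
            den = np.maximum(S.T @ Wh ** (beta - 1.0), _EPS)
            H *= (num / den) ** gamma
            Wh = np.maximum(S @ H, _EPS)
            num = (Wh ** (beta - 2.0) * V) @ H.T
            den = np.maximum(Wh ** (beta - 1.0) @ H.T, _EPS)
            S *= (num / den) ** gamma
            obj = _objective(V, S @ H, beta)
        prev = trace[-1]
        trace.append(obj)
        if abs(prev - obj) <= config.tol * max(abs(prev), _EPS):
            converged = True
            break
    return FactorPair(
        S=S, H=H, objective_trace=trace, divergence=config.divergence, converged=converged
    )


def _highpass_energy(image: np.ndarray) -> float:
    """Fraction of spectral power above the radial median frequency."""
    x = image - image.mean()
    P = np.abs(np.fft.fft2(x)) ** 2
    fy = np.fft.fftfreq(image.shape[0])
    fx = np.fft.fftfreq(image.shape[1])
    f = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    total = P.sum()
    if total <= 0:
        return 0.0
    return float(P[f > np.median(f)].sum() / total)


def assign_channels(candidate_a: np.ndarray, candidate_b: np.ndarray) -> ChannelPair:
    """Label the channel with the larger normalized high-pass energy as W1.

    Particles carry the high-spatial-frequency content, so the sharper
    channel is the structure channel. Exact ties keep component order
    (candidate_a becomes W1).
    """
    a = np.asarray(candidate_a, dtype=np.float64)
    b = np.asarray(candidate_b, dtype=np.float64)
    if a.shape != b.shape:
        raise InvalidInputError("channel candidates must share one shape")
    if a.min() < 0 or b.min() < 0:
        raise InvalidInputError("channel candidates must be nonnegative")
    ea = _highpass_energy(a)
    eb = _highpass_energy(b)
    if eb > ea:
        score = eb / max(ea, _EPS)
        return ChannelPair(W1=b, W2=a, assignment_score=score)
    score = ea / max(eb, _EPS)
    return ChannelPair(W1=a, W2=b, assignment_score=score)


def reconstruct_channels(
    factor_pair: FactorPair,
    row_meta: list | None,
    origin_shape: tuple[int, int],
) -> ChannelPair:
    """Collapse each rank-1 slice to one image and assign W1/W2.

    For component j, the R x mn rank-1 slice S[:, j] (x) H[j, :] is averaged
    over its rows — i.e. mean(S[:, j]) * H[j, :] — and reshaped to the
    origin frame, balancing all scale rows equally.
    """
    del row_meta  # provenance only; all scale rows weigh equally
    if factor_pair.S.shape[1] != 2 or factor_pair.H.shape[0] != 2:
        raise ConfigurationError("channel reconstruction requires rank 2 factors")
    m, n = origin_shape
    cand = [
        (factor_pair.S[:, j].mean() * factor_pair.H[j]).reshape(m, n) for j in (0, 1)
    ]
    return assign_channels(cand[0], cand[1])
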