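"""Pseudo position-specific scoring matrix (PsePSSM) descriptors.

An L x 20 evolutionary profile is first squashed elementwise through the
sigmoid ``f(x) = 1 / (1 + exp(-x))`` and then summarised by

* 20 column means (the PSSM-ACC composition), and
* for each lag t = 1..xi, 20 lagged squared-difference correlations
  ``theta_j^t = mean_i (f(P)_{i,j} - f(P)_{i+t,j})^2``,

giving a ``20 + 20 * xi`` vector per protein regardless of its length.
Lags are concatenated tier-major: all 20 columns of tier 1, then tier 2, ...

For offline work (no PSI-BLAST run available) :func:`surrogate_pssm`
fabricates a profile from BLOSUM62 substitution rows plus Gaussian noise;
real profiles parsed from PSI-BLAST ASCII output are handled identically.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices
from sklearn.base import BaseEstimator, TransformerMixin

from .io import PSSM_COLUMN_ORDER, ProteinRecord, PssmProfile
from .pseaac import ParameterBoundError

DEFAULT_XI = 10

_BLOSUM_CACHE: dict[str, np.ndarray] | None = None


def _blosum62_rows() -> dict[str, np.ndarray]:
    """BLOSUM62 row per residue, columns in PSI-BLAST PSSM order."""
    global _BLOSUM_CACHE
    if _BLOSUM_CACHE is None:
        mat = substitution_matrices.load("BLOSUM62")
        _BLOSUM_CACHE = {
            aa: np.array([mat[aa, bb] for bb in PSSM_COLUMN_ORDER], dtype=float)
            for aa in PSSM_COLUMN_ORDER
        }
    return _BLOSUM_CACHE


def sigmoid_normalize(profile: PssmProfile) -> np.ndarray:
    """Map raw log-odds scores into (0, 1) elementwise: 1 / (1 + e^-x)."""
    # expit via stable formulation; scores are small integers so plain is fine
    return 1.0 / (1.0 + np.exp(-profile.scores))


def mean_profile(norm: np.ndarray) -> np.ndarray:
    """Column means of the normalized profile (the 20-dim PSSM-ACC vector)."""
    norm = np.asarray(norm, dtype=float)
    return norm.mean(axis=0)


def psepssm_correlation(norm: np.ndarray, xi: int) -> np.ndarray:
    """Lagged squared-difference correlations, tiers 1..xi concatenated.

    ``theta_j^t = (1/(L-t)) * sum_i (norm[i,j] - norm[i+t,j])^2``.
    Returns a ``20 * xi`` vector; requires ``1 <= xi < L``.
    """
    norm = np.asarray(norm, dtype=float)
    L = norm.shape[0]
    if xi < 1 or xi >= L:
        raise ParameterBoundError(
            f"xi={xi} not admissible for profile length L={L}; require 1 <= xi <= {L - 1}"
        )
    tiers = []
    for t in range(1, xi + 1):
        diff = norm[:-t] - norm[t:]
        tiers.append((diff**2).sum(axis=0) / (L - t))
    return np.concatenate(tiers)


def psepssm_vector(profile: PssmProfile, xi: int = DEFAULT_XI) -> np.ndarray:
    """The ``20 + 20 * xi`` PsePSSM descriptor of a profile.

    ``xi=0`` degenerates to the plain 20-dim PSSM-ACC composition.
    """
    if xi < 0 or xi >= profile.length:
        raise ParameterBoundError(
            f"xi={xi} not admissible for profile length L={profile.length}"
        )
    norm = sigmoid_normalize(profile)
    parts = [mean_profile(norm)]
    if xi > 0:
        parts.append(psepssm_correlation(norm, xi))
    return np.concatenate(parts)


def surrogate_pssm(
    record: ProteinRecord, noise_sd: float = 2.0, seed: int = 0
) -> PssmProfile:
    """Fabricate a plausible profile for a sequence without a database search.

    Row i is the BLOSUM62 substitution row of residue i (PSI-BLAST column
    order) plus independent Gaussian noise of standard deviation
    ``noise_sd``, rounded to integers.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    rows = _blosum62_rows()
    base = np.array([rows[aa] for aa in record.sequence])
    if noise_sd > 0:
        base = base + rng.normal(0.0, noise_sd, size=base.shape)
    return PssmProfile(id=record.id, scores=np.round(base))


class PsePssmEncoder(TransformerMixin, BaseEstimator):
    """Transform PSSM profiles (or records, via surrogate profiles) into
    PsePSSM descriptors.

    Parameters
    ----------
    xi : int, default 10
        Number of lag tiers; must be smaller than every profile length.
    surrogate_noise_sd : float, default 2.0
        Noise level for surrogate profiles generated when a record rather
        than a profile is supplied.
    seed : int, default 0
        Seed for surrogate-profile noise.
    """

    def __init__(self, xi: int = DEFAULT_XI, surrogate_noise_sd: float = 2.0,
                 seed: int = 0):
        self.xi = xi
        self.surrogate_noise_sd = surrogate_noise_sd
        self.seed = seed

    def fit(self, X, y=None):
        self.n_features_out_ = 20 + 20 * self.xi
        return self

    def transform(self, X) -> np.ndarray:
        """``X`` is a sequence of :class:`PssmProfile` or :class:`ProteinRecord`
        (records get deterministic surrogate profiles)."""
        profiles = []
        for i, x in enumerate(X):
            if isinstance(x, PssmProfile):
                profiles.append(x)
            elif isinstance(x, ProteinRecord):
                profiles.append(
                    surrogate_pssm(x, self.surrogate_noise_sd, seed=self.seed + i)
                )
            else:
                raise TypeError(f"expected PssmProfile or ProteinRecord, got {type(x)}")
        return np.array([psepssm_vector(p, self.xi) for p in profiles])
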