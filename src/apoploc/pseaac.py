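"""Chou's pseudo-amino-acid composition (type 1).

A sequence of length L is summarised by 20 residue frequencies plus
``lam`` sequence-order correlation factors computed from three
physicochemical properties (hydrophobicity, hydrophilicity, side-chain
mass), giving a ``20 + lam`` vector

    p_u = f_u / (sum_v f_v + w * sum_k tau_k)          for u = 1..20
    p_u = w * tau_{u-20} / (sum_v f_v + w * sum_k tau_k)  for u = 21..20+lam

where tau_k averages the squared property differences between residues k
positions apart.  The weight ``w`` (omega) defaults to 0.05 and the tier
count ``lam`` (lambda) must be strictly smaller than the sequence length.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import AMINO_ACIDS, ProteinRecord

DEFAULT_LAMBDA = 15
DEFAULT_OMEGA = 0.05


class PropertyTableError(ValueError):
    """Raised for incomplete or degenerate amino-acid property tables."""


class ParameterBoundError(ValueError):
    """Raised when a correlation tier count is not admissible for a sequence."""


def load_property_table(path=None) -> pd.DataFrame:
    """Load the raw amino-acid property table (columns: hydrophobicity,
    hydrophilicity, mass; index: one-letter residue codes).

    By default the bundled canonical table is used; pass ``path`` to
    override with a user TSV of the same layout (``aa  H1  H2  M``).
    """
    if path is None:
        ref = resources.files("apoploc.data").joinpath("aa_properties.tsv")
        with resources.as_file(ref) as p:
            table = pd.read_csv(p, sep="\t", index_col="aa")
    else:
        table = pd.read_csv(path, sep="\t", index_col="aa")
    missing = set(AMINO_ACIDS) - set(table.index)
    if missing:
        raise PropertyTableError(f"property table missing residues {sorted(missing)}")
    return table.loc[list(AMINO_ACIDS)]


def standardize_properties(raw: pd.DataFrame) -> pd.DataFrame:
    """Zero-mean, unit-SD standardization of each property over the 20
    amino acids (population SD).  Idempotent up to floating-point error."""
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0, ddof=0)
    if (sd == 0).any():
        cols = list(sd.index[sd == 0])
        raise PropertyTableError(f"constant property column(s) {cols}: SD is zero")
    return (raw - mean) / sd


_PROPS_CACHE: pd.DataFrame | None = None


def default_properties() -> pd.DataFrame:
    """Bundled property table, standardized; cached."""
    global _PROPS_CACHE
    if _PROPS_CACHE is None:
        _PROPS_CACHE = standardize_properties(load_property_table())
    return _PROPS_CACHE


def correlation_theta(ri: str, rj: str, props: pd.DataFrame) -> float:
    """Pairwise correlation Theta(R_i, R_j): mean squared difference of the
    three standardized properties.  Symmetric, zero for identical residues."""
    try:
        a = props.loc[ri].to_numpy()
        b = props.loc[rj].to_numpy()
    except KeyError as exc:
        raise KeyError(f"unknown residue in pair ({ri!r}, {rj!r})") from exc
    return float(np.mean((b - a) ** 2))


def _property_arrays(seq: str, props: pd.DataFrame) -> np.ndarray:
    """Per-position property matrix (L x 3) for a sanitized sequence."""
    idx = props.index.get_indexer(list(seq))
    if (idx < 0).any():
        bad = sorted({seq[i] for i in np.where(idx < 0)[0]})
        raise KeyError(f"unknown residues {bad} in sequence")
    return props.to_numpy()[idx]


def tau_factors(seq: str, lam: int, props: pd.DataFrame | None = None) -> np.ndarray:
    """Tier correlation factors tau_k = mean_i Theta(R_i, R_{i+k}), k = 1..lam."""
    if props is None:
        props = default_properties()
    L = len(seq)
    if lam < 0 or lam >= L:
        raise ParameterBoundError(
            f"lambda={lam} not admissible for sequence length L={L}; "
            f"require 0 <= lambda <= {L - 1}"
        )
    if lam == 0:
        return np.zeros(0)
    pp = _property_arrays(seq, props)  # L x 3
    taus = np.empty(lam)
    for k in range(1, lam + 1):
        diff = pp[k:] - pp[:-k]
        taus[k - 1] = np.mean(diff**2, axis=1).sum() / (L - k)
    return taus


def composition(seq: str) -> np.ndarray:
    """Occurrence frequencies of the 20 amino acids (sums to 1)."""
    L = len(seq)
    counts = np.array([seq.count(a) for a in AMINO_ACIDS], dtype=float)
    return counts / L


def pseaac_vector(
    seq: str,
    lam: int = DEFAULT_LAMBDA,
    omega: float = DEFAULT_OMEGA,
    props: pd.DataFrame | None = None,
) -> np.ndarray:
    """The ``20 + lam`` pseudo-amino-acid composition vector of a sequence.

    Components are non-negative and sum to one.
    """
    if not seq:
        raise ValueError("empty sequence")
    if omega <= 0:
        raise ValueError(f"omega must be > 0, got {omega}")
    if props is None:
        props = default_properties()
    f = composition(seq)
    taus = tau_factors(seq, lam, props)
    denom = f.sum() + omega * taus.sum()
    return np.concatenate([f, omega * taus]) / denom


class PseAACEncoder(TransformerMixin, BaseEstimator):
    """Transform protein records into pseudo-amino-acid composition vectors.

    Parameters
    ----------
    lam : int, default 15
        Number of sequence-order correlation tiers; must be smaller than
        every sequence length.
    omega : float, default 0.05
        Weight of the correlation tiers relative to composition.
    property_table : str or None
        Path to a TSV overriding the bundled physicochemical property table.

    Attributes
    ----------
    props_ : pandas.DataFrame
        Standardized property table used for the correlation factors.
    n_features_out_ : int
        Output dimension, ``20 + lam``.
    """

    def __init__(self, lam: int = DEFAULT_LAMBDA, omega: float = DEFAULT_OMEGA,
                 property_table=None):
        self.lam = lam
        self.omega = omega
        self.property_table = property_table

    def fit(self, X, y=None):
        if self.property_table is None:
            self.props_ = default_properties()
        else:
            self.props_ = standardize_properties(load_property_table(self.property_table))
        self.n_features_out_ = 20 + self.lam
        return self

    def transform(self, X) -> np.ndarray:
        """``X`` is a sequence of :class:`ProteinRecord` or residue strings."""
        if not hasattr(self, "props_"):
            self.fit(X)
        seqs = [x.sequence if isinstance(x, ProteinRecord) else x for x in X]
        too_short = [i for i, s in enumerate(seqs) if len(s) <= self.lam]
        if too_short:
            raise ParameterBoundError(
                f"lambda={self.lam} >= sequence length for {len(too_short)} "
                f"record(s) (first indices: {too_short[:5]})"
            )
        return np.array(
            [pseaac_vector(s, self.lam, self.omega, self.props_) for s in seqs]
        )
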