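"""Fused PseAAC + PsePSSM feature matrices.

Each protein contributes one row: its ``20 + lam`` pseudo-amino-acid
composition followed by its ``20 + 20 * xi`` PsePSSM descriptor, so the
dataset becomes an ``n x ((20 + lam) + (20 + 20 * xi))`` matrix (255
columns at the default operating point lam=15, xi=10).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import LabeledDataset
from .pseaac import DEFAULT_LAMBDA, DEFAULT_OMEGA, ParameterBoundError, PseAACEncoder
from .psepssm import DEFAULT_XI, PsePssmEncoder


@dataclass
class FeatureMatrix:
    """An n x d feature matrix with row identity, labels and column blocks."""

    values: np.ndarray
    row_ids: list[str]
    labels: list[str]
    column_blocks: dict[str, tuple[int, int]] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, d = self.values.shape
        if len(self.row_ids) != n or len(self.labels) != n:
            raise ValueError(
                f"row_ids/labels length must match {n} rows "
                f"(got {len(self.row_ids)}, {len(self.labels)})"
            )
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains NaN")
        for name, (lo, hi) in self.column_blocks.items():
            if not (0 <= lo < hi <= d):
                raise ValueError(f"column block {name!r} span ({lo}, {hi}) out of range")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def block(self, name: str) -> np.ndarray:
        lo, hi = self.column_blocks[name]
        return self.values[:, lo:hi]

    def with_values(self, values: np.ndarray) -> "FeatureMatrix":
        """Copy carrying new values but the same ids/labels/blocks."""
        return FeatureMatrix(
            values=values,
            row_ids=list(self.row_ids),
            labels=list(self.labels),
            column_blocks=dict(self.column_blocks),
            params=dict(self.params),
        )


def build_matrix(
    data: LabeledDataset,
    lam: int = DEFAULT_LAMBDA,
    omega: float = DEFAULT_OMEGA,
    xi: int = DEFAULT_XI,
    profile_source: str = "auto",
    surrogate_noise_sd: float = 2.0,
    seed: int = 0,
) -> FeatureMatrix:
    """Build the fused n x ((20+lam)+(20+20*xi)) feature matrix of a dataset.

    ``profile_source`` is ``"real"`` (dataset must carry parsed profiles),
    ``"surrogate"`` (always fabricate), or ``"auto"`` (use parsed profiles
    when present, surrogates otherwise).
    """
    min_len = data.min_length()
    bound = max(lam, xi)
    offenders = [r.id for r in data.records if len(r) <= bound]
    if offenders:
        raise ParameterBoundError(
            f"lambda={lam}, xi={xi} require sequence length > {bound}; "
            f"{len(offenders)} record(s) violate this (first: {offenders[:5]}); "
            f"dataset minimum length is {min_len}"
        )

    pse = PseAACEncoder(lam=lam, omega=omega).fit(data.records)
    A = pse.transform(data.records)

    pp = PsePssmEncoder(xi=xi, surrogate_noise_sd=surrogate_noise_sd, seed=seed).fit(None)
    if profile_source == "real" or (profile_source == "auto" and data.profiles):
        if not data.profiles:
            raise ValueError("profile_source='real' but the dataset has no profiles")
        B = pp.transform([data.profiles[r.id] for r in data.records])
    elif profile_source in ("surrogate", "auto"):
        B = pp.transform(data.records)
    else:
        raise ValueError(f"unknown profile_source {profile_source!r}")

    d_a, d_b = A.shape[1], B.shape[1]
    return FeatureMatrix(
        values=np.hstack([A, B]),
        row_ids=[r.id for r in data.records],
        labels=[r.label for r in data.records],
        column_blocks={"pseaac": (0, d_a), "psepssm": (d_a, d_a + d_b)},
        params={"lam": lam, "omega": omega, "xi": xi,
                "profile_source": profile_source, "seed": seed},
    )


def write_feature_table(matrix: FeatureMatrix, path) -> None:
    """Serialize a feature matrix as TSV (``id  label  f1 .. fd``) with
    enough digits for a lossless round-trip at working precision."""
    if any(lbl is None for lbl in matrix.labels):
        raise ValueError("cannot serialize a feature matrix with missing labels")
    with open(path, "w", encoding="utf-8") as fh:
        header = ["id", "label"] + [f"f{i + 1}" for i in range(matrix.d)]
        fh.write("\t".join(header) + "\n")
        for rid, lbl, row in zip(matrix.row_ids, matrix.labels, matrix.values):
            vals = "\t".join(f"{v:.12g}" for v in row)
            fh.write(f"{rid}\t{lbl}\t{vals}\n")


def read_feature_table(path) -> FeatureMatrix:
    """Read a TSV feature table written by :func:`write_feature_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "label": str})
    feat_cols = [c for c in df.columns if c not in ("id", "label")]
    return FeatureMatrix(
        values=df[feat_cols].to_numpy(dtype=float),
        row_ids=df["id"].tolist(),
        labels=df["label"].tolist(),
    )


class FusedFeatureEncoder(TransformerMixin, BaseEstimator):
    """sklearn-style wrapper around :func:`build_matrix` returning the raw
    numeric array (use :func:`build_matrix` when row ids/blocks matter)."""

    def __init__(self, lam: int = DEFAULT_LAMBDA, omega: float = DEFAULT_OMEGA,
                 xi: int = DEFAULT_XI, profile_source: str = "auto",
                 surrogate_noise_sd: float = 2.0, seed: int = 0):
        self.lam = lam
        self.omega = omega
        self.xi = xi
        self.profile_source = profile_source
        self.surrogate_noise_sd = surrogate_noise_sd
        self.seed = seed

    def fit(self, X: LabeledDataset, y=None):
        self.n_features_out_ = (20 + self.lam) + (20 + 20 * self.xi)
        return self

    def transform(self, X: LabeledDataset) -> np.ndarray:
        self.fit(X)
        matrix = build_matrix(
            X, lam=self.lam, omega=self.omega, xi=self.xi,
            profile_source=self.profile_source,
            surrogate_noise_sd=self.surrogate_noise_sd, seed=self.seed,
        )
        self.feature_matrix_ = matrix
        return matrix.values
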