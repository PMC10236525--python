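"""Individual-level cluster-randomized trial data container.

One row per participant: cluster identifier, cluster-level treatment ``D``,
survival indicator ``S``, outcome ``Y`` (missing exactly when the
participant died, i.e. the outcome is truncated), and a covariate design
row whose first column is the constant 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CRTDataset"]


@dataclass
class CRTDataset:
    """Validated arrays for a two-arm CRT with death truncation.

    Attributes
    ----------
    cluster
        Integer cluster codes ``0..I-1``, one per row.
    D
        Treatment indicator per row; constant within cluster.
    S
        Survival indicator per row.
    Y
        Outcome per row, ``nan`` exactly where ``S == 0``.
    X
        Design matrix ``(n, p)``; first column is the intercept 1.
    covariate_names
        Names of the non-intercept columns of ``X``.
    cluster_labels
        Original cluster identifiers, indexed by cluster code.
    """

    cluster: np.ndarray
    D: np.ndarray
    S: np.ndarray
    Y: np.ndarray
    X: np.ndarray
    covariate_names: list[str] = field(default_factory=list)
    cluster_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cluster = np.asarray(self.cluster, dtype=np.int64)
        self.D = np.asarray(self.D, dtype=np.int8)
        self.S = np.asarray(self.S, dtype=np.int8)
        self.Y = np.asarray(self.Y, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if not self.covariate_names:
            self.covariate_names = [f"X{k}" for k in range(1, self.X.shape[1])]
        if self.cluster_labels is None:
            self.cluster_labels = np.arange(self.n_clusters)
        self.validate()

    # -- basic shape -----------------------------------------------------
    @property
    def n(self) -> int:
        return self.cluster.size

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n_clusters(self) -> int:
        return int(self.cluster.max()) + 1 if self.n else 0

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.cluster, minlength=self.n_clusters)

    @property
    def D_cluster(self) -> np.ndarray:
        """Treatment indicator per cluster."""
        out = np.zeros(self.n_clusters, dtype=np.int8)
        out[self.cluster] = self.D
        return out

    def validate(self) -> None:
        n = self.n
        for name, arr in (("D", self.D), ("S", self.S), ("Y", self.Y)):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per row")
        if self.X.shape[0] != n:
            raise ValueError("X must have one row per participant")
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("first design column must be the constant 1")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite covariates")
        if not np.all(np.isin(self.D, (0, 1))) or not np.all(np.isin(self.S, (0, 1))):
            raise ValueError("D and S must be 0/1")
        # treatment is assigned at the cluster level
        first = np.full(self.n_clusters, n, dtype=np.int64)
        np.minimum.at(first, self.cluster, np.arange(n))
        bad = np.flatnonzero(self.D != self.D[first[self.cluster]])
        if bad.size:
            raise ValueError(
                f"treatment varies within cluster at rows {bad[:10].tolist()}"
            )
        # the outcome exists exactly for survivors
        bad = np.flatnonzero(np.isnan(self.Y) != (self.S == 0))
        if bad.size:
            raise ValueError(
                "Y must be present iff S=1; violated at rows "
                f"{bad[:10].tolist()} ({bad.size} rows total)"
            )

    # -- pandas / disk round trip ---------------------------------------
    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, covariates: list[str] | None = None
    ) -> "CRTDataset":
        """Build a dataset from a table with columns cluster, D, S, Y, X1...

        ``covariates`` defaults to every column other than cluster/D/S/Y, in
        table order.  Cluster identifiers may be arbitrary labels; they are
        factorized to consecutive codes.
        """
        required = {"cluster", "D", "S", "Y"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing required columns: {sorted(missing)}")
        if covariates is None:
            covariates = [c for c in df.columns if c not in required]
        codes, labels = pd.factorize(df["cluster"], sort=True)
        X = np.column_stack(
            [np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in covariates]
        )
        return cls(
            cluster=codes,
            D=df["D"].to_numpy(),
            S=df["S"].to_numpy(),
            Y=df["Y"].to_numpy(dtype=float),
            X=X,
            covariate_names=list(covariates),
            cluster_labels=np.asarray(labels),
        )

    def to_dataframe(self) -> pd.DataFrame:
        cols = {
            "cluster": self.cluster_labels[self.cluster],
            "D": self.D,
            "S": self.S,
            "Y": self.Y,
        }
        for k, name in enumerate(self.covariate_names, start=1):
            cols[name] = self.X[:, k]
        return pd.DataFrame(cols)

    @classmethod
    def read_csv(cls, path: str | Path, covariates: list[str] | None = None) -> "CRTDataset":
        return cls.from_dataframe(pd.read_csv(path), covariates=covariates)

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)
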