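"""Readers and writers for omics expression matrices and PPI edge lists.

Expression files are plain TSV: a header row of feature identifiers and a
first column of sample identifiers, so a file with ``n`` samples and ``p``
features has ``n + 1`` rows and ``p + 1`` columns. PPI files are two- or
three-column edge lists (source, target[, score]); the score column, when
present, is ignored because score filtering happens upstream of this
package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("pdjdsnmf")

__all__ = [
    "OmicsMatrix",
    "PriorNetwork",
    "read_omics_matrix",
    "write_omics_matrix",
    "read_ppi_edges",
    "write_ppi_edges",
]


@dataclass
class OmicsMatrix:
    """One samples x features expression matrix with identifiers.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_features)
        Finite numeric expression values.
    sample_ids : list of str
        Row identifiers, unique, in row order.
    feature_ids : list of str
        Column identifiers, unique, in column order.
    omics_name : str
        Label such as ``"mrna"``, ``"lncrna"`` or ``"mirna"``.
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    omics_name: str = "omics"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"{self.omics_name}: values must be 2-D")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"{self.omics_name}: non-finite value at row {bad[0]}, column {bad[1]}"
            )
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{self.omics_name}: {len(self.sample_ids)} sample ids for {n} rows")
        if len(self.feature_ids) != p:
            raise ValueError(f"{self.omics_name}: {len(self.feature_ids)} feature ids for {p} columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError(f"{self.omics_name}: duplicate sample ids")
        if len(set(self.feature_ids)) != p:
            raise ValueError(f"{self.omics_name}: duplicate feature ids")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, omics_name: str = "omics") -> "OmicsMatrix":
        """Build from a samples x features DataFrame (index = sample ids)."""
        return cls(
            values=df.to_numpy(dtype=float),
            sample_ids=[str(i) for i in df.index],
            feature_ids=[str(c) for c in df.columns],
            omics_name=omics_name,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)


@dataclass
class PriorNetwork:
    """Symmetric binary feature-feature adjacency (a PPI prior).

    The adjacency is aligned to the feature order of one omics matrix:
    ``feature_ids`` must equal that matrix's ``feature_ids`` in the same
    order. Entries are 0/1, the diagonal is zero.
    """

    adjacency: np.ndarray
    feature_ids: list[str]
    dropped_edges: int = 0

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(A, (0.0, 1.0)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        self.adjacency = A
        self.feature_ids = [str(f) for f in self.feature_ids]
        if len(self.feature_ids) != A.shape[0]:
            raise ValueError("feature_ids length must match adjacency size")

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)


def read_omics_matrix(path, omics_name: str = "omics", transpose: bool = False) -> OmicsMatrix:
    """Read a TSV expression matrix (header = feature ids, col 1 = sample ids).

    ``transpose=True`` accommodates files stored features x samples.
    Non-numeric cells and duplicated identifiers raise ``ValueError`` naming
    the offending cell.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        raise ValueError(f"{path}: duplicate ids in header row")
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    df.columns = header
    if transpose:
        df = df.T
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            try:
                v = float(raw[i, j])
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-numeric cell at sample '{df.index[i]}', feature '{df.columns[j]}': {raw[i, j]!r}"
                ) from None
            if not np.isfinite(v):
                raise ValueError(
                    f"{path}: non-finite cell at sample '{df.index[i]}', feature '{df.columns[j]}'"
                )
            values[i, j] = v
    om = OmicsMatrix(values, list(df.index), list(df.columns), omics_name)
    logger.info("read %s: %d samples x %d features from %s", omics_name, om.n_samples, om.n_features, path)
    return om


def write_omics_matrix(om: OmicsMatrix, path) -> None:
    """Write the matrix in the same TSV dialect ``read_omics_matrix`` reads."""
    om.to_dataframe().to_csv(path, sep="\t", index_label="sample")


def read_ppi_edges(path, features: list[str]) -> PriorNetwork:
    """Read a 2/3-column TSV edge list into a binary adjacency over ``features``.

    Self-loops are removed; edges naming features outside ``features`` are
    dropped and counted in ``PriorNetwork.dropped_edges``.
    """
    features = [str(f) for f in features]
    if len(features) == 0:
        raise ValueError("empty feature list")
    index = {f: i for i, f in enumerate(features)}
    p = len(features)
    A = np.zeros((p, p))
    dropped = 0
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: edge list needs at least two columns")
    for a, b in zip(df.iloc[:, 0], df.iloc[:, 1]):
        a, b = str(a), str(b)
        if a == b:
            continue  # self-loop
        ia, ib = index.get(a), index.get(b)
        if ia is None or ib is None:
            dropped += 1
            continue
        A[ia, ib] = 1.0
        A[ib, ia] = 1.0
    if dropped:
        logger.info("read_ppi_edges: dropped %d edges naming unknown features", dropped)
    return PriorNetwork(A, features, dropped_edges=dropped)


def write_ppi_edges(net: PriorNetwork, path) -> None:
    ii, jj = np.nonzero(np.triu(net.adjacency, k=1))
    with open(path, "w") as fh:
        for i, j in zip(ii, jj):
            fh.write(f"{net.feature_ids[i]}\t{net.feature_ids[j]}\n")
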