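"""Participant-by-variable data containers and their on-disk format.

A :class:`DataBlock` holds one side of the analysis (imaging or behaviour)
as a dense float matrix with missing cells encoded as NaN, plus ordered
participant IDs and variable names. A :class:`ConfoundTable` holds the
per-participant nuisance covariates (site, scan sequence, sex, age, global
volume, ...) used for residualisation and post-hoc adjustment.

Blocks round-trip through tab-separated text: first column
``participant_id``, remaining columns variables, missing cells empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DataBlock", "ConfoundTable"]


def _check_unique(names, what: str) -> None:
    seen = pd.Index(names)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups}")


@dataclass
class DataBlock:
    """Dense participant × variable matrix with explicit missingness.

    Parameters
    ----------
    values
        Float matrix, shape (n_participants, n_variables). NaN marks a
        missing cell.
    participant_ids, variable_names
        Ordered, unique labels for rows and columns.
    """

    values: np.ndarray
    participant_ids: list[str]
    variable_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        self.participant_ids = [str(p) for p in self.participant_ids]
        self.variable_names = [str(v) for v in self.variable_names]
        n, p = self.values.shape
        if len(self.participant_ids) != n or len(self.variable_names) != p:
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.participant_ids)} ids × {len(self.variable_names)} names"
            )
        _check_unique(self.participant_ids, "participant ids")
        _check_unique(self.variable_names, "variable names")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean observed-ness mask; True where the value is defined."""
        return ~np.isnan(self.values)

    @property
    def is_complete(self) -> bool:
        return bool(self.mask.all())

    def copy(self) -> "DataBlock":
        return DataBlock(self.values.copy(), list(self.participant_ids),
                         list(self.variable_names))

    # -- selection ---------------------------------------------------------
    def subset_participants(self, ids) -> "DataBlock":
        idx = pd.Index(self.participant_ids).get_indexer(list(ids))
        if (idx < 0).any():
            missing = [i for i, j in zip(ids, idx) if j < 0]
            raise KeyError(f"unknown participant ids: {missing[:5]}")
        return DataBlock(self.values[idx], list(ids), list(self.variable_names))

    def subset_variables(self, names) -> "DataBlock":
        idx = pd.Index(self.variable_names).get_indexer(list(names))
        if (idx < 0).any():
            missing = [n for n, j in zip(names, idx) if j < 0]
            raise KeyError(f"unknown variables: {missing[:5]}")
        return DataBlock(self.values[:, idx], list(self.participant_ids),
                         list(names))

    def take_rows(self, indices) -> "DataBlock":
        indices = np.asarray(indices)
        return DataBlock(self.values[indices],
                         [self.participant_ids[i] for i in indices],
                         list(self.variable_names))

    def check_aligned(self, other: "DataBlock") -> None:
        if self.participant_ids != other.participant_ids:
            raise ValueError("blocks are not row-aligned (participant ids differ)")

    # -- pandas / disk -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.participant_ids,
                                                        name="participant_id"),
                            columns=self.variable_names)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DataBlock":
        return cls(frame.to_numpy(dtype=float),
                   [str(i) for i in frame.index],
                   [str(c) for c in frame.columns])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", na_rep="")

    @classmethod
    def read_tsv(cls, path) -> "DataBlock":
        frame = pd.read_csv(path, sep="\t", index_col="participant_id")
        return cls.from_frame(frame)


@dataclass
class ConfoundTable:
    """Per-participant covariates split into categorical and continuous.

    ``frame`` is indexed by participant_id; ``categorical`` and
    ``continuous`` name its columns by role. Categorical levels are kept as
    strings and dummy-coded (first level = reference) at residualisation
    time.
    """

    frame: pd.DataFrame
    categorical: list[str] = field(default_factory=list)
    continuous: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        unknown = [c for c in self.categorical + self.continuous
                   if c not in self.frame.columns]
        if unknown:
            raise KeyError(f"confound columns not in table: {unknown}")
        if self.frame.index.has_duplicates:
            raise ValueError("duplicate participant ids in confound table")
        self.frame = self.frame.copy()
        self.frame.index = self.frame.index.astype(str)
        for c in self.categorical:
            col = self.frame[c].astype(str)
            if (col.str.len() == 0).any():
                raise ValueError(f"empty level in categorical confound {c!r}")
            self.frame[c] = col
        for c in self.continuous:
            self.frame[c] = self.frame[c].astype(float)

    @property
    def participant_ids(self) -> list[str]:
        return [str(i) for i in self.frame.index]

    def aligned_to(self, block: DataBlock) -> "ConfoundTable":
        """Reorder rows to the block's participants; error on mismatch."""
        missing = set(block.participant_ids) - set(self.participant_ids)
        if missing:
            raise KeyError(
                f"confound table lacks {len(missing)} block participants, "
                f"e.g. {sorted(missing)[:5]}")
        return ConfoundTable(self.frame.loc[block.participant_ids],
                             list(self.categorical), list(self.continuous))

    def design_matrix(self, spec: list[str]) -> tuple[np.ndarray, list[str]]:
        """Intercept + dummy-coded categoricals (first-level reference) +
        continuous columns, in the order given by ``spec``.

        Raises on a rank-deficient design, naming the collinear columns.
        """
        cols: list[np.ndarray] = [np.ones(len(self.frame))]
        names: list[str] = ["intercept"]
        for name in spec:
            if name in self.categorical:
                levels = sorted(self.frame[name].unique())
                for lev in levels[1:]:
                    cols.append((self.frame[name] == lev).to_numpy(float))
                    names.append(f"{name}[{lev}]")
            elif name in self.continuous:
                cols.append(self.frame[name].to_numpy(float))
                names.append(name)
            else:
                raise KeyError(f"unknown confound {name!r}")
        X = np.column_stack(cols)
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # identify offending columns via pivoted QR
            from scipy.linalg import qr
            _, _, piv = qr(X, mode="economic", pivoting=True)
            bad = [names[i] for i in piv[rank:]]
            raise ValueError(f"rank-deficient confound design; collinear columns: {bad}")
        return X, names

    def write_tsv(self, path) -> None:
        out = self.frame.copy()
        out.index.name = "participant_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path, categorical: list[str], continuous: list[str]) -> "ConfoundTable":
        frame = pd.read_csv(path, sep="\t", index_col="participant_id")
        return cls(frame, categorical, continuous)
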