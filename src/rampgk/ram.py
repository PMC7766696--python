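"""Residue adjacency matrix (RAM) construction and feature flattening.

For a target lysine at 1-based position ``k`` in a sequence, the RAM is a
20 x n matrix whose row ``i``, column ``j`` entry is the absolute sequence
distance ``|idx - k|`` from the lysine to the j-th nearest residue of
type ``i`` (rows ordered as in :mod:`rampgk.alphabet`).  The target lysine
itself counts as its own nearest lysine, at distance 0.

Two imputation rules fill slots the sequence cannot supply:

* rule A — a residue type present fewer than n times has its remaining
  slots filled with the mean of that row's observed distances;
* rule B — a residue type absent from the sequence has its whole row
  filled with the mean of *all* observed (raw, un-imputed) distances in
  the matrix.

Flattening concatenates a retained subset of rows, row-major (residue
type major, neighbor rank minor), giving the classifier's feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import json
import numpy as np
import pandas as pd

from .alphabet import RESIDUE_ORDER, in_alphabet_order, row_index
from .sequence_io import Dataset


@dataclass(frozen=True)
class FeatureSchema:
    """The contract under which feature vectors are comparable.

    ``retained`` is the tuple of residue-type rows kept (alphabet order)
    and ``n`` the number of nearest-neighbor columns per row.
    """

    retained: tuple[str, ...]
    n: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "retained", in_alphabet_order(self.retained))
        if not self.retained:
            raise ValueError("retained residue set must be non-empty")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")

    @property
    def n_features(self) -> int:
        return len(self.retained) * self.n

    def column_names(self) -> list[str]:
        return [f"{r}_{j}" for r in self.retained for j in range(1, self.n + 1)]

    def column_slice(self, residue: str) -> slice:
        """Columns of one residue's row within the flattened vector."""
        i = self.retained.index(residue)
        return slice(i * self.n, (i + 1) * self.n)

    def drop(self, residue: str) -> "FeatureSchema":
        if residue not in self.retained:
            raise ValueError(f"{residue} not in retained set")
        return FeatureSchema(
            retained=tuple(r for r in self.retained if r != residue), n=self.n
        )

    def to_dict(self) -> dict:
        return {
            "retained": list(self.retained),
            "n": self.n,
            "alphabet": list(RESIDUE_ORDER),
            "flattening": "row-major",
        }


def full_schema(n: int = 6) -> FeatureSchema:
    return FeatureSchema(retained=RESIDUE_ORDER, n=n)


def eliminated_schema(eliminated: Sequence[str], n: int = 6) -> FeatureSchema:
    """Schema with the given residue rows removed from the full alphabet."""
    dropped = set(eliminated)
    unknown = dropped - set(RESIDUE_ORDER)
    if unknown:
        raise ValueError(f"unknown residue codes: {sorted(unknown)}")
    return FeatureSchema(
        retained=tuple(r for r in RESIDUE_ORDER if r not in dropped), n=n
    )


@dataclass
class ResidueAdjacencyMatrix:
    """20 x n nearest-residue distance matrix for one lysine site."""

    values: np.ndarray  # (20, n) float
    imputed_mask: np.ndarray  # (20, n) bool, True where a rule filled the slot
    n: int
    target_position: int  # 1-based
    protein_id: str = ""

    def row(self, residue: str) -> np.ndarray:
        return self.values[row_index(residue)]


@dataclass
class FeatureVector:
    values: np.ndarray
    schema: FeatureSchema


@dataclass
class FeatureTable:
    """Site-by-feature matrix plus the schema and site identities."""

    X: np.ndarray  # (n_sites, n_features) float
    schema: FeatureSchema
    sites: pd.DataFrame  # columns protein_id, position

    def __len__(self) -> int:
        return self.X.shape[0]

    def select_rows(self, retained: Sequence[str]) -> "FeatureTable":
        """Restrict to a subset of residue rows (column slicing, no re-encode)."""
        sub = FeatureSchema(retained=tuple(retained), n=self.schema.n)
        cols = np.concatenate(
            [np.arange(self.schema.n_features)[self.schema.column_slice(r)]
             for r in sub.retained]
        )
        return FeatureTable(X=self.X[:, cols], schema=sub, sites=self.sites)

    def to_frame(self, labels=None) -> pd.DataFrame:
        frame = self.sites.copy().reset_index(drop=True)
        if labels is not None:
            frame["label"] = np.asarray(labels)
        feat = pd.DataFrame(self.X, columns=self.schema.column_names())
        return pd.concat([frame, feat], axis=1)


def collect_row_distances(
    sequence: str, k_position: int, residue_type: str, n: int
) -> list[int]:
    """The up-to-n smallest distances |idx - k| to residues of one type.

    The target lysine itself is included when ``residue_type`` is ``'K'``
    (distance 0).  Returns fewer than n values when the sequence holds
    fewer occurrences; ascending order.
    """
    row_index(residue_type)  # validates the code
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not (1 <= k_position <= len(sequence)):
        raise ValueError(f"position {k_position} out of range")
    if sequence[k_position - 1] != "K":
        raise ValueError(
            f"residue at position {k_position} is "
            f"{sequence[k_position - 1]!r}, not 'K'"
        )
    dists = sorted(
        abs(i + 1 - k_position)
        for i, c in enumerate(sequence)
        if c == residue_type
    )
    return dists[:n]


def build_ram(
    sequence: str, k_position: int, n: int = 6, protein_id: str = ""
) -> ResidueAdjacencyMatrix:
    """Construct the imputed residue adjacency matrix for one lysine site.

    Raises if the sequence contains no standard residues at all (the
    global mean of rule B would be undefined).
    """
    values = np.zeros((len(RESIDUE_ORDER), n), dtype=float)
    mask = np.zeros_like(values, dtype=bool)
    raw_rows: list[list[int]] = []
    for residue in RESIDUE_ORDER:
        raw_rows.append(collect_row_distances(sequence, k_position, residue, n))

    raw_pool = [d for row in raw_rows for d in row]
    if not raw_pool:
        raise ValueError("sequence contains no standard residues")
    global_mean = float(np.mean(raw_pool))

    for i, raw in enumerate(raw_rows):
        m = len(raw)
        if m == 0:
            values[i, :] = global_mean  # rule B
            mask[i, :] = True
        else:
            values[i, :m] = raw
            if m < n:
                values[i, m:] = float(np.mean(raw))  # rule A
                mask[i, m:] = True

    return ResidueAdjacencyMatrix(
        values=values,
        imputed_mask=mask,
        n=n,
        target_position=k_position,
        protein_id=protein_id,
    )


def flatten(
    ram: ResidueAdjacencyMatrix, retained: Sequence[str] = RESIDUE_ORDER
) -> FeatureVector:
    """Flatten retained rows row-major into a feature vector."""
    schema = FeatureSchema(retained=tuple(retained), n=ram.n)
    rows = [ram.values[row_index(r)] for r in schema.retained]
    return FeatureVector(values=np.concatenate(rows), schema=schema)


def encode_dataset(
    dataset: Dataset,
    n: int = 6,
    retained: Sequence[str] = RESIDUE_ORDER,
) -> tuple[FeatureTable, np.ndarray]:
    """Encode every site of a dataset; one feature row per site, in order."""
    schema = FeatureSchema(retained=tuple(retained), n=n)
    vectors = np.empty((len(dataset.sites), schema.n_features), dtype=float)
    for idx, site in enumerate(dataset.sites):
        ram = build_ram(
            dataset.sequence_of(site),
            site.position,
            n=n,
            protein_id=site.protein_id,
        )
        vectors[idx] = flatten(ram, schema.retained).values
    sites = pd.DataFrame(
        {
            "protein_id": [s.protein_id for s in dataset.sites],
            "position": [s.position for s in dataset.sites],
        }
    )
    labels = np.array(dataset.labels, dtype=int)
    return FeatureTable(X=vectors, schema=schema, sites=sites), labels


def write_feature_table(
    table: FeatureTable, labels, path, schema_path=None
) -> None:
    """Write features as TSV plus a JSON sidecar recording the schema."""
    path = Path(path)
    table.to_frame(labels).to_csv(path, sep="\t", index=False)
    sidecar = Path(schema_path) if schema_path else path.with_suffix(".schema.json")
    sidecar.write_text(json.dumps(table.schema.to_dict(), indent=2) + "\n")
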