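"""Protein sequences, lysine-site annotations, and their file formats.

Sequences are read from standard FASTA files (via Biopython); site
annotations come from a tab-separated table with columns
``protein_id``, ``position`` (1-based), ``label`` (``1``/``0`` or
``positive``/``negative``).  Every annotated position must hold a lysine.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import NONSTANDARD_RESIDUES, STANDARD_RESIDUES

logger = logging.getLogger(__name__)

_POSITIVE_LABELS = {"1", "positive", "pos", "true"}
_NEGATIVE_LABELS = {"0", "negative", "neg", "false"}


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a unique identifier.

    The sequence is stored uppercase.  Non-standard codes (X, B, Z, U, O)
    are tolerated but flagged; any other character is rejected.
    """

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")
        if not seq:
            raise ValueError(f"{self.protein_id}: empty sequence")
        bad = set(seq) - STANDARD_RESIDUES - NONSTANDARD_RESIDUES
        if bad:
            raise ValueError(
                f"{self.protein_id}: invalid residue codes {sorted(bad)}"
            )
        nonstd = set(seq) & NONSTANDARD_RESIDUES
        if nonstd:
            logger.warning(
                "%s contains non-standard residue codes %s",
                self.protein_id,
                sorted(nonstd),
            )

    @property
    def nonstandard_codes(self) -> frozenset[str]:
        return frozenset(self.sequence) & NONSTANDARD_RESIDUES

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SiteRecord:
    """A labeled lysine site: 1-based position within a named protein."""

    protein_id: str
    position: int
    label: int  # 1 = phosphoglycerylated (positive), 0 = negative

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


def parse_label(value) -> int:
    """Map a table label value (``1``/``0``/``positive``/``negative``) to int."""
    text = str(value).strip().lower()
    if text in _POSITIVE_LABELS:
        return 1
    if text in _NEGATIVE_LABELS:
        return 0
    raise ValueError(f"unrecognized site label {value!r}")


@dataclass
class Dataset:
    """Validated collection of proteins and labeled lysine sites."""

    proteins: dict[str, ProteinRecord]
    sites: list[SiteRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        problems = []
        seen: set[tuple[str, int]] = set()
        for rec in self.sites:
            key = (rec.protein_id, rec.position)
            if key in seen:
                problems.append(f"duplicate site {key}")
                continue
            seen.add(key)
            protein = self.proteins.get(rec.protein_id)
            if protein is None:
                problems.append(f"unknown protein_id {rec.protein_id!r}")
                continue
            if rec.position > len(protein):
                problems.append(
                    f"{rec.protein_id}:{rec.position} out of range "
                    f"(length {len(protein)})"
                )
                continue
            residue = protein.sequence[rec.position - 1]
            if residue != "K":
                problems.append(
                    f"{rec.protein_id}:{rec.position} is {residue!r}, not 'K'"
                )
        if problems:
            raise ValueError(
                "invalid site annotations:\n  " + "\n  ".join(problems)
            )

    @property
    def labels(self) -> list[int]:
        return [s.label for s in self.sites]

    @property
    def n_positive(self) -> int:
        return sum(self.labels)

    @property
    def n_negative(self) -> int:
        return len(self.sites) - self.n_positive

    def site_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": [s.protein_id for s in self.sites],
                "position": [s.position for s in self.sites],
                "label": [s.label for s in self.sites],
            }
        )

    def sequence_of(self, site: SiteRecord) -> str:
        return self.proteins[site.protein_id].sequence


def read_fasta(path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    The header token before the first whitespace becomes the protein id;
    sequences are uppercased.  An empty file yields an empty list with a
    warning; a non-empty file whose first non-blank line is not a FASTA
    header is a parse error.
    """
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: line {lineno} is not a FASTA header: "
                        f"{line.strip()[:40]!r}"
                    )
                break
        else:
            warnings.warn(f"{path}: empty FASTA file")
            return []

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"{path}: entry {rec.id!r} has no sequence")
        records.append(ProteinRecord(protein_id=rec.id, sequence=seq))
    return records


def write_fasta(proteins: Iterable[ProteinRecord], path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.protein_id, description="")
        for p in proteins
    ]
    SeqIO.write(records, str(path), "fasta")


def read_site_table(path, proteins: Sequence[ProteinRecord]) -> Dataset:
    """Read a site TSV and validate it against the given proteins."""
    table = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    required = {"protein_id", "position", "label"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    sites = [
        SiteRecord(
            protein_id=row.protein_id,
            position=int(row.position),
            label=parse_label(row.label),
        )
        for row in table.itertuples(index=False)
    ]
    return Dataset(proteins={p.protein_id: p for p in proteins}, sites=sites)


def write_site_table(dataset: Dataset, path) -> None:
    dataset.site_table().to_csv(path, sep="\t", index=False)


def enumerate_lysines(protein: ProteinRecord) -> list[int]:
    """All 1-based positions of lysine residues, ascending."""
    return [i + 1 for i, c in enumerate(protein.sequence) if c == "K"]
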