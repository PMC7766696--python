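"""Synthetic datasets with the statistical structure the predictor assumes.

Sequences are drawn i.i.d. uniform over the 20 standard residues, so
lysines occur at random positions with frequency 1/20.  A configurable
fraction of the enumerated lysines is labeled positive, and a local
compositional signal is planted around positive sites: residues within
``signal_window`` of a positive lysine are resampled toward
``signal_residues`` with probability ``signal_strength / (1 +
signal_strength)``.  A strength of 0 reproduces the null exactly — the
labels are then independent of the sequences.

Compositional enrichment (rather than a motif) is used because
adjacency-matrix features measure proximity of residue types; the
planted signal is therefore expressible in the feature space by
construction.  Lysine positions are never resampled, so the signal
never enters the lysine row itself and the annotated sites stay valid.

When a signal is planted, positives are drawn preferentially from
lysines with no other lysine within twice the signal window.  Without
this isolation rule, negative lysines falling inside an enriched window
would carry the positive signature themselves — label contamination
that caps attainable discrimination regardless of signal strength.  No
filter is applied at strength 0, where labels must be exchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import RESIDUE_ORDER
from .sequence_io import Dataset, ProteinRecord, SiteRecord


@dataclass
class SyntheticConfig:
    """Generator settings; defaults emulate a small benchmark-shaped set
    (dozens of proteins, lengths 60-200, ~1:29 site imbalance)."""

    num_proteins: int = 50
    length_range: tuple[int, int] = (60, 200)
    positive_fraction: float = 0.034
    signal_strength: float = 1.0
    signal_residues: tuple[str, ...] = ("A", "G", "S")
    signal_window: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 2 * self.signal_window + 1:
            raise ValueError(
                f"minimum length {lo} shorter than signal window span "
                f"{2 * self.signal_window + 1}"
            )
        if lo > hi:
            raise ValueError("length_range must be (min, max) with min <= max")
        if not 0 < self.positive_fraction < 1:
            raise ValueError("positive_fraction must be in (0, 1)")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be >= 0")
        if self.num_proteins < 1:
            raise ValueError("num_proteins must be >= 1")
        bad = set(self.signal_residues) - set(RESIDUE_ORDER)
        if bad:
            raise ValueError(f"unknown signal residues: {sorted(bad)}")
        if "K" in self.signal_residues:
            raise ValueError(
                "signal_residues must not include 'K': enrichment of the "
                "lysine row would make positives trivially separable"
            )


def generate_dataset(config: SyntheticConfig) -> tuple[Dataset, dict]:
    """Generate a labeled synthetic dataset; deterministic under the seed.

    Returns the dataset and a ground-truth description (positive sites
    and the planted-signal parameters).
    """
    rng = np.random.default_rng(config.seed)
    alphabet = np.array(list(RESIDUE_ORDER))
    lo, hi = config.length_range

    chars: list[np.ndarray] = []
    for _ in range(config.num_proteins):
        length = int(rng.integers(lo, hi + 1))
        chars.append(rng.choice(alphabet, size=length))

    # enumerate all lysines before planting signal; the mutation step
    # never creates or destroys a K, so the site list stays exact
    all_sites: list[tuple[int, int]] = []  # (protein index, 1-based position)
    for pi, seq in enumerate(chars):
        for pos0 in np.flatnonzero(seq == "K"):
            all_sites.append((pi, int(pos0) + 1))
    if not all_sites:
        raise ValueError("no lysines generated; enlarge the configuration")

    n_pos = max(1, round(config.positive_fraction * len(all_sites)))
    pool = list(range(len(all_sites)))
    if config.signal_strength > 0:
        # prefer isolated lysines so enriched windows contain no negative site
        isolation = 2 * config.signal_window
        eligible = []
        for i, (pi, pos) in enumerate(all_sites):
            ks = np.flatnonzero(chars[pi] == "K") + 1
            if np.all((np.abs(ks - pos) > isolation) | (ks == pos)):
                eligible.append(i)
        if len(eligible) >= n_pos:
            pool = eligible
    pos_choice = rng.choice(len(pool), size=n_pos, replace=False)
    positive_set = {all_sites[pool[i]] for i in pos_choice}

    replace_p = config.signal_strength / (1.0 + config.signal_strength)
    signal = np.array(list(config.signal_residues))
    if replace_p > 0:
        for pi, pos in sorted(positive_set):
            seq = chars[pi]
            center = pos - 1
            for off in range(-config.signal_window, config.signal_window + 1):
                idx = center + off
                if off == 0 or idx < 0 or idx >= len(seq):
                    continue
                if seq[idx] == "K":  # keep every lysine (and its sites) intact
                    continue
                if rng.random() < replace_p:
                    seq[idx] = rng.choice(signal)

    proteins = {}
    sites = []
    for pi, seq in enumerate(chars):
        pid = f"SYN{pi:04d}"
        proteins[pid] = ProteinRecord(protein_id=pid, sequence="".join(seq))
    for pi, pos in all_sites:
        pid = f"SYN{pi:04d}"
        sites.append(
            SiteRecord(
                protein_id=pid,
                position=pos,
                label=int((pi, pos) in positive_set),
            )
        )

    truth = {
        "positive_sites": sorted(
            (f"SYN{pi:04d}", pos) for pi, pos in positive_set
        ),
        "signal_residues": list(config.signal_residues),
        "signal_strength": config.signal_strength,
        "signal_window": config.signal_window,
        "replacement_probability": replace_p,
        "n_sites": len(all_sites),
        "n_positive": n_pos,
    }
    return Dataset(proteins=proteins, sites=sites), truth


def make_worked_example() -> Dataset:
    """The single-protein dummy dataset ('MAKAKAA', positive lysine at 3)
    used throughout the documentation and the acceptance checks."""
    protein = ProteinRecord(protein_id="P1", sequence="MAKAKAA")
    site = SiteRecord(protein_id="P1", position=3, label=1)
    return Dataset(proteins={"P1": protein}, sites=[site])
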