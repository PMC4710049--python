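"""Discriminating-site selection for padlock probe targeting.

Padlock probe ligation is sensitive to a single mismatched nucleotide at the
junction, so a probe can distinguish two homologs only at alignment columns
where every X isoform carries one unambiguous base, every Y isoform carries
one unambiguous base, and the two bases differ. This module enumerates those
columns in a pre-computed multiple alignment and reports pairwise percent
identity over comparable (gap-free) columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO

from .errors import AlignmentError, ParameterError

_UNAMBIGUOUS = frozenset("ACGT")
_GAP_CHARS = ("-", ".")


@dataclass(frozen=True)
class DiscriminatingSite:
    """A single-nucleotide X/Y discriminating alignment column (0-based)."""

    position: int
    x_base: str
    y_base: str


@dataclass
class HomologSet:
    """Aligned X- and Y-isoform transcript sequences (equal lengths)."""

    x_isoforms: list[str]
    y_isoforms: list[str]
    x_names: list[str] | None = None
    y_names: list[str] | None = None

    def __post_init__(self):
        self.x_isoforms = [s.upper().replace(".", "-") for s in self.x_isoforms]
        self.y_isoforms = [s.upper().replace(".", "-") for s in self.y_isoforms]
        if not self.x_isoforms or not self.y_isoforms:
            raise AlignmentError("need at least one isoform on each side")
        lengths = {len(s) for s in self.x_isoforms + self.y_isoforms}
        if len(lengths) != 1:
            raise AlignmentError(f"aligned sequences have unequal lengths: {sorted(lengths)}")
        (self.alignment_length,) = lengths
        if self.alignment_length == 0:
            raise AlignmentError("alignment has zero columns")

    @classmethod
    def from_fastas(cls, x_path: str | Path, y_path: str | Path) -> "HomologSet":
        """Load pre-aligned isoforms from two FASTA files (X side, Y side)."""
        xs = list(SeqIO.parse(str(x_path), "fasta"))
        ys = list(SeqIO.parse(str(y_path), "fasta"))
        return cls(
            x_isoforms=[str(r.seq) for r in xs],
            y_isoforms=[str(r.seq) for r in ys],
            x_names=[r.id for r in xs],
            y_names=[r.id for r in ys],
        )


def _char_matrix(seqs: Sequence[str]) -> np.ndarray:
    return np.array([list(s) for s in seqs], dtype="U1")


def find_discriminating_sites(homologs: HomologSet) -> list[DiscriminatingSite]:
    """Enumerate columns that discriminate all X from all Y isoforms.

    A column qualifies when the X isoforms agree on one base from {A,C,G,T},
    the Y isoforms agree on one such base, and the two bases differ; N and gap
    columns never qualify. Sites are returned in ascending position and do not
    depend on the order of the sequences within each side.
    """
    x = _char_matrix(homologs.x_isoforms)
    y = _char_matrix(homologs.y_isoforms)
    x0, y0 = x[0], y[0]
    x_uniform = (x == x0).all(axis=0)
    y_uniform = (y == y0).all(axis=0)
    x_clean = np.isin(x0, list(_UNAMBIGUOUS))
    y_clean = np.isin(y0, list(_UNAMBIGUOUS))
    ok = x_uniform & y_uniform & x_clean & y_clean & (x0 != y0)
    return [
        DiscriminatingSite(position=int(i), x_base=str(x0[i]), y_base=str(y0[i]))
        for i in np.nonzero(ok)[0]
    ]


def ungapped_positions(seq: str, positions: Sequence[int]) -> list[int | None]:
    """Map alignment columns to 0-based ungapped coordinates of one sequence.

    Returns None where the sequence has a gap at that column.
    """
    arr = np.array(list(seq), dtype="U1")
    is_base = ~np.isin(arr, list(_GAP_CHARS))
    cum = np.cumsum(is_base) - 1
    return [int(cum[p]) if is_base[p] else None for p in positions]


def percent_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity over columns where neither sequence has a gap."""
    if len(seq_a) != len(seq_b):
        raise AlignmentError("sequences must be aligned to equal length")
    if len(seq_a) == 0:
        raise ParameterError("sequences must be non-empty")
    a = np.array(list(seq_a.upper().replace(".", "-")), dtype="U1")
    b = np.array(list(seq_b.upper().replace(".", "-")), dtype="U1")
    comparable = (a != "-") & (b != "-")
    n = int(comparable.sum())
    if n == 0:
        raise ParameterError("no comparable (gap-free) columns")
    return 100.0 * float((a[comparable] == b[comparable]).sum()) / n


def sites_table(homologs: HomologSet) -> "pd.DataFrame":
    """Tabulate discriminating sites with per-isoform ungapped coordinates."""
    import pandas as pd

    sites = find_discriminating_sites(homologs)
    positions = [s.position for s in sites]
    data = {
        "alignment_pos": positions,
        "x_base": [s.x_base for s in sites],
        "y_base": [s.y_base for s in sites],
    }
    x_names = homologs.x_names or [f"X{i+1}" for i in range(len(homologs.x_isoforms))]
    y_names = homologs.y_names or [f"Y{i+1}" for i in range(len(homologs.y_isoforms))]
    for name, seq in zip(x_names, homologs.x_isoforms):
        data[f"pos_{name}"] = ungapped_positions(seq, positions)
    for name, seq in zip(y_names, homologs.y_isoforms):
        data[f"pos_{name}"] = ungapped_positions(seq, positions)
    return pd.DataFrame(data)
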