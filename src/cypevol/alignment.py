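"""Aligned sequence containers and FASTA I/O.

Alignments are rectangular: every sequence has the same length.  Gaps are
``-``; the ambiguity codes ``N`` (nucleotide) and ``X`` (protein) are
treated as missing data throughout the pipeline.  Codon alignments are
in-frame nucleotide alignments whose length is divisible by three.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"
MISSING_NT = frozenset("-N")
MISSING_AA = frozenset("-X")


class AlignmentFormatError(ValueError):
    pass


class FrameError(AlignmentFormatError):
    pass


@dataclass
class Alignment:
    """Ordered rectangular alignment of named sequences."""

    ids: list[str]
    matrix: np.ndarray  # (n_seq, n_col) of single characters
    missing: frozenset = MISSING_NT
    # 1-based original column positions (identity map unless filtered)
    column_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2:
            raise AlignmentFormatError("alignment matrix must be 2-D")
        if len(self.ids) != self.matrix.shape[0]:
            raise AlignmentFormatError("ids/rows mismatch")
        if self.column_positions is None:
            self.column_positions = np.arange(1, self.matrix.shape[1] + 1)

    @property
    def n_sequences(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, ident: str) -> str:
        i = self.ids.index(ident)
        return "".join(self.matrix[i])

    def row(self, i: int) -> str:
        return "".join(self.matrix[i])

    def is_missing(self) -> np.ndarray:
        """Boolean mask of missing cells."""
        mask = np.zeros(self.matrix.shape, dtype=bool)
        for ch in self.missing:
            mask |= self.matrix == ch
        return mask

    def subset_columns(self, keep: np.ndarray) -> "Alignment":
        return type(self)(
            ids=list(self.ids),
            matrix=self.matrix[:, keep],
            missing=self.missing,
            column_positions=np.asarray(self.column_positions)[keep],
        )


class ProteinAlignment(Alignment):
    def __init__(self, ids, matrix, missing=MISSING_AA, column_positions=None):
        super().__init__(ids, matrix, frozenset(missing), column_positions)


class CodonAlignment(Alignment):
    """In-frame nucleotide alignment; length must be a multiple of three."""

    def __init__(self, ids, matrix, missing=MISSING_NT, column_positions=None):
        super().__init__(ids, matrix, frozenset(missing), column_positions)
        if self.n_columns % 3 != 0:
            raise FrameError(
                f"codon alignment length {self.n_columns} not divisible by 3"
            )

    @property
    def n_codons(self) -> int:
        return self.n_columns // 3

    def codons(self, i: int) -> list[str]:
        s = self.row(i)
        return [s[j:j + 3] for j in range(0, len(s), 3)]


def _records(path: str | Path) -> list[tuple[str, str]]:
    out = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    return out


def _build(pairs: list[tuple[str, str]], cls):
    if not pairs:
        raise AlignmentFormatError("empty FASTA")
    lengths = {len(s) for _, s in pairs}
    if len(lengths) != 1:
        raise AlignmentFormatError(f"ragged sequence lengths {sorted(lengths)}")
    matrix = np.array([list(s) for _, s in pairs])
    return cls(ids=[i for i, _ in pairs], matrix=matrix)


def read_codon_alignment(path: str | Path) -> CodonAlignment:
    return _build(_records(path), CodonAlignment)


def read_protein_alignment(path: str | Path) -> ProteinAlignment:
    return _build(_records(path), ProteinAlignment)


def codon_alignment_from_dict(seqs: dict[str, str]) -> CodonAlignment:
    return _build([(k, v.upper()) for k, v in seqs.items()], CodonAlignment)


def protein_alignment_from_dict(seqs: dict[str, str]) -> ProteinAlignment:
    return _build([(k, v.upper()) for k, v in seqs.items()], ProteinAlignment)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(aln.row(i)), id=aln.ids[i], description="")
        for i in range(aln.n_sequences)
    ]
    SeqIO.write(recs, str(path), "fasta")
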