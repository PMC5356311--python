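"""Gapped protein alignments, reference-position mapping, pairwise identity.

The alignment is the observed data at the tips of the phylogeny.  Columns are
0-based internally; residue positions quoted in reports (e.g. the catalytic
tryptophan "172") are 1-based on the *ungapped* reference sequence, following
the numbering style used for mature peroxidase proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Canonical amino-acid ordering used for every vector/matrix in the package.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}
GAP = "-"
#: Ambiguity letters accepted on input but treated as missing data downstream.
AMBIGUOUS = set("XBZJ")
#: Sentinel state code for gap/ambiguous characters (leaf vector of ones).
MISSING = 20


class AlignmentError(ValueError):
    """Raised for malformed alignments or invalid alignment queries."""


@dataclass
class ProteinAlignment:
    """A gapped amino-acid multiple alignment with unique, ordered ids."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if not self.ids:
            raise AlignmentError("alignment is empty")
        if len(self.ids) != len(set(self.ids)):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dupes}")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            bad = next(i for i, r in zip(self.ids, self.rows)
                       if len(r) != len(self.rows[0]))
            raise AlignmentError(f"ragged alignment: row '{bad}' has a "
                                 "different length from the first row")
        allowed = set(AA_ORDER) | {GAP} | AMBIGUOUS
        for sid, row in zip(self.ids, self.rows):
            extra = set(row.upper()) - allowed
            if extra:
                raise AlignmentError(
                    f"row '{sid}' contains non-amino-acid characters {sorted(extra)}")
        self.rows = [r.upper() for r in self.rows]

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise AlignmentError(f"unknown sequence id '{seq_id}'") from None

    def ambiguous_count(self) -> int:
        """Number of ambiguity characters (X/B/Z/J) across all rows."""
        return sum(sum(c in AMBIGUOUS for c in row) for row in self.rows)

    def encode(self) -> np.ndarray:
        """Integer-encode rows: 0..19 amino acids, ``MISSING`` for gap/ambiguous.

        Gaps and ambiguity codes both become missing data for likelihood work
        (all-ones leaf partials), the convention PAML uses.
        """
        out = np.empty((self.n_sequences, self.length), dtype=np.int8)
        for i, row in enumerate(self.rows):
            out[i] = [AA_INDEX.get(c, MISSING) for c in row]
        return out

    def observed_frequencies(self, pseudocount: float = 1.0) -> np.ndarray:
        """Amino-acid frequencies over non-gap, non-ambiguous residues.

        A pseudocount (default 1 per amino acid) avoids zero frequencies,
        which would make rarely observed states unreachable in the model.
        With pseudocount 0 an alignment missing some amino acid entirely is
        rejected as degenerate.
        """
        counts = np.full(20, float(pseudocount))
        codes = self.encode()
        observed = codes[codes < MISSING]
        counts += np.bincount(observed, minlength=20)
        if np.any(counts == 0):
            missing = [AA_ORDER[i] for i in np.flatnonzero(counts == 0)]
            raise AlignmentError(
                "degenerate observed frequencies: amino acid(s) "
                f"{missing} absent and pseudocount is 0")
        return counts / counts.sum()


def read_alignment(path: str | Path) -> ProteinAlignment:
    """Read a gapped FASTA alignment, preserving record order."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records found in {path}")
    return ProteinAlignment([r.id for r in records], [str(r.seq) for r in records])


def write_alignment(aln: ProteinAlignment, path: str | Path) -> None:
    records = [SeqRecord(Seq(row), id=sid, description="")
               for sid, row in zip(aln.ids, aln.rows)]
    SeqIO.write(records, str(path), "fasta")


@dataclass
class SitePosition:
    label: str
    residue_number: int  # 1-based on the ungapped reference
    column: int          # 0-based alignment column


@dataclass
class SiteMap:
    """Maps named residue positions of a reference sequence to alignment columns."""

    reference_id: str
    positions: list[SitePosition] = field(default_factory=list)

    def column(self, label: str) -> int:
        for p in self.positions:
            if p.label == label:
                return p.column
        raise KeyError(f"no mapped position labelled '{label}'")

    def labels(self) -> list[str]:
        return [p.label for p in self.positions]


def map_reference_positions(
    aln: ProteinAlignment,
    reference_id: str,
    residue_numbers: Sequence[int],
    labels: Iterable[str] | None = None,
) -> SiteMap:
    """Locate 1-based ungapped reference residues in alignment columns.

    Column k of the result is the alignment column holding the n-th non-gap
    character of the reference row.
    """
    row = aln.row(reference_id)
    non_gap_cols = [i for i, c in enumerate(row) if c != GAP]
    if labels is None:
        labels = [str(n) for n in residue_numbers]
    positions = []
    for label, n in zip(labels, residue_numbers):
        if n < 1 or n > len(non_gap_cols):
            raise AlignmentError(
                f"residue number {n} is outside the ungapped reference "
                f"'{reference_id}' (length {len(non_gap_cols)})")
        positions.append(SitePosition(label, n, non_gap_cols[n - 1]))
    return SiteMap(reference_id, positions)


def pairwise_identity(aln: ProteinAlignment, id_a: str, id_b: str) -> tuple[float, int]:
    """Percent identity over columns where both rows are non-gap.

    Returns ``(percent_identity, aligned_pairs)`` where aligned_pairs counts
    the shared (both non-gap) columns, matching how pairwise identities
    between ancestral and extant peroxidases are quoted.
    """
    a, b = aln.row(id_a), aln.row(id_b)
    shared = [(x, y) for x, y in zip(a, b) if x != GAP and y != GAP]
    if not shared:
        return 0.0, 0
    matches = sum(x == y for x, y in shared)
    return 100.0 * matches / len(shared), len(shared)


def identity_matrix(aln: ProteinAlignment) -> "pd.DataFrame":  # noqa: F821
    """All-pairs percent-identity table (ids × ids)."""
    import pandas as pd

    n = aln.n_sequences
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pid, _ = pairwise_identity(aln, aln.ids[i], aln.ids[j])
            mat[i, j] = mat[j, i] = pid
    return pd.DataFrame(mat, index=aln.ids, columns=aln.ids)
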