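"""Core sequence, alignment and tree types shared by the whole pipeline.

The swap unit in this project is a protein domain block cut out of a larger
multiple sequence alignment (for the SH2 library, the block corresponding to
residues 281-362 of human BTK).  Everything downstream — identity banding,
ancestral reconstruction, reverse translation, read counting — manipulates
the small set of types defined here:

* :class:`ProteinSequence` / :class:`NucleotideSequence` — validated strings.
* :class:`AlignedSet` — an equal-length protein alignment.
* :class:`ResidueMap` — alignment column <-> reference residue numbering
  (1-based, inclusive; "residue 307" style coordinates).
* :class:`PhyloTree` — a phylogeny with branch lengths in expected
  substitutions/site, wrapping a dendropy tree.

File formats are plain FASTA and Newick, read and written through Biopython
and dendropy respectively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import dendropy
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PROTEIN_ALPHABET = frozenset(AMINO_ACIDS + "*-")
NUCLEOTIDE_ALPHABET = frozenset("ACGT")

#: Sentinel returned by :meth:`ResidueMap.column_to_residue` for alignment
#: columns that sit opposite a gap in the reference sequence.
UNMAPPED = None


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence over the 20 amino acids plus ``*`` (stop) and ``-`` (gap)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"protein sequence {self.id!r} contains illegal characters: "
                f"{sorted(bad)}"
            )

    def ungapped(self) -> "ProteinSequence":
        return ProteinSequence(self.id, self.residues.replace("-", ""))

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class NucleotideSequence:
    """A DNA sequence over {A, C, G, T}."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        bad = set(self.bases) - NUCLEOTIDE_ALPHABET
        if bad:
            raise ValueError(
                f"nucleotide sequence {self.id!r} contains illegal characters: "
                f"{sorted(bad)}"
            )

    def translate(self) -> ProteinSequence:
        if len(self.bases) % 3 != 0:
            raise ValueError(
                f"cannot translate {self.id!r}: length {len(self.bases)} is not "
                "a multiple of 3"
            )
        return ProteinSequence(self.id, str(Seq(self.bases).translate()))

    def reverse_complement(self) -> "NucleotideSequence":
        return NucleotideSequence(self.id, str(Seq(self.bases).reverse_complement()))

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class AlignedSet:
    """An ordered protein multiple sequence alignment of equal-length rows."""

    records: list[ProteinSequence]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment must contain at least one record")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"aligned records have unequal lengths: {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(self.records[0])

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, seq_id: str) -> ProteinSequence:
        for r in self.records:
            if r.id == seq_id:
                return r
        raise KeyError(f"sequence id {seq_id!r} not in alignment")

    def column(self, j: int) -> str:
        return "".join(r.residues[j] for r in self.records)


@dataclass
class ResidueMap:
    """Bidirectional map between alignment columns and reference residue numbers.

    Residue numbers are 1-based inclusive ("residues 281 to 362"); column
    indices are 0-based.  Columns where the reference carries a gap are
    unmapped.
    """

    ref_id: str
    ref_start: int
    _col_to_res: dict[int, int] = field(repr=False)
    _res_to_col: dict[int, int] = field(repr=False)

    def column_to_residue(self, column: int) -> int | None:
        return self._col_to_res.get(column, UNMAPPED)

    def residue_to_column(self, residue: int) -> int | None:
        return self._res_to_col.get(residue, UNMAPPED)

    @property
    def last_residue(self) -> int:
        return max(self._res_to_col)

    @property
    def mapped_columns(self) -> list[int]:
        return sorted(self._col_to_res)


def build_residue_map(msa: AlignedSet, ref_id: str, ref_start: int) -> ResidueMap:
    """Number the non-gap columns of the reference row ``ref_start, ref_start+1, ...``.

    Raises ``KeyError`` if ``ref_id`` is absent from the alignment.
    """
    ref = msa.get(ref_id)
    col_to_res: dict[int, int] = {}
    res = ref_start
    for j, aa in enumerate(ref.residues):
        if aa != "-":
            col_to_res[j] = res
            res += 1
    return ResidueMap(
        ref_id=ref_id,
        ref_start=ref_start,
        _col_to_res=col_to_res,
        _res_to_col={v: k for k, v in col_to_res.items()},
    )


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(
    path: str | Path, kind: Literal["protein", "nucleotide"] = "protein"
) -> list[ProteinSequence] | list[NucleotideSequence]:
    """Read a FASTA file into validated sequence records, preserving order.

    Record ids are the first whitespace-delimited token of each header.  An
    alphabet violation is a hard error that names the offending line.
    """
    path = Path(path)
    cls = ProteinSequence if kind == "protein" else NucleotideSequence
    records = []
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # malformed FASTA
        raise ValueError(f"malformed FASTA in {path}: {exc}") from exc
    for rec in parsed:
        try:
            records.append(cls(rec.id, str(rec.seq).upper()))
        except ValueError as exc:
            line = _find_offending_line(path, rec.id)
            raise ValueError(f"{path}:{line}: {exc}") from exc
    return records


def _find_offending_line(path: Path, rec_id: str) -> int:
    """Locate the first body line of the record ``rec_id`` (for error messages)."""
    with open(path) as fh:
        in_rec = False
        for i, line in enumerate(fh, start=1):
            if line.startswith(">"):
                in_rec = line[1:].split()[0] == rec_id if line[1:].split() else False
            elif in_rec and line.strip():
                return i
    return 0


def write_fasta(
    records: Iterable[ProteinSequence | NucleotideSequence],
    path: str | Path,
    width: int = 60,
) -> None:
    with open(path, "w") as fh:
        for rec in records:
            seq = rec.residues if isinstance(rec, ProteinSequence) else rec.bases
            fh.write(f">{rec.id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_alignment(path: str | Path) -> AlignedSet:
    return AlignedSet(read_fasta(path, kind="protein"))


# ---------------------------------------------------------------------------
# Pairwise identity

DenominatorRule = Literal["nongap_union", "nongap_both", "alignment_length"]

_aligner = Align.PairwiseAligner()
_aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
_aligner.open_gap_score = -11
_aligner.extend_gap_score = -1
_aligner.mode = "global"


def pairwise_identity(
    a: ProteinSequence,
    b: ProteinSequence,
    aligned: bool = True,
    denominator: DenominatorRule = "nongap_union",
) -> float:
    """Percent identity between two protein sequences, in [0, 100].

    For ``aligned=True`` the two sequences must have equal length and identity
    is ``100 * matches / denominator`` where a match is a column with the same
    non-gap residue in both rows.  The denominator rule is configurable
    because published identity figures rarely state their convention:

    * ``nongap_union`` (default) — columns where at least one row is non-gap
      (indels count against identity),
    * ``nongap_both`` — columns where both rows are non-gap,
    * ``alignment_length`` — all columns.

    For ``aligned=False`` both inputs must be ungapped; a global alignment is
    computed first (BLOSUM62, gap open -11 / extend -1) and the same column
    rule is applied to it.  Symmetric in its arguments by construction.
    """
    if not aligned:
        if "-" in a.residues or "-" in b.residues:
            raise ValueError("unaligned inputs must be ungapped")
        alignment = _aligner.align(a.residues, b.residues)[0]
        sa, sb = str(alignment[0]), str(alignment[1])
    else:
        if len(a) != len(b):
            raise ValueError(
                f"aligned identity requires equal lengths ({len(a)} != {len(b)})"
            )
        sa, sb = a.residues, b.residues

    matches = 0
    denom = 0
    for ca, cb in zip(sa, sb):
        both_gap = ca == "-" and cb == "-"
        if denominator == "alignment_length":
            denom += 1
        elif denominator == "nongap_union":
            if not both_gap:
                denom += 1
        else:  # nongap_both
            if ca != "-" and cb != "-":
                denom += 1
        if ca == cb and ca != "-":
            matches += 1
    if denom == 0:
        raise ValueError("identity undefined: empty denominator")
    return 100.0 * matches / denom


def hamming_distance(a: ProteinSequence, b: ProteinSequence) -> int:
    """Number of differing columns, counted over columns where both are non-gap."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(
        1
        for ca, cb in zip(a.residues, b.residues)
        if ca != "-" and cb != "-" and ca != cb
    )


# ---------------------------------------------------------------------------
# Newick I/O


@dataclass
class PhyloTree:
    """A phylogeny with non-negative branch lengths and unique leaf labels."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.leaf_labels()
        if len(labels) != len(set(labels)):
            raise ValueError("leaf labels must be unique")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError(f"negative branch length: {edge.length}")

    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def n_leaves(self) -> int:
        return len(self.tree.leaf_nodes())


def read_newick(path_or_string: str | Path) -> PhyloTree:
    """Parse a Newick tree from a file path or a literal Newick string."""
    text = str(path_or_string)
    if not text.strip().startswith("(") and Path(text).exists():
        text = Path(text).read_text()
    if text.count("(") != text.count(")"):
        offset = _paren_error_offset(text)
        raise ValueError(f"unbalanced parentheses in Newick string at offset {offset}")
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:
        raise ValueError(f"cannot parse Newick: {exc}") from exc
    return PhyloTree(tree)


def _paren_error_offset(text: str) -> int:
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                return i
    return len(text)


def write_newick(tree: PhyloTree, path: str | Path | None = None) -> str:
    """Serialize to Newick with branch lengths at 10 significant digits."""
    out = tree.tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".10g",
    ).strip()
    if path is not None:
        Path(path).write_text(out + "\n")
    return out


def translate_cds(bases: str) -> str:
    """Translate a coding sequence (length divisible by 3) to protein, '*' for stops."""
    if len(bases) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    return str(Seq(bases).translate())
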