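"""File formats touched by the alignment pipeline.

Unaligned sequences come in as multi-FASTA; results go out as wrapped FASTA or
interleaved CLUSTAL/ALN, guide trees as Newick with branch lengths, and distance
matrices in PHYLIP square format.  FASTA parsing and alignment re-reading go
through biopython; the CLUSTAL writer is local because the dialect used here is
pinned to 60-residue blocks.

Conventions (apply package-wide): the gap character is ``'-'`` everywhere and
``'.'`` is rejected on input; internal coordinates are 0-based half-open while
user-facing positions are 1-based.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

GAP = "-"

#: IUPAC nucleotide codes (T and U both accepted on input).
DNA_CHARS = frozenset("ACGTURYSWKMBDHVN")
#: IUPAC amino-acid codes incl. ambiguity (B, Z, X) and rare residues (U, O).
PROTEIN_CHARS = frozenset("ARNDCQEGHILKMFPSTWYVBZXUO")
#: Characters counted toward nucleotide content during auto-detection.
_DNA_CORE = frozenset("ACGTUN")


class Alphabet(str, enum.Enum):
    DNA = "DNA"
    PROTEIN = "PROTEIN"

    @property
    def charset(self) -> frozenset[str]:
        return DNA_CHARS if self is Alphabet.DNA else PROTEIN_CHARS


class FormatError(ValueError):
    """Malformed input file; carries the 1-based offending line when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


@dataclass(frozen=True)
class SequenceRecord:
    """One named, ungapped biological sequence."""

    id: str
    description: str
    residues: str
    alphabet: Alphabet

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - self.alphabet.charset
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains characters outside the "
                f"{self.alphabet.value} alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SequenceSet:
    """Ordered collection of records sharing one alphabet with unique ids."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
        alphabets = {rec.alphabet for rec in self.records}
        if len(alphabets) > 1:
            raise ValueError("all records in a set must share one alphabet")

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def alphabet(self) -> Alphabet:
        return self.records[0].alphabet

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]

    def by_id(self, seq_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == seq_id:
                return rec
        raise KeyError(seq_id)


@dataclass
class Msa:
    """A multiple alignment: equal-length gapped rows, uniform by construction."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment must contain at least one row")
        length = len(self.rows[0][1])
        if length == 0:
            raise ValueError("alignment must contain at least one column")
        seen: set[str] = set()
        for rid, seq in self.rows:
            if len(seq) != length:
                raise ValueError(
                    f"row {rid!r} has length {len(seq)}, expected {length}"
                )
            if rid in seen:
                raise ValueError(f"duplicate row id {rid!r}")
            seen.add(rid)

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def row(self, seq_id: str) -> str:
        for rid, seq in self.rows:
            if rid == seq_id:
                return seq
        raise KeyError(seq_id)

    def stripped(self, seq_id: str) -> str:
        """The row with gap characters removed (the original sequence)."""
        return self.row(seq_id).replace(GAP, "")

    def reordered(self, ids: Iterable[str]) -> "Msa":
        return Msa([(rid, self.row(rid)) for rid in ids])


def detect_alphabet(text: str) -> Alphabet:
    """DNA when >=85% of residues are in {A,C,G,T,U,N}, protein otherwise."""
    if not text:
        return Alphabet.DNA
    core = sum(1 for ch in text if ch in _DNA_CORE)
    return Alphabet.DNA if core / len(text) >= 0.85 else Alphabet.PROTEIN


def _locate_char(path: Path, record_id: str, chars: set[str]) -> int | None:
    """1-based line number of the first offending character in a record body."""
    in_record = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                header_id = line[1:].split(None, 1)[0] if line[1:].strip() else ""
                in_record = header_id == record_id
                continue
            if in_record and set(line.strip().upper()) & chars:
                return lineno
    return None


def _locate_duplicate_header(path: Path, record_id: str) -> int | None:
    count = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                header_id = line[1:].split(None, 1)[0] if line[1:].strip() else ""
                if header_id == record_id:
                    count += 1
                    if count == 2:
                        return lineno
    return None


def read_fasta(path: str | Path, alphabet: Alphabet | str = "auto") -> SequenceSet:
    """Read a multi-FASTA file of unaligned sequences.

    Residues are case-normalized to upper.  The alphabet is auto-detected over
    the pooled residue content unless forced.  Gap characters, duplicate ids,
    characters outside both alphabets, and empty files are rejected with the
    offending line number where it can be determined.
    """
    path = Path(path)
    raw = [(rec.id, rec.description, str(rec.seq).upper())
           for rec in SeqIO.parse(str(path), "fasta")]
    if not raw:
        raise FormatError(f"no FASTA records found in {path}")

    seen: set[str] = set()
    for rid, _desc, _seq in raw:
        if rid in seen:
            raise FormatError(
                f"duplicate sequence id {rid!r}",
                line=_locate_duplicate_header(path, rid),
            )
        seen.add(rid)

    for rid, _desc, seq in raw:
        gaps = set(seq) & {GAP, "."}
        if gaps:
            raise FormatError(
                f"gap character {sorted(gaps)[0]!r} in unaligned input "
                f"sequence {rid!r}",
                line=_locate_char(path, rid, gaps),
            )

    if alphabet == "auto":
        alpha = detect_alphabet("".join(seq for _, _, seq in raw))
    else:
        alpha = Alphabet(alphabet)

    records = []
    for rid, desc, seq in raw:
        bad = set(seq) - alpha.charset
        if bad:
            outside_both = bad - DNA_CHARS - PROTEIN_CHARS
            what = sorted(outside_both or bad)[0]
            raise FormatError(
                f"character {what!r} in sequence {rid!r} is not a valid "
                f"{alpha.value} residue",
                line=_locate_char(path, rid, set(what)),
            )
        records.append(SequenceRecord(rid, desc, seq, alpha))
    return SequenceSet(records)


def write_fasta(seqs: SequenceSet, path: str | Path) -> None:
    """Write unaligned sequences as wrapped multi-FASTA."""
    records = [
        _BioRecord(Seq(rec.residues), id=rec.id,
                   description=rec.description[len(rec.id):].strip()
                   if rec.description.startswith(rec.id) else rec.description)
        for rec in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


_CLUSTAL_BLOCK = 60
_CLUSTAL_ID_MAX = 30


def write_alignment(msa: Msa, path: str | Path, fmt: str = "fasta") -> None:
    """Write an alignment as wrapped FASTA or interleaved CLUSTAL.

    CLUSTAL output uses 60-residue blocks with sequence ids truncated to 30
    characters; FASTA keeps full ids and wraps at 60 columns.
    """
    fmt = fmt.lower()
    path = Path(path)
    if fmt == "fasta":
        records = [_BioRecord(Seq(seq), id=rid, description="")
                   for rid, seq in msa.rows]
        SeqIO.write(records, str(path), "fasta")
    elif fmt in ("clustal", "aln"):
        ids = [rid[:_CLUSTAL_ID_MAX] for rid, _ in msa.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("sequence ids collide after truncation to 30 chars")
        width = max(10, max(len(i) for i in ids) + 3)
        lines = ["CLUSTAL W multiple sequence alignment", "", ""]
        for start in range(0, msa.length, _CLUSTAL_BLOCK):
            for rid, (_full, seq) in zip(ids, msa.rows):
                lines.append(f"{rid:<{width}}{seq[start:start + _CLUSTAL_BLOCK]}")
            lines.append("")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown alignment format {fmt!r}")


def read_alignment(path: str | Path, fmt: str = "fasta") -> Msa:
    """Re-read an alignment written by :func:`write_alignment`."""
    fmt = "clustal" if fmt.lower() in ("clustal", "aln") else "fasta"
    aln = AlignIO.read(str(path), fmt)
    return Msa([(rec.id, str(rec.seq).upper()) for rec in aln])


def newick_string(tree) -> str:
    """Serialize a guide tree to Newick with branch lengths at 5 decimals."""
    leaves = tree.leaf_names()
    if len(leaves) < 2:
        raise ValueError("cannot serialize a tree with fewer than 2 leaves")

    def label(name: str) -> str:
        if any(ch in name for ch in " \t()[]':;,"):
            return "'" + name.replace("'", "''") + "'"
        return name

    def rec(node, top: bool) -> str:
        if not node.children:
            body = label(node.name)
        else:
            body = "(" + ",".join(rec(c, False) for c in node.children) + ")"
        if top:
            return body
        return f"{body}:{node.length:.5f}"

    return rec(tree.root, True) + ";"


def write_newick(tree, path: str | Path) -> None:
    Path(path).write_text(newick_string(tree) + "\n")


def write_distance_matrix(dm, path: str | Path) -> None:
    """Write a distance matrix in PHYLIP square format.

    First line holds n; each row has the id padded to 10 characters (longer
    ids are truncated) followed by distances to 6 decimals.
    """
    lines = [f"{dm.n:5d}"]
    for i, rid in enumerate(dm.ids):
        vals = " ".join(f"{dm.d[i, j]:.6f}" for j in range(dm.n))
        lines.append(f"{rid[:10]:<10} {vals}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_distance_matrix(path: str | Path):
    """Parse a PHYLIP square matrix back into a DistanceMatrix."""
    import numpy as np

    from .pairwise import DistanceMatrix

    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"empty distance-matrix file {path}")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise FormatError("first line must hold the matrix size", line=1)
    if len(lines) != n + 1:
        raise FormatError(f"expected {n} matrix rows, found {len(lines) - 1}")
    ids, d = [], np.zeros((n, n))
    for i, line in enumerate(lines[1:]):
        parts = line.split()
        if len(parts) != n + 1:
            raise FormatError(
                f"row {parts[0] if parts else '?'} has {len(parts) - 1} "
                f"entries, expected {n}", line=i + 2)
        ids.append(parts[0])
        d[i] = [float(x) for x in parts[1:]]
    return DistanceMatrix(ids=ids, d=d)
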