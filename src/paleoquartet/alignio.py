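"""Sequence I/O, alignment container, translation, progressive alignment and
concatenation.

Sequence sets are lists of Biopython ``SeqRecord`` objects; aligned data live
in the :class:`Alignment` container, which tracks taxon/individual annotations
parsed from ``taxon|individual|locus`` headers and an optional partition map
(0-based, half-open column intervals) after concatenation.

The progressive aligner is a deliberately small affine-gap Needleman-Wunsch
(pairwise-to-profile, guide order of decreasing similarity).  Ortholog panels
of closely related hominids are near-identical, so the aligner's heuristics
are immaterial; generated panels are already aligned and take the pre-aligned
path.
"""

from __future__ import annotations

import logging
import math
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentError,
    DuplicateHeaderError,
    EmptyRecordError,
    InternalStopError,
    MixedAlphabetError,
    PartitionError,
)

logger = logging.getLogger(__name__)

GAP = "-"
DNA_CHARS = frozenset("ACGTN-")
# Residues that cannot occur in a DNA sequence.
_PROTEIN_ONLY = frozenset("DEFHIKLMPQRSVWY*X")
PROTEIN_CHARS = frozenset("ACDEFGHIKLMNPQRSTVWYX*-")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


def infer_alphabet(seq: str) -> str:
    """Classify a single sequence as ``dna`` or ``protein``.

    A sequence using only ACGT/N/- is called DNA; short peptides composed
    exclusively of Ala/Cys/Gly/Thr are therefore classified as DNA, which is
    the conventional ambiguity of residue-based inference.
    """
    chars = frozenset(seq.upper())
    if chars <= DNA_CHARS:
        return "dna"
    if chars <= PROTEIN_CHARS:
        return "protein"
    bad = sorted(chars - PROTEIN_CHARS)
    raise AlignmentError(f"unrecognized residues {bad!r}")


def parse_header(header: str, scheme: str = "taxon|individual|locus") -> dict:
    """Split a ``|``-separated FASTA header according to *scheme*.

    Missing trailing fields are returned as empty strings; extra fields
    raise.
    """
    keys = scheme.split("|")
    parts = header.split("|")
    if len(parts) > len(keys):
        raise AlignmentError(
            f"header {header!r} has {len(parts)} fields, scheme {scheme!r} "
            f"allows {len(keys)}"
        )
    parts = parts + [""] * (len(keys) - len(parts))
    return dict(zip(keys, parts))


def read_fasta(path) -> list[SeqRecord]:
    """Read a FASTA file, validating headers and alphabet consistency.

    Raises :class:`DuplicateHeaderError`, :class:`EmptyRecordError` or
    :class:`MixedAlphabetError` on malformed input.  An empty file yields an
    empty list with a logged warning.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        logger.warning("FASTA file %s contains no records", path)
        return []
    seen: set[str] = set()
    alphabets: set[str] = set()
    for rec in records:
        header = rec.description or rec.id
        if header in seen:
            raise DuplicateHeaderError(f"duplicate FASTA header {header!r}")
        seen.add(header)
        if len(rec.seq) == 0:
            raise EmptyRecordError(f"record {header!r} has an empty sequence")
        alphabets.add(infer_alphabet(str(rec.seq)))
    if len(alphabets) > 1:
        raise MixedAlphabetError(
            f"mixed alphabets in {path}: {sorted(alphabets)}"
        )
    return records


def write_fasta(records: Iterable[SeqRecord | tuple[str, str]], path) -> None:
    """Write records as single-line FASTA (byte-lossless round trip)."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            if isinstance(rec, tuple):
                header, seq = rec
            else:
                header, seq = (rec.description or rec.id), str(rec.seq)
            fh.write(f">{header}\n{seq}\n")


def translate(dna: str, frame: int = 0, allow_internal_stop: bool = False) -> str:
    """Translate a DNA sequence under the standard genetic code.

    Codons containing ambiguity codes translate to ``X``; a trailing stop is
    trimmed; an internal stop raises :class:`InternalStopError` unless
    *allow_internal_stop*, in which case it is written as ``*``.
    """
    if frame not in (0, 1, 2):
        raise AlignmentError(f"frame must be 0, 1 or 2, got {frame}")
    seq = dna.upper()[frame:]
    if len(seq) % 3 != 0:
        raise AlignmentError(
            f"coding length {len(seq)} not divisible by 3 after frame offset"
        )
    out: list[str] = []
    n_codons = len(seq) // 3
    for i in range(n_codons):
        codon = seq[3 * i : 3 * i + 3]
        if codon in _STANDARD_TABLE.stop_codons:
            if i == n_codons - 1:
                break  # trailing stop trimmed
            if not allow_internal_stop:
                raise InternalStopError(
                    f"internal stop codon {codon} at codon {i}"
                )
            out.append("*")
        elif codon in _STANDARD_TABLE.forward_table:
            out.append(_STANDARD_TABLE.forward_table[codon])
        else:
            out.append("X")
    return "".join(out)


@dataclass
class Alignment:
    """Equal-length residue matrix with labels and an optional partition map.

    ``ids`` follow the ``taxon|individual|locus`` header scheme (trailing
    fields optional).  ``partitions`` maps locus name to a 0-based half-open
    column interval and, when present, must tile the columns.
    """

    ids: list[str]
    seqs: list[str]
    alphabet: str | None = None
    partitions: "OrderedDict[str, tuple[int, int]] | None" = None
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.seqs:
            raise AlignmentError("alignment needs at least one sequence")
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs differ in length")
        self.seqs = [s.upper() for s in self.seqs]
        width = len(self.seqs[0])
        if any(len(s) != width for s in self.seqs):
            raise AlignmentError("alignment rows differ in length")
        if self.alphabet is None:
            alphabets = {infer_alphabet(s) for s in self.seqs}
            if len(alphabets) > 1:
                raise MixedAlphabetError(f"mixed alphabets: {sorted(alphabets)}")
            self.alphabet = alphabets.pop()
        if self.partitions is not None:
            self._check_partitions()

    def _check_partitions(self) -> None:
        pos = 0
        for locus, (start, end) in self.partitions.items():
            if start != pos or end <= start:
                raise PartitionError(
                    f"partition {locus!r} [{start},{end}) is not contiguous "
                    f"from column {pos}"
                )
            pos = end
        if pos != self.width:
            raise PartitionError(
                f"partitions cover {pos} of {self.width} columns"
            )

    # -- basic accessors ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.seqs)

    @property
    def width(self) -> int:
        return len(self.seqs[0])

    @property
    def taxa(self) -> list[str]:
        return [i.split("|")[0] for i in self.ids]

    def column(self, j: int) -> str:
        return "".join(s[j] for s in self.seqs)

    def columns(self) -> Iterable[str]:
        for j in range(self.width):
            yield self.column(j)

    def matrix(self) -> np.ndarray:
        """(n, width) array of single characters."""
        return np.array([list(s) for s in self.seqs], dtype="U1")

    def row(self, taxon: str) -> str:
        for i, t in enumerate(self.taxa):
            if t == taxon:
                return self.seqs[i]
        raise AlignmentError(f"taxon {taxon!r} not in alignment")

    def subset_columns(self, start: int, end: int, name: str | None = None) -> "Alignment":
        return Alignment(
            ids=list(self.ids),
            seqs=[s[start:end] for s in self.seqs],
            alphabet=self.alphabet,
            name=name,
        )

    def to_records(self) -> list[tuple[str, str]]:
        return list(zip(self.ids, self.seqs))

    def write(self, path) -> None:
        write_fasta(self.to_records(), path)

    @classmethod
    def read(cls, path, name: str | None = None) -> "Alignment":
        records = read_fasta(path)
        if not records:
            raise AlignmentError(f"no records in {path}")
        return cls(
            ids=[r.description or r.id for r in records],
            seqs=[str(r.seq) for r in records],
            name=name,
        )


def alignment_from_records(records, name: str | None = None) -> Alignment:
    return Alignment(
        ids=[r.description or r.id for r in records],
        seqs=[str(r.seq) for r in records],
        name=name,
    )


# ---------------------------------------------------------------------------
# Progressive alignment (affine-gap Needleman-Wunsch, pairwise-to-profile)
# ---------------------------------------------------------------------------

_NEG = -1e30


def _profile_score(col_a: str, col_b: str, match: float, mismatch: float) -> float:
    """Mean pairwise substitution score between two profile columns.

    Gap characters inside a profile contribute zero (neutral), so the score
    reduces to the plain match/mismatch score for single sequences.
    """
    total = 0.0
    pairs = 0
    for a in col_a:
        if a == GAP:
            continue
        for b in col_b:
            if b == GAP:
                continue
            total += match if a == b else mismatch
            pairs += 1
    return total / pairs if pairs else 0.0


def _align_profiles(
    prof_a: list[str],
    prof_b: list[str],
    gap_open: float,
    gap_extend: float,
    match: float,
    mismatch: float,
) -> tuple[list[str], list[str], float]:
    """Gotoh affine-gap global alignment of two profiles (maximization).

    A gap of length L costs ``gap_open + L * gap_extend``.  Tie-break order:
    diagonal, gap-in-B (consume A), gap-in-A.  Returns gapped profiles plus
    the optimal score.
    """
    la, lb = len(prof_a[0]), len(prof_b[0])
    cols_a = ["".join(s[j] for s in prof_a) for j in range(la)]
    cols_b = ["".join(s[j] for s in prof_b) for j in range(lb)]

    M = np.full((la + 1, lb + 1), _NEG)
    X = np.full((la + 1, lb + 1), _NEG)  # gap in B (A column consumed)
    Y = np.full((la + 1, lb + 1), _NEG)  # gap in A
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = -(gap_open + i * gap_extend)
    for j in range(1, lb + 1):
        Y[0, j] = -(gap_open + j * gap_extend)

    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = _profile_score(cols_a[i - 1], cols_b[j - 1], match, mismatch)
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(
                M[i - 1, j] - gap_open - gap_extend, X[i - 1, j] - gap_extend
            )
            Y[i, j] = max(
                M[i, j - 1] - gap_open - gap_extend, Y[i, j - 1] - gap_extend
            )

    # traceback
    i, j = la, lb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))  # 0=M, 1=X, 2=Y
    score = [M[i, j], X[i, j], Y[i, j]][state]
    ops: list[str] = []
    while i > 0 or j > 0:
        if state == 0:
            ops.append("D")
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            i, j = i - 1, j - 1
            state = int(np.argmax(prev))
        elif state == 1:
            ops.append("A")  # consume A, gap in B
            if math.isclose(X[i, j], M[i - 1, j] - gap_open - gap_extend):
                state = 0
            i -= 1
        else:
            ops.append("B")  # consume B, gap in A
            if math.isclose(Y[i, j], M[i, j - 1] - gap_open - gap_extend):
                state = 0
            j -= 1
    ops.reverse()

    out_a = [[] for _ in prof_a]
    out_b = [[] for _ in prof_b]
    ia = ib = 0
    for op in ops:
        if op in ("D", "A"):
            for k, s in enumerate(prof_a):
                out_a[k].append(s[ia])
            ia += 1
        else:
            for r in out_a:
                r.append(GAP)
        if op in ("D", "B"):
            for k, s in enumerate(prof_b):
                out_b[k].append(s[ib])
            ib += 1
        else:
            for r in out_b:
                r.append(GAP)
    return (
        ["".join(r) for r in out_a],
        ["".join(r) for r in out_b],
        float(score),
    )


def pairwise_align(
    a: str,
    b: str,
    gap_open: float = 5.0,
    gap_extend: float = 1.0,
    match: float = 1.0,
    mismatch: float = -1.0,
) -> tuple[str, str, float]:
    """Affine-gap global alignment of two sequences; returns gapped pair and score."""
    if not a or not b:
        raise AlignmentError("cannot align an empty sequence")
    ra, rb, score = _align_profiles([a], [b], gap_open, gap_extend, match, mismatch)
    return ra[0], rb[0], score


def _identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    return sum(1 for x, y in zip(a, b) if x == y) / max(len(a), len(b))


def progressive_align(
    records: Sequence[SeqRecord | tuple[str, str]],
    gap_open: float = 5.0,
    gap_extend: float = 1.0,
    match: float = 1.0,
    mismatch: float = -1.0,
    name: str | None = None,
) -> Alignment:
    """Progressive multiple alignment by pairwise-to-profile merging.

    Guide order: start from the most similar pair (crude ungapped identity),
    then greedily add the sequence most similar to any aligned one.
    Deterministic for fixed input.
    """
    pairs = [
        (r[0], r[1]) if isinstance(r, tuple) else ((r.description or r.id), str(r.seq))
        for r in records
    ]
    if not 2 <= len(pairs) <= 16:
        raise AlignmentError("progressive_align handles 2-16 sequences")
    if any(not s for _, s in pairs):
        raise AlignmentError("cannot align an empty sequence")

    n = len(pairs)
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = _identity(pairs[i][1], pairs[j][1])
    i0, j0 = divmod(int(np.argmax(sim + np.tril(np.full((n, n), -1.0)))), n)
    order = [i0, j0]
    remaining = [k for k in range(n) if k not in order]
    while remaining:
        best = max(remaining, key=lambda k: (max(sim[k][m] for m in order), -k))
        order.append(best)
        remaining.remove(best)

    profile = [pairs[order[0]][1]]
    prof_ids = [pairs[order[0]][0]]
    for k in order[1:]:
        out_a, out_b, _ = _align_profiles(
            profile, [pairs[k][1]], gap_open, gap_extend, match, mismatch
        )
        profile = out_a + out_b
        prof_ids.append(pairs[k][0])

    # restore input order
    reorder = sorted(range(n), key=lambda pos: order[pos])
    ids = [prof_ids[pos] for pos in reorder]
    seqs = [profile[pos] for pos in reorder]
    return Alignment(ids=ids, seqs=seqs, name=name)


# ---------------------------------------------------------------------------
# Concatenation
# ---------------------------------------------------------------------------


def concatenate(alignments: Sequence[Alignment]) -> Alignment:
    """Concatenate locus alignments column-wise, matching rows by taxon.

    Every input must carry exactly one row per taxon and the same taxon set;
    a missing taxon aborts (no gap padding).  The result's partition map
    records each locus interval in input order; row ids are the bare taxon
    names (individuals may differ between loci).
    """
    if not alignments:
        raise AlignmentError("nothing to concatenate")
    first = alignments[0]
    taxa = first.taxa
    if len(set(taxa)) != len(taxa):
        raise AlignmentError("concatenate needs exactly one row per taxon")
    taxon_set = set(taxa)
    parts: "OrderedDict[str, tuple[int, int]]" = OrderedDict()
    rows = {t: [] for t in taxa}
    pos = 0
    for idx, aln in enumerate(alignments):
        if aln.alphabet != first.alphabet:
            raise MixedAlphabetError("cannot concatenate across alphabets")
        these = aln.taxa
        if len(set(these)) != len(these):
            raise AlignmentError("concatenate needs exactly one row per taxon")
        if set(these) != taxon_set:
            missing = sorted(taxon_set.symmetric_difference(these))
            raise AlignmentError(
                f"taxon set mismatch at locus {aln.name or idx}: {missing}"
            )
        for t in taxa:
            rows[t].append(aln.row(t))
        locus = aln.name if aln.name is not None else f"locus{idx}"
        if locus in parts:
            raise AlignmentError(f"duplicate locus name {locus!r}")
        parts[locus] = (pos, pos + aln.width)
        pos += aln.width
    return Alignment(
        ids=list(taxa),
        seqs=["".join(rows[t]) for t in taxa],
        alphabet=first.alphabet,
        partitions=parts,
    )


def write_partition_map(aln: Alignment, path) -> None:
    """Export the partition map as RAxML-style ``locus = start-end`` lines (1-based)."""
    if aln.partitions is None:
        raise PartitionError("alignment has no partition map")
    with Path(path).open("w") as fh:
        for locus, (start, end) in aln.partitions.items():
            fh.write(f"{locus} = {start + 1}-{end}\n")
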