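"""Protein sequence containers and FASTA / TSV input-output.

Sequences are modelled over the canonical 20-letter amino-acid alphabet.
Anything else in a FASTA record (ambiguity codes B/Z/J, the rare residues
U/O, placeholders X and ``*``, gap characters) is handled by an explicit
sanitization policy rather than silently:

``drop``
    remove the offending character, keep the sequence (default; keeps the
    20-letter event space closed while preserving maximal training data);
``reject``
    raise :class:`~protlm.errors.SanitizationError` naming the first
    offending residue and its 1-based position;
``map-to-x``
    map unknown residues to ``X`` for accounting, then remove them — the
    retained residues equal the ``drop`` result, but the report counts
    mapped residues separately.

Whitespace and digits are always removed and case is always folded to
upper; soft-masking lowercase carries no meaning for proteins.
"""

from __future__ import annotations

import gzip
import io
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DuplicateIdError, FastaFormatError, ParameterError, SanitizationError

#: The 20 canonical amino acids, alphabetically by one-letter code.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

_CANONICAL_SET = frozenset(CANONICAL_AA)
_ALWAYS_STRIP = set(" \t\r\n\v\f0123456789")

#: Recognized sanitization policies.
POLICIES = ("drop", "reject", "map-to-x")


def sanitize(raw: str, policy: str = "drop") -> str:
    """Normalize a raw residue string to the canonical alphabet.

    Parameters
    ----------
    raw
        Residue string as read from a FASTA record; may contain
        whitespace, digits, lowercase and non-canonical codes.
    policy
        One of :data:`POLICIES`.

    Returns
    -------
    str
        Uppercase string containing only canonical residues.

    Raises
    ------
    SanitizationError
        Under ``reject`` when a non-canonical residue is present (the
        message names the residue and its 1-based position in the
        whitespace-stripped string), or under any policy when nothing
        canonical remains.
    """
    if policy not in POLICIES and policy != "map-to-x-then-drop":
        raise ParameterError(f"unknown sanitization policy {policy!r}; expected one of {POLICIES}")
    stripped = "".join(c for c in raw if c not in _ALWAYS_STRIP).upper()
    if policy == "reject":
        for pos, c in enumerate(stripped, start=1):
            if c not in _CANONICAL_SET:
                raise SanitizationError(
                    f"non-canonical residue {c!r} at position {pos} (policy=reject)"
                )
    cleaned = "".join(c for c in stripped if c in _CANONICAL_SET)
    if not cleaned:
        raise SanitizationError("empty after sanitization")
    return cleaned


@dataclass(frozen=True)
class ProteinSequence:
    """An identifier plus a residue string over the canonical alphabet."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ParameterError(f"sequence {self.id!r}: empty residue string")
        bad = set(self.residues) - _CANONICAL_SET
        if bad:
            raise ParameterError(
                f"sequence {self.id!r}: non-canonical residues {sorted(bad)}; sanitize first"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SanitizationReport:
    """What sanitization did to a corpus while reading it."""

    n_records_read: int = 0
    n_records_kept: int = 0
    n_records_dropped_empty: int = 0
    n_residues_removed: int = 0
    n_residues_mapped_to_x: int = 0
    dropped_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class Corpus:
    """An ordered, label-tagged collection of protein sequences.

    Identifiers are unique within a corpus; duplicates are a hard error
    so downstream joins (cluster assignments, decision tables) stay
    unambiguous.
    """

    label: str
    sequences: tuple[ProteinSequence, ...]
    report: SanitizationReport | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequences", tuple(self.sequences))
        seen: Counter[str] = Counter(s.id for s in self.sequences)
        dups = sorted(i for i, c in seen.items() if c > 1)
        if dups:
            raise DuplicateIdError(f"duplicate sequence ids in corpus {self.label!r}: {dups}")

    @property
    def size(self) -> int:
        return len(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[ProteinSequence]:
        return iter(self.sequences)

    def __getitem__(self, i: int) -> ProteinSequence:
        return self.sequences[i]

    def ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.sequences)


def _open_text(path: str | Path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path, label: str, policy: str = "drop") -> Corpus:
    """Read a (possibly gzipped) FASTA file into a :class:`Corpus`.

    Record order is preserved. Records whose residues vanish entirely
    under sanitization are omitted and counted in the corpus
    :class:`SanitizationReport`.

    Raises
    ------
    FastaFormatError
        Empty file, or content before the first header (the message
        names the offending line number).
    DuplicateIdError
        Repeated record identifiers (all duplicates listed).
    SanitizationError
        Under ``reject``, the first non-canonical residue found.
    """
    path = Path(path)
    with _open_text(path) as handle:
        text = handle.read()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise FastaFormatError(
                    f"{path}: line {lineno} precedes the first '>' header; not FASTA"
                )
            break
    else:
        raise FastaFormatError(f"{path}: empty FASTA file (no records)")

    sequences: list[ProteinSequence] = []
    n_read = n_dropped = n_removed = n_mapped = 0
    dropped: list[str] = []
    for record in SeqIO.parse(io.StringIO(text), "fasta"):
        n_read += 1
        raw = str(record.seq)
        try:
            cleaned = sanitize(raw, policy=policy)
        except SanitizationError as exc:
            if policy == "reject":
                raise SanitizationError(f"record {record.id!r}: {exc}") from exc
            n_dropped += 1
            dropped.append(record.id)
            continue
        stripped = "".join(c for c in raw if c not in _ALWAYS_STRIP).upper()
        removed = len(stripped) - len(cleaned)
        n_removed += removed
        if policy == "map-to-x":
            n_mapped += removed
        sequences.append(ProteinSequence(id=record.id, residues=cleaned))

    report = SanitizationReport(
        n_records_read=n_read,
        n_records_kept=len(sequences),
        n_records_dropped_empty=n_dropped,
        n_residues_removed=n_removed,
        n_residues_mapped_to_x=n_mapped,
        dropped_ids=tuple(dropped),
    )
    return Corpus(label=label, sequences=tuple(sequences), report=report)


def write_fasta(corpus: Corpus | Iterable[ProteinSequence], path: str | Path) -> Path:
    """Write sequences to ``path`` in FASTA format (60-column wrap)."""
    path = Path(path)
    seqs = corpus.sequences if isinstance(corpus, Corpus) else tuple(corpus)
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")
    return path


def _fmt(x: float) -> str:
    if math.isnan(x):
        return "nan"
    return f"{x:.6g}"


def write_tsv_report(decisions: Sequence, path: str | Path) -> Path:
    """Write a ranked tab-separated decision report.

    Rows are sorted by descending log-odds, ties broken by id; scores are
    printed with 6 significant digits and a ``.`` decimal point. Raises
    :class:`ParameterError` on an empty collection.
    """
    decisions = list(decisions)
    if not decisions:
        raise ParameterError("cannot write a report for zero decisions")
    path = Path(path)
    header = ["id", "length", "loglik_human", "loglik_nonhuman",
              "log_odds", "log_odds_per_pos", "label"]
    rows = sorted(decisions, key=lambda d: (-d.log_odds, d.id))
    with open(path, "w", newline="") as handle:
        handle.write("\t".join(header) + "\n")
        for d in rows:
            handle.write("\t".join([
                d.id,
                str(d.length),
                _fmt(d.loglik_human),
                _fmt(d.loglik_nonhuman),
                _fmt(d.log_odds),
                _fmt(d.log_odds_per_pos),
                d.label,
            ]) + "\n")
    return path
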