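"""FASTQ/FASTA input-output and base-level utilities.

Reads are Illumina Casava 1.8 records: Phred+33 qualities, the mate number
in the first field after the space in the header.  The identity code (the
instrument/run/flowcell/lane/tile/x/y token before the first space) is
shared by the two mates of a pair and is the key used for duplicate removal
and mate recovery.

Checkpoint files use the same FASTQ dialect with a ``TW`` annotation
appended to the header line (``TW pos=<1-based int> strand=<F|R> mm=<int>``)
recording each read's placement on the consensus; the consensus itself is
the first record of a checkpoint.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33
MAX_PHRED = 60
VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FORWARD = "forward"
REVERSE_COMPLEMENT = "reverse_complement"

CONSENSUS_IDENTITY = "TW_consensus"


class FastqParseError(ValueError):
    """Raised for malformed FASTQ records; message names the record number."""


@dataclass(frozen=True)
class QualityScale:
    """Phred quality semantics: Q = -10*log10(p_error), ASCII offset 33."""

    ascii_offset: int = PHRED_OFFSET

    @staticmethod
    def error_prob(q: int | float) -> float:
        return 10.0 ** (-q / 10.0)

    def decode(self, qual_string: str, record: int | None = None) -> list[int]:
        quals = []
        for ch in qual_string:
            q = ord(ch) - self.ascii_offset
            if q < 0:
                where = f" in record {record}" if record is not None else ""
                raise FastqParseError(
                    f"quality character {ch!r} below ASCII {self.ascii_offset}{where}"
                )
            quals.append(min(q, MAX_PHRED))
        return quals

    def encode(self, quals: Sequence[int]) -> str:
        return "".join(chr(min(max(int(q), 0), MAX_PHRED) + self.ascii_offset) for q in quals)


SCALE = QualityScale()


@dataclass(frozen=True)
class Read:
    """One sequenced read: identity code, mate number, bases, Phred scores."""

    identity: str
    mate: int
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self):
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.identity}/{self.mate}: {len(self.bases)} bases "
                f"but {len(self.quals)} quality values"
            )
        if len(self.bases) == 0:
            raise ValueError(f"read {self.identity}/{self.mate}: empty sequence")
        if self.mate not in (1, 2):
            raise ValueError(f"read {self.identity}: mate must be 1 or 2, got {self.mate}")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def key(self) -> tuple[str, int]:
        return (self.identity, self.mate)


@dataclass(frozen=True)
class ReadMatch:
    """A read placed ungapped on a target sequence.

    ``offset`` is the 0-based target position of the read's leftmost aligned
    base; ``read_start`` is the index of that base within the oriented read
    (the read as aligned: reverse-complemented first if ``orientation`` is
    reverse_complement).  The read's base 0 therefore sits at target
    coordinate ``offset - read_start`` (the *placement*), which may be
    negative when the read hangs off the 5' end of the consensus.
    """

    read: Read
    offset: int
    orientation: str = FORWARD
    mismatches: int = 0
    matched_span: int = 0
    read_start: int = 0

    @property
    def placement(self) -> int:
        return self.offset - self.read_start

    def oriented_bases(self) -> str:
        if self.orientation == REVERSE_COMPLEMENT:
            return reverse_complement(self.read.bases)
        return self.read.bases

    def oriented_quals(self) -> tuple[int, ...]:
        if self.orientation == REVERSE_COMPLEMENT:
            return self.read.quals[::-1]
        return self.read.quals

    def shifted(self, shift: int) -> "ReadMatch":
        return replace(self, offset=self.offset + shift)


@dataclass
class DataSet:
    """A target sequence (template or growing consensus) plus placed reads."""

    target: str
    target_quals: list[int] = field(default_factory=list)
    matches: list[ReadMatch] = field(default_factory=list)

    def __post_init__(self):
        if not self.target_quals:
            self.target_quals = [MAX_PHRED] * len(self.target)

    def keys(self) -> set[tuple[str, int]]:
        return {m.read.key for m in self.matches}


def reverse_complement(s: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    bad = set(s) - VALID_BASES
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return s.translate(_COMPLEMENT)[::-1]


def _parse_header(title: str) -> tuple[str, int, str]:
    """Split a Casava 1.8 title into (identity, mate, remainder).

    Falls back to trailing ``/1`` / ``/2`` on the identity token for older
    header styles; defaults to mate 1 when neither form is present.
    """
    parts = title.split(None, 1)
    identity = parts[0]
    rest = parts[1] if len(parts) > 1 else ""
    mate = 0
    if rest:
        first = rest.split()[0]
        head = first.split(":", 1)[0]
        if head in ("1", "2"):
            mate = int(head)
    if mate == 0 and len(identity) > 2 and identity[-2] == "/" and identity[-1] in "12":
        mate = int(identity[-1])
        identity = identity[:-2]
    if mate == 0:
        mate = 1
    return identity, mate, rest


def read_fastq(path: str | os.PathLike, limit: Optional[int] = None) -> Iterator[Read]:
    """Stream Reads from a Casava 1.8 FASTQ file in file order.

    Malformed records raise :class:`FastqParseError` naming the record
    number (1-based).
    """
    n = 0
    with open(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                n += 1
                if limit is not None and n > limit:
                    return
                if len(seq) != len(qual):
                    raise FastqParseError(
                        f"record {n}: sequence length {len(seq)} != quality length {len(qual)}"
                    )
                identity, mate, _ = _parse_header(title)
                yield Read(identity, mate, seq.upper(), tuple(SCALE.decode(qual, n)))
        except ValueError as exc:
            if isinstance(exc, FastqParseError):
                raise
            raise FastqParseError(f"record {n + 1}: {exc}") from exc


def write_fastq(
    reads: Iterable[Read],
    path: str | os.PathLike,
    annotations: Optional[Iterable[str]] = None,
) -> None:
    """Write 4-line Casava 1.8 records; optional per-read annotation text is
    appended to the header line after the Casava fields."""
    ann_iter = iter(annotations) if annotations is not None else None
    with open(path, "w") as out:
        for r in reads:
            _write_record(out, r, next(ann_iter) if ann_iter is not None else None)


def _write_record(out, r: Read, annotation: Optional[str]) -> None:
    header = f"@{r.identity} {r.mate}:N:0:0"
    if annotation:
        header += " " + annotation
    out.write(f"{header}\n{r.bases}\n+\n{SCALE.encode(r.quals)}\n")


def read_fasta(path: str | os.PathLike) -> tuple[str, str]:
    """Return (identity, sequence) of the first FASTA record.

    Sequence is uppercased with U mapped to T (RNA templates accepted).
    """
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise ValueError(f"empty sequence for record {rec.id!r} in {path}")
        return rec.description, seq
    raise ValueError(f"no FASTA records in {path}")


# ---------------------------------------------------------------------------
# TW annotation dialect (checkpoint / match files)

def match_annotation(m: ReadMatch) -> str:
    strand = "R" if m.orientation == REVERSE_COMPLEMENT else "F"
    return f"TW pos={m.placement + 1} strand={strand} mm={m.mismatches}"


def write_match_fastq(
    ds: DataSet,
    path: str | os.PathLike,
    step: int = 0,
    origin_shift: int = 0,
) -> None:
    """Write a checkpoint: consensus record first, then all placed reads.

    Reads are sorted by (placement, identity, mate) so that checkpoints are
    byte-identical for equal DataSets regardless of construction order.
    """
    with open(path, "w") as out:
        header = (
            f"@{CONSENSUS_IDENTITY} 1:N:0:0 TW consensus step={step} shift={origin_shift}"
        )
        out.write(f"{header}\n{ds.target}\n+\n{SCALE.encode(ds.target_quals)}\n")
        for m in sorted(ds.matches, key=lambda m: (m.placement, m.read.identity, m.read.mate)):
            _write_record(out, m.read, match_annotation(m))


def read_match_fastq(path: str | os.PathLike) -> tuple[DataSet, dict]:
    """Load a checkpoint written by :func:`write_match_fastq`.

    Returns the DataSet and a metadata dict (step, shift).  Aligned spans
    are recomputed against the stored consensus.
    """
    meta = {"step": 0, "shift": 0}
    ds: DataSet | None = None
    with open(path) as handle:
        for n, (title, seq, qual) in enumerate(FastqGeneralIterator(handle), start=1):
            identity, mate, rest = _parse_header(title)
            quals = tuple(SCALE.decode(qual, n))
            fields = dict(
                kv.split("=", 1) for kv in rest.split() if "=" in kv
            )
            if n == 1:
                if identity != CONSENSUS_IDENTITY:
                    raise FastqParseError(
                        f"record 1: expected consensus record {CONSENSUS_IDENTITY!r}, got {identity!r}"
                    )
                meta["step"] = int(fields.get("step", 0))
                meta["shift"] = int(fields.get("shift", 0))
                ds = DataSet(target=seq.upper(), target_quals=list(quals))
                continue
            assert ds is not None
            placement = int(fields["pos"]) - 1
            orientation = REVERSE_COMPLEMENT if fields.get("strand") == "R" else FORWARD
            mm = int(fields.get("mm", 0))
            m = _place(
                Read(identity, mate, seq.upper(), quals), placement, orientation,
                len(ds.target), mm,
            )
            ds.matches.append(m)
    if ds is None:
        raise FastqParseError("record 1: empty checkpoint file")
    return ds, meta


def _place(
    read: Read, placement: int, orientation: str, target_len: int, mismatches: int
) -> ReadMatch:
    """Build a ReadMatch from a placement, computing the span that actually
    intersects the target."""
    start = max(placement, 0)
    end = min(placement + len(read), target_len)
    span = max(end - start, 0)
    return ReadMatch(
        read=read,
        offset=start,
        orientation=orientation,
        mismatches=mismatches,
        matched_span=span,
        read_start=start - placement,
    )
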