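"""Stage 2 — walking: iterative extension of a discovered contig.

Each step searches the complete groomed read files, at much higher
stringency than discovery, for reads that overlap the growing end of the
consensus by at least ``min_overlap`` bases (with at most ``max_errors``
mismatches over the ungapped overlap) and extend past it.  The accepted
reads are *melded* onto the end: proceeding outward one position at a
time, a position is called only while at least ``min_ragged`` reads cover
it (the ragged-end rule), and the called base is the one with the greatest
sum of Phred scores among the covering reads.  Reads are retained in the
DataSet after melding, and the whole state is checkpointed to disk after
every step.

A 3'->5' walk grows the sequence leftward by prepending; the accumulated
leftward growth is the *origin shift*, which must later be applied to any
DataSet from a previous walk before the two are combined and re-melded
into the final sequence.

With 100-base reads and a minimum overlap of 30, the maximum single-step
extension is 70 bases.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from transwalk.seqio import (
    FORWARD,
    REVERSE_COMPLEMENT,
    DataSet,
    Read,
    ReadMatch,
    read_fastq,
    reverse_complement,
    write_match_fastq,
)

THREE_TO_FIVE = "three_to_five"
FIVE_TO_THREE = "five_to_three"

MAX_CONSENSUS_Q = 40

# read bases encode A,C,G,T,N -> 1..5 (0 is padding); the consensus encodes
# N as 6 so that N never equals anything, in either sequence
_READ_CODE = {"A": 1, "C": 2, "G": 3, "T": 4, "N": 5}
_CONS_CODE = {"A": 1, "C": 2, "G": 3, "T": 4, "N": 6}


class IntegrityError(ValueError):
    """A read no longer aligns within the error tolerance after combining."""


@dataclass(frozen=True)
class WalkParams:
    """Walk settings; defaults are the method's typical values."""

    direction: str = THREE_TO_FIVE
    target_length: Optional[int] = None
    min_overlap: int = 30
    max_errors: int = 2
    min_ragged: int = 5
    max_find: int = 50
    max_add: int = 50
    max_steps: Optional[int] = None

    def __post_init__(self):
        if self.direction not in (THREE_TO_FIVE, FIVE_TO_THREE):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.min_overlap < 1 or self.max_errors < 0 or self.min_ragged < 1:
            raise ValueError("min_overlap, min_ragged must be >= 1; max_errors >= 0")
        if not 1 <= self.max_add <= self.max_find:
            raise ValueError("need 1 <= max_add <= max_find")


@dataclass
class WalkState:
    consensus: str
    consensus_quals: list[int] = field(default_factory=list)
    matches: list[ReadMatch] = field(default_factory=list)
    step_index: int = 0
    origin_shift: int = 0
    terminated: bool = False
    reason: str = ""

    def __post_init__(self):
        if not self.consensus_quals:
            self.consensus_quals = [MAX_CONSENSUS_Q] * len(self.consensus)

    def as_dataset(self) -> DataSet:
        return DataSet(
            target=self.consensus,
            target_quals=list(self.consensus_quals),
            matches=list(self.matches),
        )


class ReadBank:
    """All groomed reads from one or two files, encoded as numpy arrays for
    fast ungapped diagonal comparison (one row per read, left-justified,
    zero padding)."""

    def __init__(self, reads: Sequence[Read]):
        self.reads = list(reads)
        n = len(self.reads)
        self.max_len = max((len(r) for r in self.reads), default=0)
        self.lengths = np.array([len(r) for r in self.reads], dtype=np.int32)
        self.fwd = np.zeros((n, self.max_len), dtype=np.uint8)
        self.rc = np.zeros((n, self.max_len), dtype=np.uint8)
        for i, r in enumerate(self.reads):
            self.fwd[i, : len(r)] = [_READ_CODE[b] for b in r.bases]
            self.rc[i, : len(r)] = [_READ_CODE[b] for b in reverse_complement(r.bases)]

    @classmethod
    def from_files(cls, files: Iterable) -> "ReadBank":
        reads: list[Read] = []
        for path in files:
            reads.extend(read_fastq(path))
        return cls(reads)


def _as_bank(files) -> ReadBank:
    if isinstance(files, ReadBank):
        return files
    return ReadBank.from_files(files)


def _encode_consensus(consensus: str) -> np.ndarray:
    return np.array([_CONS_CODE[b] for b in consensus], dtype=np.uint8)


def _scan_right(
    consensus: str,
    bank: ReadBank,
    p: WalkParams,
    excluded: set,
    exclude_ids: set,
) -> list[ReadMatch]:
    """Candidates overlapping the 3' (right) end and extending past it.

    Returns the single best placement per read (longest overlap, then
    fewest mismatches).
    """
    L = len(consensus)
    if L < p.min_overlap or not bank.reads:
        return []
    cons = _encode_consensus(consensus)
    best: dict[tuple[str, int], ReadMatch] = {}
    lo_d = max(0, L - bank.max_len + 1)
    for d in range(lo_d, L - p.min_overlap + 1):
        w = L - d
        window = cons[d:L]
        for mat, orientation in ((bank.fwd, FORWARD), (bank.rc, REVERSE_COMPLEMENT)):
            eq = (mat[:, :w] == window).sum(axis=1)
            ok = np.nonzero((bank.lengths > w) & (w - eq <= p.max_errors))[0]
            for i in ok:
                r = bank.reads[i]
                if r.key in excluded or r.identity in exclude_ids:
                    continue
                key = (r.identity, r.mate)
                if key in best:  # earlier (smaller d) placement has longer overlap
                    continue
                best[key] = ReadMatch(
                    read=r,
                    offset=d,
                    orientation=orientation,
                    mismatches=int(w - eq[i]),
                    matched_span=w,
                    read_start=0,
                )
    out = sorted(
        best.values(),
        key=lambda m: (-m.matched_span, m.mismatches, m.read.identity, m.read.mate),
    )
    return out[: p.max_find]


def _flip_to_left(m: ReadMatch, L: int) -> ReadMatch:
    """Map a right-end match found on the reverse-complemented consensus back
    onto the forward consensus (it becomes a left-end match)."""
    n = len(m.read)
    placement = L - (m.offset + n)  # usually negative: read hangs off the left
    orientation = FORWARD if m.orientation == REVERSE_COMPLEMENT else REVERSE_COMPLEMENT
    return ReadMatch(
        read=m.read,
        offset=0,
        orientation=orientation,
        mismatches=m.mismatches,
        matched_span=m.matched_span,
        read_start=-placement,
    )


def find_overlapping_reads(
    state: WalkState,
    files,
    p: WalkParams,
    exclude_ids: Iterable[str] = (),
) -> list[ReadMatch]:
    """Up to max_find reads overlapping the growing end by >= min_overlap
    aligned bases with <= max_errors mismatches, each extending at least one
    base past the end in the walk direction.

    Ranked by overlap length descending, then mismatches ascending, then
    identity — a deterministic order independent of file order.  Reads
    already contributing to the state are not returned again.
    """
    bank = _as_bank(files)
    excluded = {m.read.key for m in state.matches}
    exclude_set = set(exclude_ids)
    if p.direction == FIVE_TO_THREE:
        return _scan_right(state.consensus, bank, p, excluded, exclude_set)
    L = len(state.consensus)
    flipped = _scan_right(reverse_complement(state.consensus), bank, p, excluded, exclude_set)
    out = [_flip_to_left(m, L) for m in flipped]
    out.sort(key=lambda m: (-m.matched_span, m.mismatches, m.read.identity, m.read.mate))
    return out


def weighted_vote(votes: Sequence[tuple[str, int]]) -> tuple[str, int]:
    """Phred-weighted base vote over (base, qual) pairs; N bases never vote.

    The winner is the base with the greatest Phred sum; ties go to the base
    seen in more reads, then to alphabetical order.  The returned consensus
    quality is min(40, round(winning Phred sum / number of voting reads)).
    """
    sums: dict[str, int] = {}
    counts: dict[str, int] = {}
    for base, q in votes:
        if base == "N":
            continue
        sums[base] = sums.get(base, 0) + q
        counts[base] = counts.get(base, 0) + 1
    if not sums:
        return "N", 0
    winner = min(sums, key=lambda b: (-sums[b], -counts[b], b))
    n = sum(counts.values())
    return winner, min(MAX_CONSENSUS_Q, round(sums[winner] / n))


def _column_votes(matches: Sequence[ReadMatch], pos: int) -> list[tuple[str, int]]:
    votes = []
    for m in matches:
        i = pos - m.placement
        if 0 <= i < len(m.read):
            b = m.oriented_bases()[i]
            if b != "N":
                votes.append((b, m.oriented_quals()[i]))
    return votes


def meld(state: WalkState, new_matches: Sequence[ReadMatch], p: WalkParams) -> WalkState:
    """Meld accepted reads onto the growing end (in place).

    Extends the consensus outward one position at a time past its current
    end; a position is called only while >= min_ragged reads (with a called
    base) cover it, by the Phred-weighted vote.  Interior positions are
    never modified.  For a 3'->5' walk the extension is prepended and all
    coordinates (and the origin shift) are updated.
    """
    state.matches.extend(new_matches)
    L = len(state.consensus)
    if p.direction == FIVE_TO_THREE:
        overhang = [m for m in state.matches if m.placement + len(m.read) > L]
        new_bases: list[str] = []
        new_quals: list[int] = []
        pos = L
        while True:
            if p.target_length is not None and L + len(new_bases) >= p.target_length:
                break
            votes = _column_votes(overhang, pos)
            if len(votes) < p.min_ragged:
                break
            b, q = weighted_vote(votes)
            new_bases.append(b)
            new_quals.append(q)
            pos += 1
        state.consensus = state.consensus + "".join(new_bases)
        state.consensus_quals.extend(new_quals)
    else:
        overhang = [m for m in state.matches if m.placement < 0]
        new_bases = []
        new_quals = []
        pos = -1
        while True:
            if p.target_length is not None and L + len(new_bases) >= p.target_length:
                break
            votes = _column_votes(overhang, pos)
            if len(votes) < p.min_ragged:
                break
            b, q = weighted_vote(votes)
            new_bases.append(b)
            new_quals.append(q)
            pos -= 1
        k = len(new_bases)
        if k:
            state.consensus = "".join(reversed(new_bases)) + state.consensus
            state.consensus_quals = list(reversed(new_quals)) + state.consensus_quals
            state.matches = [m.shifted(k) for m in state.matches]
            state.origin_shift += k
    return state


def walk(
    state: WalkState,
    files,
    p: WalkParams,
    checkpoint_dir: Optional[str | os.PathLike] = None,
    exclude_ids: Iterable[str] = (),
    log=None,
) -> WalkState:
    """Run walk steps until the data is exhausted or a limit is reached.

    After every step the full state (consensus first, then every
    contributing read with its placement) is checkpointed to
    ``step_<index>.tw.fastq`` in checkpoint_dir.
    """
    bank = _as_bank(files)
    ckpt = Path(checkpoint_dir) if checkpoint_dir is not None else None
    if ckpt is not None:
        ckpt.mkdir(parents=True, exist_ok=True)
    while True:
        if p.max_steps is not None and state.step_index >= p.max_steps:
            state.terminated, state.reason = True, "max_steps"
            break
        if p.target_length is not None and len(state.consensus) >= p.target_length:
            state.terminated, state.reason = True, "target_length"
            break
        found = find_overlapping_reads(state, bank, p, exclude_ids)
        if not found:
            state.terminated, state.reason = True, "data_exhausted"
            break
        added = found[: p.max_add]
        old_len = len(state.consensus)
        meld(state, added, p)
        state.step_index += 1
        if ckpt is not None:
            write_match_fastq(
                state.as_dataset(),
                ckpt / f"step_{state.step_index}.tw.fastq",
                step=state.step_index,
                origin_shift=state.origin_shift,
            )
        if log is not None:
            log(
                json.dumps(
                    {
                        "stage": "walk",
                        "step": state.step_index,
                        "found": len(found),
                        "added": len(added),
                        "extension": len(state.consensus) - old_len,
                        "consensus_length": len(state.consensus),
                    }
                )
            )
    return state


def apply_origin_shift(ds: DataSet, shift: int) -> DataSet:
    """Shift all match offsets rightward by ``shift`` (consensus unchanged)."""
    if shift < 0:
        raise ValueError("shift must be >= 0")
    return DataSet(
        target=ds.target,
        target_quals=list(ds.target_quals),
        matches=[m.shifted(shift) for m in ds.matches],
    )


def combine_and_meld(sets: Sequence[DataSet], p: WalkParams) -> DataSet:
    """Combine walk DataSets sharing one coordinate system and re-meld the
    full-length consensus position by position.

    Duplicate reads (same identity and mate) keep the lower-mismatch copy.
    Terminal positions require >= min_ragged covering reads; interior
    positions >= 1 (uncovered interior positions are written as N).

    Every combined read is re-verified against the re-melded consensus; a
    read whose mismatch count indicates a coordinate inconsistency (more
    than max(max_errors, 20% of its aligned span) mismatches — unplaced
    sequences disagree at ~75% of positions, while sequencing errors
    accumulate at the Phred-implied rate) raises an
    :class:`IntegrityError` naming it.
    """
    merged: dict[tuple[str, int], ReadMatch] = {}
    for ds in sets:
        for m in ds.matches:
            prev = merged.get(m.read.key)
            if prev is None or (m.mismatches, m.offset) < (prev.mismatches, prev.offset):
                merged[m.read.key] = m
    if not merged:
        return DataSet(target="")
    matches = sorted(
        merged.values(), key=lambda m: (m.placement, m.read.identity, m.read.mate)
    )
    lo = min(m.placement for m in matches)
    hi = max(m.placement + len(m.read) for m in matches)

    columns: list[list[tuple[str, int]]] = [[] for _ in range(hi - lo)]
    for m in matches:
        bases = m.oriented_bases()
        quals = m.oriented_quals()
        for i in range(len(bases)):
            if bases[i] != "N":
                columns[m.placement - lo + i].append((bases[i], quals[i]))

    cov = [len(c) for c in columns]
    start = 0
    while start < len(cov) and cov[start] < p.min_ragged:
        start += 1
    end = len(cov)
    while end > start and cov[end - 1] < p.min_ragged:
        end -= 1
    if end <= start:
        return DataSet(target="")

    bases_out: list[str] = []
    quals_out: list[int] = []
    for c in columns[start:end]:
        if c:
            b, q = weighted_vote(c)
        else:
            b, q = "N", 0
        bases_out.append(b)
        quals_out.append(q)
    consensus = "".join(bases_out)

    shift = -(lo + start)
    out = DataSet(target=consensus, target_quals=quals_out)
    for m in matches:
        placed = m.shifted(shift)
        mm, span, aligned = _recount(placed, consensus)
        limit = max(p.max_errors, -(-span // 5))  # 20% of the aligned span
        if mm > limit:
            raise IntegrityError(
                f"read {m.read.identity}/{m.read.mate} aligns with {mm} mismatches "
                f"over {span} bases (limit {limit}) after combination"
            )
        out.matches.append(aligned)
    return out


def _recount(m: ReadMatch, consensus: str) -> tuple[int, int, ReadMatch]:
    """Recompute mismatches/span of a placed read against a consensus
    (N positions, in either sequence, never match and never mismatch)."""
    bases = m.oriented_bases()
    start = max(m.placement, 0)
    end = min(m.placement + len(bases), len(consensus))
    mm = 0
    for pos in range(start, end):
        b = bases[pos - m.placement]
        c = consensus[pos]
        if b != "N" and c != "N" and b != c:
            mm += 1
    from dataclasses import replace

    aligned = replace(
        m, offset=start, read_start=start - m.placement, matched_span=end - start, mismatches=mm
    )
    return mm, end - start, aligned
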