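"""Stage 1 — seed discovery against a heterologous template.

Reads are matched to the template at low stringency: a match is a run of at
least ``min_contig_match`` contiguous identical bases (typically 15-20)
between the read, in either orientation, and the template.  Runs are exact
and ungapped; N never matches.  Matching reads can then be screened for
stop codons in the template's reading frame and assembled into an initial
contig by perfect suffix-prefix overlap detection.

The matching contract is exact equivalence with a brute-force all-offsets
scan; the k-mer index used here is purely an optimization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from transwalk.seqio import (
    FORWARD,
    REVERSE_COMPLEMENT,
    DataSet,
    Read,
    ReadMatch,
    read_fastq,
    reverse_complement,
)

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class SearchParams:
    """Low-stringency search settings.

    ``mask`` is a sequence of 0-based half-open template intervals excluded
    from the search (the template regions not used for seeding); masked
    positions never start or extend a run.
    """

    min_contig_match: int = 18
    orientations: tuple[str, ...] = (FORWARD, REVERSE_COMPLEMENT)
    max_reads: Optional[int] = None
    mask: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.min_contig_match < 8:
            raise ValueError("min_contig_match must be >= 8")
        if not self.orientations:
            raise ValueError("at least one orientation required")


@dataclass
class Contig:
    bases: str
    support: list[ReadMatch] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.bases)


def _masked_positions(target_len: int, mask) -> set[int]:
    masked: set[int] = set()
    for lo, hi in mask:
        masked.update(range(max(lo, 0), min(hi, target_len)))
    return masked


def _index_target(target: str, k: int, masked: set[int]) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for t in range(len(target) - k + 1):
        kmer = target[t : t + k]
        if "N" in kmer:
            continue
        if masked and any(p in masked for p in range(t, t + k)):
            continue
        index.setdefault(kmer, []).append(t)
    return index


def find_contiguous_matches(
    target: str,
    r: Read,
    p: SearchParams = SearchParams(),
    _index: Optional[dict] = None,
) -> list[ReadMatch]:
    """All distinct maximal exact runs of >= min_contig_match bases between
    the read (in the requested orientations) and the target.

    Each reported run is maximal: extended left and right while bases agree
    (N and masked template positions never agree).  matched_span is the run
    length and mismatches is 0.  ``_index`` allows callers to reuse a
    prebuilt k-mer index of the target.
    """
    k = p.min_contig_match
    if len(target) < k:
        return []
    masked = _masked_positions(len(target), p.mask)
    index = _index if _index is not None else _index_target(target, k, masked)
    matches: list[ReadMatch] = []
    for orientation in p.orientations:
        oriented = reverse_complement(r.bases) if orientation == REVERSE_COMPLEMENT else r.bases
        seen_runs: set[tuple[int, int]] = set()
        for i in range(len(oriented) - k + 1):
            kmer = oriented[i : i + k]
            if "N" in kmer:
                continue
            for t in index.get(kmer, ()):
                diag = t - i
                # extend maximally on this diagonal
                lo_t, lo_i = t, i
                while (
                    lo_t > 0
                    and lo_i > 0
                    and target[lo_t - 1] == oriented[lo_i - 1]
                    and oriented[lo_i - 1] != "N"
                    and (lo_t - 1) not in masked
                ):
                    lo_t -= 1
                    lo_i -= 1
                hi_t, hi_i = t + k, i + k
                while (
                    hi_t < len(target)
                    and hi_i < len(oriented)
                    and target[hi_t] == oriented[hi_i]
                    and oriented[hi_i] != "N"
                    and hi_t not in masked
                ):
                    hi_t += 1
                    hi_i += 1
                if (diag, lo_t) in seen_runs:
                    continue
                seen_runs.add((diag, lo_t))
                matches.append(
                    ReadMatch(
                        read=r,
                        offset=lo_t,
                        orientation=orientation,
                        mismatches=0,
                        matched_span=hi_t - lo_t,
                        read_start=lo_i,
                    )
                )
    matches.sort(key=lambda m: (-m.matched_span, m.offset, m.orientation))
    return matches


def best_match(matches: Sequence[ReadMatch]) -> Optional[ReadMatch]:
    """Longest run; ties broken by smallest offset, forward orientation first."""
    if not matches:
        return None
    return min(matches, key=lambda m: (-m.matched_span, m.offset, m.orientation != FORWARD))


def search_files(
    target: str,
    files: Sequence,
    p: SearchParams = SearchParams(),
) -> DataSet:
    """Search one or two FASTQ files for template matches.

    The best match per read is retained.  The result is independent of file
    order: matches are sorted by (offset, identity, mate).
    """
    k = p.min_contig_match
    masked = _masked_positions(len(target), p.mask)
    index = _index_target(target, k, masked)
    found: dict[tuple[str, int], ReadMatch] = {}
    n_kept = 0
    for path in files:
        for r in read_fastq(path):
            if p.max_reads is not None and n_kept >= p.max_reads:
                break
            m = best_match(find_contiguous_matches(target, r, p, _index=index))
            if m is None:
                continue
            prev = found.get(r.key)
            if prev is None:
                found[r.key] = m
                n_kept += 1
            elif (-m.matched_span, m.offset) < (-prev.matched_span, prev.offset):
                found[r.key] = m
    ds = DataSet(target=target)
    ds.matches = sorted(
        found.values(), key=lambda m: (m.offset, m.read.identity, m.read.mate)
    )
    return ds


def reject_noncoding(ds: DataSet, frame_offset: int = 0) -> tuple[DataSet, int]:
    """Drop matches whose aligned span contains a stop codon in the target's
    reading frame (codon boundaries at target positions == frame_offset mod 3).

    Only complete codons fully inside the aligned span are considered; a
    stop straddling the span edge or out of frame does not reject a read.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    kept: list[ReadMatch] = []
    removed = 0
    for m in ds.matches:
        if _has_inframe_stop(m, frame_offset):
            removed += 1
        else:
            kept.append(m)
    out = DataSet(target=ds.target, target_quals=list(ds.target_quals))
    out.matches = kept
    return out, removed


def _has_inframe_stop(m: ReadMatch, frame_offset: int) -> bool:
    oriented = m.oriented_bases()
    span_start, span_end = m.offset, m.offset + m.matched_span
    # first codon start >= span_start congruent to frame_offset mod 3
    t = span_start + ((frame_offset - span_start) % 3)
    while t + 3 <= span_end:
        i = m.read_start + (t - span_start)
        if oriented[i : i + 3] in STOP_CODONS:
            return True
        t += 3
    return False


class _Piece:
    """A growing contig during greedy assembly."""

    __slots__ = ("bases", "support", "anchor")

    def __init__(self, bases: str, support: list[tuple[int, ReadMatch]], anchor):
        self.bases = bases
        self.support = support  # (placement within piece, source match)
        self.anchor = anchor  # deterministic tie-break token

    def __len__(self):
        return len(self.bases)


def _best_overlap(a: str, b: str, min_overlap: int) -> int:
    """Longest L >= min_overlap with a[-L:] == b[:L]; 0 if none."""
    for L in range(min(len(a), len(b)), min_overlap - 1, -1):
        if a[-L:] == b[:L]:
            return L
    return 0


def overlap_assemble(ds: DataSet, min_overlap: int = 21) -> list[Contig]:
    """Greedy perfect-overlap assembly of the matched reads.

    Repeatedly joins the pair with the longest perfect (0-mismatch)
    suffix-prefix overlap >= min_overlap (a sequence fully contained in
    another counts as an overlap of its whole length), with consistent
    orientations already baked into the oriented sequences, until no join
    is possible.  Contigs are returned sorted by length descending; ties
    broken by earliest read identity, forward orientation first.
    """
    pieces: list[_Piece] = []
    for m in sorted(
        ds.matches, key=lambda m: (m.read.identity, m.read.mate, m.orientation != FORWARD)
    ):
        full = ReadMatch(
            read=m.read,
            offset=0,
            orientation=m.orientation,
            mismatches=0,
            matched_span=len(m.read),
            read_start=0,
        )
        pieces.append(
            _Piece(
                m.oriented_bases(),
                [(0, full)],
                (m.read.identity, m.read.mate, m.orientation != FORWARD),
            )
        )

    while len(pieces) > 1:
        best = None  # (-L, anchor_a, anchor_b, ia, ib, kind, pos)
        for ia, a in enumerate(pieces):
            for ib, b in enumerate(pieces):
                if ia == ib:
                    continue
                if len(b) <= len(a):
                    pos = a.bases.find(b.bases)
                    if pos >= 0 and len(b) >= min_overlap:
                        cand = (-len(b), a.anchor, b.anchor, ia, ib, "contain", pos)
                        if best is None or cand < best:
                            best = cand
                        continue
                L = _best_overlap(a.bases, b.bases, min_overlap)
                if L:
                    cand = (-L, a.anchor, b.anchor, ia, ib, "join", L)
                    if best is None or cand < best:
                        best = cand
        if best is None:
            break
        _, _, _, ia, ib, kind, pos = best
        a, b = pieces[ia], pieces[ib]
        if kind == "contain":
            a.support.extend((pos + off, src) for off, src in b.support)
        else:
            shift = len(a) - pos
            a.bases = a.bases + b.bases[pos:]
            a.support.extend((shift + off, src) for off, src in b.support)
        a.anchor = min(a.anchor, b.anchor)
        del pieces[ib]

    contigs = []
    for piece in sorted(pieces, key=lambda x: (-len(x), x.anchor)):
        support = [
            ReadMatch(
                read=src.read,
                offset=off,
                orientation=src.orientation,
                mismatches=0,
                matched_span=len(src.read),
                read_start=0,
            )
            for off, src in sorted(
                piece.support, key=lambda t: (t[0], t[1].read.identity, t[1].read.mate)
            )
        ]
        contigs.append(Contig(bases=piece.bases, support=support))
    return contigs
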