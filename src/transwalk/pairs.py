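"""Duplicate removal, mate recovery and fragment-size estimation.

The two mates of a cDNA fragment share an identity code, so pairing needs
no alignment: after walking, duplicates are dropped by (identity, mate),
the groomed files are searched once more for the missing member of each
incomplete pair, and recovered mates are placed on the final consensus
with the discovery matcher.  The effective fragment size of each complete
pair is the inclusive span between the outermost aligned bases of its two
reads, which makes a pair of fully-overlapping 100-base mates a 100-base
fragment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from transwalk.discover import SearchParams, best_match, find_contiguous_matches, _index_target
from transwalk.seqio import FORWARD, REVERSE_COMPLEMENT, DataSet, Read, ReadMatch, read_fastq
from transwalk.walk import WalkParams, _recount


@dataclass(frozen=True)
class PairLink:
    """Two mated ReadMatches and the fragment span they imply."""

    mate1: ReadMatch
    mate2: ReadMatch
    fragment_length: int
    improper: bool = False


@dataclass(frozen=True)
class FragmentStats:
    count: int
    mean: float
    min: int
    max: int


def remove_duplicates(ds: DataSet) -> DataSet:
    """At most one match per (identity, mate); the copy with fewest
    mismatches (ties: smallest offset) survives.  Idempotent."""
    best: dict[tuple[str, int], ReadMatch] = {}
    order: list[tuple[str, int]] = []
    for m in ds.matches:
        key = m.read.key
        prev = best.get(key)
        if prev is None:
            best[key] = m
            order.append(key)
        elif (m.mismatches, m.offset) < (prev.mismatches, prev.offset):
            best[key] = m
    out = DataSet(target=ds.target, target_quals=list(ds.target_quals))
    out.matches = [best[k] for k in order]
    return out


def find_missing_pairs(ds: DataSet, files: Sequence) -> list[Read]:
    """Reads whose mate is in the DataSet but which are themselves absent,
    in file order."""
    present = ds.keys()
    wanted_identities = {ident for ident, _ in present}
    missing: list[Read] = []
    for path in files:
        for r in read_fastq(path):
            if r.identity in wanted_identities and r.key not in present:
                missing.append(r)
    return missing


def match_mates_to_consensus(
    ds: DataSet,
    mates: Iterable[Read],
    p: WalkParams = WalkParams(),
    search: SearchParams = SearchParams(),
) -> tuple[DataSet, list[Read]]:
    """Place recovered mates on the final consensus with the discovery
    matcher (best maximal run, then full ungapped placement).

    A mate is added only if its full aligned span carries <= p.max_errors
    mismatches; others are returned as unplaced.
    """
    out = DataSet(target=ds.target, target_quals=list(ds.target_quals))
    out.matches = list(ds.matches)
    unplaced: list[Read] = []
    index = _index_target(ds.target, search.min_contig_match, set())
    for r in mates:
        m = best_match(find_contiguous_matches(ds.target, r, search, _index=index))
        if m is None:
            unplaced.append(r)
            continue
        mm, span, aligned = _recount(m, ds.target)
        if mm > p.max_errors or span < search.min_contig_match:
            unplaced.append(r)
            continue
        out.matches.append(aligned)
    return out, unplaced


def _span(m: ReadMatch) -> tuple[int, int]:
    return m.offset, m.offset + m.matched_span - 1


def _is_proper(m1: ReadMatch, m2: ReadMatch) -> bool:
    """Inward-facing, opposite orientations."""
    if m1.orientation == m2.orientation:
        return False
    fwd = m1 if m1.orientation == FORWARD else m2
    rev = m2 if fwd is m1 else m1
    return fwd.offset <= rev.offset + rev.matched_span - 1


def pair_sort(ds: DataSet) -> tuple[DataSet, list[PairLink], Optional[FragmentStats]]:
    """Bring paired ends together and estimate fragment sizes.

    Reads are reordered so that each pair's primary (the mate that entered
    the DataSet first) keeps its position in an offset sort and its mate
    follows immediately.  Fragment length is computed for complete pairs
    only, as the inclusive span between the outermost aligned bases.
    """
    by_identity: dict[str, list[ReadMatch]] = {}
    entry_order: dict[str, int] = {}
    for i, m in enumerate(ds.matches):
        by_identity.setdefault(m.read.identity, []).append(m)
        entry_order.setdefault(m.read.identity, i)

    links: list[PairLink] = []
    groups: list[tuple[ReadMatch, list[ReadMatch]]] = []  # (primary, ordered members)
    for ident, members in by_identity.items():
        primary = members[0]
        rest = members[1:]
        groups.append((primary, [primary] + rest))
        if len(members) == 2 and {members[0].read.mate, members[1].read.mate} == {1, 2}:
            m1 = members[0] if members[0].read.mate == 1 else members[1]
            m2 = members[1] if m1 is members[0] else members[0]
            left = min(_span(m1)[0], _span(m2)[0])
            right = max(_span(m1)[1], _span(m2)[1])
            links.append(
                PairLink(
                    mate1=m1,
                    mate2=m2,
                    fragment_length=right - left + 1,
                    improper=not _is_proper(m1, m2),
                )
            )

    groups.sort(key=lambda g: (g[0].offset, g[0].read.identity, g[0].read.mate))
    out = DataSet(target=ds.target, target_quals=list(ds.target_quals))
    for _, members in groups:
        out.matches.extend(members)

    stats = None
    if links:
        lengths = [l.fragment_length for l in links]
        stats = FragmentStats(
            count=len(lengths),
            mean=sum(lengths) / len(lengths),
            min=min(lengths),
            max=max(lengths),
        )
    return out, links, stats
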