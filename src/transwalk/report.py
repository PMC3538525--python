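"""Coverage, variants, ORF/translation, and text rendering of read stacks.

The pileup collapses the placed reads onto the consensus axis (one column
per position, counting orientation-resolved bases), which both shows the
per-base read support and exposes allelic variation: a site where the
second-most-frequent base is well supported (e.g. 30 of 64 reads) is
reported as a candidate allele, and its consequence is classified against
the reading frame (silent / missense / nonsense).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from Bio.Seq import Seq

from transwalk.seqio import DataSet, ReadMatch, reverse_complement

BASES = "ACGTN"
STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class PileupColumn:
    position: int  # 1-based for reporting
    counts: dict
    depth: int


@dataclass(frozen=True)
class VariantCall:
    position: int  # 1-based consensus coordinate
    major_base: str
    major_count: int
    minor_base: str
    minor_count: int
    consequence: str  # silent | missense | nonsense | noncoding
    codon_ref: str = ""
    codon_alt: str = ""


@dataclass(frozen=True)
class Orf:
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive, includes the stop codon
    frame: int  # 0,1,2
    strand: str  # '+' or '-'
    sequence: str

    def __len__(self) -> int:
        return self.end - self.start


def pileup(ds: DataSet) -> list[PileupColumn]:
    """One column per consensus position; each read contributes its aligned
    (orientation-resolved) bases to exactly the columns it covers."""
    n = len(ds.target)
    counts = [dict.fromkeys(BASES, 0) for _ in range(n)]
    for m in ds.matches:
        bases = m.oriented_bases()
        for pos in range(m.offset, m.offset + m.matched_span):
            if 0 <= pos < n:
                counts[pos][bases[pos - m.placement]] += 1
    return [
        PileupColumn(position=i + 1, counts=c, depth=sum(c.values()))
        for i, c in enumerate(counts)
    ]


def call_variants(
    cols: Sequence[PileupColumn],
    min_minor_count: int = 5,
    frame_offset: Optional[int] = None,
    consensus: Optional[str] = None,
) -> list[VariantCall]:
    """Sites whose second-most-frequent called base has at least
    ``min_minor_count`` supporting reads.

    With a reading frame (``frame_offset`` = 0-based consensus position of
    the first codon's first base, and the consensus sequence for codon
    context), the consequence of substituting the minor base is classified
    by direct codon translation; otherwise it is reported as noncoding.
    """
    calls: list[VariantCall] = []
    for col in cols:
        ranked = sorted(
            ((b, c) for b, c in col.counts.items() if b != "N" and c > 0),
            key=lambda bc: (-bc[1], bc[0]),
        )
        if len(ranked) < 2:
            continue
        (major, major_n), (minor, minor_n) = ranked[0], ranked[1]
        if minor_n < min_minor_count:
            continue
        consequence, codon_ref, codon_alt = "noncoding", "", ""
        if frame_offset is not None and consensus is not None:
            consequence, codon_ref, codon_alt = _classify(
                consensus, col.position - 1, minor, frame_offset
            )
        calls.append(
            VariantCall(
                position=col.position,
                major_base=major,
                major_count=major_n,
                minor_base=minor,
                minor_count=minor_n,
                consequence=consequence,
                codon_ref=codon_ref,
                codon_alt=codon_alt,
            )
        )
    return calls


def _classify(consensus: str, pos: int, minor: str, frame_offset: int) -> tuple[str, str, str]:
    if pos < frame_offset:
        return "noncoding", "", ""
    codon_start = frame_offset + 3 * ((pos - frame_offset) // 3)
    if codon_start + 3 > len(consensus):
        return "noncoding", "", ""
    ref = consensus[codon_start : codon_start + 3]
    i = pos - codon_start
    alt = ref[:i] + minor + ref[i + 1 :]
    if "N" in ref or "N" in alt:
        return "noncoding", ref, alt
    aa_ref = translate(ref)
    aa_alt = translate(alt)
    if aa_alt == aa_ref:
        return "silent", ref, alt
    if aa_alt == "*":
        return "nonsense", ref, alt
    return "missense", ref, alt


def find_orf(consensus: str, include_reverse: bool = False) -> Optional[Orf]:
    """Longest complete ATG-to-stop open reading frame (stop included).

    Scans the three forward frames, plus the reverse complement when
    requested; ties are broken toward the 5'-most start (forward strand
    first).  Returns None when no complete ORF exists.
    """
    candidates: list[Orf] = []
    strands = [("+", consensus)]
    if include_reverse:
        strands.append(("-", reverse_complement(consensus)))
    for strand, seq in strands:
        for frame in range(3):
            candidates.extend(_frame_orfs(seq, frame, strand))
    if not candidates:
        return None
    return min(candidates, key=lambda o: (-len(o), o.strand, o.start))


def _frame_orfs(seq: str, frame: int, strand: str) -> list[Orf]:
    orfs = []
    start: Optional[int] = None
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in STOPS:
            if start is not None:
                orfs.append(Orf(start, i + 3, frame, strand, seq[start : i + 3]))
                start = None
        elif codon == "ATG" and start is None:
            start = i
    return orfs


def translate(cds: str) -> str:
    """Standard-code translation to one-letter amino acids; stop is '*'."""
    if len(cds) % 3 != 0:
        raise ValueError(f"coding sequence length {len(cds)} is not a multiple of 3")
    return str(Seq(cds).translate())


SORT_KEYS = {
    "match_position": lambda m: (m.offset, m.read.identity, m.read.mate),
    "pair": lambda m: (m.read.identity, m.read.mate),
    "length": lambda m: (-len(m.read), m.read.identity, m.read.mate),
    "mate": lambda m: (m.read.mate, m.offset, m.read.identity),
}


def render_alignment(ds: DataSet, sort: str = "match_position", mode: str = "stack") -> str:
    """Fixed-width text rendering of the read stack.

    In stack mode the consensus is the first line and each read is printed
    offset-aligned beneath it over its aligned span: '.' where the read
    agrees with the consensus, the read's base where it differs.  Histogram
    mode prints the per-position depth as stacked digit rows (units first).
    """
    if sort not in SORT_KEYS:
        raise ValueError(f"unknown sort {sort!r}")
    lines = [ds.target]
    if mode == "stack":
        for m in sorted(ds.matches, key=SORT_KEYS[sort]):
            bases = m.oriented_bases()
            chars = []
            for pos in range(m.offset, m.offset + m.matched_span):
                if not 0 <= pos < len(ds.target):
                    continue
                b = bases[pos - m.placement]
                chars.append("." if b == ds.target[pos] else b.lower() if b == "N" else b)
            start = max(m.offset, 0)
            lines.append(" " * start + "".join(chars))
    elif mode == "histogram":
        depths = [c.depth for c in pileup(ds)]
        digits = max(len(str(d)) for d in depths) if depths else 1
        for place in range(digits):
            row = []
            for d in depths:
                s = str(d).rjust(digits)
                row.append(s[digits - 1 - place])
            lines.append("".join(row))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return "\n".join(lines)
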