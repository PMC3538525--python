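"""Quality grooming: trim each read to its longest contiguous high-quality
run and discard reads whose best run is too short.

The filter keeps a read only if it contains at least ``min_run`` contiguous
bases with Phred >= ``min_phred`` (default: 80 bases at Q >= 20, i.e. error
probability below 1%), and trims the read to that run.  Ties between
equal-length runs are broken toward the 5' end.  Mates are groomed
independently, so one member of a pair can survive while the other does not.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Optional

from transwalk.seqio import Read, read_fastq, write_fastq


@dataclass(frozen=True)
class GroomParams:
    min_run: int = 80
    min_phred: int = 20

    def __post_init__(self):
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if not 0 <= self.min_phred <= 60:
            raise ValueError("min_phred must be in [0, 60]")


@dataclass
class GroomSummary:
    input: int = 0
    kept: int = 0
    discarded: int = 0
    length_histogram: Counter = field(default_factory=Counter)

    def to_json(self) -> str:
        return json.dumps(
            {
                "input": self.input,
                "kept": self.kept,
                "discarded": self.discarded,
                "length_histogram": dict(sorted(self.length_histogram.items())),
            }
        )


def longest_quality_run(quals, min_phred: int) -> tuple[int, int]:
    """(start, end) half-open bounds of the longest run with Q >= min_phred;
    the 5'-most run wins ties.  Returns (0, 0) if no base qualifies."""
    best_start = best_end = 0
    start = None
    for i, q in enumerate(quals):
        if q >= min_phred:
            if start is None:
                start = i
        elif start is not None:
            if i - start > best_end - best_start:
                best_start, best_end = start, i
            start = None
    if start is not None and len(quals) - start > best_end - best_start:
        best_start, best_end = start, len(quals)
    return best_start, best_end


def groom_read(r: Read, p: GroomParams = GroomParams()) -> Optional[Read]:
    """Trim to the longest qualifying run; None if that run is too short."""
    start, end = longest_quality_run(r.quals, p.min_phred)
    if end - start < p.min_run:
        return None
    if start == 0 and end == len(r):
        return r
    return replace(r, bases=r.bases[start:end], quals=r.quals[start:end])


def groom_file(
    in_path, out_path, p: GroomParams = GroomParams()
) -> GroomSummary:
    """Groom a FASTQ file; kept reads are written in input order."""
    summary = GroomSummary()

    def kept_reads():
        for r in read_fastq(in_path):
            summary.input += 1
            g = groom_read(r, p)
            if g is None:
                summary.discarded += 1
                continue
            summary.kept += 1
            summary.length_histogram[len(g)] += 1
            yield g

    write_fastq(kept_reads(), out_path)
    return summary
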