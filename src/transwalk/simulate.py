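"""Synthetic paired-end RNA-Seq data with known ground truth.

Emulates the data model every other stage is tested against: one
transcript carrying a single long open reading frame; cDNA fragments with
truncated-normal lengths (mean 219, sd 50, floor 100 — the floor
reproduces the observed minimum fragment size, which equals the read
length); 100-base mates sequenced inward from the two fragment ends;
per-base Phred scores with a small low-quality fraction; substitution
errors injected at exactly the Phred-implied rate 10^(-Q/10); optional
biallelic variant sites mixed per fragment.  Everything is reproducible
from the seed, and the returned truth table records each read's origin,
strand, allele and injected error positions so that downstream results can
be scored exactly.

Not modelled: position-dependent quality decay, indel errors, and
multi-transcript mixtures.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import truncnorm

from transwalk.seqio import Read, reverse_complement, write_fastq

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class SimParams:
    transcript_length: int = 1500
    gc_fraction: float = 0.5
    n_fragments: int = 1000
    fragment_mean: float = 219.0
    fragment_sd: float = 50.0
    fragment_min: int = 100
    read_length: int = 100
    high_q: int = 37
    low_q: int = 12
    low_fraction: float = 0.005
    # (0-based transcript position, alternative base, alternative-allele fraction)
    variant_sites: tuple = ()
    orf_length: Optional[int] = None  # multiple of 3; default ~80% of transcript
    seed: int = 0

    def __post_init__(self):
        for pos, alt, frac in self.variant_sites:
            if not 0 < frac < 1:
                raise ValueError("allele_fraction must be in (0,1)")
            if alt not in "ACGT":
                raise ValueError("variant alternative base must be A/C/G/T")


@dataclass
class ReadTruth:
    identity: str
    mate: int
    position: int  # 0-based leftmost transcript coordinate of the read
    strand: str  # '+' (mate 1) or '-' (mate 2)
    allele: str  # 'ref' or comma-joined 'pos>alt' tokens
    error_positions: tuple  # 0-based, in read (as-written) orientation


@dataclass
class SimTruth:
    transcript: str
    orf_start: int  # 0-based
    orf_end: int  # 0-based exclusive (stop codon included)
    reads: list = field(default_factory=list)


def _rngs(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _random_bases(rng, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def simulate_transcript(p: SimParams) -> tuple[str, SimTruth]:
    """Random transcript at the requested GC fraction with one embedded
    complete ORF (ATG ... stop, no internal stops) spanning most of it.

    An in-frame stop is planted just upstream of the ATG so that the
    embedded ORF is exactly the longest ORF of the transcript.
    """
    if p.transcript_length < 300:
        raise ValueError("transcript_length must be >= 300")
    rng = _rngs(p.seed, 2)[0]
    L = p.transcript_length
    orf_len = p.orf_length
    if orf_len is None:
        orf_len = 3 * int(0.8 * L / 3)
    if orf_len % 3 != 0 or orf_len < 9 or orf_len > L - 3:
        raise ValueError("orf_length must be a multiple of 3 in [9, transcript_length-3]")

    max_start = L - orf_len
    orf_start = int(rng.integers(3, max_start + 1)) if max_start >= 3 else 0

    codons = ["ATG"]
    n_body = orf_len // 3 - 2
    while len(codons) < 1 + n_body:
        c = "".join(_random_bases(rng, 3, p.gc_fraction))
        if c not in _STOPS:
            codons.append(c)
    codons.append(["TAA", "TAG", "TGA"][int(rng.integers(3))])
    orf = "".join(codons)

    seq = list("".join(_random_bases(rng, L, p.gc_fraction)))
    seq[orf_start : orf_start + orf_len] = orf
    if orf_start >= 3:
        seq[orf_start - 3 : orf_start] = "TAA"  # close any upstream frame
    transcript = "".join(seq)
    return transcript, SimTruth(transcript, orf_start, orf_start + orf_len)


def simulate_reads(
    transcript: str,
    p: SimParams,
    out1,
    out2,
    truth: Optional[SimTruth] = None,
) -> SimTruth:
    """Simulate fragments and write the two mate files; returns the truth.

    Fragment lengths are truncated-normal on [fragment_min, transcript
    length]; starts are uniform; mate 1 is the first read_length bases of
    the fragment, mate 2 the reverse complement of the last read_length
    bases.  Each base is substituted with probability 10^(-Q/10).
    """
    L = len(transcript)
    if L <= p.fragment_min:
        raise ValueError("transcript must be longer than fragment_min")
    rng = _rngs(p.seed, 2)[1]
    if truth is None:
        truth = SimTruth(transcript, 0, 0)

    a = (p.fragment_min - p.fragment_mean) / p.fragment_sd
    b = (L - p.fragment_mean) / p.fragment_sd
    flens = np.rint(
        truncnorm.rvs(a, b, loc=p.fragment_mean, scale=p.fragment_sd,
                      size=p.n_fragments, random_state=rng)
    ).astype(int)
    flens = np.clip(flens, p.fragment_min, L)
    starts = np.array([int(rng.integers(0, L - fl + 1)) for fl in flens])

    reads1: list[Read] = []
    reads2: list[Read] = []
    for i, (start, flen) in enumerate(zip(starts, flens)):
        frag = list(transcript[start : start + flen])
        tokens = []
        for pos, alt, frac in p.variant_sites:
            if start <= pos < start + flen and rng.random() < frac:
                frag[pos - start] = alt
                tokens.append(f"{pos}>{alt}")
        allele = ",".join(tokens) if tokens else "ref"
        frag = "".join(frag)
        identity = f"SIM:1:FC1:1:1:{i + 1}:{p.seed}"

        rl = min(p.read_length, flen)
        for mate, bases, position, strand in (
            (1, frag[:rl], start, "+"),
            (2, reverse_complement(frag[-rl:]), start + flen - rl, "-"),
        ):
            quals = np.full(rl, p.high_q, dtype=int)
            quals[rng.random(rl) < p.low_fraction] = p.low_q
            p_err = 10.0 ** (-quals / 10.0)
            err_mask = rng.random(rl) < p_err
            seq = np.array(list(bases))
            for j in np.nonzero(err_mask)[0]:
                others = [x for x in "ACGT" if x != seq[j]]
                seq[j] = others[int(rng.integers(3))]
            read = Read(identity, mate, "".join(seq), tuple(int(q) for q in quals))
            (reads1 if mate == 1 else reads2).append(read)
            truth.reads.append(
                ReadTruth(
                    identity=identity,
                    mate=mate,
                    position=int(position),
                    strand=strand,
                    allele=allele,
                    error_positions=tuple(int(j) for j in np.nonzero(err_mask)[0]),
                )
            )

    write_fastq(reads1, out1)
    write_fastq(reads2, out2)
    return truth


def simulated_depth(truth: SimTruth, read_length: int = 100) -> np.ndarray:
    """Per-position read depth implied by the truth table."""
    depth = np.zeros(len(truth.transcript), dtype=int)
    for rt in truth.reads:
        depth[rt.position : rt.position + read_length] += 1
    return depth


def write_truth_tsv(truth: SimTruth, path) -> None:
    with open(path, "w", newline="") as out:
        w = csv.writer(out, delimiter="\t")
        w.writerow(["identity", "mate", "position", "strand", "allele", "error_positions"])
        for rt in truth.reads:
            w.writerow(
                [
                    rt.identity,
                    rt.mate,
                    rt.position,
                    rt.strand,
                    rt.allele,
                    ",".join(map(str, rt.error_positions)),
                ]
            )
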