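"""Independent brute-force oracles used to check the implementation.

These deliberately share no code with the package beyond the Read/ReadMatch
containers: matching is an all-offsets scan, grooming enumerates every
maximal run, consensus calling is a direct pileup vote, and ORF finding
enumerates every ATG/stop pair.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_STOPS = ("TAA", "TAG", "TGA")


def revcomp(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


def brute_force_runs(target: str, read_bases: str, min_run: int, orientations=("forward", "reverse_complement")):
    """All distinct maximal exact runs >= min_run between read and target.

    Returns a set of (orientation, target_start, read_start, length).
    N never matches.
    """
    found = set()
    for orientation in orientations:
        seq = revcomp(read_bases) if orientation == "reverse_complement" else read_bases
        for diag in range(-len(seq) + 1, len(target)):
            t = max(diag, 0)
            while t < len(target):
                i = t - diag
                if i >= len(seq):
                    break
                if seq[i] != "N" and seq[i] == target[t]:
                    start_t = t
                    while (
                        t < len(target)
                        and t - diag < len(seq)
                        and seq[t - diag] != "N"
                        and seq[t - diag] == target[t]
                    ):
                        t += 1
                    if t - start_t >= min_run:
                        found.add((orientation, start_t, start_t - diag, t - start_t))
                else:
                    t += 1
    return found


def brute_force_groom(quals, min_run: int, min_phred: int):
    """(start, end) of the kept segment, or None — by enumerating all runs."""
    runs = []
    i = 0
    n = len(quals)
    while i < n:
        if quals[i] >= min_phred:
            j = i
            while j < n and quals[j] >= min_phred:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    best = None
    for start, end in runs:  # first-encountered (5'-most) wins length ties
        if best is None or end - start > best[1] - best[0]:
            best = (start, end)
    if best is None or best[1] - best[0] < min_run:
        return None
    return best


def pileup_vote(column):
    """Winner of a Phred-weighted vote over (base, qual) pairs.

    Greatest Phred sum; ties to the base with more reads, then alphabetical.
    N does not vote.
    """
    sums, counts = {}, {}
    for base, q in column:
        if base == "N":
            continue
        sums[base] = sums.get(base, 0) + q
        counts[base] = counts.get(base, 0) + 1
    if not sums:
        return None
    ranked = sorted(sums, key=lambda b: (-sums[b], -counts[b], b))
    return ranked[0]


def enumerate_orfs(seq: str):
    """Every complete ATG..stop interval (stop included) in the 3 forward
    frames, as (start, end) 0-based half-open tuples."""
    orfs = []
    for start in range(len(seq) - 2):
        if seq[start : start + 3] != "ATG":
            continue
        for t in range(start + 3, len(seq) - 2, 3):
            if seq[t : t + 3] in _STOPS:
                orfs.append((start, t + 3))
                break
    return orfs


def best_orf(seq: str):
    """Longest forward-strand complete ORF; ties to the 5'-most start."""
    orfs = enumerate_orfs(seq)
    if not orfs:
        return None
    return min(orfs, key=lambda o: (-(o[1] - o[0]), o[0]))


CODON_TABLE = {}


def _build_codon_table():
    # standard genetic code written out by amino acid
    groups = {
        "F": ["TTT", "TTC"], "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
        "I": ["ATT", "ATC", "ATA"], "M": ["ATG"],
        "V": ["GTT", "GTC", "GTA", "GTG"],
        "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
        "P": ["CCT", "CCC", "CCA", "CCG"], "T": ["ACT", "ACC", "ACA", "ACG"],
        "A": ["GCT", "GCC", "GCA", "GCG"], "Y": ["TAT", "TAC"],
        "H": ["CAT", "CAC"], "Q": ["CAA", "CAG"], "N": ["AAT", "AAC"],
        "K": ["AAA", "AAG"], "D": ["GAT", "GAC"], "E": ["GAA", "GAG"],
        "C": ["TGT", "TGC"], "W": ["TGG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
        "G": ["GGT", "GGC", "GGA", "GGG"], "*": ["TAA", "TAG", "TGA"],
    }
    for aa, codons in groups.items():
        for c in codons:
            CODON_TABLE[c] = aa


_build_codon_table()


def translate_table(cds: str) -> str:
    return "".join(CODON_TABLE[cds[i : i + 3]] for i in range(0, len(cds), 3))
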