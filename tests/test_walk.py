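import numpy as np
import pytest

from oracles import pileup_vote, revcomp
from transwalk.seqio import (
    DataSet,
    FORWARD,
    REVERSE_COMPLEMENT,
    Read,
    ReadMatch,
    read_match_fastq,
    write_fastq,
)
from transwalk.seqio import _place
from transwalk.simulate import SimParams, simulate_reads, simulate_transcript, simulated_depth
from transwalk.walk import (
    FIVE_TO_THREE,
    THREE_TO_FIVE,
    IntegrityError,
    ReadBank,
    WalkParams,
    WalkState,
    apply_origin_shift,
    combine_and_meld,
    find_overlapping_reads,
    meld,
    walk,
    weighted_vote,
)


def mkread(bases, ident="r", mate=1, q=30):
    if isinstance(q, int):
        q = (q,) * len(bases)
    return Read(ident, mate, bases, tuple(q))


def placed(bases, placement, target_len, ident="r", mate=1, q=30, orientation=FORWARD):
    return _place(mkread(bases, ident, mate, q), placement, orientation, target_len, 0)


def rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestFindOverlappingReads:
    def setup_method(self):
        self.rng = np.random.default_rng(5)
        self.cons = rand_seq(self.rng, 200)

    def state(self):
        return WalkState(consensus=self.cons)

    def test_min_overlap_boundary_and_70_base_step(self, rng):
        ext = rand_seq(rng, 70)
        good = mkread(self.cons[-30:] + ext, "good:1")
        short = mkread(self.cons[-29:] + ext, "short:1")
        bank = ReadBank([good, short])
        p = WalkParams(direction=FIVE_TO_THREE, min_overlap=30, max_errors=0, min_ragged=1)
        found = find_overlapping_reads(self.state(), bank, p)
        assert [m.read.identity for m in found] == ["good:1"]
        m = found[0]
        assert m.matched_span == 30
        assert len(m.read) - m.matched_span == 70  # the maximal step size

    def test_too_many_mismatches_rejected(self, rng):
        overlap = list(self.cons[-40:])
        for i in (5, 15, 25):  # 3 mismatches
            overlap[i] = "A" if overlap[i] != "A" else "C"
        bad = mkread("".join(overlap) + rand_seq(rng, 60), "bad:1")
        p = WalkParams(direction=FIVE_TO_THREE, min_overlap=30, max_errors=2, min_ragged=1)
        assert find_overlapping_reads(self.state(), ReadBank([bad]), p) == []
        # with 2 mismatches it passes
        overlap[25] = self.cons[-40:][25]
        ok = mkread("".join(overlap) + rand_seq(rng, 60), "ok:1")
        found = find_overlapping_reads(self.state(), ReadBank([ok]), p)
        assert len(found) == 1 and found[0].mismatches == 2

    def test_reverse_complement_candidates_found(self, rng):
        ext = rand_seq(rng, 50)
        r = mkread(revcomp(self.cons[-40:] + ext), "rc:1")
        p = WalkParams(direction=FIVE_TO_THREE, min_overlap=30, min_ragged=1)
        found = find_overlapping_reads(self.state(), ReadBank([r]), p)
        assert len(found) == 1
        assert found[0].orientation == REVERSE_COMPLEMENT
        assert found[0].matched_span == 40

    def test_three_to_five_direction_finds_left_extension(self, rng):
        ext = rand_seq(rng, 60)
        r = mkread(ext + self.cons[:40], "left:1")
        p = WalkParams(direction=THREE_TO_FIVE, min_overlap=30, min_ragged=1)
        found = find_overlapping_reads(self.state(), ReadBank([r]), p)
        assert len(found) == 1
        m = found[0]
        assert m.placement == -60
        assert m.matched_span == 40

    def test_reads_already_in_state_not_returned_again(self, rng):
        ext = rand_seq(rng, 50)
        r = mkread(self.cons[-40:] + ext, "dup:1")
        st = self.state()
        p = WalkParams(direction=FIVE_TO_THREE, min_overlap=30, min_ragged=1)
        (m,) = find_overlapping_reads(st, ReadBank([r]), p)
        st.matches.append(m)
        assert find_overlapping_reads(st, ReadBank([r]), p) == []


class TestMeldVote:
    def test_weighted_vote_hand_example(self):
        # A: 30+20+3 = 53 beats G: 40+5 = 45
        base, q = weighted_vote([("A", 30), ("A", 20), ("G", 40), ("G", 5), ("A", 3)])
        assert base == "A"
        assert q == min(40, round(53 / 5))

    def test_unanimous_base_wins_regardless_of_weights(self):
        assert weighted_vote([("C", 2), ("C", 2), ("C", 40)])[0] == "C"

    def test_tie_breaks_read_count_then_alphabetical(self):
        assert weighted_vote([("G", 30), ("T", 15), ("T", 15)])[0] == "T"
        assert weighted_vote([("G", 30), ("T", 30)])[0] == "G"

    def test_vote_matches_pileup_oracle_on_random_columns(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 12))
            col = [
                (str(rng.choice(list("ACGTN"))), int(rng.integers(2, 41)))
                for _ in range(n)
            ]
            want = pileup_vote(col)
            got = weighted_vote(col)[0]
            assert got == (want if want is not None else "N")

    def test_ragged_end_gate_stops_extension(self, rng):
        cons = rand_seq(rng, 100)
        ext = rand_seq(rng, 30)
        st = WalkState(consensus=cons)
        p = WalkParams(direction=FIVE_TO_THREE, min_overlap=30, min_ragged=5)
        # 5 reads extend 10 bases, 4 reads continue to 30
        matches = []
        for i in range(5):
            matches.append(placed(cons[-40:] + ext[:10], 60, 100, f"a:{i}"))
        for i in range(4):
            matches.append(placed(cons[-40:] + ext, 60, 100, f"b:{i}"))
        meld(st, matches, p)
        # positions 100..109 have 9 covering reads, 110.. only 4 -> stop there
        assert st.consensus == cons + ext[:10]

    def test_interior_positions_never_modified(self, rng):
        cons = rand_seq(rng, 120)
        st = WalkState(consensus=cons)
        p = WalkParams(direction=FIVE_TO_THREE, min_overlap=30, min_ragged=1)
        # read disagrees with interior consensus but only extension is written
        noisy = list(cons[-50:])
        noisy[10] = "A" if noisy[10] != "A" else "G"
        m = placed("".join(noisy) + rand_seq(rng, 20), 70, 120, "n:1")
        meld(st, [m], p)
        assert st.consensus[:120] == cons


def make_sim(tmp_path, seed, error_free=True, length=800, fragments=220):
    kwargs = dict(transcript_length=length, n_fragments=fragments, seed=seed)
    if error_free:
        kwargs.update(high_q=40, low_fraction=0.0)
    p = SimParams(**kwargs)
    transcript, truth = simulate_transcript(p)
    r1, r2 = tmp_path / f"s{seed}_R1.fastq", tmp_path / f"s{seed}_R2.fastq"
    truth = simulate_reads(transcript, p, r1, r2, truth)
    return p, transcript, truth, r1, r2


def run_both_walks(transcript, r1, r2, ckpt_root=None):
    seed = transcript[300:500]
    # the seed contig carries its own supporting read, as a discovery contig does
    support = placed(seed, 0, len(seed), "seed:0", q=40)
    bank = ReadBank.from_files([r1, r2])
    finals = []
    for direction in (THREE_TO_FIVE, FIVE_TO_THREE):
        st = WalkState(consensus=seed, matches=[support])
        p = WalkParams(direction=direction)
        ck = None if ckpt_root is None else ckpt_root / direction
        finals.append(walk(st, bank, p, checkpoint_dir=ck))
    combined = combine_and_meld(
        [finals[0].as_dataset(), apply_origin_shift(finals[1].as_dataset(), finals[0].origin_shift)],
        WalkParams(),
    )
    return finals, combined


class TestWalk:
    def test_error_free_walk_recovers_reference(self, tmp_path):
        p, transcript, truth, r1, r2 = make_sim(tmp_path, seed=3)
        finals, combined = run_both_walks(transcript, r1, r2)
        for st in finals:
            assert st.terminated and st.reason == "data_exhausted"
        assert combined.target in transcript  # exact substring, no errors
        depth = simulated_depth(truth)
        off = transcript.find(combined.target)
        assert off >= 0
        covered = np.nonzero(depth >= 5)[0]
        inside = [i for i in covered if off <= i < off + len(combined.target)]
        # every adequately covered position inside the consensus is correct
        assert all(combined.target[i - off] == transcript[i] for i in inside)
        # and the consensus spans nearly all of them
        assert len(inside) >= 0.99 * len(covered)

    def test_no_reads_beyond_seed_terminates_unchanged(self, rng):
        cons = rand_seq(rng, 150)
        bank = ReadBank([mkread(cons[20:100], "inside:1")])
        st = WalkState(consensus=cons)
        out = walk(st, bank, WalkParams(direction=FIVE_TO_THREE))
        assert out.consensus == cons
        assert out.step_index == 0
        assert out.reason == "data_exhausted"

    def test_monotone_growth_and_step_bound(self, tmp_path):
        _, transcript, _, r1, r2 = make_sim(tmp_path, seed=9, fragments=150)
        seed = transcript[300:500]
        bank = ReadBank.from_files([r1, r2])
        st = WalkState(consensus=seed)
        p = WalkParams(direction=FIVE_TO_THREE)
        lengths = [len(st.consensus)]
        while True:
            found = find_overlapping_reads(st, bank, p)
            if not found:
                break
            meld(st, found[: p.max_add], p)
            st.step_index += 1
            lengths.append(len(st.consensus))
        diffs = np.diff(lengths)
        assert (diffs >= 0).all()
        assert (diffs <= bank.max_len - p.min_overlap).all()

    def test_checkpoints_deterministic_under_file_order(self, tmp_path):
        _, transcript, _, r1, r2 = make_sim(tmp_path, seed=5, fragments=150)
        seed = transcript[300:500]
        outs = []
        for files in ([r1, r2], [r2, r1]):
            ck = tmp_path / f"ck_{files[0].name}"
            st = WalkState(consensus=seed)
            walk(st, list(files), WalkParams(direction=FIVE_TO_THREE), checkpoint_dir=ck)
            steps = sorted(ck.glob("step_*.tw.fastq"))
            outs.append([(f.name, f.read_bytes()) for f in steps])
        assert outs[0] == outs[1]

    def test_restart_from_checkpoint_reproduces_final_consensus(self, tmp_path):
        _, transcript, _, r1, r2 = make_sim(tmp_path, seed=6, fragments=150)
        seed = transcript[300:500]
        ck1 = tmp_path / "full"
        st = WalkState(consensus=seed)
        final = walk(st, [r1, r2], WalkParams(direction=FIVE_TO_THREE), checkpoint_dir=ck1)
        assert final.step_index >= 3
        mid = ck1 / "step_2.tw.fastq"
        ds, meta = read_match_fastq(mid)
        resumed = WalkState(
            consensus=ds.target,
            consensus_quals=list(ds.target_quals),
            matches=list(ds.matches),
            step_index=meta["step"],
        )
        ck2 = tmp_path / "resumed"
        final2 = walk(resumed, [r1, r2], WalkParams(direction=FIVE_TO_THREE), checkpoint_dir=ck2)
        assert final2.consensus == final.consensus
        last = f"step_{final.step_index}.tw.fastq"
        assert (ck2 / last).read_bytes() == (ck1 / last).read_bytes()

    def test_origin_shift_bookkeeping(self, tmp_path):
        _, transcript, _, r1, r2 = make_sim(tmp_path, seed=8, fragments=150)
        seed_start = 300
        st = WalkState(consensus=transcript[seed_start : seed_start + 200])
        final = walk(st, [r1, r2], WalkParams(direction=THREE_TO_FIVE))
        assert final.origin_shift == len(final.consensus) - 200
        # the consensus grew exactly leftward along the reference
        assert transcript.find(final.consensus) == seed_start - final.origin_shift


class TestOriginShiftAndCombine:
    def test_shift_additivity_and_identity(self, rng):
        cons = rand_seq(rng, 100)
        ds = DataSet(target=cons)
        ds.matches = [placed(cons[10:60], 10, 100, "x:1")]
        same = apply_origin_shift(ds, 0)
        assert [m.offset for m in same.matches] == [10]
        twice = apply_origin_shift(apply_origin_shift(ds, 120), 120)
        once = apply_origin_shift(ds, 240)
        assert [m.offset for m in twice.matches] == [m.offset for m in once.matches]

    def test_combine_with_itself_idempotent(self, rng):
        cons = rand_seq(rng, 300)
        ds = DataSet(target=cons)
        for i in range(0, 201, 20):
            ds.matches.append(placed(cons[i : i + 100], i, 300, f"r:{i}"))
        p = WalkParams(min_ragged=1)
        once = combine_and_meld([ds], p)
        twice = combine_and_meld([ds, ds], p)
        assert once.target == twice.target
        assert len(once.matches) == len(twice.matches)

    def test_union_of_two_overlapping_sets(self, rng):
        ref = rand_seq(rng, 1000)
        left = DataSet(target=ref[:600])
        right = DataSet(target=ref[500:])
        for i in range(0, 501, 10):
            left.matches.append(placed(ref[i : i + 100], i, 600, f"L:{i}"))
        for i in range(500, 901, 10):
            right.matches.append(placed(ref[i : i + 100], i, 1000, f"R:{i}", mate=2))
        combined = combine_and_meld([left, right], WalkParams(min_ragged=1))
        assert combined.target == ref
        assert len(combined.matches) == len(left.matches) + len(right.matches)

    def test_biallelic_site_called_by_pileup_oracle(self, rng):
        ref = rand_seq(rng, 200)
        ds = DataSet(target=ref)
        col = []
        for i in range(12):
            bases = list(ref[40:140])
            q = [30] * 100
            base = "A" if i < 7 else ("G" if ref[90] != "G" else "C")
            bases[50] = base
            q[50] = 20 + i
            ds.matches.append(placed("".join(bases), 40, 200, f"v:{i}", q=q))
            col.append((base, q[50]))
        combined = combine_and_meld([ds], WalkParams(min_ragged=1, max_errors=2))
        # combined consensus is rebased to the first covered position (40)
        assert combined.target[50] == pileup_vote(col)

    def test_integrity_error_names_bad_read(self, rng):
        ref = rand_seq(rng, 200)
        ds = DataSet(target=ref)
        for i in range(6):
            ds.matches.append(placed(ref[50:150], 50, 200, f"ok:{i}"))
        garbage = "".join("A" if b != "A" else "C" for b in ref[50:150])
        ds.matches.append(placed(garbage, 50, 200, "bad:9"))
        with pytest.raises(IntegrityError, match="bad:9"):
            combine_and_meld([ds], WalkParams(min_ragged=1, max_errors=2))
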