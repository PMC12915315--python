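"""Array detection, catalogs, diffs, self-targeting, and protein identity."""

import itertools
from collections import defaultdict

import numpy as np
import pytest

from crisedit import fixtures, locus_scan
from crisedit.errors import AlphabetError, LengthError
from crisedit.locus_scan import (
    CrisprArray,
    apply_diff,
    build_spacer_catalog,
    consensus_repeat,
    dedupe_proteins,
    detect_arrays,
    diff_arrays,
    find_repeated_spacers,
    identity_matrix,
    pairwise_identity,
    self_target_scan,
    spacer_stats,
)
from crisedit.seqio import GenomeRecord, Interval, revcomp


def _manual_array(repeat, spacers, contig="c", pad=60, rng=None):
    """Plant an array into random padding and return (genome, array_start)."""
    rng = rng or np.random.default_rng(0)
    body = repeat + "".join(s + repeat for s in spacers)
    left = "".join(rng.choice(list("ACGT"), size=pad))
    right = "".join(rng.choice(list("ACGT"), size=pad))
    return GenomeRecord(contig, left + body + right), pad, body


class TestDetectArrays:
    def test_recovers_planted_array(self, default_sim, default_arrays):
        truth = default_sim.truth["array"]
        assert len(default_arrays) == 1
        arr = default_arrays[0]
        assert arr.n_spacers == 19
        assert len(arr.repeats) == 20
        assert arr.repeat_len == 36
        assert (arr.span.start, arr.span.end) == (truth["start"], truth["end"])
        assert arr.spacers == truth["spacers"]
        assert arr.repeats == truth["repeats"]

    def test_concatenation_invariant(self, default_sim, default_arrays):
        arr = default_arrays[0]
        sub = default_sim.genome.sequence[arr.span.start : arr.span.end]
        assert arr.sequence() == sub

    def test_two_units_below_threshold(self):
        rng = np.random.default_rng(5)
        repeat = "".join(rng.choice(list("ACGT"), size=36))
        spacer = "".join(rng.choice(list("ACGT"), size=35))
        genome, _, _ = _manual_array(repeat, [spacer], rng=rng)
        assert detect_arrays(genome) == []

    def test_random_genome_is_empty_and_matches_bruteforce(self):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), size=50_000))
        genome = GenomeRecord("r", seq)
        assert detect_arrays(genome) == []
        # brute-force: no 20-mer recurs three times with spacer-like gaps
        positions = defaultdict(list)
        for i in range(len(seq) - 19):
            positions[seq[i : i + 20]].append(i)
        for poss in positions.values():
            run = 1
            for a, b in zip(poss, poss[1:]):
                run = run + 1 if 38 <= b - a <= 100 else 1
                assert run < 3

    def test_terminal_repeat_with_mismatches_still_included(self):
        sim = fixtures.simulate_genome(
            fixtures.FixtureConfig(seed=3, terminal_repeat_mismatches=2)
        )
        arrays = detect_arrays(sim.genome)
        assert len(arrays) == 1
        truth = sim.truth["array"]
        assert arrays[0].repeats == truth["repeats"]
        assert arrays[0].repeats[-1] != truth["repeat"]


class TestConsensusRepeat:
    def test_identical_repeats(self):
        arr = CrisprArray("c", Interval("c", 0, 107), ["ACGTACGTACGTACGTACGT"] * 3,
                          ["A" * 20, "C" * 20] + [], "unknown")
        assert consensus_repeat(arr) == "ACGTACGTACGTACGTACGT"

    def test_majority_column(self):
        reps = ["A" + "C" * 19, "A" + "C" * 19, "G" + "C" * 19]
        arr = CrisprArray("c", Interval("c", 0, 100), reps, ["T" * 20, "T" * 20])
        assert consensus_repeat(arr)[0] == "A"

    def test_tie_breaks_toward_A(self):
        reps = ["A" + "C" * 19, "G" + "C" * 19]
        arr = CrisprArray("c", Interval("c", 0, 60), reps, ["T" * 20])
        assert consensus_repeat(arr)[0] == "A"

    def test_recovers_planted_repeat_despite_mutated_terminal(self):
        sim = fixtures.simulate_genome(
            fixtures.FixtureConfig(seed=3, terminal_repeat_mismatches=2)
        )
        (arr,) = detect_arrays(sim.genome)
        assert consensus_repeat(arr) == sim.truth["array"]["repeat"]

    def test_unequal_lengths_raise(self):
        reps = ["A" * 20, "A" * 20, "A" * 22]
        arr = CrisprArray("c", Interval("c", 0, 100), reps, ["C" * 20, "C" * 20])
        # longer terminal is truncated, so this consensus succeeds
        assert consensus_repeat(arr) == "A" * 20
        reps = ["A" * 20, "A" * 18, "A" * 20]
        arr = CrisprArray("c", Interval("c", 0, 100), reps, ["C" * 20, "C" * 20])
        with pytest.raises(LengthError):
            consensus_repeat(arr)


class TestSpacerStats:
    def test_planted_array_row(self, default_arrays):
        df = spacer_stats(default_arrays)
        assert len(df) == 1
        assert df.loc[0, "repeat_len"] == 36
        assert df.loc[0, "n_spacers"] == 19

    def test_empty_input(self):
        assert len(spacer_stats([])) == 0

    def test_mean_matches_independent_recompute(self, default_arrays):
        df = spacer_stats(default_arrays)
        arr = default_arrays[0]
        expected = sum(len(s) for s in arr.spacers) / len(arr.spacers)
        assert df.loc[0, "mean_spacer_len"] == pytest.approx(expected)


class TestSpacerCatalog:
    def test_identical_arrays_share_profiles(self, default_arrays):
        catalog = build_spacer_catalog(
            {"gA": default_arrays, "gB": default_arrays}
        )
        assert catalog.profiles["gA"] == catalog.profiles["gB"]
        assert len(catalog.profiles["gA"][0]) == 19

    def test_duplicate_spacer_repeats_id(self):
        rng = np.random.default_rng(9)
        repeat = "".join(rng.choice(list("ACGT"), size=36))
        s1 = "".join(rng.choice(list("ACGT"), size=35))
        s2 = "".join(rng.choice(list("ACGT"), size=35))
        genome, pad, body = _manual_array(repeat, [s1, s2, s1], rng=rng)
        arr = CrisprArray(
            "c", Interval("c", pad, pad + len(body)), [repeat] * 4, [s1, s2, s1],
            "leader-first",
        )
        catalog = build_spacer_catalog({"g": [arr]})
        profile = catalog.profiles["g"][0]
        assert profile[0] == profile[2] and profile[0] != profile[1]

    def test_id_map_is_bijective_on_random_spacers(self):
        rng = np.random.default_rng(13)
        arrays = []
        for i in range(10):
            spacers = ["".join(rng.choice(list("ACGT"), size=35)) for _ in range(20)]
            repeat = "".join(rng.choice(list("ACGT"), size=36))
            arrays.append(
                CrisprArray("c", Interval("c", 1, 2), [repeat] * 21, spacers,
                            "leader-first")
            )
        catalog = build_spacer_catalog({f"g{i}": [a] for i, a in enumerate(arrays)})
        inverted = catalog.id_to_seq
        assert len(inverted) == len(catalog.seq_to_id)
        for seq, sid in catalog.seq_to_id.items():
            assert inverted[sid] == seq

    def test_rerun_is_deterministic(self, default_arrays):
        c1 = build_spacer_catalog({"g": default_arrays})
        c2 = build_spacer_catalog({"g": default_arrays})
        assert c1.seq_to_id == c2.seq_to_id and c1.profiles == c2.profiles


class TestRepeatedSpacers:
    def _catalog(self, spacers):
        repeat = "G" * 36
        arr = CrisprArray(
            "c", Interval("c", 1, 2), [repeat] * (len(spacers) + 1), list(spacers),
            "leader-first",
        )
        return build_spacer_catalog({"g": [arr]})

    def test_distal_difference_groups_together(self):
        base = "ACGTACGTACGTACGTACGT"
        distal = base[:19] + "C"  # differs at position 20 only
        groups = find_repeated_spacers(self._catalog([base, distal, "T" * 20]))
        assert len(groups) == 1
        assert {p[2] for p in groups[0].positions} == {0, 1}

    def test_seed_difference_separates(self):
        base = "ACGTACGTACGTACGTACGT"
        seed_variant = base[:2] + "T" + base[3:]  # position 3 is in the seed
        groups = find_repeated_spacers(self._catalog([base, seed_variant]))
        assert groups == []

    def test_matches_transitive_closure_oracle(self):
        rng = np.random.default_rng(21)
        pool = ["".join(rng.choice(list("ACGT"), size=20)) for _ in range(6)]
        spacers = [pool[int(i)] for i in rng.integers(0, 6, size=8)]
        spacers += [pool[0][:15] + "TTTTT", pool[1][:8] + "A" * 12]  # distal variants
        spacers = spacers[:12]
        groups = find_repeated_spacers(self._catalog(spacers))

        def related(a, b):
            return len(a) == len(b) and a[:8] == b[:8]

        # brute-force transitive closure over pairwise relatedness
        parent = list(range(len(spacers)))

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for i, j in itertools.combinations(range(len(spacers)), 2):
            if related(spacers[i], spacers[j]):
                parent[find(i)] = find(j)
        closure = defaultdict(set)
        for i in range(len(spacers)):
            closure[find(i)].add(i)
        expected = sorted(
            tuple(sorted(v)) for v in closure.values() if len(v) > 1
        )
        got = sorted(tuple(sorted(p[2] for p in g.positions)) for g in groups)
        assert got == expected


class TestSelfTargetScan:
    def test_clean_genome_has_no_hits(self, default_sim, default_arrays):
        assert self_target_scan(default_arrays[0], default_sim.genome) == []

    def test_planted_copy_with_pam_is_reported(self, default_sim, default_arrays):
        arr = default_arrays[0]
        spacer = arr.spacers[4]
        genome, entry = fixtures.plant_offtarget(
            default_sim.genome, spacer, None, True, position=50_000
        )
        hits = self_target_scan(arr, genome)
        assert len(hits) == 1
        hit = hits[0]
        assert hit.spacer_index == 4
        assert hit.pam_found
        assert hit.interval.start == entry["protospacer_start"]
        assert hit.mismatch_positions == []

    def test_hits_match_bruteforce_sliding_window(self, default_arrays):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), size=4000))
        arr = default_arrays[0]
        spacer = arr.spacers[0]
        # plant one copy per strand
        seq = seq[:1000] + "TAT" + spacer + seq[1000 + 38 :]
        seq = seq[:2000] + revcomp("TAT" + spacer) + seq[2000 + 38 :]
        genome = GenomeRecord("chr", seq)
        hits = self_target_scan(arr, genome)
        L = len(spacer)
        expected = []
        for i in range(len(seq) - L + 1):
            if seq[i : i + L] == spacer:
                expected.append((i, "+"))
            if revcomp(seq[i : i + L]) == spacer:
                expected.append((i, "-"))
        assert sorted((h.interval.start, h.strand) for h in hits) == sorted(expected)
        assert all(h.pam_found for h in hits)

    def test_never_reports_inside_array_span(self, default_sim, default_arrays):
        arr = default_arrays[0]
        for hit in self_target_scan(arr, default_sim.genome, max_mismatches=3):
            assert not hit.interval.overlaps(arr.span)


def _bruteforce_lcs_len(a, b):
    best = 0
    for r in range(len(a), 0, -1):
        for combo in itertools.combinations(range(len(a)), r):
            sub = [a[i] for i in combo]
            it = iter(b)
            if all(x in it for x in sub):
                return r
    return best


class TestDiffArrays:
    def test_three_mid_array_insertions(self):
        a = list(range(1, 20))
        b = a[:10] + [100, 101, 102] + a[10:]
        diff = diff_arrays(a, b)
        assert diff.summary == {
            "shared": 19, "insertions": 3, "deletions": 0, "duplicated_ids": 0
        }
        assert [x for _, x in diff.insertions_in_B] == [100, 101, 102]
        assert apply_diff(b, diff) == a

    def test_identical_profiles_empty_diff(self):
        a = [1, 2, 3, 4]
        diff = diff_arrays(a, list(a))
        assert diff.insertions_in_B == [] and diff.deletions_from_A == []
        assert apply_diff(a, diff) == a

    def test_duplications_flagged(self):
        diff = diff_arrays([1, 2, 3], [1, 2, 2, 3])
        assert diff.duplicated_ids == [2]

    def test_counts_match_exhaustive_lcs_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            la, lb = int(rng.integers(1, 9)), int(rng.integers(1, 9))
            a = [int(x) for x in rng.integers(1, 5, size=la)]
            b = [int(x) for x in rng.integers(1, 5, size=lb)]
            diff = diff_arrays(a, b)
            lcs = _bruteforce_lcs_len(a, b)
            assert len(diff.shared) == lcs
            assert len(diff.deletions_from_A) == la - lcs
            assert len(diff.insertions_in_B) == lb - lcs
            assert apply_diff(b, diff) == a


class TestDedupeProteins:
    def test_copies_collapse(self):
        seqs = {f"p{i}": "MKV" for i in range(5)}
        seqs["q"] = "MKA"
        clusters = dedupe_proteins(seqs)
        assert [len(c.members) for c in clusters] == [5, 1]
        assert clusters[0].representative == "p0"

    def test_empty_input(self):
        assert dedupe_proteins({}) == []

    def test_bad_residue_rejected(self):
        with pytest.raises(AlphabetError):
            dedupe_proteins({"p": "MK1"})

    def test_partition_matches_hash_grouping_oracle(self):
        rng = np.random.default_rng(23)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        names, seqs = [], {}
        pool = ["".join(rng.choice(aa, size=12)) for _ in range(60)]
        for i in range(500):
            seqs[f"s{i}"] = pool[int(rng.integers(0, 60))]
        clusters = dedupe_proteins(seqs)
        expected = defaultdict(list)
        for name, seq in seqs.items():
            expected[seq].append(name)
        assert len(clusters) == len(expected)
        for c in clusters:
            assert c.members == expected[c.sequence]


def _enumerate_alignment_stats(a, b):
    """All global alignments as (score, matches, columns) tuples."""
    out = []

    def rec(i, j, score, matches, columns):
        if i == len(a) and j == len(b):
            out.append((score, matches, columns))
            return
        if i < len(a) and j < len(b):
            hit = a[i] == b[j]
            rec(i + 1, j + 1, score + (1 if hit else 0), matches + hit, columns + 1)
        if i < len(a):
            rec(i + 1, j, score - 1, matches, columns + 1)
        if j < len(b):
            rec(i, j + 1, score - 1, matches, columns + 1)

    rec(0, 0, 0, 0, 0)
    return out


class TestPairwiseIdentity:
    def test_identical_is_100(self):
        assert pairwise_identity("MKVLA", "MKVLA") == 100.0

    def test_three_quarters(self):
        assert pairwise_identity("AAAA", "AATA") == 75.0

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(29)
        for _ in range(30):
            a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 12))))
            b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 12))))
            x = pairwise_identity(a, b)
            assert x == pairwise_identity(b, a)
            assert 0.0 <= x <= 100.0
            assert (x == 100.0) == (a == b)

    def test_matches_exhaustive_alignment_enumeration(self):
        rng = np.random.default_rng(31)
        for _ in range(25):
            a = "".join(rng.choice(list("AC"), size=int(rng.integers(1, 7))))
            b = "".join(rng.choice(list("AC"), size=int(rng.integers(1, 7))))
            stats = _enumerate_alignment_stats(a, b)
            best = max(stats, key=lambda t: (t[0], t[1], -t[2]))
            expected = 100.0 * best[1] / best[2]
            assert pairwise_identity(a, b) == pytest.approx(expected)

    def test_identity_matrix_symmetric(self):
        seqs = {"a": "MKVL", "b": "MKVA", "c": "MML"}
        mat = identity_matrix(seqs)
        assert (mat.values == mat.values.T).all()
        assert (mat.values.diagonal() == 100.0).all()
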