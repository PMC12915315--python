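"""CRISPR array detection and comparative locus analytics.

Detection is a deterministic CRT-style exact-repeat finder: identical k-mer
anchors (k = 20) recurring with spacer-compatible gaps are extended to the
maximal common repeat; internal repeats must be exactly identical while a
terminal repeat may carry a bounded number of substitutions. This is adequate
for small and synthetic genomes where planted repeats are the only long exact
duplications; it does not attempt the degenerate-repeat recovery of dedicated
genome-mining tools.

The module also builds cross-genome spacer catalogs (identical sequences
share one integer spacer ID), diffs array profiles by longest common
subsequence, scans spacers against their source genome for self-targeting,
collapses protein sequences at 100% identity, and computes global-alignment
percent identity.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import guide_design
from .errors import AlphabetError, LengthError
from .seqio import GenomeRecord, Interval, canonical, revcomp

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class CrisprArray:
    """An ordered repeat-spacer array located on a contig.

    Invariant: ``len(repeats) == len(spacers) + 1`` and the interleaved
    concatenation repeat0 + spacer0 + repeat1 + ... equals the genome
    substring of ``span``. ``orientation`` is ``leader-first`` when the
    spacer list reads from the leader-proximal end, ``leader-last`` for the
    opposite, else ``unknown`` (detection alone cannot orient an array).
    """

    contig_id: str
    span: Interval
    repeats: list[str]
    spacers: list[str]
    orientation: str = "unknown"

    def __post_init__(self) -> None:
        if len(self.repeats) != len(self.spacers) + 1:
            raise ValueError("need exactly one more repeat than spacers")

    @property
    def n_spacers(self) -> int:
        return len(self.spacers)

    @property
    def repeat_len(self) -> int:
        return len(self.repeats[0])

    def oriented_spacers(self) -> list[str]:
        """Spacers read leader -> trailer (as stored unless leader-last)."""
        if self.orientation == "leader-last":
            return [revcomp(s) for s in reversed(self.spacers)]
        return list(self.spacers)

    def sequence(self) -> str:
        parts = []
        for i, rep in enumerate(self.repeats):
            parts.append(rep)
            if i < len(self.spacers):
                parts.append(self.spacers[i])
        return "".join(parts)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _extend_run(seq, run, k, rmin, rmax, smin, smax):
    """Extend anchor positions to the maximal exactly-shared repeat."""
    gaps = [b - a for a, b in zip(run, run[1:])]
    max_len = min(rmax, min(gaps) - smin)
    if max_len < max(k, rmin):
        return None
    left = 0
    while (
        run[0] - left - 1 >= 0
        and k + left < max_len
        and len({seq[p - left - 1] for p in run}) == 1
    ):
        left += 1
    right = 0
    while (
        run[-1] + k + right < len(seq)
        and k + left + right < max_len
        and len({seq[p + k + right] for p in run}) == 1
    ):
        right += 1
    replen = k + left + right
    if replen < rmin:
        return None
    starts = [p - left for p in run]
    for a, b in zip(starts, starts[1:]):
        spacer = b - a - replen
        if not (smin <= spacer <= smax):
            return None
    return starts, replen


def _grow_terminals(seq, starts, replen, smin, smax, max_mm):
    """Append repeats beyond the exact core: exact extensions freely, and at
    most one substitution-carrying terminal repeat per end."""
    repeat = seq[starts[0] : starts[0] + replen]
    for side in ("left", "right"):
        while True:
            best = None
            for g in range(smin, smax + 1):
                c = (starts[0] - g - replen) if side == "left" else (starts[-1] + replen + g)
                if c < 0 or c + replen > len(seq):
                    continue
                mm = _hamming(seq[c : c + replen], repeat)
                if mm <= max_mm and (best is None or (mm, g) < best[:2]):
                    best = (mm, g, c)
            if best is None:
                break
            mm, _, c = best
            starts.insert(0, c) if side == "left" else starts.append(c)
            if mm > 0:
                break  # only the outermost repeat may be degenerate
    return starts


def detect_arrays(
    genome: GenomeRecord,
    min_units: int = 3,
    repeat_len: tuple[int, int] = (20, 50),
    spacer_len: tuple[int, int] = (18, 50),
    max_terminal_repeat_mismatches: int = 2,
    anchor_k: int = 20,
) -> list[CrisprArray]:
    """Detect maximal non-overlapping CRISPR arrays on the plus strand.

    Returns arrays sorted by start coordinate; an empty list when none pass
    the ``min_units`` threshold (units = repeats).
    """
    seq = genome.sequence
    n = len(seq)
    rmin, rmax = repeat_len
    smin, smax = spacer_len
    k = min(anchor_k, rmin)
    if n < k:
        return []
    gap_min, gap_max = rmin + smin, rmax + smax
    anchors: dict[str, list[int]] = defaultdict(list)
    for i in range(n - k + 1):
        anchors[seq[i : i + k]].append(i)

    found: dict[tuple[int, int], CrisprArray] = {}
    for positions in anchors.values():
        if len(positions) < 2:
            continue
        run = [positions[0]]
        runs = []
        for p in positions[1:]:
            if gap_min <= p - run[-1] <= gap_max:
                run.append(p)
            else:
                runs.append(run)
                run = [p]
        runs.append(run)
        for run in runs:
            if len(run) < 2:
                continue
            ext = _extend_run(seq, run, k, rmin, rmax, smin, smax)
            if ext is None:
                continue
            starts, replen = ext
            starts = _grow_terminals(
                seq, starts, replen, smin, smax, max_terminal_repeat_mismatches
            )
            if len(starts) < min_units:
                continue
            span = (starts[0], starts[-1] + replen)
            if span in found:
                continue
            repeats = [seq[s : s + replen] for s in starts]
            spacers = [seq[a + replen : b] for a, b in zip(starts, starts[1:])]
            found[span] = CrisprArray(
                genome.contig_id,
                Interval(genome.contig_id, span[0], span[1]),
                repeats,
                spacers,
            )

    # keep maximal arrays, dropping any overlapped by a larger one
    ranked = sorted(
        found.values(),
        key=lambda a: (-len(a.repeats), -(a.span.end - a.span.start), a.span.start),
    )
    kept: list[CrisprArray] = []
    for arr in ranked:
        if not any(arr.span.overlaps(other.span) for other in kept):
            kept.append(arr)
    kept.sort(key=lambda a: (a.contig_id, a.span.start))
    return kept


def consensus_repeat(array: CrisprArray) -> str:
    """Per-column majority base across all repeats; ties break A < C < G < T.

    Terminal repeats longer than the internal length are truncated before the
    column vote; any remaining length disagreement raises LengthError.
    """
    reps = list(array.repeats)
    if not reps:
        raise ValueError("array has no repeats")
    lengths = sorted(len(r) for r in reps)
    internal = lengths[len(lengths) // 2]
    reps = [r[:internal] if len(r) > internal else r for r in reps]
    if any(len(r) != internal for r in reps):
        raise LengthError("repeats of unequal length after terminal truncation")
    out = []
    for col in zip(*reps):
        counts = Counter(col)
        out.append(max("ACGTN", key=lambda b: (counts.get(b, 0), -ord(b))))
    return "".join(out)


def spacer_stats(arrays: Sequence[CrisprArray]) -> pd.DataFrame:
    """One row per array: spacer count, mean spacer length, repeat length.

    Deterministically ordered by contig then start.
    """
    rows = [
        {
            "contig_id": a.contig_id,
            "start": a.span.start,
            "end": a.span.end,
            "n_spacers": a.n_spacers,
            "mean_spacer_len": (
                sum(len(s) for s in a.spacers) / a.n_spacers if a.n_spacers else 0.0
            ),
            "repeat_len": a.repeat_len,
        }
        for a in arrays
    ]
    df = pd.DataFrame(
        rows,
        columns=["contig_id", "start", "end", "n_spacers", "mean_spacer_len", "repeat_len"],
    )
    return df.sort_values(["contig_id", "start"]).reset_index(drop=True)


@dataclass
class SpacerCatalog:
    """Bijective map between distinct spacer sequences (canonical
    orientation) and integer IDs, plus ordered per-genome array profiles."""

    seq_to_id: dict[str, int]
    profiles: dict[str, list[list[int]]]

    @property
    def id_to_seq(self) -> dict[int, str]:
        return {v: k for k, v in self.seq_to_id.items()}


def _catalog_key(spacer: str, orientation: str) -> str:
    # leader-aware orientation keeps the PAM-proximal end at position 1;
    # unknown orientation falls back to the lexicographic canonical form
    return spacer if orientation in ("leader-first", "leader-last") else canonical(spacer)


def build_spacer_catalog(
    genome_arrays: Mapping[str, Sequence[CrisprArray]],
) -> SpacerCatalog:
    """Assign spacer IDs in first-seen order across genomes; identical
    sequences in different genomes share one ID."""
    seq_to_id: dict[str, int] = {}
    profiles: dict[str, list[list[int]]] = {}
    for genome_id, arrays in genome_arrays.items():
        genome_profiles = []
        for array in arrays:
            profile = []
            for spacer in array.oriented_spacers():
                key = _catalog_key(spacer, array.orientation)
                if key not in seq_to_id:
                    seq_to_id[key] = len(seq_to_id) + 1
                profile.append(seq_to_id[key])
            genome_profiles.append(profile)
        profiles[genome_id] = genome_profiles
    return SpacerCatalog(seq_to_id, profiles)


@dataclass
class RepeatedSpacerGroup:
    """Positions (genome, array index, spacer index) whose spacers are
    identical or differ only outside the PAM-proximal seed."""

    spacer_ids: list[int]
    positions: list[tuple[str, int, int]]


def find_repeated_spacers(
    catalog: SpacerCatalog, seed_len: int = guide_design.DEFAULT_SEED_LEN
) -> list[RepeatedSpacerGroup]:
    """Group catalog positions by functional equivalence: equal length and an
    identical seed (positions 1..seed_len). A mismatch inside the seed makes
    spacers functionally distinct; mismatches outside it do not."""
    id_to_seq = catalog.id_to_seq
    groups: dict[tuple[int, str], RepeatedSpacerGroup] = {}
    for genome_id, genome_profiles in catalog.profiles.items():
        for array_idx, profile in enumerate(genome_profiles):
            for pos, sid in enumerate(profile):
                seq = id_to_seq[sid]
                key = (len(seq), seq[:seed_len])
                grp = groups.setdefault(key, RepeatedSpacerGroup([], []))
                if sid not in grp.spacer_ids:
                    grp.spacer_ids.append(sid)
                grp.positions.append((genome_id, array_idx, pos))
    return [g for g in groups.values() if len(g.positions) > 1]


@dataclass
class SelfTargetHit:
    """A spacer match in its source genome outside the array span."""

    spacer_index: int
    interval: Interval
    strand: str
    pam_found: bool
    mismatch_positions: list[int]


def self_target_scan(
    array: CrisprArray,
    genome: GenomeRecord,
    pam: str = guide_design.DEFAULT_PAM,
    max_mismatches: int = 0,
) -> list[SelfTargetHit]:
    """Query every spacer against the source genome, both strands, excluding
    the array span; hits are annotated with 5' PAM presence on the hit
    strand."""
    hits: list[SelfTargetHit] = []
    for idx, spacer in enumerate(array.oriented_spacers()):
        for h in guide_design.off_target_hits(
            spacer,
            genome,
            pam=pam,
            max_total_mismatches=max_mismatches,
            exclude=array.span,
        ):
            if len(h.mismatch_positions) > max_mismatches:
                continue  # seed-perfect PAM sites beyond the mismatch budget
            hits.append(
                SelfTargetHit(idx, h.interval, h.strand, h.pam_found, h.mismatch_positions)
            )
    hits.sort(key=lambda h: (h.spacer_index, h.interval.start, h.strand))
    return hits


@dataclass
class ArrayDiff:
    """LCS-based comparison of two spacer-ID profiles."""

    shared: list[tuple[int, int]]  # aligned (index in A, index in B)
    insertions_in_B: list[tuple[int, int]]  # (position in B, id)
    deletions_from_A: list[tuple[int, int]]  # (position in A, id)
    duplicated_ids: list[int]

    @property
    def summary(self) -> dict[str, int]:
        return {
            "shared": len(self.shared),
            "insertions": len(self.insertions_in_B),
            "deletions": len(self.deletions_from_A),
            "duplicated_ids": len(self.duplicated_ids),
        }


def diff_arrays(profile_a: Sequence[int], profile_b: Sequence[int]) -> ArrayDiff:
    """Align two ID profiles by longest common subsequence.

    B-only IDs are insertions (B position recorded), A-only IDs deletions;
    IDs occurring more than once in either profile are flagged duplicated.
    LCS traceback ties break toward the leftmost match in A.
    """
    if not profile_a or not profile_b:
        raise ValueError("profiles must be nonempty")
    a, b = list(profile_a), list(profile_b)
    n, m = len(a), len(b)
    lcs = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            lcs[i][j] = (
                1 + lcs[i + 1][j + 1]
                if a[i] == b[j]
                else max(lcs[i + 1][j], lcs[i][j + 1])
            )
    shared: list[tuple[int, int]] = []
    i = j = 0
    while i < n and j < m:
        if a[i] == b[j] and lcs[i][j] == 1 + lcs[i + 1][j + 1]:
            shared.append((i, j))
            i += 1
            j += 1
        elif lcs[i][j + 1] == lcs[i][j]:
            j += 1  # keep scanning B for a match of a[i] (leftmost in A)
        else:
            i += 1
    matched_a = {ia for ia, _ in shared}
    matched_b = {jb for _, jb in shared}
    deletions = [(ia, a[ia]) for ia in range(n) if ia not in matched_a]
    insertions = [(jb, b[jb]) for jb in range(m) if jb not in matched_b]
    dup = sorted(
        {x for x, c in Counter(a).items() if c > 1}
        | {x for x, c in Counter(b).items() if c > 1}
    )
    return ArrayDiff(shared, insertions, deletions, dup)


def apply_diff(profile_b: Sequence[int], diff: ArrayDiff) -> list[int]:
    """Reconstruct profile A from B: remove the insertions, re-add the
    deletions at their A positions (the ArrayDiff round-trip invariant)."""
    core = [x for j, x in enumerate(profile_b) if j not in {p for p, _ in diff.insertions_in_B}]
    out = list(core)
    for pos, val in sorted(diff.deletions_from_A):
        out.insert(pos, val)
    return out


@dataclass
class ProteinCluster:
    """All members share one exact sequence (100% identity, equal length)."""

    cluster_id: int
    members: list[str]
    representative: str
    sequence: str


def dedupe_proteins(seqs: Mapping[str, str]) -> list[ProteinCluster]:
    """Partition protein sequences by exact identity.

    The representative is the first-seen member; clusters are numbered in
    first-seen order.
    """
    clusters: dict[str, ProteinCluster] = {}
    for name, seq in seqs.items():
        bad = set(seq) - AA_ALPHABET
        if bad:
            raise AlphabetError(
                f"protein {name!r} has characters outside the amino-acid "
                f"alphabet: {sorted(bad)!r}"
            )
        if seq not in clusters:
            clusters[seq] = ProteinCluster(len(clusters) + 1, [], name, seq)
        clusters[seq].members.append(name)
    return list(clusters.values())


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment percent identity (match +1, mismatch 0, linear gap
    -1, end gaps penalized); identity = matches / alignment columns x 100.

    Among score-optimal alignments the one with the most matches, then the
    fewest columns, defines the reported identity; this makes the value
    symmetric in its arguments. O(len_a x len_b) time and memory.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be nonempty")
    n, m = len(seq_a), len(seq_b)
    # DP over (score, matches, -columns), compared lexicographically
    prev = [(0, 0, 0)] * (m + 1)
    for j in range(1, m + 1):
        s, mt, c = prev[j - 1]
        prev[j] = (s - 1, mt, c - 1)
    for i in range(1, n + 1):
        cur = [(0, 0, 0)] * (m + 1)
        s, mt, c = prev[0]
        cur[0] = (s - 1, mt, c - 1)
        ai = seq_a[i - 1]
        for j in range(1, m + 1):
            hit = 1 if ai == seq_b[j - 1] else 0
            ds, dm, dc = prev[j - 1]
            us, um, uc = prev[j]
            ls, lm, lc = cur[j - 1]
            cur[j] = max(
                (ds + hit, dm + hit, dc - 1),
                (us - 1, um, uc - 1),
                (ls - 1, lm, lc - 1),
            )
        prev = cur
    _, matches, neg_columns = prev[m]
    return 100.0 * matches / (-neg_columns)


def identity_matrix(seqs: Mapping[str, str]) -> pd.DataFrame:
    """Symmetric pairwise-identity matrix over named sequences."""
    names = list(seqs)
    mat = pd.DataFrame(100.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            val = pairwise_identity(seqs[a], seqs[b])
            mat.loc[a, b] = mat.loc[b, a] = val
    return mat
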