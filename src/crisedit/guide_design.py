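"""Protospacer discovery and spacer panel selection for a Type I-G system.

The system recognizes a short 5'-PAM (default ``TAT``) and targets the
fixed-length protospacer immediately 3' of it; the crRNA spacer equals the
protospacer read 5'->3' on the PAM strand. Interference requires a perfect
match across the PAM-proximal seed (positions 1..seed_len, position 1 being
the base adjacent to the PAM), so off-target sites are classified BLOCKING
when they retain the PAM and a perfect seed, regardless of distal mismatches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

from ._scan import encode, window_mismatch_counts
from .errors import EmptyWindowWarning, InsufficientCandidates, LengthError
from .seqio import GeneFeature, GenomeRecord, Interval, check_dna, revcomp

DEFAULT_PAM = "TAT"
DEFAULT_SPACER_LEN = 35
DEFAULT_SEED_LEN = 8
DEFAULT_MAX_MISMATCHES = 5


@dataclass
class PamSite:
    """A PAM occurrence. ``start`` is the leftmost genomic offset of the
    motif; ``pam_seq`` is the motif read 5'->3' on ``strand``."""

    contig_id: str
    start: int
    strand: str
    pam_seq: str

    def protospacer_interval(self, spacer_len: int = DEFAULT_SPACER_LEN) -> Interval:
        """Genomic interval of the protospacer immediately 3' of the PAM on
        its strand (plus-strand coordinates, strand recorded)."""
        m = len(self.pam_seq)
        if self.strand == "+":
            return Interval(self.contig_id, self.start + m, self.start + m + spacer_len, "+")
        return Interval(self.contig_id, self.start - spacer_len, self.start, "-")

    def footprint(self, spacer_len: int = DEFAULT_SPACER_LEN) -> Interval:
        """PAM plus protospacer as one plus-strand interval."""
        proto = self.protospacer_interval(spacer_len)
        m = len(self.pam_seq)
        if self.strand == "+":
            return Interval(self.contig_id, self.start, proto.end, "+")
        return Interval(self.contig_id, proto.start, self.start + m, "-")


@dataclass
class OffTargetHit:
    """A genomic near-match of a spacer. ``mismatch_positions`` are 1-based
    PAM-proximal positions on the hit strand."""

    interval: Interval
    strand: str
    pam_found: bool
    mismatch_positions: list[int]
    seed_mismatches: int
    blocking: bool


@dataclass
class GuideCandidate:
    """A designable spacer: sequence, PAM site, genomic protospacer, strand
    relative to the gene, and (after screening) its off-target hits."""

    spacer_seq: str
    pam: PamSite
    protospacer: Interval
    target_strand: str
    offset_in_gene: int
    name: str = ""
    off_targets: list[OffTargetHit] = field(default_factory=list)

    @property
    def blocking_hits(self) -> list[OffTargetHit]:
        return [h for h in self.off_targets if h.blocking]


def scan_pam_sites(
    genome: GenomeRecord,
    region: Interval,
    pam: str = DEFAULT_PAM,
    spacer_len: int = DEFAULT_SPACER_LEN,
) -> list[PamSite]:
    """All PAM occurrences in ``region`` on both strands for which a full
    downstream protospacer fits within the contig, sorted by position then
    strand."""
    check_dna(pam, "PAM")
    seq = genome.sequence
    n = len(seq)
    m = len(pam)
    lo = max(region.start, 0)
    hi = min(region.end, n)
    rc_pam = revcomp(pam)
    sites: list[PamSite] = []
    for i in range(lo, hi - m + 1):
        triplet = seq[i : i + m]
        if triplet == pam and i + m + spacer_len <= n:
            sites.append(PamSite(genome.contig_id, i, "+", pam))
        if triplet == rc_pam and i - spacer_len >= 0:
            sites.append(PamSite(genome.contig_id, i, "-", pam))
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def extract_candidates(
    genome: GenomeRecord,
    gene: GeneFeature,
    window: Interval,
    spacer_len: int = DEFAULT_SPACER_LEN,
    pam: str = DEFAULT_PAM,
) -> list[GuideCandidate]:
    """One candidate per PAM site whose protospacer lies wholly inside
    ``window``; target_strand is ``coding`` when the protospacer is on the
    gene's sense strand, else ``template``."""
    if len(window) < spacer_len + len(pam):
        warnings.warn(
            f"window [{window.start}, {window.end}) smaller than "
            f"spacer_len + PAM ({spacer_len + len(pam)} bp)",
            EmptyWindowWarning,
        )
        return []
    # the PAM itself may sit just outside the window
    pad = len(pam)
    region = Interval(
        window.contig_id, max(0, window.start - pad), min(len(genome), window.end + pad)
    )
    candidates: list[GuideCandidate] = []
    for site in scan_pam_sites(genome, region, pam, spacer_len):
        proto = site.protospacer_interval(spacer_len)
        if proto.start < window.start or proto.end > window.end:
            continue
        spacer_seq = (
            genome.sequence[proto.start : proto.end]
            if site.strand == "+"
            else revcomp(genome.sequence[proto.start : proto.end])
        )
        target_strand = "coding" if site.strand == gene.strand else "template"
        # gene-oriented offset of the PAM-proximal protospacer base
        proximal = proto.start if site.strand == "+" else proto.end - 1
        offset = (
            proximal - gene.start if gene.strand == "+" else (gene.end - 1) - proximal
        )
        candidates.append(
            GuideCandidate(
                spacer_seq=spacer_seq,
                pam=site,
                protospacer=proto,
                target_strand=target_strand,
                offset_in_gene=offset,
                name=f"{gene.gene_id}:{offset:+d}{site.strand}",
            )
        )
    return candidates


def _strand_hit_indices(
    arr: np.ndarray,
    query: np.ndarray,
    pam_arr: np.ndarray,
    seed_len: int,
    max_total_mismatches: Optional[int],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Window starts to report on one strand, with total-mismatch vector and
    PAM-presence mask. A window is reported when its total mismatch count is
    within ``max_total_mismatches`` (if given) or when it carries a PAM and a
    perfect seed (potentially blocking, regardless of distal mismatches)."""
    total = window_mismatch_counts(arr, query)
    nwin = total.size
    seed = window_mismatch_counts(arr, query[:seed_len])[:nwin]
    m = pam_arr.size
    pam_hits = window_mismatch_counts(arr, pam_arr) == 0
    pam_ok = np.zeros(nwin, dtype=bool)
    # PAM occupies the m bases 5' of the protospacer: window start i needs a
    # PAM match starting at i - m
    if nwin > m:
        pam_ok[m:] = pam_hits[: nwin - m]
    candidate = (seed == 0) & pam_ok
    if max_total_mismatches is not None:
        candidate |= total <= max_total_mismatches
    return np.flatnonzero(candidate), total, pam_ok


def off_target_hits(
    spacer_seq: str,
    genome: GenomeRecord,
    pam: str = DEFAULT_PAM,
    seed_len: int = DEFAULT_SEED_LEN,
    max_total_mismatches: Optional[int] = DEFAULT_MAX_MISMATCHES,
    exclude: Optional[Interval] = None,
) -> list[OffTargetHit]:
    """Genome-wide near-matches of a spacer on both strands.

    Reports every window outside ``exclude`` with at most
    ``max_total_mismatches`` mismatches, plus any window carrying the PAM
    with a perfect seed (flagged ``blocking``) whatever its distal mismatch
    count. Mismatch positions are 1-based from the PAM-proximal end.
    """
    check_dna(spacer_seq, "spacer")
    L = len(spacer_seq)
    seq = genome.sequence
    n = len(seq)
    q = encode(spacer_seq)
    p = encode(pam)
    hits: list[OffTargetHit] = []

    def build(start: int, strand: str, window: str, pam_found: bool) -> OffTargetHit:
        mismatches = [i + 1 for i in range(L) if window[i] != spacer_seq[i]]
        seed_mm = sum(1 for pos in mismatches if pos <= seed_len)
        return OffTargetHit(
            interval=Interval(genome.contig_id, start, start + L),
            strand=strand,
            pam_found=pam_found,
            mismatch_positions=mismatches,
            seed_mismatches=seed_mm,
            blocking=pam_found and seed_mm == 0,
        )

    # plus strand
    idx, _, pam_ok = _strand_hit_indices(encode(seq), q, p, seed_len, max_total_mismatches)
    for i in idx:
        i = int(i)
        iv = Interval(genome.contig_id, i, i + L)
        if exclude is not None and iv.overlaps(exclude):
            continue
        hits.append(build(i, "+", seq[i : i + L], bool(pam_ok[i])))
    # minus strand: scan the reverse complement; window j there starts at
    # genomic coordinate n - L - j
    rc = revcomp(seq)
    idx, _, pam_ok = _strand_hit_indices(encode(rc), q, p, seed_len, max_total_mismatches)
    for j in idx:
        j = int(j)
        start = n - L - j
        iv = Interval(genome.contig_id, start, start + L)
        if exclude is not None and iv.overlaps(exclude):
            continue
        hits.append(build(start, "-", rc[j : j + L], bool(pam_ok[j])))
    hits.sort(key=lambda h: (h.interval.start, h.strand))
    return hits


def seed_equivalent(
    spacer_a: str, spacer_b: str, seed_len: int = DEFAULT_SEED_LEN
) -> str:
    """Classify two equal-length spacers as ``distinct`` (any mismatch within
    seed positions 1..seed_len) or ``equivalent`` (mismatches, if any, all
    PAM-distal)."""
    if len(spacer_a) != len(spacer_b):
        raise LengthError(
            f"spacer lengths differ: {len(spacer_a)} vs {len(spacer_b)}"
        )
    for pos in range(min(seed_len, len(spacer_a))):
        if spacer_a[pos] != spacer_b[pos]:
            return "distinct"
    return "equivalent"


def screen_candidates(
    candidates: Sequence[GuideCandidate],
    genome: GenomeRecord,
    pam: str = DEFAULT_PAM,
    seed_len: int = DEFAULT_SEED_LEN,
    max_total_mismatches: Optional[int] = DEFAULT_MAX_MISMATCHES,
) -> list[GuideCandidate]:
    """Fill ``off_targets`` for each candidate, excluding its own on-target
    site from the scan."""
    for cand in candidates:
        cand.off_targets = off_target_hits(
            cand.spacer_seq,
            genome,
            pam=pam,
            seed_len=seed_len,
            max_total_mismatches=max_total_mismatches,
            exclude=cand.protospacer,
        )
    return list(candidates)


def select_spacers(
    candidates: Sequence[GuideCandidate],
    k: int = 3,
    require_no_blocking: bool = True,
) -> list[GuideCandidate]:
    """Choose ``k`` spacers maximizing pairwise genomic separation.

    Candidates with blocking off-target hits are excluded when
    ``require_no_blocking``. The choice is invariant to input order: ties are
    broken toward the combination with the smallest genomic positions.
    """
    reasons: dict[str, str] = {}
    admissible: list[GuideCandidate] = []
    for cand in candidates:
        if require_no_blocking and cand.blocking_hits:
            h = cand.blocking_hits[0]
            reasons[cand.name or cand.spacer_seq] = (
                f"blocking off-target at {h.interval.start} ({h.strand})"
            )
        else:
            admissible.append(cand)
    if len(admissible) < k:
        raise InsufficientCandidates(k, len(admissible), reasons)
    admissible.sort(key=lambda c: (c.protospacer.start, c.pam.strand))
    if len(admissible) == k:
        return admissible

    def positions(combo):
        return tuple(c.protospacer.start for c in combo)

    def spread(combo):
        pos = positions(combo)
        gaps = [b - a for a, b in combinations(pos, 2)]
        return (min(gaps), sum(gaps))

    n = len(admissible)
    n_combos = 1
    for i in range(k):
        n_combos = n_combos * (n - i) // (i + 1)
    if n_combos <= 20000:
        best = min(
            combinations(admissible, k),
            key=lambda combo: (
                -spread(combo)[0],
                -spread(combo)[1],
                positions(combo),
            ),
        )
        return list(best)
    # large candidate sets: deterministic farthest-point greedy
    chosen = [admissible[0], admissible[-1]]
    while len(chosen) < k:
        rest = [c for c in admissible if c not in chosen]
        nxt = max(
            rest,
            key=lambda c: (
                min(abs(c.protospacer.start - d.protospacer.start) for d in chosen),
                -c.protospacer.start,
            ),
        )
        chosen.append(nxt)
    chosen.sort(key=lambda c: c.protospacer.start)
    return chosen
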