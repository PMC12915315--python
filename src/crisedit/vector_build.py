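"""In-silico assembly of screening/editing vectors and verification primers.

A screening vector is the circular backbone carrying a synthetic CRISPR
cassette (native-style leader, two consensus repeats flanking one spacer,
Rho-independent terminator); an editing vector additionally carries the
homology-arm editing template. Insertions model scar-free assembly at a
uniquely occurring restriction-site motif: only the final sequence matters,
so the insert is spliced in at the cut position without duplication or loss.

Verification primers are placed strictly outside the homology arms so that a
plasmid-borne template can never yield the edited-size amplicon; by
construction ``amplicon_WT - amplicon_edited`` equals the deletion length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .edit_design import EditingTemplate
from .errors import LengthError, PrimerError, SiteError
from .seqio import GenomeRecord, Interval, check_dna, revcomp

DEFAULT_ARRAY_SITE = "ACATGT"  # PciI
DEFAULT_TEMPLATE_SITE = "TCATGA"  # BspHI


@dataclass
class SyntheticArrayCassette:
    """leader + repeat + spacer + repeat + terminator, with part features."""

    leader: str
    repeat: str
    spacer: str
    terminator: str
    full_seq: str
    features: list[tuple[str, Interval, str]]


def assemble_cassette(
    leader: str,
    repeat: str,
    spacer: str,
    terminator: str,
    spacer_len: int = 35,
    repeat_len_range: tuple[int, int] = (20, 50),
) -> SyntheticArrayCassette:
    """Concatenate the synthetic CRISPR cassette and record part boundaries.

    The spacer must have the configured length and the repeat must fall in
    ``repeat_len_range``; violations raise LengthError.
    """
    for name, seq in (
        ("leader", leader),
        ("repeat", repeat),
        ("spacer", spacer),
        ("terminator", terminator),
    ):
        check_dna(seq, name)
    if len(spacer) != spacer_len:
        raise LengthError(f"spacer is {len(spacer)} nt; expected {spacer_len}")
    if not repeat_len_range[0] <= len(repeat) <= repeat_len_range[1]:
        raise LengthError(
            f"repeat is {len(repeat)} nt; expected within {repeat_len_range}"
        )
    parts = [
        ("leader", leader, "regulatory"),
        ("repeat", repeat, "repeat_region"),
        ("spacer", spacer, "misc_feature"),
        ("repeat", repeat, "repeat_region"),
        ("terminator", terminator, "terminator"),
    ]
    features = []
    cursor = 0
    for label, seq, ftype in parts:
        features.append((label, Interval("cassette", cursor, cursor + len(seq)), ftype))
        cursor += len(seq)
    full = leader + repeat + spacer + repeat + terminator
    return SyntheticArrayCassette(leader, repeat, spacer, terminator, full, features)


def count_restriction_sites(
    seq: str, motif: str, circular: bool = False
) -> tuple[int, list[tuple[int, str]]]:
    """Count motif occurrences on both strands (palindromes once).

    Returns ``(count, [(leftmost position, strand), ...])``; on circular
    sequences junction-spanning matches are included and positions are
    reported modulo the sequence length.
    """
    check_dna(seq, "sequence")
    check_dna(motif, "motif")
    if len(motif) < 4:
        raise ValueError("motif length must be >= 4")
    n = len(seq)
    search = seq + seq[: len(motif) - 1] if circular else seq
    found: list[tuple[int, str]] = []
    targets = [(motif, "+")]
    rc = revcomp(motif)
    if rc != motif:
        targets.append((rc, "-"))
    for target, strand in targets:
        start = 0
        while True:
            i = search.find(target, start)
            if i == -1:
                break
            found.append((i % n, strand))
            start = i + 1
    found = sorted(set(found))
    return len(found), found


@dataclass
class VectorDesign:
    """An assembled circular vector with annotated part features."""

    name: str
    kind: str  # screening | editing
    backbone_id: str
    insertions: list[tuple[str, str, int]]  # (part, site motif, cut position)
    full_seq: str
    features: list[tuple[str, Interval, str]]

    def __len__(self) -> int:
        return len(self.full_seq)


def _unique_cut(seq: str, motif: str) -> int:
    count, positions = count_restriction_sites(seq, motif, circular=True)
    if count != 1:
        raise SiteError(motif, count)
    return positions[0][0]


def _insert(
    seq: str,
    features: list[tuple[str, Interval, str]],
    insert_seq: str,
    insert_features: Sequence[tuple[str, Interval, str]],
    cut: int,
) -> tuple[str, list[tuple[str, Interval, str]]]:
    """Scar-free insertion at ``cut``: existing features downstream shift by
    the insert length; insert features are offset to the cut position."""
    new_seq = seq[:cut] + insert_seq + seq[cut:]
    shift = len(insert_seq)
    out: list[tuple[str, Interval, str]] = []
    for label, iv, ftype in features:
        if iv.start >= cut:
            out.append((label, Interval(iv.contig_id, iv.start + shift, iv.end + shift, iv.strand), ftype))
        else:
            out.append((label, iv, ftype))
    for label, iv, ftype in insert_features:
        out.append((label, Interval(iv.contig_id, iv.start + cut, iv.end + cut, iv.strand), ftype))
    return new_seq, out


def assemble_vector(
    backbone: GenomeRecord,
    cassette: SyntheticArrayCassette,
    template: Optional[EditingTemplate] = None,
    array_site_motif: str = DEFAULT_ARRAY_SITE,
    template_site_motif: str = DEFAULT_TEMPLATE_SITE,
    backbone_features: Optional[Sequence[tuple[str, Interval, str]]] = None,
    name: str = "vector",
) -> VectorDesign:
    """Insert the cassette (and optionally an editing template) into the
    circular backbone at uniquely occurring site motifs.

    The cassette goes in leader-first at the array site; the template, when
    given, at the template site of the intermediate construct (making the
    vector kind ``editing`` rather than ``screening``). A site that is
    absent or occurs more than once raises SiteError with the count.
    """
    if backbone.topology != "circular":
        raise ValueError("backbone must be circular")
    seq = backbone.sequence
    features = list(backbone_features or [])
    insertions: list[tuple[str, str, int]] = []

    cut = _unique_cut(seq, array_site_motif)
    seq, features = _insert(seq, features, cassette.full_seq, cassette.features, cut)
    insertions.append(("cassette", array_site_motif, cut))

    kind = "screening"
    if template is not None:
        cut = _unique_cut(seq, template_site_motif)
        arm_features = [
            ("up_arm", Interval("template", 0, len(template.up_arm)), "misc_feature"),
            (
                "down_arm",
                Interval("template", len(template.up_arm), template.total_len),
                "misc_feature",
            ),
        ]
        seq, features = _insert(seq, features, template.sequence, arm_features, cut)
        insertions.append(("template", template_site_motif, cut))
        kind = "editing"

    return VectorDesign(
        name=name,
        kind=kind,
        backbone_id=backbone.contig_id,
        insertions=insertions,
        full_seq=seq,
        features=features,
    )


def wallace_tm(primer: str) -> int:
    """Wallace-rule melting temperature: 2(A+T) + 4(G+C)."""
    at = sum(primer.count(b) for b in "AT")
    gc = sum(primer.count(b) for b in "GC")
    return 2 * at + 4 * gc


@dataclass
class PrimerPair:
    """Verification primers outside the homology arms with expected
    amplicon sizes on the wild-type and edited alleles."""

    fwd: str
    rev: str
    fwd_start: int  # genomic start of forward primer
    rev_end: int  # genomic end (exclusive) of reverse primer binding site
    tm_fwd: int
    tm_rev: int
    amplicon_wt: int
    amplicon_edited: int


def _gc_fraction(seq: str) -> float:
    return sum(seq.count(b) for b in "GC") / len(seq)


def design_screen_primers(
    genome: GenomeRecord,
    deletion: Interval,
    arm_len: int,
    search_span: int = 300,
    length: tuple[int, int] = (18, 25),
    gc: tuple[float, float] = (0.40, 0.60),
) -> PrimerPair:
    """First admissible primer per side, scanning outward from the outer arm
    boundaries; primers never overlap the arms by even one base.

    Admissibility: length within ``length`` and GC fraction within ``gc``.
    Raises PrimerError when a side has no admissible primer in the span.
    """
    seq = genome.sequence
    n = len(seq)
    up_bound = deletion.start - arm_len  # forward primer must end at or before
    down_bound = deletion.end + arm_len  # reverse primer must start at or after
    if up_bound - search_span < 0 or down_bound + search_span > n:
        raise PrimerError(
            f"search span of {search_span} bp not available beyond the arms"
        )
    lmin, lmax = length

    fwd = None
    for end in range(up_bound, up_bound - search_span, -1):
        for plen in range(lmin, lmax + 1):
            if end - plen < 0:
                continue
            cand = seq[end - plen : end]
            if gc[0] <= _gc_fraction(cand) <= gc[1]:
                fwd = (cand, end - plen)
                break
        if fwd:
            break
    if fwd is None:
        raise PrimerError("no admissible forward primer within the search span")

    rev = None
    for start in range(down_bound, down_bound + search_span):
        for plen in range(lmin, lmax + 1):
            if start + plen > n:
                continue
            cand = seq[start : start + plen]
            if gc[0] <= _gc_fraction(cand) <= gc[1]:
                rev = (revcomp(cand), start + plen)
                break
        if rev:
            break
    if rev is None:
        raise PrimerError("no admissible reverse primer within the search span")

    fwd_seq, fwd_start = fwd
    rev_seq, rev_end = rev
    amplicon_wt = rev_end - fwd_start
    return PrimerPair(
        fwd=fwd_seq,
        rev=rev_seq,
        fwd_start=fwd_start,
        rev_end=rev_end,
        tm_fwd=wallace_tm(fwd_seq),
        tm_rev=wallace_tm(rev_seq),
        amplicon_wt=amplicon_wt,
        amplicon_edited=amplicon_wt - len(deletion),
    )


def export_vector_genbank(vector: VectorDesign, path) -> None:
    """Write the vector as a circular GenBank file with all part features."""
    from .seqio import write_genbank

    write_genbank(vector.name, vector.full_seq, vector.features, path, circular=True)
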