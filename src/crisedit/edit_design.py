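"""Deletion planning, homology-arm templates, and counterselection checks.

A knockout deletes a fixed window around the gene's 5' end — by default
100 bp upstream of the start codon (removing proximal promoter sequence)
plus 400 bp of coding sequence, i.e. a 500 bp deletion. When PAM
availability forces a chosen protospacer (plus its PAM) outside that window,
the window is minimally extended on that side so that editing removes every
targeted site; the homology arms then abut the final deletion. An editing
template is the fusion of equal-length upstream and downstream arms
(600 or 1000 bp presets, 1.2 kb / 2 kb totals).

Counterselection logic: the native interference machinery destroys any
allele that still carries a PAM plus a seed-perfect protospacer match, so a
correct design must leave the wild-type allele targetable (FAIL in
:func:`validate_escape`) while the edited allele escapes (PASS).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from . import guide_design
from .errors import DesignError, FlankError
from .seqio import GeneFeature, GenomeRecord, Interval

JUNCTION_FLANK = 20  # bases taken from each arm for the edited-allele junction


@dataclass
class DeletionDesign:
    """A planned deletion: genomic window, its split into upstream/coding
    parts (gene-oriented), and the protospacers it covers."""

    gene_id: str
    deletion: Interval
    upstream_bp: int
    coding_bp: int
    length: int
    covered_protospacers: list[str]


@dataclass
class EditingTemplate:
    """Homology arms flanking a deletion; ``edited_junction`` is the 40-mer
    spanning the fusion point of the edited allele."""

    arm_len: int
    up_arm: str
    down_arm: str
    total_len: int
    edited_junction: str

    @property
    def sequence(self) -> str:
        return self.up_arm + self.down_arm


def plan_deletion(
    gene: GeneFeature,
    spacers: Sequence[guide_design.GuideCandidate],
    upstream_bp: int = 100,
    coding_bp: int = 400,
    contig_length: Optional[int] = None,
) -> DeletionDesign:
    """Place the deletion window for ``gene`` and expand it minimally to
    cover every chosen protospacer together with its PAM.

    The default window spans ``[start - upstream_bp, start + coding_bp)`` in
    gene-oriented coordinates and is mirrored for minus-strand genes. The
    upstream (promoter-side) boundary stays fixed unless a protospacer
    forces it outward; extension beyond the contig raises DesignError.
    """
    if gene.strand == "+":
        ds, de = gene.start - upstream_bp, gene.start + coding_bp
    else:
        ds, de = gene.end - coding_bp, gene.end + upstream_bp
    for cand in spacers:
        fp = cand.pam.footprint(len(cand.spacer_seq))
        ds = min(ds, fp.start)
        de = max(de, fp.end)
    if ds < 0 or (contig_length is not None and de > contig_length):
        raise DesignError(
            f"deletion window [{ds}, {de}) for {gene.gene_id} extends beyond the contig"
        )
    length = de - ds
    upstream_actual = (gene.start - ds) if gene.strand == "+" else (de - gene.end)
    return DeletionDesign(
        gene_id=gene.gene_id,
        deletion=Interval(gene.contig_id, ds, de),
        upstream_bp=upstream_actual,
        coding_bp=length - upstream_actual,
        length=length,
        covered_protospacers=[c.name or c.spacer_seq for c in spacers],
    )


def extract_arms(
    genome: GenomeRecord, deletion: Interval, arm_len: int
) -> EditingTemplate:
    """Homology arms strictly adjacent to the deletion on both sides.

    Raises FlankError (reporting the maximum feasible arm length) when a
    flank is shorter than ``arm_len``.
    """
    n = len(genome.sequence)
    feasible = min(deletion.start, n - deletion.end)
    if arm_len > feasible:
        raise FlankError(arm_len, feasible)
    up = genome.sequence[deletion.start - arm_len : deletion.start]
    down = genome.sequence[deletion.end : deletion.end + arm_len]
    return EditingTemplate(
        arm_len=arm_len,
        up_arm=up,
        down_arm=down,
        total_len=2 * arm_len,
        edited_junction=up[-JUNCTION_FLANK:] + down[:JUNCTION_FLANK],
    )


def edited_allele(genome: GenomeRecord, deletion: Interval) -> str:
    """The contig sequence with the deletion excised."""
    return genome.sequence[: deletion.start] + genome.sequence[deletion.end :]


@dataclass
class EscapeReport:
    """Outcome of scanning an allele for residual targetable sites."""

    passed: bool
    residual: dict[str, list[guide_design.OffTargetHit]]


def validate_escape(
    edited: str,
    spacers: Sequence[guide_design.GuideCandidate],
    pam: str = guide_design.DEFAULT_PAM,
    seed_len: int = guide_design.DEFAULT_SEED_LEN,
) -> EscapeReport:
    """PASS iff no spacer retains a blocking site (PAM plus seed-perfect
    match) anywhere in ``edited``; FAIL lists the residual sites per spacer.

    Run against the wild-type allele this must FAIL for the design's own
    spacers — that residual targeting is what drives counterselection.
    """
    allele = GenomeRecord("allele", edited)
    residual: dict[str, list[guide_design.OffTargetHit]] = {}
    for cand in spacers:
        blocking = [
            h
            for h in guide_design.off_target_hits(
                cand.spacer_seq,
                allele,
                pam=pam,
                seed_len=seed_len,
                max_total_mismatches=None,
            )
            if h.blocking
        ]
        if blocking:
            residual[cand.name or cand.spacer_seq] = blocking
    return EscapeReport(passed=not residual, residual=residual)
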