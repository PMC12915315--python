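"""Deterministic synthetic genomes with planted, truth-tracked features.

The generator emulates the study conditions of a small bacterial host with a
Type I-G-like locus: an i.i.d. background sequence at a configurable GC
fraction, a handful of genes, one planted CRISPR array (36 bp repeat, 19
spacers of 34-37 nt by default, AT-rich leader), TAT PAM sites planted on
both strands inside each gene's default deletion window, optional off-target
decoys, and a circular toy backbone carrying uniquely planted restriction
sites. Every planted feature is recorded in a truth table so scanners can be
checked for exact-coordinate recovery. Identical seeds produce byte-identical
output.

The background is i.i.d. with no repeats beyond the planted ones, which keeps
brute-force oracles unambiguous; real genomes (mobile elements, local repeats,
skewed composition) are deliberately not emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError, PlacementError
from .seqio import GeneFeature, GenomeRecord, Interval, revcomp

DEFAULT_PAM = "TAT"
_BASES = np.array(list("ACGT"))

# deletion-window defaults mirrored from edit_design so planted PAM
# footprints land inside the default window
_UPSTREAM_BP = 100
_CODING_BP = 400

_MOTIFS_TO_SCRUB = ("ACATGT", "TCATGA")  # keep cassette parts clonable


@dataclass
class FixtureConfig:
    """Study-condition defaults for the synthetic genome generator."""

    seed: int = 42
    genome_len: int = 60_000
    gc: float = 0.50
    genes: list[tuple[int, str]] = field(
        default_factory=lambda: [(1500, "+"), (1500, "-"), (1500, "+")]
    )
    repeat_len: int = 36
    n_spacers: int = 19
    spacer_len_range: tuple[int, int] = (34, 37)
    leader_len: int = 120
    pams_per_strand_per_gene: int = 3
    spacer_len: int = 35  # protospacer length for planted PAM/decoy footprints
    terminal_repeat_mismatches: int = 0
    decoys: list[tuple[Optional[int], bool]] = field(default_factory=list)
    backbone_len: int = 3000
    backbone_sites: dict = field(
        default_factory=lambda: {"PciI": "ACATGT", "BspHI": "TCATGA"}
    )

    def validate(self) -> None:
        if not 0.0 < self.gc < 1.0:
            raise ConfigError(f"gc must be in (0, 1); got {self.gc}")
        if self.genome_len <= 0:
            raise ConfigError("genome_len must be positive")
        if self.n_spacers < 2:
            raise ConfigError("n_spacers must be >= 2")
        if not 20 <= self.repeat_len <= 50:
            raise ConfigError("repeat_len must lie within [20, 50]")
        lo, hi = self.spacer_len_range
        if not 18 <= lo <= hi <= 50:
            raise ConfigError("spacer_len_range must lie within [18, 50]")
        if self.backbone_len < 2600:
            raise ConfigError("backbone_len must be >= 2600")


@dataclass
class SimulatedGenome:
    """A synthetic genome plus its gene table and planted-feature truth."""

    genome: GenomeRecord
    genes: list[GeneFeature]
    truth: dict


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    at = (1.0 - gc) / 2.0
    return rng.choice(_BASES, size=n, p=[at, gc / 2.0, gc / 2.0, at])


def _scrub_motifs(seq: str, motifs: Sequence[str] = _MOTIFS_TO_SCRUB) -> str:
    """Rewrite one base of any motif occurrence until none remain."""
    chars = list(seq)
    changed = True
    while changed:
        changed = False
        text = "".join(chars)
        for motif in motifs:
            for target in {motif, revcomp(motif)}:
                i = text.find(target)
                if i != -1:
                    mid = i + len(target) // 2
                    chars[mid] = {"A": "C", "C": "A", "G": "T", "T": "G"}[chars[mid]]
                    changed = True
                    break
            if changed:
                break
    return "".join(chars)


def _mutate(seq: str, position_1based: int) -> str:
    """Deterministic single substitution at a 1-based position."""
    i = position_1based - 1
    cycle = {"A": "C", "C": "G", "G": "T", "T": "A", "N": "A"}
    return seq[:i] + cycle[seq[i]] + seq[i + 1 :]


def default_deletion_window(gene: GeneFeature) -> tuple[int, int]:
    """Default deletion window for a gene in genome coordinates: 100 bp
    upstream of the start codon plus 400 bp of coding sequence, mirrored for
    minus-strand genes. Planted PAM footprints land inside this window."""
    if gene.strand == "+":
        return gene.start - _UPSTREAM_BP, gene.start + _CODING_BP
    return gene.end - _CODING_BP, gene.end + _UPSTREAM_BP


_deletion_window = default_deletion_window


def simulate_genome(config: Optional[FixtureConfig] = None) -> SimulatedGenome:
    """Generate the genome, its gene table, and the planted-feature truth.

    Raises ConfigError when the requested features cannot be packed into
    ``genome_len`` with the margins needed for arms and primer spans.
    """
    cfg = config or FixtureConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.genome_len
    arr = _random_dna(rng, n, cfg.gc)

    margin = 2500  # room for 1 kb arms + primer spans at the contig edges
    inter_gene = 3000
    lo, hi = cfg.spacer_len_range
    worst_case = (
        margin
        + sum(length + inter_gene for length, _ in cfg.genes)
        + 500
        + cfg.leader_len
        + (cfg.n_spacers + 1) * cfg.repeat_len
        + cfg.n_spacers * hi
        + margin
    )
    if worst_case > n:
        raise ConfigError(
            f"genome_len {n} too small: features need about {worst_case} bp"
        )
    cursor = margin
    genes: list[GeneFeature] = []
    for idx, (length, strand) in enumerate(cfg.genes):
        genes.append(GeneFeature(f"gene{idx + 1}", "chr", cursor, cursor + length, strand))
        cursor += length + inter_gene

    # planted PAM sites: footprints inside each gene's default deletion window
    pam_truth: list[dict] = []
    L = cfg.spacer_len
    foot = L + len(DEFAULT_PAM)
    for gene in genes:
        ws, we = _deletion_window(gene)
        slots = 2 * cfg.pams_per_strand_per_gene
        span = (we - ws) - 2 * 20 - foot
        if slots > 1 and span < (slots - 1) * (foot + 5):
            raise ConfigError(
                f"cannot pack {slots} PAM footprints into the deletion window of "
                f"{gene.gene_id}"
            )
        step = span // max(slots - 1, 1) if slots > 1 else 0
        for j in range(slots):
            x = ws + 20 + j * step
            strand = "+" if j % 2 == 0 else "-"
            if strand == "+":
                arr[x : x + 3] = list(DEFAULT_PAM)
                pam_truth.append(
                    {"gene_id": gene.gene_id, "pam_start": x, "strand": "+"}
                )
            else:
                arr[x + L : x + L + 3] = list(revcomp(DEFAULT_PAM))
                pam_truth.append(
                    {"gene_id": gene.gene_id, "pam_start": x + L, "strand": "-"}
                )

    # planted CRISPR array: leader, then repeat/spacer units, leader-first
    leader = _scrub_motifs(
        "".join(rng.choice(_BASES, size=cfg.leader_len, p=[0.4, 0.1, 0.1, 0.4]))
    )
    repeat = _scrub_motifs("".join(_random_dna(rng, cfg.repeat_len, cfg.gc)))
    spacers: list[str] = []
    seeds_seen: set[str] = set()
    while len(spacers) < cfg.n_spacers:
        slen = int(rng.integers(lo, hi + 1))
        s = "".join(_random_dna(rng, slen, cfg.gc))
        if s[:8] in seeds_seen:  # keep planted spacers mutually seed-distinct
            continue
        seeds_seen.add(s[:8])
        spacers.append(s)
    repeats = [repeat] * (cfg.n_spacers + 1)
    if cfg.terminal_repeat_mismatches:
        terminal = repeat
        positions = rng.choice(
            cfg.repeat_len, size=cfg.terminal_repeat_mismatches, replace=False
        )
        for p in sorted(int(p) for p in positions):
            terminal = _mutate(terminal, p + 1)
        repeats[-1] = terminal

    array_parts = []
    for i, rep in enumerate(repeats):
        array_parts.append(rep)
        if i < len(spacers):
            array_parts.append(spacers[i])
    array_seq = "".join(array_parts)

    leader_start = cursor + 500
    array_start = leader_start + cfg.leader_len
    array_end = array_start + len(array_seq)
    if array_end + margin > n:
        raise ConfigError(
            f"genome_len {n} too small: features need {array_end + margin} bp"
        )
    arr[leader_start:array_start] = list(leader)
    arr[array_start:array_end] = list(array_seq)

    truth = {
        "seed": cfg.seed,
        "genome_len": n,
        "genes": [
            {
                "gene_id": g.gene_id,
                "contig_id": g.contig_id,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
            }
            for g in genes
        ],
        "array": {
            "start": array_start,
            "end": array_end,
            "repeat": repeat,
            "repeats": repeats,
            "spacers": spacers,
            "leader_start": leader_start,
            "leader_end": array_start,
            "orientation": "leader-first",
        },
        "pams": pam_truth,
        "decoys": [],
    }

    genome = GenomeRecord("chr", "".join(arr.tolist()), "linear")
    sim = SimulatedGenome(genome, genes, truth)

    # off-target decoys copy the first plus-strand planted protospacer of gene1
    if cfg.decoys:
        src = next(p for p in pam_truth if p["strand"] == "+")
        proto_start = src["pam_start"] + len(DEFAULT_PAM)
        spacer_seq = genome.sequence[proto_start : proto_start + L]
        pos = array_end + 500
        for mismatch_position, with_pam in cfg.decoys:
            sim.genome, entry = plant_offtarget(
                sim.genome,
                spacer_seq,
                mismatch_position,
                with_pam,
                position=pos,
            )
            sim.truth["decoys"].append(entry)
            pos += foot + 60
    return sim


def plant_offtarget(
    genome: GenomeRecord,
    spacer_seq: str,
    mismatch_position: Optional[int],
    with_pam: bool,
    position: Optional[int] = None,
    avoid: Sequence[Interval] = (),
    pam: str = DEFAULT_PAM,
) -> tuple[GenomeRecord, dict]:
    """Plant one plus-strand decoy copy of ``spacer_seq``.

    ``mismatch_position`` (1-based, PAM-proximal) applies a single
    substitution; ``None`` plants an exact copy. With ``with_pam`` the PAM is
    written immediately 5' of the decoy; otherwise any accidental upstream
    PAM is destroyed. ``position`` is the leftmost base of the footprint
    (PAM start when present); when omitted, the first free slot clear of
    ``avoid`` is used. Returns the modified record and a truth entry.
    """
    L = len(spacer_seq)
    foot = L + len(pam)
    n = len(genome.sequence)
    if position is None:
        position = None
        for p in range(1000, n - foot - 1000, 100):
            iv = Interval(genome.contig_id, p, p + foot)
            if not any(iv.overlaps(a) for a in avoid):
                position = p
                break
        if position is None:
            raise PlacementError("no free slot for decoy placement")
    if position < len(pam) or position + foot > n:
        raise PlacementError(f"decoy footprint at {position} outside the contig")
    decoy = spacer_seq if mismatch_position is None else _mutate(spacer_seq, mismatch_position)
    chars = list(genome.sequence)
    if with_pam:
        chars[position : position + len(pam)] = list(pam)
        proto_start = position + len(pam)
    else:
        proto_start = position + len(pam)
        upstream = "".join(chars[position : position + len(pam)])
        if upstream == pam:  # make sure pam_found really is false
            chars[position] = {"A": "C", "C": "A", "G": "T", "T": "G"}[chars[position]]
    chars[proto_start : proto_start + L] = list(decoy)
    entry = {
        "protospacer_start": proto_start,
        "strand": "+",
        "mismatch_position": mismatch_position,
        "with_pam": with_pam,
        "spacer": spacer_seq,
    }
    return GenomeRecord(genome.contig_id, "".join(chars), genome.topology), entry


def simulate_backbone(
    config: Optional[FixtureConfig] = None,
) -> tuple[GenomeRecord, list[tuple[str, Interval, str]]]:
    """A circular toy backbone with each named site motif planted exactly
    once, plus synthetic ori/marker annotations."""
    cfg = config or FixtureConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1)
    seq = _scrub_motifs(
        "".join(_random_dna(rng, cfg.backbone_len, cfg.gc)),
        motifs=tuple(cfg.backbone_sites.values()),
    )
    chars = list(seq)
    site_positions = {}
    offsets = [100, 1550]
    for (name, motif), pos in zip(cfg.backbone_sites.items(), offsets):
        chars[pos : pos + len(motif)] = list(motif)
        site_positions[name] = pos
    record = GenomeRecord("backbone", "".join(chars), "circular")
    features = [
        ("ori_ec", Interval("backbone", 200, 700), "rep_origin"),
        ("cat_marker", Interval("backbone", 800, 1460), "CDS"),
        ("ori_bif", Interval("backbone", 1700, 2400), "rep_origin"),
    ]
    # the scrub cannot have reintroduced a site inside the planted region
    for name, motif in cfg.backbone_sites.items():
        occurrences = ("".join(chars) + "".join(chars)[: len(motif) - 1]).count(motif)
        if occurrences != 1:
            raise ConfigError(f"backbone site {name} occurs {occurrences} times")
    return record, features


def apply_array_edits(
    profile: Sequence[int], edits: Sequence[tuple]
) -> list[int]:
    """Apply ``(op, position, payload)`` edits to a spacer-ID profile.

    Ops: ``("insert", pos, [ids])``, ``("delete", pos, count)``,
    ``("duplicate", src_pos, dst_pos)``.
    """
    out = list(profile)
    for op, pos, payload in edits:
        if op == "insert":
            out[pos:pos] = list(payload)
        elif op == "delete":
            del out[pos : pos + int(payload)]
        elif op == "duplicate":
            out.insert(int(payload), out[pos])
        else:
            raise ValueError(f"unknown edit op {op!r}")
    return out


def make_array_variants(
    base_profile: Sequence[int], edit_sets: Sequence[Sequence[tuple]]
) -> list[list[int]]:
    """Derive one variant profile per edit set (ground truth for diffing)."""
    return [apply_array_edits(base_profile, edits) for edits in edit_sets]
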