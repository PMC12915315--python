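"""Design a complete knockout: spacers, deletion, template, vectors, primers.

Builds the default synthetic host genome, designs a three-spacer panel
against gene1 inside its default deletion window, plans the deletion,
extracts both homology-arm presets, assembles the six editing vectors, and
designs verification primers outside the arms.
"""

from crisedit.edit_design import edited_allele, extract_arms, plan_deletion, validate_escape
from crisedit.fixtures import FixtureConfig, default_deletion_window, simulate_backbone, simulate_genome
from crisedit.guide_design import extract_candidates, screen_candidates, select_spacers
from crisedit.seqio import Interval
from crisedit.vector_build import assemble_cassette, assemble_vector, design_screen_primers

sim = simulate_genome(FixtureConfig(seed=42))
gene = sim.genes[0]
print(f"host genome: {len(sim.genome):,} bp; target {gene.gene_id} "
      f"at [{gene.start}, {gene.end}) on {gene.strand}")

ws, we = default_deletion_window(gene)
candidates = extract_candidates(sim.genome, gene, Interval("chr", ws, we))
screen_candidates(candidates, sim.genome)
panel = select_spacers(candidates, k=3)
print(f"candidates in deletion window: {len(candidates)}; selected panel:")
for c in panel:
    print(f"  {c.name}: {c.spacer_seq[:12]}... ({c.target_strand} strand, "
          f"{len(c.blocking_hits)} blocking off-targets)")

design = plan_deletion(gene, panel, contig_length=len(sim.genome))
print(f"deletion: [{design.deletion.start}, {design.deletion.end}) = "
      f"{design.length} bp ({design.upstream_bp} upstream + {design.coding_bp} coding)")

wt = validate_escape(sim.genome.sequence, panel)
allele = edited_allele(sim.genome, design.deletion)
ed = validate_escape(allele, panel)
print(f"counterselection: wild-type targetable={not wt.passed}, "
      f"edited escapes={ed.passed}")

backbone, feats = simulate_backbone(FixtureConfig(seed=42))
repeat = sim.truth["array"]["repeat"]
vectors = []
for cand in panel:
    cassette = assemble_cassette("AT" * 60, repeat, cand.spacer_seq, "GC" * 20)
    for arm_len in (600, 1000):
        tpl = extract_arms(sim.genome, design.deletion, arm_len)
        vectors.append(assemble_vector(backbone, cassette, tpl, backbone_features=feats))
print(f"editing vectors assembled: {len(vectors)} "
      f"(sizes {sorted({len(v) for v in vectors})} bp)")

primers = design_screen_primers(sim.genome, design.deletion, 1000)
print(f"verification amplicons: WT {primers.amplicon_wt} bp, edited "
      f"{primers.amplicon_edited} bp (difference = deletion length: "
      f"{primers.amplicon_wt - primers.amplicon_edited} bp)")
# A correct design removes every protospacer+PAM (edited allele escapes) and
# the amplicon difference equals the deletion, so a gel band shift of that
# size identifies true chromosomal edits.
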