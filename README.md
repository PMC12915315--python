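# crisedit

A design and analysis toolkit for genome editing with **endogenous Type I-G
CRISPR-Cas systems**, aimed at microbiologists engineering bacteria — such as
probiotic *Bifidobacterium* strains — that are hard to transform and are
easiest to edit by reprogramming their own interference machinery rather
than delivering a heterologous nuclease.

The toolkit covers both sides of that workflow:

* **Editing design** — scan target genes for PAM sites, extract protospacer
  candidates on both strands, screen them genome-wide under the seed rule,
  plan knockout deletions, build homology-arm editing templates, assemble
  screening/editing vectors in silico, and design verification primers.
* **Comparative locus analytics** — detect CRISPR arrays, derive repeat
  consensus and spacer statistics, build cross-genome spacer catalogs, diff
  array profiles, scan for self-targeting, and cluster Cas proteins at 100%
  identity with pairwise-identity matrices.

A deterministic synthetic-genome generator (`crisedit.fixtures`) produces
all inputs with planted, truth-tracked features, so everything is testable
without downloading genomes.

## The model

The host machinery is a Type I-G system: a crRNA-guided Cascade complex
recognizes a short 5'-PAM (**5'-TAT-3'**) and base-pairs with the **35 nt
protospacer immediately 3' of it**; Cas3 then processively degrades the
target. Interference requires a perfect match across the PAM-proximal
**seed, positions 1–8** of the protospacer (position 1 adjacent to the PAM);
mismatches there abolish targeting, while PAM-distal mismatches generally do
not. crisedit therefore classifies a genomic site as **blocking** for a
spacer iff the PAM is present *and* the seed matches perfectly.

Editing is recombination followed by counterselection. The vector carries

```
leader — repeat — spacer(35 nt) — repeat — terminator      (synthetic array)
up_arm(600|1000 bp) — down_arm(600|1000 bp)                (editing template)
```

on a circular backbone with dual origins and a resistance marker. The
knockout window defaults to **100 bp upstream of the start codon plus
400 bp of coding sequence (a 500 bp deletion)** and is minimally extended
when PAM availability forces a chosen protospacer outside it. Cells that
recombine the template lose every protospacer+PAM and escape interference;
unedited cells keep a blocking site and are killed — the package verifies
this *counterselection invariant* for every design (wild-type allele FAILS
`validate_escape`, edited allele PASSES).

## Worked example

`python examples/design_knockout.py` designs a complete knockout against the
default synthetic host (seed 42) and prints:

```
host genome: 60,000 bp; target gene1 at [2500, 4000) on +
candidates in deletion window: 29; selected panel:
  gene1:-77+: ATGAGGTTGGCG... (coding strand, 0 blocking off-targets)
  gene1:+124+: GCGCCAACTGGC... (coding strand, 0 blocking off-targets)
  gene1:+394-: ACCATTTATTCG... (template strand, 0 blocking off-targets)
deletion: [2400, 2900) = 500 bp (100 upstream + 400 coding)
counterselection: wild-type targetable=True, edited escapes=True
editing vectors assembled: 6 (sizes [4467, 5267] bp)
verification amplicons: WT 2547 bp, edited 2047 bp (difference = deletion length: 500 bp)
```

Reading the numbers: 29 PAM sites fall inside gene1's deletion window; the
selected three-spacer panel (protospacers on both strands, no blocking
off-targets) sits inside the default window, so the deletion is exactly
500 bp. Three spacers × two arm presets yield the six editing vectors, and
the verification primers — placed strictly outside the homology arms so a
plasmid-borne template can never amplify — give a WT/edited band difference
exactly equal to the deletion.

The other examples show the comparative side: `examples/compare_arrays.py`
(array detection, 19- vs 22-spacer diff with three mid-array insertions,
self-target scan) and `examples/cluster_cas_proteins.py` (100%-identity
clustering and identity matrices).

The same functionality is exposed as a CLI:

```bash
crisedit simulate-genome --seed 42 --out-prefix fix
crisedit design-guides --genome fix.fasta --genes fix.genes.tsv \
    --gene gene1 --out guides.tsv --json panel.json
crisedit design-template --genome fix.fasta --genes fix.genes.tsv \
    --gene gene1 --spacers panel.json --arm-len 600 --out-prefix ko1
crisedit build-vector --backbone fix.backbone.fasta --cassette cassette.json \
    --template ko1.arms.fasta --mode editing --out ko1.gb
```

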