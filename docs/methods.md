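# Methods

This note documents the models, algorithms, parameter choices, and
limitations behind crisedit, in the order a design flows through the
package.

## Coordinates and sequence handling

All internal coordinates are 0-based half-open; GenBank emission converts
to 1-based inclusive locations (a bijection on valid intervals), and BED
output stays 0-based half-open. DNA is restricted to {A,C,G,T,N}: IUPAC
ambiguity codes beyond N are rejected rather than expanded because the
design arithmetic (mismatch counting, seed classification) assumes
unambiguous bases. `N` compares equal only to `N`. Plasmids default to
circular topology and genome contigs to linear; circular extraction wraps
across the origin via doubled-string slicing. Emitted GenBank files carry a
fixed LOCUS date so identical designs are byte-identical across reruns.

## Targeting model

The interference machinery recognizes a 5'-TAT-3' PAM (configurable for
other Type I systems) and the 35 nt protospacer immediately 3' of it on the
PAM strand; the crRNA spacer equals that protospacer read 5'→3'. Position 1
is the base adjacent to the PAM (PAM-proximal numbering), and the seed is
positions 1–8. Two equal-length spacers are *functionally distinct* iff
they differ at any seed position; differences from position 9 outward are
treated as functionally equivalent.

**Blocking rule.** A genomic site is blocking for a spacer iff the PAM is
present on the hit strand and the seed matches perfectly, regardless of the
distal mismatch count. The same rule drives off-target screening (a
candidate with any blocking site elsewhere is rejected), self-target
interpretation, and `validate_escape`. Whether interference in vivo
tolerates large distal mismatch counts at seed-perfect sites is not
established; the rule is a deliberately conservative proxy, and it is the
only self-consistent choice here — a deletion that spares the PAM plus seed
must count as a failed design even though the residual site has dozens of
distal mismatches. `off_target_hits` additionally *reports* (without
flagging) every site within `max_total_mismatches` (default 5) so users can
inspect near-matches; both thresholds are configurable.

Off-target scanning is a vectorized sliding-window mismatch count over both
strands (numpy, one pass per query position), with the reverse-complement
strand scanned symmetrically and coordinates mapped back to plus-strand
intervals. It is exact — no heuristic seeding — which is practical because
the intended inputs are single bacterial genomes (≲ 10 Mb).

## Spacer panels and deletion planning

Candidates are extracted from a window (CLI default: gene span ± 200 bp;
the worked examples use the deletion window itself) and must fit wholly
inside it. Panels of k = 3 spacers are chosen among blocking-free
candidates to maximize pairwise genomic separation (lexicographic objective:
minimum pairwise gap, then total gap), with ties broken toward the smallest
genomic positions so selection is invariant to input order.

The deletion window defaults to 100 bp upstream of the start codon plus
400 bp of coding sequence (500 bp), mirrored for minus-strand genes. The
"~100/~400 bp" magnitudes are treated as exact defaults with config
overrides. When a chosen protospacer+PAM footprint extends beyond the
window, the window is *minimally extended on that side only*, keeping the
promoter-side boundary fixed unless a protospacer forces it — a one-sided
minimal rule chosen for determinism; only the outcome of such expansions
(e.g. a 749 bp deletion when a protospacer ends 649 bp into the ORF), not
the rule itself, is observable from real designs. Homology arms (600 or
1000 bp presets; 1.2/2 kb templates) abut the deletion with no gap.

## Vector assembly

Cassette and vector assembly is modeled as scar-free insertion at a
restriction-site motif that must occur exactly once in the current
construct (defaults: ACATGT for the cassette, TCATGA for the template;
both live in a config table since the relevant enzymes' motifs are standard
knowledge, and other enzymes can be supplied). Scar-free splicing models
the outcome of overlap-extension/HiFi assembly: only the final verified
sequence matters, so simulating the intermediate PCR chemistry would add
nothing the tests could check. Insertion orientation is fixed
(cassette leader-first clockwise). Verification primers scan outward from
the outer arm boundaries (first admissible primer: length 18–25 nt, GC
40–60%), never overlap the arms, and use the Wallace rule 2(A+T)+4(G+C)
for Tm — adequate for the short primers involved; no thermodynamic
nearest-neighbor model is attempted.

## Array detection and comparative analytics

Detection is a CRT-style exact-repeat finder: identical 20-mer anchors
recurring with gaps of 38–100 bp are extended to the maximal shared repeat
(length 20–50), requiring ≥ 3 units with exactly identical internal repeats
and spacers of 18–50 bp; one terminal repeat per end may carry ≤ 2
substitutions. Overlapping candidates are resolved toward the array with
the most units. This is deterministic and oracle-testable; it is *not* a
replacement for dedicated genome-mining tools on degenerate natural arrays.
Leader orientation is not inferred (the field determines it by inspection
or annotation); detected arrays are `unknown`-oriented, and spacer
cataloging then falls back to the lexicographic min of a spacer and its
reverse complement for cross-genome ID stability, using leader-aware
orientation when the caller provides it.

Repeat consensus is a per-column majority vote (ties break A<C<G<T;
over-long terminal repeats are truncated to the internal length first).
Array diffing aligns spacer-ID profiles by longest common subsequence with
ties broken toward the leftmost match in A; insertions/deletions are the
off-LCS positions and the reported edits reconstruct A from B exactly.
Protein dedup is exact-identity partitioning (first-seen representatives
and numbering). Pairwise identity uses an in-package Needleman–Wunsch
(match +1, mismatch 0, linear gap −1, end gaps penalized) that optimizes
(score, matches, −columns) lexicographically; identity = matches /
alignment columns × 100, with gap columns in the denominator since no
standard normalization is universal. The tuple objective makes the value
symmetric in its arguments, which an arbitrary co-optimal traceback would
not guarantee.

## Synthetic fixtures

`fixtures.simulate_genome` emulates the study conditions: a 60 kb linear
contig (large enough for 1 kb arms plus 300 bp primer spans around every
gene, small enough for exhaustive oracles) of i.i.d. bases at GC 0.50
(an unbiased default; no background value is dictated by the biology being
emulated), three 1.5 kb genes on strands +/−/+, one planted array with a
36 bp repeat and 19 spacers of 34–37 nt behind a 120 bp AT-rich leader,
and three TAT PAMs per strand planted inside each gene's default deletion
window (enough that a three-spacer panel survives occasional chance
rejections). Planted spacers are mutually seed-distinct so equivalence
grouping has clean ground truth. Optional decoys copy a planted protospacer
with a single substitution at a stated PAM-proximal position, with or
without an upstream PAM. Every planted feature is recorded with exact
coordinates in a truth table; identical seeds give byte-identical output.

What the fixtures do *not* emulate: real bifidobacterial composition
(≈60% GC, codon structure), repeated elements beyond the planted ones,
restriction-methylation site biology, or degenerate natural repeats.
Passing the planted-recovery suite therefore shows coordinate-exact
correctness of the scanners on unambiguous inputs, not mining performance
on natural genomes.

## Problem sizes used by the test and acceptance suites

Worked examples run on single 60 kb fixtures; planted recovery uses 20
seeded fixtures; the off-target oracle comparison uses a 100 kb genome;
the counterselection invariant is checked on 50 seeded fixtures (one
design each, rotating through the three genes); diff and identity oracles
use exhaustive enumeration at profile length ≤ 8 over 4 IDs and sequence
length ≤ 6. These sizes keep every oracle exhaustive or brute-force while
exercising the same code paths as full-scale inputs.

## Known limitations

* No guide-efficiency prediction: observed spacer-to-spacer variability in
  editing outcomes has no validated predictive model in this system, so
  selection optimizes only admissibility and spacing.
* Genomic context beyond the 3 nt PAM is not modeled in off-target
  classification.
* Recombination-efficiency differences between arm lengths are not modeled;
  the two presets are emitted and compared downstream by the user.
* `find_repeated_spacers` groups by (length, seed) equivalence, which for
  unknown-orientation arrays depends on the canonical orientation chosen.
* The array detector assumes internal repeats are exact; highly degenerate
  arrays require dedicated mining tools.
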