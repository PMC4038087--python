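# Methods

## Scope and data model

The package annotates mesonivirus-like (+)ssRNA genomes and demarcates
species among them. Internally all coordinates are 0-based half-open on
the poly-A-trimmed genome; file output (GFF3) is 1-based inclusive, strand
always "+" — these genomes are single-stranded and no reverse-strand scan
is performed. RNA input (U) is normalized to the DNA alphabet on read;
every motif is stored in DNA letters. Ambiguity codes are rejected by
default; with `allow_ambiguous` they are accepted and treated as
mismatches everywhere (they match nothing in motif scans and score as
mismatches in alignments, including against themselves).

Poly-A trimming removes the trailing maximal run of A when it is at least
`polya_min_run` (default 5) long and records its length. The delimitation
of deposited tails is not standardized, so the threshold is configurable;
trimming is idempotent.

## Canonical architecture assignment

ORF discovery scans all three frames for stop-terminated reading frames,
either ATG→stop or maximal stop-to-stop open segments (used for ORF1b,
which is expressed only by frameshift and need not start with AUG). The
genome plan itself is a published observation, not an algorithm, so the
assignment rule set is this package's operationalization, with all
thresholds in `ArchitectureParams`:

- **ORF1a** — first ATG-initiated ORF of ≥ 3000 nt.
- **ORF1b** — longest open segment in frame (ORF1a.frame + 2) mod 3 that
  spans ORF1a's 3' end (for a given frame the maximal open segments
  partition the genome, so the segment crossing the boundary is unique).
- **ORF2a** — first ATG ORF ≥ 2000 nt starting at or after ORF1a's end
  *and ending past ORF1b's end*. The second condition is a deliberate
  refinement: ORF1b's interior essentially always contains internal ATGs
  that open a ≥ 2000-nt reading frame terminating at ORF1b's own stop;
  without the nesting exclusion those would capture the ORF2a label on
  any realistic genome.
- **ORF2b** — longest alternative-frame ATG ORF fully inside ORF2a whose
  start lies in ORF2a's 5' third (the region encoding the variable
  N-terminal signalase product, where the nucleoprotein gene nests).
- **ORF3a** — first ATG ORF ≥ 500 nt starting within 30 nt of ORF2a's end
  or later and extending past it.
- **ORF3b** — longest alternative-frame ATG ORF starting in ORF3a's
  3' half.
- **ORF4** — first ATG ORF of 120–200 nt after ORF3b (optional; its
  absence is not an error, matching genomes that lack it).

Ties among equal-length candidates break toward the smaller start.
Unassigned ATG ORFs of ≥ 180 nt are reported as `small_orfs`. A missing
mandatory element raises an error naming it.

## −1 frameshift translation

The fusion products pp1ab (ORF1a→1b at GGAUUUU) and p3ab (ORF3a→3b at
CACUUUU) are conceptual translations. The join convention: with slippery
heptamer at position `s`, the shift lands on the first upstream-codon
boundary `j ≥ s + 7`; the fused CDS is `genome[start:j] + genome[j−1:end]`
— nucleotide `j−1` is read twice, the shared base of the shift site. The
mechanism fixes only the heptamer, not the join arithmetic, so `j` is
advanced codon-wise up to `s + 16` until the fusion translates without an
internal stop; failure raises a frameshift error. Translation uses the
standard code (table 1) and the terminal stop is dropped.

## Motifs and protein features

TRS patterns are compiled from a mini-language: exact bases, `x` for any
base, a parenthesized symbol optional (greedy, so the longest match at a
position is reported); all overlapping hits are kept. Only `x` is treated
as a wildcard — any additional sub-element structure implied by the
typography of the published motifs is not modeled. Hits inside the 5'UTR
are classified "leader", all others "body".

Molecular weight uses average isotopic residue masses plus one water
(Biopython), reported in kDa and rounded to 2 decimals only at report
time. The isoelectric point is the root of the Henderson–Hasselbalch net
charge, found by bisection on pH ∈ [0, 14] to |charge| < 1e-4; the pKa
table defaults to EMBOSS-style values and is swappable per call — pI
values quoted to more than ~0.5 pH units are table-dependent, which is why
the table travels with the computation. Sequons follow N-X-S/T with
X ≠ P; cleavage motifs are `[C/S]|[L/A/S]TRIDL` (signalase) and
`R|WDSSYV` (S1–S2).

## Pairwise alignment and insertion detection

Nucleotide global alignment is an affine-gap Needleman–Wunsch written
here (numba kernels): a gap of length L costs `gap_open + L·gap_extend`
(defaults 10 and 0.5 with match 5 / mismatch −4, the EDNAFULL-style
values), adjacent opposite gaps are two events, and ties break
deterministically diagonal > gap-in-second > gap-in-first. A banded mode
(half-width `band`, default 2000, plus the length difference) bounds
memory at genome scale; it reproduces the full-matrix optimum whenever
the optimal path stays inside the band, which holds for the near-identical
genome pairs the band is used on and is asserted by contract tests.
Protein pairs route through Biopython's PairwiseAligner with BLOSUM62.

Substitutions are counted as gap-free mismatch columns only (gap-adjacent
columns are never substitutions); each maximal gap run is one indel event.
Insertion blocks are maximal reference-row gap runs ≥ 30 nt in the global
alignment of homologous regions, reported with the query span; when the
block length is a codon multiple and a frame anchor is supplied, the
in-frame window is translated and scanned for imperfect repeats of the
`SKRKGK` seed (Hamming distance ≤ 2), otherwise the block is flagged
frame-disrupting. An aligned identity below 30% raises a homology error
rather than reporting spurious blocks.

## Distances, clustering, sliding windows

The PED estimator and its numerical choices are described in the README;
the WAG exchangeabilities and frequencies ship as packaged PAML-format
data (the published Whelan & Goldman 2001 matrix). No gamma rate
heterogeneity is applied by default — the demarcation criterion was
defined on plain WAG distances — but a 4-category discrete-gamma option
(equal-probability categories, category-mean rates) exists for
sensitivity analysis, and outputs are labeled "WAG" vs "WAG+G4"
accordingly. Identical sequences short-circuit to d = 0 (the likelihood
is then maximized at the lower bound). Pairs with fewer than 50
comparable sites raise a precision error; estimates at the upper bound
(d = 10) are flagged as saturated. Unequal-length inputs are
pairwise-aligned (BLOSUM62) first; gap/ambiguous columns are dropped.

Domain extraction locates each reference domain in pp1ab by
Smith–Waterman (BLOSUM62, open −11 / extend −1), then extends the local
hit to full reference coverage so terminal substitutions do not erode the
span. The acceptance floor is 0.15 of the reference self-score: genuine
homologs stay above ~0.20 even at 1.5 substitutions/site under WAG, while
shuffled sequences of identical composition reach only ~0.03, leaving a
≥ 5× margin on either side. Concatenation order is fixed 3CLpro, RdRp,
ZnHel1. The packaged reference domains are a synthetic stand-in
(deterministically drawn from WAG equilibrium frequencies, documented in
the file header) — coordinates in that file are curated for the synthetic
pp1ab, and users supply a real reference FASTA for field data.

Species clustering is agglomerative, cut at t = 0.032 by default. Single
linkage is the default because the published criterion compares *pairs*
to the cutoff — single linkage is exactly the transitive closure of that
relation; complete linkage is available for sensitivity analysis.
Clusters are ordered by smallest member for determinism.

Sliding-window divergence reports, per window (default 100 residues,
step 25 — the original analysis names no parameters, so these are
package defaults chosen to resolve domain-scale structure), the mean
pairwise p-distance within and between species, with gaps excluded
pairwise and windows without comparable sites recorded as missing (NaN),
never as zero.

## Synthetic data: what it emulates, and what it does not

The generator plants the full canonical plan at study scale — ~20.1-kb
bodies (20.7 kb with the largest insertion), 360-nt 5'UTR, ~1790-nt
3' terminal region, ORF1ab ≈ two thirds of the genome, insertions of
0/180/573/588 nt starting ≈ 1300 nt from the 5' terminus with repeat
copies at the block boundaries, two leader and two body TRS elements, and
a 25-nt poly-A tail. Construction writes all planted elements as fixed
bases and fills the rest uniformly at random, then locally resamples
until (i) no constrained reading frame contains a stray stop, (ii) no
intergenic zone contains an ATG (which could seed a spurious ORF4-sized
frame), and (iii) no ORF overlap contains an unplanned slippery heptamer.
Planted ATG starts are preceded by in-frame delimiter stops so chance
stop-free runs cannot extend a discovered ORF upstream of its plant, and
a third-frame stop just past ORF3a's end bounds chance competitors of
ORF3b. A final verification pass re-annotates the genome and compares
against the truth table; a failing draw (e.g. a chance TRS match,
~1 in 300) is regenerated on a deterministic child seed, so output is a
pure function of the spec. Reference domain amino-acid sequences are
encoded into ORF1a/ORF1b (optionally pre-evolved at a controlled WAG
distance) to make the demarcation stage exercisable end to end.

Isolate sets plant exact substitution counts (avoiding all planted
elements and never creating a constrained-frame stop, intergenic ATG or
stray heptamer) and optional deletions in the 3' terminal region, which
are coordinate-neutral for every named feature. `evolve_sequence`
implements i.i.d. site evolution (Jukes–Cantor for nucleotides, WAG for
amino acids).

What the generator does *not* emulate — and hence what green tests do not
establish about field data: codon-usage and dinucleotide bias, RNA
secondary structure at the frameshift site, recombination, uneven
divergence along the genome, sequencing error, and real intergenic
sequence (which contains start codons; the sanitized gaps exist so that
planted-truth comparisons are exact). The architecture rule set is
validated against genomes that obey the canonical plan; genuinely
rearranged genomes will, correctly, fail with a named error rather than
be forced into the plan.

## Problem sizes used by the test suite and acceptance script

Recovery criteria run on 100 full-scale (~20-kb) genomes; the alignment
oracle enumerates all global alignments for all length pairs up to 6 nt;
distance recovery simulates 10,000 sites per replicate, 6 replicates per
true distance in {0.05, 0.1, 0.5, 1.0}, comparing the mean estimate
within 5%; the demarcation acceptance set is 13 genomes in species of
5 + 4 + 3 + 1. These sizes make the full suite and the acceptance script
each complete in well under a minute after JIT warm-up.

## Known limitations

- The ORF assignment rules assume the canonical plan; they do not handle
  genomes with duplicated or translocated ORFs.
- PED values are computed on domains extracted by alignment to a
  reference; a poor reference propagates into the distances. The packaged
  reference is synthetic and only suitable for synthetic data.
- The banded aligner's contract (banded = full) holds when the optimal
  path stays within the band; for highly divergent pairs with large
  structural differences, use `exact` or a wider band.
- p3ab is emitted whenever the CACUUUU heptamer permits a stop-free
  fusion; whether ORF3b is actually expressed by internal initiation or
  read-through is an open biological question, so both the ORF3b product
  and p3ab are reported.
- Whether ORF4 counts among the "major" ORFs is left unresolved; ORF4 is
  labeled separately and treated as optional.
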