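# mesoni

Genome-architecture annotation and species demarcation for mesoniviruses —
mosquito-specific (+)ssRNA viruses (family *Mesoniviridae*, order
*Nidovirales*) with ~20-kb polyadenylated genomes.

## Who this is for

Virologists characterizing new mesonivirus (or, more broadly, invertebrate
nidovirus) isolates from assembled genome sequences. Given genomes as
FASTA, the package:

- maps each genome onto the canonical mesonivirus plan: a long 5'UTR,
  ORF1a overlapped by ORF1b in the −1 frame, ORF2a (spike, S) with the
  nucleoprotein ORF2b nested in its 5' third, overlapping ORF3a/ORF3b,
  small ORF4, and a long 3' terminal region before the poly-A tail;
- locates transcription-regulatory sequences (TRS elements
  `AUxxUACUACUACUA` and `AGAx(x)ACUCUCCCA`), the slippery heptamers
  `GGAUUUU` (ORF1a/1b) and `CACUUUU` (ORF3a/3b), and conceptually
  translates the −1 programmed ribosomal frameshift products pp1ab and
  p3ab;
- computes protein-level features: signalase (`[C/S]|[L/A/S]TRIDL`) and
  S1–S2 (`R|WDSSYV`) cleavage sites, N-glycosylation sequons, cysteine
  census, average molecular weight and isoelectric point;
- detects ORF1a block insertions against a reference genome and scans them
  for imperfect `SKRKGK`-type repeats;
- demarcates species by maximum-likelihood pairwise evolutionary distance
  (PED) under the WAG amino-acid model over the concatenated conserved
  replicase domains (3CLpro, RdRp, ZnHel1), clustering at the genus cutoff
  of 0.032 substitutions/site.

A first-class synthetic-genome generator (`mesoni.synthetic_data`) builds
study-scale genomes with a fully known truth table, so every stage is
testable without any downloads.

## The statistic at the core

For two aligned domain sequences, the PED $\hat d$ maximizes

$$L(d) = \prod_i \pi_{a_i}\,P_{a_i b_i}(d),\qquad P(d) = e^{Qd},$$

where the reversible rate matrix $Q_{ab} = s_{ab}\pi_b$ is built from the
WAG exchangeabilities $s_{ab}$ and equilibrium frequencies $\pi_a$,
normalized to one expected substitution per site. Gap and ambiguous
columns are dropped; $P(d)$ comes from the eigendecomposition of the
symmetrized rate matrix and $\hat d$ from bounded 1-D optimization on
$[10^{-9}, 10]$. Two genomes belong to one species when
$\hat d \le 0.032$; single-linkage clustering turns the pairwise criterion
into a partition. Under the Poisson special case ($s_{ab}=1$,
$\pi_a=1/20$) the estimate equals the closed form
$-(19/20)\ln(1-(20/19)p)$, which the tests exploit as an oracle.

## Worked example

```bash
mesoni simulate --seed 5            # writes synthetic.fasta + truth table
mesoni annotate synthetic.fasta --out-dir out
```

`out/annotation.json` for this genome contains (abridged):

```
genome_length: 20114   polya_len: 25
utr5: [0, 360]         term3: [18324, 20114]
ORF1a: [360, 9660)  frame 0  protein 3099 aa
ORF1b: [9614, 13814) frame 2 protein 1399 aa
ORF2a: [13874, 17174) frame 2 protein 1099 aa
ORF2b: [14025, 14685) frame 0 protein 219 aa
ORF3a: [17234, 17924) frame 2 protein 229 aa
ORF3b: [17674, 18094) frame 1 protein 139 aa
ORF4:  [18174, 18324) frame 0 protein 49 aa
slippery: [GGATTTT @ 9621, CACTTTT @ 17678]
pp1ab: 4484 aa, join at 9630
N protein: 219 aa, 24.74 kDa, pI 9.13
```

Reading it: the 20,139-nt record lost a 25-nt poly-A tail; all coordinates
refer to the trimmed genome. ORF1b overlaps ORF1a's 3' end in the −1 frame
and the `GGAUUUU` heptamer at 9621 supports a −1 frameshift whose fusion
polyprotein (pp1ab, 4484 aa) re-reads nucleotide 9629. ORF2b — the
nucleoprotein — is nested inside ORF2a's 5' third in an alternative frame.
A GFF3 with the same features is written next to the JSON.

Species demarcation over a set of genomes:

```bash
mesoni demarcate g1.fasta g2.fasta ... --threshold 0.032 --out-dir out
```

writes the PED matrix (`distances.tsv`), the partition (`species.tsv`) and
run metadata, and prints the cluster count and membership.

`mesoni diff a.fasta b.fasta` summarizes substitutions and indel events
between two near-identical isolate genomes.

## Notes

- The packaged replicase-domain reference
  (`src/mesoni/data/reference_domains_synthetic.fasta`) is a synthetic
  stand-in; point `reference_domains` in the config at a real reference
  FASTA (same header format) to analyse field genomes.
- The WAG model data (`src/mesoni/data/wag.dat`) is the published
  Whelan & Goldman (2001) matrix in PAML format.
- `docs/methods.md` documents the model, the annotation rule set, every
  tunable threshold, and known limitations.
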