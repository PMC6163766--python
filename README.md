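# degenpanel

Degenerate PCR primer **panels** for gene collections too diverse for any
single primer pair.

Environmental collections of a marker gene — for example the family-B DNA
polymerase (*polB*) genes of giant viruses recovered from marine
metagenomes — are often so divergent that no single oligonucleotide, even
a degenerate one, can amplify them all: the IUPAC consensus of the whole
collection is unusable because primer pools blow up combinatorially
(degeneracy is the product of per-position base-set sizes).  `degenpanel`
takes the opposite route: it designs a *set* of degenerate primer pairs
such that every member of the collection is amplified in silico, with
zero mismatches, by at least one pair — a guarantee that holds by
construction, not by luck.

## The algorithm

Inputs: a nucleotide CDS FASTA of homologous genes, a protein multiple
alignment of their products, and optionally per-sequence abundance
weights (mapped reads / gene length) and outgroup flags.

1. **Thread** the protein alignment back to a codon-level nucleotide
   alignment (each residue replaced by its source codon, gaps by `---`).
2. **Seed** a cluster with the most abundant remaining sequence.
3. **Grow** the cluster by testing every remaining sequence once, in
   order of increasing protein p-distance to the seed.  At each step the
   cluster's alignment is reduced to a single IUPAC consensus (per column,
   the minimal code covering the union of observed bases) and primer
   pairs are enumerated on it under the design constraints — Tm optimum
   52 °C (nearest-neighbor thermodynamics, acceptance interval 47–57 °C),
   optimal length 20 (18–27), at most 8 degenerate positions, degeneracy
   at most 256, product 200–600 bp containing a fixed target window.  A
   candidate sequence joins the cluster only if a pair still exists that
   amplifies every member exactly; otherwise it is rejected and stays
   available for later clusters.
4. **Sweep**: store the best (lowest-penalty) pair as PP1, PP2, …, then
   remove the cluster members *and* every other remaining sequence the
   pair amplifies with zero mismatches — the greedy set-cover step.
5. Repeat from 2 until the collection is empty.  Pairs whose
   amplification set is purely outgroup can be pruned afterwards.

Verification uses the built-in in silico PCR engine: ungapped,
bitmask-vectorised binding-site search on both strands with a
`floor(fraction × primer length)` mismatch tolerance (0 for the strict
screen, 0.10 for the relaxed one), plus specificity screening against
decoy collections and genotype censuses of assembly sets.

A codon-aware synthetic gene-family generator (clades radiating from one
ancestor, conserved windows, log-normal abundances, no internal stop
codons) provides realistic, fully reproducible test substrates.

## Worked example

```bash
degenpanel simulate --n-clades 3 --members-per-clade 6 --gene-len 400 \
    --seed 42 --out-prefix fam
# wrote 18 sequences under prefix fam

degenpanel design --targets fam.targets.fasta --alignment fam.alignment.faa \
    --abundance fam.abundance.tsv --out-prefix run
# 1 primer pairs; 18/18 targets covered at 0 mismatches; abundance-weighted
# coverage 100.0%; 0 undesignable
```

Three clades of this family are close enough to share one pair.  The
primer table (`run.primers.tsv`) holds the panel; its first data row:

```
PP1  KSAATTCGTYACAAGCGAGG  104  50.53  54.58  8  3   ...  400  0.6660
```

read as: forward primer `KSAATTCGTYACAAGCGAGG` binding at alignment
position 104 (1-based), melting temperatures of its 8 pool variants
spanning 50.53–54.58 °C, 3 degenerate positions, a 400 bp product, and a
design penalty of 0.666 (distance from optimal length and Tm).  Running
the panel back over its own targets:

```bash
degenpanel amplify --primers run.primers.tsv --templates fam.targets.fasta \
    --out hits.tsv
# 18 amplicons
```

every target yields exactly one zero-mismatch amplicon — the designer's
construction guarantee.  `degenpanel screen` checks decoy collections
(non-zero exit when any decoy amplifies), `degenpanel census` counts
distinct amplifiable genotypes per assembly, and `degenpanel overhangs`
prepends sequencing-adapter overhangs for synthesis (never scored).

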