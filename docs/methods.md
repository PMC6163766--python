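# Methods

## Problem setting

Given a collection of homologous protein-coding genes (CDSs) with a
protein multiple alignment, find a small ordered set of degenerate primer
pairs such that every collection member is amplified in silico — both
primers binding with zero mismatches and a product within size bounds —
by at least one pair.  The package implements the design loop, the in
silico PCR machinery used to verify it, reporting utilities, and a
synthetic gene-family generator used as the test substrate.

## IUPAC algebra and consensus model

A degenerate base is a non-empty subset of {A,C,G,T}; a degenerate primer
is a Cartesian pool whose size (degeneracy) is the product of per-position
subset sizes.  Primer-template matching uses intersection semantics: a
primer base binds a template base iff their code sets share a plain base.
For plain templates this is ordinary pool membership; for the rare
ambiguous template base (e.g. an N in a metagenomic CDS) intersection is
the permissive generalisation, and a strict mode that rejects ambiguous
template bases is available on `base_matches`.

The consensus of an alignment column is the *minimal* IUPAC code covering
the union of non-gap bases.  Gaps are ignored unless a column is all-gap,
in which case it is dropped (a column map preserves original coordinates).
Consequently every member matches the consensus with zero mismatches over
its non-gap span — the invariant that makes the designer's coverage claim
constructive rather than statistical.  Member ambiguity propagates: an N
in any row forces consensus N, preserving the invariant.

## Codon threading

The nucleotide alignment is obtained by back-translating the protein
alignment with each row's CDS (residue → source codon, gap → `---`),
equivalent to the standard protein-guided threading used for codon
alignments.  One terminal stop codon is tolerated and dropped, matching
common CDS deposition practice.  Translation of ambiguous codons returns
the unique residue all expansions agree on, else `X`; an `X` in the
protein alignment accepts any codon.  Frameshift tolerance is out of
scope: a CDS/protein mismatch is a hard, position-reporting error.

## Melting temperatures

Plain-sequence Tm uses unified nearest-neighbor thermodynamics
(SantaLucia 1998): per-stack ΔH/ΔS with A·T / G·C initiation terms, the
entropic salt correction ΔS' = ΔS + 0.368·(N−1)·ln[Na⁺], and
Tm(K) = ΔH / (ΔS' + R·ln(C/4)), assuming a non-self-complementary primer
in excess (the factor 4); no symmetry correction is applied.  Defaults:
[Na⁺] = 50 mM, C = 50 nM.  The implementation agrees with Biopython's
independent NN implementation to ~1e-6 °C (cross-checked in the tests).
A degenerate primer's Tm is summarised as the exact (min, max) over its
full expansion — affordable because designed pools are capped at 256
variants — and a primer is Tm-acceptable when that interval intersects
[tm_min, tm_max].  A consensus-base approximation was rejected as neither
oracle-checkable nor obviously conservative.

## Candidate enumeration and ranking

On a cluster consensus with target window (w_s, w_e) (0-based half-open),
a forward primer is a slice starting at or before w_s, a reverse primer
the reverse complement of a slice ending at or after w_e; the product
interval [fwd_start, rev_end) must contain the window, lie within the
product-size bounds (default 200–600 bp), and the primer footprints must
not overlap.  Per-primer constraints: length 18–27 (optimum 20),
≤ 8 degenerate positions, degeneracy ≤ 256, Tm interval intersecting
47–57 °C (optimum 52 °C); pair constraint: midpoint-Tm difference ≤ 5 °C.
Ranking penalty = Σ|len − len_opt| + Σ|midTm − tm_opt| over both primers,
ties broken by (fwd start, rev binding start, fwd length, rev length).
Hairpin/self-dimer screening, GC clamps and other secondary-structure
heuristics of classical primer-design tools are deliberately not modelled:
the stated constraint set *is* the design criterion here, and hidden
heuristics would fake precision.  A degenerate 3' terminal base is allowed
by default (`allow_degenerate_3prime=False` to forbid).

The enumerator is lazy (best-first frontier over penalty-sorted slice
lists), so the designer's inner loop pays only for the top-ranked pairs;
the eager variant materialises the full ranked list and is tested for
equality against brute-force slice-pair filtering on small consensi.

## In silico PCR

Binding sites are ungapped windows where the number of non-intersecting
positions is ≤ floor(fraction × primer length); fraction 0 is exact
degenerate matching, 0.10 the relaxed screen.  No indel tolerance and no
thermodynamic binding model.  Both template strands are scanned (a
palindromic primer reports each duplex site once); amplification pairs
every forward site with every compatible downstream reverse site within
the product bounds.  Matching is vectorised with a 4-bit base-mask
encoding (match ⇔ mask AND ≠ 0), which keeps whole-collection sweeps at
microseconds per template.

## The design loop

* **Seeding**: most abundant remaining sequence, ties by lexicographic id.
  Default abundance is 1.0, so an unweighted run degenerates to id order.
* **Guide order**: protein p-distance (mismatch fraction over mutually
  non-gap columns; 1.0 when no columns are shared) to the seed, ties by
  descending abundance then id.  This replaces an external aligner's
  guide tree with the same "order of sequence similarity" semantics while
  staying fully reproducible.
* **Master alignment instead of per-step realignment**: clusters are
  subsets of one threaded master alignment rather than being realigned at
  each agglomeration step.  This is a deliberate deviation from designs
  that realign per iteration: it is deterministic, aligner-free, and
  identical whenever the master alignment is consistent; collections with
  alignment-unstable regions inherit whatever the input alignment chose.
  The target window is therefore expressed in master-alignment nucleotide
  columns (CLI: 1-based inclusive, default 106–214) and mapped through
  each cluster's column map; if all window columns gap out of a cluster,
  that cluster is undesignable.
* **Acceptance test for a joining candidate**: after tentatively adding
  the candidate, the designer walks the ranked candidate-pair stream and
  accepts the first pair that amplifies *every* cluster member exactly
  (checked with the same PCR engine used for final verification), giving
  up after 25 pairs.  Requiring member-level amplification — not merely
  the existence of a constraint-passing pair — is what makes the final
  coverage claim airtight even when members carry gaps or indels under a
  primer footprint; the cap bounds worst-case work and was never reached
  in the test fixtures.  Each remaining sequence is tested once per
  cluster, in guide order; rejected sequences remain eligible for later
  clusters (and as future seeds).
* **Sweep**: after a pair is stored, every remaining sequence it
  amplifies at fraction 0 (requiring a valid product size by default;
  `removal_requires_product=False` relaxes to site presence) is removed.
* **Bookkeeping**: a seed with no single-sequence design moves to the
  undesignable set.  If a later pair happens to amplify such a sequence,
  it is reclassified as covered at the end, so the final partition is
  exact: every input id is either covered at 0 mismatches or listed
  undesignable, and the designer raises if its own invariant fails.
  Every grow/reject/sweep decision is recorded in a per-iteration log.

Pair ids are dense (PP1, PP2, …) in emission order.  Outgroup-only
pruning drops pairs whose non-empty strict amplification set consists
solely of outgroup-flagged targets, without renumbering the survivors;
targets that lose all coverage are reported as outgroup-only.

## Synthetic families

`simulate_family` draws a random ancestral CDS from the 61 non-stop
codons, derives per-clade consensus sequences by per-site substitution,
and members from their clade consensus.  Defaults model a diverse
environmental marker-gene collection: 12 clades, 400-codon genes, one
conserved 40-codon window (codons 36–75, 1-based) mutating at 0.01 per
site on every branch, variable regions at 0.15 between clades and 0.02
within, log-normal(0, 1.5) abundance weights.  Substitutions are uniform
over the three alternative bases with stop-creating draws redrawn (a site
whose every alternative creates a stop is skipped), so no internal stops
ever arise.  No indels are simulated — the trivial column-wise protein
alignment is then exact, which keeps generated fixtures aligned by
construction; real data additionally contain indels, alignment error and
partial genes, so passing tests demonstrate algorithmic correctness on
well-aligned collections, not robustness to upstream alignment problems.
With these defaults the conserved core keeps clades amplifiable while the
reverse primer necessarily binds variable sequence (the 200 bp product
minimum pushes it beyond the 120-nt core), so panels of several pairs
emerge rather than one universal pair.

`simulate_incompatible_clades` builds the sharpest test case: internally
identical clades whose sequences are rejection-sampled so that every
18-mer window of any clade pair differs at ≥ 9 sites — one more than the
degenerate-position cap — making any cross-clade consensus undesignable
and forcing exactly k clusters.  `simulate_decoys` rejection-samples
uniform random sequences until no panel pair amplifies them exactly.

## Numerical and degenerate-input choices

* Degeneracy slice filtering uses cumulative log2 sums with a 1e-9 slack,
  then an exact integer recheck, so float error can never mis-filter.
* All randomness flows through `numpy.random.default_rng` from explicit
  seeds; design itself is deterministic and independent of input record
  order (orderings derive from abundance/id/distance rules only).
* Amplicons are deduplicated strand-canonically in the genotype census
  (a product equals its reverse complement's genotype).
* Degenerate guards: empty collections, empty alignments, windows outside
  the consensus, expansion blow-ups and gap characters in primers are
  hard errors with positions named; "no candidate passes" is an empty
  result, not an error.

## Problem sizes

The documented benchmark — 200 sequences in 12 clades, 400-codon genes —
designs in well under a minute on one CPU, and the randomized oracle
suites (1000 site-finding instances, 500 threading/consensus fixtures)
run in seconds; these sizes were chosen as the package's standing test
conditions.

## Known limitations

* No hairpin/dimer/GC-clamp modelling; no multiplex cross-dimer checks.
* No indel tolerance in primer binding; no PCR efficiency model — in
  silico coverage is a presence/absence statement, not a quantitative
  yield prediction.
* The protein alignment is an input; building or improving it is out of
  scope, and design quality inherits alignment quality.
* Tm for pools reports the exact range over variants, but pooled-primer
  hybridisation kinetics (competition between variants) is not modelled.
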