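# Methods

This note documents the models and procedures implemented in `sh2swap`,
their assumptions, the defaults that matter, and the design choices made
where the design was genuinely open.

## The fitness score and its estimand

The screen couples cell sorting on a phenotype (CD69 surface marker for
signalling fitness; a fluorescent fusion for protein abundance) to deep
sequencing of the variant library before and after sorting. For variant *i*
in one replicate the score is

    fitness_i = log10(SortCount_i / InputCount_i) − N_r,

where the replicate's normalization constant N_r is the mean of
log10(Sort/Input) over the synonymous wild-type sequences in the library.
Consequences that the test suite asserts as invariants:

* the mean score of the wild-type synonyms is exactly 0 in every replicate;
* scores are invariant to sequencing depth per sample (rescaling all counts
  in one sample cancels between a variant and the wild-type anchor);
* under the generative model below, the score is a consistent estimator of
  g_i − mean(g_wt), the variant's true log10 enrichment relative to wild
  type.

**Numerical choices.** Eq. 1 is undefined at a sorted count of 0. A zero
sort count is replaced by a pseudocount c = 0.5 (configurable); nonzero
counts are never inflated, and a drop-the-replicate mode is available.
Variants with fewer than 50 input reads in a replicate are dropped *in that
replicate* (a count of exactly 50 is retained); replicate means and SEM
(sd/√n, ddof = 1) adjust n to the surviving replicates. Synonymous codon
realizations of one protein are scored separately and averaged afterwards
(counts are not pooled), preserving the replicate-level variance structure;
pooling first is a config switch.

Background comparisons report Δ_i = mean_B,i − mean_A,i with the standard
quadrature propagation SE_Δ = √(SE_A² + SE_B²) over the shared variant set.
Note that with 3–4 replicates the SEM is a low-degrees-of-freedom estimate,
so ±2·SE_Δ intervals cover well below the nominal 95 %; the test suite uses
a ±3·SE_Δ band, which is approximately nominal under the matching
t distribution.

## Read assignment

Reads are assigned to designed variants by exact k-mer equivalence classes
(default k = 25) over the **variable region** only, on both strands: the
candidate set of a read is the intersection of the reference sets of its
matching k-mers, and only a unique survivor is counted. This is the
pseudoalignment idea reduced to the amplicon setting, where references are
designed and pairwise distinguishable — the index build fails loudly if two
references are identical over the covered window. Reads matching only
shared constant sequence, or no k-mer at all, are counted as unassigned.
Precomputed count tables (e.g. from an external quantifier) are accepted
unchanged.

For the kinase-helix library, one read resolves both identities: the helix
variant by exact occurrence of its variable region, and the SH2 background
by the 3-nt barcode immediately after the stop codon
(TTC/CCT → BTK background, GGA/AAG → BMX-H background). The barcodes are
not error-correcting at Hamming distance 1, so any unrecognized barcode is
reported as unassigned data with a reason code, never "corrected".

## Ancestral sequence reconstruction

The substitution model is a reversible 20-state continuous-time Markov
chain Q_ij = s_ij π_j built from an empirical exchangeability matrix and
equilibrium frequencies, normalized to one expected substitution per site
so branch lengths are in substitutions/site. The packaged default is JTT
(estimated from pairwise-aligned SWISS-PROT sequences); any PAML-layout
`.dat` file can be substituted, since the reconstruction *mode*, not the
matrix, is the scientifically active choice here. There is no
rate-heterogeneity across sites and no branch-length re-optimization — the
tree is an input.

P(t) = exp(Qt) is computed once per branch by symmetric eigendecomposition
of D^{1/2} Q D^{−1/2} (exact for reversible Q, fast at 20 states); rows of
P(t) are verified to sum to 1 within 1e-10 over t ∈ [0, 10].

* **Likelihood** — Felsenstein pruning with per-site rescaling; invariant
  to root placement for the reversible model (pulley principle, asserted to
  1e-9).
* **Marginal mode** — the posterior distribution of the state at one
  internal node given all leaf data, obtained by re-rooting the tree at
  that node (valid under reversibility) and combining π with the
  conditional likelihoods of its incident subtrees. The reported sequence
  is the per-site argmax.
* **Joint mode** — the single assignment to *all* internal nodes
  maximizing the joint probability, by per-site max-product dynamic
  programming with backpointers.

States are ordered alphabetically, so argmax ties resolve to the
lexicographically first amino acid; ties are logged. Both modes are
verified site-by-site against exhaustive enumeration over all internal
state combinations on 4-leaf fixture trees (1e-9 in log space).

**Gaps.** Two strategies, matching the two ways a gapped block can be
forced through a gap-free reconstruction: `prune` removes every column
containing at least one gap (reconstruction against the shortest
sequence); `fill` keeps all columns and treats gaps as missing data whose
likelihood contribution is marginalized (a vector of ones at that leaf and
site), so a residue is emitted at every column (against the longest
sequence). Missing-data marginalization is the statistically standard
reading of "interpolating from the other sequences": the reconstruction at
a gapped column is driven entirely by the non-gapped rows.

## Library curation rules

* **Deduplication** keeps the first occurrence by exact ungapped-sequence
  identity.
* **Pairwise identity** between aligned sequences is
  100 × matches / (columns where at least one row is non-gap) — indels
  count against identity. Because published identity figures rarely state
  their convention, the denominator rule is configurable
  (`nongap_both`, `alignment_length`); unaligned pairs are globally aligned
  first (BLOSUM62, gap −11/−1). Identity bands are inclusive-low,
  exclusive-high so adjacent bands partition the range.
* **Progressive selection** of k = 14 domains per paralog: candidates at
  Hamming distance exactly 1 from the reference are excluded as
  uninformative near-duplicates, survivors are ranked by identity
  ascending, and picks step through the ranked list at a stride of
  ⌊n/k⌋ from the least identical survivor, climbing evenly through the
  identity range.
* **Controls** substitute the residue at the column mapped to reference
  position 307 (1-based numbering anchored at 281): lysine for domains
  above 60 % identity, a stop for domains above 95 % (both strict, as
  printed). Domains without an arginine at that column are skipped with a
  warning — the rule describes an Arg replacement, so forcing it on other
  residues would manufacture controls the design never had.

## Oligo design

Reverse translation preserves the reference codon wherever the variant
residue equals the reference residue at the aligned position, and draws a
uniform synonymous codon elsewhere (stops draw from the three stop
codons). The BsaI recognition site (GGTCTC) and its reverse complement
(GAGACC) are banned from the variable region — both strands, because BsaI
is a Type IIS enzyme — while the two 18-nt cloning handles contain the site
by design. A draw creating a forbidden motif is resampled locally at the
free codons overlapping the motif window (bounded at 100 rounds; a motif
forced entirely by reference-fixed codons is an error identifying the
window). Local resampling rather than whole-sequence rejection gives the
same distribution over accepted sequences and always terminates in
practice.

Each protein is realized as four synonymous sequences; positions identical
to the reference are invariant across the four by rule. Wild-type
normalization anchors are synthesized separately as recodings of the
reference CDS at exactly five randomly chosen codon positions (31 for the
SH2-format library, 44 for the helix-format library, both configurable).
Finished oligos are `left handle + CDS (+ 3-nt barcode after the stop
codon, helix library only) + right handle + filler`, cut to exactly
300 nt. The packaged filler is a 500-nt seeded-random constant, BsaI-free
on both strands, used from offset 0 and 3′ of the construct; it is a
synthetic stand-in for the phage-genome padding used in real designs and
is configurable. Randomness is keyed by (pool seed, CRC32 of variant id,
synonym index), so draws are independent of processing order and the whole
pool is byte-reproducible from one seed.

## The synthetic experiment generator

The generator emulates the structure of the real assay, not its biology:

* library proportions π ~ Dirichlet(α = 5) — realistic unevenness in
  per-variant depth without modelling cloning;
* input counts ~ Multinomial(N_in, π) per replicate;
* sorting as multinomial resampling with selection weights
  w_i ∝ π_i · 10^{g_i} — the minimal model under which the fitness score
  is a consistent estimator of g_i − mean(g_wt);
* optional reads: uniform fixed-length fragments of each variant's oligo
  with uniform substitution errors (rate ≤ 0.1).

Default study conditions: 300 variants including 20 wild-type synonyms
(g = 0 exactly), 10 stop-class variants at g = −1.5, one gain variant at
g = +0.23, the remainder Normal(0, 0.3); 4 replicates; 10⁶ reads per
sample. What passing tests show: the scoring arithmetic, normalization,
filtering and error propagation are correct, and planted effects of the
magnitudes the assay reports are recoverable at its depths (RMSE < 0.05
log10 units; the +0.23 gain within 2·SEM; stop-class variants in the bottom
decile). What they do not show: robustness to PCR jackpots, index hopping,
cell-growth dynamics, gating inaccuracy, or any other real-data pathology
the generator deliberately omits.

The desk-scale study emulation (`study` module) additionally reproduces the
library *accounting* as a computed consequence of the curation rules: a
synthetic 249-domain base set with 16 + 45 + 1 domains above the 60 %
control threshold (17 of them above 95 %) yields 62 R→K and 17 stop
controls, hence 79 controls and 328 sequences; a redundant 364-sequence
helix pool collapses to 113 uniques plus 5 human paralogs, 118 total; and a
screen with 128 planted gains, 44 strong losses, and 77 mild losses among
249 scored variants measures as 51 % fitness-gaining and 17 %
strong-loss.

## Known limitations

* No rate heterogeneity, no codon/nucleotide models, no tree or
  branch-length inference — the phylogeny and model are inputs.
* The k-mer assigner assumes designed, pairwise-distinguishable amplicon
  references; it is not a general RNA-seq quantifier and does no
  error-tolerant matching.
* The generator's sorting model has no gating noise; fitted SEMs reflect
  counting noise only.
* Identity conventions in published tables vary; when reproducing printed
  identity figures, the denominator rule may need to be switched.
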