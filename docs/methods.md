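# Methods

## Scope and model

promscan predicts transcription-factor binding sites (TFBSs) in promoter
sequences by position-weight-matrix (PWM) scanning against a 0-order
nucleotide background, then summarizes the predictions with compositional
statistics (GC by region class, site density), population-genetic divergence
(Tajima's D on aligned TFBS/CDS/intron sets) and pathway-level count tables.
All stages operate equally on real inputs (FASTA/GFF3/JASPAR/MEME/TSV) and on
the package's own synthetic data, which carries planted ground truth.

## Position matrices

A motif is stored in probability form: an L×4 matrix over (A, C, G, T) with
unit column sums, with the raw count matrix retained when the source was a
count PFM. Metadata (TF name, family, species, evidence level) joins from a
TSV association table; motifs absent from the table get family "unknown".

**Log-odds conversion.** `s[j][b] = log2(((p[j][b] + ε)/(1 + 4ε)) / q[b])`,
with pseudo-probability ε = 1e-8 by default. ε is applied to probabilities,
not counts, so matrices distributed as probabilities (the common case in
pooled collections) are handled uniformly; ε = 0 is rejected because zero
probabilities would produce non-finite scores. The conversion is exactly
invertible given the background and ε, which the tests exploit.

**Similarity and deduplication.** Collections pooled across databases and
species contain near-duplicates. Similarity between two matrices is the
maximum, over all ungapped offsets with at least 70 % overlap of the shorter
motif and over both orientations of the second matrix, of the mean
column-wise Pearson correlation between overlapping probability columns.
Columns with zero variance (exactly uniform) carry no preference: two equal
constant columns correlate 1, a constant against a non-constant column 0.
Deduplication is greedy at threshold 0.8 in a canonical order — evidence
level first (experimental, inferred, unknown), then descending total
information content, then motif id — so results are independent of input
order and the retained representative of each redundant group is the
best-supported matrix. Greedy clustering does not guarantee the kept set is
pairwise below threshold; what is guaranteed (and tested) is that every
dropped motif exceeds the threshold against its recorded representative.

**DKL conservation index.** `DKL = − Σ_j Σ_b p[j][b] log2(p[j][b]/q[b])`
in bits, with 0·log 0 = 0 — the negated total Kullback–Leibler divergence of
the motif columns from the background. Against a uniform background it is
≤ 0 with equality only for a fully uniform motif; a deterministic column
contributes −2 bits. More negative means more information-rich/conserved.
The total (not per-column average) is reported so longer informative motifs
rank as more conserved.

## Background models

Backgrounds are 0-order frequencies estimated from a promoter FASTA by
counting A/C/G/T on the forward strand and its reverse complement
(strand-averaged, since scanning is two-stranded), ignoring non-ACGT
letters, with an add-one floor: `q[b] = (c[b] + 1)/(total + 4)`. Strand
averaging forces q[A] = q[T] and q[C] = q[G], which in turn makes a motif and
its reverse complement have identical null score distributions.

## Promoter extraction and filtering

A promoter is up to 1000 bp immediately 5' of the TSS (transcript-level TSS
when mRNA features exist, else the gene 5' end), truncated at the nearest
boundary of any other annotated gene on either strand and clipped at the
chromosome edge; minus-strand promoters are reverse complemented so the
sequence reads 5'→3' relative to the gene. Genes whose upstream neighbour is
adjacent or overlapping yield no promoter and are reported absent rather
than failing the run. Coordinates are 1-based inclusive (GFF3 convention)
throughout; BED output converts at the writer.

Draft-genome promoters can be dominated by assembly gaps. The filter removes
promoters with N-fraction > 0.9 or fewer than 20 informative (non-N) bases,
recording the reason. The informative-base check runs first so that
short-informative promoters get the more specific reason; both orders remove
the same set. The 20-base floor guarantees every kept promoter can host at
least one scan window for the motif widths in common use.

## Scanning and significance

**Exact p-values.** Per-column log-odds scores are discretized to bins of
δ = 1e-3 bits (scores clamped below −100 bits per column), and the null
distribution of the binned window score under the background is built by
positional convolution of the per-column score kernels; tail probabilities
follow by suffix summation. A window's p-value is the tail probability at
its own binned score, computed with the same per-column bins, so DP and scan
are exactly consistent, and agree with brute-force enumeration over all 4^L
windows (tested for L ≤ 6).

Kernels are convolved in a canonical sorted order rather than left to right.
Convolution is commutative mathematically, but float addition is not
associative; the canonical order makes the distribution bit-identical under
column permutation — and therefore identical for a motif and its reverse
complement under a strand-symmetric background.

**Reported scores are δ-quantized** (δ times the integer bin sum). Integer
sums are permutation-invariant, which makes the strand-symmetry invariant —
scanning revcomp(sequence), or scanning with revcomp(motif), yields the
mirrored site list with bit-identical scores and p-values — hold exactly in
floating point. The quantization error is at most L·δ/2 (0.005 bits for a
10-bp motif), far below any decision threshold. `window_score` remains the
exact float sum for callers who want it.

**Strand handling.** A minus-strand hit at a forward window means the motif
matches the reverse complement of that window; it is scored via the
reverse-complement column bins, which is bin-for-bin identical to scoring
the reverse strand. Windows containing non-ACGT letters are skipped, never
scored — fabricating scores inside assembly gaps would be worse than missing
a site. Site coordinates are always reported on the promoter's forward axis
with start < stop.

**q-values.** Candidates are pre-filtered at p ≤ 1e-3 but significance is
judged against the full null set: all scored-window p-values in the
(motif, species) stratum. `q(p_i) = min over null p_j ≥ p_i of
π0 · m · p_j / rank(p_j)` with m and ranks over the full set. π0 defaults to
the Storey λ = 0.5 plug-in `(1 + #{p > λ})/((1 − λ)m)`, floored at 1/m and
capped at 1; an explicit `pi0=1.0` gives Benjamini–Hochberg. On realistic
window-level null sets the plug-in is ≈ 1 anyway, so the default is
conservative. Sites with q > 0.2 are discarded.

## Site cleaning

Within each (gene, TF family), sites sharing at least one base — on either
strand; occupancy is on the DNA duplex — form transitive overlap clusters,
each resolved to one site: longest first (a long site often covers several
short motifs), then smallest p-value, then a deterministic positional
tiebreak. Sites of different families never compete. The operation is
idempotent and order-independent. The overlap summary then reports, per
species and family, how many kept sites still overlap a kept site of a
*different* family.

## Region statistics

GC % is compositional: `100·(G+C)/(A+C+G+T)` with N excluded from numerator
and denominator (a promoter that is half gap still has a well-defined
composition). TFBS density is per retrieved sequence length, so Ns count in
its denominator. The GC table reports unweighted per-sequence mean and
sample sd (n−1) per (species, pathway, region class); singleton cells report
sd as NA. TFBS region sequences are the matched sequences of kept sites.

## Tajima's D

Gap handling is complete deletion: rows that are entirely gap/N are dropped,
then every column containing any gap or N is removed. S counts remaining
columns with ≥ 2 distinct bases; π is the mean pairwise difference count per
block (raw counts, not per site). The a1…e2 coefficients follow the standard
formulas, and `D = (π − S/a1)/sqrt(e1·S + e2·S·(S−1))`, undefined (NaN, not
an error) when S = 0 or the variance term vanishes (which also covers
n ≤ 3); the default minimum sample size is 4. The statistic is used
descriptively — to summarize binding-site variation within TF families and
divergence of TFBS vs CDS vs intron regions across ortholog groups — not for
demographic inference, so no significance thresholds are attached. The
region comparison reports per-class mean/min/max D and the ordering of
means only.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *structure* of the study inputs with known
truth:

- **Genomes/promoters** — i.i.d. bases at a chosen GC (0.32 Arabidopsis-like,
  0.44 cereal-like), genes alternating strand, every fifth gene closer than
  1 kb to its neighbour to exercise promoter truncation. Defaults: 1-kb
  promoters, 300-bp gene bodies, seed 42.
- **Planted sites** — consensus or matrix-sampled instances replacing the
  background at non-overlapping positions, strands Bernoulli(0.5), truth
  recorded as (gene, start, stop, strand, sequence).
- **Gap corruption** — a contiguous N run covering a chosen fraction of each
  promoter.
- **Coalescent blocks** — a hand-written Kingman coalescent (waiting times
  Exp(k(k−1)/2) in units of 2N generations, Poisson(θ/2·branch) mutations)
  with infinite-sites emulation by unique column assignment, so
  E[S] = θ·a1 exactly; blocks whose mutation count exceeds L are resampled
  with bounded retries.
- **Ortholog groups** — per-region ancestral sequences diverged independently
  per species at per-region rates (uniform choice among the 3 alternative
  bases), positional alignment, no indels. Rates r_TFBS > r_intron > r_CDS
  produce the divergence ordering the region comparison is meant to detect:
  with few species, low rates give singleton-dominated spectra (negative D)
  and higher rates push D upward, so mean D orders with the rate.

Real promoters are not i.i.d. (they have CpG structure, repeats, TATA
grammar), real motif instances are degenerate rather than consensus, and
real ortholog alignments contain indels and alignment error. Passing tests
therefore demonstrate the *machinery* — exactness of p-values, coordinate
bookkeeping, FDR control under the stated null, estimator fidelity — not
biological accuracy on any particular genome release.

## Numerical and design choices

- δ = 1e-3 bits score bins; per-column scores clamped at −100 bits.
- Similarity ties broken toward the forward orientation and smaller offset;
  dedup order as above; overlap-resolution ties by (start, '+', motif id).
- Problem sizes in the test and acceptance runs (200+200 promoters, 2000
  coalescent replicates, 200 ortholog groups, 100 oracle alignments) were
  chosen to put 3-SE bands well inside the asserted tolerances while keeping
  the suite quick to run.
- Pipeline configuration round-trips through YAML; the run manifest records
  per-stage input hashes, parameters and row counts, and identical
  (inputs, config, seed) reproduce identical site tables.

## Known limitations

- Only 0-order backgrounds (no higher-order Markov correction) and no
  position-specific priors.
- Greedy deduplication is order-canonical but not a globally optimal
  clustering.
- The q-value stratification (per motif × species) is one defensible choice
  among several; pooled alternatives would change borderline calls.
- Tajima's D is reported without confidence bounds, matching its
  descriptive use here.
- The coalescent generator has no recombination, indels or selection, and
  the ortholog generator no rate heterogeneity within a region.
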