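# Methods

This note documents the models behind each stage of `bacm6a`, the defaults
that matter, what the synthetic-data generator does and does not emulate, and
the numerical and design choices made where the design was genuinely open.

## Internal-reference correction of m⁶A/A ratios

Purified bacterial mRNA retains a residual rRNA fraction. Bacterial rRNA
carries both m⁶A (two 23S residues, RlmF and RlmJ substrates in *E. coli*)
and N⁶,N⁶-dimethyladenosine (m⁶₂A, two KsgA substrates on 16S rRNA), while
mRNA carries no m⁶₂A. The measured m⁶₂A quantity therefore traces the rRNA
residue, and given the rRNA-intrinsic ratio R = m⁶₂A/m⁶A, the rRNA-derived
m⁶A equals m⁶₂A/R. The corrected mRNA methylation level is

    m6A/A = (m6A_measured − m62A_measured / R) / A_measured.

Constants: R defaults to 1.30 (wild-type rRNA); deleting one of the two rRNA
m⁶A writers halves the rRNA m⁶A while leaving m⁶₂A unchanged, giving
R = 2.04 for *rlmF* or *rlmJ* single mutants. Both are exposed as
`WILD_TYPE_R` and `SINGLE_MUTANT_R`, with a per-strain override
(`ReferenceRatio`). A sample without detectable m⁶₂A (a *ksgA*-like strain)
cannot anchor the correction and is refused with a dedicated error.

Choices worth noting:

- A corrected value ≤ 0 means the entire m⁶A signal is attributable to the
  rRNA residue (over-correction within noise). It is clamped to 0 and
  flagged rather than propagated: negative molar ratios are unphysical.
- The denominator is the total measured adenosine, which still includes the
  rRNA adenosine residue. At ≤10% contamination this biases the ratio down
  by at most the contamination fraction; the generator defines its "true"
  ratio on the same denominator, so recovery is exact by construction and
  round-trip tests check the formula, not the residual-A approximation.
- Standard curves are ordinary least squares with a free intercept (not
  forced through the origin — the less restrictive choice), and negative
  back-calculated amounts are clamped to zero with a flag.
- Replicate summaries use the sample standard deviation (n−1), appropriate
  for the three-replicate designs typical of these measurements.

## Synthetic data generator

The generator defines the conditions under which the pipeline is validated:

- **Genome** — one linear chromosome; genes non-overlapping, ≥300 nt,
  alternating strand, with lengths (default 900–1500 nt) and intergenic gaps
  (default 100–300 nt) drawn uniformly; base composition i.i.d. at a given
  GC fraction (default 0.5). Circularity is ignored: peaks never wrap the
  origin.
- **Sites** — hexamer windows inside genes overwritten with a methylation
  motif (default `TGCCAG`, the DNA form of the UGCCAG consensus). Context
  labels are drawn multinomially from a (start, inside, end) mix whose
  default (0.15, 0.72, 0.13) matches the ORF-interior preference of
  bacterial m⁶A; "start"/"end" sites fall within 100 nt of the respective
  codon and "inside" sites more than 100 nt from both. Sites within one gene
  are kept ≥200 nt apart so planted peaks are individually resolvable at the
  default caller settings. On − strand genes the genomic window receives the
  reverse complement, so the transcript (sense) sequence reads the motif —
  required for the strand-aware motif analysis downstream.
- **Reads** — single-end fragments with normal lengths (default mean 30 nt,
  the short-fragment regime of photo-crosslinking-assisted m⁶A-seq, sd 5)
  truncated at 20 nt; starts uniform over gene bodies. IP fragments come
  from the same proposal with rejection: a fragment covering a planted site
  is always accepted, background fragments with probability
  1/enrichment_factor. IP reads inherit the gene strand (strand-specific
  library); input reads are unstranded. Default depth 50,000 fragments per
  library, default enrichment 10.
- **Nucleoside tables** — an adenosine pool split into mRNA and an rRNA
  residue (default 5% contamination); the rRNA contributes m⁶A (default
  0.01 per rRNA adenosine, the order of two modified residues per rRNA
  molecule) plus m⁶₂A at R times that; mRNA methylation contributes
  `true_m6a_ratio` of the total adenosine. Multiplicative Gaussian noise
  with a given CV (default 0 for exact round-trips; 5% is a realistic
  instrument-level choice for the noisy recovery checks).

Not emulated: sequencing errors and read identity (the caller is
coverage-based), paired ends, operon structure, transcription-level
variation between genes beyond uniform sampling, RNase T1 digestion bias
(the true post-digestion fragment-length law is unknown; the truncated
normal is a stand-in), and genomic repeats. Passing tests therefore show
correctness of the statistical machinery under idealized coverage, not
robustness to mappability artifacts or library-prep biases in real data.

## Peak calling

Model-free sliding-window scan: windows of 50 nt at 25-nt steps; the test
statistic is the IP fragment-start count k per window; the null is Poisson
with mean

    lambda = window · max(global input rate, window-scale input rate,
                          1 kb input rate, 10 kb input rate) · (ip_total/input_total)

floored at the genome-wide IP expectation `ip_total·window/genome_size`
(effective genome size default 6 Mb, a bacterial-genome scale). Windows with
upper-tail probability ≤ 1e-5 (raw, no multiple-testing correction — the
conventional cutoff for this assay) are merged when ≤30 nt apart; merged
intervals shorter than 23 nt (the assay's fragment resolution) are dropped.
The summit is the leftmost position of maximal IP depth (deterministic
tie-break); fold enrichment is IP summit depth over the scaled local input
depth.

The window-scale term in the maximum is essential on transcriptome-
restricted data: the 1 kb/10 kb averages include intergenic gaps and
underestimate the genic background (by ~18% under the default geometry),
which produced about 11 false peaks per null replicate. Including the
candidate region's own control count — as MACS's lambda-local also does —
brings the null to 0.2 false peaks per replicate over 20 seeds, with
planted-site recovery of 90–100% and ≤1 spurious peak at enrichment 10.

`call_peaks` consumes the IP and input read sets directly (the statistic is
a fragment-start count, which a per-position depth track cannot recover);
`build_coverage` remains the public primitive for depth tracks.

## Gene context and metagene profiles

Peaks are classified by their summit, the sharpest point estimate, so the
trichotomy is exhaustive and mutually exclusive (interval overlap would
not be). OverlapStart/OverlapEnd are ±100 nt windows around the start/stop
codon positions in genomic coordinates honoring strand. For genes short
enough that the windows overlap, the nearer codon wins and an exact tie
goes to OverlapStart. Assignment extends each gene by the same 100-nt flank;
summits claimed by two adjacent extensions go to the gene with the nearer
body, ties to the genomically upstream gene. Intergenic peaks are reported
but excluded from context fractions, which are computed in exact rational
arithmetic.

Metagene profiles map every gene onto fixed-width 5′ and 3′ flanks (100 nt)
plus a length-scaled body, each with 20 bins (binning granularity is a free
choice), oriented 5′→3′. Bin values are depth per nt divided by the track's
total fragments; genes contribute equally (per-transcript reading of the
density normalization — the alternative, weighting genes by expression, is
deliberately not used). Genes shorter than the bin count are skipped with a
warning.

## Motif enrichment

Peak sequences are extracted in the sense orientation of the assigned gene
(the IP library is stranded and m⁶A is a transcript mark; antisense matches
are not counted). Backgrounds are per-sequence letter permutations —
"scrambled" in its plainest reading — preserving mononucleotide composition
exactly; a dinucleotide-preserving shuffle is a recognized alternative that
is intentionally not the default.

The enrichment statistic for a hexamer is the number of peaks containing it
at least once. Only hexamers recurring in ≥2 peaks are examined, which is a
data-dependent selection: comparing each such hexamer against its own
per-k-mer shuffle distribution would be anti-conservative (every selected
k-mer already beat the null once). The p-value therefore uses the
Westfall–Young max-statistic null: the observed count is compared against
the per-shuffle maximum count over all k-mers, with the +1 correction so
p > 0. This is exact for the top-ranked k-mer and conservative below it;
under the null it is super-uniform, which the test suite checks directly.
BH q-values are computed across the tested k-mers, and ranking is by
(p, count descending, lexicographic).

The shuffle count defaults to 30,000: the attainable q for a single
strongly enriched hexamer is roughly m/(n_shuffles+1) with m ≈ 300 tested
hexamers, so this default resolves q below 0.01; ~15 s for a 20-peak set.

The consensus is built from the top-ranked k-mers within Hamming distance 1
of the best (no shifts — the motifs of interest are fixed-width hexamers),
weighted by peak counts; every base reaching 0.25 column frequency enters
the column's IUPAC code (GGTCAG + GGCCAG at equal weight → GGYCAG). A
low-weight member whose base misses the 0.25 cut would not match the
emitted code and is dropped from the member list, keeping the
members-match-consensus invariant, which the constructor asserts.

## Functional enrichment

One-sided Fisher exact test (hypergeometric upper tail, computed in
log-space via scipy) for over-representation only, with BH correction over
tested categories and k/K effect strings. The universe defaults to all
genes in the supplied map and is configurable — the "correct" background is
a genuine judgment call in any over-representation analysis. Categories
with fewer than two universe members have untestable margins and are
skipped. No EASE-style (k−1) deflation is applied.

## Numerical choices and problem sizes

- Poisson and hypergeometric tails delegate to `scipy.stats` survival
  functions; the test suite cross-checks both against independent
  brute-force oracles (forward series summation, exact rational
  enumeration) at 1e-9 relative tolerance over >500 parameter points.
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; every generator is byte-deterministic per seed.
- Validation problem sizes — 10 genes / 20 sites / 50,000 fragments per
  library for recovery and null calibration (20 replicates), 40 genes /
  100 sites for context-fraction estimation — were chosen so the full
  validation runs in well under a minute while leaving the binomial/
  multinomial error bands tight enough to be informative.

## Known limitations

- The caller has no duplicate filtering, fragment-shift model, broad-peak
  mode, or control-swap FDR; it reports raw Poisson p-values.
- The local-lambda schedule is a documented surrogate for MACS 2.0.0's,
  not a reimplementation of it; absolute p-values will differ from a MACS
  run on the same data.
- Motif p-values are empirical and floor at 1/(n_shuffles+1); reported
  motif fractions count degenerate-consensus matches, which is one of two
  defensible conventions (the other being exact-hexamer matches).
- The correction formula leaves the rRNA adenosine residue in the
  denominator (see above); at the ≤10% contamination this assay targets
  the effect is below the replicate noise.
- Enrichment results depend on the supplied category map and universe; no
  ontology structure or term hierarchy is modeled.
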