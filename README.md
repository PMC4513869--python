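# bacm6a

Tools for mapping and quantifying N⁶-methyladenosine (m⁶A) in bacterial mRNA.

m⁶A is the most abundant internal mRNA modification in eukaryotes, and it is
also present in bacterial messengers — but measuring it there is complicated by
the biology of bacterial RNA. Purified bacterial mRNA always retains a residue
of rRNA, and bacterial rRNA itself carries m⁶A (two residues on 23S rRNA,
installed by RlmF and RlmJ in *E. coli*), so a raw LC-MS/MS m⁶A/A ratio
overstates mRNA methylation. Bacterial transcripts also lack annotated UTRs, so
the eukaryotic 5′UTR/CDS/3′UTR metagene does not apply, and m⁶A-IP peak calling
must work on a dense, intronless transcriptome.

`bacm6a` implements the full analysis chain for this setting:

- **`ms_quant`** — nucleoside quantification from standard curves and the
  internal-reference correction. rRNA uniquely carries
  N⁶,N⁶-dimethyladenosine (m⁶₂A, installed by KsgA), absent from mRNA, so
  the measured m⁶₂A traces the rRNA residue. With the rRNA-intrinsic ratio
  R = m⁶₂A/m⁶A (1.30 wild type; 2.04 in *rlmF* or *rlmJ* single mutants),
  the corrected level is

  ```
  m⁶A/A = (m⁶A − m⁶₂A / R) / A
  ```

- **`peaks`** — a native IP-vs-input peak caller: sliding-window Poisson test
  against a depth-scaled local background (MACS-style "nomodel" local lambda),
  window merging, and summit calling, at a raw p ≤ 1e-5 cutoff with a 23-nt
  minimum peak length matching photo-crosslinking-assisted m⁶A-seq resolution.
- **`gene_context`** — peak-to-gene assignment, the Overlap Start / Inside /
  Overlap End trichotomy (±100 nt around the start and stop codons), and
  metagene density profiles over flank / scaled-body / flank coordinates.
- **`motif`** — hexamer enrichment of sense-strand peak sequences against
  composition-preserving scrambled backgrounds (Westfall–Young max-count
  null), IUPAC consensus building (e.g. GGYCAG), and consensus match
  fractions.
- **`enrichment`** — functional-category over-representation by one-sided
  Fisher exact test with BH correction, reporting k/K effect sizes.
- **`synthetic_data`** — a generator for genomes, planted methylation sites,
  IP/input read sets and nucleoside tables with known ground truth, so every
  stage is testable offline.

## Worked example

```python
from bacm6a import (generate_genome, plant_sites, simulate_reads,
                    simulate_nucleoside_table, call_peaks,
                    corrected_ratio, gene_context, motif, ms_quant)

# 1. contamination-corrected m6A/A quantification
ref = ms_quant.ReferenceRatio(R=1.30, source="wild-type")
table = simulate_nucleoside_table(true_m6a_ratio=0.002, rrna_contam_frac=0.08,
                                  cv=0.05, n_reps=3, seed=1)
for m in table:
    cr = corrected_ratio(m, ref)
    print(f"replicate {m.replicate}: raw m6A/A = {m.quantity_m6A/m.quantity_A:.2%}, "
          f"corrected = {cr.value:.3%}")

# 2. peak calling on a planted simulation
genome = generate_genome(n_genes=10, seed=1)
sites = plant_sites(genome, n_sites=20, seed=3)
ip, inp = simulate_reads(genome, sites, n_input_reads=50_000,
                         enrichment_factor=10.0, seed=5)
called = call_peaks(ip, inp)
for p in called:
    p.gene_id = gene_context.assign_gene(p, genome.genes)
    p.context = gene_context.classify_context(p, genome.gene(p.gene_id))
hit = sum(any(p.start <= s.position < p.end for p in called) for s in sites)
print(f"{len(called)} peaks, {hit}/{len(sites)} planted sites recovered")
p0 = called[0]
print(f"first peak: [{p0.start}, {p0.end}) summit={p0.summit} p={p0.p_value:.2e} "
      f"fold={p0.fold_enrichment:.1f} gene={p0.gene_id} context={p0.context}")
fs, fi, fe = gene_context.context_fractions([p.context for p in called])
print(f"context fractions: start={float(fs):.0%} inside={float(fi):.0%} end={float(fe):.0%}")

# 3. motif enrichment against scrambled backgrounds
seqs = motif.extract_sequences(called, genome.sequence, genome.genes)
ranked = motif.kmer_enrichment(seqs, motif.shuffle_background(seqs, seed=7))
cons = motif.build_consensus(ranked)
print(f"top hexamer: {ranked[0].kmer} in {ranked[0].obs_count}/{len(seqs)} peaks, "
      f"q = {ranked[0].q_value:.4f}")
print(f"consensus {cons.iupac}, matched by {motif.motif_fraction(seqs, cons):.0%} of peaks")
```

This prints:

```
replicate 1: raw m6A/A = 0.29%, corrected = 0.207%
replicate 2: raw m6A/A = 0.31%, corrected = 0.226%
replicate 3: raw m6A/A = 0.30%, corrected = 0.212%
20 peaks, 20/20 planted sites recovered
first peak: [200, 300) summit=270 p=6.38e-290 fold=8.5 gene=gene0001 context=Inside
context fractions: start=5% inside=85% end=10%
top hexamer: TGCCAG in 20/20 peaks, q = 0.0044
consensus TGCCAG, matched by 100% of peaks
```

The raw ratio of ~0.3% contains rRNA-derived m⁶A; subtracting m⁶₂A/1.30
recovers the planted 0.2% mRNA level. The caller finds every planted site, the
context split reflects the planted ORF-interior preference, and the planted
hexamer is recovered as the top-ranked, significantly enriched motif.

The same pipeline is available from the shell:

```sh
bacm6a simulate --n-genes 10 --n-sites 20 --depth 50000 --seed 1 --outdir sim/
bacm6a callpeaks --ip sim/ip.bed --input sim/input.bed \
    --genome sim/genome.fasta --gff sim/genes.gff3 --out peaks.bed
bacm6a motif --peaks peaks.bed --genome sim/genome.fasta --gff sim/genes.gff3 \
    --seed 1 --out motifs.tsv
bacm6a quantify --table nucleosides.tsv --r 1.30 --out ratios.tsv
bacm6a enrich --genes m6a_genes.txt --map categories.tsv --out enrichment.tsv
```

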