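# mycometer

A toolkit for **quantitative profiling of the gut mycobiome** — the fungal
fraction of a microbial community — and for the statistics that connect it
to the bacterial community and to habitual diet.

## The problem

Fungal communities are usually profiled by amplicon sequencing of the
**ITS** region (the internal transcribed spacer between the rRNA genes of
the rDNA tandem array). But the rDNA **copy number (CN)** varies enormously
between fungal species and even strains — tens to hundreds of copies — so
ITS read counts measure *abundance × CN*, not abundance. Shotgun sequencing
scored against **single-copy marker genes** does not carry this bias.
`mycometer` implements the computational workflow needed to demonstrate and
quantify this, end to end, plus the downstream community ecology:

- **CN-HMM** (`mycometer.rdna_hmm`) — ITS copy number from a genome
  assembly: profile HMMs are trained on alignments of the conserved LSU/SSU
  flanks (588 bp and 142 bp), both strands are scanned with a local Viterbi
  search, hits are E-value filtered (E ≤ 0.001), and LSU/SSU hits are paired
  into ITS loci when the inner gap — the ITS length — lies in 400–800 bp
  (average ≈ 550 bp). A hit whose partner window runs off a contig end
  still counts as one end-truncated copy.
- **CN-MD** (`mycometer.depthcn`) — ITS copy number from shotgun reads:
  CN = trimmed-mean ITS depth / *median* trimmed-mean single-copy-marker
  depth, with MAPQ ≥ 30 filtering and 50 bp end trimming. A minimal
  exact-seed ungapped aligner is included so no external mapper is needed.
- **Profiling & diversity** (`mycometer.profiler`) — mapping-depth
  taxonomic profiles with the depth ≥ 15 off-target filter, TMM
  normalization, observed/Shannon/Chao1 alpha diversity, Bray–Curtis,
  weighted UniFrac over a rank-lineage tree, rarefaction curves, the
  fungal-enrichment fold change, and a Stokes-law sedimentation calculator.
- **Mock-community benchmark** (`mycometer.mockbench`) — simulates both
  sequencing modes on communities with known composition and CN, and scores
  each against the truth with weighted UniFrac.
- **Inter-kingdom networks** (`mycometer.ecologynet`) — SparCC
  compositional correlations, permutation p-values, network deconvolution,
  random-matrix-theory thresholding, BH-FDR edge filtering, centralities,
  keystone selection (top-20 degree ∩ top-20 betweenness), power-law degree
  fits.
- **Diet statistics** (`mycometer.dietstat`) — residual-method energy
  adjustment, ICC(2,1) and exact paired Wilcoxon reproducibility, Spearman +
  BH association screens, longitudinal intra-/inter-individual dynamics.
- **Synthetic data** (`mycometer.simkit`) — genomes with planted rDNA
  arrays and ground truth, shotgun/amplicon read simulation, compositional
  count matrices with planted basis correlations, longitudinal diet tables.
  Everything the other modules consume can be generated here, deterministic
  per seed.

## Worked example

```python
from mycometer import simkit, rdna_hmm, depthcn

# a genome with 20 tandem ITS copies
spec = simkit.SyntheticGenomeSpec(
    contig_lengths=(90_000,),
    arrays=(simkit.ArraySpec(contig=0, start=8000, copy_number=20,
                             spacer_length=2000),),
    flank_divergence=0.02, marker_genes=(8, 1000), seed=7)
asm, truth = simkit.synthesize_genome(spec)

# CN-HMM: train flank profiles, scan, pair
lsu = rdna_hmm.build_profile(
    simkit.flank_training_alignment(truth.flank_templates[0], seed=1), "LSU")
ssu = rdna_hmm.build_profile(
    simkit.flank_training_alignment(truth.flank_templates[1], seed=2), "SSU")
res = rdna_hmm.cn_hmm_pipeline(asm, lsu, ssu)
print(res.copy_number)                      # -> 20

# CN-MD: simulate ~30x reads, map, take the depth ratio
reads = simkit.simulate_shotgun_reads(
    asm, simkit.ReadSimParams(n_reads=28_000, read_length=100,
                              substitution_error_rate=0.005, seed=3))
markers = {m[3]: asm.contigs[m[0]][m[1]:m[2]] for m in truth.marker_loci}
md = depthcn.cn_md_pipeline(reads, {"ITS": truth.its_sequence}, markers)
print(round(md.cn_md, 1))                   # -> 19.8
```

`res.copy_number` counts the planted loci found by flank pairing;
`md.cn_md` is the ITS depth over the median marker depth, i.e. how many
genome-equivalents of ITS the reads contain — both agree with the planted
truth of 20.

The same pipeline is scriptable from the shell:

```bash
mycometer simulate genome --copy-number 5 --seed 1 --out sim/
mycometer cn hmm --assembly sim/genome.fa --lsu sim/lsu_alignment.afa \
    --ssu sim/ssu_alignment.afa --out cn/
mycometer network --counts counts.tsv --kingdoms kingdoms.tsv --out net/
```

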