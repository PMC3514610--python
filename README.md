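# tetrabin

Two-step compositional binning of metagenomic contigs:

1. **Unsupervised priming.** Contigs are represented as 136-dimensional vectors
   of canonical tetranucleotide frequencies (each 4-mer merged with its reverse
   complement, normalized so the vector mean is 1). An empirically calibrated
   lookup table gives the expected dispersion of each frequency as a function of
   the source-genome mean and the fragment length; a multivariate Gaussian
   log-probability then scores contig-vs-bin membership. Contigs are greedily
   assigned from longest to shortest against log-probability thresholds
   calibrated to accept 90 / 95 / 98 % of same-genome fragments, and the whole
   pass is run once per confidence level.
2. **IMM rebinning.** Good seed bins (long, taxonomically consistent, even
   coverage) train interpolated Markov models; every contig is reassigned to
   the highest-scoring model.

Supporting machinery: BLAST-tabular taxonomic profiling of bins (500 bp
fragments, best hit per fragment, five-rank majority profiles), assembler-header
coverage parsing (`cov_…` / `numreads=` dialects), nucleotide-weighted
accuracy/recall evaluation, and a simulator that generates synthetic genomes,
communities, hit tables and lineages so the entire pipeline runs with no
external data.

## CLI

All functionality is exposed through one entry point:

```sh
# synthetic community with truth labels, hits and lineage
tetrabin simulate --genomes 3 --genome-length 1000000 --seed 1 --out data/

# calibrate dispersion + threshold tables from reference genomes
tetrabin calibrate --genomes data/genomes.fasta --seed 1 --out tables.tsv

# greedy tetranucleotide binning (one FASTA per bin + partition table)
tetrabin bin --contigs data/contigs.fasta --tables tables.tsv \
    --confidence all --out run

# taxonomic profiles per bin from BLAST outfmt-6 hits
tetrabin profile --contigs data/contigs.fasta --partition run.partition.tsv \
    --hits data/hits.tsv --lineage data/lineage.tsv --out profiles.tsv

# train IMMs on selected seed bins, then rebin everything
tetrabin imm-train --contigs data/contigs.fasta --partition run.partition.tsv \
    --bins 1,2,3 --out models/
tetrabin imm-bin --models models/ --contigs data/contigs.fasta --out imm.tsv

# evaluate against simulation truth; per-bin summary report
tetrabin evaluate --contigs data/contigs.fasta --partition run.partition.tsv \
    --truth data/truth.tsv --out eval.tsv
tetrabin report --contigs data/contigs.fasta --partition run.partition.tsv --out report.tsv
```

`tetrabin bin --force-assign` places short contigs that match no bin into the
best-scoring bin anyway (without updating the bin mean); by default they are
reported as unassigned.

## Package layout

| module        | contents                                                            |
|---------------|---------------------------------------------------------------------|
| `tetra`       | canonical 4-mer map, 136-dim frequency vectors                      |
| `calibration` | dispersion table σ = f(m, l), recall thresholds, log-probability    |
| `greedybin`   | greedy length-sorted binning, partition evaluation                  |
| `imm`         | interpolated Markov models: train / score / assign, seed-bin report |
| `taxprofile`  | contig fragmentation, hit filtering, five-rank profiles, cross-validation |
| `seqio`       | FASTA I/O, coverage parsing from assembler headers                  |
| `simulate`    | synthetic genomes, repeat libraries, communities, hit fixtures      |
| `cli`         | `tetrabin` command group                                            |
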