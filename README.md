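# consgen

Conservation-genetics toolkit for dual neutral/adaptive marker analyses
of small, fragmented fish populations: microsatellite diversity,
structure and demography on one side; MHC class IIβ amplicon
genotyping, positive-selection statistics and physicochemical supertype
classification on the other. Every analysis stage has a matching
synthetic-data generator, so the full pipeline is testable without any
external downloads.

## Layout

| Subpackage | Contents |
| --- | --- |
| `consgen.io_formats` | Genepop reader/writer (2- and 3-digit dialects), FASTA/FASTQ (Sanger), Structure input matrices, pairwise-table CSVs, flat key=value run configuration, logging |
| `consgen.synthetic_data` | forward Wright–Fisher microsatellite simulator (SMM/IAM/TPM mutation, migration, bottlenecks), amplicon read simulator (error, chimeras, dual indices), codon-alignment simulator with per-codon selection intensity |
| `consgen.msat_stats` | allelic richness (rarefaction), unbiased heterozygosity, F_IS, Markov-chain exact HWE and linkage tests, null-allele screen, Weir–Cockerham θ, R_ST, Nei G_ST, Mantel isolation-by-distance, principal coordinates, Bonferroni |
| `consgen.demography` | heterozygosity-excess bottleneck test (coalescent conditional on allele count), allele-frequency mode shift, M-ratio |
| `consgen.structure_model` | admixture-model Gibbs sampler (genotype or presence/absence input), Evanno delta-K |
| `consgen.mhc_genotyping` | quality filtering, draft mapping, dual-index demultiplexing with IUPAC-aware primer trimming, two-rule allele validation |
| `consgen.selection` | Nei–Gojobori dN/dS with Jukes–Cantor correction, codon-bootstrap Z-test, binding-site partitions, PHYLIP export |
| `consgen.supertyping` | five-dimensional z-scale descriptor matrices, cluster-number choice by validity-index majority vote, DAPC assignment |
| `consgen.mhc_popgen` | haplotype/nucleotide diversity, pairwise φ_ST with permutation tests, presence/absence Structure encoding |

## CLI

```sh
consgen simulate-msat --populations 3 --ne 200 --loci 10 \
    --sample-size 30 --generations 500 --seed 1 --out sim.gen
consgen summary sim.gen --out summary.csv
consgen fst sim.gen --permutations 1000 --seed 1 --out fst_rst.csv
consgen mratio sim.gen
consgen structure sim.gen --k-min 1 --k-max 5 --runs 3 \
    --burnin 2000 --generations 8000 --seed 1 --out q.csv
consgen dnds alleles.fasta --partition pbr
consgen supertype alleles.fasta --out supertypes.csv
```

All stochastic subcommands accept `--config cfg.txt` (flat `key =
value` pairs; see `consgen.io_formats.config` for the recognized keys
and defaults) and `--seed N`; a fixed seed reproduces identical output.

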