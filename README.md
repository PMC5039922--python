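# phaseai

Detection of subtle allelic imbalance (AI) — amplification, deletion and
copy-neutral LOH — from next-generation sequencing data, using allele-specific
read depths and statistically estimated germline haplotypes. The method is
designed for heterogeneous samples where the aberration is carried by only a
small fraction of cells, and requires no paired normal sample.

## How it works

1. **Input**: a VCF with `GT` and `AD` FORMAT fields (WES or WGS) and a phased
   VCF with the germline haplotype estimates for the same sites.
2. Heterozygous biallelic SNVs are filtered by depth and joined with the phase
   estimates; each site's reference-allele frequency (RAF) is compared against
   a genome-wide threshold (default: the median RAF).
3. The over-represented allele at each marker is assigned to a haplotype
   ("frequency-based phasing"), giving a per-marker concordance indicator.
4. A three-state hidden Markov model (balanced + two imbalance orientations,
   which absorb switch errors in the statistical phasing) produces per-site AI
   posterior probabilities; the emission parameter is self-calibrated by EM.
5. Output: a per-site posterior report (TSV) and called AI segments (BED),
   with an implied aberrant-cell fraction per event under a cn-LOH model.

A built-in simulator generates exome-like (80x, clustered ~1 het/3 kb) and
genome-like (30x, uniform ~1 het/1.5 kb) synthetic datasets with configurable
events, aberrant-cell fractions, overdispersion and haplotype switch errors,
so detection power can be measured end to end without any external data.

## CLI

```sh
# detect AI events
phaseai detect --vcf sample.vcf --phased-vcf phased.vcf --out-dir out/ \
    [--preset wes|wgs] [--min-depth 10] [--posterior-cut 0.9] [--em/--no-em] \
    [--config run_config.yaml]

# simulate a dataset (sample.vcf + phased.vcf + truth.tsv)
phaseai simulate --preset wes --region-length 100000000 \
    --event 45000001:55000000:cnloh:0.16 --seed 1 --out-dir sim/

# sensitivity grid over aberrant-cell fractions
phaseai power --preset wgs --event 45000001:55000000:cnloh:0.2 \
    --fractions 0.04,0.08,0.16 --replicates 20 --seed 1 --out-dir power/
```

Configuration precedence is CLI flags > YAML config (`--config`) > defaults;
the resolved configuration is written next to the outputs, and re-running it
reproduces the outputs byte-for-byte.

## Package layout

- `phaseai.vcf_io` — VCF/AD parsing, phase joining, TSV/BED writers
- `phaseai.raf_model` — RAF threshold, frequency-based phasing, phase concordance
- `phaseai.ai_hmm` — HMM posteriors, Viterbi, EM, event calling, fraction estimates
- `phaseai.simulator` — synthetic datasets and power-grid experiments
- `phaseai.cli` — `detect` / `simulate` / `power` subcommands
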