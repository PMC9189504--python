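# parscan

Toolkit for detecting sex-specific selection signals on young sex
chromosomes from phased pedigree data. The pipeline covers:

1. **synthetic_data** — pedigree-cross simulator: X/Y/sister-species
   haplotype panels over a chromosome with a non-recombining SDR and a
   recombining PAR, optional planted X–Y allele-frequency differentials,
   rendered to multi-sample VCF (GT:GQ:DP) with configurable genotyping
   error, missingness and depth overdispersion, plus exact truth tables.
2. **phasing** — variant filters (site QUAL ≥ 999, genotype GQ ≥ 20, site
   mean depth ≥ 10× and ≤ 1.5× the chromosome median, biallelic SNPs only)
   and trio-based recovery of paternal X (daughters) and Y (sons)
   haplotypes; sites missing phased calls in more than five offspring are
   dropped.
3. **windowed_popgen** — per-window Hudson F_ST (ratio of averages), π,
   between-group divergence K, Tajima's D, son/daughter read-depth ratio,
   neighbour-joining gene trees with an X|Y-bipartition ("XY consistency")
   test, change-point detection of the SDR/PAR boundary, and
   Nei–Gojobori dN/dS.
4. **permutation_scan** — per-window null from balanced X/Y label
   randomizations (p = proportion of relabellings with F_ST ≥ observed),
   Storey–Tibshirani q-values, significance at a configurable FDR.
5. **coalescent_sim** — structured coalescent for a PAR window linked to
   the SDR: Y-linked and X-linked pools (1/4 and 3/4 of 2N copies),
   male-meiosis migration (Y→X at r, X→Y at r/3), an instantaneous Y sweep
   when the neo-Y arose, population-size epochs, infinite-sites mutations;
   used to calibrate a familywise critical p-value.
6. **stats_utils** — exact binomial tails, independence products, and
   physical↔ρ distance conversion (ρ = 4·Ne·r).

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the statistical acceptance criteria
(50-seed power/null-calibration runs, 10⁴-replicate coalescent checks) and
takes a few minutes; the remaining files run in seconds.

## CLI

```bash
parscan simulate-data --out data/ --seed 1                  # synthetic crosses
parscan phase --vcf data/crosses.vcf --ped data/pedigree.tsv --out phased/
parscan stats --phased phased/phased_panel.tsv --out stats/
parscan scan --phased phased/phased_panel.tsv --out scan/ \
    --focal-start 7500000 --focal-end 11500000 --min-snps 10 \
    --n-perm 1000000 --fdr 0.2 --seed 1
parscan simulate --out sim/ --distances 1,10,40,60,460 --reps 1000 --seed 1
parscan calibrate --null-scans nulls.tsv --rate 0.2
parscan report --config pipeline.yaml                       # full pipeline
parscan prob product --rate 0.2 --k 4
parscan prob binomial-tail --n 178 --p 0.00061 --k 4
parscan prob rho --distance-bp 600000
```

`parscan report` runs synthesize → phase → stats → scan → simulate →
calibrate → compare end to end from one YAML config (see
`parscan.pipeline.default_config()` for the schema and desk-scale
defaults: 10⁴ permutations, 100 calibration simulations) and writes a
deterministic `summary.json` plus TSV/BED/VCF/Newick artifacts, all
stamped with the seed and a config hash.

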