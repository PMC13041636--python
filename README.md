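# vinekit

Toolkit for designing and exploiting a mid-density SNP genotyping array in
grapevine (*Vitis* spp.) and similar clonally propagated, highly
heterozygous crops. It covers the computational path around the wet lab
end to end:

1. **Array design** — filter a pool of resequencing-derived candidate
   variants (QUAL < 100, indels, multiallelic sites, per-sample depth < 8,
   > 20% missingness, strand-ambiguous A/T and C/G polymorphisms, variants
   within 35 nt of a neighbour), then fill per-(species, chromosome)
   quotas: 130 SNPs per chromosome for *V. vinifera*, 40 per chromosome
   for each wild species, plus a 60-SNP bonus pool on chromosomes carrying
   known disease-resistance (R) loci.
2. **Genotype curation** — sample QC (call rate ≥ 0.85, observed
   heterozygosity), marker QC (call rate, allele-count MAF, monomorphy),
   and iterative exclusion of markers with > 3% Mendelian segregation
   error across confirmed parent–offspring relationships.
3. **Pedigree inference** — duplicate/clone detection by call discordance,
   parent–offspring (duo) and parent-pair–offspring (trio) discovery from
   Mendelian incompatibilities, and a relationship-class PCA on the four
   pairwise statistics with unknown pairs projected as supplementary
   individuals.
4. **Diversity & concordance** — per-species heterozygosity summaries
   (ascertainment bias made visible), genotype PCA on 0/1/2 dosages, and
   het/hom concordance between two genotyping platforms.
5. **Chlorotypes** — plastid haplotype assignment from a handful of
   chloroplast SNPs and maternal-lineage confirmation/exclusion for every
   pedigreed offspring.
6. **Trait markers** — a declarative rule engine scoring trait-predictive
   markers (flower sex, seedlessness, OIV-225 berry colour, muscat taste,
   methoxypyrazine marker haplotypes) against observed phenotypes.

Every stage is exercisable without any external data: the `simulate`
module generates multi-species panels with planted ground truth
(Balding–Nichols population structure, Mendelian transmission over a
two-generation breeding pedigree, genotyping error, missingness, somatic
duplicates, maternally inherited chlorotypes, fully penetrant trait loci)
so that each analysis can be validated by parameter recovery.

## The statistics at the core

For samples $a,b$ with diploid calls at $n$ markers called in both, the
pairwise screen uses opposing homozygotes and directional heterozygous
mismatches:

- `duo_errors_perc` $= 100 \cdot \#\{AA \leftrightarrow BB\} / n$ — a true
  parent–offspring pair shares one allele at every locus, so this is ~0 up
  to genotyping error;
- `het_mismatch_A1A2`, `het_mismatch_A2A1` — markers where one sample is
  AB and the other homozygous, in each direction;
- `perc_mismatches` — both directional counts as a percentage of $n$.

A trio (offspring $o$; parents $p_1, p_2$) is incompatible at a marker iff
$o$ cannot be assembled from one allele of each parent (e.g. $o = AA$ with
any parent $BB$). Candidate pairs are screened at a duo-error threshold
that is relaxed to the maximum error observed among pedigree-known pairs,
so that every expected true relationship is retained; markers with > 3%
pooled incompatibility across confirmed duos/trios are then removed, and
the loop repeats to a fixed point.

## Worked example

Simulate the default 120-sample, ~5,000-marker breeding panel and run the
kinship stage (plastid markers are excluded from biparental checks):

```bash
vinekit simulate --seed 2 --out demo --with-vcf
vinekit kinship --genotypes demo/genotypes.tsv --pedigree demo/pedigree.csv \
                --markers demo/markers.csv --out demo/kin
# -> 152 candidate PO duos, 76 candidate PPO trios (threshold 0.50%),
#    2 duplicate pairs, 125 markers removed
```

The two reported duplicate pairs are the planted somatic variants (six
discordant calls each, the signature of a bud sport); the 152/76
candidates are exactly the planted parent–offspring relations; the ~125
removed markers are dominated by the 100 planted failing probesets, with
clean-marker loss below 1%.

```bash
vinekit chlorotype --genotypes demo/genotypes.tsv --markers demo/markers.csv \
                   --pedigree demo/pedigree.csv --out demo/chl
# -> 3 types; verdicts: inconclusive=46, confirmed=30
```

Three plastid haplotypes segregate in this panel; maternity is confirmed
wherever the two parents carry different chlorotypes (30 offspring) and is
undecidable when they share one (46) — no true mother is ever excluded.

```bash
vinekit design --vcf demo/candidates.vcf --r-loci chr12,chr14,chr18 --out demo/design
# -> kept 31350 / rejected 6650 candidates; selected 5690 markers
```

5,690 = 19 chromosomes × 130 vinifera + 4 wild species × 19 × 40 + 3
R-locus chromosomes × 60.

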