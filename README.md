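# hybstand

Genotype analysis for two-species poplar hybrid stands: diagnostic-SNP
classification of individuals into pure and hybrid classes, pedigree-aware
paternal-gamete inference, hybridization/introgression rate estimation, and
a Mendelian segregation simulator that quantifies marker-panel
misclassification risk.

## The problem

Balsam poplar (*Populus balsamifera*, **B**) and eastern cottonwood
(*P. deltoides*, **D**) meet in a narrow zone of sympatry where they form
F1 hybrids and advanced-generation backcrosses.  Surveys of such stands
genotype adults, seed lots from known mothers, and naturally regenerated
seedlings on a panel of unlinked SNPs with **fixed** allelic differences
between the species, then ask:

* which genotype class is each individual — pure B, pure D, F1, F2-type,
  or a backcross (BC-B / BC-D) — and are any carrying alleles of
  non-native (exotic) poplars?
* which pollen fathered each seed?  With the mother's genotype known,
  *haplotype subtraction* removes the maternal allele(s) at each locus,
  leaving the paternal gamete.
* how often do pure mothers produce hybrid seed (the spontaneous
  hybridization rate, hybrids / seeds examined), and in which direction
  does introgression run?
* how often would the panel *mis*-score a seed — e.g. a backcross seed
  whose hybrid parent transmitted the same species' allele at every
  heterozygous locus looks pure, with probability (1/2)^h over h
  heterozygous parental loci?

`hybstand` implements this pipeline with a synthetic-stand generator in
place of field data: Mendelian transmission at unlinked loci, maternal
chloroplast inheritance, per-call missingness and allelic dropout
(heterozygote scored as a random constituent homozygote), with every
generated stand carrying a ground-truth table.

## Worked example

Type 698 seeds from 14 mothers (a deterministic cohort shaped like a
surveyed natural stand), infer each seed's cross, and estimate rates:

```python
from hybstand import (
    default_interspecific_panel, reference_seed_cohort, infer_crosses,
    spontaneous_hybridization_rate, cross_composition, HYBRID_CLASSES,
)

panel = default_interspecific_panel()          # 35 diagnostic SNPs, alleles b/d
mothers, seeds = reference_seed_cohort(panel)  # 14 mothers, 698 seeds
crosses = infer_crosses(seeds, mothers, panel)

hyb = spontaneous_hybridization_rate(crosses)
for row in hyb.rows:
    print(f"{row.group} mothers: {row.numerator}/{row.denominator} hybrid seeds = {row.percent()}%")

print(cross_composition(crosses, HYBRID_CLASSES).to_frame()[["group", "numerator", "percent"]])
```

```
B mothers: 1/139 hybrid seeds = 0.7%
D mothers: 3/234 hybrid seeds = 1.3%
      group  numerator  percent
0   BC_to_B        255     78.5
1   BC_to_D         60     18.5
2  F2_cross         10      3.1
```

Reading the output: pure D mothers hybridize slightly more often than
pure B mothers (1.3% vs 0.7% of their seeds), while among hybrid
mothers most reproductive events are backcrosses toward B (78.5%) —
F1 formation runs through D seed parents, but subsequent introgression
is biased toward B.

The same steps are available from a shell:

```bash
hybstand classify --panel panel.yaml --genotypes seeds.csv --out classes.csv
hybstand pedigree --panel panel.yaml --genotypes seeds.csv --mothers adults.csv --out crosses.csv
hybstand rates    --crosses crosses.csv --out rates.csv
hybstand simulate --seed 4 --out-dir sim/      # synthetic stand + truth table
hybstand power    --reps 100000 --out power.csv
```

See `docs/methods.md` for the model, its assumptions, the closed-form
misclassification probabilities and the design choices.

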