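# Methods

`hybstand` analyses genotype data from a mixed stand of balsam poplar
(*Populus balsamifera*, species code **B**), eastern cottonwood
(*P. deltoides*, **D**) and their natural hybrids.  This note documents
the models and procedures, the parameters that matter, what the
synthetic-data generator does and does not emulate, and the numerical
and design choices made where the design was genuinely open.

## Diagnostic-marker classification

The classifier assumes a panel of unlinked biallelic SNPs with *fixed*
allelic differences between the two species: every B chromosome carries
the B-diagnostic allele, every D chromosome the D-diagnostic allele.
Under that assumption the per-locus state (`HOM_B`, `HET`, `HOM_D`) of a
diploid individual is a direct readout of its ancestry at that locus,
and the multiset of states over the panel determines the genotype class
deterministically:

| observed states (non-missing)      | class |
|------------------------------------|-------|
| only `HOM_B`                       | B     |
| only `HOM_D`                       | D     |
| only `HET`                         | F1    |
| `HET` + `HOM_B`                    | BC-B  |
| `HET` + `HOM_D`                    | BC-D  |
| `HOM_B` + `HOM_D` (± `HET`)        | F2    |

Three deliberate choices:

* **Exotic screen first.**  Any allele matching neither native species'
  diagnostic allele marks the individual `EXOTIC` (ancestry from a
  non-native poplar such as *P. nigra* or *P. maximowiczii*) and it is
  excluded from native classification.  In mixed urban stands this
  screen must run before anything else, because exotic hybrids would
  otherwise masquerade as native classes.
* **No discordance tolerance.**  Because the markers are fixed
  differences, a single discordant locus is real information, not noise
  to be smoothed over.  Genotyping error is quantified separately by
  the power module rather than absorbed by a fuzzy classifier; softening
  the rule would silently change every downstream rate.
* **F2 is a consistency class, not a generation.**  Fixed markers
  cannot separate F2 from F3, three-way backcrosses or other advanced
  generations; any profile with both homozygote states is labelled F2
  and flagged `F2_CONSISTENT`.

`min_informative` (default 5 loci) is the floor below which a record is
`UNRESOLVED` rather than classified.  The genotyping QC removes
individuals with more than 10 missing loci of 35, but that still admits
records with as few as 25 informative loci; the separate floor exists
so that heavily missing records from other sources cannot be classified
from one or two loci.  Five loci bound the pure/backcross collision
probability at (1/2)^5 ≈ 3% per seed, acceptable for flag-assisted
review; the value is a package choice, adjustable per call.

Pure classifications additionally carry an `ALL_HOM_AMBIGUOUS` flag: an
all-homozygous profile is also what a backcross seed looks like when its
hybrid parent transmitted the same species' allele at every
heterozygous locus (probability (1/2)^h, h = parental het loci).  The
flag makes that residual ambiguity visible in output tables.

Maternal lineage is read directly from the chloroplast haplotype label
(cpDNA is maternally inherited in poplars); the package treats the
haplotype as an input label and does not model the RFLP assay behind it.

## Missingness QC and call-rate accounting

Call-rate accounting is exact integer arithmetic: total calls are
`n_individuals × n_loci`, a success rate is `(total − missing)/total`,
and percentages are rounded half-up to one decimal only at report time.
The QC rule removes individuals with strictly more than `max_missing`
(default 10) missing loci; the retained set is monotone non-shrinking in
the threshold and missing-call counts are conserved across the
partition — both are property-tested.

## Haplotype subtraction

For a seed with a known mother, the paternal gamete is inferred per
locus by removing the maternal contribution:

* mother homozygous `x/x`: seed `x/x` → paternal `x`; seed het
  containing `x` → paternal is the other allele; otherwise the locus is
  a **Mendelian exclusion** (inconsistent).
* mother heterozygous: seed homozygous `p/p` with `p` maternal →
  paternal `p`; seed het equal to the mother → **ambiguous** (both
  transmissions explain the data); a seed het sharing one maternal
  allele → the non-maternal allele is paternal.
* either call missing → missing.

Ambiguity is *exactly* the mother-het × seed-het case, which is why
subtraction is most informative for seeds of homozygous (pure) mothers
and progressively less so for hybrid mothers.  Inconsistent loci do not
abort inference: they are reported, excluded from gamete typing, and
more than 2 of them flags the trio `DUBIOUS_MATERNITY` (the recorded
maternity is then suspect — mislabelled catkin lots are the usual field
cause).  The paternal gamete is typed `B_gamete` / `D_gamete` /
`hybrid_gamete` by the species of its unambiguous alleles, with the same
5-locus floor before a type is asserted.

## Cross typing and rates

Each seed becomes a cross record from (maternal class, offspring class,
paternal gamete class).  Pure mothers are typed from the offspring class
alone — a D mother with an F1 seed is an F1-formation event; a B mother
with a BC-B seed received hybrid pollen.  Hybrid mothers are typed from
the gamete: a B gamete is a backcross toward B, a D gamete toward D, a
hybrid gamete an F2-type cross.  The rule table is deliberately
symmetric in the two species even where the motivating survey only
observed one direction (e.g. an F1 seed from a *B* mother is
F1-formation, although none occurred in the data the defaults emulate):
the event is biologically well-defined and a classifier that returned
`OTHER` for it would miscount hybridization in B-dominant stands.
Combinations no rule covers are `OTHER` with an `UNMATCHED_COMBINATION`
flag rather than an error, because single-locus typing errors can
produce them in real data.

The spontaneous hybridization rate is hybrid seeds over genotyped seeds
per pure maternal species.  `UNRESOLVED` seeds are excluded from
denominators and surfaced in a `dropped` count — rates are computed on
the final, classifiable data set.  Composition tables partition the
selected seeds by cross type; intraspecific crosses are pooled by
default.  Exact Clopper–Pearson intervals are available on every rate
row.  All percentages print half-up at one decimal.

## Clone and half-sib detection

Two records are clone-identical on an intraspecific panel iff they agree
at every locus where both are called *and* share at least `min_shared`
(default 20) called loci — the floor prevents two sparsely typed records
from matching vacuously.  Half-sib candidates are pairs identical on
exactly one of the two intraspecific panels; the output names the shared
*side* (B-lineage or D-lineage parent) without asserting which sex that
parent was, because the genotypes alone cannot prove it.  Note that
panel-wide identity is a strong criterion: it detects clones reliably,
and flags "half-sibs" only in the special situation (shared parent of
low heterozygosity, matching transmissions) the field survey that
motivated the operation encountered.  The implementation is
pairwise over all records and is tested for exact agreement with an
independently written brute-force oracle.

## Synthetic-stand generator

The generator emulates the study system: unlinked loci, Mendelian
transmission (each parent passes one allele per locus, independent
across loci), fixed diagnostic differences, maternal cpDNA, and two
genotyping-error processes — per-call missingness and symmetric allelic
dropout (a heterozygote scored as a homozygote for a uniformly chosen
constituent allele).  Defaults are the conditions of the motivating
stand:

| parameter | default | meaning |
|---|---|---|
| `n_loci` | 35 | diagnostic panel length |
| `n_adults` | 125 | adult cohort; classes 77.6% D, 10.4% B, 10.4% F1, 1.6% BC-B |
| `crosses` | 698 seeds | Table-shaped list: 231 D×D, 3 D×B, 138 B×B, 1 B×F1, 255 F1×B, 60 F1×D, 10 F1×F1 |
| `n_seedlings` | 73 | 62 B / 11 D, no hybrids |
| `missing_rate` | 0.004 | adult/seed per-call failure rate of the assay |
| `dropout_rate` | 0.0 | error processes are opt-in knobs |
| `rng_seed` | 0 | one seeded generator threads through everything |

BC and F2 *parent* genotypes are drawn from their generating crosses
(each locus het with probability 1/2, or segregating 1:2:1), so
multi-generation structure is respected one generation back.  Hybrid
individuals simulated without an explicit mother receive a D-type
chloroplast, matching the observed one-way direction of F1 formation in
this system (D seed parents).  Truth tables record every individual's
generating class and every seed's parents, transmitted paternal
haplotype, gamete class and cross type, so downstream tests are
self-validating.

What the generator does **not** emulate: linkage (the panel is stated
unlinked; no map option), intraspecific allele-frequency structure at
the diagnostic loci (fixed differences are assumed exact), spatial
pollen dispersal, selection between life stages, and multi-generation
forward dynamics.  Passing tests therefore demonstrate correctness of
the inference pipeline under its own model assumptions, not robustness
to marker panels with imperfectly fixed differences.

Truth labels are *nominal* generating classes.  A cross can, with
computable probability, produce a seed whose realized genotype belongs
to another class — e.g. an F1×F1 seed drawing no `HOM_D` locus at all
(probability (3/4)^35 ≈ 4×10⁻⁵ per seed, both sides ≈ 9×10⁻⁵) is
genuinely indistinguishable from BC-B.  At the default stand size the
expected number of such collisions is ≈10⁻³ per stand, so error-free
recovery tests assert 100% agreement and will fail with that
probability; this is the information limit of the markers, not a defect.

## Panel power and the pure-scored-seed anomaly

`misclassification_power` simulates seeds for each parent-class pair,
applies the error processes, classifies with the vectorized
state-matrix classifier (bridge-tested against the per-record rules),
and tabulates a true-cross × assigned-class confusion matrix with
Monte-Carlo standard errors.  Closed forms are overlaid where they
exist, for k unlinked loci, dropout e, missingness m, informative floor
t:

* **Backcross seed scored recurrent-pure** (F1 mother × pure father):
  per maternal-het locus the seed ends recurrent-homozygous with
  probability (1 + e/2)/2, so error-free the collision is (1/2)^h.
  With missingness, P = Σ_{j≤k−t} C(k,j) m^j ((1−m)(1+e/2)/2)^{k−j}.
* **F1 seed scored pure (either side)**:
  P = 2 Σ_{j≤k−t} C(k,j) m^j ((1−m) e/2)^{k−j}.

Both expressions are verified against an exact enumeration oracle (all
state vectors at k = 5, probabilities multiplied through the per-locus
distribution, the real classifier run on each vector) and against
Monte-Carlo simulation within 3 SE.

The motivating survey observed a handful of hybrid-mother seeds scored
as pure because every typed SNP was homozygous.  The closed forms show
what it takes: at k = 35 informative loci the probability is ~10⁻¹⁰
even at 5% dropout — far too small to observe.  The anomaly becomes
likely only when few informative loci survive (heavy missingness, small
k), which is why the package tests it quantitatively at small k where
Monte-Carlo can see it, and analytically (positive, monotone in e,
vanishing as e → 0 toward the (1/2)^h segregation floor) at k = 35.
The simulator exposes missingness and dropout as independent knobs
rather than fixing their relative contribution, which the source data
cannot identify.

## Numerical conventions

* Percentages: half-up rounding (`Decimal`), one decimal for rates,
  nearest integer for stand shares, applied only at report time.
* Genotypes: unordered pairs, serialized with alleles sorted
  lexicographically; `NA` (CSV) / `./.` (VCF) for missing; a one-allele
  call is treated as fully missing (conservative: half a call cannot
  distinguish het from hom).
* RNG: one `numpy.random.Generator` seeded from the config threads
  through every stochastic operation; identical seeds give bit-identical
  stands and confusion matrices.
* Degenerate inputs: empty cohorts are errors for summaries and
  compositions; zero-denominator rate rows are flagged `UNDEFINED`
  rather than NaN; an exotic parent in a simulated cross is an error.

## Problem sizes used in the shipped checks

The end-to-end recovery check runs a 1.5×-scaled stand (≈1,050 seeds,
≈1,250 individuals); Monte-Carlo/analytic agreement uses 10⁵ replicates
per panel size at k ∈ {5, 12, 35}; the rate-estimator coverage check
uses 200 replicate stands of 400 seeds.  These sizes give standard
errors an order of magnitude below the asserted tolerances while keeping
the default suite fast.

## Known limitations

* Everything downstream of classification inherits the fixed-difference
  assumption; panels with residual shared polymorphism need a different
  (likelihood-based) classifier, which is out of scope here.
* Paternity is typed to gamete species, not assigned to candidate
  fathers; no pollen-dispersal or paternity-share modelling.
* Bayesian admixture assignment (Structure/NewHybrids-style) is not
  reimplemented; the deterministic rule is a formalization of manual
  fixed-marker reading.
* Half-sib detection implements the identity-based operational
  definition discussed above, which is narrower than genealogical
  half-sibship.
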