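"""Synthetic hybrid-stand generator and Mendelian segregation simulator.

The generator emulates the study system this package was built for: a
naturally regenerated stand of balsam poplar (B), eastern cottonwood (D)
and their hybrids, screened with a panel of unlinked species-diagnostic
SNPs.  Each parent transmits one allele per locus independently across
loci (all loci unlinked); pure parents transmit their fixed diagnostic
allele; chloroplast haplotypes are copied from the mother.  Two error
processes can be layered on the clean genotypes: per-call missingness
and allelic dropout (a heterozygote scored as a random constituent
homozygote).

Default parameters are the observed conditions of the motivating stand:
125 adults (77.6% D, 10.4% B, 10.4% F1, 1.6% BC-B), a 698-seed cross
list shaped like its seed survey, 73 seedlings (62 B / 11 D), a 0.4%
per-call missing rate for adult/seed tissue, and no dropout unless
requested.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .classify import (
    CLASS_CODE,
    GenotypeClass,
    HYBRID_CLASSES,
    LocusState,
    NATIVE_CLASSES,
)
from .genotypes import CpHaplotype, GenotypeRecord, Sex, Stage, make_call
from .panel import MarkerPanel, SPECIES_B, SPECIES_D, default_interspecific_panel
from .pedigree import CrossType, GameteClass, classify_cross

__all__ = [
    "CrossSpec",
    "SimConfig",
    "Stand",
    "SeedSimResult",
    "make_individual",
    "simulate_cross",
    "apply_error",
    "generate_stand",
    "reference_stand_config",
    "nominal_offspring_class",
    "gamete_species_class",
    "draw_genotype_codes",
    "transmit_codes",
    "simulate_seed_codes",
    "apply_error_codes",
    "callrate_reference_cohort",
    "reference_adult_cohort",
    "reference_seedling_cohort",
    "reference_seed_cohort",
    "simulate_intraspecific_genotype",
]


# ---------------------------------------------------------------------------
# configuration

@dataclass
class CrossSpec:
    mother_class: GenotypeClass
    father_class: GenotypeClass
    n_seeds: int


def _default_class_frequencies() -> Dict[GenotypeClass, float]:
    return {
        GenotypeClass.D: 0.776,
        GenotypeClass.B: 0.104,
        GenotypeClass.F1: 0.104,
        GenotypeClass.BC_B: 0.016,
    }


def _default_crosses() -> List[CrossSpec]:
    B, D, F1 = GenotypeClass.B, GenotypeClass.D, GenotypeClass.F1
    return [
        CrossSpec(D, D, 231),
        CrossSpec(D, B, 3),
        CrossSpec(B, B, 138),
        CrossSpec(B, F1, 1),
        CrossSpec(F1, B, 255),
        CrossSpec(F1, D, 60),
        CrossSpec(F1, F1, 10),
    ]


def _default_seedling_frequencies() -> Dict[GenotypeClass, float]:
    return {GenotypeClass.B: 62 / 73, GenotypeClass.D: 11 / 73}


@dataclass
class SimConfig:
    """Synthetic-stand parameters.  Identical seed implies identical output."""

    n_loci: int = 35
    n_adults: int = 125
    class_frequencies: Dict[GenotypeClass, float] = field(
        default_factory=_default_class_frequencies
    )
    crosses: List[CrossSpec] = field(default_factory=_default_crosses)
    n_seedlings: int = 73
    seedling_class_frequencies: Dict[GenotypeClass, float] = field(
        default_factory=_default_seedling_frequencies
    )
    missing_rate: float = 0.004
    dropout_rate: float = 0.0
    rng_seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_loci < 1:
            problems.append("n_loci must be >= 1")
        if self.n_adults < 0 or self.n_seedlings < 0:
            problems.append("cohort sizes must be >= 0")
        for name, freqs in (
            ("class_frequencies", self.class_frequencies),
            ("seedling_class_frequencies", self.seedling_class_frequencies),
        ):
            if freqs and abs(sum(freqs.values()) - 1.0) > 1e-9:
                problems.append(f"{name} must sum to 1")
            if any(v < 0 for v in freqs.values()):
                problems.append(f"{name} must be non-negative")
        for name, rate in (("missing_rate", self.missing_rate), ("dropout_rate", self.dropout_rate)):
            if not 0.0 <= rate <= 1.0:
                problems.append(f"{name} must be in [0, 1]")
        for spec in self.crosses:
            if spec.n_seeds < 0:
                problems.append("cross n_seeds must be >= 0")
            for cls in (spec.mother_class, spec.father_class):
                if cls not in NATIVE_CLASSES:
                    problems.append(f"cross parent class {cls.value} is not native")
        if problems:
            raise ValueError("invalid SimConfig: " + "; ".join(problems))

    def to_yaml(self, path: Union[str, Path]) -> None:
        data = {
            "n_loci": self.n_loci,
            "n_adults": self.n_adults,
            "class_frequencies": {c.value: f for c, f in self.class_frequencies.items()},
            "crosses": [
                {"mother": s.mother_class.value, "father": s.father_class.value, "n_seeds": s.n_seeds}
                for s in self.crosses
            ],
            "n_seedlings": self.n_seedlings,
            "seedling_class_frequencies": {
                c.value: f for c, f in self.seedling_class_frequencies.items()
            },
            "missing_rate": self.missing_rate,
            "dropout_rate": self.dropout_rate,
            "rng_seed": self.rng_seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        config = cls(
            n_loci=data.get("n_loci", 35),
            n_adults=data.get("n_adults", 125),
            class_frequencies={
                GenotypeClass(k): float(v)
                for k, v in data.get("class_frequencies", {}).items()
            } or _default_class_frequencies(),
            crosses=[
                CrossSpec(GenotypeClass(s["mother"]), GenotypeClass(s["father"]), int(s["n_seeds"]))
                for s in data.get("crosses", [])
            ] or _default_crosses(),
            n_seedlings=data.get("n_seedlings", 73),
            seedling_class_frequencies={
                GenotypeClass(k): float(v)
                for k, v in data.get("seedling_class_frequencies", {}).items()
            } or _default_seedling_frequencies(),
            missing_rate=float(data.get("missing_rate", 0.004)),
            dropout_rate=float(data.get("dropout_rate", 0.0)),
            rng_seed=int(data.get("rng_seed", 0)),
        )
        config.validate()
        return config


def reference_stand_config(
    rng_seed: int = 0,
    seed_scale: float = 1.0,
    missing_rate: float = 0.004,
    dropout_rate: float = 0.0,
) -> SimConfig:
    """The default study-shaped configuration, with the cross list optionally
    scaled by ``seed_scale`` (per-cross counts rounded to nearest integer)."""
    config = SimConfig(rng_seed=rng_seed, missing_rate=missing_rate, dropout_rate=dropout_rate)
    if seed_scale != 1.0:
        config.crosses = [
            CrossSpec(s.mother_class, s.father_class, int(round(s.n_seeds * seed_scale)))
            for s in config.crosses
        ]
    config.validate()
    return config


# ---------------------------------------------------------------------------
# record-based simulation

def _default_cp(cls: GenotypeClass) -> CpHaplotype:
    """Maternal lineages as observed in the stand: hybrids all carry D cpDNA
    (F1 formation runs through D seed parents)."""
    if cls is GenotypeClass.B:
        return CpHaplotype.B_TYPE
    return CpHaplotype.D_TYPE


def _class_calls(
    cls: GenotypeClass, panel: MarkerPanel, rng: np.random.Generator
) -> Dict[str, tuple]:
    """Draw an interspecific-panel genotype for a class.

    B, D and F1 genotypes are deterministic under fixed markers; BC and
    F2 genotypes segregate (each hybrid parent transmits b or d with
    probability 1/2 per locus, independently — all loci unlinked).
    """
    calls: Dict[str, tuple] = {}
    for locus in panel:
        b = locus.diagnostic_allele(SPECIES_B)
        d = locus.diagnostic_allele(SPECIES_D)
        if cls is GenotypeClass.B:
            calls[locus.locus_id] = make_call(b, b)
        elif cls is GenotypeClass.D:
            calls[locus.locus_id] = make_call(d, d)
        elif cls is GenotypeClass.F1:
            calls[locus.locus_id] = make_call(b, d)
        elif cls is GenotypeClass.BC_B:
            hybrid_allele = b if rng.integers(2) == 0 else d
            calls[locus.locus_id] = make_call(hybrid_allele, b)
        elif cls is GenotypeClass.BC_D:
            hybrid_allele = b if rng.integers(2) == 0 else d
            calls[locus.locus_id] = make_call(hybrid_allele, d)
        elif cls is GenotypeClass.F2:
            a1 = b if rng.integers(2) == 0 else d
            a2 = b if rng.integers(2) == 0 else d
            calls[locus.locus_id] = make_call(a1, a2)
        else:
            raise ValueError(f"cannot simulate genotype for class {cls.value}")
    return calls


def make_individual(
    cls: GenotypeClass,
    panel: MarkerPanel,
    rng: np.random.Generator,
    individual_id: str,
    stage: Stage = Stage.ADULT,
    sex: Sex = Sex.UNKNOWN,
    mother_id: Optional[str] = None,
    cp_haplotype: Optional[CpHaplotype] = None,
) -> GenotypeRecord:
    """Simulate one error-free individual of a native genotype class."""
    return GenotypeRecord(
        individual_id=individual_id,
        stage=stage,
        sex=sex,
        mother_id=mother_id,
        cp_haplotype=cp_haplotype if cp_haplotype is not None else _default_cp(cls),
        calls=_class_calls(cls, panel, rng),
    )


@dataclass
class SeedSimResult:
    seed: GenotypeRecord
    maternal_gamete: Tuple[str, ...]
    paternal_gamete: Tuple[str, ...]


def simulate_cross(
    mother: Union[GenotypeRecord, GenotypeClass],
    father: Union[GenotypeRecord, GenotypeClass],
    panel: MarkerPanel,
    rng: np.random.Generator,
    seed_id: str = "seed",
) -> SeedSimResult:
    """Mendelian cross: each parent transmits one allele per locus,
    independently across loci.  The transmitted haplotypes are returned as
    ground truth.  cpDNA and mother ID are copied from the mother."""
    if isinstance(mother, GenotypeClass):
        mother = make_individual(mother, panel, rng, "simulated_mother", sex=Sex.FEMALE)
    if isinstance(father, GenotypeClass):
        father = make_individual(father, panel, rng, "simulated_father", sex=Sex.MALE)
    maternal: List[str] = []
    paternal: List[str] = []
    calls: Dict[str, tuple] = {}
    for locus in panel:
        mother_call = mother.calls.get(locus.locus_id)
        father_call = father.calls.get(locus.locus_id)
        if mother_call is None or father_call is None:
            calls[locus.locus_id] = None
            maternal.append("?")
            paternal.append("?")
            continue
        m_allele = mother_call[rng.integers(2)]
        p_allele = father_call[rng.integers(2)]
        calls[locus.locus_id] = make_call(m_allele, p_allele)
        maternal.append(m_allele)
        paternal.append(p_allele)
    seed = GenotypeRecord(
        individual_id=seed_id,
        stage=Stage.SEED,
        sex=Sex.UNKNOWN,
        mother_id=mother.individual_id,
        cp_haplotype=mother.cp_haplotype,
        calls=calls,
    )
    return SeedSimResult(seed, tuple(maternal), tuple(paternal))


def apply_error(
    record: GenotypeRecord,
    missing_rate: float,
    dropout_rate: float,
    rng: np.random.Generator,
) -> GenotypeRecord:
    """Layer genotyping error on a record (new record; input untouched).

    Each call independently becomes missing with ``missing_rate``; each
    surviving heterozygous call is scored as a homozygote for a uniformly
    chosen constituent allele with ``dropout_rate`` (symmetric allelic
    dropout)."""
    for name, rate in (("missing_rate", missing_rate), ("dropout_rate", dropout_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    new_calls: Dict[str, tuple] = {}
    for locus_id, call in record.calls.items():
        if call is None:
            new_calls[locus_id] = None
            continue
        if missing_rate > 0 and rng.random() < missing_rate:
            new_calls[locus_id] = None
            continue
        if call[0] != call[1] and dropout_rate > 0 and rng.random() < dropout_rate:
            allele = call[rng.integers(2)]
            new_calls[locus_id] = (allele, allele)
        else:
            new_calls[locus_id] = call
    return dataclasses.replace(record, calls=new_calls)


# ---------------------------------------------------------------------------
# vectorized simulation (genotype codes = number of D alleles: 0, 1, 2)

def draw_genotype_codes(
    cls: GenotypeClass, n: int, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n interspecific genotypes of a class as an (n, k) code matrix."""
    if cls is GenotypeClass.B:
        return np.zeros((n, k), dtype=np.int8)
    if cls is GenotypeClass.D:
        return np.full((n, k), 2, dtype=np.int8)
    if cls is GenotypeClass.F1:
        return np.ones((n, k), dtype=np.int8)
    if cls is GenotypeClass.BC_B:
        return rng.integers(0, 2, size=(n, k), dtype=np.int8)
    if cls is GenotypeClass.BC_D:
        return (1 + rng.integers(0, 2, size=(n, k))).astype(np.int8)
    if cls is GenotypeClass.F2:
        return (
            rng.integers(0, 2, size=(n, k)) + rng.integers(0, 2, size=(n, k))
        ).astype(np.int8)
    raise ValueError(f"cannot simulate genotype for class {cls.value}")


def transmit_codes(codes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One transmitted allele per locus (0 = b, 1 = d); hets segregate 1:1."""
    random_allele = rng.integers(0, 2, size=codes.shape, dtype=np.int8)
    return np.where(codes == 1, random_allele, codes // 2).astype(np.int8)


def simulate_seed_codes(
    mother: Union[GenotypeClass, np.ndarray],
    father: Union[GenotypeClass, np.ndarray],
    n: int,
    k: int,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate n seeds: returns (seed codes, maternal alleles, paternal alleles).

    Parents may be classes (a fresh parent genotype is drawn per seed) or
    fixed (n, k) / (k,) genotype-code arrays."""

    def as_codes(parent: Union[GenotypeClass, np.ndarray]) -> np.ndarray:
        if isinstance(parent, GenotypeClass):
            return draw_genotype_codes(parent, n, k, rng)
        arr = np.asarray(parent, dtype=np.int8)
        return np.broadcast_to(arr, (n, k))

    maternal = transmit_codes(as_codes(mother), rng)
    paternal = transmit_codes(as_codes(father), rng)
    return (maternal + paternal).astype(np.int8), maternal, paternal


def apply_error_codes(
    codes: np.ndarray,
    missing_rate: float,
    dropout_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Genotype codes -> LocusState matrix with missingness and dropout applied."""
    states = codes.astype(np.int8).copy()
    if dropout_rate > 0:
        het = states == 1
        drop = het & (rng.random(states.shape) < dropout_rate)
        homozygote = 2 * rng.integers(0, 2, size=states.shape, dtype=np.int8)
        states = np.where(drop, homozygote, states)
    if missing_rate > 0:
        states = np.where(
            rng.random(states.shape) < missing_rate, np.int8(LocusState.MISSING), states
        )
    return states


# ---------------------------------------------------------------------------
# stand generation

_NOMINAL_OFFSPRING: Dict[tuple, GenotypeClass] = {
    (GenotypeClass.B, GenotypeClass.B): GenotypeClass.B,
    (GenotypeClass.D, GenotypeClass.D): GenotypeClass.D,
    (GenotypeClass.B, GenotypeClass.D): GenotypeClass.F1,
    (GenotypeClass.D, GenotypeClass.B): GenotypeClass.F1,
    (GenotypeClass.F1, GenotypeClass.B): GenotypeClass.BC_B,
    (GenotypeClass.B, GenotypeClass.F1): GenotypeClass.BC_B,
    (GenotypeClass.F1, GenotypeClass.D): GenotypeClass.BC_D,
    (GenotypeClass.D, GenotypeClass.F1): GenotypeClass.BC_D,
    (GenotypeClass.F1, GenotypeClass.F1): GenotypeClass.F2,
}


def nominal_offspring_class(
    mother_class: GenotypeClass, father_class: GenotypeClass
) -> GenotypeClass:
    """Expected genotype class of a cross's offspring.

    Crosses involving backcrossed or F2 parents yield advanced-generation
    offspring that fixed markers cannot separate from F2 ("F2-consistent")."""
    try:
        return _NOMINAL_OFFSPRING[(mother_class, father_class)]
    except KeyError:
        return GenotypeClass.F2


def gamete_species_class(
    alleles: Sequence[str], panel: MarkerPanel
) -> GameteClass:
    """Type a transmitted haplotype by the species of its alleles."""
    species = set()
    for locus, allele in zip(panel, alleles):
        if allele == "?":
            continue
        if allele == locus.allele_by_species.get(SPECIES_B):
            species.add(SPECIES_B)
        elif allele == locus.allele_by_species.get(SPECIES_D):
            species.add(SPECIES_D)
    if species == {SPECIES_B, SPECIES_D}:
        return GameteClass.HYBRID_GAMETE
    if species == {SPECIES_B}:
        return GameteClass.B_GAMETE
    if species == {SPECIES_D}:
        return GameteClass.D_GAMETE
    return GameteClass.UNRESOLVED


TRUTH_COLUMNS = (
    "individual_id",
    "stage",
    "true_class",
    "mother_id",
    "father_id",
    "paternal_gamete",
    "true_gamete_class",
    "true_cross_type",
)


@dataclass
class Stand:
    """A generated stand with its ground truth.

    ``truth`` has one row per individual; for seeds it records the
    generating parents, the transmitted paternal haplotype (allele string
    in panel locus order), its species class and the generating cross
    type, making every downstream analysis self-validating."""

    panel: MarkerPanel
    config: SimConfig
    adults: List[GenotypeRecord]
    seeds: List[GenotypeRecord]
    seedlings: List[GenotypeRecord]
    truth: pd.DataFrame

    def all_records(self) -> List[GenotypeRecord]:
        return list(self.adults) + list(self.seeds) + list(self.seedlings)


def _draw_classes(
    frequencies: Dict[GenotypeClass, float], n: int, rng: np.random.Generator
) -> List[GenotypeClass]:
    classes = list(frequencies)
    probs = np.array([frequencies[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    picks = rng.choice(len(classes), size=n, p=probs)
    return [classes[i] for i in picks]


def generate_stand(config: SimConfig, panel: Optional[MarkerPanel] = None) -> Stand:
    """Generate adults, seeds and seedlings plus their truth table.

    Deterministic under a fixed ``config.rng_seed``.  Cross parents are
    taken from the generated adults of the right class where available
    (their sexes are forced accordingly); extra adults are created only
    if a class is exhausted."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    if panel is None:
        panel = default_interspecific_panel(config.n_loci)

    adults: List[GenotypeRecord] = []
    truth_rows: List[dict] = []

    def add_adult(cls: GenotypeClass, sex: Sex) -> GenotypeRecord:
        record = make_individual(
            cls, panel, rng, f"A{len(adults) + 1:03d}", Stage.ADULT, sex
        )
        adults.append(record)
        truth_rows.append(
            {
                "individual_id": record.individual_id,
                "stage": Stage.ADULT.value,
                "true_class": cls.value,
                "mother_id": "",
                "father_id": "",
                "paternal_gamete": "",
                "true_gamete_class": "",
                "true_cross_type": "",
            }
        )
        return record

    adult_class: Dict[str, GenotypeClass] = {}
    for cls in _draw_classes(config.class_frequencies, config.n_adults, rng):
        sex = Sex.FEMALE if rng.random() < 0.5 else Sex.MALE
        record = add_adult(cls, sex)
        adult_class[record.individual_id] = cls

    used_as_parent: set = set()

    def take_parent(cls: GenotypeClass, sex: Sex) -> GenotypeRecord:
        for record in adults:
            if record.individual_id in used_as_parent:
                continue
            if adult_class.get(record.individual_id) is cls:
                record.sex = sex
                used_as_parent.add(record.individual_id)
                return record
        record = add_adult(cls, sex)
        adult_class[record.individual_id] = cls
        used_as_parent.add(record.individual_id)
        return record

    seeds: List[GenotypeRecord] = []
    seed_counter = 0
    for spec in config.crosses:
        mother = take_parent(spec.mother_class, Sex.FEMALE)
        father = take_parent(spec.father_class, Sex.MALE)
        nominal = nominal_offspring_class(spec.mother_class, spec.father_class)
        for _ in range(spec.n_seeds):
            seed_counter += 1
            result = simulate_cross(mother, father, panel, rng, f"S{seed_counter:04d}")
            gamete_cls = gamete_species_class(result.paternal_gamete, panel)
            true_cross = classify_cross(spec.mother_class, nominal, gamete_cls).cross_type
            seeds.append(result.seed)
            truth_rows.append(
                {
                    "individual_id": result.seed.individual_id,
                    "stage": Stage.SEED.value,
                    "true_class": nominal.value,
                    "mother_id": mother.individual_id,
                    "father_id": father.individual_id,
                    "paternal_gamete": "".join(result.paternal_gamete),
                    "true_gamete_class": gamete_cls.value,
                    "true_cross_type": true_cross.value,
                }
            )

    seedlings: List[GenotypeRecord] = []
    for i, cls in enumerate(
        _draw_classes(config.seedling_class_frequencies, config.n_seedlings, rng)
    ):
        record = make_individual(cls, panel, rng, f"R{i + 1:03d}", Stage.SEEDLING)
        seedlings.append(record)
        truth_rows.append(
            {
                "individual_id": record.individual_id,
                "stage": Stage.SEEDLING.value,
                "true_class": cls.value,
                "mother_id": "",
                "father_id": "",
                "paternal_gamete": "",
                "true_gamete_class": "",
                "true_cross_type": "",
            }
        )

    noisy = lambda records: [
        apply_error(r, config.missing_rate, config.dropout_rate, rng) for r in records
    ]
    return Stand(
        panel=panel,
        config=config,
        adults=noisy(adults),
        seeds=noisy(seeds),
        seedlings=noisy(seedlings),
        truth=pd.DataFrame(truth_rows, columns=list(TRUTH_COLUMNS)),
    )


# ---------------------------------------------------------------------------
# deterministic reference cohorts (study-shaped fixtures, built in code)

def _hom(panel: MarkerPanel, species: str) -> Dict[str, tuple]:
    return {
        l.locus_id: make_call(l.diagnostic_allele(species), l.diagnostic_allele(species))
        for l in panel
    }


def _het(panel: MarkerPanel) -> Dict[str, tuple]:
    return {
        l.locus_id: make_call(l.diagnostic_allele(SPECIES_B), l.diagnostic_allele(SPECIES_D))
        for l in panel
    }


def _pattern_calls(panel: MarkerPanel, states: Sequence[LocusState]) -> Dict[str, tuple]:
    calls: Dict[str, tuple] = {}
    for locus, state in zip(panel, states):
        b = locus.diagnostic_allele(SPECIES_B)
        d = locus.diagnostic_allele(SPECIES_D)
        if state is LocusState.HOM_B:
            calls[locus.locus_id] = make_call(b, b)
        elif state is LocusState.HOM_D:
            calls[locus.locus_id] = make_call(d, d)
        elif state is LocusState.HET:
            calls[locus.locus_id] = make_call(b, d)
        else:
            calls[locus.locus_id] = None
    return calls


def _class_pattern(cls: GenotypeClass, k: int) -> List[LocusState]:
    """A deterministic, class-consistent state pattern over k loci."""
    if cls is GenotypeClass.B:
        return [LocusState.HOM_B] * k
    if cls is GenotypeClass.D:
        return [LocusState.HOM_D] * k
    if cls is GenotypeClass.F1:
        return [LocusState.HET] * k
    if cls is GenotypeClass.BC_B:
        return [LocusState.HOM_B] * (k // 2) + [LocusState.HET] * (k - k // 2)
    if cls is GenotypeClass.BC_D:
        return [LocusState.HOM_D] * (k // 2) + [LocusState.HET] * (k - k // 2)
    if cls is GenotypeClass.F2:
        third = k // 3
        return (
            [LocusState.HOM_B] * third
            + [LocusState.HOM_D] * third
            + [LocusState.HET] * (k - 2 * third)
        )
    raise ValueError(cls)


def callrate_reference_cohort(panel: Optional[MarkerPanel] = None) -> List[GenotypeRecord]:
    """Deterministic 1448-individual cohort shaped like the study's genotyping run.

    142 adults, 902 seeds and 404 seedlings over a 35-locus panel, with
    per-individual missing-locus counts arranged so that the cohort has
    10,494 missing calls in total, the adult+seed subset has 153, and
    exactly 1 adult, 2 seeds and 323 seedlings exceed the 10-missing-locus
    QC threshold.  Genotypes are all pure-D; only missingness matters here.
    """
    if panel is None:
        panel = default_interspecific_panel()
    k = len(panel)
    plan = [
        (Stage.ADULT, "AD", [11] * 1 + [1] * 39 + [0] * 102),
        (Stage.SEED, "SD", [11] * 2 + [1] * 81 + [0] * 819),
        (Stage.SEEDLING, "SL", [31] * 323 + [10] * 32 + [8] * 1 + [0] * 48),
    ]
    records: List[GenotypeRecord] = []
    for stage, prefix, missing_counts in plan:
        for i, n_missing in enumerate(missing_counts):
            calls = _hom(panel, SPECIES_D)
            for locus_id in panel.locus_ids[:n_missing]:
                calls[locus_id] = None
            records.append(
                GenotypeRecord(
                    individual_id=f"{prefix}{i + 1:04d}",
                    stage=stage,
                    cp_haplotype=CpHaplotype.D_TYPE,
                    calls=calls,
                )
            )
    return records


def reference_adult_cohort(panel: Optional[MarkerPanel] = None) -> List[GenotypeRecord]:
    """Deterministic adult cohort matching the surveyed stand: 13 B, 97 D,
    13 F1 and 2 BC-B trees (125 total)."""
    if panel is None:
        panel = default_interspecific_panel()
    k = len(panel)
    composition = [
        (GenotypeClass.B, 13),
        (GenotypeClass.D, 97),
        (GenotypeClass.F1, 13),
        (GenotypeClass.BC_B, 2),
    ]
    records: List[GenotypeRecord] = []
    i = 0
    for cls, count in composition:
        for _ in range(count):
            i += 1
            records.append(
                GenotypeRecord(
                    individual_id=f"T{i:03d}",
                    stage=Stage.ADULT,
                    cp_haplotype=_default_cp(cls),
                    calls=_pattern_calls(panel, _class_pattern(cls, k)),
                )
            )
    return records


def reference_seedling_cohort(panel: Optional[MarkerPanel] = None) -> List[GenotypeRecord]:
    """Deterministic seedling cohort: 62 B and 11 D, no hybrids."""
    if panel is None:
        panel = default_interspecific_panel()
    k = len(panel)
    records: List[GenotypeRecord] = []
    i = 0
    for cls, count in ((GenotypeClass.B, 62), (GenotypeClass.D, 11)):
        for _ in range(count):
            i += 1
            records.append(
                GenotypeRecord(
                    individual_id=f"G{i:03d}",
                    stage=Stage.SEEDLING,
                    cp_haplotype=_default_cp(cls),
                    calls=_pattern_calls(panel, _class_pattern(cls, k)),
                )
            )
    return records


def reference_seed_cohort(
    panel: Optional[MarkerPanel] = None,
) -> Tuple[List[GenotypeRecord], List[GenotypeRecord]]:
    """Deterministic mothers and seeds mirroring the study's seed survey.

    Returns ``(mothers, seeds)``: 3 pure-B, 4 pure-D and 7 F1 female
    trees, and 698 seeds distributed as 138 B + 1 BC-B (B mothers),
    231 D + 3 F1 (D mothers) and 255 BC-B + 60 BC-D + 10 F2 (hybrid
    mothers).  Genotypes are exact class-consistent patterns, so the
    classification -> subtraction -> cross-typing pipeline is
    deterministic on this cohort.
    """
    if panel is None:
        panel = default_interspecific_panel()
    k = len(panel)
    mothers: List[GenotypeRecord] = []

    def add_mothers(cls: GenotypeClass, prefix: str, count: int) -> List[str]:
        ids = []
        for i in range(count):
            individual_id = f"{prefix}{i + 1}"
            mothers.append(
                GenotypeRecord(
                    individual_id=individual_id,
                    stage=Stage.ADULT,
                    sex=Sex.FEMALE,
                    cp_haplotype=_default_cp(cls),
                    calls=_pattern_calls(panel, _class_pattern(cls, k)),
                )
            )
            ids.append(individual_id)
        return ids

    b_mothers = add_mothers(GenotypeClass.B, "MB", 3)
    d_mothers = add_mothers(GenotypeClass.D, "MD", 4)
    h_mothers = add_mothers(GenotypeClass.F1, "MH", 7)

    seeds: List[GenotypeRecord] = []
    counter = 0

    def add_seeds(cls: GenotypeClass, mother_ids: List[str], count: int) -> None:
        nonlocal counter
        for i in range(count):
            counter += 1
            mother_id = mother_ids[i % len(mother_ids)]
            mother = next(m for m in mothers if m.individual_id == mother_id)
            seeds.append(
                GenotypeRecord(
                    individual_id=f"S{counter:04d}",
                    stage=Stage.SEED,
                    mother_id=mother_id,
                    cp_haplotype=mother.cp_haplotype,
                    calls=_pattern_calls(panel, _class_pattern(cls, k)),
                )
            )

    add_seeds(GenotypeClass.B, b_mothers, 138)
    add_seeds(GenotypeClass.BC_B, b_mothers, 1)
    add_seeds(GenotypeClass.D, d_mothers, 231)
    add_seeds(GenotypeClass.F1, d_mothers, 3)
    add_seeds(GenotypeClass.BC_B, h_mothers, 255)
    add_seeds(GenotypeClass.BC_D, h_mothers, 60)
    add_seeds(GenotypeClass.F2, h_mothers, 10)
    return mothers, seeds


def simulate_intraspecific_genotype(
    panel: MarkerPanel, rng: np.random.Generator, maf: float = 0.5
) -> Dict[str, tuple]:
    """Random Hardy-Weinberg genotype over an intraspecific panel
    (biallelic a/g, minor-allele frequency ``maf``)."""
    calls: Dict[str, tuple] = {}
    for locus in panel:
        a1 = "a" if rng.random() < maf else "g"
        a2 = "a" if rng.random() < maf else "g"
        calls[locus.locus_id] = make_call(a1, a2)
    return calls
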