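"""Genotype-class assignment from species-diagnostic locus states.

Because every diagnostic locus carries a fixed difference between the two
species, the multiset of per-locus states over the panel determines the
genotype class deterministically:

* all loci homozygous for the B allele        -> pure B
* all loci homozygous for the D allele        -> pure D
* all loci heterozygous                       -> F1
* heterozygous + B-homozygous loci only       -> backcross to B (BC-B)
* heterozygous + D-homozygous loci only       -> backcross to D (BC-D)
* both homozygous states present              -> F2-consistent (F2, advanced
  and complex generations cannot be separated by fixed markers)

Any allele diagnostic for a non-native species makes the individual
EXOTIC before native classification is attempted.  There is no tolerance
for discordant loci: genotyping error is quantified by the simulator and
power module, not absorbed by softening the classifier.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum, IntEnum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .genotypes import Call, CpHaplotype, GenotypeRecord, Stage
from .panel import Locus, MarkerPanel, SPECIES_B, SPECIES_D


class GenotypeClass(str, Enum):
    B = "B"
    D = "D"
    F1 = "F1"
    F2 = "F2"
    BC_B = "BC-B"
    BC_D = "BC-D"
    UNRESOLVED = "UNRESOLVED"
    EXOTIC = "EXOTIC"


PURE_CLASSES = frozenset({GenotypeClass.B, GenotypeClass.D})
HYBRID_CLASSES = frozenset(
    {GenotypeClass.F1, GenotypeClass.F2, GenotypeClass.BC_B, GenotypeClass.BC_D}
)
NATIVE_CLASSES = PURE_CLASSES | HYBRID_CLASSES

#: Stable integer coding shared by the vectorized classifier.
CLASS_ORDER: tuple[GenotypeClass, ...] = (
    GenotypeClass.B,
    GenotypeClass.D,
    GenotypeClass.F1,
    GenotypeClass.F2,
    GenotypeClass.BC_B,
    GenotypeClass.BC_D,
    GenotypeClass.UNRESOLVED,
    GenotypeClass.EXOTIC,
)
CLASS_CODE: Dict[GenotypeClass, int] = {cls: i for i, cls in enumerate(CLASS_ORDER)}


class LocusState(IntEnum):
    HOM_B = 0
    HET = 1
    HOM_D = 2
    MISSING = 3
    EXOTIC = 4


class MaternalLineage(str, Enum):
    B_LINEAGE = "B_lineage"
    D_LINEAGE = "D_lineage"
    UNKNOWN = "unknown"


def locus_state(call: Call, locus: Locus) -> LocusState:
    """Map a call to its diagnostic state at a species-diagnostic locus.

    An allele matching neither native species' diagnostic allele makes
    the state EXOTIC (it belongs to a non-native poplar); this is not an
    error condition.
    """
    if call is None:
        return LocusState.MISSING
    allele_b = locus.allele_by_species.get(SPECIES_B)
    allele_d = locus.allele_by_species.get(SPECIES_D)
    for allele in call:
        if allele != allele_b and allele != allele_d:
            return LocusState.EXOTIC
    a1, a2 = call
    if a1 == a2:
        return LocusState.HOM_B if a1 == allele_b else LocusState.HOM_D
    return LocusState.HET


@dataclass(frozen=True)
class ClassificationResult:
    individual_id: str
    genotype_class: GenotypeClass
    state_counts: Mapping[LocusState, int]
    n_informative: int
    flags: frozenset


def _class_from_counts(
    hom_b: int, het: int, hom_d: int, exotic: int, min_informative: int
) -> tuple[GenotypeClass, frozenset]:
    flags: set = set()
    if exotic > 0:
        return GenotypeClass.EXOTIC, frozenset()
    informative = hom_b + het + hom_d
    if informative == 0:
        return GenotypeClass.UNRESOLVED, frozenset({"NO_INFORMATIVE_LOCI"})
    if informative < min_informative:
        return GenotypeClass.UNRESOLVED, frozenset({"LOW_INFORMATIVE"})
    if hom_b > 0 and hom_d > 0:
        return GenotypeClass.F2, frozenset({"F2_CONSISTENT"})
    if het > 0 and hom_b > 0:
        return GenotypeClass.BC_B, frozenset()
    if het > 0 and hom_d > 0:
        return GenotypeClass.BC_D, frozenset()
    if het > 0:
        return GenotypeClass.F1, frozenset()
    # all-homozygous one species: a pure genotype, but indistinguishable from a
    # backcross seed whose hybrid parent happened to transmit only that species'
    # alleles (probability (1/2)^h over h heterozygous parental loci).
    flags.add("ALL_HOM_AMBIGUOUS")
    cls = GenotypeClass.B if hom_b > 0 else GenotypeClass.D
    return cls, frozenset(flags)


def classify_individual(
    record: GenotypeRecord, panel: MarkerPanel, min_informative: int = 5
) -> ClassificationResult:
    """Assign a genotype class from the record's diagnostic locus states."""
    states = [locus_state(record.calls.get(locus.locus_id), locus) for locus in panel]
    counts = Counter(states)
    for state in LocusState:
        counts.setdefault(state, 0)
    cls, flags = _class_from_counts(
        counts[LocusState.HOM_B],
        counts[LocusState.HET],
        counts[LocusState.HOM_D],
        counts[LocusState.EXOTIC],
        min_informative,
    )
    n_informative = (
        counts[LocusState.HOM_B] + counts[LocusState.HET] + counts[LocusState.HOM_D]
    )
    return ClassificationResult(
        individual_id=record.individual_id,
        genotype_class=cls,
        state_counts=dict(counts),
        n_informative=n_informative,
        flags=flags,
    )


def classify_state_codes(states: np.ndarray, min_informative: int = 5) -> np.ndarray:
    """Vectorized classifier over an (n_individuals, n_loci) state matrix.

    States use the :class:`LocusState` integer coding; the return value
    uses :data:`CLASS_CODE`.  Semantics are identical to
    :func:`classify_individual`; a bridging test asserts agreement.
    """
    S = np.asarray(states)
    if S.ndim != 2:
        raise ValueError("state matrix must be 2-D")
    hom_b = (S == LocusState.HOM_B).sum(axis=1)
    het = (S == LocusState.HET).sum(axis=1)
    hom_d = (S == LocusState.HOM_D).sum(axis=1)
    exotic = (S == LocusState.EXOTIC).sum(axis=1)
    informative = hom_b + het + hom_d

    out = np.full(S.shape[0], CLASS_CODE[GenotypeClass.UNRESOLVED], dtype=np.int64)
    ok = informative >= min_informative
    out[ok & (hom_b > 0) & (het == 0) & (hom_d == 0)] = CLASS_CODE[GenotypeClass.B]
    out[ok & (hom_d > 0) & (het == 0) & (hom_b == 0)] = CLASS_CODE[GenotypeClass.D]
    out[ok & (het > 0) & (hom_b == 0) & (hom_d == 0)] = CLASS_CODE[GenotypeClass.F1]
    out[ok & (het > 0) & (hom_b > 0) & (hom_d == 0)] = CLASS_CODE[GenotypeClass.BC_B]
    out[ok & (het > 0) & (hom_d > 0) & (hom_b == 0)] = CLASS_CODE[GenotypeClass.BC_D]
    out[ok & (hom_b > 0) & (hom_d > 0)] = CLASS_CODE[GenotypeClass.F2]
    out[exotic > 0] = CLASS_CODE[GenotypeClass.EXOTIC]
    return out


def maternal_lineage(record: GenotypeRecord) -> MaternalLineage:
    """Species lineage of the seed parent, from the maternally inherited cpDNA type."""
    if record.cp_haplotype is CpHaplotype.B_TYPE:
        return MaternalLineage.B_LINEAGE
    if record.cp_haplotype is CpHaplotype.D_TYPE:
        return MaternalLineage.D_LINEAGE
    return MaternalLineage.UNKNOWN


def stand_composition(
    results: Sequence[ClassificationResult],
    stages: Optional[Mapping[str, Stage]] = None,
    pool_hybrids: bool = False,
) -> pd.DataFrame:
    """Per-class counts and percentages, optionally broken down by life stage.

    With ``pool_hybrids=True`` the hybrid classes (F1, F2, BC-B, BC-D) are
    pooled into a single ``D x B`` group, the reporting convention for
    stands where advanced classes cannot be separated.  Percentages are
    within-stage, half-up at one decimal; counts are conserved.
    """
    if not results:
        raise ValueError("stand_composition requires at least one result")

    def group_of(cls: GenotypeClass) -> str:
        if pool_hybrids and cls in HYBRID_CLASSES:
            return "D x B"
        return cls.value

    counts: Dict[tuple, int] = {}
    for result in results:
        stage_label = (
            stages[result.individual_id].value if stages is not None else "all"
        )
        key = (stage_label, group_of(result.genotype_class))
        counts[key] = counts.get(key, 0) + 1
    totals: Dict[str, int] = {}
    for (stage_label, _), n in counts.items():
        totals[stage_label] = totals.get(stage_label, 0) + n
    rows = []
    for (stage_label, group), n in sorted(counts.items()):
        fraction = n / totals[stage_label]
        rows.append(
            {
                "stage": stage_label,
                "group": group,
                "count": n,
                "fraction": fraction,
                "percent": round_half_up(fraction * 100.0, 1),
            }
        )
    return pd.DataFrame(rows, columns=["stage", "group", "count", "fraction", "percent"])
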