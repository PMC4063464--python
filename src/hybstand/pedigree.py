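"""Pedigree-aware inference: paternal gametes, cross types, clones and half-sibs.

The paternal gamete of a seed is recovered by *haplotype subtraction*:
at each locus the allele(s) attributable to the known seed mother are
removed from the seed genotype, leaving the paternal contribution.  With
a homozygous mother the subtraction is forced; with a heterozygous
mother and a heterozygous seed both transmissions are possible and the
locus is ambiguous.  A seed call that no Mendelian transmission can
explain (e.g. mother b/b, seed d/d) is flagged inconsistent — possible
genotyping error or null allele — and excluded from gamete typing
rather than aborting the trio (standard parentage-exclusion practice).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd

from .classify import (
    ClassificationResult,
    GenotypeClass,
    HYBRID_CLASSES,
    classify_individual,
)
from .genotypes import GenotypeRecord
from .panel import MarkerPanel, SPECIES_B, SPECIES_D

#: Per-locus paternal-allele tokens used alongside plain allele symbols.
AMBIGUOUS = "AMBIGUOUS"
MISSING = "MISSING"
INCONSISTENT = "INCONSISTENT"


class GameteClass(str, Enum):
    B_GAMETE = "B_gamete"
    D_GAMETE = "D_gamete"
    HYBRID_GAMETE = "hybrid_gamete"
    UNRESOLVED = "unresolved"


class CrossType(str, Enum):
    INTRA_B = "intra_B"
    INTRA_D = "intra_D"
    F1_FORMATION = "F1_formation"
    BC_TO_B = "BC_to_B"
    BC_TO_D = "BC_to_D"
    F2_CROSS = "F2_cross"
    OTHER = "other"


@dataclass(frozen=True)
class GameteInference:
    """Per-locus paternal alleles for one seed-mother pair.

    ``paternal`` maps each panel locus to an allele symbol or one of the
    tokens AMBIGUOUS / MISSING / INCONSISTENT.  ``gamete_class`` types
    the paternal contribution by the species of its unambiguous alleles.
    """

    seed_id: str
    mother_id: str
    paternal: Mapping[str, str]
    inconsistent_loci: Tuple[str, ...]
    gamete_class: GameteClass
    n_unambiguous: int
    n_ambiguous: int
    flags: frozenset


def subtract_gamete(
    seed: GenotypeRecord,
    mother: GenotypeRecord,
    panel: MarkerPanel,
    min_informative: int = 5,
    max_inconsistent: int = 2,
) -> GameteInference:
    """Infer the paternal gamete of ``seed`` given its known mother.

    More than ``max_inconsistent`` Mendelian exclusions flags the trio
    DUBIOUS_MATERNITY (the recorded mother is suspect), but inference
    still proceeds on the consistent loci.
    """
    if mother is None:
        raise ValueError("mother record missing")
    if seed.mother_id is not None and seed.mother_id != mother.individual_id:
        raise ValueError(
            f"seed {seed.individual_id!r} records mother {seed.mother_id!r}, "
            f"got record for {mother.individual_id!r}"
        )
    for locus_id in panel.locus_ids:
        if locus_id not in seed.calls or locus_id not in mother.calls:
            raise ValueError(
                f"records not typed on panel {panel.panel_id!r} (locus {locus_id!r} absent)"
            )

    paternal: Dict[str, str] = {}
    inconsistent: List[str] = []
    for locus in panel:
        locus_id = locus.locus_id
        seed_call = seed.calls[locus_id]
        mother_call = mother.calls[locus_id]
        if seed_call is None or mother_call is None:
            paternal[locus_id] = MISSING
            continue
        mother_alleles = set(mother_call)
        seed_alleles = set(seed_call)
        if len(mother_alleles) == 1:  # mother homozygous x/x
            x = mother_call[0]
            if seed_alleles == {x}:
                paternal[locus_id] = x
            elif x in seed_alleles:
                paternal[locus_id] = next(a for a in seed_call if a != x)
            else:
                paternal[locus_id] = INCONSISTENT
                inconsistent.append(locus_id)
        else:  # mother heterozygous x/y
            if len(seed_alleles) == 1:
                p = seed_call[0]
                if p in mother_alleles:
                    paternal[locus_id] = p
                else:
                    paternal[locus_id] = INCONSISTENT
                    inconsistent.append(locus_id)
            else:
                extra = seed_alleles - mother_alleles
                if not extra:
                    paternal[locus_id] = AMBIGUOUS
                elif len(extra) == 1:
                    paternal[locus_id] = extra.pop()
                else:
                    paternal[locus_id] = INCONSISTENT
                    inconsistent.append(locus_id)

    species_seen: set = set()
    exotic_allele = False
    n_unambiguous = 0
    for locus in panel:
        allele = paternal[locus.locus_id]
        if allele in (AMBIGUOUS, MISSING, INCONSISTENT):
            continue
        n_unambiguous += 1
        if allele == locus.allele_by_species.get(SPECIES_B):
            species_seen.add(SPECIES_B)
        elif allele == locus.allele_by_species.get(SPECIES_D):
            species_seen.add(SPECIES_D)
        else:
            exotic_allele = True
    if n_unambiguous < min_informative:
        gamete_class = GameteClass.UNRESOLVED
    elif species_seen == {SPECIES_B, SPECIES_D}:
        gamete_class = GameteClass.HYBRID_GAMETE
    elif species_seen == {SPECIES_B}:
        gamete_class = GameteClass.B_GAMETE
    elif species_seen == {SPECIES_D}:
        gamete_class = GameteClass.D_GAMETE
    else:
        gamete_class = GameteClass.UNRESOLVED

    flags = set()
    if len(inconsistent) > max_inconsistent:
        flags.add("DUBIOUS_MATERNITY")
    if exotic_allele:
        flags.add("EXOTIC_PATERNAL_ALLELE")
    n_ambiguous = sum(1 for v in paternal.values() if v == AMBIGUOUS)
    return GameteInference(
        seed_id=seed.individual_id,
        mother_id=mother.individual_id,
        paternal=paternal,
        inconsistent_loci=tuple(inconsistent),
        gamete_class=gamete_class,
        n_unambiguous=n_unambiguous,
        n_ambiguous=n_ambiguous,
        flags=frozenset(flags),
    )


@dataclass(frozen=True)
class CrossRecord:
    """One typed reproductive event (a seed with its maternal context)."""

    seed_id: str
    mother_id: str
    maternal_class: GenotypeClass
    offspring_class: GenotypeClass
    gamete_class: Optional[GameteClass]
    n_ambiguous: int
    n_inconsistent: int
    cross_type: CrossType
    flags: frozenset = field(default_factory=frozenset)


def classify_cross(
    maternal_class: GenotypeClass,
    offspring_class: GenotypeClass,
    gamete: Union[GameteInference, GameteClass, None] = None,
    *,
    seed_id: str = "",
    mother_id: str = "",
) -> CrossRecord:
    """Type the reproductive event behind a seed.

    Pure mothers are typed from the offspring class alone (the pollen
    species is implied); hybrid mothers require the inferred paternal
    gamete, since their offspring class does not identify the father.
    """
    if maternal_class is GenotypeClass.EXOTIC:
        raise ValueError("cannot type crosses for exotic mothers")
    if isinstance(gamete, GameteInference):
        gamete_class: Optional[GameteClass] = gamete.gamete_class
        n_ambiguous, n_inconsistent = gamete.n_ambiguous, len(gamete.inconsistent_loci)
    else:
        gamete_class = gamete
        n_ambiguous = n_inconsistent = 0

    flags: set = set()
    cross_type = CrossType.OTHER
    B, D = GenotypeClass.B, GenotypeClass.D
    if maternal_class is D:
        if offspring_class is D:
            cross_type = CrossType.INTRA_D
        elif offspring_class is GenotypeClass.F1:
            cross_type = CrossType.F1_FORMATION
        elif offspring_class is GenotypeClass.BC_D:
            cross_type = CrossType.BC_TO_D  # hybrid pollen onto a pure D mother
        else:
            flags.add("UNMATCHED_COMBINATION")
    elif maternal_class is B:
        if offspring_class is B:
            cross_type = CrossType.INTRA_B
        elif offspring_class is GenotypeClass.F1:
            cross_type = CrossType.F1_FORMATION
        elif offspring_class is GenotypeClass.BC_B:
            cross_type = CrossType.BC_TO_B  # hybrid pollen onto a pure B mother
        else:
            flags.add("UNMATCHED_COMBINATION")
    elif maternal_class in HYBRID_CLASSES:
        if gamete_class is GameteClass.HYBRID_GAMETE:
            cross_type = CrossType.F2_CROSS
        elif gamete_class is GameteClass.B_GAMETE and offspring_class in (
            GenotypeClass.BC_B,
            B,
            GenotypeClass.F1,
        ):
            cross_type = CrossType.BC_TO_B
        elif gamete_class is GameteClass.D_GAMETE and offspring_class in (
            GenotypeClass.BC_D,
            D,
            GenotypeClass.F1,
        ):
            cross_type = CrossType.BC_TO_D
        else:
            flags.add("UNMATCHED_COMBINATION")
    else:  # UNRESOLVED mother
        flags.add("UNRESOLVED_MOTHER")
    return CrossRecord(
        seed_id=seed_id,
        mother_id=mother_id,
        maternal_class=maternal_class,
        offspring_class=offspring_class,
        gamete_class=gamete_class,
        n_ambiguous=n_ambiguous,
        n_inconsistent=n_inconsistent,
        cross_type=cross_type,
        flags=frozenset(flags),
    )


def infer_crosses(
    seeds: Sequence[GenotypeRecord],
    mothers: Sequence[GenotypeRecord],
    panel: MarkerPanel,
    min_informative: int = 5,
) -> List[CrossRecord]:
    """Full seed pipeline: classify mother and seed, subtract, type the cross."""
    mothers_by_id = {m.individual_id: m for m in mothers}
    mother_class: Dict[str, GenotypeClass] = {}
    crosses: List[CrossRecord] = []
    for seed in seeds:
        if seed.mother_id is None:
            raise ValueError(f"seed {seed.individual_id!r} has no recorded mother")
        mother = mothers_by_id.get(seed.mother_id)
        if mother is None:
            raise ValueError(
                f"mother record {seed.mother_id!r} missing for seed {seed.individual_id!r}"
            )
        if mother.individual_id not in mother_class:
            mother_class[mother.individual_id] = classify_individual(
                mother, panel, min_informative
            ).genotype_class
        offspring = classify_individual(seed, panel, min_informative)
        gamete = subtract_gamete(seed, mother, panel, min_informative)
        crosses.append(
            classify_cross(
                mother_class[mother.individual_id],
                offspring.genotype_class,
                gamete,
                seed_id=seed.individual_id,
                mother_id=mother.individual_id,
            )
        )
    return crosses


CROSS_COLUMNS = (
    "seed_id",
    "mother_id",
    "maternal_class",
    "offspring_class",
    "gamete_class",
    "n_ambiguous",
    "n_inconsistent",
    "cross_type",
)


def crosses_to_frame(crosses: Sequence[CrossRecord]) -> pd.DataFrame:
    rows = [
        {
            "seed_id": c.seed_id,
            "mother_id": c.mother_id,
            "maternal_class": c.maternal_class.value,
            "offspring_class": c.offspring_class.value,
            "gamete_class": c.gamete_class.value if c.gamete_class else "",
            "n_ambiguous": c.n_ambiguous,
            "n_inconsistent": c.n_inconsistent,
            "cross_type": c.cross_type.value,
        }
        for c in crosses
    ]
    return pd.DataFrame(rows, columns=list(CROSS_COLUMNS))


def write_crosses_csv(crosses: Sequence[CrossRecord], path: Union[str, Path]) -> None:
    crosses_to_frame(crosses).to_csv(path, index=False)


def read_crosses_csv(path: Union[str, Path]) -> List[CrossRecord]:
    frame = pd.read_csv(path, keep_default_na=False)
    crosses = []
    for row in frame.itertuples(index=False):
        crosses.append(
            CrossRecord(
                seed_id=str(row.seed_id),
                mother_id=str(row.mother_id),
                maternal_class=GenotypeClass(row.maternal_class),
                offspring_class=GenotypeClass(row.offspring_class),
                gamete_class=GameteClass(row.gamete_class) if row.gamete_class else None,
                n_ambiguous=int(row.n_ambiguous),
                n_inconsistent=int(row.n_inconsistent),
                cross_type=CrossType(row.cross_type),
            )
        )
    return crosses


def _clone_identical(
    a: GenotypeRecord, b: GenotypeRecord, panel: MarkerPanel, min_shared: int
) -> bool:
    """Identical at every locus where both are called, with enough shared loci."""
    shared = 0
    for locus_id in panel.locus_ids:
        call_a = a.calls.get(locus_id)
        call_b = b.calls.get(locus_id)
        if call_a is None or call_b is None:
            continue
        if call_a != call_b:
            return False
        shared += 1
    return shared >= min_shared


def find_clones(
    records: Sequence[GenotypeRecord], panel: MarkerPanel, min_shared: int = 20
) -> List[Tuple[str, str]]:
    """Pairs with identical multilocus genotypes on one intraspecific panel.

    A pair is reported iff the two records agree at every locus where
    both are called AND share at least ``min_shared`` called loci — the
    floor guards against missingness-driven false identity.
    """
    pairs: List[Tuple[str, str]] = []
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            if _clone_identical(records[i], records[j], panel, min_shared):
                a, b = sorted((records[i].individual_id, records[j].individual_id))
                pairs.append((a, b))
    return sorted(pairs)


@dataclass(frozen=True)
class HalfSibPair:
    """A pair identical on exactly one intraspecific panel.

    ``shared_side`` names the species panel on which the pair matched
    ("B" or "D") — i.e. the pair shares its parent of that species'
    lineage.  Which sex that parent was cannot be decided from the
    genotypes alone, so no mother/father assertion is made.
    """

    id_a: str
    id_b: str
    shared_side: str


def find_half_sibs(
    records: Sequence[GenotypeRecord],
    panel_b: MarkerPanel,
    panel_d: MarkerPanel,
    min_shared: int = 20,
) -> List[HalfSibPair]:
    """Pairs clone-identical on exactly one of the two intraspecific panels.

    Pairs identical on both panels are clones, not half-sibs, and are
    not reported here.  Records must carry calls for both panels.
    """
    out: List[HalfSibPair] = []
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            match_b = _clone_identical(records[i], records[j], panel_b, min_shared)
            match_d = _clone_identical(records[i], records[j], panel_d, min_shared)
            if match_b == match_d:
                continue  # clone (both) or unrelated (neither)
            a, b = sorted((records[i].individual_id, records[j].individual_id))
            out.append(HalfSibPair(a, b, SPECIES_B if match_b else SPECIES_D))
    return sorted(out, key=lambda p: (p.id_a, p.id_b))
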