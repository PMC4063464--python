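"""Hybridization-rate and cross-composition tables.

The spontaneous hybridization rate is the classical estimator: hybrid
offspring divided by the total offspring examined for a set of mothers.
All counts are exact integers; rates are rounded half-up to one decimal
only at report time.  Seeds whose genotype class is UNRESOLVED are
excluded from denominators and accounted for in ``RateTable.dropped``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set

import pandas as pd
from scipy import stats

from ._util import round_half_up
from .classify import GenotypeClass, HYBRID_CLASSES, PURE_CLASSES
from .pedigree import CrossRecord, CrossType

_INTRASPECIFIC = (CrossType.INTRA_B, CrossType.INTRA_D)


@dataclass(frozen=True)
class RateRow:
    group: str
    numerator: int
    denominator: int
    flags: frozenset = field(default_factory=frozenset)

    @property
    def rate(self) -> Optional[float]:
        if self.denominator == 0:
            return None
        return self.numerator / self.denominator

    def percent(self, ndigits: int = 1) -> Optional[float]:
        if self.rate is None:
            return None
        return round_half_up(self.rate * 100.0, ndigits)

    def interval(self, level: float = 0.95) -> Optional[tuple]:
        """Clopper-Pearson exact binomial confidence interval for the rate."""
        if self.denominator == 0:
            return None
        alpha = 1.0 - level
        k, n = self.numerator, self.denominator
        lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
        hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
        return (lo, hi)


@dataclass(frozen=True)
class RateTable:
    rows: tuple
    dropped: int = 0

    def row(self, group: str) -> RateRow:
        for r in self.rows:
            if r.group == group:
                return r
        raise KeyError(group)

    def percent(self, group: str, ndigits: int = 1) -> Optional[float]:
        return self.row(group).percent(ndigits)

    def rate(self, group: str) -> Optional[float]:
        return self.row(group).rate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "group": r.group,
                    "numerator": r.numerator,
                    "denominator": r.denominator,
                    "rate": r.rate,
                    "percent": r.percent(),
                    "flags": ";".join(sorted(r.flags)),
                }
                for r in self.rows
            ],
            columns=["group", "numerator", "denominator", "rate", "percent", "flags"],
        )


def spontaneous_hybridization_rate(crosses: Sequence[CrossRecord]) -> RateTable:
    """Per maternal species: hybrid seeds / genotyped seeds of that species' mothers.

    Only pure-species mothers enter (hybrid-mother seeds are reproductive
    events of the hybrid pool, not new hybridization); a seed counts as
    hybrid iff its genotype class is F1, F2, BC-B or BC-D.  A species
    with no seeds gets an UNDEFINED-flagged row.
    """
    dropped = 0
    counts: Dict[GenotypeClass, List[int]] = {
        GenotypeClass.B: [0, 0],
        GenotypeClass.D: [0, 0],
    }
    for cross in crosses:
        if cross.maternal_class not in PURE_CLASSES:
            continue
        if cross.offspring_class is GenotypeClass.UNRESOLVED:
            dropped += 1
            continue
        bucket = counts[cross.maternal_class]
        bucket[1] += 1
        if cross.offspring_class in HYBRID_CLASSES:
            bucket[0] += 1
    rows = []
    for species in (GenotypeClass.B, GenotypeClass.D):
        numerator, denominator = counts[species]
        flags = frozenset({"UNDEFINED"}) if denominator == 0 else frozenset()
        rows.append(RateRow(species.value, numerator, denominator, flags))
    return RateTable(tuple(rows), dropped=dropped)


def cross_composition(
    crosses: Sequence[CrossRecord],
    mother_classes: Iterable[GenotypeClass],
    pool_intraspecific: bool = True,
) -> RateTable:
    """Proportions of cross types among the seeds of the selected mothers.

    With ``pool_intraspecific=True`` the two within-species cross types
    are pooled into one ``intraspecific`` group (the convention for
    pure-mother seed lots).  Rows partition the genotyped seeds; counts
    are conserved and percentages sum to 100 within rounding.
    """
    mother_classes = set(mother_classes)
    dropped = 0
    group_counts: Dict[str, int] = {}
    order: List[str] = []
    total = 0
    for cross in crosses:
        if cross.maternal_class not in mother_classes:
            continue
        if cross.offspring_class is GenotypeClass.UNRESOLVED:
            dropped += 1
            continue
        if pool_intraspecific and cross.cross_type in _INTRASPECIFIC:
            group = "intraspecific"
        else:
            group = cross.cross_type.value
        if group not in group_counts:
            group_counts[group] = 0
            order.append(group)
        group_counts[group] += 1
        total += 1
    rows = tuple(
        RateRow(group, group_counts[group], total)
        for group in sorted(order, key=lambda g: -group_counts[g])
    )
    return RateTable(rows, dropped=dropped)
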