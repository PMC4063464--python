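"""Marker-panel power: misclassification of seed genotype classes.

Fixed diagnostic markers classify seeds deterministically, so the only
misassignment routes are (a) genuine segregation collisions — a
backcross seed whose hybrid parent happened to transmit one species'
allele at every heterozygous locus — and (b) genotyping error, chiefly
allelic dropout scoring heterozygotes as homozygotes.  Both routes have
closed forms at unlinked loci; this module computes them and checks them
against Monte-Carlo simulation of the full simulate -> classify path.

Key closed forms (k unlinked loci, missingness m, dropout e, minimum
informative-locus count t):

* backcross seed, mother heterozygous at h loci, pure recurrent father,
  error-free: P(scored recurrent-pure) = (1/2)^h
* F1 seed: P(scored pure either side)
  = 2 * sum_{j=0}^{k-t} C(k,j) m^j ((1-m) e/2)^(k-j)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb, sqrt
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .classify import CLASS_ORDER, GenotypeClass, classify_state_codes
from .sim import (
    SimConfig,
    apply_error_codes,
    nominal_offspring_class,
    simulate_seed_codes,
)

__all__ = [
    "ConfusionMatrix",
    "misclassification_power",
    "prob_backcross_scored_pure",
    "prob_f1_scored_pure",
]


def _prob_all_one_state(k: int, p_state: float, p_missing: float, min_informative: int) -> float:
    """P(every non-missing locus is in one target state and enough loci are called),
    for k iid loci with per-locus P(missing) = p_missing and joint per-locus
    P(called and in the target state) = p_state."""
    if k < min_informative:
        return 0.0
    return float(
        sum(
            comb(k, j) * p_missing**j * p_state ** (k - j)
            for j in range(0, k - min_informative + 1)
        )
    )


def prob_backcross_scored_pure(
    n_maternal_het_loci: int,
    dropout: float = 0.0,
    missing_rate: float = 0.0,
    min_informative: int = 5,
) -> float:
    """P(a backcross seed is scored as the recurrent pure species).

    The mother is heterozygous at ``n_maternal_het_loci`` loci and the
    father is the pure recurrent species; at each maternal-het locus the
    seed is recurrent-homozygous with probability (1 + e/2)/2 once
    dropout e is applied.  Error-free this is the segregation collision
    (1/2)^h.  With ``missing_rate`` > 0 the expression assumes the
    mother is heterozygous at every panel locus (an F1 mother), so that
    h equals the panel size."""
    h = n_maternal_het_loci
    p_hom = 0.5 * (1.0 + dropout / 2.0)
    if missing_rate == 0.0:
        return p_hom**h
    return _prob_all_one_state(h, (1.0 - missing_rate) * p_hom, missing_rate, min_informative)


def prob_f1_scored_pure(
    n_loci: int,
    dropout: float,
    missing_rate: float = 0.0,
    min_informative: int = 5,
) -> float:
    """P(an F1 seed is scored as a pure class, either species).

    Every locus is heterozygous; dropout e converts a het to either
    homozygote with probability e/2 each, so an all-one-side profile has
    per-locus probability (1-m) e/2 and either side can occur."""
    p_hom = (1.0 - missing_rate) * dropout / 2.0
    return 2.0 * _prob_all_one_state(n_loci, p_hom, missing_rate, min_informative)


@dataclass
class ConfusionMatrix:
    """True cross (rows) x assigned genotype class (columns) counts.

    ``analytic`` overlays closed-form probabilities for the cells where
    they exist, keyed by (row label, class label); ``mc_se`` gives the
    Monte-Carlo standard error of an estimated cell probability."""

    counts: pd.DataFrame
    true_class: Dict[str, GenotypeClass]
    n_reps: int
    analytic: Dict[Tuple[str, str], float] = field(default_factory=dict)

    def probabilities(self) -> pd.DataFrame:
        return self.counts / self.n_reps

    def probability(self, row: str, assigned: GenotypeClass) -> float:
        return float(self.counts.loc[row, assigned.value]) / self.n_reps

    def mc_se(self, row: str, assigned: GenotypeClass) -> float:
        p = self.probability(row, assigned)
        return sqrt(p * (1.0 - p) / self.n_reps)


def misclassification_power(
    config: SimConfig,
    n_reps: int = 100_000,
    min_informative: int = 5,
) -> ConfusionMatrix:
    """Simulate -> classify -> tabulate for every parent-class pair in the config.

    Each distinct (mother class, father class) pair in ``config.crosses``
    becomes one row of ``n_reps`` simulated seeds at the config's error
    rates.  Closed-form overlays are attached for the cells covered by
    :func:`prob_backcross_scored_pure` (F1 mother x pure father) and
    :func:`prob_f1_scored_pure` (pure x pure F1 formation)."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    k = config.n_loci

    pairs: List[Tuple[GenotypeClass, GenotypeClass]] = []
    for spec in config.crosses:
        pair = (spec.mother_class, spec.father_class)
        if pair not in pairs:
            pairs.append(pair)

    class_labels = [cls.value for cls in CLASS_ORDER]
    rows = []
    labels = []
    true_class: Dict[str, GenotypeClass] = {}
    analytic: Dict[Tuple[str, str], float] = {}
    for mother_cls, father_cls in pairs:
        label = f"{mother_cls.value} x {father_cls.value}"
        labels.append(label)
        true_class[label] = nominal_offspring_class(mother_cls, father_cls)
        codes, _, _ = simulate_seed_codes(mother_cls, father_cls, n_reps, k, rng)
        states = apply_error_codes(codes, config.missing_rate, config.dropout_rate, rng)
        assigned = classify_state_codes(states, min_informative)
        rows.append(np.bincount(assigned, minlength=len(CLASS_ORDER)))

        pure = (GenotypeClass.B, GenotypeClass.D)
        if mother_cls is GenotypeClass.F1 and father_cls in pure:
            analytic[(label, father_cls.value)] = prob_backcross_scored_pure(
                k, config.dropout_rate, config.missing_rate, min_informative
            )
        if mother_cls in pure and father_cls in pure and mother_cls is not father_cls:
            per_side = prob_f1_scored_pure(
                k, config.dropout_rate, config.missing_rate, min_informative
            ) / 2.0
            analytic[(label, GenotypeClass.B.value)] = per_side
            analytic[(label, GenotypeClass.D.value)] = per_side

    counts = pd.DataFrame(np.vstack(rows), index=labels, columns=class_labels)
    return ConfusionMatrix(
        counts=counts, true_class=true_class, n_reps=n_reps, analytic=analytic
    )
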