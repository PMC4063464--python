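"""Marker panels: species-diagnostic and intraspecific SNP loci.

A *diagnostic* (interspecific) locus carries a fixed allelic difference
between the two parental species — here *Populus balsamifera* (species
code ``B``) and *P. deltoides* (``D``) — so that an individual's genotype
state at the locus directly reveals its ancestry.  Intraspecific panels
are polymorphic within one species and are used for clone and sibship
detection, not species assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Mapping, Optional, Union

import yaml

#: Species codes used throughout the package.
SPECIES_B = "B"  # Populus balsamifera
SPECIES_D = "D"  # Populus deltoides
NATIVE_SPECIES = (SPECIES_B, SPECIES_D)


class PanelKind(str, Enum):
    INTERSPECIFIC = "interspecific"
    INTRASPECIFIC_B = "intraspecific_B"
    INTRASPECIFIC_D = "intraspecific_D"


@dataclass(frozen=True)
class Locus:
    """One biallelic SNP locus.

    ``allele_by_species`` maps a species code to its diagnostic allele;
    it is empty for intraspecific loci.  Allele symbols are free single
    tokens — the abstract ``b``/``d`` pair for simulated diagnostic
    panels, or nucleotides for assay-derived panels.
    """

    locus_id: str
    chromosome: Optional[str] = None
    allele_by_species: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "allele_by_species", dict(self.allele_by_species))
        alleles = list(self.allele_by_species.values())
        if len(alleles) != len(set(alleles)):
            raise ValueError(
                f"locus {self.locus_id!r}: diagnostic alleles must differ between species"
            )

    def diagnostic_allele(self, species: str) -> str:
        return self.allele_by_species[species]

    @property
    def is_diagnostic(self) -> bool:
        """True if the locus maps both native species to distinct alleles."""
        return set(self.allele_by_species) == set(NATIVE_SPECIES)


@dataclass(frozen=True)
class MarkerPanel:
    """An ordered set of loci with a panel kind.

    Invariants: locus IDs are unique; every locus of an interspecific
    panel carries a fixed difference between the two native species.
    """

    panel_id: str
    kind: PanelKind
    loci: tuple[Locus, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "loci", tuple(self.loci))
        ids = [locus.locus_id for locus in self.loci]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"panel {self.panel_id!r}: duplicate locus IDs {dup}")
        if self.kind is PanelKind.INTERSPECIFIC:
            for locus in self.loci:
                if not locus.is_diagnostic:
                    raise ValueError(
                        f"panel {self.panel_id!r}: locus {locus.locus_id!r} does not map "
                        f"both species to distinct alleles"
                    )
        object.__setattr__(self, "_by_id", {l.locus_id: l for l in self.loci})

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self) -> Iterator[Locus]:
        return iter(self.loci)

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self._by_id  # type: ignore[attr-defined]

    @property
    def locus_ids(self) -> tuple[str, ...]:
        return tuple(l.locus_id for l in self.loci)

    def locus(self, locus_id: str) -> Locus:
        return self._by_id[locus_id]  # type: ignore[attr-defined]


def default_interspecific_panel(n_loci: int = 35, panel_id: str = "diagnostic_BD") -> MarkerPanel:
    """Abstract diagnostic panel: ``n_loci`` unlinked SNPs fixed between the species.

    Species B (P. balsamifera) carries allele ``b`` and species D
    (P. deltoides) allele ``d`` at every locus.  The default length of 35
    matches the per-call accounting of the genotyping assay this panel
    emulates; chromosomes are assigned cyclically over the 18 poplar
    chromosome arms the assay spans.
    """
    loci = tuple(
        Locus(
            locus_id=f"snp{i + 1:03d}",
            chromosome=f"Chr{(i % 18) + 1:02d}",
            allele_by_species={SPECIES_B: "b", SPECIES_D: "d"},
        )
        for i in range(n_loci)
    )
    return MarkerPanel(panel_id=panel_id, kind=PanelKind.INTERSPECIFIC, loci=loci)


def default_intraspecific_panel(species: str = SPECIES_B, n_loci: Optional[int] = None) -> MarkerPanel:
    """Intraspecific panel for clone/sibship detection (35 loci for B, 33 for D)."""
    if species == SPECIES_B:
        n = 35 if n_loci is None else n_loci
        prefix, panel_id, kind = "bal", "intra_B", PanelKind.INTRASPECIFIC_B
    elif species == SPECIES_D:
        n = 33 if n_loci is None else n_loci
        prefix, panel_id, kind = "del", "intra_D", PanelKind.INTRASPECIFIC_D
    else:
        raise ValueError(f"unknown species code {species!r}")
    loci = tuple(Locus(locus_id=f"{prefix}{i + 1:03d}") for i in range(n))
    return MarkerPanel(panel_id=panel_id, kind=kind, loci=loci)


def save_panel(panel: MarkerPanel, path: Union[str, Path]) -> None:
    """Serialize a panel to YAML (``panel_id``, ``kind``, per-locus entries)."""
    data: dict = {
        "panel_id": panel.panel_id,
        "kind": panel.kind.value,
        "loci": [],
    }
    for locus in panel:
        entry: dict = {"locus_id": locus.locus_id}
        if locus.chromosome is not None:
            entry["chromosome"] = locus.chromosome
        if locus.allele_by_species:
            entry["alleles"] = dict(locus.allele_by_species)
        data["loci"].append(entry)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_panel(path: Union[str, Path]) -> MarkerPanel:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    loci = tuple(
        Locus(
            locus_id=entry["locus_id"],
            chromosome=entry.get("chromosome"),
            allele_by_species=entry.get("alleles", {}),
        )
        for entry in data["loci"]
    )
    return MarkerPanel(panel_id=data["panel_id"], kind=PanelKind(data["kind"]), loci=loci)
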