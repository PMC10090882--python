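"""Packaged taxon inventory for the comparative design.

The study sample comprises 51 specimens of 47 extant amniote species —
21 Aves, 8 Mammalia (endotherms), 4 Crocodylia, 3 Testudines and
11 Lepidosauria (ectotherms) — plus the dromaeosaurid fossil the airway
reconstruction targets.  Three species are represented by short
ontogenetic series (multiple specimens): *Struthio camelus*,
*Larus crassirostris* and *Alligator mississippiensis*.  The 4 extra
specimens are apportioned 3/2/2 across those series (a package choice;
only the per-species multiplicity, not the split, is fixed by the design).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["TaxonEntry", "packaged_taxon_fixture", "taxon_table"]

ENDOTHERM = "endotherm"
ECTOTHERM = "ectotherm"

# (species, clade, thermoregulatory class, number of specimens)
_TAXA: list[tuple[str, str, str, int]] = [
    ("Struthio camelus", "Aves", ENDOTHERM, 3),
    ("Dromaius novaehollandiae", "Aves", ENDOTHERM, 1),
    ("Coturnix japonica", "Aves", ENDOTHERM, 1),
    ("Numida meleagris", "Aves", ENDOTHERM, 1),
    ("Anas platyrhynchos", "Aves", ENDOTHERM, 1),
    ("Chordeiles minor", "Aves", ENDOTHERM, 1),
    ("Musophaga violacea", "Aves", ENDOTHERM, 1),
    ("Columba livia", "Aves", ENDOTHERM, 1),
    ("Gallinula chloropus", "Aves", ENDOTHERM, 1),
    ("Phoenicopterus roseus", "Aves", ENDOTHERM, 1),
    ("Fratercula cirrhata", "Aves", ENDOTHERM, 1),
    ("Fratercula arctica", "Aves", ENDOTHERM, 1),
    ("Larus crassirostris", "Aves", ENDOTHERM, 2),
    ("Gavia immer", "Aves", ENDOTHERM, 1),
    ("Phoebastria nigripes", "Aves", ENDOTHERM, 1),
    ("Phalacrocorax carbo", "Aves", ENDOTHERM, 1),
    ("Alcedo atthis", "Aves", ENDOTHERM, 1),
    ("Sarcoramphus papa", "Aves", ENDOTHERM, 1),
    ("Loriculus galgulus", "Aves", ENDOTHERM, 1),
    ("Corvus macrorhynchos", "Aves", ENDOTHERM, 1),
    ("Passer montanus", "Aves", ENDOTHERM, 1),
    ("Gorilla gorilla", "Mammalia", ENDOTHERM, 1),
    ("Macaca fuscata", "Mammalia", ENDOTHERM, 1),
    ("Pan troglodytes", "Mammalia", ENDOTHERM, 1),
    ("Symphalangus syndactylus", "Mammalia", ENDOTHERM, 1),
    ("Panthera leo", "Mammalia", ENDOTHERM, 1),
    ("Tapirus indicus", "Mammalia", ENDOTHERM, 1),
    ("Equus quagga", "Mammalia", ENDOTHERM, 1),
    ("Ceratotherium simum", "Mammalia", ENDOTHERM, 1),
    ("Crocodylus porosus", "Crocodylia", ECTOTHERM, 1),
    ("Crocodylus siamensis", "Crocodylia", ECTOTHERM, 1),
    ("Alligator mississippiensis", "Crocodylia", ECTOTHERM, 2),
    ("Caiman crocodilus", "Crocodylia", ECTOTHERM, 1),
    ("Chelodina mccordi", "Testudines", ECTOTHERM, 1),
    ("Chelydra serpentina", "Testudines", ECTOTHERM, 1),
    ("Geoclemys hamiltonii", "Testudines", ECTOTHERM, 1),
    ("Nephrurus amyae", "Lepidosauria", ECTOTHERM, 1),
    ("Eumeces schneideri", "Lepidosauria", ECTOTHERM, 1),
    ("Heloderma suspectum", "Lepidosauria", ECTOTHERM, 1),
    ("Pseudopus apodus", "Lepidosauria", ECTOTHERM, 1),
    ("Varanus albigularis", "Lepidosauria", ECTOTHERM, 1),
    ("Varanus exanthematicus", "Lepidosauria", ECTOTHERM, 1),
    ("Chlamydosaurus kingii", "Lepidosauria", ECTOTHERM, 1),
    ("Furcifer pardalis", "Lepidosauria", ECTOTHERM, 1),
    ("Iguana iguana", "Lepidosauria", ECTOTHERM, 1),
    ("Physignathus concincinus", "Lepidosauria", ECTOTHERM, 1),
    ("Python regius", "Lepidosauria", ECTOTHERM, 1),
]

_FOSSIL = ("Velociraptor mongoliensis", "Dinosauria", "unknown", 1)


@dataclass(frozen=True)
class TaxonEntry:
    species: str
    clade: str
    thermo_class: str
    n_specimens: int

    @property
    def multiple_specimens(self) -> bool:
        return self.n_specimens > 1


def packaged_taxon_fixture(include_fossil: bool = False) -> list[TaxonEntry]:
    """Return the packaged taxon inventory as a list of species entries.

    The default covers the 47 extant species (51 specimens) entering the
    allometric comparisons; ``include_fossil=True`` appends the
    dromaeosaurid target of the reconstruction stage, whose
    thermoregulatory class is by construction unknown.
    """
    taxa = [TaxonEntry(*row) for row in _TAXA]
    if include_fossil:
        taxa.append(TaxonEntry(*_FOSSIL))
    return taxa


def taxon_table(include_fossil: bool = False) -> pd.DataFrame:
    """Specimen-level inventory as a DataFrame (one row per specimen)."""
    rows = []
    for t in packaged_taxon_fixture(include_fossil=include_fossil):
        for i in range(t.n_specimens):
            sid = t.species if t.n_specimens == 1 else f"{t.species}_{i + 1}"
            rows.append(
                {
                    "species": t.species,
                    "specimen_id": sid,
                    "clade": t.clade,
                    "thermo_class": t.thermo_class,
                }
            )
    return pd.DataFrame(rows)
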