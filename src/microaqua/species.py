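"""Species registry: names, formulas and molar masses of the reaction system.

The canonical labels used throughout the package are ``H2O``, ``CPME``
(cyclopentyl methyl ether), ``FA`` (ferulic acid), ``4VG`` (4-vinylguaiacol)
and ``Na``. Sodium appears only in trajectory bookkeeping, never in the
thermodynamic mixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from .accounting import molar_mass
from .errors import RegistryError

WATER = "H2O"


@dataclass(frozen=True)
class Species:
    name: str
    formula: str
    molar_mass: float  # g/mol


def _sp(name: str, formula: str) -> Species:
    return Species(name, formula, molar_mass(formula))


#: Default registry of the reaction system.
DEFAULT_SPECIES: dict[str, Species] = {
    s.name: s
    for s in (
        _sp("H2O", "H2O"),
        _sp("CPME", "C6H12O"),
        _sp("FA", "C10H10O4"),
        _sp("4VG", "C9H10O2"),
        _sp("Na", "Na"),
    )
}

#: Density of CPME at 30 °C, g/mL; used to convert solvent volume to moles.
CPME_DENSITY_G_PER_ML = 0.86


def get_species(name: str, registry: dict[str, Species] | None = None) -> Species:
    registry = DEFAULT_SPECIES if registry is None else registry
    try:
        return registry[name]
    except KeyError:
        raise RegistryError(f"unknown species {name!r}; registered: {sorted(registry)}") from None


def load_species_registry(path) -> dict[str, Species]:
    """Read a species registry from a YAML file.

    Expected layout::

        species:
          - {name: H2O, formula: H2O}          # molar mass derived
          - {name: CPME, molar_mass: 100.158}  # or given explicitly
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries = (doc or {}).get("species")
    if not entries:
        raise RegistryError(f"{path}: no 'species' section")
    out = {}
    for e in entries:
        name = e["name"]
        formula = e.get("formula", "")
        mm = e.get("molar_mass", molar_mass(formula) if formula else None)
        if mm is None:
            raise RegistryError(f"{path}: species {name!r} needs a formula or molar_mass")
        out[name] = Species(name, formula, float(mm))
    return out
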