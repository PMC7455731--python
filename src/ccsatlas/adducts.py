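"""Adduct mass arithmetic and ppm utilities.

An electrospray adduct is the ionized form of a neutral molecule, e.g.
``[M+H]+`` or ``[M-H]-``, with a fixed net mass shift.  The shipped adduct
table carries the *net ion shift* in Da (electron mass already folded in,
so ``[M+H]+`` is exactly one proton: 1.00727646688 Da) for nine positive
and six negative singly charged adducts common in small-molecule IM-MS.
The table is versioned data (``data/adducts.tsv``) and user-extensible:
pass your own table to :func:`load_adducts`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "PROTON_MASS",
    "AdductSpec",
    "compute_adduct_mz",
    "default_adducts",
    "load_adducts",
    "ppm_error",
    "signed_ppm_error",
    "training_adducts",
]

#: Monoisotopic mass of the proton (the [M+H]+ ion shift), Da.
PROTON_MASS = 1.00727646688

# Unicode minus signs seen in adduct names copied from manuscripts.
_MINUS_VARIANTS = {"−": "-", "–": "-", "—": "-"}


def _canonical_name(name: str) -> str:
    for bad, good in _MINUS_VARIANTS.items():
        name = name.replace(bad, good)
    return name.replace(" ", "")


@dataclass(frozen=True)
class AdductSpec:
    """One adduct: name, polarity, net ion mass shift (Da) and charge."""

    name: str
    polarity: str  # "+" or "-"
    mass_shift: float
    charge: int = 1
    training: bool = False

    def __post_init__(self) -> None:
        if self.polarity not in ("+", "-"):
            raise ValueError(f"polarity must be '+' or '-', got {self.polarity!r}")
        if abs(self.charge) != 1:
            raise ValueError("only singly charged adducts are supported")


class AdductTable:
    """Lookup of :class:`AdductSpec` by canonicalized name."""

    def __init__(self, specs: list[AdductSpec]):
        self._specs = {_canonical_name(s.name): s for s in specs}

    def __contains__(self, name: str) -> bool:
        return _canonical_name(name) in self._specs

    def __iter__(self):
        return iter(self._specs.values())

    def __len__(self) -> int:
        return len(self._specs)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self._specs.values()]

    def get(self, name: str) -> AdductSpec:
        key = _canonical_name(name)
        if key not in self._specs:
            raise KeyError(
                f"unknown adduct {name!r}; known adducts: {', '.join(self.names)}"
            )
        return self._specs[key]

    def for_polarity(self, polarity: str) -> list[AdductSpec]:
        return [s for s in self._specs.values() if s.polarity == polarity]


def load_adducts(path: str | Path) -> AdductTable:
    """Load an adduct table from TSV (columns name, polarity, mass_shift, charge[, training])."""
    df = pd.read_csv(path, sep="\t")
    specs = [
        AdductSpec(
            name=row["name"],
            polarity=row["polarity"],
            mass_shift=float(row["mass_shift"]),
            charge=int(row["charge"]),
            training=bool(row.get("training", 0)),
        )
        for _, row in df.iterrows()
    ]
    return AdductTable(specs)


def default_adducts() -> AdductTable:
    """The shipped whitelist: 9 positive + 6 negative singly charged adducts."""
    with resources.as_file(resources.files("ccsatlas.data") / "adducts.tsv") as p:
        return load_adducts(p)


def training_adducts() -> AdductTable:
    """The seven most common adducts retained for model training.

    [M+H]+, [M+Na]+, [M+NH4]+, [M+H-H2O]+ in positive mode and
    [M-H]-, [M+Na-2H]-, [M+HCOO]- in negative mode.
    """
    return AdductTable([s for s in default_adducts() if s.training])


def compute_adduct_mz(neutral_mass: float, adduct: AdductSpec | str, table: AdductTable | None = None) -> float:
    """Theoretical ion m/z of ``neutral_mass`` under ``adduct``.

    For |z| = 1 this is ``neutral_mass + mass_shift``; the division by
    charge is reserved for future multiply charged support.
    """
    if neutral_mass <= 0:
        raise ValueError("neutral_mass must be positive")
    if isinstance(adduct, str):
        adduct = (table or default_adducts()).get(adduct)
    return (neutral_mass + adduct.mass_shift) / abs(adduct.charge)


def ppm_error(observed: float, theoretical: float) -> float:
    """Absolute mass error in parts per million: |obs - theo| / theo * 1e6."""
    return abs(signed_ppm_error(observed, theoretical))


def signed_ppm_error(observed: float, theoretical: float) -> float:
    """Signed mass error in ppm (positive when observed is heavier)."""
    if observed <= 0 or theoretical <= 0:
        raise ValueError("masses must be positive")
    return (observed - theoretical) / theoretical * 1e6
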