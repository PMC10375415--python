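"""Material definitions for proton transport.

Each material carries an effective atomic number Z, effective mass number A
(g/mol) and mean excitation energy I (eV) — the three composition parameters
the Bethe–Bloch stopping power and the Rutherford cross-section need — plus
the bulk mass density in g/cm^3.

Only Z/A and I enter the electronic stopping power, so for compounds the
effective (Z, A) pair is chosen to reproduce the tabulated Z/A of the
mixture; Z itself additionally sets the hard-scattering strength (Z^2) and
the radiation length used for multiple scattering.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import yaml

__all__ = [
    "Material",
    "MaterialRegistry",
    "PhysicsConstants",
    "CONSTANTS",
    "default_registry",
]


@dataclasses.dataclass(frozen=True)
class Material:
    """A homogeneous transport medium.

    Parameters
    ----------
    name:
        Registry label.
    density:
        Bulk mass density in g/cm^3. Must be positive.
    Z:
        Effective atomic number (dimensionless, >= 1).
    A:
        Effective mass number in g/mol (>= Z).
    I:
        Mean excitation energy in eV (> 0).
    """

    name: str
    density: float
    Z: float
    A: float
    I: float

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"{self.name}: density must be > 0, got {self.density}")
        if self.Z < 1:
            raise ValueError(f"{self.name}: Z must be >= 1, got {self.Z}")
        if self.A < self.Z:
            raise ValueError(f"{self.name}: A must be >= Z ({self.A} < {self.Z})")
        if self.I <= 0:
            raise ValueError(f"{self.name}: I must be > 0, got {self.I}")

    @property
    def radiation_length(self) -> float:
        """Approximate radiation length X0 in cm (Dahl's parameterization)."""
        x0_mass = 716.4 * self.A / (self.Z * (self.Z + 1) * math.log(287.0 / math.sqrt(self.Z)))
        return x0_mass / self.density

    def with_density(self, density: float) -> "Material":
        """Same composition at a different bulk density."""
        return dataclasses.replace(self, density=density)


@dataclasses.dataclass(frozen=True)
class PhysicsConstants:
    """Fixed physical constants (MeV / elementary-charge units)."""

    electron_mass: float = 0.51099895  # MeV
    proton_mass: float = 938.27208816  # MeV
    K: float = 0.307075  # Bethe-Bloch prefactor, MeV cm^2 / mol
    e2: float = 1.43996  # e^2 = alpha*hbar*c in MeV fm (Gaussian units)
    bohr_coeff: float = 0.1569  # energy-straggling variance, MeV^2 cm^2 / g


CONSTANTS = PhysicsConstants()


# Densities for water/hydroxyapatite/glass follow the phantom definition used
# throughout (water 1.0, hydroxyapatite 3.076, glass 1.8 g/cm^3); Z/A and I
# from standard stopping-power compilations.
_DEFAULTS = [
    Material("water", 1.0, 7.42, 13.37, 75.0),
    Material("air", 1.20479e-3, 7.64, 15.31, 85.7),
    Material("hydroxyapatite", 3.076, 14.07, 28.29, 145.9),
    Material("glass", 1.8, 10.80, 21.63, 139.2),
    Material("Pb", 11.35, 82.0, 207.2, 823.0),
    Material("scintillator", 1.032, 5.61, 10.36, 64.7),  # polyvinyltoluene-like
]


class MaterialRegistry:
    """Ordered name -> Material mapping with stable integer ids."""

    def __init__(self, materials=()):
        self._materials: dict[str, Material] = {}
        self._ids: dict[str, int] = {}
        for m in materials:
            self.add(m)

    def add(self, m: Material) -> int:
        if m.name in self._materials:
            raise ValueError(f"material {m.name!r} already registered")
        self._materials[m.name] = m
        self._ids[m.name] = len(self._ids)
        return self._ids[m.name]

    def __contains__(self, name: str) -> bool:
        return name in self._materials

    def __getitem__(self, name: str) -> Material:
        try:
            return self._materials[name]
        except KeyError:
            raise KeyError(
                f"unknown material {name!r}; registered: {sorted(self._materials)}"
            ) from None

    def __iter__(self):
        return iter(self._materials.values())

    def __len__(self) -> int:
        return len(self._materials)

    def id_of(self, name: str) -> int:
        self[name]  # raise on unknown
        return self._ids[name]

    def name_of(self, mid: int) -> str:
        for name, i in self._ids.items():
            if i == mid:
                return name
        raise KeyError(f"no material with id {mid}")

    def arrays(self):
        """Per-id (density, Z, A, I) float arrays for vectorized lookups."""
        import numpy as np

        mats = list(self._materials.values())
        return (
            np.array([m.density for m in mats]),
            np.array([m.Z for m in mats]),
            np.array([m.A for m in mats]),
            np.array([m.I for m in mats]),
        )

    # -- serialization ----------------------------------------------------
    def to_yaml(self, path) -> None:
        entries = [
            {"name": m.name, "density": m.density, "Z": m.Z, "A": m.A, "I": m.I}
            for m in self
        ]
        Path(path).write_text(yaml.safe_dump({"materials": entries}, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "MaterialRegistry":
        data = yaml.safe_load(Path(path).read_text())
        return cls(Material(**e) for e in data["materials"])


def default_registry() -> MaterialRegistry:
    """Registry with the six standard phantom/detector materials."""
    return MaterialRegistry(_DEFAULTS)
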