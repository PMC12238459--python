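"""Material definitions and photon/electron interaction data.

Each :class:`MaterialSpec` carries a mass density, a linear attenuation
table (1/cm vs keV), and a unitless electron stopping-power scale relative
to liquid water.  Attenuation tables are assembled from a bundled
photoelectric table for water (scaled by an effective-Z factor) plus an
analytic Klein-Nishina incoherent term; coherent scattering is neglected.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "MaterialSpec",
    "builtin_materials",
    "klein_nishina_total",
    "klein_nishina_mean_scatter_fraction",
    "photon_energy_grid",
    "pe_mass_water",
    "ELECTRONS_PER_GRAM_WATER",
]

#: classical electron cross-section prefactor, barn
_R_E2_BARN = 0.079408  # pi * r_e^2 ... used only through klein_nishina_total
MEC2_KEV = 510.998950

ELECTRONS_PER_GRAM_WATER = 3.3428e23

ENERGY_MIN_KEV = 10.0
ENERGY_MAX_KEV = 600.0


def _read_table(name: str, columns: tuple[str, ...]) -> dict[str, np.ndarray]:
    path = resources.files("voxdose.data").joinpath(name)
    rows: list[list[float]] = []
    with path.open() as fh:
        for rec in csv.DictReader(
            line for line in fh if not line.startswith("#")
        ):
            rows.append([float(rec[c]) for c in columns])
    arr = np.asarray(rows, dtype=float)
    return {c: arr[:, i] for i, c in enumerate(columns)}


_PE_WATER = _read_table("photon_pe_water.csv", ("energy_kev", "pe_mass"))


def photon_energy_grid(n: int = 64) -> np.ndarray:
    """Log-spaced photon energy grid (keV) spanning the supported range."""
    return np.geomspace(ENERGY_MIN_KEV, ENERGY_MAX_KEV, n)


def pe_mass_water(energy_kev: np.ndarray | float) -> np.ndarray:
    """Photoelectric mass attenuation of water, cm^2/g (log-log interp)."""
    e = np.atleast_1d(np.asarray(energy_kev, dtype=float))
    out = np.exp(
        np.interp(
            np.log(e),
            np.log(_PE_WATER["energy_kev"]),
            np.log(_PE_WATER["pe_mass"]),
        )
    )
    return out if np.ndim(energy_kev) else float(out[0])


def klein_nishina_total(energy_kev: np.ndarray | float) -> np.ndarray:
    """Total Klein-Nishina cross section per electron, barn."""
    k = np.asarray(energy_kev, dtype=float) / MEC2_KEV
    t1 = (1 + k) / k**2 * (2 * (1 + k) / (1 + 2 * k) - np.log(1 + 2 * k) / k)
    t2 = np.log(1 + 2 * k) / (2 * k)
    t3 = -(1 + 3 * k) / (1 + 2 * k) ** 2
    sigma_thomson = 0.66525  # barn
    return 0.75 * sigma_thomson * (t1 + t2 + t3)


def klein_nishina_mean_scatter_fraction(energy_kev: float, n: int = 4000) -> float:
    """Mean scattered-photon energy fraction <E'/E> by quadrature of the
    Klein-Nishina differential cross section (independent oracle for the
    in-kernel Kahn sampler)."""
    k = energy_kev / MEC2_KEV
    mu = np.linspace(-1.0, 1.0, n)
    x = 1.0 + k * (1.0 - mu)  # E/E'
    # dsigma/dOmega ~ (1/x^2) (x + 1/x - 1 + mu^2)
    w = (1.0 / x**2) * (x + 1.0 / x - 1.0 + mu**2)
    return float(np.trapezoid(w / x, mu) / np.trapezoid(w, mu))


@dataclass(frozen=True)
class MaterialSpec:
    """A simulation material.

    Parameters
    ----------
    name : str
    density : float
        Mass density, g/cm^3.  Must be positive.
    electrons_per_gram : float
        Electron density, e/g; drives the incoherent attenuation term.
    pe_scale : float
        Photoelectric cross section per gram relative to water
        (an effective-Z^3.6 style factor).
    stopping_power_scale : float
        Mass collision stopping power relative to water (unitless).
    """

    name: str
    density: float
    electrons_per_gram: float = ELECTRONS_PER_GRAM_WATER
    pe_scale: float = 1.0
    stopping_power_scale: float = 1.0
    mu_by_energy: tuple = field(default=None, compare=False)  # type: ignore[assignment]

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError(f"material {self.name!r}: density must be > 0")
        if self.mu_by_energy is None:
            e = photon_energy_grid()
            object.__setattr__(self, "mu_by_energy", (tuple(e), tuple(self.mu(e))))
        mu = np.asarray(self.mu_by_energy[1])
        if np.any(mu < 0):
            raise ValueError(f"material {self.name!r}: mu values must be >= 0")

    # -- photon coefficients ------------------------------------------------
    def pe_mass(self, energy_kev) -> np.ndarray:
        """Photoelectric mass attenuation, cm^2/g."""
        return pe_mass_water(energy_kev) * self.pe_scale

    def incoherent_mass(self, energy_kev) -> np.ndarray:
        """Incoherent (Klein-Nishina) mass attenuation, cm^2/g."""
        return klein_nishina_total(energy_kev) * 1e-24 * self.electrons_per_gram

    def mu(self, energy_kev) -> np.ndarray:
        """Total linear attenuation coefficient, 1/cm."""
        return self.density * (self.pe_mass(energy_kev) + self.incoherent_mass(energy_kev))


def builtin_materials() -> dict[str, MaterialSpec]:
    """Bundled material library.

    Densities follow Woodard & White conventions for soft tissues and
    marrow (1.03 g/cm^3); the photoelectric scale of bone corresponds to
    its higher effective Z.
    """
    return {
        "air": MaterialSpec("air", 0.0012, electrons_per_gram=3.006e23, pe_scale=1.1),
        "soft": MaterialSpec("soft", 1.00),
        "tumour": MaterialSpec("tumour", 1.00),
        "marrow": MaterialSpec("marrow", 1.03, stopping_power_scale=0.99),
        "lung": MaterialSpec("lung", 0.26),
        "bone": MaterialSpec(
            "bone",
            1.92,
            electrons_per_gram=3.10e23,
            pe_scale=6.7,
            stopping_power_scale=0.92,
        ),
    }
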