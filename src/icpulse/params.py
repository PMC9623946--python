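"""Physical parameters, unit conversions and derived elastic constants.

All quantities are stored internally in SI units (m, s, Pa, m^3).  Clinical
units (mmHg, ml) are accepted and produced only at the boundary of the
package, via explicit conversion helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "MMHG_TO_PA",
    "ML_TO_M3",
    "MaterialParams",
    "lame_from_elastic",
    "elastic_from_lame",
    "pressure_convert",
]

#: 1 mmHg in Pa.
MMHG_TO_PA = 133.322

#: 1 ml in m^3.
ML_TO_M3 = 1e-6

_PRESSURE_UNITS = ("Pa", "mmHg")


def lame_from_elastic(E: float, nu: float) -> tuple[float, float]:
    """First Lame parameter and shear modulus from engineering constants.

    Parameters
    ----------
    E : float
        Young modulus in Pa, must be positive.
    nu : float
        Poisson ratio, must satisfy ``0 <= nu < 0.5``.

    Returns
    -------
    lam, mu_s : float
        ``lam = nu*E/((1-2*nu)*(1+nu))`` and ``mu_s = E/(2*(1+nu))``.
    """
    if E <= 0:
        raise ValueError(f"Young modulus must be positive, got E={E}")
    if not 0.0 <= nu < 0.5:
        raise ValueError(
            f"Poisson ratio must satisfy 0 <= nu < 0.5 (lambda is undefined "
            f"in the incompressible limit), got nu={nu}"
        )
    lam = nu * E / ((1.0 - 2.0 * nu) * (1.0 + nu))
    mu_s = E / (2.0 * (1.0 + nu))
    return lam, mu_s


def elastic_from_lame(lam: float, mu_s: float) -> tuple[float, float]:
    """Invert :func:`lame_from_elastic`: engineering constants from (lam, mu_s)."""
    if mu_s <= 0:
        raise ValueError(f"shear modulus must be positive, got {mu_s}")
    if lam < 0:
        raise ValueError(f"first Lame parameter must be nonnegative, got {lam}")
    E = mu_s * (3.0 * lam + 2.0 * mu_s) / (lam + mu_s)
    nu = lam / (2.0 * (lam + mu_s))
    return E, nu


def pressure_convert(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a pressure between Pa and mmHg (1 mmHg = 133.322 Pa)."""
    for u in (from_unit, to_unit):
        if u not in _PRESSURE_UNITS:
            raise ValueError(f"unknown pressure unit {u!r}; expected one of {_PRESSURE_UNITS}")
    if from_unit == to_unit:
        return value
    if from_unit == "mmHg":
        return value * MMHG_TO_PA
    return value / MMHG_TO_PA


@dataclass(frozen=True)
class MaterialParams:
    """All physical constants of the model, in SI units.

    The elastic Lame constants ``lam`` and ``mu_s`` are always derived from
    ``(E, nu)`` and kept consistent with them.  ``rho_s`` is recorded for
    completeness but does not enter the quasi-static solid momentum balance.

    Defaults are the values used by the standard parameterization of the
    model (see :func:`standard_params`).
    """

    E: float = 1500.0            # Young modulus [Pa]
    nu: float = 0.479            # Poisson ratio [-]
    alpha: float = 1.0           # Biot-Willis coefficient [-]
    c: float = 1e-6              # storage coefficient [1/Pa]
    kappa: float = 1e-16         # permeability [m^2]
    mu_f: float = 0.8e-3         # CSF/ISF dynamic viscosity [Pa s]
    rho_f: float = 1007.0        # CSF density [kg/m^3]
    rho_s: float = 1081.0        # tissue density [kg/m^3] (recorded, unused)
    gamma: float = 1.0           # BJS slip-rate coefficient [-]
    PVI: float = 3.0 * ML_TO_M3  # spinal pressure-volume index [m^3]
    p0: float = 4.5 * MMHG_TO_PA # initial ICP [Pa]
    lam: float = field(init=False)   # first Lame parameter [Pa], derived
    mu_s: float = field(init=False)  # shear modulus [Pa], derived

    def __post_init__(self) -> None:
        lam, mu_s = lame_from_elastic(self.E, self.nu)
        object.__setattr__(self, "lam", lam)
        object.__setattr__(self, "mu_s", mu_s)
        if self.kappa <= 0:
            raise ValueError(f"permeability must be positive, got {self.kappa}")
        if self.mu_f <= 0:
            raise ValueError(f"fluid viscosity must be positive, got {self.mu_f}")
        if self.c < 0:
            raise ValueError(f"storage coefficient must be nonnegative, got {self.c}")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"Biot-Willis coefficient must be in (0, 1], got {self.alpha}")
        if self.PVI <= 0:
            raise ValueError(f"pressure-volume index must be positive, got {self.PVI}")
        if self.p0 <= 0:
            raise ValueError(f"initial ICP must be positive, got {self.p0}")
        if self.rho_f <= 0 or self.rho_s <= 0:
            raise ValueError("densities must be positive")
        if self.gamma < 0:
            raise ValueError(f"slip-rate coefficient must be nonnegative, got {self.gamma}")

    @classmethod
    def from_clinical(
        cls,
        *,
        PVI_ml: float | None = None,
        p0_mmHg: float | None = None,
        **kwargs,
    ) -> "MaterialParams":
        """Construct with PVI given in ml and/or p0 given in mmHg."""
        if PVI_ml is not None:
            kwargs["PVI"] = PVI_ml * ML_TO_M3
        if p0_mmHg is not None:
            kwargs["p0"] = pressure_convert(p0_mmHg, "mmHg", "Pa")
        return cls(**kwargs)

    def with_(self, **kwargs) -> "MaterialParams":
        """Return a copy with the given fields replaced (lam/mu_s re-derived)."""
        kwargs.pop("lam", None)
        kwargs.pop("mu_s", None)
        return replace(self, **kwargs)

    @property
    def p0_mmHg(self) -> float:
        return pressure_convert(self.p0, "Pa", "mmHg")

    @property
    def PVI_ml(self) -> float:
        return self.PVI / ML_TO_M3

    def as_dict(self) -> dict:
        """Resolved SI values, e.g. for the run log."""
        return {
            "E": self.E, "nu": self.nu, "lam": self.lam, "mu_s": self.mu_s,
            "alpha": self.alpha, "c": self.c, "kappa": self.kappa,
            "mu_f": self.mu_f, "rho_f": self.rho_f, "rho_s": self.rho_s,
            "gamma": self.gamma, "PVI": self.PVI, "p0": self.p0,
        }


def standard_params() -> MaterialParams:
    """The standard parameterization of the model."""
    return MaterialParams()
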