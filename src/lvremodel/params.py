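"""Model parameters and state for the post-MI left-ventricular remodeling model.

The model tracks two cell populations and five chemical species in the
infarct region over days 0-30 after myocardial infarction:

* macrophage density ``M_phi`` (cells/mm^3) and fibroblast density ``F``
  (cells/mm^3),
* active TGF-beta1 ``T_beta`` (pg/uL), free activated MMP-9 ``M9A`` (pg/uL),
* free collagen ``C`` (ug/uL), the MMP-9/collagen enzyme-substrate complex
  ``CM9`` (ug/uL) and degraded collagen peptides ``CID`` (ug/uL).

Note that 1 mm^3 == 1 uL, so densities per mm^3 and concentrations per uL
share the same volume basis.

All rate constants are per day.  The enzyme-kinetic constants ``k_on``,
``k_off`` and ``k_onc`` are usable either as per-day values (the default,
which is the only choice consistent with the published complex equilibrium)
or converted from per-second via ``kinetic_time_unit="per-second"``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterator

import numpy as np

__all__ = ["ModelParameters", "ModelState", "STATE_COMPONENTS"]

_SECONDS_PER_DAY = 86400.0

_KINETIC_TIME_UNITS = ("per-day-as-printed", "per-second")


@dataclasses.dataclass(frozen=True)
class ModelParameters:
    """Rate constants, capacities and structural fractions of the model.

    Defaults are the published pre-determined values; ``u_T0`` (baseline
    TGF-beta1 activation) and ``d_CID`` (peptide clearance) default to zero.
    """

    #: macrophage removal (emigration to lymphatics) rate, 1/day
    d_Mphi: float = 0.6
    #: maximal macrophage density in scar tissue, cells/mm^3
    rho_Mphi: float = 2500.0
    #: maximal fibroblast density in scar tissue, cells/mm^3
    rho_F: float = 1250.0
    #: maximal collagen density in scar tissue, ug/mm^3
    rho_C: float = 3300.0
    #: fibroblast growth rate, 1/day
    k_F: float = 0.924
    #: fibroblast apoptosis rate, 1/day
    d_F: float = 0.12
    #: macrophage TGF-beta1 production rate, pg/cell/day
    k_MphiT: float = 0.07
    #: fibroblast TGF-beta1 production rate, pg/cell/day
    k_FT: float = 0.004
    #: TGF-beta1 degradation rate, 1/day
    d_Tbeta: float = 15.0
    #: macrophage MMP-9 secretion rate, pg/cell/day
    k_MphiM9: float = 3.0
    #: free MMP-9 degradation rate, 1/day
    d_M9: float = 0.875
    #: MMP-9/collagen association constant, 1/(ug/mm^3)/time
    k_on: float = 3e-4
    #: complex dissociation constant, 1/time
    k_off: float = 4e-4
    #: complex catalytic turnover constant, 1/time
    k_onc: float = 0.004
    #: fibroblast collagen production rate, ug/cell/day
    k_FC: float = 20.0
    #: TIMP-mediated inhibition half-effect TGF-beta1 concentration, pg/uL
    T_betaN: float = 6.0
    #: myocyte death rate in the infarct, 1/day
    d_mc: float = 0.05
    #: endothelial + smooth-muscle structural occupancy fraction
    frac_endo_smc: float = 0.17
    #: myocyte structural occupancy fraction (pre-MI)
    frac_myocyte: float = 0.56
    #: time unit declared for k_on/k_off/k_onc
    kinetic_time_unit: str = "per-day-as-printed"
    #: baseline (pre-MI) TGF-beta1 activation, pg/uL/day
    u_T0: float = 0.0
    #: collagen-peptide clearance rate, 1/day (0 = pure accumulation)
    d_CID: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "d_Mphi", "rho_Mphi", "rho_F", "rho_C", "k_F", "d_F", "k_MphiT",
            "k_FT", "d_Tbeta", "k_MphiM9", "d_M9", "k_on", "k_off", "k_onc",
            "k_FC", "T_betaN", "d_mc", "frac_endo_smc", "frac_myocyte",
        ):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"parameter {name!r} must be strictly positive, got {value}")
        for name in ("u_T0", "d_CID"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"parameter {name!r} must be >= 0, got {value}")
        if self.frac_endo_smc + self.frac_myocyte >= 1.0:
            raise ValueError(
                "structural fractions frac_endo_smc + frac_myocyte must sum to < 1"
            )
        if self.kinetic_time_unit not in _KINETIC_TIME_UNITS:
            raise ValueError(
                f"kinetic_time_unit must be one of {_KINETIC_TIME_UNITS}, "
                f"got {self.kinetic_time_unit!r}"
            )

    # -- kinetics in working (per-day) units ---------------------------------

    def kinetics_per_day(self) -> tuple[float, float, float]:
        """Return (k_on, k_off, k_onc) expressed per day."""
        if self.kinetic_time_unit == "per-second":
            s = _SECONDS_PER_DAY
            return self.k_on * s, self.k_off * s, self.k_onc * s
        return self.k_on, self.k_off, self.k_onc

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**data)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)


#: canonical ordering of the state vector
STATE_COMPONENTS = ("M_phi", "F", "T_beta", "M9A", "C", "CM9", "CID")


@dataclasses.dataclass(frozen=True)
class ModelState:
    """The seven dynamic quantities, in the model's published units."""

    M_phi: float  # cells/mm^3
    F: float      # cells/mm^3
    T_beta: float  # pg/uL
    M9A: float    # pg/uL
    C: float      # ug/uL
    CM9: float    # ug/uL
    CID: float = 0.0  # ug/uL

    def __post_init__(self) -> None:
        for name in STATE_COMPONENTS:
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ValueError(f"state component {name!r} must be finite, got {value}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in STATE_COMPONENTS], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "ModelState":
        y = np.asarray(y, dtype=float)
        if y.shape != (len(STATE_COMPONENTS),):
            raise ValueError(f"expected a vector of length {len(STATE_COMPONENTS)}")
        return cls(**dict(zip(STATE_COMPONENTS, y.tolist())))

    def __iter__(self) -> Iterator[float]:
        return iter(self.as_array())

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in STATE_COMPONENTS}
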