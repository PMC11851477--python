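"""Poiseuille-law hemodynamics, ABI computation, and limb-pressure scaling.

This module holds the macro-scale plumbing of the capillary model: laminar
(Poiseuille) resistance and flow for a cylindrical vessel, unit conversion,
the ankle-brachial index (ABI) and its clinical strata, and the
limb-pressure scaling rule that maps a patient's ankle systolic pressure
onto arterial and capillary pressures/flows relative to a 120 mmHg
normotensive baseline.

Reference constants describe a posterior tibial artery (PTA) and a skin
capillary of a normotensive adult (ABI = 1).  The arterial resistance and
baseline arterial flow are literature constants taken as given; they are
*not* recomputed from the arterial geometry, which is insufficient to
reproduce them by Poiseuille's law.  The capillary quantities, in
contrast, are fully derived: R = 8*eta*l/(pi*r^4) with r = diameter/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .exceptions import ConfigurationError, InvalidInputError

#: mmHg -> Pa conversion factor (one conventional millimetre of mercury).
MMHG_TO_PA = 133.322

#: Ankle systolic pressure of the normotensive reference subject, mmHg.
BASELINE_ANKLE_MMHG = 120.0

#: Mean capillary pressure of the reference subject, mmHg.
BASELINE_CAPILLARY_MMHG = 25.0

#: PTA resistance, Pa*s/m^3 — literature value, used as a given constant.
ARTERIAL_RESISTANCE = 3.02e7

#: PTA flow at the 120 mmHg baseline, m^3/s — literature value, given.
ARTERIAL_BASELINE_FLOW = 5.30e-4


@dataclass(frozen=True)
class VesselGeometry:
    """Geometric and rheological description of a cylindrical vessel.

    Parameters
    ----------
    diameter_mm : float
        Luminal diameter in millimetres.  The radius used everywhere is
        ``diameter_mm / 2``.
    length_m : float
        Vessel length in metres.
    wall_thickness_mm : float
        Wall thickness in millimetres (descriptive; not used by
        Poiseuille's law).
    viscosity_pa_s : float
        Dynamic viscosity of blood in the vessel, Pa*s.
    density_kg_m3 : float
        Blood mass density, kg/m^3.
    reference_pressure_mmhg : float
        Typical driving pressure for the vessel, mmHg.
    """

    diameter_mm: float
    length_m: float
    wall_thickness_mm: float
    viscosity_pa_s: float
    density_kg_m3: float
    reference_pressure_mmhg: float

    def __post_init__(self) -> None:
        for name in (
            "diameter_mm",
            "length_m",
            "wall_thickness_mm",
            "viscosity_pa_s",
            "density_kg_m3",
            "reference_pressure_mmhg",
        ):
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise InvalidInputError(f"VesselGeometry.{name} must be a positive finite number, got {value!r}")

    @property
    def radius_m(self) -> float:
        """Luminal radius in metres (diameter/2)."""
        return self.diameter_mm / 2.0 * 1e-3


#: Reference capillary vessel (normotensive adult, ABI = 1).
CAPILLARY = VesselGeometry(
    diameter_mm=0.007,
    length_m=0.0007,
    wall_thickness_mm=0.0005,
    viscosity_pa_s=0.0012,
    density_kg_m3=1060.0,
    reference_pressure_mmhg=25.0,
)

#: Reference posterior tibial artery.
ARTERY = VesselGeometry(
    diameter_mm=3.0,
    length_m=0.05,
    wall_thickness_mm=0.5,
    viscosity_pa_s=0.0045,
    density_kg_m3=1060.0,
    reference_pressure_mmhg=120.0,
)


@dataclass(frozen=True)
class PatientRecord:
    """Per-patient hemodynamic record.

    ``abi`` must agree with ``ankle_systolic / brachial_systolic`` within
    printed rounding (0.03), which guards against transcription errors.
    """

    patient_id: str
    brachial_systolic: float
    ankle_systolic: float
    abi: float
    wound_area_cm2: float

    def __post_init__(self) -> None:
        if self.brachial_systolic <= 0 or self.ankle_systolic <= 0:
            raise InvalidInputError("systolic pressures must be positive")
        if self.abi <= 0:
            raise InvalidInputError("ABI must be positive")
        if abs(self.abi - self.ankle_systolic / self.brachial_systolic) > 0.03:
            raise InvalidInputError(
                f"ABI {self.abi} inconsistent with ankle/brachial "
                f"{self.ankle_systolic}/{self.brachial_systolic}"
            )


@dataclass(frozen=True)
class HemodynamicProfile:
    """Derived arterial and capillary pressures, flows and resistances."""

    arterial_pressure_mmhg: float
    capillary_pressure_mmhg: float
    arterial_flow_m3_s: float
    capillary_flow_m3_s: float
    arterial_resistance: float
    capillary_resistance: float

    def __post_init__(self) -> None:
        if self.arterial_resistance <= 0 or self.capillary_resistance <= 0:
            raise InvalidInputError("resistances must be positive")
        if self.capillary_resistance <= self.arterial_resistance:
            raise InvalidInputError("capillary resistance must exceed arterial resistance")
        if self.arterial_flow_m3_s < 0 or self.capillary_flow_m3_s < 0:
            raise InvalidInputError("flows must be nonnegative")


def poiseuille_resistance(geom: VesselGeometry) -> float:
    """Hydraulic resistance of a cylindrical vessel, 8*eta*l/(pi*r^4).

    Returns Pa*s/m^3.  For the reference capillary this evaluates to
    1.43e16 (3 s.f.).
    """
    r = geom.radius_m
    return 8.0 * geom.viscosity_pa_s * geom.length_m / (math.pi * r**4)


def poiseuille_flow(delta_p_pa: float, resistance: float) -> float:
    """Laminar volumetric flow Q = dp / R, in m^3/s."""
    if resistance <= 0:
        raise InvalidInputError("resistance must be positive")
    return delta_p_pa / resistance


def mmhg_to_pa(p_mmhg: float) -> float:
    """Convert a pressure from mmHg to Pa."""
    return p_mmhg * MMHG_TO_PA


def compute_abi(ankle_mmhg: float, brachial_mmhg: float) -> float:
    """Ankle-brachial index: ankle over brachial systolic pressure."""
    if brachial_mmhg <= 0:
        raise InvalidInputError("brachial pressure must be positive")
    return ankle_mmhg / brachial_mmhg


def classify_abi(abi: float) -> str:
    """Clinical ABI stratum.

    Strata (boundaries inclusive as conventionally printed):
    severe <= 0.4; moderate 0.41-0.7; normal 0.9-1.3; moenckeberg >= 1.4
    (medial calcification producing an artificially stiff, high-ABI
    artery).  Values in the gaps between strata return ``unclassified``
    rather than being forced into a neighbouring class.
    """
    if abi <= 0:
        raise InvalidInputError("ABI must be positive")
    if abi <= 0.4:
        return "severe"
    if 0.41 <= abi <= 0.7:
        return "moderate"
    if 0.9 <= abi <= 1.3:
        return "normal"
    if abi >= 1.4:
        return "moenckeberg"
    return "unclassified"


def baseline_capillary_flow(capillary_geom: VesselGeometry = CAPILLARY) -> float:
    """Capillary flow of the reference subject: 25 mmHg across R_cap.

    Full precision is retained; the 3 s.f. rendering is 2.34e-13 m^3/s.
    """
    return poiseuille_flow(mmhg_to_pa(BASELINE_CAPILLARY_MMHG), poiseuille_resistance(capillary_geom))


def abi_scaled_capillary_flow(
    ankle_mmhg: float, capillary_geom: VesselGeometry = CAPILLARY
) -> float:
    """Capillary flow scaled by the patient's ankle pressure.

    The reference capillary flow (25 mmHg over the Poiseuille capillary
    resistance) is scaled linearly by ankle/120.  This is the amplitude
    used for the target (capillary-exit) flow waveform.
    """
    if ankle_mmhg <= 0:
        raise InvalidInputError("ankle pressure must be positive")
    return baseline_capillary_flow(capillary_geom) * (ankle_mmhg / BASELINE_ANKLE_MMHG)


def limb_scaled_profile(
    patient: PatientRecord,
    capillary_geom: VesselGeometry = CAPILLARY,
    *,
    arterial_resistance: float = ARTERIAL_RESISTANCE,
    arterial_baseline_flow: float = ARTERIAL_BASELINE_FLOW,
) -> HemodynamicProfile:
    """Hemodynamic profile of a patient by limb-pressure scaling.

    All pressures and flows scale linearly with the ratio
    s = ankle_systolic / 120 relative to the normotensive baseline:
    capillary pressure 25*s mmHg, arterial flow 5.30e-4*s m^3/s,
    capillary flow Q_cap_baseline*s.  Resistances are geometry
    properties and are copied unchanged.  The linear rule is the unique
    scaling consistent with Poiseuille's law at fixed resistance.
    """
    if arterial_resistance is None or arterial_baseline_flow is None:
        raise ConfigurationError("arterial baseline resistance and flow are required")
    s = patient.ankle_systolic / BASELINE_ANKLE_MMHG
    return HemodynamicProfile(
        arterial_pressure_mmhg=patient.ankle_systolic,
        capillary_pressure_mmhg=BASELINE_CAPILLARY_MMHG * s,
        arterial_flow_m3_s=arterial_baseline_flow * s,
        capillary_flow_m3_s=baseline_capillary_flow(capillary_geom) * s,
        arterial_resistance=arterial_resistance,
        capillary_resistance=poiseuille_resistance(capillary_geom),
    )


_PATIENT_COLUMNS = [
    "patient_id",
    "brachial_systolic_mmHg",
    "ankle_systolic_mmHg",
    "abi",
    "wound_area_cm2",
]


def load_patients(path: str | Path | None = None) -> list[PatientRecord]:
    """Load patient records from CSV (default: the packaged fixture cohort).

    The CSV must carry the header
    ``patient_id,brachial_systolic_mmHg,ankle_systolic_mmHg,abi,wound_area_cm2``.
    """
    if path is None:
        source = resources.files("capfit").joinpath("data/patients.csv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    missing = [c for c in _PATIENT_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"patient CSV missing columns: {missing}")
    return [
        PatientRecord(
            patient_id=str(row.patient_id),
            brachial_systolic=float(row.brachial_systolic_mmHg),
            ankle_systolic=float(row.ankle_systolic_mmHg),
            abi=float(row.abi),
            wound_area_cm2=float(row.wound_area_cm2),
        )
        for row in df.itertuples(index=False)
    ]
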