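"""TEER and apparent-permeability computation for insert-grown cell layers.

Transepithelial electrical resistance (TEER) is reported as a
resistance-area product (ohm * cm^2) after subtracting the resistance of a
cell-free (blank) insert.  The apparent permeability coefficient of a
tracer crossing the layer from the donor to the acceptor compartment is

    Papp (cm/s) = dC_A * V_A / (A * C_D * dt)

where ``dC_A`` is the acceptor-concentration increase over the assay,
``C_D`` the donor concentration at t = 0, ``V_A`` the acceptor volume,
``A`` the insert area and ``dt`` the assay duration.  Millilitres are
treated as cm^3 (exact), and the concentration units cancel, so the result
comes out in cm/s.  Donor depletion is neglected (sink assumption),
appropriate for short (30-60 min) assays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TeerReading",
    "PermeabilityRecord",
    "FluorescenceCalibration",
    "compute_teer",
    "fluorescence_to_concentration",
    "compute_papp",
    "percent_of_control",
    "papp_table",
]

#: Blank (cell-free insert) resistance-area product, ohm*cm^2. Typical
#: cell-free polycarbonate inserts read 90-100 ohm*cm^2; the midpoint is
#: used when no blank measurement is supplied.
DEFAULT_BLANK_OHM_CM2 = 95.0


@dataclass(frozen=True)
class TeerReading:
    """One raw volt-ohmmeter reading of an insert.

    Parameters
    ----------
    raw_ohm : float
        Measured resistance of the insert with cells, ohm.
    blank_ohm : float
        Resistance of a cell-free insert (same medium), ohm.
    area_cm2 : float
        Growth area of the insert membrane, cm^2.
    label : str
        Free-form well/timepoint label.
    """

    raw_ohm: float
    blank_ohm: float = DEFAULT_BLANK_OHM_CM2 / 1.12
    area_cm2: float = 1.12
    label: str = ""

    def __post_init__(self) -> None:
        if self.area_cm2 <= 0:
            raise ValueError(f"insert area must be positive, got {self.area_cm2}")
        if self.blank_ohm < 0:
            raise ValueError(f"blank resistance must be >= 0, got {self.blank_ohm}")


@dataclass(frozen=True)
class PermeabilityRecord:
    """Donor/acceptor tracer measurements for one insert.

    ``dc_acceptor`` is the acceptor-compartment concentration at assay end
    minus at assay start (start assumed 0 unless the caller subtracts it).
    Negative measured values, which arise from plate-reader noise near the
    blank, are clamped to 0 with a warning rather than rejected.
    """

    c_donor: float
    dc_acceptor: float
    v_acceptor_ml: float = 1.5
    area_cm2: float = 1.12
    duration_s: float = 1800.0
    tracer: str = "fluorescein"

    def __post_init__(self) -> None:
        if self.c_donor <= 0:
            raise ValueError(f"donor concentration must be positive, got {self.c_donor}")
        if self.duration_s <= 0:
            raise ValueError(f"assay duration must be positive, got {self.duration_s}")
        if self.v_acceptor_ml <= 0 or self.area_cm2 <= 0:
            raise ValueError("acceptor volume and insert area must be positive")
        if self.dc_acceptor < 0:
            warnings.warn(
                f"negative acceptor concentration change ({self.dc_acceptor:g}) "
                "clamped to 0 (plate-reader noise near blank)",
                RuntimeWarning,
                stacklevel=3,
            )
            object.__setattr__(self, "dc_acceptor", 0.0)


@dataclass(frozen=True)
class FluorescenceCalibration:
    """Standard curve mapping tracer concentration to fluorescence."""

    concentrations: tuple = field(default=())
    readings: tuple = field(default=())
    blank: float = 0.0

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        read = np.asarray(self.readings, dtype=float)
        if conc.size < 2:
            raise ValueError("need at least 2 calibration standards")
        if conc.size != read.size:
            raise ValueError("concentrations and readings differ in length")
        order = np.argsort(conc)
        if not np.all(np.diff(read[order]) > 0):
            raise ValueError("calibration readings must increase with concentration")
        object.__setattr__(self, "concentrations", tuple(conc[order]))
        object.__setattr__(self, "readings", tuple(read[order]))


def compute_teer(reading: TeerReading) -> float:
    """Resistance-area product (ohm*cm^2) of one insert, blank-subtracted.

    Returns ``(raw - blank) * area``.  A negative result (blank exceeding
    the sample) is returned as-is but warned about, since it signals a
    measurement problem rather than a physically tight layer.
    """
    teer = (reading.raw_ohm - reading.blank_ohm) * reading.area_cm2
    if teer < 0:
        warnings.warn(
            f"blank resistance exceeds sample ({reading.label or 'unlabelled'}): "
            f"TEER = {teer:.3g} ohm*cm^2",
            RuntimeWarning,
            stacklevel=2,
        )
    return teer


def fluorescence_to_concentration(cal: FluorescenceCalibration, reading: float) -> float:
    """Convert a plate-reader fluorescence value to tracer concentration.

    A least-squares line is fitted to (concentration, blank-subtracted
    reading) and inverted.  Readings below the blank return 0 with a
    warning; readings beyond the calibrated range extrapolate with a
    warning.
    """
    conc = np.asarray(cal.concentrations, dtype=float)
    resp = np.asarray(cal.readings, dtype=float) - cal.blank
    signal = reading - cal.blank
    if signal < 0:
        warnings.warn("reading below blank; concentration floored at 0", RuntimeWarning, stacklevel=2)
        return 0.0
    slope, intercept = np.polyfit(conc, resp, 1)
    if signal < resp.min() - 1e-12 or signal > resp.max() + 1e-12:
        warnings.warn("reading outside calibrated range; extrapolating", RuntimeWarning, stacklevel=2)
    return float((signal - intercept) / slope)


def compute_papp(record: PermeabilityRecord) -> float:
    """Apparent permeability coefficient, cm/s.

    ``Papp = dC_A * V_A / (A * C_D * dt)`` with the acceptor volume in
    cm^3 (1 mL = 1 cm^3, exact).
    """
    return (record.dc_acceptor * record.v_acceptor_ml) / (
        record.area_cm2 * record.c_donor * record.duration_s
    )


def percent_of_control(values, control_values) -> np.ndarray:
    """Express measurements as a percentage of the control-group mean.

    The control group's own mean maps to exactly 100%.
    """
    control = np.asarray(control_values, dtype=float)
    if control.size == 0:
        raise ValueError("control group is empty")
    mean = control.mean()
    if mean == 0:
        raise ValueError("control mean is zero; percent-of-control undefined")
    return np.asarray(values, dtype=float) * 100.0 / mean


def papp_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-insert Papp from a tidy assay table.

    Expects columns ``group, tracer, donor_conc, acceptor_conc, va_ml,
    area_cm2, dt_s`` (one row per insert per tracer) and returns the table
    with a ``papp_cm_s`` column appended.  Papp is computed per insert;
    any averaging over replicate wells happens downstream.
    """
    required = {"group", "tracer", "donor_conc", "acceptor_conc", "va_ml", "area_cm2", "dt_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = df.copy()
    out["papp_cm_s"] = [
        compute_papp(
            PermeabilityRecord(
                c_donor=row.donor_conc,
                dc_acceptor=row.acceptor_conc,
                v_acceptor_ml=row.va_ml,
                area_cm2=row.area_cm2,
                duration_s=row.dt_s,
                tracer=str(row.tracer),
            )
        )
        for row in df.itertuples()
    ]
    return out
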