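"""NPP, R, GPP and carbon assimilation from closed-bottle O2 incubations.

Paired light/dark incubations in ~130-ml jars, each set accompanied by a
~270-ml blank; O2 is read at 0, 10 and 30 min, giving two measurement
windows (0-10 and 10-30 min).  Blank-corrected, mass-specific rates

    NPP = [(c_S1 - c_S0) V_S - (c_B1 - c_B0) V_B] / (M * dt)
    R   = [(c_S0 - c_S1) V_S - (c_B0 - c_B1) V_B] / (M * dt)

are computed per window, averaged, and converted to umol O2 g^-1 h^-1
(wet mass).  GPP = NPP + R.  Net carbon assimilation per g dry mass is

    CA = NPP * 1e-6 * 12.0107 / M_R        (g C g^-1 h^-1)

assuming photosynthetic and respiratory quotients of 1; M_R is the
species dry:wet mass ratio.  Incubations from days whose ambient photon
flux reached the photoinhibition range are excluded before averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .species import Species

log = logging.getLogger(__name__)

CARBON_ATOMIC_MASS = 12.0107
#: Ambient photon flux (umol photons m^-2 s^-1) above which in situ
#: photoinhibition has been shown to depress O2 production.
PHOTOINHIBITION_PAR = 971.0
#: Read times (min) delimiting the two incubation windows.
READ_TIMES_MIN = (0.0, 10.0, 30.0)


@dataclass(frozen=True)
class IncubationRecord:
    species: Species
    detrital_age: float  # days
    mode: str  # "light" | "dark"
    c_s: tuple[float, float, float]  # sample O2 at 0/10/30 min (umol L^-1)
    c_b: tuple[float, float, float]  # blank O2 at 0/10/30 min
    v_s: float  # sample jar volume (L)
    v_b: float  # blank jar volume (L)
    mass: float  # sample wet (buoyant) mass (g)
    ambient_par: float = 0.0  # field photon flux on the collection day

    def __post_init__(self) -> None:
        if self.v_s <= 0 or self.v_b <= 0 or self.mass <= 0:
            raise ValueError("volumes and mass must be positive")
        if any(c < 0 for c in self.c_s) or any(c < 0 for c in self.c_b):
            raise ValueError("O2 concentrations cannot be negative")
        if self.mode not in ("light", "dark"):
            raise ValueError(f"mode must be light or dark, got {self.mode!r}")


def _windowed_rate(rec: IncubationRecord, sign: float) -> float:
    """Blank-corrected rate per window, averaged, in umol O2 g^-1 min^-1."""
    rates = []
    for i in range(len(READ_TIMES_MIN) - 1):
        dt = READ_TIMES_MIN[i + 1] - READ_TIMES_MIN[i]
        ds = rec.c_s[i + 1] - rec.c_s[i]
        db = rec.c_b[i + 1] - rec.c_b[i]
        rates.append(sign * (ds * rec.v_s - db * rec.v_b) / (rec.mass * dt))
    return float(np.mean(rates))


def npp(rec: IncubationRecord) -> float:
    """Net primary production (umol O2 g^-1 min^-1) from a light incubation."""
    if rec.mode != "light":
        raise ValueError("NPP requires a light incubation")
    return _windowed_rate(rec, +1.0)


def respiration(rec: IncubationRecord) -> float:
    """Respiration (umol O2 g^-1 min^-1) from a dark incubation.

    Positive under net O2 consumption (the sign-flipped analogue of NPP).
    """
    if rec.mode != "dark":
        raise ValueError("respiration requires a dark incubation")
    return _windowed_rate(rec, -1.0)


def per_hour(rate_per_min: float) -> float:
    return rate_per_min * 60.0


def gpp(npp_val: float, r_val: float) -> float:
    """Gross primary production GPP = NPP + R (same units as inputs)."""
    return npp_val + r_val


def carbon_assimilation(npp_o2_h: float, m_r: float) -> float:
    """CA (g C g^-1 dry h^-1) from an O2 rate in umol O2 g^-1 wet h^-1."""
    if m_r <= 0 or m_r > 1:
        raise ValueError("dry:wet ratio must be in (0, 1]")
    return npp_o2_h * 1e-6 * CARBON_ATOMIC_MASS / m_r


def photoinhibition_filter(
    records: pd.DataFrame, par_threshold: float = PHOTOINHIBITION_PAR
) -> pd.DataFrame:
    """Drop rows whose collection-day ambient PAR reached the threshold."""
    keep = records["ambient_par"] < par_threshold
    dropped = int((~keep).sum())
    if dropped:
        log.info("photoinhibition filter removed %d of %d records", dropped, len(records))
    return records[keep].reset_index(drop=True)


def _record_from_row(row) -> IncubationRecord:
    return IncubationRecord(
        species=Species.parse(row["species"]),
        detrital_age=float(row["detrital_age_d"]),
        mode=str(row["mode"]),
        c_s=(float(row["c_S0"]), float(row["c_S10"]), float(row["c_S30"])),
        c_b=(float(row["c_B0"]), float(row["c_B10"]), float(row["c_B30"])),
        v_s=float(row["V_S_L"]),
        v_b=float(row["V_B_L"]),
        mass=float(row["mass_g"]),
        ambient_par=float(row.get("ambient_par", 0.0)),
    )


def process_incubations(
    incubations: pd.DataFrame,
    m_r_by_species: dict[str, float],
    par_threshold: float = PHOTOINHIBITION_PAR,
) -> pd.DataFrame:
    """Per-sample production table from raw paired light/dark rows.

    Light and dark rows are paired in order within each (species,
    detrital age) group.  Returns NPP/R/GPP in umol O2 g^-1 h^-1 and
    net/gross CA in g C g^-1 dry h^-1.
    """
    df = photoinhibition_filter(incubations, par_threshold)
    rows = []
    for (sp, age), grp in df.groupby(["species", "detrital_age_d"], sort=True):
        lights = [r for _, r in grp[grp["mode"] == "light"].iterrows()]
        darks = [r for _, r in grp[grp["mode"] == "dark"].iterrows()]
        m_r = m_r_by_species[Species.parse(sp).value]
        for lrow, drow in zip(lights, darks):
            npp_h = per_hour(npp(_record_from_row(lrow)))
            r_h = per_hour(respiration(_record_from_row(drow)))
            if r_h < 0:
                log.warning("%s age %s: negative respiration %.3f", sp, age, r_h)
            gpp_h = gpp(npp_h, r_h)
            rows.append(
                {
                    "species": Species.parse(sp).value,
                    "detrital_age_d": float(age),
                    "NPP_umol_g_h": npp_h,
                    "R_umol_g_h": r_h,
                    "GPP_umol_g_h": gpp_h,
                    "CA_net_gC_g_h": carbon_assimilation(npp_h, m_r),
                    "CA_gross_gC_g_h": carbon_assimilation(gpp_h, m_r),
                }
            )
    if not rows:
        raise ValueError("no light/dark incubation pairs to process")
    return pd.DataFrame(rows)
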