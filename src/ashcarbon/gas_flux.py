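"""Alkali-trap CO2 accounting: titration records to interval and cumulative C.

Respired CO2 is absorbed in an NaOH trap (CO2 + 2 NaOH -> Na2CO3 + H2O).
At each sampling day the trap is exchanged; carbonate is precipitated with
BaCl2 and the remaining NaOH back-titrated with standard HCl. The difference
against a soil-free blank gives the moles of NaOH consumed by CO2:

    mol CO2 = (HCl_blank - HCl_sample) * conc / 2

so each record yields mg CO2-C per kg dry soil for the interval since the
previous exchange. Because the trap is continuous between exchanges, the
cumulative mineralization at any sampling day is simply the running sum of
interval values; no interpolation is performed (the first record covers
days 0 to its sampling day).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "titration_to_co2c",
    "accumulate",
    "flux_series",
    "treatment_summary",
]

_MOLAR_MASS_C = 12.0  # g/mol
_NAOH_PER_CO2 = 2.0   # stoichiometry of trap absorption


def titration_to_co2c(
    hcl_conc: float,
    hcl_vol_sample: float,
    hcl_vol_blank: float,
    soil_mass: float,
) -> float:
    """CO2-C trapped over one interval, mg C per kg dry soil.

    Parameters
    ----------
    hcl_conc : float
        Titrant concentration, mol L-1 (0.1 in the standard protocol).
    hcl_vol_sample, hcl_vol_blank : float
        Back-titration volumes (mL) of the sample trap and the soil-free
        blank. The sample cannot titrate more than the blank.
    soil_mass : float
        Dry soil per jar, kg.
    """
    if hcl_conc <= 0:
        raise ValueError("hcl_conc must be positive")
    if soil_mass <= 0:
        raise ValueError("soil_mass must be positive")
    if hcl_vol_sample < 0 or hcl_vol_blank < 0:
        raise ValueError("titration volumes must be nonnegative")
    if hcl_vol_sample > hcl_vol_blank:
        raise ValueError(
            f"sample titration volume ({hcl_vol_sample} mL) exceeds blank "
            f"({hcl_vol_blank} mL): trap cannot consume negative NaOH"
        )
    delta_mol_hcl = hcl_conc * (hcl_vol_blank - hcl_vol_sample) / 1000.0
    mol_co2 = delta_mol_hcl / _NAOH_PER_CO2
    mg_c = mol_co2 * _MOLAR_MASS_C * 1000.0
    return mg_c / soil_mass


def accumulate(interval_c: np.ndarray, days: np.ndarray) -> pd.DataFrame:
    """Running-sum cumulative CO2-C over sampling days.

    ``days`` must be strictly increasing with one interval value per day.
    Returns a frame with ``day``, ``interval_c`` (mg C kg-1) and
    ``cumulative_c`` (mg C kg-1).
    """
    days = np.asarray(days, dtype=float)
    interval_c = np.asarray(interval_c, dtype=float)
    if days.ndim != 1 or interval_c.shape != days.shape:
        raise ValueError("days and interval values must be 1-D and aligned")
    if len(days) == 0:
        raise ValueError("no records")
    if np.any(np.diff(days) <= 0):
        raise ValueError("sampling days must be strictly increasing (no duplicates)")
    return pd.DataFrame(
        {"day": days, "interval_c": interval_c, "cumulative_c": np.cumsum(interval_c)}
    )


def flux_series(titrations: pd.DataFrame) -> pd.DataFrame:
    """Convert a long titration table into per-jar flux series.

    Expects columns ``treatment``, ``replicate``, ``day``, ``hcl_conc``,
    ``v_sample``, ``v_blank``, ``soil_mass``. Returns a tidy frame with
    ``interval_c`` and ``cumulative_c`` (mg C kg-1) per jar and day.
    """
    required = {"treatment", "replicate", "day", "hcl_conc", "v_sample", "v_blank", "soil_mass"}
    missing = required - set(titrations.columns)
    if missing:
        raise ValueError(f"titration table missing columns: {sorted(missing)}")
    out = []
    for (trt, rep), grp in titrations.groupby(["treatment", "replicate"], sort=False):
        grp = grp.sort_values("day")
        interval = np.array(
            [
                titration_to_co2c(r.hcl_conc, r.v_sample, r.v_blank, r.soil_mass)
                for r in grp.itertuples()
            ]
        )
        series = accumulate(interval, grp["day"].to_numpy())
        series.insert(0, "replicate", rep)
        series.insert(0, "treatment", trt)
        out.append(series)
    return pd.concat(out, ignore_index=True)


def treatment_summary(fluxes: pd.DataFrame) -> pd.DataFrame:
    """Per-treatment mean and SE of final cumulative CO2-C.

    SE is SD/sqrt(n) over replicate jars; at least two replicates are
    required. Reports both mg kg-1 and g kg-1.
    """
    finals = (
        fluxes.sort_values("day")
        .groupby(["treatment", "replicate"], sort=False)["cumulative_c"]
        .last()
        .reset_index()
    )
    rows = []
    for trt, grp in finals.groupby("treatment", sort=False):
        n = len(grp)
        if n < 2:
            raise ValueError(f"treatment {trt!r} has {n} replicate(s); need >= 2 for an SE")
        vals = grp["cumulative_c"].to_numpy()
        rows.append(
            {
                "treatment": trt,
                "n": n,
                "cumulative_mg_per_kg": vals.mean(),
                "se_mg_per_kg": vals.std(ddof=1) / np.sqrt(n),
                "cumulative_g_per_kg": vals.mean() / 1000.0,
                "se_g_per_kg": vals.std(ddof=1) / np.sqrt(n) / 1000.0,
            }
        )
    return pd.DataFrame(rows)
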