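"""Trait derivation and record-level filters.

Respiration-chamber methane records yield three analysis traits: gross
emissions (g CH4/day), methane yield per unit intake (g CH4/kg DMI) and the
molar fraction CH4/(CH4+CO2).  Chamber days on which the animal ate less
than 95% of the offered feed, or on which the chamber seal was broken, are
discarded before analysis, as are incomplete records.  Faecal and
Nematodirus egg counts are analysed on the log_e(x + 50) scale; litter
survival to weaning is lambs weaned divided by lambs born, undefined for
ewes that did not lamb.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Molar masses (g/mol) used for the CH4/(CH4+CO2) molar fraction.
MOLAR_MASS_CH4 = 16.04
MOLAR_MASS_CO2 = 44.01

#: Minimum fraction of offered feed eaten for a chamber day to be retained.
EATEN_THRESHOLD = 0.95

#: Offset added before the natural-log transform of egg counts.
EGG_COUNT_OFFSET = 50.0

CHAMBER_REQUIRED = ["animal", "ch4_g", "co2_g", "dmi_kg", "offered_kg", "seal_ok"]


class DataError(ValueError):
    """A record violates a hard data constraint (not a model error)."""


def filter_chamber_records(
    records: pd.DataFrame, eaten_threshold: float = EATEN_THRESHOLD
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the chamber-day record filters; return (retained, rejection log).

    A record is retained iff the seal held, the eaten fraction
    ``dmi_kg / offered_kg`` is at least ``eaten_threshold`` (the boundary is
    kept: "less than 95% eaten" is discarded), and no required field is
    missing.  The rejection log has one row per discarded record with columns
    ``index`` (the input row label) and ``reason`` in
    {"seal", "refusal", "missing"}.
    """
    if not 0.0 < eaten_threshold <= 1.0:
        raise ValueError("eaten_threshold must be in (0, 1]")
    df = records.copy()
    missing_cols = [c for c in CHAMBER_REQUIRED if c not in df.columns]
    if missing_cols:
        raise DataError(f"chamber table lacks required columns {missing_cols}")
    offered = pd.to_numeric(df["offered_kg"], errors="coerce")
    if (offered <= 0).any():
        bad = df.index[offered <= 0][0]
        raise DataError(f"offered_kg must be positive (row {bad!r})")

    incomplete = df[CHAMBER_REQUIRED].isna().any(axis=1)
    seal_broken = ~incomplete & ~df["seal_ok"].astype(bool)
    eaten_frac = pd.to_numeric(df["dmi_kg"], errors="coerce") / offered
    refusal = ~incomplete & ~seal_broken & (eaten_frac < eaten_threshold)

    reasons = pd.Series("", index=df.index, dtype=object)
    reasons[incomplete] = "missing"
    reasons[seal_broken] = "seal"
    reasons[refusal] = "refusal"
    rejected = reasons != ""
    log = pd.DataFrame(
        {"index": df.index[rejected], "reason": reasons[rejected].to_numpy()}
    ).reset_index(drop=True)
    return df.loc[~rejected].copy(), log


def methane_traits(
    records: pd.DataFrame,
    molar_mass_ch4: float = MOLAR_MASS_CH4,
    molar_mass_co2: float = MOLAR_MASS_CO2,
) -> pd.DataFrame:
    """Derive the three methane analysis traits from a chamber-day table.

    Returns a frame aligned with ``records`` holding ``ch4_gpd`` (gross
    emissions, g/day), ``ch4_dmi`` (g CH4 per kg dry matter intake; missing,
    not zero, when intake is non-positive) and ``ch4_frac``
    (mol CH4 / (mol CH4 + mol CO2), scale-invariant in the gas amounts).
    """
    ch4 = pd.to_numeric(records["ch4_g"], errors="coerce").to_numpy(dtype=float)
    co2 = pd.to_numeric(records["co2_g"], errors="coerce").to_numpy(dtype=float)
    dmi = pd.to_numeric(records["dmi_kg"], errors="coerce").to_numpy(dtype=float)
    if np.nanmin(co2, initial=0.0) < 0 or np.nanmin(ch4, initial=0.0) < 0:
        raise DataError("gas amounts must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        ch4_dmi = np.where(dmi > 0, ch4 / dmi, np.nan)
        mol_ch4 = ch4 / molar_mass_ch4
        mol_co2 = co2 / molar_mass_co2
        total = mol_ch4 + mol_co2
        ch4_frac = np.where(total > 0, mol_ch4 / total, np.nan)
    return pd.DataFrame(
        {"ch4_gpd": ch4, "ch4_dmi": ch4_dmi, "ch4_frac": ch4_frac},
        index=records.index,
    )


def transform_egg_count(
    x: float | np.ndarray | pd.Series, offset: float = EGG_COUNT_OFFSET
) -> float | np.ndarray | pd.Series:
    """log_e(x + offset) transform for faecal/Nematodirus egg counts (eggs/g)."""
    arr = np.asarray(x, dtype=float)
    if np.nanmin(arr, initial=0.0) < 0:
        raise DataError("egg counts must be non-negative")
    out = np.log(arr + offset)
    if isinstance(x, pd.Series):
        return pd.Series(out, index=x.index, name=x.name)
    if np.isscalar(x) or arr.ndim == 0:
        return float(out)
    return out


def litter_survival(
    nlb: int | np.ndarray | pd.Series, n_weaned: int | np.ndarray | pd.Series
) -> float | np.ndarray | pd.Series:
    """Litter survival to weaning: lambs weaned / lambs born (NLB).

    Missing (NaN) when NLB = 0 — a ewe that did not lamb has no litter to
    survive.  ``n_weaned > nlb`` is a data error.
    """
    scalar = np.isscalar(nlb)
    nlb_a = np.asarray(nlb, dtype=float)
    wn_a = np.asarray(n_weaned, dtype=float)
    ok = ~(np.isnan(nlb_a) | np.isnan(wn_a))
    if np.any(wn_a[ok] > nlb_a[ok]):
        raise DataError("lambs weaned exceeds lambs born")
    if np.any(nlb_a[ok] < 0) or np.any(wn_a[ok] < 0):
        raise DataError("litter counts must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(nlb_a > 0, wn_a / nlb_a, np.nan)
    if isinstance(nlb, pd.Series):
        return pd.Series(out, index=nlb.index, name="lsw")
    if scalar:
        return float(out)
    return out


def derive_chamber_traits(
    records: pd.DataFrame,
    eaten_threshold: float = EATEN_THRESHOLD,
    molar_mass_ch4: float = MOLAR_MASS_CH4,
    molar_mass_co2: float = MOLAR_MASS_CO2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter chamber days and attach the derived methane traits.

    Convenience wrapper: returns (analysis table, rejection log).  The
    analysis table carries the original factor columns plus ``ch4_gpd``,
    ``ch4_dmi`` and ``ch4_frac``.
    """
    kept, log = filter_chamber_records(records, eaten_threshold)
    traits = methane_traits(kept, molar_mass_ch4, molar_mass_co2)
    return pd.concat([kept, traits], axis=1), log
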