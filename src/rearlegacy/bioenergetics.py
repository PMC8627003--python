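"""Growth performance, marker-based digestibility and nutrient partitioning.

This module implements the arithmetic of a fish feeding trial: tank-level
growth metrics (growth rate, SGR, FCR, survival), apparent digestibility
coefficients estimated with an inert dietary marker (yttrium), the
carbohydrate-by-difference calculation, and the full nitrogen and energy
partition chains (digestible -> retained -> branchial/urinary losses;
digestible -> metabolisable -> retained -> heat -> maintenance).

All composition arithmetic is on a dry-matter (DM) basis.  ADC values are
*returned* as percentages (the reporting convention) but *consumed* by the
balance functions as fractions in [0, 1]; the conversion happens exactly once
at that boundary and is the caller's responsibility (use ``adc(...) / 100``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional

import pandas as pd

__all__ = [
    "KJ_PER_G_NH3_N",
    "EFF_ME_PROTEIN",
    "EFF_ME_FAT",
    "KJELDAHL_FACTOR",
    "TankGrowthRecord",
    "GrowthMetrics",
    "CompositionProfile",
    "NitrogenBalance",
    "EnergyBalance",
    "growth_performance",
    "hatching_rate",
    "adc",
    "carbohydrate_content",
    "nitrogen_balance",
    "energy_balance",
    "total_inorganic_nitrogen",
    "round_half_up",
    "growth_table",
]

#: Energy content of excreted ammonia nitrogen: 24.85 kJ per 1000 mg N.
KJ_PER_G_NH3_N = 24.85
#: Efficiency of metabolisable energy for protein gain.
EFF_ME_PROTEIN = 0.5
#: Efficiency of metabolisable energy for fat gain.
EFF_ME_FAT = 0.9
#: Kjeldahl nitrogen to crude protein conversion factor.
KJELDAHL_FACTOR = 6.25


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero upward, the convention of printed report tables.

    Applied only at presentation; never inside computation chains.
    """
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TankGrowthRecord:
    """One tank over one experimental period.

    Parameters
    ----------
    n_initial, n_final : int
        Fish counts at stocking and at the end of the period.
    w_initial, w_final : float
        Mean individual body weight (g).
    duration : float
        Length of the period (days).
    feed_intake : float
        Feed intake per fish per day (g dry matter), averaged over the period.
    """

    n_initial: int
    n_final: int
    w_initial: float
    w_final: float
    duration: float
    feed_intake: float = 0.0

    def __post_init__(self) -> None:
        if self.n_final > self.n_initial:
            raise ValueError("n_final cannot exceed n_initial")
        if self.n_initial <= 0:
            raise ValueError("n_initial must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.w_initial <= 0 or self.w_final <= 0:
            raise ValueError("body weights must be positive")
        if self.feed_intake < 0:
            raise ValueError("feed_intake cannot be negative")


@dataclass(frozen=True)
class GrowthMetrics:
    """Tank growth summary.

    ``fcr`` is ``None`` when weight gain is zero or negative (the ratio is
    undefined / not meaningful); it is never silently infinite.
    """

    growth: float  # g/day
    sgr: float  # % body weight / day
    fcr: Optional[float]
    survival: float  # %


def growth_performance(record: TankGrowthRecord) -> GrowthMetrics:
    """Compute growth rate, SGR, FCR and survival for one tank.

    growth = (W_f - W_i) / t ;  SGR = 100 (ln W_f - ln W_i) / t ;
    FCR = cumulative feed intake / per-fish weight gain ;
    survival = 100 N_f / N_i.

    FCR uses dry-matter feed intake as recorded in ``record.feed_intake``
    (the reporting basis for feeding-trial tables); convert as-fed intake to
    DM before building the record if needed.
    """
    r = record
    gain = r.w_final - r.w_initial
    growth = gain / r.duration
    sgr = 100.0 * (math.log(r.w_final) - math.log(r.w_initial)) / r.duration
    if gain > 0 and r.feed_intake > 0:
        fcr: Optional[float] = (r.feed_intake * r.duration) / gain
    else:
        fcr = None
    survival = 100.0 * r.n_final / r.n_initial
    return GrowthMetrics(growth=growth, sgr=sgr, fcr=fcr, survival=survival)


def hatching_rate(hatched: int, incubated: int) -> float:
    """Percentage of incubated eggs that hatched."""
    if incubated <= 0:
        raise ValueError("incubated must be positive")
    if hatched < 0 or hatched > incubated:
        raise ValueError("hatched must lie in [0, incubated]")
    return 100.0 * hatched / incubated


@dataclass(frozen=True)
class CompositionProfile:
    """Nutrient and marker concentrations of a feed, faeces or body sample.

    All concentrations are per kg dry matter unless noted: crude protein,
    crude fat, ash and carbohydrate in g/kg DM; gross energy in kJ/g DM;
    yttrium (the inert digestibility marker), phosphorus, calcium and
    magnesium in mg/kg DM; nitrogen in mg/g DM.  ``dry_matter`` is the DM
    content of the fresh sample (g/kg) used to convert fresh-weight body
    composition onto the DM basis.
    """

    role: str  # "feed" | "faeces" | "body"
    dry_matter: Optional[float] = None
    crude_protein: Optional[float] = None
    crude_fat: Optional[float] = None
    ash: Optional[float] = None
    carbohydrate: Optional[float] = None
    gross_energy: Optional[float] = None
    yttrium: Optional[float] = None
    phosphorus: Optional[float] = None
    calcium: Optional[float] = None
    magnesium: Optional[float] = None
    nitrogen: Optional[float] = None

    def __post_init__(self) -> None:
        if self.role not in ("feed", "faeces", "body"):
            raise ValueError(f"unknown role {self.role!r}")
        for name in (
            "dry_matter", "crude_protein", "crude_fat", "ash", "carbohydrate",
            "gross_energy", "yttrium", "phosphorus", "calcium", "magnesium",
            "nitrogen",
        ):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} cannot be negative")
        # Crude protein is defined as Kjeldahl-N x 6.25; when both are given
        # they must agree (nitrogen mg/g DM -> protein g/kg DM is N * 6.25).
        if self.crude_protein is not None and self.nitrogen is not None:
            expected = self.nitrogen * KJELDAHL_FACTOR
            if expected > 0 and abs(self.crude_protein - expected) > 0.01 * expected:
                raise ValueError(
                    "crude_protein inconsistent with nitrogen * 6.25 "
                    f"({self.crude_protein} vs {expected})"
                )

    def nutrient(self, name: str) -> float:
        """Return the named concentration, raising if absent."""
        if not hasattr(self, name):
            raise KeyError(f"unknown nutrient {name!r}")
        v = getattr(self, name)
        if v is None:
            raise ValueError(f"nutrient {name!r} not measured in this profile")
        return float(v)


def adc(feed: CompositionProfile, faeces: CompositionProfile, nutrient: str) -> float:
    """Apparent digestibility coefficient (%) of ``nutrient`` via the yttrium marker.

    ADC (%) = 100 [1 - (Y_feed * nutrient_faeces) / (Y_faeces * nutrient_feed)]

    where Y_feed and Y_faeces are the marker concentrations in feed and
    faeces.  Both profiles must be on the same dry-matter basis.
    """
    y_feed = feed.nutrient("yttrium")
    y_faeces = faeces.nutrient("yttrium")
    if y_feed <= 0 or y_faeces <= 0:
        raise ValueError("yttrium marker concentration must be positive in feed and faeces")
    n_feed = feed.nutrient(nutrient)
    n_faeces = faeces.nutrient(nutrient)
    if n_feed <= 0:
        raise ValueError(f"feed concentration of {nutrient!r} must be positive for ADC")
    return 100.0 * (1.0 - (y_feed * n_faeces) / (y_faeces * n_feed))


def carbohydrate_content(profile: CompositionProfile) -> float:
    """Total carbohydrate by difference: DM - (crude protein + fat + ash), g/kg DM.

    On the per-kg-DM scale the dry-matter term is 1000 g/kg.
    """
    cp = profile.nutrient("crude_protein")
    fat = profile.nutrient("crude_fat")
    ash_ = profile.nutrient("ash")
    total = cp + fat + ash_
    if total > 1000.0 + 1e-9:
        raise ValueError(
            f"protein + fat + ash = {total} g/kg DM exceeds the dry-matter basis"
        )
    return 1000.0 - total


@dataclass(frozen=True)
class NitrogenBalance:
    """Per-fish daily nitrogen partition (all mg/day; efficiency in %)."""

    gross_n_intake: float
    digestible_n_intake: float
    retained_n: float
    branchial_urinary_n: float
    n_efficiency: float


def nitrogen_balance(
    feed_intake: float,
    diet_n: float,
    adc_n: float,
    body_n_initial: float,
    body_n_final: float,
    duration: float,
) -> NitrogenBalance:
    """Nitrogen partition chain for one fish over one period.

    gross N intake = feed intake (g DM/d) * dietary N (mg/g DM);
    DN = gross * ADC_N; RN = (body N final - initial) / t; BUN = DN - RN;
    N efficiency = 100 RN / DN.  The identity DN = RN + BUN holds exactly by
    construction.

    ``adc_n`` is a fraction in [0, 1] (divide a percentage ADC by 100).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not 0.0 <= adc_n <= 1.0:
        raise ValueError("adc_n must be a fraction in [0, 1]")
    if feed_intake < 0:
        raise ValueError("feed_intake cannot be negative")
    gross = feed_intake * diet_n
    dn = gross * adc_n
    rn = (body_n_final - body_n_initial) / duration
    bun = dn - rn
    if dn == 0:
        raise ValueError(
            "digestible N intake is zero; N efficiency undefined "
            "(inconsistent inputs if retained N is nonzero)"
        )
    eff = 100.0 * rn / dn
    return NitrogenBalance(
        gross_n_intake=gross,
        digestible_n_intake=dn,
        retained_n=rn,
        branchial_urinary_n=bun,
        n_efficiency=eff,
    )


@dataclass(frozen=True)
class EnergyBalance:
    """Per-fish daily energy partition (all kJ/day)."""

    energy_intake: float
    digestible_energy: float
    branchial_urinary_energy: float
    metabolisable_energy: float
    retained_energy: float
    heat_production: float
    maintenance_energy: float


def energy_balance(
    feed_intake: float,
    diet_energy: float,
    adc_e: float,
    bun: float,
    body_e_initial: float,
    body_e_final: float,
    duration: float,
    retained_protein_energy: float = 0.0,
    retained_fat_energy: float = 0.0,
) -> EnergyBalance:
    """Energy partition chain for one fish over one period.

    energy intake = feed intake (g DM/d) * dietary energy (kJ/g DM);
    DE = intake * ADC_E; BUE = BUN (mg/d) * 24.85 / 1000, assuming all
    branchial/urinary N is excreted as ammonia; ME = DE - BUE;
    RE = (body E final - initial) / t; HE = ME - RE;
    Emain = ME - RE_protein / 0.5 - RE_fat / 0.9.

    ``adc_e`` is a fraction in [0, 1].
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not 0.0 <= adc_e <= 1.0:
        raise ValueError("adc_e must be a fraction in [0, 1]")
    if feed_intake < 0:
        raise ValueError("feed_intake cannot be negative")
    intake = feed_intake * diet_energy
    de = intake * adc_e
    bue = bun * KJ_PER_G_NH3_N / 1000.0
    me = de - bue
    re = (body_e_final - body_e_initial) / duration
    he = me - re
    emain = me - retained_protein_energy / EFF_ME_PROTEIN - retained_fat_energy / EFF_ME_FAT
    return EnergyBalance(
        energy_intake=intake,
        digestible_energy=de,
        branchial_urinary_energy=bue,
        metabolisable_energy=me,
        retained_energy=re,
        heat_production=he,
        maintenance_energy=emain,
    )


def total_inorganic_nitrogen(tan: float, no2_n: float, no3_n: float) -> float:
    """Total inorganic nitrogen (mg/L): TAN + NO2-N + NO3-N."""
    for name, v in (("tan", tan), ("no2_n", no2_n), ("no3_n", no3_n)):
        if v < 0:
            raise ValueError(f"{name} cannot be negative")
    return tan + no2_n + no3_n


def growth_table(records: dict[str, TankGrowthRecord], decimals: int = 2) -> pd.DataFrame:
    """Growth-performance report table, one row per tank/treatment label.

    Values are rounded half-up at this presentation boundary only.
    """
    rows = {}
    for label, rec in records.items():
        m = growth_performance(rec)
        rows[label] = {
            "BW_i (g)": round_half_up(rec.w_initial, 1),
            "BW_f (g)": round_half_up(rec.w_final, 1),
            "FI (g DM/d)": round_half_up(rec.feed_intake, decimals),
            "Growth (g/d)": round_half_up(m.growth, decimals),
            "FCR": round_half_up(m.fcr, decimals) if m.fcr is not None else float("nan"),
            "SGR (%BW/d)": round_half_up(m.sgr, 1),
            "Survival (%)": round_half_up(m.survival, 0),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
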