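"""Synthetic pharmacy dispensing registry.

Generates dispensing records with the statistical structure a
community-pharmacy registry of antidepressant/anxiolytic users exhibits:
a stable ~37:63 male:female ratio, a weekday dispensing cycle (Monday
peak, Saturday trough), yearly seasonality, slowly rising antidepressant
and declining anxiolytic volumes, multimorbidity-driven co-prescription
across somatic classes, and per-record DDD ratios scattered below 1.

Events are drawn per patient x class from an inhomogeneous Poisson
process with intensity

    base_rate_c * weekday(d) * seasonal(d) * trend_c(d) * exp(z_p * g_c - g_c^2/2)

where ``z_p`` is a standard-normal latent multimorbidity factor per
patient and ``g_c`` the class's comorbidity loading (the ``-g^2/2`` term
keeps the population mean rate at ``base_rate_c``).  Class base rates
follow the relative dispensing volumes of the 24 therapeutic classes in
a Dutch dispensing population, scaled to ~19.4 dispensings per
patient-year.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atc import ANTIDEPRESSANTS, ANXIOLYTICS, AtcClassMap, default_class_map

__all__ = ["SimulationConfig", "simulate_registry", "registry_summary", "CLASS_PROFILES"]

# Per-class profile: (relative dispensing share, ddd mean, ddd sd, ATC code pool).
# Shares follow the relative five-year class volumes of a Dutch
# antidepressant/anxiolytic dispensing population; DDD moments are the
# class-level means/SDs of prescribed-dose-to-DDD ratios in that population.
CLASS_PROFILES: dict[str, tuple[float, float, float, tuple[str, ...]]] = {
    "Alimentary and metabolism": (0.2059, 0.597, 0.326, ("A02BC01", "A10BA02", "A06AD11")),
    "Blood": (0.0520, 0.693, 0.391, ("B01AC06", "B01AA03", "B03BA01")),
    "Cardiovascular": (0.1748, 0.538, 0.305, ("C07AB02", "C10AA01", "C09AA02")),
    "Dermatologicals": (0.0373, 0.808, 0.339, ("D07AC01", "D06BB03", "D10BA01")),
    "Genitourinary": (0.0375, 0.746, 0.369, ("G03CA03", "G04BD08", "G03AA07")),
    "Systemic hormonal": (0.0287, 0.497, 0.276, ("H03AA01", "H02AB06", "H01BA02")),
    "Systemic anti-infectives": (0.0131, 0.634, 0.323, ("J01CA04", "J01FA09", "J02AC01")),
    "Antineoplastics": (0.0080, 0.613, 0.301, ("L04AX03", "L02BA01", "L01BA01")),
    "Musculoskeletal": (0.0259, 0.559, 0.326, ("M01AE01", "M05BA04", "M03BX01")),
    "Anesthetic": (0.0007, 0.645, 0.447, ("N01BB02", "N01AX10")),
    "Analgesics": (0.0457, 0.423, 0.260, ("N02BE01", "N02AA05", "N02CC01")),
    "Antiepileptics": (0.0193, 0.429, 0.252, ("N03AX09", "N03AG01", "N03AX16")),
    "Antiparkinson": (0.0055, 0.353, 0.221, ("N04BA02", "N04BC05")),
    "Antipsychotics": (0.0442, 0.404, 0.265, ("N05AH04", "N05AX08", "N05AA01")),
    "Anxiolytics": (0.0473, 0.463, 0.288, ("N05BA01", "N05BA06", "N05BA12", "N05BE01")),
    "Hypnotics and sedatives": (0.0262, 0.631, 0.316, ("N05CF01", "N05CF02", "N05CD07")),
    "Antidepressants": (0.1092, 0.536, 0.309, ("N06AB06", "N06AB04", "N06AX11", "N06AA09")),
    "Psychostimulants": (0.0082, 0.520, 0.313, ("N06BA04", "N06BA09")),
    "Antidementia": (0.0002, 0.680, 0.285, ("N06DA02", "N06DX01")),
    "Other nervous system drugs": (0.0065, 0.523, 0.316, ("N07BB01", "N07CA01")),
    "Antiparasitics": (0.0016, 0.524, 0.253, ("P01BA02", "P02CA01")),
    "Respiratory": (0.0982, 0.655, 0.325, ("R03AC02", "R06AE07", "R03BA02")),
    "Sensory": (0.0035, 0.466, 0.287, ("S01AA01", "S01EE01")),
    "Others": (0.0003, 0.455, 0.273, ("V03AE02", "V04CA02")),
}

# Weekday cycle of dispensing volumes (Mon..Sun), normalised to mean 1:
# Monday peak, Saturday trough, as observed in community pharmacies.
_WEEKDAY_SHAPE = (7222.0, 6793.0, 6865.0, 7109.0, 6726.0, 2808.0, 2991.0)
DEFAULT_WEEKDAY_MULTIPLIERS = tuple(
    v * 7.0 / sum(_WEEKDAY_SHAPE) for v in _WEEKDAY_SHAPE
)


@dataclass
class SimulationConfig:
    """Parameters of the registry simulator (defaults = study conditions)."""

    n_patients: int = 2000
    window_start: dt.date = dt.date(2018, 1, 1)
    window_end: dt.date = dt.date(2022, 12, 31)
    female_fraction: float = 0.633
    weekday_multipliers: tuple[float, ...] = DEFAULT_WEEKDAY_MULTIPLIERS
    #: mean dispensings per patient-year; sets the scale of class base rates
    dispensings_per_patient_year: float = 19.4
    #: optional absolute per-patient-day intensity per class; overrides the
    #: share-based default when given
    class_base_rates: dict[str, float] | None = None
    #: relative yearly drift per class, e.g. +0.02 = +2%/year
    class_trend_slopes: dict[str, float] = field(
        default_factory=lambda: {ANTIDEPRESSANTS: 0.02, ANXIOLYTICS: -0.02}
    )
    seasonal_amplitude: float = 0.10
    seasonal_peak_doy: float = 15.0
    #: latent-multimorbidity loading per class (scalar = same for all)
    comorbidity_loadings: dict[str, float] | float = 0.3
    days_supplied_values: tuple[int, ...] = (7, 14, 30, 90)
    days_supplied_probs: tuple[float, ...] = (0.15, 0.20, 0.50, 0.15)
    ddd_max: float = 3.0
    planted_hub_class: str | None = None
    hub_boost: float = 3.0
    mean_entry_age: float = 44.0
    sd_entry_age: float = 13.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if len(self.weekday_multipliers) != 7:
            raise ValueError("weekday_multipliers must have length 7")
        if any(m <= 0 for m in self.weekday_multipliers):
            raise ValueError("weekday_multipliers must be positive")
        if not 0 < self.female_fraction < 1:
            raise ValueError("female_fraction must be in (0, 1)")
        if self.seasonal_amplitude < 0 or self.seasonal_amplitude >= 1:
            raise ValueError("seasonal_amplitude must be in [0, 1)")
        if self.window_start >= self.window_end:
            raise ValueError("window_start must be < window_end")
        if self.hub_boost <= 0:
            raise ValueError("hub_boost must be > 0")
        if self.planted_hub_class is not None and self.planted_hub_class not in CLASS_PROFILES:
            raise ValueError(f"unknown planted_hub_class {self.planted_hub_class!r}")
        if abs(sum(self.days_supplied_probs) - 1.0) > 1e-9:
            raise ValueError("days_supplied_probs must sum to 1")

    def base_rate(self, label: str) -> float:
        """Per-patient-day dispensing intensity of one class."""
        if self.class_base_rates is not None:
            rate = self.class_base_rates[label]
        else:
            share = CLASS_PROFILES[label][0]
            rate = self.dispensings_per_patient_year * share / 365.25
        if label == self.planted_hub_class:
            rate *= self.hub_boost
        if rate <= 0:
            raise ValueError(f"base rate for {label!r} must be > 0")
        return rate

    def loading(self, label: str) -> float:
        if isinstance(self.comorbidity_loadings, dict):
            return float(self.comorbidity_loadings.get(label, 0.0))
        return float(self.comorbidity_loadings)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - s2 / 2.0, np.sqrt(s2)


def _sample_ddd(
    rng: np.random.Generator, label: str, size: int, ddd_max: float
) -> np.ndarray:
    mu, sigma = _lognormal_params(*CLASS_PROFILES[label][1:3])
    out = rng.lognormal(mu, sigma, size)
    while True:  # truncate to (0, ddd_max] by resampling the upper tail
        bad = out > ddd_max
        if not bad.any():
            return out
        out[bad] = rng.lognormal(mu, sigma, int(bad.sum()))


def simulate_registry(config: SimulationConfig | None = None) -> pd.DataFrame:
    """Generate a dispensing registry (deterministic given ``config.seed``).

    Every patient is guaranteed at least one index-class (antidepressant
    or anxiolytic) dispensing, so the output is itself a valid study
    cohort.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)

    dates = pd.date_range(cfg.window_start, cfg.window_end, freq="D")
    n_days = len(dates)
    weekday = dates.weekday.to_numpy()
    doy = dates.dayofyear.to_numpy()
    years_elapsed = np.arange(n_days) / 365.25

    wd = np.asarray(cfg.weekday_multipliers)[weekday]
    seasonal = 1.0 + cfg.seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - cfg.seasonal_peak_doy) / 365.25
    )
    day_factor = wd * seasonal  # (n_days,)

    # patient attributes
    n = cfg.n_patients
    width = max(6, len(str(n)))
    patient_ids = np.array([f"P{i:0{width}d}" for i in range(n)])
    sex = np.where(rng.random(n) < cfg.female_fraction, "female", "male")
    age0 = np.clip(rng.normal(cfg.mean_entry_age, cfg.sd_entry_age, n), 18, 65)
    birth_year = cfg.window_start.year - np.round(age0).astype(int)
    latent = rng.normal(size=n)

    labels = list(CLASS_PROFILES)
    p_idx_parts: list[np.ndarray] = []
    d_idx_parts: list[np.ndarray] = []
    lab_parts: list[np.ndarray] = []
    for label in labels:
        rate = cfg.base_rate(label)
        g = cfg.loading(label)
        slope = cfg.class_trend_slopes.get(label, 0.0)
        trend = np.power(1.0 + slope, years_elapsed)
        lam_day = rate * day_factor * trend  # (n_days,)
        patient_mult = np.exp(latent * g - g * g / 2.0)  # (n,)
        counts = rng.poisson(np.outer(patient_mult, lam_day))
        p_i, d_i = np.nonzero(counts)
        reps = counts[p_i, d_i]
        p_i = np.repeat(p_i, reps)
        d_i = np.repeat(d_i, reps)
        p_idx_parts.append(p_i)
        d_idx_parts.append(d_i)
        lab_parts.append(np.full(len(p_i), label, dtype=object))

    p_idx = np.concatenate(p_idx_parts)
    d_idx = np.concatenate(d_idx_parts)
    lab = np.concatenate(lab_parts)

    # guarantee the cohort property: >=1 index-class dispensing per patient
    has_index = np.zeros(n, dtype=bool)
    index_mask = (lab == ANTIDEPRESSANTS) | (lab == ANXIOLYTICS)
    has_index[p_idx[index_mask]] = True
    missing = np.flatnonzero(~has_index)
    if missing.size:
        r_ad = cfg.base_rate(ANTIDEPRESSANTS)
        r_ax = cfg.base_rate(ANXIOLYTICS)
        pick_ad = rng.random(missing.size) < r_ad / (r_ad + r_ax)
        extra_lab = np.where(pick_ad, ANTIDEPRESSANTS, ANXIOLYTICS).astype(object)
        extra_day = rng.choice(n_days, size=missing.size, p=day_factor / day_factor.sum())
        p_idx = np.concatenate([p_idx, missing])
        d_idx = np.concatenate([d_idx, extra_day])
        lab = np.concatenate([lab, extra_lab])

    m = len(p_idx)
    atc = np.empty(m, dtype=object)
    ddd = np.empty(m, dtype=float)
    for label in labels:
        sel = np.flatnonzero(lab == label)
        if sel.size == 0:
            continue
        pool = CLASS_PROFILES[label][3]
        atc[sel] = np.asarray(pool, dtype=object)[rng.integers(len(pool), size=sel.size)]
        ddd[sel] = _sample_ddd(rng, label, sel.size, cfg.ddd_max)

    days_supplied = rng.choice(
        cfg.days_supplied_values, size=m, p=cfg.days_supplied_probs
    )

    df = pd.DataFrame(
        {
            "patient_id": patient_ids[p_idx],
            "sex": sex[p_idx],
            "birth_year": birth_year[p_idx],
            "atc_code": atc,
            "dispense_date": dates[d_idx],
            "days_supplied": days_supplied.astype(int),
            "ddd_ratio": ddd,
        }
    )
    df = df.sort_values(
        ["patient_id", "dispense_date", "atc_code"], kind="stable"
    ).reset_index(drop=True)
    return df


def registry_summary(
    df: pd.DataFrame,
    window_start: dt.date | None = None,
    window_end: dt.date | None = None,
) -> pd.DataFrame:
    """Yearly patient counts, sex split and mean ages.

    One row per calendar year covered by the window (or by the data);
    years without dispensings appear with zero counts.
    """
    if df.empty:
        raise ValueError("registry is empty")
    dates = pd.to_datetime(df["dispense_date"])
    y0 = window_start.year if window_start else int(dates.dt.year.min())
    y1 = window_end.year if window_end else int(dates.dt.year.max())

    per = df.assign(year=dates.dt.year)
    rows = []
    for year in range(y0, y1 + 1):
        sub = per[per["year"] == year]
        pat = sub.drop_duplicates("patient_id")
        n_male = int((pat["sex"] == "male").sum())
        n_female = int((pat["sex"] == "female").sum())
        total = n_male + n_female
        age = year - pat["birth_year"]
        rows.append(
            {
                "year": year,
                "n_male": n_male,
                "n_female": n_female,
                "n_total": total,
                "pct_female": 100.0 * n_female / total if total else 0.0,
                "mean_age_male": float(age[pat["sex"] == "male"].mean()) if n_male else np.nan,
                "mean_age_female": float(age[pat["sex"] == "female"].mean()) if n_female else np.nan,
            }
        )
    return pd.DataFrame(rows)
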