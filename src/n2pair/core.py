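"""Isotope-pairing analysis of N2 production in anoxic incubations.

After addition of a 15N-labeled substrate (nitrite or ammonium) to an anoxic
water sample, the distribution of N2 isotopologues (28N2, 29N2, 30N2)
accumulating over time identifies the process that produced them:
denitrification draws both product N atoms from the nitrite pool, so it
produces 30N2 at rate D*Fn**2, while anammox pairs one ammonium-N with one
nitrite-N and therefore can never produce 30N2 from an unlabeled ammonium
pool. Inverting this binomial pairing model converts the measured zero-order
accumulation rates of 29N2 and 30N2 into process rates for anammox (A) and
denitrification (D).

Rates are expressed in nmol N2 per liter of incubation water per day; times
are entered in hours and converted internally.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

HOURS_PER_DAY = 24.0

__all__ = [
    "Treatment",
    "IncubationDesign",
    "LabeledFraction",
    "IsotopologueSeries",
    "ProductionRates",
    "PairingRates",
    "ProcessRates",
    "InsufficientDataError",
    "NonIdentifiableError",
    "compute_labeled_fraction",
    "forward_pairing",
    "headspace_to_aqueous",
    "fit_production_rates",
    "estimate_rates_nitrite_label",
    "estimate_rate_ammonium_label",
    "bootstrap_rates_nitrite_label",
    "contribution_and_total",
]


class InsufficientDataError(ValueError):
    """Raised when a regression or test has too few usable observations."""


class NonIdentifiableError(ValueError):
    """Raised when the labeled fraction makes a rate impossible to infer."""


class Treatment(enum.Enum):
    """Tracer addition scheme of an incubation.

    AMMONIUM_15N: 15NH4+ plus unlabeled 14NO2-; only anammox produces 29N2.
    NITRITE_15N: 15NO2- only; both anammox and denitrification leave a
    signature in (29N2, 30N2).
    """

    AMMONIUM_15N = "ammonium_15n"
    NITRITE_15N = "nitrite_15n"


@dataclass(frozen=True)
class IncubationDesign:
    """Physical set-up of a destructive-sampling incubation experiment.

    Defaults mirror a groundwater assay: 30 mL water under an 8 mL helium
    headspace at 15 degC, triplicate bottles sacrificed at 0, 14, 24, 36
    and 48 h. Concentrations are in umol per liter of incubation water.
    """

    water_volume_ml: float = 30.0
    headspace_volume_ml: float = 8.0
    temperature_c: float = 15.0
    sampling_times_h: tuple[float, ...] = (0.0, 14.0, 24.0, 36.0, 48.0)
    replicates_per_time: int = 3
    treatment: Treatment = Treatment.NITRITE_15N
    added_15n_ammonium: float = 0.0
    added_15n_nitrite: float = 5.0
    added_14n_nitrite: float = 0.0
    background_ammonium: float = 0.0
    background_nitrite: float = 0.0

    def __post_init__(self) -> None:
        if self.water_volume_ml <= 0 or self.headspace_volume_ml <= 0:
            raise ValueError("volumes must be positive")
        times = tuple(float(t) for t in self.sampling_times_h)
        if len(times) == 0 or times[0] != 0.0:
            raise ValueError("sampling times must start at 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("sampling times must be strictly increasing")
        if self.replicates_per_time < 1:
            raise ValueError("need at least one replicate per time")
        for name in (
            "added_15n_ammonium",
            "added_15n_nitrite",
            "added_14n_nitrite",
            "background_ammonium",
            "background_nitrite",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.treatment is Treatment.AMMONIUM_15N and self.added_15n_nitrite != 0:
            raise ValueError("AMMONIUM_15N treatment must not add 15N-nitrite")
        if self.treatment is Treatment.NITRITE_15N and self.added_15n_ammonium != 0:
            raise ValueError("NITRITE_15N treatment must not add 15N-ammonium")
        object.__setattr__(self, "sampling_times_h", times)

    def labeled_fractions(self) -> "LabeledFraction":
        """Labeled fractions of both substrate pools implied by the design.

        Background pools dilute the label; an unmeasured (below-detection)
        background enters as 0 and yields F = 1 for the amended pool.
        """
        f_nitrite = compute_labeled_fraction(
            self.added_15n_nitrite,
            background_14n=self.background_nitrite + self.added_14n_nitrite,
        )
        f_ammonium = compute_labeled_fraction(
            self.added_15n_ammonium, background_14n=self.background_ammonium
        )
        return LabeledFraction(f_nitrite=f_nitrite, f_ammonium=f_ammonium)


@dataclass(frozen=True)
class LabeledFraction:
    """15N atom fraction of the nitrite and ammonium substrate pools."""

    f_nitrite: float
    f_ammonium: float = 0.0

    def __post_init__(self) -> None:
        for name in ("f_nitrite", "f_ammonium"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class IsotopologueSeries:
    """Per-bottle excess 29N2 and 30N2 observations over incubation time.

    ``data`` holds one row per sacrificed bottle with columns ``time_h``,
    ``replicate``, ``excess29_nmol_per_L`` and ``excess30_nmol_per_L``.
    Excess amounts are relative to the t=0 natural-abundance baseline and
    may dip slightly below zero through measurement noise; such rows are
    flagged, never discarded.
    """

    data: pd.DataFrame
    design: IncubationDesign | None = None

    REQUIRED_COLUMNS = (
        "time_h",
        "replicate",
        "excess29_nmol_per_L",
        "excess30_nmol_per_L",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"series table missing columns: {missing}")
        self.data = self.data.reset_index(drop=True)
        if (self.data["time_h"] < 0).any():
            raise ValueError("negative incubation times")
        if self.design is not None:
            allowed = set(self.design.sampling_times_h)
            extra = set(self.data["time_h"].unique()) - allowed
            if extra:
                raise ValueError(
                    f"times {sorted(extra)} not in design schedule {sorted(allowed)}"
                )

    @property
    def negative_flags(self) -> pd.DataFrame:
        """Rows whose excess went negative (noise artifacts, kept as data)."""
        mask = (self.data["excess29_nmol_per_L"] < 0) | (
            self.data["excess30_nmol_per_L"] < 0
        )
        return self.data[mask]

    def n_times(self) -> int:
        return self.data["time_h"].nunique()


@dataclass(frozen=True)
class ProductionRates:
    """OLS accumulation rates of the labeled isotopologues.

    Slopes ``p29`` and ``p30`` are in nmol N2 L^-1 d^-1 with standard
    errors, coefficients of determination, and one-sided p-values for a
    positive slope. ``n_points`` counts the pooled bottle observations.
    """

    p29: float
    p30: float
    se_p29: float
    se_p30: float
    r2_29: float
    r2_30: float
    p_value_29: float
    p_value_30: float
    n_points: int

    def __post_init__(self) -> None:
        if self.se_p29 < 0 or self.se_p30 < 0:
            raise ValueError("standard errors must be non-negative")


@dataclass(frozen=True)
class PairingRates:
    """Instantaneous production of each N2 isotopologue (nmol L^-1 d^-1)."""

    p28: float
    p29: float
    p30: float

    @property
    def total(self) -> float:
        return self.p28 + self.p29 + self.p30

    def proportions(self) -> tuple[float, float, float]:
        t = self.total
        if t == 0:
            return (0.0, 0.0, 0.0)
        return (self.p28 / t, self.p29 / t, self.p30 / t)


@dataclass(frozen=True)
class ProcessRates:
    """Partitioned N2 production: anammox (A) and denitrification (D).

    ``contribution`` is A/(A+D), the anammox share of total N2 production.
    ``detected_*`` report whether the underlying isotopologue slope passed a
    one-sided positivity test; a denitrification rate that the treatment
    cannot constrain (15NH4+ assays) is NaN with ``detected_d`` False.
    Negative point estimates are carried through untouched and flagged via
    ``warnings_``.
    """

    anammox: float
    denitrification: float
    se_a: float
    se_d: float
    detected_a: bool
    detected_d: bool
    warnings_: tuple[str, ...] = field(default=())

    @property
    def total(self) -> float:
        if math.isnan(self.denitrification):
            return self.anammox
        return self.anammox + self.denitrification

    @property
    def contribution(self) -> float:
        total, contrib, _ = contribution_and_total(
            self.anammox,
            0.0 if math.isnan(self.denitrification) else self.denitrification,
        )
        return contrib


def compute_labeled_fraction(
    added_15n: float,
    background_14n: float | None = None,
    measured_total: float | None = None,
) -> float:
    """15N fraction of a substrate pool after tracer addition.

    Either the unlabeled background concentration or a measured
    post-addition total must be supplied (exactly one of the two). With a
    background b, F = added / (b + added); with a measured total T,
    F = added / T — the convention used when the amended pool is assayed
    after spiking (typical for ammonium). All concentrations share units.
    """
    if added_15n < 0:
        raise ValueError("added_15n must be non-negative")
    if (background_14n is None) == (measured_total is None):
        raise ValueError(
            "provide exactly one of background_14n or measured_total"
        )
    if measured_total is not None:
        if measured_total < 0:
            raise ValueError("measured_total must be non-negative")
        if measured_total < added_15n:
            raise ValueError(
                "inconsistent input: measured total is smaller than the "
                "amount of label added"
            )
        if measured_total == 0:
            if added_15n > 0:
                raise ValueError("zero total with positive label added")
            return 0.0
        return added_15n / measured_total
    assert background_14n is not None
    if background_14n < 0:
        raise ValueError("background_14n must be non-negative")
    total = background_14n + added_15n
    if total == 0:
        if added_15n > 0:  # unreachable: total >= added; kept for clarity
            raise ValueError("zero total with positive label added")
        return 0.0
    return added_15n / total


def forward_pairing(a: float, d: float, f: LabeledFraction) -> PairingRates:
    """Isotopologue production rates implied by process rates A and D.

    Denitrification forms N2 from two independent draws of the nitrite
    pool (binomial in ``f.f_nitrite``); anammox combines one draw from the
    ammonium pool with one from the nitrite pool. The three isotopologue
    rates always sum to A + D.
    """
    if a < 0 or d < 0:
        raise ValueError("process rates must be non-negative")
    fn = f.f_nitrite
    fa = f.f_ammonium
    p30 = d * fn * fn + a * fa * fn
    p29 = 2.0 * d * fn * (1.0 - fn) + a * (fa * (1.0 - fn) + fn * (1.0 - fa))
    p28 = d * (1.0 - fn) ** 2 + a * (1.0 - fa) * (1.0 - fn)
    return PairingRates(p28=p28, p29=p29, p30=p30)


def headspace_to_aqueous(
    amount_nmol: float,
    design: IncubationDesign,
    include_dissolved: bool = False,
    solubility_coeff: float = 0.015,
) -> float:
    """Convert a headspace N2 amount to nmol per liter of incubation water.

    By default the headspace amount alone is normalized to the water
    volume. With ``include_dissolved`` the amount is scaled up by the
    equilibrium fraction remaining dissolved, using a Bunsen-type
    solubility coefficient beta (aqueous/gas concentration ratio): total
    bottle N2 = headspace * (1 + beta * V_water / V_headspace).
    """
    if solubility_coeff < 0:
        raise ValueError("solubility coefficient must be non-negative")
    total = amount_nmol
    if include_dissolved:
        total *= 1.0 + solubility_coeff * (
            design.water_volume_ml / design.headspace_volume_ml
        )
    return total / (design.water_volume_ml / 1000.0)


def _fit_one_slope(t_days: np.ndarray, y: np.ndarray) -> tuple[float, ...]:
    """OLS of excess vs time: slope, se, r2, one-sided p for slope > 0."""
    x = sm.add_constant(t_days)
    fit = sm.OLS(y, x).fit()
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    r2 = float(fit.rsquared)
    if not np.isfinite(r2):
        r2 = 0.0
    if se == 0.0:
        # exact line: p-value degenerates; positive slope is certain
        p_one = 0.0 if slope > 0 else (0.5 if slope == 0 else 1.0)
    else:
        tval = slope / se
        p_one = float(stats.t.sf(tval, df=fit.df_resid))
    return slope, se, max(0.0, min(1.0, r2)), p_one


def fit_production_rates(
    series: IsotopologueSeries, average_replicates: bool = False
) -> ProductionRates:
    """Zero-order accumulation rates of 29N2 and 30N2 from a bottle series.

    All bottles enter one pooled OLS fit per isotopologue (destructive
    sampling makes every bottle an independent observation); hours are
    converted to days so the slopes come out per day. Set
    ``average_replicates`` to regress on time-point means instead.
    """
    df = series.data
    if average_replicates:
        df = (
            df.groupby("time_h", as_index=False)[
                ["excess29_nmol_per_L", "excess30_nmol_per_L"]
            ]
            .mean()
        )
    n_distinct = df["time_h"].nunique()
    if n_distinct == 1:
        raise InsufficientDataError("all observations share one time point")
    if n_distinct < 3:
        raise InsufficientDataError(
            f"need >=3 distinct sampling times, got {n_distinct}"
        )
    t_days = df["time_h"].to_numpy(dtype=float) / HOURS_PER_DAY
    s29, se29, r29, p29 = _fit_one_slope(
        t_days, df["excess29_nmol_per_L"].to_numpy(dtype=float)
    )
    s30, se30, r30, p30 = _fit_one_slope(
        t_days, df["excess30_nmol_per_L"].to_numpy(dtype=float)
    )
    return ProductionRates(
        p29=s29,
        p30=s30,
        se_p29=se29,
        se_p30=se30,
        r2_29=r29,
        r2_30=r30,
        p_value_29=p29,
        p_value_30=p30,
        n_points=len(df),
    )


def estimate_rates_nitrite_label(
    production: ProductionRates, f: LabeledFraction, alpha: float = 0.05
) -> ProcessRates:
    """Invert the pairing model for a 15NO2- incubation.

    With nitrite labeled at fraction Fn (ammonium unlabeled),

        D = P30 / Fn^2
        A = (P29 - 2 Fn (1 - Fn) D) / Fn

    Standard errors are propagated by the delta method treating Fn as
    exact. Detection flags come from the one-sided slope tests at level
    ``alpha``. A negative anammox estimate (sampling noise pushing the
    29N2 slope below the denitrification-only expectation) is reported
    as-is with ``detected_a`` False and a warning.
    """
    fn = f.f_nitrite
    if fn == 0:
        raise NonIdentifiableError(
            "nitrite pool carries no label; rates are not identifiable"
        )
    d_rate = production.p30 / fn**2
    a_rate = (production.p29 - 2.0 * fn * (1.0 - fn) * d_rate) / fn
    se_d = production.se_p30 / fn**2
    # A = P29/Fn - 2(1-Fn)/Fn^2 * P30, slopes independent (separate fits)
    se_a = math.hypot(
        production.se_p29 / fn, 2.0 * (1.0 - fn) / fn**2 * production.se_p30
    )
    warn: list[str] = []
    detected_a = production.p_value_29 < alpha and a_rate > 0
    detected_d = production.p_value_30 < alpha and d_rate > 0
    if a_rate < 0:
        msg = (
            f"negative anammox estimate ({a_rate:.4g}); reported unclamped, "
            "detected_a set False"
        )
        warn.append(msg)
        warnings.warn(msg, stacklevel=2)
        detected_a = False
    if d_rate < 0:
        warn.append(f"negative denitrification estimate ({d_rate:.4g})")
    return ProcessRates(
        anammox=a_rate,
        denitrification=d_rate,
        se_a=se_a,
        se_d=se_d,
        detected_a=detected_a,
        detected_d=detected_d,
        warnings_=tuple(warn),
    )


def estimate_rate_ammonium_label(
    production: ProductionRates, f: LabeledFraction, alpha: float = 0.05
) -> ProcessRates:
    """Anammox rate from a 15NH4+ (+ unlabeled nitrite) incubation.

    Each anammox N2 pairs one ammonium-N with one (unlabeled) nitrite-N,
    so A = P29 / Fa. Denitrification leaves no labeled signature in this
    treatment and is returned as NaN. A significantly positive 30N2 slope
    violates the model (the nitrite pool should be unlabeled) and is
    surfaced as a warning.
    """
    fa = f.f_ammonium
    if fa == 0:
        raise NonIdentifiableError(
            "ammonium pool carries no label; anammox rate is not identifiable"
        )
    a_rate = production.p29 / fa
    se_a = production.se_p29 / fa
    warn: list[str] = []
    if production.p_value_30 < alpha and production.p30 > 0:
        msg = (
            f"significant 30N2 production (slope {production.p30:.4g}) in an "
            "ammonium-label treatment: pairing-model assumption violated "
            "(nitrite pool should be unlabeled)"
        )
        warn.append(msg)
        warnings.warn(msg, stacklevel=2)
    detected_a = production.p_value_29 < alpha and a_rate > 0
    if a_rate < 0:
        warn.append(f"negative anammox estimate ({a_rate:.4g})")
        detected_a = False
    return ProcessRates(
        anammox=a_rate,
        denitrification=float("nan"),
        se_a=se_a,
        se_d=float("nan"),
        detected_a=detected_a,
        detected_d=False,
        warnings_=tuple(warn),
    )


def bootstrap_rates_nitrite_label(
    series: IsotopologueSeries,
    f: LabeledFraction,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Bottle-resampling bootstrap of the 15NO2--treatment rate estimates.

    Alternative to the delta method: whole bottles (time, excess pairs)
    are resampled with replacement — the classic pairs bootstrap, valid
    because destructive sampling makes bottles independent — the slope
    fits and pairing inversion are re-run, and the replicate estimates
    are returned as a DataFrame with columns ``anammox`` and
    ``denitrification`` (one row per bootstrap replicate). Summarize with
    e.g. ``df.std()`` or percentile intervals. Draws that collapse onto
    fewer than three distinct times are redrawn. Deterministic under seed.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if f.f_nitrite == 0:
        raise NonIdentifiableError("nitrite pool carries no label")
    rng = np.random.default_rng(seed)
    data = series.data
    n = len(data)
    out = np.empty((n_boot, 2))
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            resampled = IsotopologueSeries(data.iloc[idx])
            if resampled.n_times() >= 3:
                break
        prod = fit_production_rates(resampled)
        d_rate = prod.p30 / f.f_nitrite**2
        a_rate = (prod.p29 - 2.0 * f.f_nitrite * (1.0 - f.f_nitrite) * d_rate) / f.f_nitrite
        out[b] = (a_rate, d_rate)
    return pd.DataFrame(out, columns=["anammox", "denitrification"])


def contribution_and_total(
    a: float, d: float, clamp_contribution: bool = False
) -> tuple[float, float, str | None]:
    """Total N2 production A + D and the anammox share A/(A+D).

    Returns ``(total, contribution, flag)``. With a zero total the
    contribution is NaN and flagged undefined. Negative inputs propagate
    untouched unless ``clamp_contribution`` pins the share into [0, 1];
    either way a flag records what happened.
    """
    if not (math.isfinite(a) and math.isfinite(d)):
        raise ValueError("rates must be finite")
    total = a + d
    if total == 0:
        return total, float("nan"), "undefined: total production is zero"
    contribution = a / total
    flag = None
    if a < 0 or d < 0:
        if clamp_contribution:
            contribution = min(1.0, max(0.0, contribution))
            flag = "negative input rate; contribution clamped to [0, 1]"
        else:
            flag = "negative input rate; contribution reported raw"
    return total, contribution, flag
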