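"""Standard curves, LOQ, internal-standard lot assignment, correction factors.

The standard series spans nine pre-mix concentrations (0, 0.1, 0.2, 0.6, 2,
6, 20, 60, 200 uM).  Mixed 1:1 with the internal-standard dilution and
injected at 2.5 ul, the nonzero levels put 0.125-250 pmol of each analyte on
column (uM x ul = pmol, and only half the injected volume is standard).

Curves are unweighted ordinary least squares of light-channel peak area on
on-column pmol with a free intercept; the zero standard carries no analyte
and is excluded from the fit.  The limit of quantification is the amount
whose peak reaches signal-to-noise 10, interpolated log-log from the series.

The same standard injections, because they are mixed 1:1 with the heavy
internal-standard lot, also calibrate the lot itself: each heavy-channel
area is interpolated on the corresponding light curve, giving the pmol of
heavy metabolite co-injected with every future sample.  Metabolites whose
heavy form is absent or too weak (IMP in the yeast extract; NA, which is
never labeled) are covered by a correction factor — the ratio of response
factors (area per pmol) between target and surrogate measured in the same
standard solutions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "LOQEstimate",
    "InternalStandardLot",
    "LotObservation",
    "STANDARD_SERIES_UM",
    "DEFAULT_MIX_FRACTION",
    "DEFAULT_INJECTION_VOLUME_UL",
    "on_column_amounts",
    "fit_curve",
    "interpolate_amount",
    "loq_from_series",
    "assign_lot",
    "correction_factor",
]

#: The nine pre-mix standard concentrations, uM.
STANDARD_SERIES_UM = (0.0, 0.1, 0.2, 0.6, 2.0, 6.0, 20.0, 60.0, 200.0)

#: Standards and samples are diluted two-fold into the internal-standard mix.
DEFAULT_MIX_FRACTION = 0.5

#: Injected volume of the final mixed material, ul.
DEFAULT_INJECTION_VOLUME_UL = 2.5

#: Back-calculated standards may deviate this much (relative) and still count
#: as inside the linear range.
LINEAR_RANGE_TOLERANCE = 0.15

#: Standards below this S/N are excluded from response-factor ratios.
_CF_MIN_S2N = 10.0


@dataclass(frozen=True)
class CalibrationPoint:
    nominal_conc: float     # uM, pre-mix
    on_column_pmol: float
    light_area: float       # counts * min
    s2n: float = math.inf


@dataclass(frozen=True)
class CalibrationCurve:
    metabolite: str
    slope: float            # counts*min per pmol
    intercept: float        # counts*min
    r_squared: float
    linear_range: tuple[float, float]   # pmol
    loq_pmol: float = math.nan


@dataclass(frozen=True)
class LOQEstimate:
    """LOQ in pmol; ``censored`` marks an open bound ("> pmol") when the
    series never reaches S/N 10."""

    pmol: float
    censored: bool = False


@dataclass
class InternalStandardLot:
    """Assigned heavy amounts co-injected with every sample.

    ``assigned_pmol`` maps metabolite -> pmol of its heavy isotopologue in
    the standard aliquot; ``replicate_cv`` the percent CV of that assignment
    over technical replicates; ``correction_factors`` maps
    (target, surrogate) -> response-factor ratio for surrogate-quantified
    metabolites; ``via`` maps metabolite -> surrogate for those.
    """

    assigned_pmol: dict[str, float] = field(default_factory=dict)
    replicate_cv: dict[str, float] = field(default_factory=dict)
    correction_factors: dict[tuple[str, str], float] = field(default_factory=dict)
    via: dict[str, str] = field(default_factory=dict)


def on_column_amounts(
    series_conc_um,
    mix_fraction: float = DEFAULT_MIX_FRACTION,
    injection_volume_ul: float = DEFAULT_INJECTION_VOLUME_UL,
):
    """On-column pmol for each standard concentration.

    pmol = uM x mix_fraction x ul — numerically exact because uM*ul = pmol.
    """
    conc = np.asarray(series_conc_um, dtype=float)
    if np.any(conc < 0) or mix_fraction <= 0 or injection_volume_ul <= 0:
        raise ValueError("concentrations must be >= 0 and volumes/fractions > 0")
    return conc * mix_fraction * injection_volume_ul


def fit_curve(metabolite: str, points: list[CalibrationPoint]) -> CalibrationCurve:
    """OLS calibration line over the nonzero standards.

    The linear range is the widest contiguous run of fitted standards whose
    back-calculated amounts deviate less than 15% from nominal.
    """
    nonzero = sorted(
        (p for p in points if p.on_column_pmol > 0 and np.isfinite(p.light_area)),
        key=lambda p: p.on_column_pmol,
    )
    if len(nonzero) < 3:
        raise ValueError("need at least 3 nonzero calibration points")
    x = np.array([p.on_column_pmol for p in nonzero])
    y = np.array([p.light_area for p in nonzero])
    if np.all(y == 0):
        raise ValueError("all calibration areas are zero")
    res = stats.linregress(x, y)
    slope, intercept = float(res.slope), float(res.intercept)
    if slope <= 0:
        raise ValueError(f"{metabolite}: calibration slope is not positive")
    r_squared = float(res.rvalue**2)

    back = (y - intercept) / slope
    ok = np.abs(back - x) <= LINEAR_RANGE_TOLERANCE * x
    lo, hi = _widest_true_run(ok)
    linear_range = (float(x[lo]), float(x[hi])) if lo is not None else (math.nan, math.nan)
    return CalibrationCurve(
        metabolite=metabolite,
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        linear_range=linear_range,
    )


def _widest_true_run(ok: np.ndarray):
    best = (None, None)
    best_len = 0
    start = None
    for i, flag in enumerate(list(ok) + [False]):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start > best_len:
                best_len = i - start
                best = (start, i - 1)
            start = None
    return best


def interpolate_amount(curve: CalibrationCurve, area: float) -> tuple[float, bool]:
    """Invert the calibration line: pmol = (area - intercept) / slope.

    Returns ``(pmol, in_linear_range)``.
    """
    if area < 0:
        raise ValueError("area must be non-negative")
    if curve.slope <= 0:
        raise ValueError("curve slope must be positive")
    pmol = (area - curve.intercept) / curve.slope
    lo, hi = curve.linear_range
    in_range = bool(np.isfinite(lo) and lo <= pmol <= hi)
    return pmol, in_range


def loq_from_series(points: list[CalibrationPoint]) -> LOQEstimate:
    """Amount producing S/N = 10, interpolated log-log on the series.

    Peak S/N is proportional to amount for a linear detector, so log(S/N)
    vs log(pmol) is interpolated linearly between the two levels bracketing
    10.  A series that never reaches S/N 10 yields a censored (open upper
    bound) estimate at the largest amount measured; a series already above
    10 at its lowest level yields the lowest amount scaled down along the
    proportionality (reported uncensored: the true LOQ is below the series).
    """
    usable = sorted(
        (p for p in points if p.on_column_pmol > 0 and np.isfinite(p.s2n) and p.s2n > 0),
        key=lambda p: p.on_column_pmol,
    )
    if not usable:
        raise ValueError("no usable points with finite S/N")
    amounts = np.array([p.on_column_pmol for p in usable])
    s2n = np.array([p.s2n for p in usable])

    exact = np.isclose(s2n, 10.0)
    if exact.any():
        return LOQEstimate(float(amounts[np.argmax(exact)]))
    if np.all(s2n < 10.0):
        return LOQEstimate(float(amounts[-1]), censored=True)
    if np.all(s2n > 10.0):
        # extrapolate along S/N proportional to amount from the lowest level
        return LOQEstimate(float(amounts[0] * 10.0 / s2n[0]))
    above = int(np.argmax(s2n >= 10.0))
    below = above - 1
    la, lb = math.log(amounts[below]), math.log(amounts[above])
    sa, sb = math.log(s2n[below]), math.log(s2n[above])
    frac = (math.log(10.0) - sa) / (sb - sa)
    return LOQEstimate(math.exp(la + frac * (lb - la)))


@dataclass(frozen=True)
class LotObservation:
    """One metabolite's heavy (and co-injected light) peak in one replicate."""

    heavy_area: float
    light_area: float = math.nan
    light_pmol: float = math.nan
    light_s2n: float = 0.0


def assign_lot(
    observations_by_replicate: list[dict[str, "LotObservation"]],
    curves: dict[str, CalibrationCurve],
    surrogates: dict[str, str] | None = None,
    min_light_s2n: float = _CF_MIN_S2N,
) -> InternalStandardLot:
    """Assign pmol amounts to the heavy internal-standard lot.

    Each technical replicate is a standard injection mixed 1:1 with the lot,
    so every replicate carries the heavy peak alongside a light peak of known
    amount.  When the light peak is quantifiable (S/N above
    ``min_light_s2n``) the assignment is ratio-based within the injection —
    heavy_area / light_area x light_pmol — which cancels any injection-wide
    intensity scale, exactly as the isotope-dilution ratio does for samples.
    A replicate without a usable light peak falls back to interpolating the
    heavy area on the metabolite's light calibration curve.  The assigned
    amount is the mean over replicates and the CV its replicate precision.

    ``surrogates`` maps metabolites expected to lack a usable heavy peak to
    the metabolite whose heavy peak stands in for them (default: IMP via
    NMN, NA via Nam).  Those are recorded in ``via`` instead of raising.
    Any other quantifiable metabolite with a curve but no heavy peak in any
    replicate is an error.
    """
    if len(observations_by_replicate) < 2:
        raise ValueError("lot assignment requires at least 2 technical replicates")
    surrogates = {"IMP": "NMN", "NA": "Nam"} if surrogates is None else surrogates

    lot = InternalStandardLot(via=dict(surrogates))
    per_met: dict[str, list[LotObservation]] = {}
    for rep in observations_by_replicate:
        for name, obs in rep.items():
            per_met.setdefault(name, []).append(obs)

    missing = [
        name
        for name in curves
        if name not in per_met and name not in surrogates
    ]
    if missing:
        raise ValueError(f"no heavy peak found for: {', '.join(sorted(missing))}")

    for name, observations in per_met.items():
        if name in surrogates:
            continue
        curve = curves.get(name)
        pmols = []
        for obs in observations:
            ratio_usable = (
                obs.light_s2n >= min_light_s2n
                and math.isfinite(obs.light_area)
                and obs.light_area > 0
                and math.isfinite(obs.light_pmol)
                and obs.light_pmol > 0
            )
            if ratio_usable:
                pmols.append(obs.heavy_area / obs.light_area * obs.light_pmol)
            elif curve is not None:
                pmols.append(interpolate_amount(curve, obs.heavy_area)[0])
        if not pmols:
            continue
        arr = np.array(pmols)
        mean = float(arr.mean())
        lot.assigned_pmol[name] = mean
        lot.replicate_cv[name] = (
            float(arr.std(ddof=1) / mean * 100.0)
            if mean != 0 and arr.size > 1
            else math.inf
        )
    return lot


def correction_factor(
    target_points: list[CalibrationPoint],
    surrogate_points: list[CalibrationPoint],
) -> float:
    """Response-factor ratio target/surrogate from shared standard levels.

    The response factor of a standard is area / on-column pmol.  Levels are
    matched by nominal concentration; only levels where both analytes reach
    S/N 10 contribute (below that the surrogate's area is noise-dominated
    and the ratio estimator is unstable).  The correction factor is the mean
    ratio over contributing levels.
    """
    t_by_level = {p.nominal_conc: p for p in target_points if p.on_column_pmol > 0}
    s_by_level = {p.nominal_conc: p for p in surrogate_points if p.on_column_pmol > 0}
    ratios = []
    for level in sorted(set(t_by_level) & set(s_by_level)):
        t, s = t_by_level[level], s_by_level[level]
        if t.s2n < _CF_MIN_S2N or s.s2n < _CF_MIN_S2N:
            continue
        rf_s = s.light_area / s.on_column_pmol
        if rf_s == 0:
            raise ValueError("surrogate response factor is zero")
        rf_t = t.light_area / t.on_column_pmol
        ratios.append(rf_t / rf_s)
    if not ratios:
        raise ValueError("no shared standard level with S/N >= 10 for both analytes")
    return float(np.mean(ratios))
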