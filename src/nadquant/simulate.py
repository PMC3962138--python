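"""Synthetic SRM run generator with ground truth.

Emulates the phenomena that make isotope-dilution quantification necessary
and sufficient:

* Gaussian peaks at each metabolite's expected retention time, with area =
  pmol on column x response factor (counts*min per pmol).
* Multiplicative ionization suppression, drawn once per sample injection and
  applied to EVERY channel of that injection — the sample-complexity model.
  Standards are clean solutions and are simulated unsuppressed.  Because
  light and heavy isotopologues co-elute, they always share the factor,
  which is exactly why area ratios survive suppression.
* On-source fragmentation crosstalk: a fraction of a source analyte's signal
  (both isotopologue channels) is lost in the ion source and reappears in
  the fragment's channel at the SOURCE retention time (e.g. NR sheds its
  nicotinamide and lights up the Nam channel at NR's elution).
* Isotopologue bleed: a fraction of a source's light signal appears in the
  one-or-two-Dalton neighbor channel at the source retention time (e.g. the
  13C isotope peak of cytidine in the uridine channel).
* Zero-mean Gaussian baseline noise (detector counts are baseline-subtracted,
  so small negative excursions are legitimate), plus per-preparation and
  per-injection multiplicative replicate noise.

Every simulated injection writes a :class:`TruthRecord` per channel with the
true pmol on column and the pre-noise area, so recovery can be measured
exactly.  Default response factors place each metabolite's limit of
quantification at its literature value under the default baseline noise,
which also reproduces the qualitative LOQ ordering (NMN, ATP, NA and
uridine least sensitive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .calibration import (
    DEFAULT_INJECTION_VOLUME_UL,
    DEFAULT_MIX_FRACTION,
    STANDARD_SERIES_UM,
)
from .chromatography import TransitionTrace
from .quantify import HELA_CELL_VOLUME_FL, SamplePrep
from .registry import ACIDIC_RUN_MIN, ALKALINE_RUN_MIN, Panel, load_registry

__all__ = [
    "SimConfig",
    "TruthRecord",
    "SimulatedInjection",
    "default_response_factors",
    "simulate_injection",
    "simulate_standard_series",
    "simulate_method_qc",
    "simulate_system_qc",
    "simulate_experiment",
    "demo_prep",
    "DEFAULT_BASELINE_SIGMA",
    "DEFAULT_PEAK_SIGMA_MIN",
    "DEMO_TRUE_CONC_UM",
]

#: Baseline noise sigma, counts.
DEFAULT_BASELINE_SIGMA = 50.0

#: Chromatographic peak sigma, minutes (both separations).
DEFAULT_PEAK_SIGMA_MIN = 0.05

#: Trace sampling interval, minutes.
DEFAULT_DT_MIN = 0.01

#: Heavy 13C-extract amounts on column, pmol (the lot aliquot co-injected
#: with every standard and sample).  IMP's heavy peak in the extract is too
#: small to use, so its lot amount is zero and it is quantified through NMN.
DEFAULT_LOT_PMOL = 20.0

#: 18O-labeled Nam and NR are spiked into every solution at 1.5 uM final
#: concentration, i.e. 1.5 uM x 2.5 ul = 3.75 pmol on column.
O18_SPIKE_PMOL = 1.5 * DEFAULT_INJECTION_VOLUME_UL

#: Limit-of-quantification targets (pmol) used to place response factors.
LOQ_TARGET_PMOL = {
    "Nam": 0.6, "NA": 2.5, "Cytidine": 0.01, "Uridine": 3.1, "NR": 0.01,
    "NAR": 0.1, "Inosine": 0.03, "CMP": 0.09, "UMP": 0.06, "NMN": 1.0,
    "NAMN": 0.06, "IMP": 0.1, "ADP": 0.03, "ATP": 1.0, "ADPr": 0.02,
    "NAD": 0.19, "NAAD": 0.02, "NADH": 0.19, "NADP": 0.06, "NADPH": 0.19,
}

#: Demo ground truth: intracellular concentrations (uM) of a cultured
#: mammalian cell line with a high-energy-charge nucleotide profile;
#: vitamins and biosynthetic intermediates near or below detection.
DEMO_TRUE_CONC_UM = {
    "ATP": 1010.0, "ADP": 890.0, "UMP": 370.0, "NAD": 260.0, "Inosine": 250.0,
    "Uridine": 210.0, "CMP": 170.0, "IMP": 98.0, "NADP": 57.0, "Nam": 39.0,
    "Cytidine": 6.7, "NADH": 6.7, "ADPr": 6.7, "NMN": 1.3,
    "NA": 0.0, "NR": 0.0, "NAMN": 0.0, "NAAD": 0.0, "NAR": 0.0,
}


def default_response_factors(
    baseline_sigma: float = DEFAULT_BASELINE_SIGMA,
    peak_sigma_min: float = DEFAULT_PEAK_SIGMA_MIN,
) -> dict[str, float]:
    """Response factors placing each metabolite's LOQ at its target value.

    A Gaussian peak of area ``pmol x RF`` has height
    ``pmol x RF / (sigma sqrt(2 pi))``; solving height = 10 x noise at the
    target LOQ gives RF = 10 x noise x sigma x sqrt(2 pi) / LOQ.
    """
    k = 10.0 * baseline_sigma * peak_sigma_min * math.sqrt(2.0 * math.pi)
    return {name: k / loq for name, loq in LOQ_TARGET_PMOL.items()}


@dataclass(frozen=True)
class TruthRecord:
    injection_id: str
    metabolite: str
    channel: str        # "light" | "heavy"
    true_pmol: float
    pre_noise_area: float


@dataclass
class SimulatedInjection:
    injection_id: str
    kind: str           # "standard" | "sample" | "qc_method" | "qc_system"
    separation: str
    traces: dict[str, TransitionTrace]
    truth: list[TruthRecord]
    level_um: float | None = None
    sample_id: str | None = None


@dataclass
class SimConfig:
    """Everything the generator needs; defaults are the study conditions."""

    seed: int = 0
    panel: Panel = field(default_factory=load_registry)
    true_conc_um: dict[str, float] = field(
        default_factory=lambda: dict(DEMO_TRUE_CONC_UM)
    )
    lot_pmol: dict[str, float] | None = None
    response_factor: dict[str, float] = field(default_factory=default_response_factors)
    suppression_range: tuple[float, float] = (0.3, 1.0)
    suppression_overrides: dict[str, float] | None = None
    peak_sigma_min: float = DEFAULT_PEAK_SIGMA_MIN
    baseline_sigma: float = DEFAULT_BASELINE_SIGMA
    fragmentation_fraction: dict[tuple[str, str], float] | None = None
    bleed_fraction: dict[tuple[str, str], float] | None = None
    crosstalk_enabled: bool = True
    prep_cv: float = 0.05
    injection_cv: float = 0.02
    mix_fraction: float = DEFAULT_MIX_FRACTION
    injection_volume_ul: float = DEFAULT_INJECTION_VOLUME_UL
    dt_min: float = DEFAULT_DT_MIN

    def noise_free(self) -> "SimConfig":
        """Copy of this config with every stochastic term switched off."""
        return replace(self, baseline_sigma=0.0, prep_cv=0.0, injection_cv=0.0)

    # -- derived defaults ------------------------------------------------

    def lot_amounts(self) -> dict[str, float]:
        """Heavy pmol on column for every internal-standard channel."""
        if self.lot_pmol is not None:
            return dict(self.lot_pmol)
        lot: dict[str, float] = {}
        for spec in self.panel.quantifiable():
            std_set = self.panel.internal_standard_set(spec.name)
            if std_set == "C13_extract":
                lot[spec.name] = 0.0 if spec.name == "IMP" else DEFAULT_LOT_PMOL
            elif std_set == "O18_vitamins":
                lot[spec.name] = O18_SPIKE_PMOL
        return lot

    def crosstalk_fractions(self) -> dict[tuple[str, str], float]:
        if not self.crosstalk_enabled:
            return {}
        fractions: dict[tuple[str, str], float] = {}
        for rule in self.panel.crosstalk:
            key = (rule.source, rule.target)
            override = None
            if rule.mechanism == "on_source_fragmentation":
                override = (self.fragmentation_fraction or {}).get(key)
            else:
                override = (self.bleed_fraction or {}).get(key)
            fractions[key] = rule.fraction if override is None else override
        return fractions

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _run_length(separation: str) -> float:
    return ALKALINE_RUN_MIN if separation == "alkaline" else ACIDIC_RUN_MIN


def _monitored_channels(config: SimConfig, separation: str) -> list[tuple[str, str]]:
    """(metabolite, light|heavy) channels acquired in one separation."""
    channels: list[tuple[str, str]] = []
    for spec in config.panel.by_separation(separation):
        channels.append((spec.name, "light"))
        if spec.quantifiable and config.panel.internal_standard_set(spec.name):
            channels.append((spec.name, "heavy"))
    return channels


def _gaussian_peak(t: np.ndarray, area: float, rt: float, sigma: float) -> np.ndarray:
    return area / (sigma * math.sqrt(2 * math.pi)) * np.exp(
        -0.5 * ((t - rt) / sigma) ** 2
    )


def simulate_injection(
    config: SimConfig,
    injection_id: str,
    separation: str,
    light_pmol: dict[str, float],
    heavy_pmol: dict[str, float],
    rng: np.random.Generator,
    suppression: float | None = None,
    injection_scale: float = 1.0,
    kind: str = "standard",
    level_um: float | None = None,
    sample_id: str | None = None,
) -> SimulatedInjection:
    """Render all monitored channels of one injection.

    ``light_pmol``/``heavy_pmol`` give true on-column amounts per metabolite;
    unlisted monitored channels are rendered as baseline only.  ``suppression``
    multiplies every channel (None means 1.0); per-metabolite overrides in the
    config win over the shared factor.  ``injection_scale`` models shot-to-shot
    intensity variation and likewise multiplies every channel.
    """
    unknown = set(light_pmol) | set(heavy_pmol)
    unknown -= set(config.panel.names())
    if unknown:
        raise KeyError(f"metabolites not in panel: {', '.join(sorted(unknown))}")

    t = np.arange(0.0, _run_length(separation) + config.dt_min / 2, config.dt_min)
    channels = _monitored_channels(config, separation)
    shared = 1.0 if suppression is None else suppression
    overrides = config.suppression_overrides or {}

    def factor(met: str) -> float:
        return overrides.get(met, shared) * injection_scale

    # pre-crosstalk areas per channel
    areas: dict[tuple[str, str], float] = {}
    pmols: dict[tuple[str, str], float] = {}
    for met, kind_ in channels:
        pmol = (light_pmol if kind_ == "light" else heavy_pmol).get(met, 0.0)
        rf = config.response_factor.get(met, 0.0)
        areas[(met, kind_)] = pmol * rf * factor(met)
        pmols[(met, kind_)] = pmol

    # crosstalk: deposit (source_rt, area) contributions per channel
    deposits: dict[tuple[str, str], list[tuple[float, float]]] = {}
    fractions = config.crosstalk_fractions()
    rules = {(r.source, r.target): r for r in config.panel.crosstalk}
    for (source, target), frac in fractions.items():
        if frac == 0.0:
            continue
        rule = rules[(source, target)]
        src_spec = config.panel.metabolites.get(source)
        if src_spec is None or src_spec.separation != separation:
            continue
        src_rt = src_spec.expected_rt
        if rule.mechanism == "on_source_fragmentation":
            # both isotopologues of the source fragment; each loses the
            # fraction, which reappears in the matching target channel
            for ch in ("light", "heavy"):
                src_area = areas.get((source, ch), 0.0)
                if src_area == 0.0:
                    continue
                areas[(source, ch)] = src_area * (1.0 - frac)
                if (target, ch) in areas:
                    deposits.setdefault((target, ch), []).append(
                        (src_rt, src_area * frac)
                    )
        else:  # isotopologue bleed: light source envelope into light target
            src_area = areas.get((source, "light"), 0.0)
            if src_area and (target, "light") in areas:
                deposits.setdefault((target, "light"), []).append(
                    (src_rt, src_area * frac)
                )

    traces: dict[str, TransitionTrace] = {}
    truth: list[TruthRecord] = []
    sigma = config.peak_sigma_min
    for met, ch in channels:
        rt = config.panel[met].expected_rt
        y = np.zeros_like(t)
        area = areas[(met, ch)]
        if area > 0:
            y += _gaussian_peak(t, area, rt, sigma)
        for dep_rt, dep_area in deposits.get((met, ch), []):
            y += _gaussian_peak(t, dep_area, dep_rt, sigma)
        if config.baseline_sigma > 0:
            y = y + rng.normal(0.0, config.baseline_sigma, size=t.size)
        channel_id = f"{met}:{ch}"
        traces[channel_id] = TransitionTrace(channel_id, t, y)
        truth.append(
            TruthRecord(
                injection_id=injection_id,
                metabolite=met,
                channel=ch,
                true_pmol=pmols[(met, ch)],
                pre_noise_area=area,
            )
        )
    return SimulatedInjection(
        injection_id=injection_id,
        kind=kind,
        separation=separation,
        traces=traces,
        truth=truth,
        level_um=level_um,
        sample_id=sample_id,
    )


def _standard_light_pmol(config: SimConfig, separation: str, conc_um: float) -> dict[str, float]:
    on_column = conc_um * config.mix_fraction * config.injection_volume_ul
    return {
        spec.name: on_column
        for spec in config.panel.by_separation(separation)
        if spec.quantifiable
    }


def _heavy_pmol(config: SimConfig, separation: str) -> dict[str, float]:
    lot = config.lot_amounts()
    return {
        spec.name: lot.get(spec.name, 0.0)
        for spec in config.panel.by_separation(separation)
        if spec.quantifiable
    }


def simulate_standard_series(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    series_um=STANDARD_SERIES_UM,
) -> list[SimulatedInjection]:
    """The 9-level standard series mixed 1:1 with the lot, both separations.

    Standards are clean solutions: no suppression is applied.
    """
    rng = config.rng() if rng is None else rng
    injections = []
    for separation in ("alkaline", "acidic"):
        if not config.panel.by_separation(separation):
            continue
        for i, conc in enumerate(series_um):
            scale = (
                rng.normal(1.0, config.injection_cv) if config.injection_cv > 0 else 1.0
            )
            injections.append(
                simulate_injection(
                    config,
                    injection_id=f"std_{separation}_L{i}",
                    separation=separation,
                    light_pmol=_standard_light_pmol(config, separation, conc),
                    heavy_pmol=_heavy_pmol(config, separation),
                    rng=rng,
                    injection_scale=scale,
                    kind="standard",
                    level_um=conc,
                )
            )
    return injections


def _qc_injections(
    config: SimConfig,
    rng: np.random.Generator,
    kind: str,
    n: int,
    conc_um: float,
    with_prep_noise: bool,
) -> list[SimulatedInjection]:
    injections = []
    for separation in ("alkaline", "acidic"):
        names = [s.name for s in config.panel.by_separation(separation) if s.quantifiable]
        if not names:
            continue
        for rep in range(n):
            base = conc_um * config.mix_fraction * config.injection_volume_ul
            light = {}
            for name in names:
                prep = (
                    rng.normal(1.0, config.prep_cv)
                    if with_prep_noise and config.prep_cv > 0
                    else 1.0
                )
                light[name] = base * prep
            scale = (
                rng.normal(1.0, config.injection_cv) if config.injection_cv > 0 else 1.0
            )
            injections.append(
                simulate_injection(
                    config,
                    injection_id=f"{kind}_{separation}_R{rep}",
                    separation=separation,
                    light_pmol=light,
                    heavy_pmol=_heavy_pmol(config, separation),
                    rng=rng,
                    injection_scale=scale,
                    kind=kind,
                    level_um=conc_um,
                )
            )
    return injections


def simulate_method_qc(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    n: int = 6,
    conc_um: float = 10.0,
) -> list[SimulatedInjection]:
    """Six independently prepared 10 uM standard solutions (method precision)."""
    rng = config.rng() if rng is None else rng
    return _qc_injections(config, rng, "qc_method", n, conc_um, with_prep_noise=True)


def simulate_system_qc(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    n: int = 4,
    conc_um: float = 10.0,
) -> list[SimulatedInjection]:
    """Four repeat injections of one 10 uM solution (system precision)."""
    rng = config.rng() if rng is None else rng
    return _qc_injections(config, rng, "qc_system", n, conc_um, with_prep_noise=False)


def demo_prep(sample_id: str = "S1") -> SamplePrep:
    """Default experimental prep: 2e7 cultured mammalian cells, 3.6 mg pellet."""
    return SamplePrep(
        cell_count=2e7,
        per_cell_volume_fl=HELA_CELL_VOLUME_FL,
        dry_pellet_mass_mg=3.6,
        od260_initial=14.0,
        sample_id=sample_id,
    )


def simulate_experiment(
    config: SimConfig,
    prep: SamplePrep | None = None,
    replicates: int = 3,
    rng: np.random.Generator | None = None,
) -> tuple[list[SimulatedInjection], list[SamplePrep]]:
    """Simulate replicate dishes of an experimental sample.

    Per replicate, each metabolite's true intracellular concentration gets an
    independent preparation factor (CV ``prep_cv``); each injection draws one
    shared suppression factor from ``suppression_range`` plus a shot-to-shot
    scale.  True on-column pmol (after prep noise, before suppression — which
    the ratio method must cancel) is written to the truth records.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rng = config.rng() if rng is None else rng
    preps: list[SamplePrep] = []
    injections: list[SimulatedInjection] = []
    for rep in range(1, replicates + 1):
        p = prep if prep is not None else demo_prep()
        p = replace(p, sample_id=f"{p.sample_id or 'S1'}_r{rep}" if replicates > 1 else (p.sample_id or "S1"))
        preps.append(p)
        eff_nl = p.effective_volume_nl
        conc = {
            name: c * (rng.normal(1.0, config.prep_cv) if config.prep_cv > 0 else 1.0)
            for name, c in config.true_conc_um.items()
            if name in config.panel.metabolites and config.panel[name].quantifiable
        }
        for separation in ("alkaline", "acidic"):
            names = [
                s.name for s in config.panel.by_separation(separation) if s.quantifiable
            ]
            if not names:
                continue
            light = {n: conc.get(n, 0.0) * eff_nl / 1e3 for n in names}
            lo, hi = config.suppression_range
            suppression = float(rng.uniform(lo, hi)) if hi > lo else float(hi)
            scale = (
                rng.normal(1.0, config.injection_cv) if config.injection_cv > 0 else 1.0
            )
            injections.append(
                simulate_injection(
                    config,
                    injection_id=f"{p.sample_id}_{separation}",
                    separation=separation,
                    light_pmol=light,
                    heavy_pmol=_heavy_pmol(config, separation),
                    rng=rng,
                    suppression=suppression,
                    injection_scale=scale,
                    kind="sample",
                    sample_id=p.sample_id,
                )
            )
    return injections, preps
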