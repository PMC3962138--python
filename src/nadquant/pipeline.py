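"""End-to-end orchestration: traces -> peaks -> curves -> lot -> sample report.

The processing order mirrors the bench workflow: integrate every channel of
every injection; calibrate each metabolite's light channel on the standard
series; assign the heavy internal-standard lot from the same standards-plus-
lot injections; derive the two surrogate correction factors (IMP against the
heavy NMN peak, NA against the heavy Nam spike); then quantify samples by
light/heavy area ratio and convert to intracellular concentrations through
the prep bookkeeping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from . import calibration as cal
from . import chromatography as chrom
from . import qc as qc_mod
from . import quantify as quant
from .dataset import Dataset
from .registry import Panel
from .simulate import SimulatedInjection

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "integrate_injection",
    "build_calibration",
    "quantify_dataset",
    "qc_dataset",
]

#: Default void times per separation (minutes); inferred from published
#: (RT, k') pairs, which imply t0 ~ 1.4 min on both columns.
DEFAULT_T0 = {"alkaline": 1.4, "acidic": 1.4}

#: Surrogate internal standards: target -> heavy surrogate whose peak is used.
DEFAULT_SURROGATES = {"IMP": "NMN", "NA": "Nam"}


@dataclass
class PipelineConfig:
    rt_window: float = chrom.DEFAULT_RT_WINDOW
    detection_snr: float = chrom.DEFAULT_DETECTION_SNR
    t0_min: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_T0))
    mix_fraction: float = cal.DEFAULT_MIX_FRACTION
    injection_volume_ul: float = cal.DEFAULT_INJECTION_VOLUME_UL
    surrogates: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_SURROGATES))
    quant_min_s2n: float = 10.0

    def as_flat_dict(self) -> dict[str, str]:
        d = {
            "rt_window": self.rt_window,
            "detection_snr": self.detection_snr,
            "t0_alkaline": self.t0_min["alkaline"],
            "t0_acidic": self.t0_min["acidic"],
            "mix_fraction": self.mix_fraction,
            "injection_volume_ul": self.injection_volume_ul,
            "quant_min_s2n": self.quant_min_s2n,
        }
        for target, surrogate in self.surrogates.items():
            d[f"surrogate_{target}"] = surrogate
        return {k: str(v) for k, v in d.items()}


@dataclass
class IntegratedInjection:
    injection: SimulatedInjection
    peaks: dict[str, list[chrom.Peak]]              # channel_id -> all peaks
    selected: dict[tuple[str, str], chrom.Peak | None]  # (metabolite, light|heavy)


@dataclass
class PipelineResult:
    curves: dict[str, cal.CalibrationCurve]
    loq: dict[str, cal.LOQEstimate]
    lot: cal.InternalStandardLot
    sample_results: dict[str, list[quant.QuantResult]]
    reports: dict[str, pd.DataFrame]
    flags_log: list[str] = field(default_factory=list)


def _exclusion_windows(panel: Panel, separation: str, window: float):
    return [
        (m.expected_rt - window, m.expected_rt + window)
        for m in panel.by_separation(separation)
    ]


def integrate_injection(
    inj: SimulatedInjection, panel: Panel, config: PipelineConfig
) -> IntegratedInjection:
    """Detect, integrate and assign peaks on every channel of one injection."""
    windows = _exclusion_windows(panel, inj.separation, config.rt_window)
    peaks: dict[str, list[chrom.Peak]] = {}
    selected: dict[tuple[str, str], chrom.Peak | None] = {}
    for channel_id, trace in inj.traces.items():
        met, _, ch = channel_id.partition(":")
        noise = chrom.estimate_noise(trace, windows)
        found = chrom.detect_and_integrate(trace, noise=noise, threshold_snr=config.detection_snr)
        peaks[channel_id] = found
        selected[(met, ch)] = chrom.select_peak(
            found, panel[met].expected_rt, config.rt_window
        )
    return IntegratedInjection(injection=inj, peaks=peaks, selected=selected)


@dataclass
class CalibrationBundle:
    curves: dict[str, cal.CalibrationCurve]
    loq: dict[str, cal.LOQEstimate]
    lot: cal.InternalStandardLot
    points: dict[str, list[cal.CalibrationPoint]]
    heavy_points: dict[str, list[cal.CalibrationPoint]]


def build_calibration(
    standards: list[IntegratedInjection], panel: Panel, config: PipelineConfig
) -> CalibrationBundle:
    """Curves, LOQs, lot assignment and correction factors from the series."""
    if not standards:
        raise ValueError("dataset contains no standard injections")

    points: dict[str, list[cal.CalibrationPoint]] = {}
    observations: list[dict[str, cal.LotObservation]] = []
    heavy_points: dict[str, list[cal.CalibrationPoint]] = {}

    for integrated in standards:
        inj = integrated.injection
        level = inj.level_um
        if level is None:
            continue
        rep_obs: dict[str, cal.LotObservation] = {}
        for spec in panel.by_separation(inj.separation):
            if not spec.quantifiable:
                continue
            pmol = level * config.mix_fraction * config.injection_volume_ul
            light = integrated.selected.get((spec.name, "light"))
            points.setdefault(spec.name, []).append(
                cal.CalibrationPoint(
                    nominal_conc=level,
                    on_column_pmol=pmol,
                    light_area=light.area if light else math.nan,
                    s2n=light.s2n if light else 0.0,
                )
            )
            heavy = integrated.selected.get((spec.name, "heavy"))
            if heavy is not None:
                rep_obs[spec.name] = cal.LotObservation(
                    heavy_area=heavy.area,
                    light_area=light.area if light else math.nan,
                    light_pmol=pmol,
                    light_s2n=light.s2n if light else 0.0,
                )
                heavy_points.setdefault(spec.name, []).append(
                    cal.CalibrationPoint(
                        nominal_conc=level,
                        on_column_pmol=math.nan,
                        light_area=heavy.area,
                        s2n=heavy.s2n,
                    )
                )
        observations.append(rep_obs)

    curves: dict[str, cal.CalibrationCurve] = {}
    loq: dict[str, cal.LOQEstimate] = {}
    for name, pts in points.items():
        curves[name] = cal.fit_curve(name, pts)
        loq[name] = cal.loq_from_series(pts)

    lot = cal.assign_lot(observations, curves, surrogates=config.surrogates)

    # correction factors: target quantified against its surrogate's heavy peak
    for target, surrogate in config.surrogates.items():
        if target not in points:
            continue
        surrogate_pmol = lot.assigned_pmol.get(surrogate)
        if surrogate_pmol is None:
            raise ValueError(
                f"surrogate {surrogate} for {target} has no assigned lot amount"
            )
        surrogate_pts = [
            cal.CalibrationPoint(
                nominal_conc=p.nominal_conc,
                on_column_pmol=surrogate_pmol,
                light_area=p.light_area,
                s2n=p.s2n,
            )
            for p in heavy_points.get(surrogate, [])
        ]
        lot.correction_factors[(target, surrogate)] = cal.correction_factor(
            points[target], surrogate_pts
        )
    return CalibrationBundle(
        curves=curves, loq=loq, lot=lot, points=points, heavy_points=heavy_points
    )


def _quantify_sample_injection(
    integrated: IntegratedInjection,
    panel: Panel,
    bundle: CalibrationBundle,
    config: PipelineConfig,
    prep: quant.SamplePrep | None,
    flags_log: list[str],
) -> list[quant.QuantResult]:
    inj = integrated.injection
    eff_nl = prep.effective_volume_nl if prep is not None else math.nan
    ic_ul = prep.intracellular_volume_ul if prep is not None else math.nan
    results: list[quant.QuantResult] = []

    for spec in panel.by_separation(inj.separation):
        name = spec.name
        if not spec.quantifiable:
            results.append(
                quant.QuantResult(metabolite=name, flag="excluded", notes=spec.notes)
            )
            continue
        surrogate = config.surrogates.get(name)
        if surrogate is not None:
            heavy_name = surrogate
            heavy_pmol = bundle.lot.assigned_pmol.get(surrogate)
            cf = bundle.lot.correction_factors.get((name, surrogate), math.nan)
        else:
            heavy_name = name
            heavy_pmol = bundle.lot.assigned_pmol.get(name)
            cf = 1.0

        light = integrated.selected.get((name, "light"))
        heavy = integrated.selected.get((heavy_name, "heavy"))

        loq_est = bundle.loq.get(name)
        loq_pmol = loq_est.pmol if loq_est else math.nan
        bound_um = (
            quant.to_concentration(loq_pmol, eff_nl)
            if prep is not None and math.isfinite(loq_pmol)
            else math.nan
        )

        if heavy is None or heavy_pmol is None or not math.isfinite(cf):
            results.append(
                quant.QuantResult(
                    metabolite=name,
                    flag="excluded",
                    notes=f"internal standard peak unavailable ({heavy_name})",
                )
            )
            flags_log.append(f"{inj.injection_id}/{name}: missing internal standard")
            continue

        if light is None or light.s2n < config.quant_min_s2n:
            results.append(
                quant.QuantResult(
                    metabolite=name,
                    flag="below_loq",
                    loq_bound_um=bound_um,
                    notes="no light peak above quantification S/N",
                )
            )
            flags_log.append(f"{inj.injection_id}/{name}: below LOQ (<{bound_um:.3g} uM)")
            continue

        pmol = quant.corrected_pmol(light.area, heavy.area, heavy_pmol, cf)
        if math.isfinite(loq_pmol) and pmol < loq_pmol:
            results.append(
                quant.QuantResult(
                    metabolite=name,
                    pmol_on_column=pmol,
                    flag="below_loq",
                    loq_bound_um=bound_um,
                )
            )
            flags_log.append(f"{inj.injection_id}/{name}: below LOQ (<{bound_um:.3g} uM)")
            continue

        conc = (
            quant.to_concentration(pmol, eff_nl) if prep is not None else math.nan
        )
        mol = conc * 1e-6 * ic_ul * 1e-6 if prep is not None else math.nan
        flag = "via_correction" if surrogate is not None else "ok"
        if surrogate is not None:
            flags_log.append(
                f"{inj.injection_id}/{name}: quantified via {surrogate} "
                f"correction factor"
            )
        results.append(
            quant.QuantResult(
                metabolite=name,
                pmol_on_column=pmol,
                mol_in_sample=mol,
                conc_um=conc,
                flag=flag,
                loq_bound_um=math.nan,
            )
        )
    return results


def quantify_dataset(
    ds: Dataset, panel: Panel, config: PipelineConfig | None = None
) -> PipelineResult:
    """Full quantification of a dataset directory's worth of injections."""
    config = config or PipelineConfig()
    standards = [
        integrate_injection(inj, panel, config) for inj in ds.by_kind("standard")
    ]
    bundle = build_calibration(standards, panel, config)

    flags_log: list[str] = []
    sample_results: dict[str, list[quant.QuantResult]] = {}
    for inj in ds.by_kind("sample"):
        integrated = integrate_injection(inj, panel, config)
        prep = ds.preps.get(inj.sample_id) if inj.sample_id else None
        results = _quantify_sample_injection(
            integrated, panel, bundle, config, prep, flags_log
        )
        sample_results.setdefault(inj.sample_id or inj.injection_id, []).extend(results)

    reports = {
        sample_id: quant.report(results)
        for sample_id, results in sample_results.items()
    }
    return PipelineResult(
        curves=bundle.curves,
        loq=bundle.loq,
        lot=bundle.lot,
        sample_results=sample_results,
        reports=reports,
        flags_log=flags_log,
    )


def qc_dataset(
    ds: Dataset, panel: Panel, config: PipelineConfig | None = None
) -> qc_mod.QCReport:
    """Robustness metrics from a dataset's standards and QC injections."""
    config = config or PipelineConfig()
    standards = [
        integrate_injection(inj, panel, config) for inj in ds.by_kind("standard")
    ]
    bundle = build_calibration(standards, panel, config)

    report = qc_mod.QCReport()
    for name, curve in bundle.curves.items():
        report.r_squared[name] = curve.r_squared
        report.loq_pmol[name] = bundle.loq[name].pmol

    # capacity factors from the top standard's observed retention times
    top: dict[str, tuple[float, float]] = {}
    for integrated in standards:
        level = integrated.injection.level_um or 0.0
        for (name, ch), peak in integrated.selected.items():
            if ch != "light" or peak is None:
                continue
            if level >= top.get(name, (-1.0, 0.0))[0]:
                top[name] = (level, peak.apex_rt)
    for name, (_, rt) in top.items():
        t0 = config.t0_min[panel[name].separation]
        if rt >= t0:
            report.k_prime[name] = chrom.capacity_factor(rt, t0)

    def _back_calculated(kind: str) -> list[dict[str, float]]:
        runs = []
        by_rep: dict[str, dict[str, float]] = {}
        for inj in ds.by_kind(kind):
            integrated = integrate_injection(inj, panel, config)
            rep_key = inj.injection_id.rsplit("_", 1)[-1]
            amounts = by_rep.setdefault(rep_key, {})
            for (name, ch), peak in integrated.selected.items():
                if ch != "light" or peak is None or name not in bundle.curves:
                    continue
                amounts[name], _ = cal.interpolate_amount(bundle.curves[name], peak.area)
        return [by_rep[k] for k in sorted(by_rep)]

    method_runs = _back_calculated("qc_method")
    if method_runs:
        report.method_rsd_pct = qc_mod.method_rsd(method_runs)
    system_runs = _back_calculated("qc_system")
    if system_runs:
        report.system_rsd_pct = qc_mod.system_rsd(system_runs)

    # audit one standard injection's extra peaks against the crosstalk map
    if standards:
        richest = max(standards, key=lambda s: s.injection.level_um or 0.0)
        light_peaks = {
            cid.split(":")[0]: pk
            for cid, pk in richest.peaks.items()
            if cid.endswith(":light")
        }
        light_selected = {
            name: richest.selected.get((name, "light")) for name in light_peaks
        }
        report.crosstalk_notes = qc_mod.crosstalk_audit(
            light_peaks, light_selected, panel, window=config.rt_window
        )
    return report
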