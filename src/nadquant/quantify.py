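"""Isotope-dilution quantification and intracellular concentration bookkeeping.

The central quantity is the light/heavy peak-area ratio.  Ionization
suppression in a complex extract is multiplicative on peak area and is
shared by co-eluting isotopologues, so the ratio of a 12C analyte to its
13C (or 18O) internal standard is suppression-free; multiplying by the known
pmol of heavy standard co-injected with every sample gives pmol of analyte
on column.

Converting pmol on column to an intracellular molar concentration follows
the extraction bookkeeping: a dried metabolite pellet is resuspended at
100 ul per 3.6 mg of particulate, diluted to OD260 = 14, mixed 1:1 with the
internal-standard dilution, and injected at 2.5 ul — so 1.25 ul of extract
is analyzed.  The cells' total intracellular volume (cell count x per-cell
volume: 70 fl for yeast, 2.5 pl for HeLa) times the analyzed fraction of the
final resuspension gives the effective intracellular volume on column, and
pmol / volume gives uM.  Worked example: 3e7 yeast cells = 2.1 ul
intracellular volume; 1.25 ul analyzed out of a 100 ul resuspension is
1.25%, so 26.25 nl of cell water is on column and 1 pmol there means ~38 uM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "SamplePrep",
    "QuantResult",
    "YEAST_CELL_VOLUME_FL",
    "HELA_CELL_VOLUME_FL",
    "resuspension_volume",
    "od_normalized_volume",
    "intracellular_volume",
    "effective_analyzed_volume",
    "isotope_dilution_pmol",
    "corrected_pmol",
    "to_concentration",
    "round_sig",
    "report",
]

#: Reference dry particulate mass resuspended in the reference volume.
PELLET_REFERENCE_MG = 3.6
PELLET_REFERENCE_UL = 100.0

#: Target optical density after resuspension; denser extracts are diluted.
OD260_TARGET = 14.0

#: Per-cell volumes, femtoliters.
YEAST_CELL_VOLUME_FL = 70.0
HELA_CELL_VOLUME_FL = 2500.0

_FL_PER_UNIT = {"fl": 1.0, "pl": 1e3, "nl": 1e6, "ul": 1e9}


@dataclass
class SamplePrep:
    """Extraction bookkeeping for one sample."""

    cell_count: float
    per_cell_volume_fl: float = YEAST_CELL_VOLUME_FL
    dry_pellet_mass_mg: float = PELLET_REFERENCE_MG
    od260_initial: float = OD260_TARGET
    mix_fraction: float = 0.5
    injection_volume_ul: float = 2.5
    sample_id: str = ""
    notes: str = ""

    def __post_init__(self) -> None:
        if self.cell_count < 0 or self.per_cell_volume_fl <= 0:
            raise ValueError("cell count must be >= 0 and per-cell volume > 0")
        if not 0 < self.mix_fraction <= 1:
            raise ValueError("mix_fraction must lie in (0, 1]")
        if self.injection_volume_ul <= 0:
            raise ValueError("injection volume must be positive")

    @property
    def resuspension_volume_ul(self) -> float:
        return resuspension_volume(self.dry_pellet_mass_mg)

    @property
    def final_volume_ul(self) -> float:
        vol, _ = od_normalized_volume(self.resuspension_volume_ul, self.od260_initial)
        return vol

    @property
    def od_below_target(self) -> bool:
        return self.od260_initial < OD260_TARGET

    @property
    def intracellular_volume_ul(self) -> float:
        return intracellular_volume(self.cell_count, self.per_cell_volume_fl, unit="fl")

    @property
    def effective_volume_nl(self) -> float:
        return effective_analyzed_volume(
            self.intracellular_volume_ul, self.final_volume_ul, self
        )


@dataclass
class QuantResult:
    """Per-metabolite quantification outcome for one sample."""

    metabolite: str
    pmol_on_column: float = math.nan
    mol_in_sample: float = math.nan
    conc_um: float = math.nan
    flag: str = "ok"        # ok | below_loq | excluded | via_correction
    loq_bound_um: float = math.nan
    notes: str = ""


def resuspension_volume(dry_mass_mg: float) -> float:
    """Resuspension volume (ul) for a dried metabolite pellet.

    Scales linearly from the empirical reference of 100 ul per 3.6 mg of
    dry cell-derived particulate.
    """
    if dry_mass_mg <= 0:
        raise ValueError("dry pellet mass must be positive")
    return dry_mass_mg / PELLET_REFERENCE_MG * PELLET_REFERENCE_UL


def od_normalized_volume(volume_ul: float, od260: float) -> tuple[float, bool]:
    """Dilute the resuspension to OD260 = 14; never concentrate.

    Returns ``(final volume ul, warned)`` — ``warned`` is set when the
    extract came in below the target OD and was left undiluted.
    """
    if volume_ul <= 0:
        raise ValueError("volume must be positive")
    if od260 <= 0:
        raise ValueError("OD260 must be positive")
    if od260 >= OD260_TARGET:
        return volume_ul * od260 / OD260_TARGET, False
    return volume_ul, True


def intracellular_volume(cell_count: float, per_cell_volume: float, unit: str = "fl") -> float:
    """Total intracellular volume of the extracted cells, in ul."""
    if cell_count < 0 or per_cell_volume < 0:
        raise ValueError("inputs must be non-negative")
    try:
        fl = per_cell_volume * _FL_PER_UNIT[unit]
    except KeyError:
        raise ValueError(f"unknown volume unit {unit!r}") from None
    return cell_count * fl / 1e9  # fl -> ul


def effective_analyzed_volume(
    intracellular_ul: float, final_volume_ul: float, prep: SamplePrep
) -> float:
    """Intracellular volume effectively on column, in nl.

    The injection analyzes ``injection_volume x mix_fraction`` of the final
    resuspension; the same fraction of the total intracellular volume is what
    the detector sees.
    """
    if final_volume_ul <= 0:
        raise ValueError("final volume must be positive")
    analyzed_ul = prep.injection_volume_ul * prep.mix_fraction
    fraction = analyzed_ul / final_volume_ul
    if fraction > 1:
        raise ValueError("analyzed volume exceeds the final sample volume")
    return fraction * intracellular_ul * 1e3  # ul -> nl


def isotope_dilution_pmol(light_area: float, heavy_area: float, heavy_pmol: float) -> float:
    """pmol of analyte from the light/heavy area ratio.

    Any multiplicative suppression common to the co-eluting isotopologues
    cancels here — the design point of the internal-standard scheme.
    """
    if heavy_area <= 0:
        raise ValueError("heavy-channel area must be positive (peak missing?)")
    if heavy_pmol <= 0:
        raise ValueError("heavy standard amount must be positive")
    if light_area < 0:
        raise ValueError("light area must be non-negative")
    return light_area / heavy_area * heavy_pmol


def corrected_pmol(
    light_area_target: float,
    heavy_area_surrogate: float,
    surrogate_pmol: float,
    cf: float,
) -> float:
    """Quantify against a surrogate heavy peak via a correction factor.

    ``cf`` is the target/surrogate response-factor ratio measured in standard
    solutions; dividing the raw ratio-based amount by it converts surrogate
    response into target amount.  With ``cf = 1`` this reduces exactly to
    ``isotope_dilution_pmol``.
    """
    if cf <= 0:
        raise ValueError("correction factor must be positive")
    return isotope_dilution_pmol(light_area_target, heavy_area_surrogate, surrogate_pmol) / cf


def to_concentration(pmol_on_column: float, effective_volume_nl: float) -> float:
    """Convert pmol on column to intracellular uM.

    1 pmol in 1 ul is 1 uM; the effective volume arrives in nl, so
    uM = pmol / (nl / 1000).  E.g. 6.76 pmol in 26 nl -> 260 uM.
    """
    if effective_volume_nl <= 0:
        raise ValueError("effective volume must be positive")
    if pmol_on_column < 0:
        raise ValueError("pmol must be non-negative")
    return pmol_on_column * 1e3 / effective_volume_nl


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (report convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


# Metabolites never reported: AMP cannot be resolved from on-source ATP/ADP
# fragmentation, NADPH is not preserved reliably through analysis.
NEVER_REPORTED = ("AMP", "NADPH")

_NADP_CAVEAT = "NADP may include oxidized cellular NADPH"
_NAM_CAVEAT = "Nam is membrane permeable; cellular Nam is easily lost to supernatants"


def report(results: list[QuantResult]) -> "pandas.DataFrame":
    """Render quantification results as a report table.

    Concentrations are rounded to 2 significant figures; below-LOQ analytes
    are shown as ``<bound``; AMP and NADPH never appear; NADP and Nam carry
    interpretation caveats; NAD+:NADH (nearest integer) and NAD+:NADP (one
    decimal) summary ratios are appended.
    """
    import pandas as pd

    rows = []
    by_name = {}
    for r in results:
        if r.metabolite in NEVER_REPORTED or r.flag == "excluded":
            continue
        by_name[r.metabolite] = r
        if r.flag == "below_loq":
            rendered = f"<{round_sig(r.loq_bound_um):g}"
            conc = math.nan
        else:
            rendered = f"{round_sig(r.conc_um):g}"
            conc = r.conc_um
        notes = r.notes
        if r.metabolite == "NADP":
            notes = (notes + "; " if notes else "") + _NADP_CAVEAT
        if r.metabolite == "Nam":
            notes = (notes + "; " if notes else "") + _NAM_CAVEAT
        rows.append(
            {
                "metabolite": r.metabolite,
                "conc_um": conc,
                "reported": rendered,
                "pmol_on_column": r.pmol_on_column,
                "flag": r.flag,
                "bound_um": r.loq_bound_um,
                "notes": notes,
            }
        )

    def _ratio(num: str, den: str, ndigits: int | None):
        a, b = by_name.get(num), by_name.get(den)
        if not a or not b or a.flag == "below_loq" or b.flag == "below_loq":
            return None
        if not (math.isfinite(a.conc_um) and math.isfinite(b.conc_um)) or b.conc_um == 0:
            return None
        ratio = a.conc_um / b.conc_um
        return round(ratio) if ndigits is None else round(ratio, ndigits)

    table = pd.DataFrame(rows)
    nadh_ratio = _ratio("NAD", "NADH", None)
    nadp_ratio = _ratio("NAD", "NADP", 1)
    extras = []
    if nadh_ratio is not None:
        extras.append(
            {"metabolite": "NAD/NADH", "reported": f"{nadh_ratio}", "flag": "ratio",
             "conc_um": math.nan, "pmol_on_column": math.nan, "bound_um": math.nan,
             "notes": ""}
        )
    if nadp_ratio is not None:
        extras.append(
            {"metabolite": "NAD/NADP", "reported": f"{nadp_ratio}", "flag": "ratio",
             "conc_um": math.nan, "pmol_on_column": math.nan, "bound_um": math.nan,
             "notes": ""}
        )
    if extras:
        table = pd.concat([table, pd.DataFrame(extras)], ignore_index=True)
    return table
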