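"""Robustness metrics: method/system RSD, and a crosstalk audit of peak tables.

Two precision figures are tracked per metabolite.  *Method* RSD spans
independently prepared standard solutions (default six, at 10 uM) and so
includes preparation variability; *system* RSD spans repeat injections of a
single solution (default four) and isolates instrument variability.  Both
are computed on back-calculated amounts rather than raw areas, which makes
them insensitive to any injection-wide multiplicative effect (consistent
with the ratio-based quantification philosophy of the assay).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chromatography import DEFAULT_RT_WINDOW, Peak
from .registry import Panel

__all__ = ["QCReport", "rsd", "method_rsd", "system_rsd", "crosstalk_audit"]

METHOD_REPLICATES = 6
SYSTEM_REPLICATES = 4


@dataclass
class QCReport:
    """Per-metabolite quality metrics mirroring the assay's robustness table."""

    method_rsd_pct: dict[str, float] = field(default_factory=dict)
    system_rsd_pct: dict[str, float] = field(default_factory=dict)
    r_squared: dict[str, float] = field(default_factory=dict)
    k_prime: dict[str, float] = field(default_factory=dict)
    loq_pmol: dict[str, float] = field(default_factory=dict)
    crosstalk_notes: list[str] = field(default_factory=list)


def rsd(values) -> float:
    """Relative standard deviation, percent: 100 x sd(n-1) / mean."""
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise ValueError("RSD needs at least 2 values")
    mean = vals.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return float(vals.std(ddof=1) / mean * 100.0)


def _rsd_over_runs(
    amounts_by_run: list[dict[str, float]], expected_n: int, label: str
) -> dict[str, float]:
    if len(amounts_by_run) != expected_n:
        raise ValueError(
            f"{label} RSD requires exactly {expected_n} runs, got {len(amounts_by_run)}"
        )
    names = set(amounts_by_run[0])
    for i, run in enumerate(amounts_by_run[1:], start=2):
        missing = names - set(run)
        if missing:
            raise ValueError(
                f"{label} RSD: run {i} is missing {', '.join(sorted(missing))}"
            )
        names &= set(run)
    return {name: rsd([run[name] for run in amounts_by_run]) for name in sorted(names)}


def method_rsd(
    amounts_by_run: list[dict[str, float]], replicates: int = METHOD_REPLICATES
) -> dict[str, float]:
    """Per-metabolite RSD over independently prepared standard solutions.

    ``amounts_by_run`` holds the back-calculated amount of each metabolite in
    each of the (default six) separate preparations.
    """
    return _rsd_over_runs(amounts_by_run, replicates, "method")


def system_rsd(
    amounts_by_run: list[dict[str, float]], replicates: int = SYSTEM_REPLICATES
) -> dict[str, float]:
    """Per-metabolite RSD over repeat injections of one standard solution."""
    return _rsd_over_runs(amounts_by_run, replicates, "system")


def crosstalk_audit(
    peaks_by_channel: dict[str, list[Peak]],
    selected: dict[str, Peak | None],
    panel: Panel,
    window: float = DEFAULT_RT_WINDOW,
) -> list[str]:
    """Explain extra (unselected) peaks in each channel via the crosstalk map.

    Channel keys are metabolite names (light channels).  An unselected peak
    whose apex falls within ``window`` of a crosstalk source's expected
    retention time is annotated with that rule; anything else is flagged as
    unexplained.
    """
    notes: list[str] = []
    rules_by_target: dict[str, list] = {}
    for rule in panel.crosstalk:
        rules_by_target.setdefault(rule.target, []).append(rule)

    for channel, peaks in peaks_by_channel.items():
        chosen = selected.get(channel)
        for peak in peaks:
            if chosen is not None and peak.apex_rt == chosen.apex_rt:
                continue
            explained = False
            for rule in rules_by_target.get(channel, []):
                src_rt = panel[rule.source].expected_rt
                if abs(peak.apex_rt - src_rt) <= window:
                    mech = (
                        "on-source fragmentation of"
                        if rule.mechanism == "on_source_fragmentation"
                        else "isotopologue bleed from"
                    )
                    notes.append(
                        f"{channel}: peak at {peak.apex_rt:.2f} min explained by "
                        f"{mech} {rule.source}"
                    )
                    explained = True
                    break
            if not explained:
                notes.append(
                    f"{channel}: unexplained extra peak at {peak.apex_rt:.2f} min"
                )
    return notes
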