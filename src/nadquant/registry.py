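"""Assay panel registry: metabolites, SRM transitions, heavy channels, crosstalk.

The panel models a targeted triple-quadrupole assay of the NAD+ metabolome:
19 quantifiable metabolites split between an alkaline separation (16 analytes,
32.2 min run) and an acidic separation (Nam, NA, NR; 23.4 min run), plus a
NADPH channel that is monitored but never reported.

Two internal-standard sets exist.  ``C13_extract`` is a uniformly
13C-glucose-grown yeast extract: every carbohydrate-containing metabolite is
shifted by +5 Da per ribosyl moiety (mononucleotides/nucleosides +5 Da,
dinucleotides +10 Da).  Nam and NA carry no carbohydrate and are therefore
unlabeled in that extract; Nam and NR are instead covered by 18O-labeled
spikes (``O18_vitamins``, +2 Da per substitution) used in the acidic
separation.  Heavy MS2 fragment offsets are stored explicitly because they
depend on which labeled moieties each fragment retains.

Crosstalk rules record two interference mechanisms that put signal into
*another* metabolite's channel at the *source* metabolite's retention time:
on-source fragmentation (e.g. NR and NMN shed their nicotinamide before the
first quadrupole) and isotopologue bleed (the natural-abundance or labeled
isotope envelope of a neighbor, e.g. the 13C peak of cytidine landing in the
uridine channel one Dalton up).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "MetaboliteSpec",
    "HeavyChannelSpec",
    "CrosstalkRule",
    "Panel",
    "PanelValidationError",
    "load_registry",
    "ALKALINE_RUN_MIN",
    "ACIDIC_RUN_MIN",
]

#: Total run length of each separation (gradient table end points), minutes.
ALKALINE_RUN_MIN = 32.2
ACIDIC_RUN_MIN = 23.4

#: Metabolites resolved in the acidic separation; everything else is alkaline.
ACIDIC_METABOLITES = ("Nam", "NA", "NR")


class PanelValidationError(ValueError):
    """Raised when a panel file violates a structural invariant."""


@dataclass(frozen=True)
class MetaboliteSpec:
    """One SRM assay: analyte, transition, tuning, and expected elution."""

    name: str
    precursor_mz: float
    fragment_mz: float
    collision_energy: float
    cone_voltage: float
    expected_rt: float          # minutes
    separation: str             # "alkaline" | "acidic"
    quantifiable: bool = True
    notes: str = ""

    def __post_init__(self) -> None:
        if self.separation not in ("alkaline", "acidic"):
            raise PanelValidationError(
                f"{self.name}: unknown separation {self.separation!r}"
            )
        if self.quantifiable and not (self.precursor_mz > self.fragment_mz > 0):
            raise PanelValidationError(
                f"{self.name}: transition must satisfy precursor > fragment > 0"
            )
        if not 0 < self.expected_rt <= self.run_length:
            raise PanelValidationError(
                f"{self.name}: RT {self.expected_rt} min outside the "
                f"{self.separation} run ({self.run_length} min)"
            )

    @property
    def run_length(self) -> float:
        return ALKALINE_RUN_MIN if self.separation == "alkaline" else ACIDIC_RUN_MIN


@dataclass(frozen=True)
class HeavyChannelSpec:
    """Heavy-isotopologue channel of one metabolite in one standard set."""

    metabolite: str
    standard_set: str           # "C13_extract" | "O18_vitamins"
    precursor_offset_da: float
    fragment_offset_da: float

    @property
    def mass_offset(self) -> float:
        return self.precursor_offset_da


@dataclass(frozen=True)
class CrosstalkRule:
    """Signal from ``source`` contaminating ``target``'s channel.

    The contaminating peak always appears at the SOURCE metabolite's
    retention time; retention-time windows are what reject it downstream.
    """

    source: str
    target: str
    mechanism: str              # "on_source_fragmentation" | "isotopologue_bleed"
    fraction: float

    def __post_init__(self) -> None:
        if self.mechanism not in ("on_source_fragmentation", "isotopologue_bleed"):
            raise PanelValidationError(f"unknown crosstalk mechanism {self.mechanism!r}")
        if not 0 <= self.fraction < 1:
            raise PanelValidationError("crosstalk fraction must lie in [0, 1)")


@dataclass
class Panel:
    """Validated assay panel: metabolites, heavy channels, crosstalk map."""

    metabolites: dict[str, MetaboliteSpec]
    heavy_channels: dict[tuple[str, str], HeavyChannelSpec] = field(default_factory=dict)
    crosstalk: list[CrosstalkRule] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- queries ---------------------------------------------------------

    def __contains__(self, name: str) -> bool:
        return name in self.metabolites

    def __getitem__(self, name: str) -> MetaboliteSpec:
        return self.metabolites[name]

    def names(self) -> list[str]:
        return list(self.metabolites)

    def quantifiable(self) -> list[MetaboliteSpec]:
        return [m for m in self.metabolites.values() if m.quantifiable]

    def by_separation(self, separation: str) -> list[MetaboliteSpec]:
        return [m for m in self.metabolites.values() if m.separation == separation]

    def has_heavy(self, name: str, standard_set: str) -> bool:
        return (name, standard_set) in self.heavy_channels

    def heavy_transition(self, name: str, standard_set: str) -> tuple[float, float]:
        """Heavy-channel (precursor, fragment) m/z for a metabolite.

        Raises ``KeyError`` when the metabolite has no heavy form in the
        requested set (Nam and NA carry no carbohydrate, so the 13C extract
        does not label them).
        """
        spec = self.metabolites[name]
        try:
            heavy = self.heavy_channels[(name, standard_set)]
        except KeyError:
            raise KeyError(
                f"{name} has no heavy channel in standard set {standard_set!r}"
            ) from None
        return (
            spec.precursor_mz + heavy.precursor_offset_da,
            spec.fragment_mz + heavy.fragment_offset_da,
        )

    def internal_standard_set(self, name: str) -> str | None:
        """Which standard set supplies this metabolite's own heavy channel.

        Acidic analytes use the 18O vitamin spikes, alkaline ones the 13C
        extract; NA has no heavy form in either set (surrogate quantification
        through heavy Nam).
        """
        spec = self.metabolites[name]
        preferred = "O18_vitamins" if spec.separation == "acidic" else "C13_extract"
        if self.has_heavy(name, preferred):
            return preferred
        return None

    def subset(self, names: list[str]) -> "Panel":
        """Restricted panel (e.g. for fast focused simulations)."""
        keep = set(names)
        return Panel(
            metabolites={n: m for n, m in self.metabolites.items() if n in keep},
            heavy_channels={
                k: v for k, v in self.heavy_channels.items() if k[0] in keep
            },
            crosstalk=[
                r for r in self.crosstalk if r.source in keep and r.target in keep
            ],
        )

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        if not self.metabolites:
            raise PanelValidationError("panel is empty")
        for key, spec in self.metabolites.items():
            if key != spec.name:
                raise PanelValidationError(f"panel key {key!r} != spec name {spec.name!r}")
        for (name, _), heavy in self.heavy_channels.items():
            if name not in self.metabolites:
                raise PanelValidationError(
                    f"heavy channel for unknown metabolite {name!r}"
                )
            if heavy.metabolite != name:
                raise PanelValidationError(f"heavy channel key/name mismatch for {name}")
        for rule in self.crosstalk:
            for end in (rule.source, rule.target):
                if end not in self.metabolites:
                    raise PanelValidationError(
                        f"crosstalk rule references unknown metabolite {end!r}"
                    )

    # -- serialization ---------------------------------------------------

    def to_files(self, panel_path: Path, crosstalk_path: Path | None = None) -> None:
        with open(panel_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_PANEL_HEADER)
            for m in self.metabolites.values():
                writer.writerow(
                    [
                        m.name,
                        _fmt(m.precursor_mz),
                        _fmt(m.fragment_mz),
                        _fmt(m.collision_energy),
                        _fmt(m.cone_voltage),
                        _fmt(m.expected_rt),
                        m.separation,
                        "true" if m.quantifiable else "false",
                        m.notes,
                    ]
                )
        if crosstalk_path is not None:
            with open(crosstalk_path, "w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(["source", "target", "mechanism", "fraction"])
                for r in self.crosstalk:
                    writer.writerow([r.source, r.target, r.mechanism, _fmt(r.fraction)])


_PANEL_HEADER = [
    "name",
    "precursor_mz",
    "fragment_mz",
    "collision_energy",
    "cone_voltage",
    "rt_min",
    "separation",
    "quantifiable",
    "notes",
]


def _fmt(x: float) -> str:
    return format(x, "g")


def _read_rows(path_or_text) -> list[dict[str, str]]:
    if isinstance(path_or_text, str) and "\n" in path_or_text:
        lines = path_or_text.splitlines()
    else:
        lines = Path(path_or_text).read_text().splitlines()
    return list(csv.DictReader(lines))


def _parse_panel_rows(rows: list[dict[str, str]]) -> dict[str, MetaboliteSpec]:
    metabolites: dict[str, MetaboliteSpec] = {}
    for i, row in enumerate(rows, start=2):
        name = (row.get("name") or "").strip()
        if not name:
            raise PanelValidationError(f"panel row {i}: missing metabolite name")
        if name in metabolites:
            raise PanelValidationError(f"panel row {i}: duplicate metabolite {name!r}")
        try:
            spec = MetaboliteSpec(
                name=name,
                precursor_mz=float(row["precursor_mz"]),
                fragment_mz=float(row["fragment_mz"]),
                collision_energy=float(row["collision_energy"]),
                cone_voltage=float(row["cone_voltage"]),
                expected_rt=float(row["rt_min"]),
                separation=row["separation"].strip(),
                quantifiable=row["quantifiable"].strip().lower() in ("true", "1", "yes"),
                notes=(row.get("notes") or "").strip(),
            )
        except (KeyError, ValueError) as err:
            if isinstance(err, PanelValidationError):
                raise
            raise PanelValidationError(f"panel row {i} ({name}): {err}") from err
        metabolites[name] = spec
    if not metabolites:
        raise PanelValidationError("panel file contains no metabolites")
    return metabolites


def _builtin_text(filename: str) -> str:
    return resources.files("nadquant").joinpath("data", filename).read_text()


def load_registry(
    panel_file: str | Path = "builtin",
    crosstalk_file: str | Path | None = None,
    heavy_file: str | Path | None = None,
) -> Panel:
    """Load and validate an assay panel.

    ``panel_file="builtin"`` loads the packaged 20-row panel (19 quantifiable
    metabolites plus the monitored-but-unreported NADPH channel), the heavy
    channel definitions of both standard sets, and the default crosstalk map.
    Custom CSVs use the headers documented on the packaged files.
    """
    if panel_file == "builtin":
        panel_rows = _read_rows(_builtin_text("panel.csv"))
        heavy_rows = _read_rows(_builtin_text("heavy_channels.csv"))
        xt_rows = _read_rows(_builtin_text("crosstalk.csv"))
    else:
        panel_rows = _read_rows(panel_file)
        heavy_rows = _read_rows(heavy_file) if heavy_file else []
        xt_rows = _read_rows(crosstalk_file) if crosstalk_file else []

    metabolites = _parse_panel_rows(panel_rows)

    heavy_channels: dict[tuple[str, str], HeavyChannelSpec] = {}
    for row in heavy_rows:
        heavy = HeavyChannelSpec(
            metabolite=row["metabolite"].strip(),
            standard_set=row["standard_set"].strip(),
            precursor_offset_da=float(row["precursor_offset_da"]),
            fragment_offset_da=float(row["fragment_offset_da"]),
        )
        heavy_channels[(heavy.metabolite, heavy.standard_set)] = heavy

    crosstalk = [
        CrosstalkRule(
            source=row["source"].strip(),
            target=row["target"].strip(),
            mechanism=row["mechanism"].strip(),
            fraction=float(row["fraction"]),
        )
        for row in xt_rows
    ]

    return Panel(metabolites=metabolites, heavy_channels=heavy_channels, crosstalk=crosstalk)
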