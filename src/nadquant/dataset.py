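"""On-disk layout of a simulated or acquired run set.

A dataset directory holds one trace CSV per injection plus run-level tables::

    dataset/
      manifest.csv   injection_id,kind,separation,level_um,sample_id
      samples.csv    sample_id,cell_count,per_cell_volume_fl,dry_mass_mg,od260,notes
      truth.csv      injection_id,metabolite,channel,true_pmol,pre_noise_area
      traces/<injection_id>.csv   channel_id,time_min,intensity

``truth.csv`` exists only for simulated data.  Channel ids are
``<metabolite>:light`` / ``<metabolite>:heavy``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chromatography import TransitionTrace
from .quantify import SamplePrep
from .simulate import SimulatedInjection, TruthRecord

__all__ = ["Dataset", "write_dataset", "read_dataset"]


@dataclass
class Dataset:
    injections: list[SimulatedInjection]
    preps: dict[str, SamplePrep] = field(default_factory=dict)

    def by_kind(self, kind: str) -> list[SimulatedInjection]:
        return [inj for inj in self.injections if inj.kind == kind]

    def truth_frame(self) -> pd.DataFrame:
        rows = [
            {
                "injection_id": rec.injection_id,
                "metabolite": rec.metabolite,
                "channel": rec.channel,
                "true_pmol": rec.true_pmol,
                "pre_noise_area": rec.pre_noise_area,
            }
            for inj in self.injections
            for rec in inj.truth
        ]
        return pd.DataFrame(rows)


def write_dataset(dataset: Dataset, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    (out / "traces").mkdir(parents=True, exist_ok=True)

    manifest = pd.DataFrame(
        [
            {
                "injection_id": inj.injection_id,
                "kind": inj.kind,
                "separation": inj.separation,
                "level_um": "" if inj.level_um is None else inj.level_um,
                "sample_id": inj.sample_id or "",
            }
            for inj in dataset.injections
        ]
    )
    manifest.to_csv(out / "manifest.csv", index=False)

    for inj in dataset.injections:
        frames = []
        for channel_id, trace in inj.traces.items():
            frames.append(
                pd.DataFrame(
                    {
                        "channel_id": channel_id,
                        "time_min": trace.times,
                        "intensity": trace.intensities,
                    }
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(
            out / "traces" / f"{inj.injection_id}.csv", index=False, float_format="%.6g"
        )

    if dataset.preps:
        pd.DataFrame(
            [
                {
                    "sample_id": p.sample_id,
                    "cell_count": p.cell_count,
                    "per_cell_volume_fl": p.per_cell_volume_fl,
                    "dry_mass_mg": p.dry_pellet_mass_mg,
                    "od260": p.od260_initial,
                    "notes": p.notes,
                }
                for p in dataset.preps.values()
            ]
        ).to_csv(out / "samples.csv", index=False)

    truth = dataset.truth_frame()
    if not truth.empty:
        truth.to_csv(out / "truth.csv", index=False, float_format="%.10g")
    return out


def read_dataset(in_dir: str | Path) -> Dataset:
    src = Path(in_dir)
    manifest_path = src / "manifest.csv"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.csv in {src}")
    manifest = pd.read_csv(manifest_path, keep_default_na=False)

    truth_by_injection: dict[str, list[TruthRecord]] = {}
    truth_path = src / "truth.csv"
    if truth_path.exists():
        # keep_default_na: the metabolite "NA" (nicotinic acid) is data here
        for row in pd.read_csv(truth_path, keep_default_na=False).itertuples():
            truth_by_injection.setdefault(row.injection_id, []).append(
                TruthRecord(
                    injection_id=row.injection_id,
                    metabolite=row.metabolite,
                    channel=row.channel,
                    true_pmol=row.true_pmol,
                    pre_noise_area=row.pre_noise_area,
                )
            )

    injections: list[SimulatedInjection] = []
    for row in manifest.itertuples():
        trace_path = src / "traces" / f"{row.injection_id}.csv"
        table = pd.read_csv(trace_path)
        traces = {
            channel_id: TransitionTrace(
                channel_id,
                np.asarray(group["time_min"], dtype=float),
                np.asarray(group["intensity"], dtype=float),
            )
            for channel_id, group in table.groupby("channel_id", sort=False)
        }
        level = row.level_um
        level_um = float(level) if level not in ("", None) and not (
            isinstance(level, float) and math.isnan(level)
        ) else None
        injections.append(
            SimulatedInjection(
                injection_id=row.injection_id,
                kind=row.kind,
                separation=row.separation,
                traces=traces,
                truth=truth_by_injection.get(row.injection_id, []),
                level_um=level_um,
                sample_id=row.sample_id or None,
            )
        )

    preps: dict[str, SamplePrep] = {}
    samples_path = src / "samples.csv"
    if samples_path.exists():
        for row in pd.read_csv(samples_path, keep_default_na=False).itertuples():
            preps[row.sample_id] = SamplePrep(
                cell_count=float(row.cell_count),
                per_cell_volume_fl=float(row.per_cell_volume_fl),
                dry_pellet_mass_mg=float(row.dry_mass_mg),
                od260_initial=float(row.od260),
                sample_id=row.sample_id,
                notes=str(row.notes),
            )
    return Dataset(injections=injections, preps=preps)
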