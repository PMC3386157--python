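"""Readers and writers for the package's plain-text dialects.

Time courses and sensorgrams travel as CSV (pandas), sequences as FASTA
(Biopython), fit reports as JSON, and region definitions as small YAML/JSON
maps.  A time-course CSV declares its time unit in a ``# unit=`` comment
line above the header.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cycle import Sensorgram, TimeCourse
from .errors import ValidationError
from .fitting import FitResult
from .profiles import GAlphaProfile
from .seqdet import ProteinRecord

__all__ = [
    "write_timecourses",
    "read_timecourses",
    "write_sensorgrams",
    "read_sensorgrams",
    "read_protein_fasta",
    "write_fasta",
    "read_region_config",
    "write_fit_report",
    "write_profile_table",
]


def write_timecourses(path, tcs: Sequence[TimeCourse], unit: str = "min") -> None:
    """Write replicate traces as one CSV: columns time, value, replicate."""
    rows = []
    for i, tc in enumerate(tcs):
        rep = tc.meta.get("replicate", i)
        for t, v in zip(tc.times, tc.values):
            rows.append((t, v, rep))
    df = pd.DataFrame(rows, columns=["time", "value", "replicate"])
    with open(path, "w") as fh:
        fh.write(f"# unit={unit}\n")
        df.to_csv(fh, index=False)


def read_timecourses(path, assay_kind: str) -> list[TimeCourse]:
    """Read a time-course CSV back into one TimeCourse per replicate."""
    path = Path(path)
    unit = "min"
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("#"):
        skip = 1
        if "unit=" in first:
            unit = first.split("unit=")[1].strip()
    df = pd.read_csv(path, skiprows=skip)
    if df.empty:
        raise ValidationError(f"{path} contains no data rows")
    for col in ("time", "value", "replicate"):
        if col not in df.columns:
            raise ValidationError(f"{path} is missing required column {col!r}")
    out = []
    for rep, grp in df.groupby("replicate", sort=True):
        grp = grp.sort_values("time")
        out.append(
            TimeCourse(
                grp["time"].to_numpy(float),
                grp["value"].to_numpy(float),
                assay_kind,
                {"replicate": rep, "unit": unit, "source": str(path)},
            )
        )
    return out


def write_sensorgrams(path, series: Sequence[Sensorgram]) -> None:
    """Columns: time_s, response_RU, conc_M, phase {assoc, dissoc}."""
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": s.times,
                    "response_RU": s.response,
                    "conc_M": s.conc,
                    "phase": s.phase,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_sensorgrams(path) -> list[Sensorgram]:
    df = pd.read_csv(path)
    for col in ("time_s", "response_RU", "conc_M", "phase"):
        if col not in df.columns:
            raise ValidationError(f"{path} is missing required column {col!r}")
    if df.empty:
        raise ValidationError(f"{path} contains no data rows")
    out = []
    for conc, grp in df.groupby("conc_M", sort=True):
        grp = grp.sort_values("time_s")
        assoc = grp[grp["phase"] == "assoc"]
        t_assoc = float(assoc["time_s"].max()) if len(assoc) else 0.0
        out.append(
            Sensorgram(
                grp["time_s"].to_numpy(float),
                grp["response_RU"].to_numpy(float),
                float(conc),
                t_assoc,
            )
        )
    return out


def read_protein_fasta(path) -> list[ProteinRecord]:
    records = [
        ProteinRecord(id=rec.id, sequence=str(rec.seq)) for rec in SeqIO.parse(path, "fasta")
    ]
    if not records:
        raise ValidationError(f"{path} contains no FASTA records")
    return records


def write_fasta(path, records: dict[str, str] | Sequence[ProteinRecord]) -> None:
    if isinstance(records, dict):
        seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    else:
        seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, path, "fasta")


def read_region_config(path) -> dict[str, tuple[int, int]]:
    """Region map {name: [start_codon, end_codon]} from YAML or JSON (1-based, inclusive)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a JSON superset
    if not isinstance(data, dict) or not data:
        raise ValidationError(f"{path}: expected a mapping of region name -> [start, end]")
    out = {}
    for name, bounds in data.items():
        if not (isinstance(bounds, (list, tuple)) and len(bounds) == 2):
            raise ValidationError(f"{path}: region {name!r} must map to [start, end]")
        out[str(name)] = (int(bounds[0]), int(bounds[1]))
    return out


def write_fit_report(path, assay: str, fit: FitResult) -> None:
    payload = {"assay": assay, **fit.to_dict()}
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable) + "\n")


def write_profile_table(path, profiles: Sequence[GAlphaProfile], fmt: str = "csv") -> None:
    rows = [p.to_dict() for p in profiles]
    columns = [
        "name", "k_obs_binding", "k_obs_fluorescence", "k_cat", "rate_limiting",
        "pct_gtp_bound", "activation_class", "self_inactivating", "kd_rgs",
        "gap_fold", "rgs_stimulated",
    ]
    df = pd.DataFrame(rows, columns=columns)
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "json":
        Path(path).write_text(df.to_json(orient="records", indent=2) + "\n")
    else:
        raise ValidationError(f"unknown profile table format {fmt!r}")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
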