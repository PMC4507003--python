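"""Delimited-text readers and writers for the pipeline's tables.

Trajectory files carry columns ``track_id,frame,t_s,x_um,y_um[,bound_truth]``
(0-based frame index, header required).  Parameter configs are flat
``key = value`` text; genomes are FASTA.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mobility import BindingEvent
from .protocols import ImagingProtocol
from .simulate import Trajectory
from .survival import SurvivalCurve

TRAJECTORY_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um"]


def write_trajectories(trajs: Iterable[Trajectory], path: str | Path) -> None:
    frames = [t.to_dataframe() for t in trajs]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trajectories(path: str | Path, protocol: Optional[ImagingProtocol] = None) -> list[Trajectory]:
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory file missing columns: {missing}")
    out = []
    for tid, grp in df.groupby("track_id", sort=False):
        grp = grp.sort_values("frame")
        truth = grp["bound_truth"].to_numpy().astype(bool) if "bound_truth" in df.columns else None
        out.append(
            Trajectory(
                track_id=tid,
                frame_index=grp["frame"].to_numpy(),
                t_s=grp["t_s"].to_numpy(),
                x_um=grp["x_um"].to_numpy(),
                y_um=grp["y_um"].to_numpy(),
                protocol=protocol,
                bound_truth=truth,
            )
        )
    return out


def events_to_frame(events: Sequence[BindingEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "track_id": [e.track_id for e in events],
            "start_s": [e.start_s for e in events],
            "duration_s": [e.duration_s for e in events],
            "censored": [int(e.censored) for e in events],
            "protocol": [e.protocol for e in events],
        }
    )


def write_events(events: Sequence[BindingEvent], path: str | Path) -> None:
    events_to_frame(events).to_csv(path, index=False)


def read_events(path: str | Path) -> list[BindingEvent]:
    df = pd.read_csv(path)
    return [
        BindingEvent(
            track_id=row.track_id,
            start_s=float(row.start_s),
            duration_s=float(row.duration_s),
            censored=bool(row.censored),
            protocol=str(row.protocol) if not pd.isna(row.protocol) else "",
        )
        for row in df.itertuples()
    ]


def write_survival(curves: Sequence[SurvivalCurve], path: str | Path) -> None:
    rows = []
    for c in curves:
        for t, s in zip(c.times_s, c.sp):
            rows.append({"time_s": t, "sp": s, "protocol": c.protocol, "scale": c.scale})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_config(path: str | Path) -> dict:
    """Flat ``key = value`` config; '#' starts a comment; numbers parsed."""
    out: dict[str, object] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        try:
            out[key] = int(val)
        except ValueError:
            try:
                out[key] = float(val)
            except ValueError:
                out[key] = val
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_hits_bed(hits, motif_len: int, path: str | Path) -> None:
    """Motif hits as BED-like text: chrom, start, end, strand, match_len, mismatches."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\tmatch_len\tmismatches\n")
        for h in hits:
            fh.write(f"{h.chrom}\t{h.start}\t{h.start + motif_len}\t{h.strand}\t{h.match_len}\t{h.mismatches}\n")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
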