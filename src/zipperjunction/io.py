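"""Plain-text readers and writers for traces, sweeps and trajectories.

Traces and sweeps are two-column delimited text with a '#'-prefixed JSON
metadata header; ensembles live one file per record in a directory next to
a ``manifest.json``. Sequences use FASTA, trajectories tab-separated tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import ConductanceTrace, IVSweep
from .zipper_sim import Trajectory

__all__ = [
    "write_trace", "read_trace", "write_trace_ensemble", "read_trace_ensemble",
    "write_iv_sweep", "read_iv_sweep", "write_iv_ensemble", "read_iv_ensemble",
    "write_fasta", "read_fasta", "write_trajectory", "read_trajectory",
]


def _write_two_column(path, meta: dict, header: str, a, b) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# " + json.dumps(meta) + "\n")
        fh.write("# " + header + "\n")
        np.savetxt(fh, np.column_stack([a, b]), fmt="%.10g", delimiter="\t")


def _read_two_column(path) -> tuple[dict, np.ndarray, np.ndarray]:
    path = Path(path)
    meta: dict = {}
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("#"):
            try:
                meta = json.loads(first.lstrip("#").strip())
            except json.JSONDecodeError:
                meta = {}
    data = np.loadtxt(path, comments="#")
    if data.ndim == 1:
        data = data.reshape(1, -1)
    return meta, data[:, 0], data[:, 1]


def write_trace(trace: ConductanceTrace, path) -> None:
    _write_two_column(path, trace.meta, "displacement_nm\tconductance_G0",
                      trace.displacement, trace.conductance)


def read_trace(path) -> ConductanceTrace:
    meta, z, g = _read_two_column(path)
    return ConductanceTrace(z, g, meta)


def write_trace_ensemble(ensemble: list[ConductanceTrace], directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for i, tr in enumerate(ensemble):
        name = f"trace_{i:05d}.tsv"
        write_trace(tr, directory / name)
        names.append(name)
    (directory / "manifest.json").write_text(
        json.dumps({"kind": "trace_ensemble", "n": len(names), "files": names},
                   indent=1))


def read_trace_ensemble(directory) -> list[ConductanceTrace]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    return [read_trace(directory / name) for name in manifest["files"]]


def write_iv_sweep(sweep: IVSweep, path) -> None:
    _write_two_column(path, sweep.meta, "bias_V\tcurrent_A",
                      sweep.bias, sweep.current)


def read_iv_sweep(path) -> IVSweep:
    meta, v, i = _read_two_column(path)
    return IVSweep(v, i, meta)


def write_iv_ensemble(sweeps: list[IVSweep], directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for i, sw in enumerate(sweeps):
        name = f"iv_{i:05d}.tsv"
        write_iv_sweep(sw, directory / name)
        names.append(name)
    (directory / "manifest.json").write_text(
        json.dumps({"kind": "iv_ensemble", "n": len(names), "files": names},
                   indent=1))


def read_iv_ensemble(directory) -> list[IVSweep]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    return [read_iv_sweep(directory / name) for name in manifest["files"]]


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_trajectory(traj: Trajectory, path) -> None:
    df = pd.DataFrame({
        "time_s": traj.time,
        "z_tip_nm": traj.z_tip,
        "n_open": traj.n_open,
        "force_pN": traj.force,
    })
    if traj.pair_state is not None:
        df["pair_state"] = traj.pair_state
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# " + json.dumps({"n_bp": traj.n_bp,
                                    "termination": traj.termination,
                                    **traj.meta}) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_trajectory(path) -> Trajectory:
    path = Path(path)
    with path.open() as fh:
        meta = json.loads(fh.readline().lstrip("#").strip())
    df = pd.read_csv(path, sep="\t", comment="#")
    return Trajectory(
        time=df["time_s"].to_numpy(), z_tip=df["z_tip_nm"].to_numpy(),
        n_open=df["n_open"].to_numpy(), force=df["force_pN"].to_numpy(),
        n_bp=int(meta.pop("n_bp")), termination=meta.pop("termination"),
        pair_state=(df["pair_state"].tolist() if "pair_state" in df else None),
        meta=meta,
    )
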