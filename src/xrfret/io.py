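"""Readers and writers for the package's on-disk formats.

Traces travel as TSV (columns: trace_id, frame, time_s, I_donor,
I_acceptor and optionally truth_state) or as an HDF5 bundle; movies as
multi-page TIFF; scattering curves as 3-column whitespace ``.dat``
(q, I, sigma); plate-reader decay data as a wide CSV plus a well-map
JSON.  Every writer emits a JSON sidecar carrying the generator or
analysis parameters and the seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .trace import DecayTrace, FretTrace, ScatteringCurve


def write_sidecar(path, params: dict, seed=None) -> Path:
    side = Path(str(path) + ".json")
    payload = {"parameters": params, "seed": seed}
    side.write_text(json.dumps(payload, indent=2, default=_jsonify))
    return side


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if hasattr(obj, "__dict__"):
        return {k: v for k, v in vars(obj).items() if not k.startswith("_")}
    return str(obj)


def traces_to_frame(traces) -> pd.DataFrame:
    rows = []
    for tr in traces:
        df = pd.DataFrame(
            {
                "trace_id": tr.trace_id,
                "frame": np.arange(tr.n_frames),
                "time_s": tr.time,
                "I_donor": tr.donor,
                "I_acceptor": tr.acceptor,
            }
        )
        if tr.truth_state is not None:
            df["truth_state"] = tr.truth_state
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def write_traces_tsv(traces, path, params: dict | None = None, seed=None) -> Path:
    path = Path(path)
    traces_to_frame(traces).to_csv(path, sep="\t", index=False)
    write_sidecar(path, params or {}, seed)
    return path


def read_traces_tsv(path) -> list[FretTrace]:
    df = pd.read_csv(path, sep="\t")
    traces = []
    for tid, g in df.groupby("trace_id", sort=False):
        g = g.sort_values("frame")
        t = g["time_s"].to_numpy()
        dt = float(t[1] - t[0]) if len(t) > 1 else 0.025
        traces.append(
            FretTrace(
                time=t,
                donor=g["I_donor"].to_numpy(),
                acceptor=g["I_acceptor"].to_numpy(),
                frame_interval=dt,
                trace_id=str(tid),
                truth_state=(
                    g["truth_state"].to_numpy() if "truth_state" in g else None
                ),
            )
        )
    return traces


def write_trace_bundle_h5(dataset, path, seed=None) -> Path:
    """HDF5 bundle of a titration dataset (one group per condition)."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["seed"] = -1 if seed is None else seed
        for cond in dataset:
            g = f.create_group(f"mg_{cond.mg_mM:g}")
            g.attrs["mg_mM"] = cond.mg_mM
            for key, val in cond.truth_rates.as_dict().items():
                g.attrs[key] = val
            for tr in cond.traces:
                tg = g.create_group(tr.trace_id)
                tg.create_dataset("time_s", data=tr.time)
                tg.create_dataset("I_donor", data=tr.donor)
                tg.create_dataset("I_acceptor", data=tr.acceptor)
                tg.attrs["frame_interval"] = tr.frame_interval
                if tr.truth_state is not None:
                    tg.create_dataset("truth_state", data=tr.truth_state)
    return path


def read_trace_bundle_h5(path):
    """Read back a bundle as {mg_mM: (traces, truth_rates_dict)}."""
    import h5py

    out = {}
    with h5py.File(path, "r") as f:
        for name in f:
            g = f[name]
            mg = float(g.attrs["mg_mM"])
            rates = {k: float(v) for k, v in g.attrs.items() if k.startswith("k_")}
            traces = []
            for tid in g:
                tg = g[tid]
                traces.append(
                    FretTrace(
                        time=tg["time_s"][:],
                        donor=tg["I_donor"][:],
                        acceptor=tg["I_acceptor"][:],
                        frame_interval=float(tg.attrs["frame_interval"]),
                        trace_id=tid,
                        truth_state=(
                            tg["truth_state"][:] if "truth_state" in tg else None
                        ),
                    )
                )
            out[mg] = (traces, rates)
    return out


def write_movie_tiff(movie, path_donor, path_acceptor) -> tuple[Path, Path]:
    import tifffile

    tifffile.imwrite(path_donor, movie.donor.astype(np.float32))
    tifffile.imwrite(path_acceptor, movie.acceptor.astype(np.float32))
    return Path(path_donor), Path(path_acceptor)


def read_movie_tiff(path) -> np.ndarray:
    import tifffile

    stack = tifffile.imread(path)
    return stack[None] if stack.ndim == 2 else stack


def write_scattering_dat(curve: ScatteringCurve, path) -> Path:
    path = Path(path)
    sigma = curve.sigma if curve.sigma is not None else np.zeros_like(curve.q)
    np.savetxt(path, np.column_stack([curve.q, curve.intensity, sigma]),
               header="q I sigma")
    return path


def read_scattering_dat(path) -> ScatteringCurve:
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("expected a whitespace table with columns q, I[, sigma]")
    sigma = data[:, 2] if data.shape[1] >= 3 and np.any(data[:, 2] > 0) else None
    return ScatteringCurve(q=data[:, 0], intensity=data[:, 1], sigma=sigma)


def read_plate_csv(csv_path, well_map_path) -> list[DecayTrace]:
    """Plate-reader CSV (column ``time_min`` + one column per well) and a
    well-map JSON assigning each well a construct, Mg2+ and +/-Xrn1 role.

    Wells are paired by (construct, mg_mM): the ``+Xrn1`` well becomes
    the experimental channel, the ``-Xrn1`` well the control.
    """
    df = pd.read_csv(csv_path)
    well_map = json.loads(Path(well_map_path).read_text())
    groups: dict[tuple, dict] = {}
    for well, meta in well_map.items():
        key = (meta["construct"], float(meta["mg_mM"]))
        groups.setdefault(key, {})[meta["xrn1"]] = well
    traces = []
    for (construct, mg), wells in sorted(groups.items()):
        if "+" not in wells or "-" not in wells:
            raise ValueError(f"condition {construct}@{mg} mM lacks a +/- Xrn1 pair")
        traces.append(
            DecayTrace(
                time_min=df["time_min"].to_numpy(),
                f_exp=df[wells["+"]].to_numpy(),
                f_con=df[wells["-"]].to_numpy(),
                condition={"construct": construct, "mg_mM": mg},
            )
        )
    return traces
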