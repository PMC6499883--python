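"""Readers and writers: spectrum CSV, JCAMP-DX, FID containers, matrices.

Every writer has a matching reader and all containers round-trip.  Complex
time-domain data go into a small npz container with a JSON parameter
header; spectra export as two-column CSV and as JCAMP-DX (XYDATA,
``(X++(Y..Y))`` AFFN encoding, 6 significant digits).
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

from .acquisition import AcquisitionParams, Fid, Interferogram, PureShiftParams
from .preprocessing import SpectralMatrix
from .reconstruction import Spectrum

# ---------------------------------------------------------------------------
# Spectrum CSV


def write_spectrum_csv(sp: Spectrum, path) -> None:
    pd.DataFrame({"ppm": sp.ppm, "intensity": sp.intensity}).to_csv(path, index=False)


def read_spectrum_csv(path, field_mhz: float, carrier_ppm: float,
                      sample_id: str = "", mode: str = "") -> Spectrum:
    df = pd.read_csv(path)
    return Spectrum(df["ppm"].to_numpy(), df["intensity"].to_numpy(),
                    field_mhz, carrier_ppm, sample_id, mode)


# ---------------------------------------------------------------------------
# JCAMP-DX (XYDATA, fixed-point AFFN, 6 significant digits)


def write_jcamp(sp: Spectrum, path, title: str = "pureshift spectrum") -> None:
    y = sp.intensity
    first_x, last_x = float(sp.ppm[0]), float(sp.ppm[-1])
    lines = [
        "##TITLE=" + title,
        "##JCAMP-DX=5.00",
        "##DATA TYPE=NMR SPECTRUM",
        "##XUNITS=PPM",
        "##YUNITS=ARBITRARY",
        f"##NPOINTS={y.size}",
        f"##FIRSTX={first_x:.6g}",
        f"##LASTX={last_x:.6g}",
        "##XFACTOR=1.0",
        "##YFACTOR=1.0",
        f"##.OBSERVE FREQUENCY={sp.field_mhz:.6g}",
        f"##$CARRIER PPM={sp.carrier_ppm:.6g}",
        "##XYDATA=(X++(Y..Y))",
    ]
    per_line = 6
    for i in range(0, y.size, per_line):
        chunk = y[i:i + per_line]
        lines.append(" ".join([f"{sp.ppm[i]:.6g}"] + [f"{v:.6g}" for v in chunk]))
    lines.append("##END=")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_jcamp(path) -> Spectrum:
    meta: dict[str, str] = {}
    ys: list[float] = []
    in_data = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("##"):
                if line.startswith("##XYDATA"):
                    in_data = True
                    continue
                if line.startswith("##END"):
                    break
                key, _, val = line[2:].partition("=")
                meta[key.strip()] = val.strip()
                in_data = False
                continue
            if in_data:
                parts = line.split()
                ys.extend(float(v) for v in parts[1:])  # first token is X
    n = int(meta["NPOINTS"])
    if len(ys) != n:
        raise ValueError(f"JCAMP file declares {n} points but contains {len(ys)}")
    first_x, last_x = float(meta["FIRSTX"]), float(meta["LASTX"])
    ppm = np.linspace(first_x, last_x, n)
    return Spectrum(ppm, np.array(ys), float(meta.get(".OBSERVE FREQUENCY", 500.0)),
                    float(meta.get("$CARRIER PPM", 4.7)))


# ---------------------------------------------------------------------------
# Complex time-domain containers (npz + JSON header)


def _params_header(acq: AcquisitionParams, ps: PureShiftParams | None = None) -> str:
    head = {"acquisition": dataclasses.asdict(acq)}
    if ps is not None:
        head["pure_shift"] = dataclasses.asdict(ps)
    return json.dumps(head, sort_keys=True)


def save_fids(fids: dict[str, Fid], path) -> None:
    if not fids:
        raise ValueError("no FIDs to save")
    acq = next(iter(fids.values())).params
    arrays = {f"fid_{sid}": f.data for sid, f in fids.items()}
    np.savez(path, header=np.array(_params_header(acq)),
             sample_ids=np.array(list(fids)), **arrays)


def load_fids(path) -> dict[str, Fid]:
    with np.load(path, allow_pickle=False) as z:
        head = json.loads(str(z["header"]))
        acq = AcquisitionParams(**head["acquisition"])
        return {sid: Fid(z[f"fid_{sid}"], acq, sid) for sid in z["sample_ids"]}


def save_interferograms(igs: dict[str, Interferogram], path) -> None:
    if not igs:
        raise ValueError("no interferograms to save")
    first = next(iter(igs.values()))
    arrays = {f"ig_{sid}": ig.data for sid, ig in igs.items()}
    np.savez(path, header=np.array(_params_header(first.acq, first.ps)),
             sample_ids=np.array(list(igs)), **arrays)


def load_interferograms(path) -> dict[str, Interferogram]:
    with np.load(path, allow_pickle=False) as z:
        head = json.loads(str(z["header"]))
        acq = AcquisitionParams(**head["acquisition"])
        ps = PureShiftParams(**head["pure_shift"])
        return {sid: Interferogram(z[f"ig_{sid}"], acq, ps, sid)
                for sid in z["sample_ids"]}


# ---------------------------------------------------------------------------
# Spectral matrix: CSV + JSON sidecar


def save_matrix(m: SpectralMatrix, csv_path, sidecar_path) -> None:
    df = pd.DataFrame(m.X, index=pd.Index(m.sample_ids, name="sample"))
    df.to_csv(csv_path)
    with open(sidecar_path, "w") as fh:
        json.dump({
            "ppm": m.ppm.tolist(),
            "groups": list(m.group_labels),
            "excluded_regions": [list(r) for r in m.excluded_regions],
            "normalized": m.normalized,
        }, fh)


def load_matrix(csv_path, sidecar_path) -> SpectralMatrix:
    df = pd.read_csv(csv_path, index_col="sample")
    with open(sidecar_path) as fh:
        side = json.load(fh)
    return SpectralMatrix(df.to_numpy(), np.array(side["ppm"]), list(df.index),
                          list(side["groups"]),
                          [tuple(r) for r in side["excluded_regions"]],
                          side["normalized"])
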