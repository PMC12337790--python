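"""Tabular and image IO: clone tables, apoptosis tables, recoil traces.

CSV files written by the pipeline carry a short comment header
(``# key=value``) with the tool version, seed and config hash so any
output can be traced back to its run; readers skip those lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .recoil import RecoilTrace


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:12]


def write_csv(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_csv_meta(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("# "):
                break
            k, _, v = line[2:].strip().partition("=")
            meta[k] = v
    return meta


# ----------------------------------------------------------------------
# Clone-membership table: cell_id, group ∈ {control, clone}, genotype
# ----------------------------------------------------------------------

def write_clone_table(path, clonal_ids, all_ids, genotype: str = "control") -> None:
    clonal = set(clonal_ids)
    df = pd.DataFrame(
        {
            "cell_id": sorted(all_ids),
            "group": ["clone" if c in clonal else "control" for c in sorted(all_ids)],
            "genotype": genotype,
        }
    )
    write_csv(df, path)


def read_clone_table(path) -> tuple[set[int], pd.DataFrame]:
    df = read_csv(path)
    clonal = set(df.loc[df["group"] == "clone", "cell_id"].astype(int))
    return clonal, df


# ----------------------------------------------------------------------
# Apoptosis table: cell_id, apoptotic, debris
# ----------------------------------------------------------------------

def write_apoptosis_table(path, apoptotic_ids, all_ids, debris_ids=()) -> None:
    apo, deb = set(apoptotic_ids), set(debris_ids)
    df = pd.DataFrame(
        {
            "cell_id": sorted(all_ids),
            "apoptotic": [c in apo for c in sorted(all_ids)],
            "debris": [c in deb for c in sorted(all_ids)],
        }
    )
    write_csv(df, path)


def read_apoptosis_table(path) -> set[int]:
    df = read_csv(path)
    keep = df["apoptotic"] & ~df.get("debris", False)
    return set(df.loc[keep, "cell_id"].astype(int))


# ----------------------------------------------------------------------
# Recoil traces: columns time_s, distance_um; header keys t0_s, lc_um
# ----------------------------------------------------------------------

def write_recoil_trace(path, trace: RecoilTrace, meta: dict | None = None) -> None:
    df = pd.DataFrame({"time_s": trace.times, "distance_um": trace.distances})
    m = {"t0_s": trace.t0, "lc_um": trace.lc}
    m.update(meta or {})
    write_csv(df, path, meta=m)


def read_recoil_trace(path) -> RecoilTrace:
    meta = read_csv_meta(path)
    df = read_csv(path)
    return RecoilTrace(
        times=df["time_s"].to_numpy(),
        distances=df["distance_um"].to_numpy(),
        t0=float(meta["t0_s"]),
        lc=float(meta["lc_um"]),
    )


def write_tiff(path, image: np.ndarray) -> None:
    import tifffile

    tifffile.imwrite(path, image)


def read_tiff(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)
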