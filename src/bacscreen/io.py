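"""Plain-text I/O: TSV pool manifests and results, CSV melt curves,
FASTA/plain-text primers, YAML simulator configs."""

from __future__ import annotations

import io as _io
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from bacscreen.decoder import Call, DecodedCandidate, PoolResult, StageResults
from bacscreen.melt_hrm import MeltCurve, MeltGrid
from bacscreen.pooling_design import PoolManifest
from bacscreen.simulator import SimConfig

__all__ = [
    "write_manifests",
    "read_manifests",
    "write_pool_results",
    "read_pool_results",
    "read_stage_results",
    "write_anchoring_report",
    "write_melt_curve",
    "read_melt_curve",
    "read_primers",
    "load_sim_config",
]

MANIFEST_COLUMNS = ["pool_id", "tier", "member", "volume_ul"]
RESULT_COLUMNS = ["pool_id", "marker_id", "call", "parent"]


def write_manifests(manifests: list[PoolManifest], path: str | Path) -> None:
    rows = [
        {"pool_id": m.pool_id, "tier": m.tier, "member": member, "volume_ul": vol}
        for m in manifests
        for member, vol in zip(m.members, m.volumes_ul)
    ]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


def read_manifests(path: str | Path) -> list[PoolManifest]:
    df = pd.read_csv(path, sep="\t", dtype={"member": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest TSV missing columns {sorted(missing)}")
    out = []
    for (pool_id, tier), grp in df.groupby(["pool_id", "tier"], sort=False):
        out.append(
            PoolManifest(
                pool_id=str(pool_id),
                tier=str(tier),
                members=tuple(grp["member"]),
                volumes_ul=tuple(grp["volume_ul"].astype(float)),
            )
        )
    return out


def write_pool_results(
    results: list[PoolResult], path: str | Path,
    parents: list[int | None] | None = None,
) -> None:
    parents = parents or [None] * len(results)
    rows = [
        {"pool_id": r.pool_id, "marker_id": r.marker_id,
         "call": r.call.value, "parent": "" if p is None else p}
        for r, p in zip(results, parents)
    ]
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(path, sep="\t", index=False)


def _parse_call(text: str, line: int) -> Call:
    t = str(text).strip().lower()
    if t in ("positive", "pos", "+", "1", "true"):
        return Call.POSITIVE
    if t in ("negative", "neg", "-", "0", "false"):
        return Call.NEGATIVE
    raise ValueError(f"line {line}: unrecognized call {text!r}")


def read_pool_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"pool_id", "marker_id", "call"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"results TSV missing columns {sorted(missing)}")
    df["call"] = [
        _parse_call(c, i + 2) for i, c in enumerate(df["call"])
    ]
    if "parent" not in df.columns:
        df["parent"] = None
    return df


def read_stage_results(path: str | Path) -> dict[str, StageResults]:
    """Group a results TSV into per-marker stage results.

    Pool IDs carry the tier: ``SP#`` superpool, ``H#``/``V#`` matrix
    (``parent`` = superpool ID, default 1), ``R#``/``C#`` single-plate
    (``parent`` = plate ID, required).
    """
    df = read_pool_results(path)
    out: dict[str, StageResults] = {}
    for i, row in df.iterrows():
        m = str(row["marker_id"])
        sr = out.setdefault(m, StageResults(marker_id=m))
        pr = PoolResult(str(row["pool_id"]), m, row["call"])
        pid = str(row["pool_id"])
        parent = row["parent"]
        has_parent = parent not in (None, "") and not pd.isna(parent)
        if pid.startswith("SP"):
            sr.superpool.append(pr)
        elif pid[0] in "HV":
            sp = int(parent) if has_parent else 1
            sr.matrix.setdefault(sp, []).append(pr)
        elif pid[0] in "RC":
            if not has_parent:
                raise ValueError(
                    f"line {i + 2}: single-plate pool {pid} needs a 'parent' "
                    "plate ID"
                )
            sr.plate.setdefault(int(parent), []).append(pr)
        else:
            raise ValueError(f"line {i + 2}: unrecognized pool ID {pid!r}")
    return out


def write_anchoring_report(
    decoded: dict[str, DecodedCandidate], path: str | Path
) -> None:
    """Marker -> clone address table (marker_id, plate, row, column, status)."""
    rows = []
    for m, dec in decoded.items():
        if not dec.candidates:
            rows.append({"marker_id": m, "plate": "", "row": "", "column": "",
                         "status": dec.status.value})
        for addr in dec.candidates:
            rows.append({
                "marker_id": m,
                "plate": "" if addr.plate is None else addr.plate,
                "row": addr.row,
                "column": addr.column,
                "status": dec.status.value,
            })
    pd.DataFrame(rows, columns=["marker_id", "plate", "row", "column", "status"]
                 ).to_csv(path, sep="\t", index=False)


def write_melt_curve(curve: MeltCurve, path: str | Path) -> None:
    pd.DataFrame({
        "temperature_C": curve.grid.temperatures,
        "fluorescence": curve.fluorescence,
    }).to_csv(path, index=False)


def read_melt_curve(path: str | Path) -> MeltCurve:
    df = pd.read_csv(path)
    missing = {"temperature_C", "fluorescence"} - set(df.columns)
    if missing:
        raise ValueError(f"melt CSV missing columns {sorted(missing)}")
    t = df["temperature_C"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("melt CSV needs at least 2 points")
    step = float(t[1] - t[0])
    grid = MeltGrid(t_start=float(t[0]), t_end=float(t[-1]) + step / 2, step=step)
    if grid.n_points != len(t):
        grid = MeltGrid(t_start=float(t[0]),
                        t_end=float(t[0]) + step * (len(t) - 1) + step / 2,
                        step=step)
    return MeltCurve(grid=grid, fluorescence=df["fluorescence"].to_numpy(float))


def read_primers(path: str | Path) -> dict[str, str]:
    """Primers from FASTA, or one sequence per line (optionally ``name<TAB>seq``)."""
    text = Path(path).read_text()
    if text.lstrip().startswith(">"):
        return {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(_io.StringIO(text), "fasta")
        }
    primers: dict[str, str] = {}
    for i, line in enumerate(text.splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) == 1:
            primers[f"primer{i + 1}"] = parts[0].upper()
        else:
            primers[parts[0]] = parts[1].upper()
    return primers


def load_sim_config(path: str | Path) -> SimConfig:
    """Simulator config from YAML; keys are the SimConfig fields."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "marker_positions" in data and data["marker_positions"] is not None:
        data["marker_positions"] = tuple(int(p) for p in data["marker_positions"])
    known = set(SimConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown simulator config keys {sorted(unknown)}")
    if "coverage" in data and "n_clones" in data:
        pass  # SimConfig validates mutual exclusion
    elif "n_clones" in data:
        data.setdefault("coverage", None)
    return SimConfig(**data)


def sim_config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    if d.get("marker_positions") is not None:
        d["marker_positions"] = list(d["marker_positions"])
    return d
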