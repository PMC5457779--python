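"""Plain-text serialization: model files, time-course TSV, front JSON, network CSV."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import SSystem, Trajectory

__all__ = [
    "write_model",
    "read_model",
    "write_timecourse",
    "read_timecourse",
    "write_front",
    "read_front",
    "write_network_csv",
    "read_network_csv",
]

_FMT = "%.17g"  # round-trips float64 exactly


def _fmt_vec(v) -> str:
    return "\t".join(_FMT % x for x in np.atleast_1d(v))


def write_model(model: SSystem, path) -> None:
    """Write a model as a flat key-value text file (N, alpha, beta, G/H rows, fixed_vars)."""
    lines = [f"n_dep\t{model.n_dep}"]
    lines.append("alpha\t" + _fmt_vec(model.alpha))
    lines.append("beta\t" + _fmt_vec(model.beta))
    for i in range(model.n_dep):
        lines.append(f"G{i + 1}\t" + _fmt_vec(model.G[i]))
    for i in range(model.n_dep):
        lines.append(f"H{i + 1}\t" + _fmt_vec(model.H[i]))
    if model.fixed_vars.size:
        lines.append("fixed_vars\t" + _fmt_vec(model.fixed_vars))
    Path(path).write_text("\n".join(lines) + "\n")


def read_model(path) -> SSystem:
    kv = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, *vals = line.split("\t")
        kv[key] = vals
    n = int(kv["n_dep"][0])
    alpha = np.array(kv["alpha"], dtype=float)
    beta = np.array(kv["beta"], dtype=float)
    G = np.array([kv[f"G{i + 1}"] for i in range(n)], dtype=float)
    H = np.array([kv[f"H{i + 1}"] for i in range(n)], dtype=float)
    fixed = np.array(kv.get("fixed_vars", []), dtype=float)
    return SSystem(alpha=alpha, beta=beta, G=G, H=H, fixed_vars=fixed)


def write_timecourse(trajectories: list[Trajectory], path) -> None:
    """Write trajectories as TSV with columns ``condition  time  X1 .. XN``."""
    n = trajectories[0].n_components
    header = "condition\ttime\t" + "\t".join(f"X{j + 1}" for j in range(n))
    rows = [header]
    for traj in trajectories:
        for t, x in zip(traj.times, traj.values):
            rows.append(f"{traj.condition_id}\t" + (_FMT % t) + "\t" + _fmt_vec(x))
    Path(path).write_text("\n".join(rows) + "\n")


def read_timecourse(path) -> list[Trajectory]:
    df = pd.read_csv(path, sep="\t", dtype={"condition": str}, float_precision="round_trip")
    xcols = [c for c in df.columns if c.startswith("X")]
    out = []
    for cond, grp in df.groupby("condition", sort=False):
        out.append(
            Trajectory(
                times=grp["time"].to_numpy(),
                values=grp[xcols].to_numpy(),
                condition_id=str(cond),
            )
        )
    return out


def write_front(front, path) -> None:
    """Serialize a per-equation nondominated front to JSON."""
    payload = {
        "eq_index": front.eq_index,
        "solutions": [
            {
                "bx": "".join(str(int(b)) for b in sol.bx),
                "rx": [float(v) for v in sol.rx],
                "err": float(sol.err),
                "l0": int(sol.l0),
            }
            for sol in front.solutions
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_front(path):
    from .objectives import Front, MixedSolution

    payload = json.loads(Path(path).read_text())
    sols = [
        MixedSolution(
            bx=np.array([int(c) for c in d["bx"]], dtype=np.uint8),
            rx=np.array(d["rx"], dtype=float),
            err=float(d["err"]),
            l0=int(d["l0"]),
            eq_index=int(payload["eq_index"]),
        )
        for d in payload["solutions"]
    ]
    return Front(eq_index=int(payload["eq_index"]), solutions=tuple(sols))


def network_frame(model: SSystem) -> pd.DataFrame:
    """Parameter table in the conventional layout: i, alpha, g_i*, beta, h_i*."""
    n = model.n_dep
    cols = (
        ["i", "alpha"]
        + [f"g{j + 1}" for j in range(model.n_vars)]
        + ["beta"]
        + [f"h{j + 1}" for j in range(model.n_vars)]
    )
    rows = [
        [i + 1, model.alpha[i], *model.G[i], model.beta[i], *model.H[i]]
        for i in range(n)
    ]
    return pd.DataFrame(rows, columns=cols)


def write_network_csv(model: SSystem, path) -> None:
    network_frame(model).to_csv(path, index=False, float_format="%.17g")


def read_network_csv(path, fixed_vars=()) -> SSystem:
    df = pd.read_csv(path, float_precision="round_trip")
    gcols = sorted((c for c in df.columns if c.startswith("g")), key=lambda c: int(c[1:]))
    hcols = sorted((c for c in df.columns if c.startswith("h")), key=lambda c: int(c[1:]))
    return SSystem(
        alpha=df["alpha"].to_numpy(),
        beta=df["beta"].to_numpy(),
        G=df[gcols].to_numpy(),
        H=df[hcols].to_numpy(),
        fixed_vars=np.asarray(fixed_vars, dtype=float),
    )
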