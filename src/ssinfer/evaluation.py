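"""Scoring inferred networks against a known ground truth.

Topology is judged *structurally*: a kinetic-order entry is a predicted
connection iff it is nonzero (its bit was set) — no magnitude threshold.
Counts run over the ``2 N^2`` dependent-variable kinetic orders (g and h);
rate constants are always present in the model form and are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SSystem, SimulationError, simulate

__all__ = ["ConfusionCounts", "confusion", "tpr_fpr", "roc_curve", "dynamics_discrepancy"]


@dataclass(frozen=True)
class ConfusionCounts:
    """Connection-level confusion counts; ``sign_tp`` additionally counts
    true positives whose inferred kinetic order has the correct sign
    (reported separately; it does not enter the rates)."""

    tp: int
    fp: int
    tn: int
    fn: int
    sign_tp: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _dep_orders(model: SSystem) -> np.ndarray:
    n = model.n_dep
    return np.vstack([model.G[:, :n], model.H[:, :n]])


def confusion(truth: SSystem, inferred: SSystem) -> ConfusionCounts:
    """Structural confusion counts of ``inferred`` against ``truth``."""
    if truth.n_dep != inferred.n_dep:
        raise ValueError("models must have the same number of dependent components")
    t = _dep_orders(truth)
    p = _dep_orders(inferred)
    tpos = (t != 0) & (p != 0)
    return ConfusionCounts(
        tp=int(tpos.sum()),
        fp=int(((t == 0) & (p != 0)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
        fn=int(((t != 0) & (p == 0)).sum()),
        sign_tp=int((tpos & (np.sign(t) == np.sign(p))).sum()),
    )


def tpr_fpr(c: ConfusionCounts) -> tuple[float, float]:
    """``TPR = TP/(TP+FN)`` and ``FPR = FP/(TN+FP)``, with 0/0 defined as 0."""
    tpr = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    fpr = c.fp / (c.tn + c.fp) if (c.tn + c.fp) else 0.0
    return tpr, fpr


def roc_curve(sweep, truth: SSystem) -> pd.DataFrame:
    """Operating points of the lambda sweep: one (FPR, TPR, lambda) row per
    sweep point, sorted by FPR then TPR, exact duplicates collapsed (the
    lowest lambda of each duplicate group is kept)."""
    rows = []
    for p in sweep:
        tpr, fpr = tpr_fpr(confusion(truth, p.system))
        rows.append((fpr, tpr, p.lam))
    df = pd.DataFrame(rows, columns=["fpr", "tpr", "lam"]).sort_values(
        ["fpr", "tpr", "lam"], kind="stable"
    )
    df = df.drop_duplicates(subset=["fpr", "tpr"], keep="first")
    return df.reset_index(drop=True)


def dynamics_discrepancy(
    truth: SSystem,
    inferred: SSystem,
    x0s: np.ndarray,
    times: np.ndarray,
) -> np.ndarray:
    """Per-component RMSE between the two models' trajectories, averaged
    over initial conditions.  Conditions where either model fails to
    integrate are excluded with a warning."""
    x0s = np.atleast_2d(np.asarray(x0s, dtype=float))
    rmses = []
    for c, x0 in enumerate(x0s):
        try:
            a = simulate(truth, x0, times, condition_id=str(c))
            b = simulate(inferred, x0, times, condition_id=str(c))
        except SimulationError as exc:
            warnings.warn(f"condition {c} excluded from dynamics comparison: {exc}")
            continue
        rmses.append(np.sqrt(np.mean((a.values - b.values) ** 2, axis=0)))
    if not rmses:
        raise SimulationError("no condition could be simulated by both models")
    return np.mean(rmses, axis=0)
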