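"""Evaluation protocols for the ICP forecaster.

Two designs are provided:

* **Random split** — within each patient, 80% of the window anchors train the
  model and 20% test it; class-wise accuracies (specificity: true class-1
  rows predicted 1; sensitivity: true class-2 rows predicted 2) are reported
  per horizon for both the MAP and the alpha-balanced predictions, with
  non-parametric (percentile) bootstrap confidence intervals.
* **Leave-one-patient-out** — the model is fitted on all patients but one and
  evaluated on that patient's full continuous window stream; per-patient
  class-wise accuracies are combined into weighted means, each patient
  weighted by its own proportion of the relevant response class.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import DEFAULT_ALPHA_GRID, ICPForecaster, decide_enhanced
from .preprocess import WindowedDataset, make_windows

__all__ = [
    "EvalReport",
    "split_random",
    "class_accuracies",
    "bootstrap_ci",
    "evaluate_split",
    "loocv",
    "weighted_summary",
]


def split_random(
    data: WindowedDataset, fraction: float = 0.8, seed: int = 0
) -> tuple[WindowedDataset, WindowedDataset]:
    """Split window anchors into train/test within each patient.

    All horizon rows of an anchor travel together, so no future interval ends
    up on both sides of the split. The train share per patient is
    ``round-half-up(fraction * n_anchors)``. Patients with fewer than two
    anchors go entirely to train, with a warning. Deterministic given seed.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    anchors = data.frame[["patient_id", "anchor"]].drop_duplicates()
    train_parts, test_parts = [], []
    for pid, grp in anchors.groupby("patient_id", sort=True):
        a = np.sort(grp["anchor"].to_numpy())
        if a.size < 2:
            warnings.warn(f"patient {pid!r} has < 2 anchors; assigned wholly to train")
            train_parts.append(pd.DataFrame({"patient_id": pid, "anchor": a}))
            continue
        n_train = int(np.floor(fraction * a.size + 0.5))
        n_train = min(max(n_train, 1), a.size - 1)
        perm = rng.permutation(a)
        train_parts.append(pd.DataFrame({"patient_id": pid, "anchor": perm[:n_train]}))
        test_parts.append(pd.DataFrame({"patient_id": pid, "anchor": perm[n_train:]}))
    train_keep = pd.concat(train_parts, ignore_index=True) if train_parts else anchors.iloc[:0]
    test_keep = pd.concat(test_parts, ignore_index=True) if test_parts else anchors.iloc[:0]
    return data.subset_anchors(train_keep), data.subset_anchors(test_keep)


def class_accuracies(predictions: pd.DataFrame, label_col: str) -> pd.DataFrame:
    """Per-horizon specificity/sensitivity from a prediction frame.

    ``predictions`` needs columns ``horizon``, ``y`` (truth) and
    ``label_col``. A horizon with no truths of a class gets ``NaN`` for that
    accuracy and ``defined = False``.
    """
    rows = []
    for k, grp in predictions.groupby("horizon", sort=True):
        y = grp["y"].to_numpy()
        pred = grp[label_col].to_numpy()
        n1, n2 = int((y == 1).sum()), int((y == 2).sum())
        spec = float((pred[y == 1] == 1).mean()) if n1 else np.nan
        sens = float((pred[y == 2] == 2).mean()) if n2 else np.nan
        rows.append(
            {"horizon": int(k), "specificity": spec, "sensitivity": sens,
             "n1": n1, "n2": n2, "defined": bool(n1 and n2)}
        )
    return pd.DataFrame(rows)


def bootstrap_ci(
    correct: np.ndarray, B: int = 1000, level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap CI for a mean of 0/1 correctness indicators.

    Rows are resampled with replacement ``B`` times; the interval is the
    ``(1-level)/2`` and ``(1+level)/2`` empirical quantiles of the resampled
    means. Returns ``(nan, nan)`` on empty input.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    correct = np.asarray(correct, dtype=float)
    n = correct.size
    if n == 0:
        return (np.nan, np.nan)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    means = correct[idx].mean(axis=1)
    lo, hi = np.percentile(means, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return float(lo), float(hi)


@dataclass
class EvalReport:
    """Evaluation results, serializable to JSON and a flat CSV.

    ``per_horizon`` holds one row per horizon × method (map/enhanced) with
    sensitivity, specificity and (for split mode) bootstrap CI bounds.
    ``per_patient`` and ``weighted`` are populated by :func:`loocv`.
    """

    mode: str
    config: dict
    per_horizon: pd.DataFrame
    per_patient: pd.DataFrame | None = None
    weighted: pd.DataFrame | None = None

    def to_flat(self) -> pd.DataFrame:
        """One row per horizon × class × method with accuracy and CI bounds."""
        rows = []
        for _, r in self.per_horizon.iterrows():
            for cls, acc in (("1", "specificity"), ("2", "sensitivity")):
                rows.append(
                    {
                        "horizon": int(r["horizon"]),
                        "method": r["method"],
                        "true_class": cls,
                        "accuracy": r[acc],
                        "ci_lo": r.get(f"{acc}_lo", np.nan),
                        "ci_hi": r.get(f"{acc}_hi", np.nan),
                    }
                )
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "mode": self.mode,
            "config": self.config,
            "per_horizon": self.per_horizon.to_dict(orient="records"),
        }
        if self.per_patient is not None:
            doc["per_patient"] = self.per_patient.to_dict(orient="records")
        if self.weighted is not None:
            doc["weighted"] = self.weighted.to_dict(orient="records")
        text = json.dumps(doc, indent=1, allow_nan=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_csv(self, path: str | Path) -> None:
        self.to_flat().to_csv(path, index=False)


def _accuracy_rows(pred: pd.DataFrame, method: str, label_col: str,
                   B: int | None, level: float, seed: int) -> list[dict]:
    rows = []
    acc = class_accuracies(pred, label_col)
    for _, r in acc.iterrows():
        k = int(r["horizon"])
        sub = pred[pred["horizon"] == k]
        row = {
            "horizon": k, "method": method,
            "specificity": r["specificity"], "sensitivity": r["sensitivity"],
            "n1": r["n1"], "n2": r["n2"],
        }
        if B:
            for cls, name in ((1, "specificity"), (2, "sensitivity")):
                mask = sub["y"] == cls
                correct = (sub.loc[mask, label_col] == cls).to_numpy(dtype=float)
                lo, hi = bootstrap_ci(correct, B=B, level=level,
                                      seed=seed + 7919 * k + cls)
                row[f"{name}_lo"], row[f"{name}_hi"] = lo, hi
        rows.append(row)
    return rows


def evaluate_split(
    windows: WindowedDataset,
    *,
    fraction: float = 0.8,
    seed: int = 0,
    mode: str = "per_lag",
    smoothing: float = 1.0,
    alpha: float | None = None,
    w: float = 2.0,
    grid: tuple[float, ...] = DEFAULT_ALPHA_GRID,
    B: int = 1000,
    level: float = 0.95,
) -> EvalReport:
    """Random 80/20 anchor-split evaluation with bootstrap CIs.

    When ``alpha`` is None, the balancing factor is selected on the training
    split by the T criterion (never on the test split); otherwise the given
    value is used directly.
    """
    train, test = split_random(windows, fraction=fraction, seed=seed)
    model = ICPForecaster(d1=windows.d1, m=windows.m, mode=mode,
                          smoothing=smoothing, alpha=1.0, w=w)
    model.fit(train)
    if alpha is None:
        model.select_alpha(train, grid=grid)
    else:
        model.alpha = alpha
    pred = model.predict_frame(test)
    rows = _accuracy_rows(pred, "map", "map_class", B, level, seed)
    rows += _accuracy_rows(pred, "enhanced", "enhanced_class", B, level, seed + 1)
    cfg = {"fraction": fraction, "seed": seed, "mode": mode, "smoothing": smoothing,
           "alpha": model.alpha, "w": w, "B": B, "level": level,
           "d1": windows.d1, "m": windows.m}
    return EvalReport(mode="split", config=cfg, per_horizon=pd.DataFrame(rows))


def loocv(
    cohort: list[pd.DataFrame],
    *,
    d1: int = 6,
    m: int = 6,
    mode: str = "per_lag",
    smoothing: float = 1.0,
    alpha: float = 0.60,
    w: float = 2.0,
) -> EvalReport:
    """Leave-one-patient-out evaluation with class-proportion-weighted means.

    ``cohort`` is a list of per-patient interval tables. For each fold the
    model is fitted on every other patient's windows and evaluated on the
    held-out patient's full continuous window stream. The summary weights
    patient ``i``'s class-``c`` accuracy by that patient's proportion of
    class-``c`` responses, normalized over patients; ranges across patients
    are reported alongside.
    """
    if len(cohort) < 2:
        raise ValueError("leave-one-out needs at least 2 patients")
    per_patient_ws = [make_windows(t, d1=d1, m=m) for t in cohort]
    pids = [t["patient_id"].iloc[0] for t in cohort]

    pp_rows = []
    for i, pid in enumerate(pids):
        held = per_patient_ws[i]
        if len(held) == 0:
            warnings.warn(f"patient {pid!r} has no valid windows; excluded from LOOCV")
            continue
        train = WindowedDataset.concat([w_ for j, w_ in enumerate(per_patient_ws) if j != i])
        model = ICPForecaster(d1=d1, m=m, mode=mode, smoothing=smoothing,
                              alpha=alpha, w=w).fit(train)
        pred = model.predict_frame(held)
        for method, col in (("map", "map_class"), ("enhanced", "enhanced_class")):
            acc = class_accuracies(pred, col)
            for _, r in acc.iterrows():
                n = r["n1"] + r["n2"]
                pp_rows.append(
                    {"patient_id": pid, "horizon": int(r["horizon"]), "method": method,
                     "specificity": r["specificity"], "sensitivity": r["sensitivity"],
                     "prop1": r["n1"] / n if n else np.nan,
                     "prop2": r["n2"] / n if n else np.nan,
                     "n1": r["n1"], "n2": r["n2"]}
                )
    per_patient = pd.DataFrame(pp_rows)
    if per_patient.empty:
        raise ValueError("no patient produced valid windows")

    weighted = weighted_summary(per_patient)
    ph = weighted.pivot_table(
        index=["horizon", "method"], columns="true_class", values="weighted_mean"
    ).reset_index()
    ph = ph.rename(columns={1: "specificity", 2: "sensitivity"})
    cfg = {"d1": d1, "m": m, "mode": mode, "smoothing": smoothing,
           "alpha": alpha, "w": w, "n_patients": len(pids)}
    return EvalReport(
        mode="loocv", config=cfg,
        per_horizon=ph,
        per_patient=per_patient,
        weighted=weighted,
    )


def weighted_summary(per_patient: pd.DataFrame) -> pd.DataFrame:
    """Class-proportion-weighted means and ranges of per-patient accuracies.

    For each horizon × method × class, patient ``i``'s accuracy is weighted by
    its proportion of that response class (``prop1``/``prop2``), normalized
    over the patients whose accuracy is defined; equal proportions reduce the
    weighted mean to the plain arithmetic mean.
    """
    w_rows = []
    for (k, method), grp in per_patient.groupby(["horizon", "method"], sort=True):
        for cls, acc_name, prop_name in ((1, "specificity", "prop1"), (2, "sensitivity", "prop2")):
            sub = grp.dropna(subset=[acc_name])
            weights = sub[prop_name].to_numpy(dtype=float)
            accs = sub[acc_name].to_numpy(dtype=float)
            if weights.sum() > 0:
                wm = float(np.average(accs, weights=weights))
                lo, hi = float(accs.min()), float(accs.max())
            else:
                wm = lo = hi = np.nan
            w_rows.append(
                {"horizon": int(k), "method": method, "true_class": cls,
                 "weighted_mean": wm, "min": lo, "max": hi, "n_patients": len(sub)}
            )
    return pd.DataFrame(w_rows)
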