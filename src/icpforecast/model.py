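"""Dynamic naïve-Bayes forecaster for elevated intracranial pressure.

The model predicts, for each of ``m`` future 10-minute intervals, the binary
response class (1: mean ICP < 20 mmHg, 2: mean ICP >= 20 mmHg) from the
three-level predictor codes of the ``d1`` preceding intervals. For horizon
``k`` the posterior is Bayes' rule on the class prior and the
class-conditional probability of the observed history:

    P(y_k = c | x) ∝ P(y_k = c) · P(x | y_k = c)

with the class-conditional history likelihood either factorized across lag
positions (``per_lag`` — the naïve-Bayes reading, one categorical
distribution per lag and class) or kept as a joint table over all ``3**d1``
histories (``joint``). All parameters are closed-form maximum-likelihood
counts, optionally Laplace-smoothed.

Because the model is generative, a lag whose level is unknown is simply
marginalized out of the likelihood — per-lag, its factor drops; jointly, the
table is summed over that axis — so predictions remain available with
partially missing histories.

The decision rule compensates class imbalance with a balancing factor
``alpha`` in (0, 1]: predict class 2 unless ``alpha * P(y=1|x) >
P(y=2|x)``. ``alpha = 1`` recovers the MAP prediction; smaller values trade
specificity for sensitivity. ``alpha`` is chosen on a grid by maximizing the
total accuracy gain

    T = A·f1(alpha) + w·(1 − A)·f2(alpha)

where ``A`` is the fraction of class-1 responses, ``f_i(alpha)`` the class-i
accuracy change relative to ``alpha = 1``, and ``w >= 1`` the clinical weight
of a missed elevation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .preprocess import WindowedDataset

__all__ = [
    "CategoricalLagNB",
    "ICPForecaster",
    "AlphaSelectionResult",
    "DEFAULT_ALPHA_GRID",
    "fit",
    "posterior",
    "posterior_with_missing",
    "predict_map",
    "predict_enhanced",
    "select_alpha",
    "enhanced_scores",
    "decide_enhanced",
]

N_LEVELS = 3
CLASSES = np.array([1, 2])

#: Grid over which the balancing factor is searched: 0.50 .. 0.85 step 0.05.
DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.50, 0.851, 0.05), 2))


def enhanced_scores(posterior_probs: np.ndarray, alpha: float) -> np.ndarray:
    """Alpha-weighted decision scores ``(alpha * p1, p2)`` for each row."""
    p = np.atleast_2d(np.asarray(posterior_probs, dtype=float))
    _check_alpha(alpha)
    return np.column_stack([alpha * p[:, 0], p[:, 1]])


def decide_enhanced(posterior_probs: np.ndarray, alpha: float) -> np.ndarray:
    """Apply the balancing rule; ties resolve to class 2 (the alert class)."""
    s = enhanced_scores(posterior_probs, alpha)
    return np.where(s[:, 0] > s[:, 1], 1, 2)


def _check_alpha(alpha: float) -> None:
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")


class CategoricalLagNB(ClassifierMixin, BaseEstimator):
    """Naïve-Bayes classifier over lagged three-level ICP codes, one horizon.

    Parameters
    ----------
    mode : {"per_lag", "joint"}
        Factorization of the class-conditional history likelihood.
    smoothing : float
        Laplace pseudo-count lambda >= 0 added to every cell; 0 gives pure
        maximum likelihood.
    alpha : float
        Balancing factor in (0, 1] used by :meth:`predict`; 1.0 is MAP.

    Attributes
    ----------
    classes_ : ndarray (2,)
        Always ``[1, 2]``.
    class_prior_ : ndarray (2,)
        Smoothed class frequencies.
    feature_prob_ : ndarray (2, d1, 3), per_lag mode
        ``feature_prob_[c, j, l]`` = P(lag j has level l+1 | class c+1).
    joint_prob_ : ndarray (2, 3, ..., 3), joint mode
        Smoothed joint distribution of the full history per class.
    """

    def __init__(self, mode: str = "per_lag", smoothing: float = 1.0, alpha: float = 1.0):
        self.mode = mode
        self.smoothing = smoothing
        self.alpha = alpha

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y):
        if self.mode not in ("per_lag", "joint"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.smoothing < 0:
            raise ValueError("smoothing (lambda) must be >= 0")
        _check_alpha(self.alpha)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one row per element of y")
        if X.shape[0] == 0:
            raise ValueError("cannot fit on an empty dataset")
        if np.isnan(X).any():
            raise ValueError("training histories must be fully observed")
        Xi = X.astype(int)
        if not np.array_equal(Xi, X) or Xi.min() < 1 or Xi.max() > N_LEVELS:
            raise ValueError("predictor levels must be integers in {1, 2, 3}")
        if not np.isin(y, CLASSES).all():
            raise ValueError("response classes must be in {1, 2}")

        n, d1 = Xi.shape
        lam = float(self.smoothing)
        self.classes_ = CLASSES.copy()
        self.n_features_in_ = d1
        counts = np.array([(y == 1).sum(), (y == 2).sum()], dtype=float)
        self.class_count_ = counts
        self.class_prior_ = (counts + lam) / (n + 2 * lam)

        if self.mode == "per_lag":
            tab = np.zeros((2, d1, N_LEVELS))
            for ci, c in enumerate(CLASSES):
                Xc = Xi[y == c]
                for l in range(N_LEVELS):
                    tab[ci, :, l] = (Xc == l + 1).sum(axis=0)
                denom = counts[ci] + N_LEVELS * lam
                if denom > 0:
                    tab[ci] = (tab[ci] + lam) / denom
            self.feature_prob_ = tab
        else:
            shape = (2,) + (N_LEVELS,) * d1
            tab = np.zeros(shape)
            flat = np.ravel_multi_index((Xi - 1).T, (N_LEVELS,) * d1)
            for ci, c in enumerate(CLASSES):
                binc = np.bincount(flat[y == c], minlength=N_LEVELS**d1).astype(float)
                denom = counts[ci] + (N_LEVELS**d1) * lam
                if denom > 0:
                    tab[ci] = ((binc + lam) / denom).reshape((N_LEVELS,) * d1)
            self.joint_prob_ = tab
        return self

    # -- posterior --------------------------------------------------------

    def _check_X(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"history length {X.shape[1]} != fitted d1 = {self.n_features_in_}"
            )
        obs = ~np.isnan(X)
        vals = X[obs]
        if vals.size and (
            not np.array_equal(vals, vals.astype(int)) or vals.min() < 1 or vals.max() > N_LEVELS
        ):
            raise ValueError("observed predictor levels must be in {1, 2, 3}")
        return X

    def _joint_likelihood(self, X: np.ndarray) -> np.ndarray:
        """Class-conditional likelihood of each (possibly partial) history."""
        obs = ~np.isnan(X)
        n, d1 = X.shape
        if self.mode == "per_lag":
            Xi = np.where(obs, X, 1).astype(int) - 1
            # factors[c, i, j] = P(level of lag j in row i | class c)
            factors = self.feature_prob_[:, np.arange(d1), Xi]
            factors[:, ~obs] = 1.0  # marginalized lags contribute a unit factor
            return factors.prod(axis=2).T
        lik = np.empty((n, 2))
        for i in range(n):
            missing_axes = tuple(np.flatnonzero(~obs[i]))
            idx = tuple(
                int(X[i, j]) - 1 if obs[i, j] else slice(None) for j in range(d1)
            )
            for ci in range(2):
                cell = self.joint_prob_[ci][idx]
                lik[i, ci] = cell.sum() if missing_axes else float(cell)
        return lik

    def predict_proba(self, X) -> np.ndarray:
        """Posterior P(y = c | history); missing lags are marginalized out.

        Rows with no observed lag at all, and rows whose history has zero
        probability under both classes (possible with ``smoothing = 0``),
        fall back to the class prior.
        """
        proba, _ = self.posterior_with_missing(X)
        return proba

    def posterior_with_missing(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Posterior plus a flag marking rows that fell back to the prior."""
        X = self._check_X(X)
        lik = self._joint_likelihood(X)
        num = lik * self.class_prior_
        total = num.sum(axis=1)
        fallback = (total == 0) | ((~np.isnan(X)).sum(axis=1) == 0)
        proba = np.where(fallback[:, None], self.class_prior_, num / np.where(total == 0, 1, total)[:, None])
        return proba, fallback

    # -- decision ---------------------------------------------------------

    def predict(self, X) -> np.ndarray:
        """Balanced prediction with the fitted ``alpha`` (MAP when alpha=1)."""
        return decide_enhanced(self.predict_proba(X), self.alpha)

    def predict_map(self, X) -> np.ndarray:
        """Maximum-posterior prediction; posterior ties resolve to class 2."""
        return decide_enhanced(self.predict_proba(X), 1.0)


@dataclass
class AlphaSelectionResult:
    """Outcome of the grid search for the balancing factor.

    ``table`` has one row per (alpha, horizon) with the class-1 fraction
    ``A``, the accuracy gains ``f1`` (typically <= 0) and ``f2`` (typically
    >= 0) relative to alpha = 1, and ``T = A f1 + w (1 - A) f2``.
    ``chosen_alpha`` maximizes the pooled T subject to T > 0 (largest alpha
    on ties); 1.0 means no grid point improved on MAP.
    """

    grid: tuple[float, ...]
    w: float
    table: pd.DataFrame
    pooled: pd.DataFrame
    chosen_alpha: float
    chosen_per_horizon: dict[int, float]


class ICPForecaster(BaseEstimator):
    """Multi-horizon CPT model: one :class:`CategoricalLagNB` per horizon.

    This is the full forecaster a bedside tool would carry: for each horizon
    ``k = 1..m`` (the k-th 10-minute interval of the coming hour) it holds
    the class prior and class-conditional history tables, plus the shared
    decision parameters ``alpha`` and ``w``. Serializes to JSON.
    """

    def __init__(
        self,
        d1: int = 6,
        m: int = 6,
        mode: str = "per_lag",
        smoothing: float = 1.0,
        alpha: float = 0.60,
        w: float = 2.0,
    ):
        self.d1 = d1
        self.m = m
        self.mode = mode
        self.smoothing = smoothing
        self.alpha = alpha
        self.w = w

    def fit(self, windows: WindowedDataset) -> "ICPForecaster":
        if windows.d1 != self.d1:
            raise ValueError(f"dataset d1 = {windows.d1} != model d1 = {self.d1}")
        if self.w < 1:
            raise ValueError("w must be >= 1")
        _check_alpha(self.alpha)
        self.estimators_: dict[int, CategoricalLagNB] = {}
        for k in range(1, self.m + 1):
            X, y = windows.rows_for_horizon(k)
            if len(y) == 0:
                raise ValueError(f"no training rows for horizon k = {k}")
            est = CategoricalLagNB(mode=self.mode, smoothing=self.smoothing, alpha=self.alpha)
            self.estimators_[k] = est.fit(X, y)
        return self

    def _est(self, k: int) -> CategoricalLagNB:
        if not hasattr(self, "estimators_"):
            raise ValueError("forecaster is not fitted")
        if k not in self.estimators_:
            raise ValueError(f"horizon k = {k} not in 1..{self.m}")
        return self.estimators_[k]

    def predict_proba(self, X, k: int) -> np.ndarray:
        return self._est(k).predict_proba(X)

    def posterior_with_missing(self, X, k: int) -> tuple[np.ndarray, np.ndarray]:
        return self._est(k).posterior_with_missing(X)

    def predict_map(self, X, k: int) -> np.ndarray:
        return self._est(k).predict_map(X)

    def predict_enhanced(self, X, k: int, alpha: float | None = None) -> np.ndarray:
        a = self.alpha if alpha is None else alpha
        return decide_enhanced(self.predict_proba(X, k), a)

    def predict_frame(self, windows: WindowedDataset, alpha: float | None = None) -> pd.DataFrame:
        """Predict every row of a window frame; returns provenance + posteriors
        + MAP and enhanced labels, one row per (patient, anchor, horizon)."""
        a = self.alpha if alpha is None else alpha
        outs = []
        for k in np.intersect1d(windows.horizons, list(self.estimators_)):
            sub = windows.frame[windows.frame["horizon"] == k]
            X = sub[windows.lag_columns].to_numpy(dtype=float)
            proba = self.predict_proba(X, int(k))
            outs.append(
                pd.DataFrame(
                    {
                        "patient_id": sub["patient_id"].to_numpy(),
                        "anchor": sub["anchor"].to_numpy(),
                        "horizon": int(k),
                        "y": sub["y"].to_numpy(),
                        "p1": proba[:, 0],
                        "p2": proba[:, 1],
                        "map_class": decide_enhanced(proba, 1.0),
                        "enhanced_class": decide_enhanced(proba, a),
                    }
                )
            )
        return pd.concat(outs, ignore_index=True)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "d1": self.d1,
            "m": self.m,
            "mode": self.mode,
            "smoothing": self.smoothing,
            "alpha": self.alpha,
            "w": self.w,
            "horizons": {},
        }
        for k, est in self.estimators_.items():
            h = {
                "class_prior": est.class_prior_.tolist(),
                "class_count": est.class_count_.tolist(),
            }
            if self.mode == "per_lag":
                h["feature_prob"] = est.feature_prob_.tolist()
            else:
                h["joint_prob"] = est.joint_prob_.reshape(2, -1).tolist()
            d["horizons"][str(k)] = h
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "ICPForecaster":
        self = cls(
            d1=int(d["d1"]), m=int(d["m"]), mode=d["mode"],
            smoothing=float(d["smoothing"]), alpha=float(d["alpha"]), w=float(d["w"]),
        )
        self.estimators_ = {}
        for key, h in d["horizons"].items():
            est = CategoricalLagNB(mode=self.mode, smoothing=self.smoothing, alpha=self.alpha)
            est.classes_ = CLASSES.copy()
            est.n_features_in_ = self.d1
            est.class_prior_ = np.asarray(h["class_prior"], dtype=float)
            est.class_count_ = np.asarray(h["class_count"], dtype=float)
            if self.mode == "per_lag":
                est.feature_prob_ = np.asarray(h["feature_prob"], dtype=float)
            else:
                est.joint_prob_ = np.asarray(h["joint_prob"], dtype=float).reshape(
                    (2,) + (N_LEVELS,) * self.d1
                )
            self.estimators_[int(key)] = est
        return self

    @classmethod
    def from_json(cls, path: str | Path) -> "ICPForecaster":
        return cls.from_dict(json.loads(Path(path).read_text()))

    # -- alpha selection --------------------------------------------------

    def select_alpha(
        self,
        validation: WindowedDataset,
        grid: tuple[float, ...] = DEFAULT_ALPHA_GRID,
        w: float | None = None,
        set_alpha: bool = True,
    ) -> AlphaSelectionResult:
        """Grid-search the balancing factor by maximizing the T criterion.

        For every alpha on the grid and every horizon, the class-wise accuracy
        gains relative to alpha = 1 are combined into
        ``T = A f1 + w (1 - A) f2``. The chosen alpha maximizes the pooled T
        (all horizons' rows together) subject to T > 0, taking the largest
        alpha on ties (the least intervention); if no alpha achieves T > 0,
        alpha stays at 1 (plain MAP). Per-horizon winners are also reported.
        """
        w = self.w if w is None else w
        if w < 1:
            raise ValueError("w must be >= 1")
        grid = tuple(float(a) for a in grid)
        if not grid or any(not 0 < a <= 1 for a in grid):
            raise ValueError("alpha grid must be non-empty within (0, 1]")
        if len(validation) == 0:
            raise ValueError("validation set is empty")

        horizons = [int(k) for k in np.intersect1d(validation.horizons, list(self.estimators_))]
        rows, pooled_rows = [], []
        per_h: dict[int, dict] = {}
        for k in horizons:
            X, y = validation.rows_for_horizon(k)
            if not ((y == 1).any() and (y == 2).any()):
                raise ValueError(
                    f"validation rows for horizon {k} lack one response class; "
                    "accuracy gains are undefined"
                )
            proba = self.predict_proba(X, k)
            per_h[k] = {"proba": proba, "y": y, "A": float((y == 1).mean())}

        all_y = np.concatenate([per_h[k]["y"] for k in horizons])
        all_p = np.vstack([per_h[k]["proba"] for k in horizons])
        A_pool = float((all_y == 1).mean())

        def class_acc(proba, y, a):
            pred = decide_enhanced(proba, a)
            return (
                float((pred[y == 1] == 1).mean()),
                float((pred[y == 2] == 2).mean()),
            )

        base = {k: class_acc(per_h[k]["proba"], per_h[k]["y"], 1.0) for k in horizons}
        base_pool = class_acc(all_p, all_y, 1.0)

        for a in grid:
            for k in horizons:
                acc1, acc2 = class_acc(per_h[k]["proba"], per_h[k]["y"], a)
                f1, f2 = acc1 - base[k][0], acc2 - base[k][1]
                A = per_h[k]["A"]
                rows.append(
                    {"alpha": a, "horizon": k, "A": A, "f1": f1, "f2": f2,
                     "T": A * f1 + w * (1 - A) * f2}
                )
            acc1, acc2 = class_acc(all_p, all_y, a)
            f1, f2 = acc1 - base_pool[0], acc2 - base_pool[1]
            pooled_rows.append(
                {"alpha": a, "A": A_pool, "f1": f1, "f2": f2,
                 "T": A_pool * f1 + w * (1 - A_pool) * f2}
            )

        table = pd.DataFrame(rows)
        pooled = pd.DataFrame(pooled_rows)

        def pick(df: pd.DataFrame) -> float:
            pos = df[df["T"] > 0]
            if pos.empty:
                return 1.0
            best = pos[pos["T"] == pos["T"].max()]
            return float(best["alpha"].max())

        chosen = pick(pooled)
        per_horizon = {k: pick(table[table["horizon"] == k]) for k in horizons}
        if set_alpha:
            self.alpha = chosen
            for est in self.estimators_.values():
                est.alpha = chosen
        return AlphaSelectionResult(
            grid=grid, w=w, table=table, pooled=pooled,
            chosen_alpha=chosen, chosen_per_horizon=per_horizon,
        )


# -- module-level convenience wrappers -------------------------------------


def fit(
    data: WindowedDataset, mode: str = "per_lag", smoothing: float = 1.0,
    alpha: float = 0.60, w: float = 2.0,
) -> ICPForecaster:
    """Fit the multi-horizon forecaster on a window dataset."""
    return ICPForecaster(
        d1=data.d1, m=data.m, mode=mode, smoothing=smoothing, alpha=alpha, w=w
    ).fit(data)


def posterior(model: ICPForecaster, history, k: int) -> np.ndarray:
    """Posterior class probabilities for one fully observed history."""
    h = np.asarray(history, dtype=float)
    if np.isnan(h).any():
        raise ValueError("history contains missing values; use posterior_with_missing")
    return model.predict_proba(h.reshape(1, -1), k)[0]


def posterior_with_missing(model: ICPForecaster, history, k: int) -> tuple[np.ndarray, bool]:
    """Posterior with missing lags marginalized out.

    Returns ``(probabilities, prior_fallback)``; the flag is True when every
    lag was missing and the class prior was returned.
    """
    h = np.asarray(history, dtype=float).reshape(1, -1)
    proba, fb = model.posterior_with_missing(h, k)
    return proba[0], bool(fb[0])


def predict_map(model: ICPForecaster, history, k: int) -> int:
    """MAP class for one history (ties to class 2)."""
    return int(model.predict_map(np.asarray(history, dtype=float).reshape(1, -1), k)[0])


def predict_enhanced(model: ICPForecaster, history, k: int, alpha: float | None = None) -> int:
    """Balanced prediction for one history at the given alpha."""
    return int(
        model.predict_enhanced(np.asarray(history, dtype=float).reshape(1, -1), k, alpha)[0]
    )


def select_alpha(
    model: ICPForecaster, validation: WindowedDataset,
    grid: tuple[float, ...] = DEFAULT_ALPHA_GRID, w: float | None = None,
) -> AlphaSelectionResult:
    """Grid-search the balancing factor on a validation window set."""
    return model.select_alpha(validation, grid=grid, w=w)
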