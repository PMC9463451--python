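"""Treatment-response modeling from TiME features.

Binary response to topical immune therapy is predicted from ordinal TiME
grades with a linear probability model: ordinary least squares of the 0/1
response on the selected features, classifying at a 0.5 cutoff. Because
cohorts are small (~13 lesions), performance is measured out-of-bag with
leave-one-out cross-validation: each sample is predicted by a model fitted
on the remaining n-1. Features are chosen by greedy forward selection under
either a specificity-prioritizing criterion (maximize out-of-bag
specificity, ties by accuracy then lower AIC) or an AIC-prioritizing one
(minimize AIC, ties by accuracy). The AIC convention is fixed as
``n * ln(RSS / n) + 2 * (p + 2)`` with p predictors (intercept and error
variance counted as parameters).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.optimize import linprog

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ResponseResults:
    """LOOCV performance and full-data fit for one feature set."""

    selected_features: list[str]
    coefficients: dict[str, float]  # includes 'intercept'
    oob_predictions: np.ndarray  # per-sample predicted class; -1 = skipped fold
    oob_scores: np.ndarray  # raw linear predictions
    labels: np.ndarray
    sensitivity: float
    specificity: float
    accuracy: float
    aic: float
    cutoff: float = 0.5
    selection_trace: list[dict] | None = None

    def summary(self) -> str:
        lines = [f"features: {', '.join(self.selected_features)}",
                 f"LOOCV sensitivity {self.sensitivity:.2f}  "
                 f"specificity {self.specificity:.2f}  "
                 f"accuracy {self.accuracy:.2f}  AIC {self.aic:.2f}",
                 "coefficients:"]
        for name, val in self.coefficients.items():
            lines.append(f"  {name:28s} {val:+.4f}")
        return "\n".join(lines)


def _design(table: pd.DataFrame, features: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise ValueError(f"features not in table: {missing}")
    if "response" not in table.columns:
        raise ValueError("table must contain a binary 'response' column")
    x = table[list(features)].to_numpy(dtype=float)
    y = table["response"].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(x)), x]), y


def _check_rank(design: np.ndarray, features: Sequence[str]) -> None:
    """Raise naming the collinear features when the design is singular."""
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        _, r, piv = linalg.qr(design, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(design.shape) * np.finfo(float).eps
        bad = [piv[i] for i in range(len(diag)) if diag[i] <= tol]
        names = ["intercept"] + list(features)
        raise ValueError("singular design; collinear columns: "
                         f"{[names[i] for i in sorted(bad)]}")


def _ols(design: np.ndarray, y: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return beta


class ResponseModel:
    """Linear-probability response model with LOOCV evaluation."""

    def __init__(self, table: pd.DataFrame) -> None:
        if "response" not in table.columns:
            raise ValueError("table must contain a binary 'response' column")
        y = table["response"].to_numpy()
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("response must be binary in {0, 1}")
        if len(table) < 4:
            raise ValueError("response modeling needs at least 4 samples")
        if len(np.unique(y)) < 2:
            raise ValueError("both response classes must be present")
        self.table = table

    @classmethod
    def from_csv(cls, path) -> "ResponseModel":
        return cls(pd.read_csv(path, index_col=0))

    def aic(self, features: Sequence[str]) -> float:
        """AIC of the full-data OLS fit: n*ln(RSS/n) + 2*(p + 2)."""
        design, y = _design(self.table, features)
        _check_rank(design, features)
        beta = _ols(design, y)
        rss = float(((y - design @ beta) ** 2).sum())
        if rss <= 1e-12 * max(1.0, float((y ** 2).sum())):
            raise ValueError("perfect fit (RSS = 0); AIC undefined")
        n = len(y)
        return n * math.log(rss / n) + 2.0 * (len(features) + 2)

    def fit_loocv(self, features: Sequence[str],
                  cutoff: float = 0.5) -> ResponseResults:
        """Out-of-bag metrics by leave-one-out cross-validation.

        Each sample is classified (linear prediction >= cutoff) by an OLS
        fit on the other n-1 samples; folds whose training split loses a
        class are skipped with a warning and excluded from the metrics. The
        reported coefficients and AIC come from the full-data fit.
        """
        design, y = _design(self.table, features)
        _check_rank(design, features)
        n = len(y)
        preds = np.full(n, -1, dtype=int)
        scores = np.full(n, np.nan)
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            if len(np.unique(y[mask])) < 2:
                logger.warning("LOOCV fold %d has a single class in "
                               "training; skipped", i)
                continue
            beta = _ols(design[mask], y[mask])
            scores[i] = design[i] @ beta
            preds[i] = int(scores[i] >= cutoff)
        evaluated = preds >= 0
        pos = evaluated & (y == 1)
        neg = evaluated & (y == 0)
        tp = int(np.sum(preds[pos] == 1))
        tn = int(np.sum(preds[neg] == 0))
        sens = tp / pos.sum() if pos.sum() else float("nan")
        spec = tn / neg.sum() if neg.sum() else float("nan")
        acc = (tp + tn) / evaluated.sum() if evaluated.sum() else float("nan")
        beta_full = _ols(design, y)
        coefficients = {"intercept": float(beta_full[0])}
        coefficients.update({f: float(b) for f, b
                             in zip(features, beta_full[1:])})
        return ResponseResults(
            selected_features=list(features), coefficients=coefficients,
            oob_predictions=preds, oob_scores=scores, labels=y.astype(int),
            sensitivity=float(sens), specificity=float(spec),
            accuracy=float(acc), aic=self.aic(features), cutoff=cutoff)

    def forward_select(self, candidate_features: Sequence[str],
                       mode: str = "specificity_first",
                       max_features: int = 2,
                       cutoff: float = 0.5) -> list[ResponseResults]:
        """Greedy forward selection of features by out-of-bag performance.

        ``specificity_first`` adds the candidate maximizing out-of-bag
        specificity (ties by accuracy, then lower AIC); ``aic_first``
        minimizes AIC (ties by accuracy). Remaining ties keep the earliest
        candidate. Returns the best model of each iteration, in order.
        """
        if mode not in ("specificity_first", "aic_first"):
            raise ValueError("mode must be 'specificity_first' or 'aic_first'")
        if not candidate_features:
            raise ValueError("need at least one candidate feature")
        selected: list[str] = []
        out: list[ResponseResults] = []
        remaining = list(candidate_features)
        while remaining and len(selected) < max_features:
            best = None
            trace = []
            for cand in remaining:
                try:
                    res = self.fit_loocv(selected + [cand], cutoff=cutoff)
                except ValueError:
                    continue  # singular with this candidate
                if mode == "specificity_first":
                    key = (res.specificity, res.accuracy, -res.aic)
                else:
                    key = (-res.aic, res.accuracy)
                trace.append({"candidate": cand,
                              "sensitivity": res.sensitivity,
                              "specificity": res.specificity,
                              "accuracy": res.accuracy, "aic": res.aic})
                if best is None or key > best[0]:
                    best = (key, cand, res)
            if best is None:
                break
            _, cand, res = best
            selected.append(cand)
            remaining.remove(cand)
            res.selection_trace = trace
            out.append(res)
        return out


def separability_check(table: pd.DataFrame,
                       feature_pair: Sequence[str]) -> tuple[bool, float]:
    """Exact linear-separability check in 1-D or 2-D feature space.

    Decides feasibility of a strict linear separator via linear programming
    and, when separable, reports the maximal margin (hard-margin linear
    SVM). Returns ``(separable, margin)``; margin is 0 when inseparable.
    """
    if not 1 <= len(feature_pair) <= 2:
        raise ValueError("feature_pair must contain 1 or 2 features")
    x = table[list(feature_pair)].to_numpy(dtype=float)
    y = table["response"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    sign = np.where(y == 1, 1.0, -1.0)
    d = x.shape[1]
    # feasibility of sign_i * (w . x_i + b) >= 1
    a_ub = -sign[:, None] * np.column_stack([x, np.ones(len(x))])
    res = linprog(c=np.zeros(d + 1), A_ub=a_ub, b_ub=-np.ones(len(x)),
                  bounds=[(None, None)] * (d + 1), method="highs")
    if not res.success:
        return False, 0.0
    from sklearn.svm import SVC
    svm = SVC(kernel="linear", C=1e9).fit(x, y)
    margin = 2.0 / float(np.linalg.norm(svm.coef_))
    return True, margin


# -- functional wrappers matching the module's operation surface ------------

def loocv_linear_classifier(table: pd.DataFrame, features: Sequence[str],
                            cutoff: float = 0.5) -> ResponseResults:
    return ResponseModel(table).fit_loocv(features, cutoff=cutoff)


def aic_ols(table: pd.DataFrame, features: Sequence[str]) -> float:
    return ResponseModel(table).aic(features)


def forward_select(table: pd.DataFrame, candidate_features: Sequence[str],
                   mode: str = "specificity_first",
                   max_features: int = 2) -> list[ResponseResults]:
    return ResponseModel(table).forward_select(candidate_features, mode=mode,
                                               max_features=max_features)
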