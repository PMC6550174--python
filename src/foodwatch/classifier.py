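"""The web-search model (WSM): a log-linear maximum-entropy classifier over
hashed query features.

For binary outcomes the maximum-entropy model coincides with logistic
regression: P(illness | query) = sigma(b + w.x) with sigma the logistic
function. Training maximizes the L2-penalized log-likelihood

    sum_i log sigma(y_i (b + w.x_i)) - lambda/2 ||w||^2,   y_i in {-1, +1}

with the bias b unregularized. The optimizer is a trust-region Newton
method (second order, Hessian-vector products only, so the 50,000-dim
default stays cheap); convergence is declared when the gradient norm drops
below ``tol``. Training is deterministic given its inputs.
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize, sparse
from scipy.stats import rankdata

from foodwatch.exceptions import DegenerateDataError, ParameterError, ShortfallError
from foodwatch.features import design_matrix, extract_features
from foodwatch.types import QueryEvent
from foodwatch.weak_labels import LabeledQuery


@dataclass
class WSMModel:
    """Trained weights over the hashed feature space plus a bias term."""

    dim: int
    weights: np.ndarray  # shape (dim,)
    bias: float
    meta: dict = field(default_factory=dict)

    def decision(self, x: dict[int, float]) -> float:
        return self.bias + sum(self.weights[i] * v for i, v in x.items())

    def save(self, path: str | Path) -> None:
        payload = {
            "format": "foodwatch-wsm-1",
            "dim": self.dim,
            "bias": self.bias,
            "weights_dtype": "float64",
            "weights_b64": base64.b64encode(
                np.ascontiguousarray(self.weights, dtype="<f8").tobytes()
            ).decode("ascii"),
            "meta": self.meta,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "WSMModel":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        if payload.get("format") != "foodwatch-wsm-1":
            raise ParameterError(f"{path}: not a foodwatch WSM model file")
        w = np.frombuffer(base64.b64decode(payload["weights_b64"]), dtype="<f8")
        return cls(dim=int(payload["dim"]), weights=w.astype(np.float64),
                   bias=float(payload["bias"]), meta=payload.get("meta", {}))


@dataclass
class EvalReport:
    """Classifier evaluation: rank-based ROC AUC plus F1 at a threshold."""

    roc_auc: float
    f1: float
    threshold: float
    tp: int
    fp: int
    fn: int
    tn: int

    def to_dict(self) -> dict:
        return {"roc_auc": self.roc_auc, "f1": self.f1,
                "threshold": self.threshold, "tp": self.tp, "fp": self.fp,
                "fn": self.fn, "tn": self.tn}


def _sigmoid(z: np.ndarray | float):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(z, dtype=float)))


def train_wsm(train: list[LabeledQuery], dim: int, l2_lambda: float = 1.0,
              max_iter: int = 200, tol: float = 1e-8) -> WSMModel:
    """Fit the maxent model on weakly labeled queries.

    Raises :class:`DegenerateDataError` unless both classes are present.
    """
    if l2_lambda < 0:
        raise ParameterError("l2_lambda must be >= 0")
    labels = np.array([1.0 if lq.label else -1.0 for lq in train])
    if len(np.unique(labels)) < 2:
        raise DegenerateDataError(
            "training set must contain both positive and negative examples")
    X = design_matrix([lq.query for lq in train], dim)
    return _fit_logistic(X, labels, l2_lambda, max_iter, tol)


def _fit_logistic(X: sparse.csr_matrix, y: np.ndarray, l2_lambda: float,
                  max_iter: int, tol: float) -> WSMModel:
    n, dim = X.shape

    def unpack(theta):
        return theta[0], theta[1:]

    def nll(theta):
        b, w = unpack(theta)
        z = y * (X @ w + b)
        # log(1 + exp(-z)) computed stably
        loss = np.logaddexp(0.0, -z).sum()
        return loss + 0.5 * l2_lambda * w @ w

    def grad(theta):
        b, w = unpack(theta)
        z = y * (X @ w + b)
        s = _sigmoid(-z)  # dloss/dz per example
        coef = -y * s
        g = np.empty_like(theta)
        g[0] = coef.sum()
        g[1:] = X.T @ coef + l2_lambda * w
        return g

    def hessp(theta, p):
        b, w = unpack(theta)
        z = X @ w + b
        s = _sigmoid(z)
        d = s * (1.0 - s)
        zp = X @ p[1:] + p[0]
        dzp = d * zp
        out = np.empty_like(p)
        out[0] = dzp.sum()
        out[1:] = X.T @ dzp + l2_lambda * p[1:]
        return out

    theta0 = np.zeros(dim + 1)
    trace = [float(nll(theta0))]
    res = optimize.minimize(
        nll, theta0, jac=grad, hessp=hessp, method="trust-ncg",
        callback=lambda xk: trace.append(float(nll(xk))),
        options={"gtol": tol, "maxiter": max_iter},
    )
    gnorm = float(np.linalg.norm(grad(res.x)))
    b, w = res.x[0], res.x[1:]
    meta = {
        "l2_lambda": l2_lambda,
        "iterations": int(res.nit),
        "final_loss": float(res.fun),
        "grad_norm": gnorm,
        "converged": bool(gnorm <= tol or res.success),
        "n_train": int(n),
        "loss_trace": trace,
    }
    return WSMModel(dim=dim, weights=np.asarray(w, dtype=float),
                    bias=float(b), meta=meta)


def classify_query(model: WSMModel, query: QueryEvent) -> float:
    """P(illness | query) = sigma(b + w.x); pure and deterministic."""
    x = extract_features(query, model.dim)
    return float(_sigmoid(model.decision(x)))


def score_queries(model: WSMModel, queries: list[QueryEvent]) -> np.ndarray:
    X = design_matrix(queries, model.dim)
    return np.asarray(_sigmoid(X @ model.weights + model.bias), dtype=float)


# ---------------------------------------------------------------------------
# Evaluation-set sampling
# ---------------------------------------------------------------------------

def _traffic_weighted_unique(strings: list[str], freqs: dict[str, int],
                             n: int, rng: np.random.Generator) -> list[str]:
    if len(strings) < n:
        raise ShortfallError(
            f"need {n} unique strings, pool has {len(strings)}",
            requested=n, available=len(strings))
    w = np.array([freqs[s] for s in strings], dtype=float)
    picked = rng.choice(len(strings), size=n, replace=False, p=w / w.sum())
    return [strings[int(i)] for i in picked]


def sample_evaluation_set(query_log: list[QueryEvent], n: int,
                          topical_urls: set[str],
                          exclude_strings: set[str],
                          rng: np.random.Generator) -> list[QueryEvent]:
    """Stratified evaluation sample: ``n/2`` queries from a high-recall pool
    (queries that clicked a topical page), traffic-weighted within the pool,
    plus ``n/2`` traffic-weighted from the full stream. All strings are
    unique and disjoint from ``exclude_strings`` (the training pool); pool
    exhaustion raises :class:`ShortfallError` rather than silently
    shrinking the sample.
    """
    if n % 2:
        raise ParameterError("evaluation sample size must be even")
    freqs: dict[str, int] = {}
    first_occurrence: dict[str, QueryEvent] = {}
    clicked_topical: set[str] = set()
    for q in query_log:
        s = q.query_text
        freqs[s] = freqs.get(s, 0) + 1
        if s not in first_occurrence:
            first_occurrence[s] = q
        if any(url in topical_urls for url, _ in q.clicks):
            clicked_topical.add(s)

    half = n // 2
    hr_pool = sorted(s for s in clicked_topical if s not in exclude_strings)
    if not hr_pool:
        raise ShortfallError("high-recall pool is empty", requested=half,
                             available=0)
    chosen = _traffic_weighted_unique(hr_pool, freqs, half, rng)
    taken = set(chosen) | exclude_strings
    stream_pool = sorted(s for s in freqs if s not in taken)
    chosen += _traffic_weighted_unique(stream_pool, freqs, half, rng)
    return [first_occurrence[s] for s in chosen]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the rank (Mann-Whitney) definition; ties count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateDataError("AUC needs at least one positive and one "
                                  "negative truth label")
    ranks = rankdata(scores)  # average ranks on ties
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def f1_at_threshold(scores, labels, threshold: float):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pred = scores >= threshold
    tp = int((pred & labels).sum())
    fp = int((pred & ~labels).sum())
    fn = int((~pred & labels).sum())
    tn = int((~pred & ~labels).sum())
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return f1, (tp, fp, fn, tn)


def evaluate_wsm(scores: np.ndarray, truth_labels: np.ndarray,
                 threshold_policy: str = "fixed:0.5") -> EvalReport:
    """Score the classifier against ground truth.

    ``threshold_policy`` is either ``"fixed:<t>"`` or ``"max_f1"`` (the
    F1-maximizing threshold over the supplied scores, intended for use on a
    validation split).
    """
    auc = roc_auc(scores, truth_labels)
    if threshold_policy.startswith("fixed:"):
        thr = float(threshold_policy.split(":", 1)[1])
    elif threshold_policy == "max_f1":
        candidates = np.unique(np.asarray(scores, dtype=float))
        thr = max(candidates,
                  key=lambda t: f1_at_threshold(scores, truth_labels, t)[0])
        thr = float(thr)
    else:
        raise ParameterError(f"unknown threshold policy {threshold_policy!r}")
    f1, (tp, fp, fn, tn) = f1_at_threshold(scores, truth_labels, thr)
    return EvalReport(roc_auc=auc, f1=f1, threshold=thr,
                      tp=tp, fp=fp, fn=fn, tn=tn)
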