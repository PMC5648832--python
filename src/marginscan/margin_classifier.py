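"""Statistical margin classification layer.

Three pieces mirror the study's analysis of biopsy-validated margin
spots:

* Welch two-sample t-tests (unequal variance, two-tailed) on band
  ratios (1265/1304 and 1445/1265 1/cm) between fatty and
  fibroadenomatoid spots, significance at p < 0.01;
* sparse multinomial logistic regression (SMLR) on the preprocessed,
  AUC-normalised spectra as direct features: an L1 (Laplacian-prior)
  penalised logistic model with no bias term, lambda = 0.01;
* leave-one-specimen-out (LOSO) cross-validation with confusion-matrix
  metrics (sensitivity, specificity, accuracy, Cohen's kappa), with
  fibroadenomatoid as the positive, disease-suspicious class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import minimize

from .spectral_processing import Spectrum, common_axis

POSITIVE_CLASS = "fibroadenomatoid"
NEGATIVE_CLASS = "fatty"


# ---------------------------------------------------------------------------
# Data container
# ---------------------------------------------------------------------------

@dataclass
class LabeledSpectraSet:
    """Labelled, specimen-grouped spectra for cross-validated classification."""

    spectra: list
    labels: list
    specimen_ids: list

    def __post_init__(self):
        n = len(self.spectra)
        if len(self.labels) != n or len(self.specimen_ids) != n:
            raise ValueError("spectra, labels and specimen_ids must align")
        bad = set(self.labels) - {POSITIVE_CLASS, NEGATIVE_CLASS}
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}")
        if len(set(self.specimen_ids)) < 2:
            raise ValueError("need >= 2 specimens for leave-one-specimen-out")
        common_axis(self.spectra)

    @property
    def features(self) -> np.ndarray:
        return np.stack([s.intensities for s in self.spectra])

    @property
    def y(self) -> np.ndarray:
        return np.array([1 if l == POSITIVE_CLASS else 0 for l in self.labels])

    def __len__(self):
        return len(self.spectra)


# ---------------------------------------------------------------------------
# Welch t-test
# ---------------------------------------------------------------------------

def welch_t_test(group_a, group_b) -> tuple[float, float]:
    """Two-tailed Welch t-test (unequal variances).

    Returns (t, p) with Welch-Satterthwaite degrees of freedom. Groups
    must each have >= 2 values and at least one group nonzero variance.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise ValueError("degenerate groups: zero variance, unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Sparse multinomial logistic regression (direct spectral features)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SMLRModel:
    """L1-penalised logistic weights over wavenumber features, no bias.

    Binary multinomial with the negative class as reference: one weight
    vector, posterior P(positive | x) = sigmoid(x . w).
    """

    weights: np.ndarray
    lam: float
    classes: tuple = (NEGATIVE_CLASS, POSITIVE_CLASS)
    objective_trace: tuple = ()
    converged: bool = True

    @property
    def sparsity_level(self) -> float:
        return float(np.mean(np.abs(self.weights) < 1e-8))

    def posterior(self, X: np.ndarray) -> np.ndarray:
        """P(positive class) for each row of X."""
        z = np.atleast_2d(np.asarray(X, float)) @ self.weights
        return 1.0 / (1.0 + np.exp(-z))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Labels at posterior threshold 0.5; ties go to the positive
        (fibroadenomatoid) class — the stringent, suspicion-first call."""
        post = self.posterior(X)
        return np.where(post >= 0.5, self.classes[1], self.classes[0])


def _fit_l1_logistic(X: np.ndarray, y: np.ndarray, lam: float,
                     tol: float = 1e-10, max_iter: int = 2000):
    """Minimise NLL(w) + lam*||w||_1 via the split w = u - v, u,v >= 0."""
    n, p = X.shape

    def nll_grad(w):
        z = X @ w
        # stable log(1+exp(z)) and sigmoid
        nll = float(np.sum(np.logaddexp(0.0, z) - y * z))
        sig = 0.5 * (1.0 + np.tanh(0.5 * z))
        gw = X.T @ (sig - y)
        return nll, gw

    trace = []

    def fun(uv):
        u, v = uv[:p], uv[p:]
        w = u - v
        nll, gw = nll_grad(w)
        f = nll + lam * float(np.sum(u) + np.sum(v))
        g = np.concatenate([gw + lam, -gw + lam])
        return f, g

    def cb(uv):
        u, v = uv[:p], uv[p:]
        nll, _ = nll_grad(u - v)
        trace.append(nll + lam * float(np.sum(u) + np.sum(v)))

    x0 = np.zeros(2 * p)
    res = minimize(fun, x0, jac=True, method="L-BFGS-B",
                   bounds=[(0.0, None)] * (2 * p), callback=cb,
                   options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-9})
    w = res.x[:p] - res.x[p:]
    # shrink numerically-dead coordinates to exact zero
    w[np.abs(w) < 1e-10] = 0.0
    return w, tuple(trace), bool(res.success)


def train_smlr(data: LabeledSpectraSet, lam: float = 0.01,
               seed: int = 0) -> SMLRModel:
    """Train the sparse logistic classifier on raw spectral features.

    The 'direct kernel' formulation: features are the preprocessed,
    AUC-normalised intensities themselves, no kernel expansion and no
    intercept. The optimiser is deterministic (zero initialisation), so
    ``seed`` only matters for downstream consumers; the penalised
    objective decreases monotonically over iterations.
    """
    y = data.y
    if len(set(y.tolist())) < 2:
        raise ValueError("single-class training data")
    X = data.features
    w, trace, ok = _fit_l1_logistic(X, y, lam)
    return SMLRModel(w, lam, objective_trace=trace, converged=ok)


# ---------------------------------------------------------------------------
# Confusion metrics and LOSO cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassificationReport:
    """Confusion counts and derived metrics; positive = fibroadenomatoid."""

    tp: int
    fn: int
    tn: int
    fp: int
    notes: tuple = ()
    fold_predictions: tuple = ()   # rows: (specimen_id, spot_id, true, pred, posterior)

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.n == 0:
            raise ValueError("empty confusion table")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def kappa(self) -> float:
        """Cohen's kappa with marginal-based expected agreement."""
        n = self.n
        po = self.accuracy
        pe = ((self.tp + self.fn) * (self.tp + self.fp)
              + (self.tn + self.fp) * (self.tn + self.fn)) / (n * n)
        if pe == 1.0:
            return float("nan")
        return (po - pe) / (1.0 - pe)

    def as_display(self) -> dict:
        """Metrics at printed precision: whole percents, kappa to 2 dp."""
        def pct(x):
            return float("nan") if np.isnan(x) else int(round(100.0 * x))
        return {
            "sensitivity_percent": pct(self.sensitivity),
            "specificity_percent": pct(self.specificity),
            "accuracy_percent": pct(self.accuracy),
            "kappa": float("nan") if np.isnan(self.kappa) else round(self.kappa, 2),
            "counts": {"tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp},
        }


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> ClassificationReport:
    """Build a report from confusion counts (positive = fibroadenomatoid)."""
    return ClassificationReport(int(tp), int(fn), int(tn), int(fp))


def loso_cv(data: LabeledSpectraSet, lam: float = 0.01,
            seed: int = 0) -> ClassificationReport:
    """Leave-one-specimen-out cross-validation of the SMLR classifier.

    Each fold holds out every spot of one specimen, trains on the rest
    and predicts the held-out spots at posterior threshold 0.5. Confusion
    counts aggregate over folds. A training fold that lost a class is
    noted in the report but still predicted.
    """
    X = data.features
    y = data.y
    ids = np.asarray(data.specimen_ids)
    tp = fn = tn = fp = 0
    notes = []
    rows = []
    for spec_id in sorted(set(data.specimen_ids), key=str):
        held = ids == spec_id
        train = ~held
        assert not np.any(ids[train] == spec_id), "held-out specimen leaked into training"
        y_tr = y[train]
        if len(set(y_tr.tolist())) < 2:
            notes.append(f"fold {spec_id}: single-class training data")
        sub = LabeledSpectraSet(
            [s for s, h in zip(data.spectra, train) if h],
            [l for l, h in zip(data.labels, train) if h],
            [i for i, h in zip(data.specimen_ids, train) if h],
        ) if len(set(y_tr.tolist())) >= 2 else None
        if sub is not None:
            model = train_smlr(sub, lam, seed)
        else:
            # degenerate fold: constant model predicting the only seen class
            only = POSITIVE_CLASS if y_tr[0] == 1 else NEGATIVE_CLASS
            model = SMLRModel(np.zeros(X.shape[1]) + (1e-6 if only == POSITIVE_CLASS
                                                      else -1e-6), lam)
        post = model.posterior(X[held])
        pred = np.where(post >= 0.5, 1, 0)
        truth = y[held]
        tp += int(np.sum((pred == 1) & (truth == 1)))
        fn += int(np.sum((pred == 0) & (truth == 1)))
        tn += int(np.sum((pred == 0) & (truth == 0)))
        fp += int(np.sum((pred == 1) & (truth == 0)))
        for spot_i, (pr, po, tr) in enumerate(zip(pred, post, truth)):
            rows.append((str(spec_id), spot_i,
                         POSITIVE_CLASS if tr == 1 else NEGATIVE_CLASS,
                         POSITIVE_CLASS if pr == 1 else NEGATIVE_CLASS,
                         float(po)))
    return ClassificationReport(tp, fn, tn, fp, tuple(notes), tuple(rows))


__all__ = [
    "LabeledSpectraSet", "SMLRModel", "ClassificationReport",
    "welch_t_test", "train_smlr", "loso_cv", "confusion_metrics",
    "POSITIVE_CLASS", "NEGATIVE_CLASS",
]
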