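"""Fuzzy C-means classification with Bayesian defuzzification.

Cells are classified by clustering the training feature vectors into c fuzzy
clusters and converting cluster memberships into class posteriors:

* Fuzzy C-means: each point k holds a graded membership in every cluster i,

      m_ik = 1 / sum_j (d_ik / d_jk)^(2/(q-1)),

  with Euclidean distances d and fuzzifier q > 1; centers are the
  membership^q-weighted means.  The alternating updates monotonically
  decrease the objective sum_ik m_ik^q d_ik^2.

* Defuzzification: training points are hard-assigned to their
  maximum-membership cluster; the per-cluster class composition gives the
  likelihoods P(cluster | class) (Laplace-smoothed), class priors are
  proportional to class mass, and Bayes' rule yields the posterior
  P(class | cluster).  A new point's class posterior is its membership vector
  mixed through these per-cluster posteriors.

The reference operating point is c = 25 clusters with fuzzifier q = 1.0930
chosen by cross-validation, with 60 seeded restarts; all of it configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from scipy.special import logsumexp

from ._errors import ContractError, DataError
from .cell_features import FEATURE_NAMES, LABEL_COLUMN, CellClass, binary_label

DEFAULT_FUZZIFIER = 1.0930
DEFAULT_N_CLUSTERS = 25
DEFAULT_RERUNS = 60


@dataclass
class FCMModel:
    """Converged fuzzy C-means clustering of standardized training data."""

    centers: np.ndarray            # c x d
    fuzzifier: float
    objective_trace: list[float] = field(default_factory=list)
    seed: int = 0
    tol: float = 1e-5

    @property
    def n_clusters(self) -> int:
        return self.centers.shape[0]


@dataclass
class DefuzzModel:
    """Cluster -> class probabilistic model (likelihoods, priors, posteriors)."""

    classes: np.ndarray            # class codes, declaration order
    conditionals: np.ndarray       # n_classes x c, P(cluster j | class i)
    priors: np.ndarray             # n_classes
    posteriors: np.ndarray         # n_classes x c, P(class i | cluster j)
    smoothing: float = 1.0


@dataclass
class ClusterCountReport:
    candidates: list[int]
    cv_errors: list[float]
    chosen: int


@dataclass
class SlideDiagnosis:
    positive: bool
    n_abnormal: int
    n_cells: int
    class_counts: dict[str, int]

    @property
    def label(self) -> str:
        return "POSITIVE" if self.positive else "NEGATIVE"


# ---------------------------------------------------------------------------
# fuzzy C-means core

def _memberships_from_distances(d2: np.ndarray, q: float) -> np.ndarray:
    """Fuzzy memberships from squared distances, shape (n, c).

    Computed in log space (the exponent 2/(q-1) is large for q near 1).
    Points coinciding with a center get full membership there (split evenly
    over ties).
    """
    n, c = d2.shape
    with np.errstate(divide="ignore"):
        logd2 = np.log(d2)
    e = 1.0 / (q - 1.0)
    logm = -e * logd2
    zero = d2 <= 0.0
    any_zero = zero.any(axis=1)
    out = np.empty_like(d2)
    ok = ~any_zero
    if ok.any():
        out[ok] = np.exp(logm[ok] - logsumexp(logm[ok], axis=1, keepdims=True))
    if any_zero.any():
        out[any_zero] = zero[any_zero] / zero[any_zero].sum(axis=1, keepdims=True)
    return out


def _sq_distances(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    diff = X[:, None, :] - centers[None, :, :]
    return np.einsum("ncd,ncd->nc", diff, diff)


def _farthest_point_init(X: np.ndarray, c: int, rng: np.random.Generator
                         ) -> np.ndarray:
    """Seeded farthest-point sampling: random first center, then argmax of
    the distance to the nearest chosen center."""
    n = X.shape[0]
    idx = [int(rng.integers(n))]
    d = np.linalg.norm(X - X[idx[0]], axis=1)
    for _ in range(1, c):
        nxt = int(np.argmax(d))
        idx.append(nxt)
        d = np.minimum(d, np.linalg.norm(X - X[nxt], axis=1))
    return X[idx].copy()


def fcm_fit(X: np.ndarray, c: int = DEFAULT_N_CLUSTERS,
            q: float = DEFAULT_FUZZIFIER, tol: float = 1e-5,
            max_iter: int = 300, seed: int = 0,
            n_restarts: int = 1) -> FCMModel:
    """Fit fuzzy C-means on a standardized feature matrix.

    Runs ``n_restarts`` seeded initializations and keeps the run with the
    lowest final objective.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise DataError("X must be a 2-D matrix")
    if not np.isfinite(X).all():
        raise DataError("X contains non-finite values")
    n = X.shape[0]
    if c < 2:
        raise ContractError("need at least 2 clusters")
    if q <= 1:
        raise ContractError("fuzzifier q must be > 1")
    if n <= c:
        raise ContractError(f"need more data points ({n}) than clusters ({c})")

    best: FCMModel | None = None
    for r in range(n_restarts):
        rng = np.random.default_rng(seed + r)
        centers = _farthest_point_init(X, c, rng)
        trace: list[float] = []
        for _ in range(max_iter):
            d2 = _sq_distances(X, centers)
            m = _memberships_from_distances(d2, q)
            mq = m**q
            trace.append(float((mq * d2).sum()))
            new_centers = (mq.T @ X) / mq.sum(axis=0)[:, None]
            shift = np.abs(new_centers - centers).max()
            centers = new_centers
            if shift < tol:
                break
        d2 = _sq_distances(X, centers)
        m = _memberships_from_distances(d2, q)
        trace.append(float((m**q * d2).sum()))
        model = FCMModel(centers=centers, fuzzifier=q, objective_trace=trace,
                         seed=seed + r, tol=tol)
        if best is None or trace[-1] < best.objective_trace[-1]:
            best = model
    return best


def membership(x: np.ndarray, model: FCMModel) -> np.ndarray:
    """Membership vector of one point (or matrix of points) in the fitted
    clusters; rows sum to 1."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != model.centers.shape[1]:
        raise ContractError(
            f"dimension mismatch: point has {X.shape[1]} features, model "
            f"expects {model.centers.shape[1]}"
        )
    m = _memberships_from_distances(_sq_distances(X, model.centers),
                                    model.fuzzifier)
    return m[0] if single else m


def defuzz_fit(model: FCMModel, X: np.ndarray, labels: np.ndarray,
               smoothing: float = 1.0,
               classes: np.ndarray | None = None) -> DefuzzModel:
    """Build the Bayesian cluster -> class model from labelled training data.

    Each training point is assigned to its maximum-membership cluster; the
    smoothed class composition of each cluster gives the likelihoods, and
    priors proportional to class mass complete Bayes' rule.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if len(labels) != len(X):
        raise ContractError("labels must align with training points")
    if classes is None:
        classes = np.unique(labels)
    c = model.n_clusters
    m = np.atleast_2d(membership(X, model))
    hard = np.argmax(m, axis=1)
    counts = np.zeros((len(classes), c))
    for i, cls_ in enumerate(classes):
        sel = labels == cls_
        if not sel.any():
            raise ContractError(f"class {cls_!r} has no training points")
        counts[i] = np.bincount(hard[sel], minlength=c)
    class_totals = counts.sum(axis=1)
    conditionals = (counts + smoothing) / (class_totals[:, None] + smoothing * c)
    priors = class_totals / class_totals.sum()
    joint = conditionals * priors[:, None]
    col_mass = joint.sum(axis=0)
    col_mass[col_mass == 0] = 1.0
    posteriors = joint / col_mass
    return DefuzzModel(classes=np.asarray(classes), conditionals=conditionals,
                       priors=priors, posteriors=posteriors, smoothing=smoothing)


def predict_posteriors(X: np.ndarray, model: FCMModel, defuzz: DefuzzModel
                       ) -> np.ndarray:
    """Class-posterior matrix (n x n_classes): memberships mixed through the
    per-cluster class posteriors, renormalized."""
    m = np.atleast_2d(membership(np.atleast_2d(X), model))
    post = m @ defuzz.posteriors.T
    total = post.sum(axis=1, keepdims=True)
    total[total == 0] = 1.0
    return post / total


# ---------------------------------------------------------------------------
# classifier wrapper (standardization + FCM + defuzzification)

@dataclass
class FCMClassifierConfig:
    n_clusters: int = DEFAULT_N_CLUSTERS
    fuzzifier: float = DEFAULT_FUZZIFIER
    tol: float = 1e-5
    max_iter: int = 300
    n_restarts: int = DEFAULT_RERUNS
    smoothing: float = 1.0


class FCMClassifier:
    """End-to-end cell classifier: z-score standardization, fuzzy C-means,
    Bayesian defuzzification.

    Features are standardized with training-split statistics because the raw
    morphometric features span several orders of magnitude and the cluster
    distances are scale-sensitive.
    """

    def __init__(self, config: FCMClassifierConfig | None = None, seed: int = 0,
                 feature_names: list[str] | None = None):
        self.config = config or FCMClassifierConfig()
        self.seed = seed
        self.feature_names = feature_names
        self.model: FCMModel | None = None
        self.defuzz: DefuzzModel | None = None
        self.mean_: np.ndarray | None = None
        self.std_: np.ndarray | None = None

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.std_

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FCMClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.mean_ = X.mean(axis=0)
        std = X.std(axis=0)
        std[std == 0] = 1.0
        self.std_ = std
        Z = self._standardize(X)
        cfg = self.config
        self.model = fcm_fit(Z, c=cfg.n_clusters, q=cfg.fuzzifier, tol=cfg.tol,
                             max_iter=cfg.max_iter, seed=self.seed,
                             n_restarts=cfg.n_restarts)
        self.defuzz = defuzz_fit(self.model, Z, y, smoothing=cfg.smoothing)
        return self

    def _check_fitted(self):
        if self.model is None or self.defuzz is None:
            raise ContractError("classifier is not fitted")

    def predict_posteriors(self, X: np.ndarray) -> np.ndarray:
        self._check_fitted()
        Z = self._standardize(np.atleast_2d(np.asarray(X, dtype=float)))
        return predict_posteriors(Z, self.model, self.defuzz)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Argmax class per row; ties resolved by class declaration order."""
        post = self.predict_posteriors(X)
        return self.defuzz.classes[np.argmax(post, axis=1)]

    def predict_binary(self, X: np.ndarray) -> list[str]:
        return [binary_label(CellClass(c)) for c in self.predict(X)]

    def abnormal_score(self, X: np.ndarray) -> np.ndarray:
        """Posterior probability mass on the abnormal classes (ROC score)."""
        post = self.predict_posteriors(X)
        abnormal = np.array([binary_label(CellClass(c)) == "ABNORMAL"
                             for c in self.defuzz.classes])
        return post[:, abnormal].sum(axis=1)

    def save(self, path) -> None:
        self._check_fitted()
        joblib.dump({"version": 1, "config": self.config, "seed": self.seed,
                     "feature_names": self.feature_names, "model": self.model,
                     "defuzz": self.defuzz, "mean": self.mean_,
                     "std": self.std_}, path)

    @classmethod
    def load(cls, path) -> "FCMClassifier":
        d = joblib.load(path)
        obj = cls(config=d["config"], seed=d["seed"],
                  feature_names=d["feature_names"])
        obj.model, obj.defuzz = d["model"], d["defuzz"]
        obj.mean_, obj.std_ = d["mean"], d["std"]
        return obj


def table_to_xy(df: pd.DataFrame, subset: list[str] | None = None
                ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Split a labelled feature table into (X, y, used feature names).

    Rows with missing values in the chosen feature columns (cells without an
    attached cytoplasm) are dropped rather than imputed.
    """
    if LABEL_COLUMN not in df.columns:
        raise DataError(f"feature table has no '{LABEL_COLUMN}' column")
    names = subset or FEATURE_NAMES
    unknown = set(names) - set(df.columns)
    if unknown:
        raise DataError(f"unknown feature names: {sorted(unknown)}")
    sub = df[names + [LABEL_COLUMN]].dropna()
    vals = sub[LABEL_COLUMN].to_numpy()
    if all(isinstance(v, str) and v in CellClass.__members__ for v in vals):
        y = np.array([CellClass[v].value for v in vals])
    else:  # generic labels (e.g. bench tables); kept as-is
        y = vals
    return sub[names].to_numpy(dtype=float), y, list(names)


def choose_cluster_count(df: pd.DataFrame, candidates: list[int],
                         k: int = 10, seed: int = 0,
                         subset: list[str] | None = None,
                         base_config: FCMClassifierConfig | None = None
                         ) -> ClusterCountReport:
    """Cross-validation error as a function of the cluster count; the chosen
    count minimizes the error (ties go to the smallest count)."""
    from .feature_selection import wrapper_fitness  # circular at module level

    if not candidates:
        raise ContractError("need at least one candidate cluster count")
    base = base_config or FCMClassifierConfig()
    errors = []
    for c in candidates:
        cfg = FCMClassifierConfig(
            n_clusters=c, fuzzifier=base.fuzzifier, tol=base.tol,
            max_iter=base.max_iter, n_restarts=base.n_restarts,
            smoothing=base.smoothing,
        )
        errors.append(wrapper_fitness(df, subset=subset, k=k, seed=seed,
                                      clf_config=cfg))
    chosen = candidates[int(np.argmin(errors))]
    return ClusterCountReport(candidates=list(candidates), cv_errors=errors,
                              chosen=chosen)


def screen_slide(cell_classes, min_abnormal: int = 1) -> SlideDiagnosis:
    """Slide-level diagnosis: positive iff at least ``min_abnormal`` cells are
    abnormal."""
    counts: dict[str, int] = {}
    n_abnormal = 0
    cells = list(cell_classes)
    for c in cells:
        cls_ = CellClass(c)
        counts[cls_.name] = counts.get(cls_.name, 0) + 1
        if binary_label(cls_) == "ABNORMAL":
            n_abnormal += 1
    return SlideDiagnosis(positive=n_abnormal >= min_abnormal,
                          n_abnormal=n_abnormal, n_cells=len(cells),
                          class_counts=counts)
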