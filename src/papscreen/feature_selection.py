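"""Wrapper feature selection by simulated annealing.

Feature subsets are scored by the stratified k-fold cross-validated
misclassification rate of the downstream fuzzy C-means classifier (the
classifier is the black box of the wrapper).  Simulated annealing searches
the subset lattice: a move flips one uniformly chosen feature bit (redrawn if
it would empty the subset), improvements are always accepted, and a worse
subset is accepted with probability exp(-delta_error / T) under a geometric
cooling schedule.  The best subset ever visited is returned together with the
full trace.  Fitness evaluations use one fixed CV seed, so the fitness is a
deterministic function of the subset and the whole search is reproducible.

``REFERENCE_SELECTED_FEATURES`` ships the 18-feature operating subset used by
the reference tool; a fresh search on other data is seed- and data-dependent
and need not reproduce it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from ._errors import ContractError
from .cell_features import FEATURE_NAMES
from .fcm_classifier import FCMClassifier, FCMClassifierConfig, table_to_xy

#: the 18-feature reference subset (nucleus-dominated; shipped as a default)
REFERENCE_SELECTED_FEATURES: list[str] = [
    "nucleus_area",
    "nucleus_gray_level",
    "nucleus_shortest_diameter",
    "nucleus_longest_diameter",
    "nucleus_perimeter",
    "nucleus_maxima",
    "nucleus_minima",
    "cytoplasm_area",
    "cytoplasm_gray_level",
    "cytoplasm_perimeter",
    "nc_ratio",
    "nucleus_eccentricity",
    "nucleus_std",
    "nucleus_variance",
    "nucleus_entropy",
    "nucleus_relative_position",
    "nucleus_mean",
    "nucleus_energy",
]


@dataclass(frozen=True)
class SAConfig:
    """Annealing schedule and cross-validation settings."""

    t_initial: float = 1.0
    cooling: float = 0.95
    moves_per_temperature: int = 20
    t_min: float = 1e-3
    k_folds: int = 10
    reruns: int = 60
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.cooling < 1):
            raise ContractError("cooling factor must be in (0, 1)")
        if self.k_folds < 2:
            raise ContractError("need at least 2 folds")


@dataclass
class SATraceEntry:
    subset: tuple[int, ...]
    fitness: float
    temperature: float
    accepted: bool


@dataclass
class SelectionResult:
    feature_names: list[str]
    best_subset: np.ndarray       # boolean mask over feature_names
    best_fitness: float
    trace: list[SATraceEntry] = field(default_factory=list)

    @property
    def selected(self) -> list[str]:
        return [n for n, b in zip(self.feature_names, self.best_subset) if b]

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "fitness": self.best_fitness,
            "n_evaluated": len(self.trace),
        }


def wrapper_fitness(df: pd.DataFrame, subset=None, k: int = 10, seed: int = 0,
                    clf_config: FCMClassifierConfig | None = None,
                    feature_names: list[str] | None = None) -> float:
    """Stratified k-fold CV misclassification rate of the FCM classifier
    restricted to ``subset`` (a boolean mask over ``feature_names`` or a list
    of column names; None = all features)."""
    universe = feature_names or [n for n in FEATURE_NAMES if n in df.columns]
    if subset is None:
        names = list(universe)
    elif isinstance(subset, (list, tuple)) and subset and isinstance(subset[0], str):
        names = list(subset)
    else:
        mask = np.asarray(subset, dtype=bool)
        names = [n for n, b in zip(universe, mask) if b]
    if not names:
        raise ContractError("feature subset is empty")
    X, y, _ = table_to_xy(df, subset=names)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ContractError(
            f"stratified {k}-fold CV needs at least {k} members per class "
            f"(smallest class has {counts.min()})"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    wrong = 0
    for train_idx, test_idx in skf.split(X, y):
        clf = FCMClassifier(config=clf_config, seed=seed)
        clf.fit(X[train_idx], y[train_idx])
        pred = clf.predict(X[test_idx])
        wrong += int((pred != y[test_idx]).sum())
    return wrong / len(y)


def sa_select(df: pd.DataFrame, cfg: SAConfig | None = None,
              clf_config: FCMClassifierConfig | None = None,
              feature_names: list[str] | None = None,
              initial_subset: np.ndarray | None = None) -> SelectionResult:
    """Simulated-annealing subset search; returns the best-ever subset.

    Single-bit neighbourhood moves, geometric cooling T <- cooling * T after
    ``moves_per_temperature`` proposals, acceptance exp(-delta/T) for worse
    moves.  Deterministic under ``cfg.seed``; fitness values are cached per
    subset.
    """
    cfg = cfg or SAConfig()
    universe = feature_names or [n for n in FEATURE_NAMES if n in df.columns]
    n_feat = len(universe)
    if "label" not in df.columns or df["label"].nunique() < 2:
        raise ContractError("selection needs a labelled table with >= 2 classes")
    rng = np.random.default_rng(cfg.seed)

    cache: dict[tuple[int, ...], float] = {}

    def fitness(mask: np.ndarray) -> float:
        key = tuple(int(b) for b in mask)
        if key not in cache:
            cache[key] = wrapper_fitness(df, subset=mask, k=cfg.k_folds,
                                         seed=cfg.seed, clf_config=clf_config,
                                         feature_names=universe)
        return cache[key]

    current = (np.ones(n_feat, dtype=bool) if initial_subset is None
               else np.asarray(initial_subset, dtype=bool).copy())
    if not current.any():
        raise ContractError("initial subset is empty")
    cur_fit = fitness(current)
    best, best_fit = current.copy(), cur_fit
    trace = [SATraceEntry(tuple(int(b) for b in current), cur_fit,
                          cfg.t_initial, True)]

    t = cfg.t_initial
    while t >= cfg.t_min:
        for _ in range(cfg.moves_per_temperature):
            while True:
                flip = int(rng.integers(n_feat))
                cand = current.copy()
                cand[flip] = ~cand[flip]
                if cand.any():
                    break
            cand_fit = fitness(cand)
            delta = cand_fit - cur_fit
            accept = delta <= 0 or rng.random() < np.exp(-delta / max(t, 1e-300))
            trace.append(SATraceEntry(tuple(int(b) for b in cand), cand_fit,
                                      t, bool(accept)))
            if accept:
                current, cur_fit = cand, cand_fit
                if cur_fit < best_fit:
                    best, best_fit = current.copy(), cur_fit
        t *= cfg.cooling

    return SelectionResult(feature_names=list(universe), best_subset=best,
                           best_fitness=best_fit, trace=trace)


def selection_frequency(df: pd.DataFrame, cfg: SAConfig | None = None,
                        clf_config: FCMClassifierConfig | None = None,
                        reruns: int | None = None,
                        feature_names: list[str] | None = None
                        ) -> pd.Series:
    """Subset-stability report: fraction of independent SA reruns (differing
    only in seed) that select each feature."""
    cfg = cfg or SAConfig()
    n = reruns if reruns is not None else cfg.reruns
    universe = feature_names or [c for c in FEATURE_NAMES if c in df.columns]
    counts = np.zeros(len(universe))
    for r in range(n):
        run_cfg = SAConfig(t_initial=cfg.t_initial, cooling=cfg.cooling,
                           moves_per_temperature=cfg.moves_per_temperature,
                           t_min=cfg.t_min, k_folds=cfg.k_folds,
                           reruns=1, seed=cfg.seed + r)
        res = sa_select(df, run_cfg, clf_config, feature_names=universe)
        counts += res.best_subset
    return pd.Series(counts / n, index=universe, name="selection_frequency")
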