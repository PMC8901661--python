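"""Permuted discriminant function analysis (pDFA) with a control factor.

Plain discriminant analysis on repeated calls from the same animals
pseudoreplicates: calls from one pig are not independent, so classification
"success" can reflect pig identity rather than the factor of interest.  The
pDFA addresses this for incomplete crossed designs:

* a *balanced derivation subset* draws the same number of calls from every
  (pig x test-level) cell that is large enough, so no pig or level
  dominates the discriminant functions;
* all remaining complete-case calls form the holdout, whose accuracy is
  the *cross-classification*;
* the null distribution permutes test-factor labels **within pigs only**
  (pigs observed at a single level keep their labels), so the permutations
  preserve the control-factor structure;
* the *chance level* is the mean permuted accuracy, and the p-value is the
  +1-corrected fraction of permutations at or above the observed
  statistic.

The reported percentages average ``n_selection_reps`` balanced re-draws;
the p-value compares a single balanced draw with true labels against
single-draw permutations, so observed and permuted statistics are
exchangeable under the null (an averaged observed statistic would have
less selection noise than the permuted ones and break the test's
calibration).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

__all__ = ["PdfaDesign", "PdfaResult", "build_cells", "balanced_selection",
           "dfa_classify", "run_pdfa"]

DEFAULT_FEATURES = ("Dur", "AmpModRate", "Q50", "WienEntropy")


@dataclass
class PdfaDesign:
    features: tuple = DEFAULT_FEATURES
    test_factor: str = "valence"  # "valence" | "context"
    control_factor: str = "pig_id"
    n_selection_reps: int = 100
    n_permutations: int = 1000
    min_calls_per_cell: int = 2
    ridge_rel: float = 1e-6
    rng_seed: int = 0

    def validate(self, features_table: pd.DataFrame | None = None) -> None:
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if self.min_calls_per_cell < 1:
            raise ValueError("min_calls_per_cell must be >= 1")
        if features_table is not None:
            missing = [f for f in self.features if f not in features_table.columns]
            if missing:
                raise ValueError(f"features not in table: {missing}")


@dataclass
class PdfaResult:
    test_factor: str
    n_levels: int
    n_individuals: int
    n_calls_total: int
    n_calls_selected: int
    n_dropped_incomplete: int
    pct_classified: float
    chance_classified: float
    p_classified: float
    pct_cross_classified: float
    chance_cross_classified: float
    p_cross: float
    provenance: dict = field(default_factory=dict)

    @property
    def relative_cross(self) -> float:
        return self.pct_cross_classified / self.chance_cross_classified


@dataclass
class CellMap:
    """Complete-case calls grouped by (pig, test level)."""

    X: np.ndarray  # n x d feature matrix
    labels: np.ndarray  # test-level codes, n
    pigs: np.ndarray  # pig codes, n
    level_names: list
    pig_names: list
    cells: dict  # (pig code, level code) -> index array
    crossed_pigs: set  # pig codes spanning >= 2 levels
    n_dropped: int


def build_cells(features: pd.DataFrame, design: PdfaDesign) -> CellMap:
    """Drop incomplete rows, encode labels, and index calls by cell."""
    design.validate(features)
    cols = list(design.features)
    complete = features.dropna(subset=cols)
    n_dropped = len(features) - len(complete)
    levels = sorted(complete[design.test_factor].astype(str).unique())
    if len(levels) < 2:
        raise ValueError("need >= 2 test-factor levels")
    pigs = sorted(complete[design.control_factor].astype(str).unique())
    lcode = {l: i for i, l in enumerate(levels)}
    pcode = {p: i for i, p in enumerate(pigs)}
    y = complete[design.test_factor].astype(str).map(lcode).to_numpy()
    g = complete[design.control_factor].astype(str).map(pcode).to_numpy()
    X = complete[cols].to_numpy(float)
    cells: dict = {}
    for i in range(len(y)):
        cells.setdefault((g[i], y[i]), []).append(i)
    cells = {k: np.array(v) for k, v in cells.items()}
    pig_levels: dict = {}
    for (p, l) in cells:
        pig_levels.setdefault(p, set()).add(l)
    crossed = {p for p, ls in pig_levels.items() if len(ls) >= 2}
    return CellMap(X=X, labels=y, pigs=g, level_names=levels, pig_names=pigs,
                   cells=cells, crossed_pigs=crossed, n_dropped=n_dropped)


def _cells_from_labels(cm: CellMap, labels: np.ndarray) -> dict:
    cells: dict = {}
    for i in range(labels.size):
        cells.setdefault((cm.pigs[i], labels[i]), []).append(i)
    return {k: np.array(v) for k, v in cells.items()}


def balanced_selection(cells: dict, design: PdfaDesign, rng: np.random.Generator,
                       n_total: int | None = None):
    """Draw the balanced derivation subset; everything else is holdout.

    Every cell holding at least ``min_calls_per_cell`` calls contributes
    exactly that many (without replacement); calls from smaller cells all
    go to the holdout.  Raises if some test level has fewer than two
    eligible cells.
    """
    m = design.min_calls_per_cell
    eligible = {k: idx for k, idx in cells.items() if idx.size >= m}
    per_level: dict = {}
    for (p, l), idx in eligible.items():
        per_level.setdefault(l, []).append(idx)
    levels_present = {l for (_, l) in cells}
    for l in levels_present:
        if len(per_level.get(l, [])) < 2:
            raise ValueError(f"test level {l} has < 2 eligible cells")
    deriv = []
    for key in sorted(eligible):
        idx = eligible[key]
        deriv.append(rng.choice(idx, size=m, replace=False))
    deriv = np.sort(np.concatenate(deriv))
    if n_total is None:
        n_total = int(max(i.max() for i in cells.values())) + 1
    holdout = np.setdiff1d(np.arange(n_total), deriv)
    return deriv, holdout


def dfa_classify(X_deriv, y_deriv, X_hold, y_hold, ridge_rel=1e-6):
    """Linear discriminant classification with equal priors.

    Class means and a pooled within-class covariance are estimated on the
    derivation set; each call is assigned to the nearest class mean in the
    whitened (Mahalanobis) metric, which with equal priors is exactly the
    linear discriminant rule.  A singular pooled covariance is
    ridge-regularized with a warning.  Returns percent correct on the
    derivation and holdout sets.
    """
    X_deriv = np.asarray(X_deriv, float)
    classes = np.unique(y_deriv)
    if classes.size < 2:
        raise ValueError("derivation set needs >= 2 levels")
    n, d = X_deriv.shape
    if n <= d + classes.size:
        raise ValueError("derivation set too small for the feature count")
    means = np.stack([X_deriv[y_deriv == c].mean(axis=0) for c in classes])
    pooled = np.zeros((d, d))
    for j, c in enumerate(classes):
        diff = X_deriv[y_deriv == c] - means[j]
        pooled += diff.T @ diff
    pooled /= n - classes.size
    try:
        chol = np.linalg.cholesky(pooled)
        if np.linalg.cond(pooled) > 1e10:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("singular pooled covariance; ridge-regularizing")
        pooled = pooled + (ridge_rel * np.trace(pooled) / d + 1e-300) * np.eye(d)
        chol = np.linalg.cholesky(pooled)

    def predict(X):
        # squared Mahalanobis distance to each class mean
        d2 = np.empty((X.shape[0], classes.size))
        for j in range(classes.size):
            w = solve_triangular(chol, (X - means[j]).T, lower=True)
            d2[:, j] = np.sum(w**2, axis=0)
        return classes[np.argmin(d2, axis=1)]

    pct_deriv = 100.0 * np.mean(predict(X_deriv) == y_deriv)
    pct_hold = 100.0 * np.mean(predict(np.asarray(X_hold, float)) == np.asarray(y_hold)) if len(y_hold) else float("nan")
    return float(pct_deriv), float(pct_hold)


def _permute_within_pigs(cm: CellMap, rng: np.random.Generator) -> np.ndarray:
    """Shuffle test labels within each pig's calls (control-factor-restricted)."""
    labels = cm.labels.copy()
    for p in cm.crossed_pigs:
        idx = np.flatnonzero(cm.pigs == p)
        labels[idx] = labels[idx[rng.permutation(idx.size)]]
    return labels


def _select_and_classify(cm: CellMap, labels, cells, design, rng):
    deriv, hold = balanced_selection(cells, design, rng, n_total=cm.labels.size)
    return dfa_classify(cm.X[deriv], labels[deriv], cm.X[hold], labels[hold],
                        ridge_rel=design.ridge_rel)


def run_pdfa(features: pd.DataFrame, design: PdfaDesign) -> PdfaResult:
    """Full pDFA: observed statistics, permutation null, chance levels, p-values."""
    rng = np.random.default_rng(design.rng_seed)
    cm = build_cells(features, design)
    cells_obs = cm.cells

    obs_deriv, obs_hold = [], []
    for _ in range(design.n_selection_reps):
        pd_, ph_ = _select_and_classify(cm, cm.labels, cells_obs, design, rng)
        obs_deriv.append(pd_)
        obs_hold.append(ph_)
    # single-draw observed statistic, exchangeable with the permuted draws
    obs_deriv_single, obs_hold_single = obs_deriv[0], obs_hold[0]

    perm_deriv = np.empty(design.n_permutations)
    perm_hold = np.empty(design.n_permutations)
    for b in range(design.n_permutations):
        for _attempt in range(20):
            labels_b = _permute_within_pigs(cm, rng)
            cells_b = _cells_from_labels(cm, labels_b)
            try:
                perm_deriv[b], perm_hold[b] = _select_and_classify(
                    cm, labels_b, cells_b, design, rng)
                break
            except ValueError:
                continue
        else:
            raise RuntimeError("could not find a valid permutation layout")

    n_sel = design.min_calls_per_cell * sum(
        1 for idx in cells_obs.values() if idx.size >= design.min_calls_per_cell)
    nperm = design.n_permutations
    result = PdfaResult(
        test_factor=design.test_factor,
        n_levels=len(cm.level_names),
        n_individuals=len(cm.pig_names),
        n_calls_total=int(cm.labels.size),
        n_calls_selected=int(n_sel),
        n_dropped_incomplete=int(cm.n_dropped),
        pct_classified=float(np.mean(obs_deriv)),
        chance_classified=float(np.mean(perm_deriv)),
        p_classified=float((np.sum(perm_deriv >= obs_deriv_single) + 1) / (nperm + 1)),
        pct_cross_classified=float(np.mean(obs_hold)),
        chance_cross_classified=float(np.mean(perm_hold)),
        p_cross=float((np.sum(perm_hold >= obs_hold_single) + 1) / (nperm + 1)),
        provenance={
            "rng_seed": design.rng_seed,
            "n_selection_reps": design.n_selection_reps,
            "n_permutations": nperm,
            "min_calls_per_cell": design.min_calls_per_cell,
            "features": list(design.features),
        },
    )
    return result
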