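"""Molecular descriptors: computation, preprocessing, and RFECV selection.

Descriptors are numeric features of a chemical structure (topological
indices, surface areas, counts...) used as regression inputs for CCS
prediction.  The backend is RDKit's 2-D descriptor catalogue (~210
descriptors); the catalogue name and version are recorded with every
matrix so models stay auditable across backend upgrades.

Preprocessing removes non-differential (zero-variance) columns, imputes
missing cells with K nearest neighbours and Z-scores each column, storing
the training statistics so future query compounds are normalized
identically.

Selection is recursive feature elimination driven by LASSO coefficient
magnitudes, repeated over random subsamples of the training set (50-90%
fractions); descriptors kept in more than 70% of replications survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import rdkit
from rdkit.Chem import Descriptors as _RD
from sklearn.impute import KNNImputer
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold, cross_val_predict

from ccsatlas.chemio import mol_from_structure

__all__ = [
    "DEFAULT_PANEL",
    "DescriptorPreprocessor",
    "SelectionResult",
    "compute_descriptors",
    "descriptor_catalogue",
    "preprocess",
    "rfecv_select",
]

#: Compact default panel of size/shape/polarity descriptors for building a
#: model without running the full RFECV selection (15 names, mirroring the
#: dimensionality the selection typically converges to).
DEFAULT_PANEL = [
    "MolWt", "HeavyAtomCount", "NumRotatableBonds", "TPSA", "MolLogP",
    "NumHAcceptors", "NumHDonors", "RingCount", "FractionCSP3", "LabuteASA",
    "BalabanJ", "Chi0v", "Chi1v", "Kappa2", "MolMR",
]


def descriptor_catalogue() -> list[str]:
    """Names of all descriptors the backend can compute."""
    return [name for name, _ in _RD.descList]


def compute_descriptors(
    structures, ids=None, subset: list[str] | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Compute a descriptor matrix (one row per structure).

    Returns ``(matrix, failures)`` where ``failures`` lists the ids of
    structures that did not parse; they are reported, never silently
    dropped.  Non-finite descriptor values become NaN (missing).
    """
    structures = list(structures)
    ids = list(ids) if ids is not None else [str(i) for i in range(len(structures))]
    names = subset or descriptor_catalogue()
    funcs = dict(_RD.descList)
    rows, kept_ids, failures = [], [], []
    for sid, smi in zip(ids, structures):
        mol = mol_from_structure(smi)
        if mol is None:
            failures.append(sid)
            continue
        row = {}
        for name in names:
            try:
                value = funcs[name](mol)
            except Exception:
                value = np.nan
            row[name] = value if np.isfinite(value) else np.nan
        rows.append(row)
        kept_ids.append(sid)
    if not rows:
        raise ValueError("no structure could be parsed")
    matrix = pd.DataFrame(rows, index=kept_ids, columns=names)
    matrix.attrs["backend"] = f"rdkit-{rdkit.__version__}"
    return matrix, failures


@dataclass
class DescriptorPreprocessor:
    """Z-scoring + KNN imputation with stored training statistics."""

    n_neighbors: int = 5
    columns: list[str] = field(default_factory=list)
    means: pd.Series | None = None
    sds: pd.Series | None = None

    def fit(self, matrix: pd.DataFrame) -> "DescriptorPreprocessor":
        sds = matrix.std(ddof=0)
        # non-differential = zero variance (or entirely missing)
        keep = sds[(sds > 0) & matrix.notna().any()].index
        dropped = [c for c in matrix.columns if c not in set(keep)]
        if dropped:
            import warnings

            warnings.warn(f"dropping {len(dropped)} non-differential/empty descriptor(s)")
        self.columns = list(keep)
        self.means = matrix[self.columns].mean()
        self.sds = matrix[self.columns].std(ddof=0)
        self._imputer = KNNImputer(n_neighbors=min(self.n_neighbors, len(matrix)))
        self._imputer.fit((matrix[self.columns] - self.means) / self.sds)
        return self

    def transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        z = (matrix[self.columns] - self.means) / self.sds
        values = self._imputer.transform(z)
        return pd.DataFrame(values, index=matrix.index, columns=self.columns)


def preprocess(
    matrix: pd.DataFrame, n_neighbors: int = 5
) -> tuple[pd.DataFrame, DescriptorPreprocessor]:
    """Drop zero-variance columns, KNN-impute, Z-score; returns the clean
    matrix and the fitted preprocessor for reuse on query compounds."""
    prep = DescriptorPreprocessor(n_neighbors=n_neighbors).fit(matrix)
    return prep.transform(matrix), prep


# ---------------------------------------------------------------------------
# RFECV selection
# ---------------------------------------------------------------------------


@dataclass
class SelectionResult:
    selected: list[str]
    frequencies: pd.Series
    config: dict

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def median_relative_error(y_true, y_pred) -> float:
    """Median of |pred - true| / |true| * 100 (the MRE criterion, %)."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    denom = np.maximum(np.abs(y_true), 1e-12)
    return float(np.median(np.abs(y_pred - y_true) / denom) * 100.0)


def _rfe_best_subset(
    X: np.ndarray, y: np.ndarray, columns, folds: int, rng, size_tolerance_pct: float = 5.0
) -> list:
    """One recursive-elimination pass: drop the descriptor with the
    smallest |LASSO coefficient| one at a time, score every subset size by
    k-fold CV (median relative error), and return the most parsimonious
    subset scoring within ``size_tolerance_pct`` % of the best -- near-tied
    scores must not keep uninformative descriptors alive."""
    active = list(range(X.shape[1]))
    trace: list[tuple[float, list[int]]] = []
    while active:
        Xa = X[:, active]
        alpha = LassoCV(cv=3, alphas=20, random_state=0, max_iter=5000).fit(Xa, y).alpha_
        model = Lasso(alpha=alpha, max_iter=5000)
        cv = KFold(n_splits=min(folds, len(y)), shuffle=True, random_state=int(rng.integers(2**31)))
        pred = cross_val_predict(model, Xa, y, cv=cv)
        trace.append((median_relative_error(y, pred), list(active)))
        if len(active) == 1:
            break
        coefs = np.abs(model.fit(Xa, y).coef_)
        active.pop(int(np.argmin(coefs)))
    best_score = min(score for score, _ in trace)
    cutoff = best_score + max(best_score * size_tolerance_pct / 100.0, 1e-12)
    best_set = min(
        (subset for score, subset in trace if score <= cutoff), key=len
    )
    return [columns[i] for i in best_set]


def rfecv_select(
    matrix: pd.DataFrame,
    targets,
    fractions=(0.5, 0.6, 0.7, 0.8, 0.9),
    reps_per_fraction: int = 200,
    folds: int = 10,
    threshold: int = 700,
    seed: int = 0,
) -> SelectionResult:
    """LASSO-driven RFECV over repeated training subsamples.

    For each fraction in ``fractions`` the training rows are subsampled
    ``reps_per_fraction`` times; each subsample is run through recursive
    elimination and the winning subset's members are tallied.  Descriptors
    with a tally above ``threshold`` (scaled proportionally when the total
    replication count differs from 1000) are selected.
    """
    y = np.asarray(targets, float)
    total = len(fractions) * reps_per_fraction
    effective_threshold = threshold * total / 1000.0
    if effective_threshold >= total:
        raise ValueError("threshold must be below the total replication count")
    rng = np.random.default_rng(seed)
    counts = pd.Series(0, index=matrix.columns, dtype=int)
    X = matrix.to_numpy()
    columns = list(matrix.columns)
    n = len(y)
    for fraction in fractions:
        for _ in range(reps_per_fraction):
            idx = rng.choice(n, size=max(int(round(fraction * n)), folds), replace=False)
            best = _rfe_best_subset(X[idx], y[idx], columns, folds, rng)
            counts[best] += 1
    selected = list(counts[counts > effective_threshold].index)
    if not selected:  # fall back to the single most frequent descriptor
        selected = [counts.idxmax()]
    return SelectionResult(
        selected=selected,
        frequencies=counts,
        config={
            "fractions": list(fractions),
            "reps_per_fraction": reps_per_fraction,
            "folds": folds,
            "threshold": threshold,
            "effective_threshold": effective_threshold,
            "total_reps": total,
            "seed": seed,
        },
    )
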