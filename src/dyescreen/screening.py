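"""Random-forest screening of dyes for high extinction coefficients.

Dyes with peak extinction coefficients above 150,000 M^-1 cm^-1 are proxies
for large transition dipole moments and hence strong exciton coupling in
DNA-templated aggregates. This module implements the screening workflow:

1. featurize SMILES into a fixed, versioned registry of 2-D descriptors
   (RDKit battery plus structural counts: maximum carbon chain length,
   aromatic ring, amide and ester counts);
2. dataset hygiene — records with epsilon above 800,000 M^-1 cm^-1 are
   excluded as gross outliers relative to the 150,000 threshold;
3. a stratified 90/10 development/validation split;
4. an "always low" majority baseline (classifying everything below
   threshold), which scores highly on the naturally imbalanced corpora and
   anchors what a trained classifier must beat;
5. random-forest Classifier and Regressor with 5-fold CV hyperparameter
   selection on the development set;
6. an imbalance sweep retraining at controlled low-class fractions;
7. ranking of prediction-only candidates by predicted epsilon.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import accuracy_score, r2_score
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold, train_test_split

from .errors import SmilesParseError, TrainingError, ValidationError

logger = logging.getLogger(__name__)

EPSILON_THRESHOLD = 150_000.0     # M^-1 cm^-1, high/low boundary
EPSILON_EXCLUDE_ABOVE = 800_000.0  # strict: records above this are dropped

REGISTRY_VERSION = "1.0"


@dataclass(frozen=True)
class MoleculeRecord:
    molecule_id: str
    smiles: str
    epsilon: float | None = None   # M^-1 cm^-1; None for prediction-only
    source_label: str = ""


# ---------------------------------------------------------------------------
# featurization
# ---------------------------------------------------------------------------

def max_carbon_chain_length(mol) -> int:
    """Longest simple path through carbon atoms, counted in atoms.

    n-hexane -> 6. Exhaustive DFS on the carbon-carbon bond subgraph;
    molecules in dye corpora are small enough for this to be instantaneous.
    """
    carbons = {a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 6}
    if not carbons:
        return 0
    adj: dict[int, list[int]] = {i: [] for i in carbons}
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in carbons and j in carbons:
            adj[i].append(j)
            adj[j].append(i)
    best = 1

    def dfs(node: int, visited: set[int], length: int) -> None:
        nonlocal best
        best = max(best, length)
        for nxt in adj[node]:
            if nxt not in visited:
                visited.add(nxt)
                dfs(nxt, visited, length + 1)
                visited.remove(nxt)

    for start in carbons:
        dfs(start, {start}, 1)
    return best


class FeatureRegistry:
    """Ordered, versioned descriptor registry.

    The four named structural counts come first, followed by the standard
    RDKit 2-D descriptor battery (~210 descriptors), for a fixed ordered
    name list shared by every record in a dataset. Descriptors that fail or
    return non-finite values are imputed as 0 (the caller gets the count).
    """

    NAMED = [
        "max_carbon_chain_length",
        "aromatic_ring_count",
        "amide_group_count",
        "ester_group_count",
    ]

    def __init__(self):
        from rdkit.Chem import Descriptors

        self.version = REGISTRY_VERSION
        self._battery = list(Descriptors.descList)
        self.names: list[str] = self.NAMED + [name for name, _ in self._battery]
        from rdkit import Chem

        self._amide = Chem.MolFromSmarts("[CX3](=O)[NX3]")
        self._ester = Chem.MolFromSmarts("[CX3](=O)[OX2][#6]")

    def __len__(self) -> int:
        return len(self.names)

    def compute(self, mol) -> tuple[np.ndarray, int]:
        """Feature vector for a parsed molecule; returns (vector, n_imputed)."""
        from rdkit.Chem import rdMolDescriptors

        values = np.empty(len(self.names))
        values[0] = max_carbon_chain_length(mol)
        values[1] = rdMolDescriptors.CalcNumAromaticRings(mol)
        values[2] = len(mol.GetSubstructMatches(self._amide))
        values[3] = len(mol.GetSubstructMatches(self._ester))
        n_imputed = 0
        for k, (_, fn) in enumerate(self._battery, start=len(self.NAMED)):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    v = float(fn(mol))
            except Exception:
                v = float("nan")
            if not np.isfinite(v):
                v = 0.0
                n_imputed += 1
            values[k] = v
        return values, n_imputed

    def featurize_smiles(self, smiles: str, molecule_id: str = "?") -> tuple[np.ndarray, int]:
        from rdkit import Chem
        from rdkit import RDLogger

        RDLogger.DisableLog("rdApp.error")
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise SmilesParseError(molecule_id, smiles)
        return self.compute(mol)


_default_registry: FeatureRegistry | None = None


def default_registry() -> FeatureRegistry:
    global _default_registry
    if _default_registry is None:
        _default_registry = FeatureRegistry()
    return _default_registry


def featurize(record: MoleculeRecord, registry: FeatureRegistry | None = None) -> pd.Series:
    """Descriptor vector for one molecule record.

    Raises :class:`SmilesParseError` (carrying the molecule id) on
    unparseable SMILES. Featurization is pure: a SMILES string always maps
    to the same vector.
    """
    registry = registry or default_registry()
    values, _ = registry.featurize_smiles(record.smiles, record.molecule_id)
    return pd.Series(values, index=registry.names, name=record.molecule_id)


def featurize_table(
    df: pd.DataFrame,
    registry: FeatureRegistry | None = None,
    on_error: str = "raise",
) -> tuple[pd.DataFrame, int, list[str]]:
    """Featurize a molecule table (columns molecule_id, smiles).

    Returns (X, n_imputed, failed_ids). ``on_error='skip'`` drops
    unparseable rows with a logged warning instead of raising.
    """
    registry = registry or default_registry()
    rows, index, failed = [], [], []
    n_imputed = 0
    for mol_id, smiles in zip(df["molecule_id"], df["smiles"]):
        try:
            vec, imp = registry.featurize_smiles(str(smiles), str(mol_id))
        except SmilesParseError:
            if on_error == "raise":
                raise
            logger.warning("skipping unparseable SMILES for molecule %s", mol_id)
            failed.append(str(mol_id))
            continue
        rows.append(vec)
        index.append(mol_id)
        n_imputed += imp
    if n_imputed:
        logger.info("imputed %d missing descriptor values as 0", n_imputed)
    X = pd.DataFrame(np.array(rows), index=index, columns=registry.names)
    return X, n_imputed, failed


# ---------------------------------------------------------------------------
# dataset hygiene, labels, splits
# ---------------------------------------------------------------------------

def apply_exclusions(
    df: pd.DataFrame, exclude_above: float = EPSILON_EXCLUDE_ABOVE
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop records with epsilon strictly above the cutoff.

    Returns (kept, excluded); the excluded frame carries a ``reason``
    column. epsilon == 800,000 is kept ("above" is strict).
    """
    if "epsilon" not in df.columns:
        raise ValidationError("molecule table must have an epsilon column")
    mask = df["epsilon"] > exclude_above
    excluded = df[mask].copy()
    excluded["reason"] = f"epsilon > {exclude_above:g}"
    return df[~mask].copy(), excluded


def label_high_low(epsilon, threshold: float = EPSILON_THRESHOLD):
    """'high' iff epsilon >= threshold (the boundary itself counts as high)."""
    arr = np.asarray(epsilon, dtype=float)
    labels = np.where(arr >= threshold, "high", "low")
    return labels if arr.ndim else str(labels)


@dataclass
class DatasetSplit:
    """Stratified development/validation split of a post-exclusion table."""

    dev: pd.DataFrame
    val: pd.DataFrame
    excluded: pd.DataFrame
    seed: int
    stratified: bool
    threshold: float = EPSILON_THRESHOLD


def split_dataset(
    df: pd.DataFrame,
    fraction: float = 0.9,
    seed: int = 0,
    stratified: bool = True,
    threshold: float = EPSILON_THRESHOLD,
    exclude_above: float = EPSILON_EXCLUDE_ABOVE,
) -> DatasetSplit:
    """Exclusions + reproducible stratified split.

    The development set holds round(fraction * N) records of the
    post-exclusion table; stratification is on the high/low label, keeping
    class fractions in each side within one record of the global fractions.
    """
    kept, excluded = apply_exclusions(df, exclude_above)
    n = len(kept)
    if n < 10:
        raise ValidationError(f"need at least 10 records to split, got {n}")
    n_dev = int(round(fraction * n))
    labels = label_high_low(kept["epsilon"], threshold)
    strat = labels if stratified else None
    if stratified and len(np.unique(labels)) < 2:
        strat = None  # degenerate single-class table; plain shuffle split
    dev, val = train_test_split(
        kept, train_size=n_dev, random_state=seed, shuffle=True, stratify=strat
    )
    return DatasetSplit(
        dev=dev,
        val=val,
        excluded=excluded,
        seed=seed,
        stratified=stratified,
        threshold=threshold,
    )


def always_low_baseline(labels) -> float:
    """Accuracy of the model that always predicts 'low'."""
    arr = np.asarray(labels)
    if arr.size == 0:
        raise ValidationError("no labels")
    return float(np.count_nonzero(arr == "low")) / arr.size


# ---------------------------------------------------------------------------
# model training
# ---------------------------------------------------------------------------

#: hyperparameter search grids; the tuned knobs are max depth, max features,
#: class weight (classifier) / split criterion (regressor)
DEFAULT_CLASSIFIER_GRID = {
    "max_depth": [8, 16, 32, None],
    "max_features": ["sqrt", 0.3, 0.5],
    "class_weight": [None, "balanced"],
}
DEFAULT_REGRESSOR_GRID = {
    "max_depth": [8, 16, 32, None],
    "max_features": ["sqrt", 0.3, 0.5],
    "criterion": ["squared_error", "absolute_error"],
}


@dataclass
class ModelReport:
    """Fitted model plus the diagnostics needed to reproduce it."""

    task: str                      # "classify" or "regress"
    hyperparameters: dict
    cv_folds: int
    metric_name: str               # "accuracy" or "r2"
    metric_dev: float              # mean CV score on the development set
    metric_validation: float
    threshold: float
    seed: int
    registry_version: str
    grid: dict
    n_dev: int
    n_val: int
    model: object = field(repr=False, default=None)

    def save(self, path) -> None:
        import joblib

        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ModelReport":
        import joblib

        return joblib.load(path)


def _features_for(
    split: DatasetSplit, features: pd.DataFrame | None, registry: FeatureRegistry | None
):
    if features is None:
        all_records = pd.concat([split.dev, split.val])
        features, _, _ = featurize_table(all_records, registry)
        features.index = all_records.index
    X_dev = features.loc[split.dev.index].to_numpy()
    X_val = features.loc[split.val.index].to_numpy()
    return X_dev, X_val


def _safe_r2(y_true, y_pred) -> float:
    if np.var(np.asarray(y_true, float)) == 0:
        warnings.warn(
            "target has zero variance; R^2 reported as 0 by convention",
            stacklevel=3,
        )
        return 0.0
    return float(r2_score(y_true, y_pred))


def train_classifier(
    split: DatasetSplit,
    grid: dict | None = None,
    folds: int = 5,
    seed: int = 0,
    n_estimators: int = 100,
    features: pd.DataFrame | None = None,
    registry: FeatureRegistry | None = None,
) -> ModelReport:
    """Random-forest high/low classifier with CV hyperparameter selection.

    ``features``: optional precomputed descriptor table indexed like the
    split's records (avoids re-featurizing across sweep points).
    """
    grid = dict(grid) if grid is not None else dict(DEFAULT_CLASSIFIER_GRID)
    registry = registry or default_registry()
    y_dev = label_high_low(split.dev["epsilon"], split.threshold)
    y_val = label_high_low(split.val["epsilon"], split.threshold)
    if len(np.unique(y_dev)) < 2:
        raise TrainingError("development set contains a single class")
    X_dev, X_val = _features_for(split, features, registry)
    search = GridSearchCV(
        RandomForestClassifier(n_estimators=n_estimators, random_state=seed),
        grid,
        cv=StratifiedKFold(folds, shuffle=True, random_state=seed),
        scoring="accuracy",
        n_jobs=1,
    )
    search.fit(X_dev, y_dev)
    val_acc = float(accuracy_score(y_val, search.best_estimator_.predict(X_val)))
    return ModelReport(
        task="classify",
        hyperparameters=search.best_params_,
        cv_folds=folds,
        metric_name="accuracy",
        metric_dev=float(search.best_score_),
        metric_validation=val_acc,
        threshold=split.threshold,
        seed=seed,
        registry_version=registry.version,
        grid=grid,
        n_dev=len(split.dev),
        n_val=len(split.val),
        model=search.best_estimator_,
    )


def train_regressor(
    split: DatasetSplit,
    grid: dict | None = None,
    folds: int = 5,
    seed: int = 0,
    n_estimators: int = 100,
    features: pd.DataFrame | None = None,
    registry: FeatureRegistry | None = None,
) -> ModelReport:
    """Random-forest epsilon regressor; metric is R^2 on dev CV and validation."""
    grid = dict(grid) if grid is not None else dict(DEFAULT_REGRESSOR_GRID)
    registry = registry or default_registry()
    y_dev = split.dev["epsilon"].to_numpy(float)
    y_val = split.val["epsilon"].to_numpy(float)
    X_dev, X_val = _features_for(split, features, registry)
    if np.var(y_dev) == 0:
        warnings.warn(
            "development target has zero variance; fitting a degenerate "
            "model, R^2 reported as 0 by convention"
        )
        model = RandomForestRegressor(
            n_estimators=n_estimators, random_state=seed
        ).fit(X_dev, y_dev)
        return ModelReport(
            task="regress",
            hyperparameters={},
            cv_folds=folds,
            metric_name="r2",
            metric_dev=0.0,
            metric_validation=_safe_r2(y_val, model.predict(X_val)),
            threshold=split.threshold,
            seed=seed,
            registry_version=registry.version,
            grid=grid,
            n_dev=len(split.dev),
            n_val=len(split.val),
            model=model,
        )
    search = GridSearchCV(
        RandomForestRegressor(n_estimators=n_estimators, random_state=seed),
        grid,
        cv=KFold(folds, shuffle=True, random_state=seed),
        scoring="r2",
        n_jobs=1,
    )
    search.fit(X_dev, y_dev)
    val_r2 = _safe_r2(y_val, search.best_estimator_.predict(X_val))
    return ModelReport(
        task="regress",
        hyperparameters=search.best_params_,
        cv_folds=folds,
        metric_name="r2",
        metric_dev=float(search.best_score_),
        metric_validation=val_r2,
        threshold=split.threshold,
        seed=seed,
        registry_version=registry.version,
        grid=grid,
        n_dev=len(split.dev),
        n_val=len(split.val),
        model=search.best_estimator_,
    )


# ---------------------------------------------------------------------------
# imbalance sweep
# ---------------------------------------------------------------------------

def imbalance_sweep(
    df: pd.DataFrame,
    low_fractions: list[float],
    seed: int = 0,
    grid: dict | None = None,
    folds: int = 5,
    n_estimators: int = 100,
    features: pd.DataFrame | None = None,
    threshold: float = EPSILON_THRESHOLD,
) -> pd.DataFrame:
    """Retrain the classifier at controlled low-class fractions.

    For each requested fraction the table is subsampled (keeping as many
    records as the limiting class allows), split 90/10, and a classifier is
    trained; the "always low" baseline accuracy on the subsample is recorded
    alongside. Fraction 0.5 is the balanced dataset.
    """
    labels = label_high_low(df["epsilon"], threshold)
    low_idx = df.index[labels == "low"]
    high_idx = df.index[labels == "high"]
    rng = np.random.default_rng(seed)
    rows = []
    for frac in low_fractions:
        if not 0.0 < frac < 1.0:
            raise ValidationError(f"low fraction must be in (0, 1), got {frac}")
        n_total = min(
            int(len(low_idx) / frac), int(len(high_idx) / (1.0 - frac))
        )
        n_low = int(round(frac * n_total))
        n_high = n_total - n_low
        if n_low > len(low_idx) or n_low == 0:
            raise ValidationError(
                f"fraction {frac}: 'low' class is limiting "
                f"(need {n_low}, have {len(low_idx)})"
            )
        if n_high > len(high_idx) or n_high == 0:
            raise ValidationError(
                f"fraction {frac}: 'high' class is limiting "
                f"(need {n_high}, have {len(high_idx)})"
            )
        sub_idx = np.concatenate(
            [
                rng.choice(low_idx, n_low, replace=False),
                rng.choice(high_idx, n_high, replace=False),
            ]
        )
        sub = df.loc[sub_idx]
        baseline = always_low_baseline(label_high_low(sub["epsilon"], threshold))
        split = split_dataset(sub, seed=seed, threshold=threshold)
        sub_features = features.loc[sub_idx] if features is not None else None
        report = train_classifier(
            split,
            grid=grid,
            folds=folds,
            seed=seed,
            n_estimators=n_estimators,
            features=sub_features,
        )
        rows.append(
            {
                "low_fraction": frac,
                "n": n_total,
                "achieved_low_fraction": baseline,
                "baseline_accuracy": baseline,
                "classifier_accuracy": report.metric_validation,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# candidate ranking
# ---------------------------------------------------------------------------

def predict_and_rank(
    report: ModelReport,
    df: pd.DataFrame,
    top_n: int | None = None,
    registry: FeatureRegistry | None = None,
) -> pd.DataFrame:
    """Rank prediction-only molecules by predicted epsilon, descending.

    Ties are broken by molecule_id; unparseable SMILES are skipped with a
    logged warning. Entries with predicted epsilon below the report's
    threshold get ``below_threshold = True``.
    """
    if report.task != "regress":
        raise ValidationError("ranking requires a trained regressor report")
    X, _, failed = featurize_table(df, registry, on_error="skip")
    if len(X) == 0:
        raise ValidationError("no parseable molecules to rank")
    pred = report.model.predict(X.to_numpy())
    out = pd.DataFrame(
        {
            "molecule_id": [str(i) for i in X.index],
            "predicted_epsilon": pred,
        }
    )
    out["below_threshold"] = out["predicted_epsilon"] < report.threshold
    out = out.sort_values(
        ["predicted_epsilon", "molecule_id"], ascending=[False, True]
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    if top_n is not None:
        out = out.head(top_n)
    if failed:
        logger.warning("skipped %d unparseable molecules", len(failed))
    return out
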