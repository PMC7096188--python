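"""Cross-validated regression engine and the 7 x 6 benchmark grid.

The central object is :class:`CVRegressor`, a model built from a feature
matrix, a target vector and a :class:`ModelConfig`; ``fit()`` trains one
regressor per cross-validation fold and returns a :class:`CVResults`
carrying the fold models, out-of-fold predictions, per-fold metrics and a
``summary()`` table.  Prediction on new data averages the fold models'
outputs, so exactly the trained artifacts are reused for external
validation.

Fold assignment uses an internal, fully specified PRNG (splitmix64 driving
a Fisher-Yates shuffle) rather than delegating to an ML library, so fold
membership is bit-reproducible across library versions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from .evaluate import MetricSet, metrics

logger = logging.getLogger(__name__)

DEFAULT_SEED = 24
DEFAULT_K = 5

MODEL_FAMILIES = (
    "random_forest",
    "svr_default",
    "svr_gamma_auto",
    "mlp_500_500",
    "mlp_500_500_es",
    "mlp_250_250_250_es",
    "gradient_boosting",
)


@dataclass
class ModelConfig:
    """A named regressor configuration.

    The seven families mirror the benchmark: a 1000-tree random forest,
    two support-vector configurations (default kernel parameters, and
    gamma='auto'), three multilayer perceptrons ((500,500) without and with
    early stopping, (250,250,250) with early stopping — early stopping holds
    out 10% of the training rows and stops after 10 epochs without an
    improvement above 0.001), and gradient boosting at library defaults.
    ``hyperparameters`` overrides individual constructor arguments.
    """

    family: str = "random_forest"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = DEFAULT_SEED
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; "
                             f"expected one of {MODEL_FAMILIES}")

    def build(self):
        """Instantiate a fresh, unfitted scikit-learn-style regressor."""
        from sklearn.ensemble import RandomForestRegressor
        from sklearn.neural_network import MLPRegressor
        from sklearn.svm import SVR
        from xgboost import XGBRegressor

        family = self.family
        if family == "random_forest":
            params = dict(n_estimators=1000, random_state=self.seed,
                          n_jobs=self.n_jobs)
        elif family == "svr_default":
            params = dict(cache_size=4096)
        elif family == "svr_gamma_auto":
            params = dict(cache_size=4096, gamma="auto")
        elif family == "mlp_500_500":
            params = dict(hidden_layer_sizes=(500, 500), random_state=self.seed)
        elif family == "mlp_500_500_es":
            params = dict(hidden_layer_sizes=(500, 500), early_stopping=True,
                          validation_fraction=0.1, tol=1e-3, n_iter_no_change=10,
                          random_state=self.seed)
        elif family == "mlp_250_250_250_es":
            params = dict(hidden_layer_sizes=(250, 250, 250), early_stopping=True,
                          validation_fraction=0.1, tol=1e-3, n_iter_no_change=10,
                          random_state=self.seed)
        else:  # gradient_boosting
            params = dict(random_state=self.seed, n_jobs=self.n_jobs)
        params.update(self.hyperparameters)
        if family == "random_forest":
            return RandomForestRegressor(**params)
        if family.startswith("svr"):
            return SVR(**params)
        if family.startswith("mlp"):
            return MLPRegressor(**params)
        return XGBRegressor(**params)


# ---------------------------------------------------------------------------
# internal fold PRNG
# ---------------------------------------------------------------------------

_MASK64 = (1 << 64) - 1


def _splitmix64(state: int) -> tuple[int, int]:
    state = (state + 0x9E3779B97F4A7C15) & _MASK64
    z = state
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    return state, (z ^ (z >> 31)) & _MASK64


def make_folds(n: int, k: int = DEFAULT_K, seed: int = DEFAULT_SEED) -> np.ndarray:
    """Assign ``n`` rows to ``k`` shuffled, near-equal folds.

    Deterministic given ``seed``: a splitmix64 stream drives a Fisher-Yates
    shuffle of the row indices, which are then dealt into k contiguous
    blocks whose sizes differ by at most one.
    """
    if n < k:
        raise ValueError(f"need at least k={k} rows, got n={n}")
    order = np.arange(n)
    state = seed & _MASK64
    for i in range(n - 1, 0, -1):
        state, draw = _splitmix64(state)
        j = draw % (i + 1)
        order[i], order[j] = order[j], order[i]
    assignment = np.empty(n, dtype=np.int64)
    base, extra = divmod(n, k)
    start = 0
    for fold in range(k):
        size = base + (1 if fold < extra else 0)
        assignment[order[start:start + size]] = fold
        start += size
    return assignment


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class CVRegressor:
    """A k-fold cross-validated regressor over a fixed design matrix.

    Parameters
    ----------
    X : (n, p) array
        Feature matrix (no NaN/Inf).
    y : (n,) array
        Targets (pKa values in log units).
    config : ModelConfig
        Which regressor family and hyperparameters to train.
    k : int
        Number of folds (default 5).
    column_manifest : list of str, optional
        Names of the feature columns; stored with the results so that
        serialized bundles can verify prediction-time feature layouts.
    """

    def __init__(self, X, y, config: ModelConfig | None = None,
                 k: int = DEFAULT_K, column_manifest: list[str] | None = None):
        self.X = np.asarray(X, dtype=np.float64)
        self.y = np.asarray(y, dtype=np.float64)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X must be 2-D with one target per row")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.y))):
            raise ValueError("X and y must be finite")
        self.config = config or ModelConfig()
        self.k = k
        self.column_manifest = column_manifest

    @classmethod
    def from_entries(cls, entries, feature_config: str = "desc+fp_scaled",
                     config: ModelConfig | None = None, k: int = DEFAULT_K):
        """Build the model from curated entries via a feature configuration."""
        from .featurize import FeatureMatrix
        fm = FeatureMatrix.from_entries(entries)
        model = cls(fm.get(feature_config), [e.pka for e in entries],
                    config=config, k=k)
        model._feature_matrix = fm
        model._feature_config = feature_config
        return model

    def fit(self) -> "CVResults":
        """Train the k fold models and collect out-of-fold predictions."""
        folds = make_folds(len(self.y), self.k, self.config.seed)
        fold_models: list = []
        oof = np.full(len(self.y), np.nan)
        fold_metrics: list[MetricSet] = []
        for fold in range(self.k):
            test_mask = folds == fold
            model = self.config.build()
            model.fit(self.X[~test_mask], self.y[~test_mask])
            pred = np.asarray(model.predict(self.X[test_mask]), dtype=np.float64)
            if not np.all(np.isfinite(pred)):
                raise FloatingPointError(
                    f"fold {fold} produced non-finite predictions "
                    f"({self.config.family}); training diverged")
            oof[test_mask] = pred
            fold_models.append(model)
            fold_metrics.append(metrics(self.y[test_mask], pred))
        return CVResults(model=self, fold_assignment=folds,
                         fold_models=fold_models, oof_predictions=oof,
                         fold_metrics=fold_metrics)


@dataclass
class CVResults:
    """Results of fitting a :class:`CVRegressor`.

    Carries the trained fold models, the fold assignment, one out-of-fold
    prediction per row, and per-fold MAE/RMSE/r2.  ``predict`` on new data
    returns the arithmetic mean of the k fold models' outputs.
    """

    model: CVRegressor
    fold_assignment: np.ndarray
    fold_models: list
    oof_predictions: np.ndarray
    fold_metrics: list[MetricSet]

    @property
    def k(self) -> int:
        return len(self.fold_models)

    def metric_summary(self) -> dict[str, float]:
        """Mean and SD (population convention) of each metric across folds."""
        out = {}
        for name in ("mae", "rmse", "r2"):
            values = np.array([getattr(m, name) for m in self.fold_metrics])
            out[f"{name}_mean"] = float(values.mean())
            out[f"{name}_std"] = float(values.std())
        return out

    def oof_metrics(self) -> MetricSet:
        """Pooled metrics over all out-of-fold predictions."""
        return metrics(self.model.y, self.oof_predictions)

    def predict(self, X) -> np.ndarray:
        """Mean of the k fold models' predictions for new rows."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.model.X.shape[1]:
            raise ValueError(
                f"feature count mismatch: model expects {self.model.X.shape[1]} "
                f"columns, got {X.shape[1] if X.ndim == 2 else 'non-2D input'}")
        preds = np.stack([np.asarray(m.predict(X), dtype=np.float64)
                          for m in self.fold_models])
        return preds.mean(axis=0)

    def summary(self) -> str:
        s = self.metric_summary()
        lines = [
            f"{self.k}-fold cross-validated {self.model.config.family} "
            f"(seed={self.model.config.seed})",
            f"  n = {len(self.model.y)}, p = {self.model.X.shape[1]}",
            f"  MAE  = {s['mae_mean']:.3f} +/- {s['mae_std']:.3f}",
            f"  RMSE = {s['rmse_mean']:.3f} +/- {s['rmse_std']:.3f}",
            f"  r2   = {s['r2_mean']:.3f} +/- {s['r2_std']:.3f}",
        ]
        return "\n".join(lines)

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        """Serialize a versioned bundle (fold models + manifest + config)."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.fold_models, path / "fold_models.joblib")
        np.save(path / "fold_assignment.npy", self.fold_assignment)
        np.save(path / "oof_predictions.npy", self.oof_predictions)
        meta = {
            "format_version": 1,
            "family": self.model.config.family,
            "seed": self.model.config.seed,
            "k": self.k,
            "n_features": int(self.model.X.shape[1]),
            "column_manifest": self.model.column_manifest,
            "feature_config": getattr(self.model, "_feature_config", None),
            "metrics": self.metric_summary(),
        }
        (path / "bundle.json").write_text(json.dumps(meta, indent=2))
        fm = getattr(self.model, "_feature_matrix", None)
        fc = getattr(self.model, "_feature_config", None)
        if fm is not None and fc in fm.scaling:
            state = fm.scaling[fc]
            np.savez(path / "scaling.npz", mean=state.mean, sd=state.sd)

    @staticmethod
    def load(path) -> "LoadedBundle":
        return LoadedBundle(Path(path))


class LoadedBundle:
    """A deserialized model bundle: predicts without retraining."""

    def __init__(self, path: Path):
        self.path = Path(path)
        self.meta = json.loads((self.path / "bundle.json").read_text())
        self.fold_models = joblib.load(self.path / "fold_models.joblib")
        scaling_file = self.path / "scaling.npz"
        self.scaling = None
        if scaling_file.exists():
            data = np.load(scaling_file)
            from .featurize import ScalingState
            self.scaling = ScalingState(mean=data["mean"], sd=data["sd"])

    @property
    def feature_config(self) -> str | None:
        return self.meta.get("feature_config")

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.meta["n_features"]:
            raise ValueError(
                f"feature count mismatch: bundle expects "
                f"{self.meta['n_features']} columns, got {X.shape[1]}")
        preds = np.stack([np.asarray(m.predict(X), dtype=np.float64)
                          for m in self.fold_models])
        return preds.mean(axis=0)

    def predict_mols(self, mols) -> np.ndarray:
        """Featurize molecules per the bundle's configuration and predict."""
        from .featurize import FeatureMatrix
        fc = self.feature_config
        if fc is None:
            raise ValueError("bundle carries no feature configuration")
        fm = FeatureMatrix.from_mols(mols)
        base = fc.removesuffix("_scaled")
        raw = {"desc": fm.descriptors, "fp": fm.fingerprints,
               "desc+fp": np.hstack([fm.descriptors, fm.fingerprints])}[base]
        if fc.endswith("_scaled"):
            if self.scaling is None:
                raise ValueError("bundle is scaled but has no scaling state")
            raw = self.scaling.apply(raw)
        return self.predict(raw)


# ---------------------------------------------------------------------------
# the benchmark grid
# ---------------------------------------------------------------------------

def run_grid(entries, families=MODEL_FAMILIES, feature_configs=None,
             seed: int = DEFAULT_SEED, k: int = DEFAULT_K, n_jobs: int = 1,
             hyperparameters: dict | None = None) -> pd.DataFrame:
    """Train every (family, feature configuration) cell with k-fold CV.

    Returns a DataFrame with one row per cell: fold-mean and fold-SD of
    MAE, RMSE and r2.  A cell whose training fails (e.g. a network
    diverging on unscaled wide-range descriptors) is recorded as
    unavailable (NaN metrics, ``available=False``), never a crash.
    """
    from .featurize import FEATURE_CONFIGS, FeatureMatrix
    feature_configs = feature_configs or FEATURE_CONFIGS
    fm = FeatureMatrix.from_entries(entries)
    y = np.array([e.pka for e in entries])
    rows = []
    for family in families:
        for fc in feature_configs:
            config = ModelConfig(family=family, seed=seed, n_jobs=n_jobs,
                                 hyperparameters=dict(hyperparameters or {}))
            row = {"family": family, "features": fc, "available": True}
            try:
                X = fm.get(fc)
                results = CVRegressor(X, y, config=config, k=k).fit()
                row.update(results.metric_summary())
            except Exception as exc:
                logger.warning("grid cell (%s, %s) unavailable: %s",
                               family, fc, exc)
                row["available"] = False
                for name in ("mae", "rmse", "r2"):
                    row[f"{name}_mean"] = np.nan
                    row[f"{name}_std"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)
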