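"""Metrics, external-test evaluation, inter-source concordance and
dataset characterization.

Two r-squared conventions coexist here on purpose.  Model evaluation uses
the empirical coefficient of determination, 1 - SS_res/SS_tot, which may be
negative for a poor model.  Cross-source concordance instead reports the
squared Pearson correlation, which is symmetric in the two sources — there
is no "observed" side when comparing two experimental datasets.  Both are
exposed; each report says which it used.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .chem_io import CuratedEntry

DISCORDANCE_CUT = 2.0  # log units; strict > comparison


@dataclass
class MetricSet:
    """MAE, RMSE and coefficient of determination, all in log units.

    Invariants: rmse >= mae >= 0; r2 <= 1 and may be negative.
    """

    mae: float
    rmse: float
    r2: float
    n: int = 0

    def __str__(self) -> str:
        return (f"MAE={self.mae:.3f}, RMSE={self.rmse:.3f}, "
                f"r2={self.r2:.3f} (n={self.n})")


def metrics(observed, predicted) -> MetricSet:
    """MAE, RMSE and the empirical coefficient of determination.

    r2 = 1 - sum((o-p)^2) / sum((o-mean(o))^2).  With zero variance in the
    observed values r2 is undefined and reported as NaN with a warning.
    """
    o = np.asarray(observed, dtype=np.float64)
    p = np.asarray(predicted, dtype=np.float64)
    if o.shape != p.shape or o.ndim != 1 or o.size == 0:
        raise ValueError("observed and predicted must be equal-length, "
                         "non-empty 1-D arrays")
    residuals = o - p
    mae = float(np.mean(np.abs(residuals)))
    rmse = float(np.sqrt(np.mean(residuals ** 2)))
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("observed values have zero variance; r2 undefined",
                      stacklevel=2)
        r2 = math.nan
    else:
        r2 = 1.0 - float(np.sum(residuals ** 2)) / ss_tot
    return MetricSet(mae=mae, rmse=rmse, r2=r2, n=o.size)


def pearson_r2(a, b) -> float:
    """Squared Pearson correlation — the symmetric r2 flavour."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.std() == 0.0 or b.std() == 0.0:
        warnings.warn("zero variance on one side; Pearson r2 undefined",
                      stacklevel=2)
        return math.nan
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def evaluate_external(cv_results, test_entries: list[CuratedEntry],
                      train_entries: list[CuratedEntry] | None = None,
                      feature_config: str | None = None,
                      train_features=None) -> MetricSet:
    """Predict an external test set with the CV fold-model ensemble.

    Enforces (not assumes) train/test disjointness by canonical SMILES when
    the training entries are supplied, raising with the offending SMILES.
    ``train_features`` (the training FeatureMatrix) supplies the scaling
    state for scaled feature configurations.
    """
    if train_entries is not None:
        overlap = ({e.canonical_smiles for e in test_entries}
                   & {e.canonical_smiles for e in train_entries})
        if overlap:
            raise ValueError(
                f"test set shares {len(overlap)} structures with training: "
                f"{sorted(overlap)[:5]}")
    from .featurize import FeatureMatrix
    fc = feature_config or getattr(cv_results.model, "_feature_config", None)
    if fc is None:
        raise ValueError("feature_config is required when the model was not "
                         "built from entries")
    fm_test = FeatureMatrix.from_entries(test_entries)
    source = train_features or getattr(cv_results.model, "_feature_matrix", None)
    if fc.endswith("_scaled"):
        if source is None:
            raise ValueError("scaled feature configuration needs the training "
                             "feature matrix for its scaling state")
        X = fm_test.transform_like(fc, source)
    else:
        X = fm_test.get(fc)
    predictions = cv_results.predict(X)
    return metrics([e.pka for e in test_entries], predictions)


@dataclass
class ConcordanceReport:
    """Matched-pair comparison of pKa values across two sources."""

    pairs: list[tuple[str, float, float]]
    metrics: MetricSet
    pearson_r2: float
    discordant: list[tuple[str, float, float]] = field(default_factory=list)
    cut: float = DISCORDANCE_CUT

    @property
    def n_matched(self) -> int:
        return len(self.pairs)

    def __str__(self) -> str:
        lines = [f"{self.n_matched} matched molecules: {self.metrics} "
                 f"(Pearson r2={self.pearson_r2:.3f})",
                 f"{len(self.discordant)} pairs deviate by more than "
                 f"{self.cut:g} log units:"]
        for smiles, a, b in self.discordant:
            lines.append(f"  {smiles}: {a:g} vs {b:g} (|d|={abs(a - b):.3f})")
        return "\n".join(lines)


def concordance(entries_a: list[CuratedEntry], entries_b: list[CuratedEntry],
                discordance_cut: float = DISCORDANCE_CUT) -> ConcordanceReport:
    """Inner-join two curated sets on canonical SMILES and compare pKa values.

    MAE/RMSE treat side A as observed and side B as predicted (they are
    symmetric anyway); the correlation reported is the squared Pearson so
    the report is direction-symmetric.  Discordant pairs (|difference|
    strictly greater than the cut) are sorted by |difference| descending.
    """
    by_a = {e.canonical_smiles: e.pka for e in entries_a}
    by_b = {e.canonical_smiles: e.pka for e in entries_b}
    shared = sorted(by_a.keys() & by_b.keys())
    pairs = [(s, by_a[s], by_b[s]) for s in shared]
    if not pairs:
        warnings.warn("no shared structures between the two sources",
                      stacklevel=2)
        return ConcordanceReport(pairs=[], discordant=[],
                                 metrics=MetricSet(math.nan, math.nan,
                                                   math.nan, 0),
                                 pearson_r2=math.nan, cut=discordance_cut)
    a = [p[1] for p in pairs]
    b = [p[2] for p in pairs]
    discordant = sorted(
        (p for p in pairs if abs(p[1] - p[2]) > discordance_cut),
        key=lambda p: abs(p[1] - p[2]), reverse=True)
    return ConcordanceReport(pairs=pairs, metrics=metrics(a, b),
                             pearson_r2=pearson_r2(a, b),
                             discordant=discordant, cut=discordance_cut)


def method_agreement(pairs: list[tuple[float, float]]) -> MetricSet:
    """Agreement between two experimental methods on the same molecules.

    ``pairs`` are (method-A value, method-B value) tuples; fewer than three
    pairs is refused because a correlation over one or two points is
    meaningless.
    """
    if len(pairs) < 3:
        raise ValueError(
            f"need at least 3 method-annotated pairs, got {len(pairs)}; "
            "a correlation over fewer points is not meaningful")
    a = [p[0] for p in pairs]
    b = [p[1] for p in pairs]
    result = metrics(a, b)
    result.r2 = pearson_r2(a, b)  # symmetric: neither method is "observed"
    return result


@dataclass
class DatasetSummary:
    """Characterization of a curated dataset: size, MW/logP spread,
    scaffold diversity and the pKa histogram."""

    n: int
    mw_min: float
    mw_max: float
    mw_mean: float
    mw_sd: float
    logp_min: float
    logp_max: float
    logp_mean: float
    logp_sd: float
    n_scaffolds: int
    pka_hist_edges: np.ndarray
    pka_hist_counts: np.ndarray

    def __str__(self) -> str:
        return (f"{self.n} molecules; MW {self.mw_min:.0f}-{self.mw_max:.0f} "
                f"(mean {self.mw_mean:.2f}, sd {self.mw_sd:.2f}); "
                f"logP {self.logp_min:.2f}-{self.logp_max:.2f} "
                f"(mean {self.logp_mean:.2f}, sd {self.logp_sd:.2f}); "
                f"{self.n_scaffolds} unique Murcko scaffolds")


def dataset_summary(entries: list[CuratedEntry],
                    hist_bin_width: float = 0.5) -> DatasetSummary:
    """Count, MW and logP statistics, scaffold count, pKa histogram.

    SDs use the sample (n-1) convention.  Histogram bins are ``hist_bin_width``
    log units wide, spanning the observed pKa range.
    """
    if not entries:
        raise ValueError("cannot summarize an empty dataset")
    from rdkit.Chem import Descriptors
    from .featurize import murcko_scaffold
    mw = np.array([Descriptors.MolWt(e.mol) for e in entries])
    logp = np.array([Descriptors.MolLogP(e.mol) for e in entries])
    pka = np.array([e.pka for e in entries])
    scaffolds = {murcko_scaffold(e.mol) for e in entries}
    lo = math.floor(pka.min() / hist_bin_width) * hist_bin_width
    hi = math.ceil(pka.max() / hist_bin_width) * hist_bin_width
    n_bins = max(1, round((hi - lo) / hist_bin_width))
    counts, edges = np.histogram(pka, bins=n_bins, range=(lo, hi))
    ddof = 1 if len(entries) > 1 else 0
    return DatasetSummary(
        n=len(entries),
        mw_min=float(mw.min()), mw_max=float(mw.max()),
        mw_mean=float(mw.mean()), mw_sd=float(mw.std(ddof=ddof)),
        logp_min=float(logp.min()), logp_max=float(logp.max()),
        logp_mean=float(logp.mean()), logp_sd=float(logp.std(ddof=ddof)),
        n_scaffolds=len(scaffolds),
        pka_hist_edges=edges, pka_hist_counts=counts,
    )
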