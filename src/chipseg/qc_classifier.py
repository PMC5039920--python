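"""All-or-none quality control of a discretization with an RBF-kernel SVM.

Five summary statistics of a finished discretization separate usable
profiles from noisy or irreproducible ones:

* ``q_high_to_low`` -- the transition probability from the high to the
  low state (large values mean fragmented, short-lived targets);
* ``min_snr`` -- the minimum over replicates of the ratio between the
  high-state and medium-state emission rates (signal-to-noise);
* ``target_fraction`` -- the fraction of windows called as targets;
* ``var_explained`` -- the fraction of variance of the per-window mean
  ChIP count explained by the called states (between-state over total
  sum of squares);
* ``replicate_correlation`` -- the mean pairwise Pearson correlation of
  the ChIP count columns.

A support vector machine with a radial basis function kernel is trained
on a balanced labeled corpus and tuned by grid search under stratified
10-fold cross-validation; the verdict is issued for the profile as a
whole at the SVM's natural zero margin.

The corpus that ships with the package is generated by the simulator:
positives are discretizations of replicated profiles with genuine
enrichment, negatives are either profiles with no enrichment treated as
ChIP or pairs of non-replicates (profiles enriched at unrelated target
sets) treated as replicates.  The bundled model is trained on this
synthetic corpus only -- it is not a classifier trained on experimental
data.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .hmm_engine import HIGH, HMMFit, discretize
from .io_binning import CountMatrix
from .simulator import SimConfig, default_truth_params, simulate

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_NAMES",
    "QCFeatures",
    "QCModel",
    "QCVerdict",
    "extract_features",
    "build_training_corpus",
    "train_qc",
    "classify",
    "load_default_model",
]

FEATURE_NAMES = (
    "q_high_to_low",
    "min_snr",
    "target_fraction",
    "var_explained",
    "replicate_correlation",
)


@dataclass(frozen=True)
class QCFeatures:
    q_high_to_low: float
    min_snr: float
    target_fraction: float
    var_explained: float
    replicate_correlation: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in FEATURE_NAMES])


@dataclass
class QCModel:
    """Trained RBF-SVM with its feature scaling, persisted as JSON.

    The decision function is evaluated directly from the stored support
    vectors: f(x) = sum_i a_i exp(-gamma ||sv_i - z||^2) + b with z the
    standardized feature vector; f > 0 means accept.
    """

    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    gamma: float
    C: float
    meta: dict = None

    def decision_value(self, features: np.ndarray) -> float:
        z = (np.asarray(features, dtype=float) - self.scaler_mean) / self.scaler_scale
        d2 = ((self.support_vectors - z) ** 2).sum(axis=1)
        return float(self.dual_coef @ np.exp(-self.gamma * d2) + self.intercept)

    def save(self, path) -> None:
        payload = {
            "format_version": 1,
            "feature_names": list(FEATURE_NAMES),
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "gamma": self.gamma,
            "C": self.C,
            "meta": self.meta or {},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "QCModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format_version") != 1:
            raise ValueError("unsupported QC model format")
        return cls(
            scaler_mean=np.array(payload["scaler_mean"]),
            scaler_scale=np.array(payload["scaler_scale"]),
            support_vectors=np.array(payload["support_vectors"]),
            dual_coef=np.array(payload["dual_coef"]),
            intercept=float(payload["intercept"]),
            gamma=float(payload["gamma"]),
            C=float(payload["C"]),
            meta=payload.get("meta"),
        )


@dataclass(frozen=True)
class QCVerdict:
    accepted: bool
    decision_value: float
    features: QCFeatures


def load_default_model() -> QCModel:
    """The bundled model, trained on the package's synthetic corpus."""
    from importlib.resources import as_file, files

    resource = files("chipseg").joinpath("data/qc_model.json")
    with as_file(resource) as path:
        return QCModel.load(path)


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def extract_features(fit: HMMFit, counts: CountMatrix) -> QCFeatures:
    """Five QC summary statistics of a finished discretization."""
    order = fit.state_order
    raw_of_role = np.empty_like(order)
    raw_of_role[order] = np.arange(order.size)
    low_raw, med_raw, high_raw = raw_of_role[0], raw_of_role[1], raw_of_role[2]

    q_high_to_low = float(fit.params.Q[high_raw, low_raw])

    rate_high = fit.params.emissions[high_raw].means()
    rate_med = fit.params.emissions[med_raw].means()
    min_snr = float(np.min(rate_high / rate_med))

    roles = fit.role_path
    all_zero = counts.counts.sum(axis=1) == 0
    target_fraction = float(((roles == HIGH) & ~all_zero).mean())

    Y = counts.chip_counts.astype(float)
    var_explained = _between_over_total(Y.mean(axis=1), roles)

    r = Y.shape[1]
    if r < 2:
        warnings.warn(
            "replicate correlation is only meaningful with >= 2 chip "
            "profiles; reporting the sentinel 1.0"
        )
        replicate_correlation = 1.0
    else:
        cors = []
        for i, j in itertools.combinations(range(r), 2):
            with np.errstate(invalid="ignore"):
                c = np.corrcoef(Y[:, i], Y[:, j])[0, 1]
            cors.append(0.0 if not np.isfinite(c) else float(c))
        replicate_correlation = float(np.mean(cors))

    return QCFeatures(
        q_high_to_low=q_high_to_low,
        min_snr=min_snr,
        target_fraction=target_fraction,
        var_explained=var_explained,
        replicate_correlation=replicate_correlation,
    )


def _between_over_total(x: np.ndarray, groups: np.ndarray) -> float:
    grand = x.mean()
    total = ((x - grand) ** 2).sum()
    if total <= 0:
        return 0.0
    between = 0.0
    for g in np.unique(groups):
        sel = groups == g
        between += sel.sum() * (x[sel].mean() - grand) ** 2
    return float(between / total)


# ---------------------------------------------------------------------------
# Training corpus
# ---------------------------------------------------------------------------

_CORPUS_WINDOWS = {"chr1": 1000}


def _case_config(rng: np.random.Generator, enriched: bool) -> SimConfig:
    """One randomized corpus case; enrichment strength varies across cases."""
    alpha = rng.uniform(2.0, 4.0)
    pi = rng.uniform(0.05, 0.15)
    base = rng.uniform(1.5, 3.0)
    if enriched:
        med = base * rng.uniform(2.0, 3.5)
        high = base * rng.uniform(7.0, 14.0)
        means = (base, med, high)
    else:
        # no immunoprecipitation: ChIP indistinguishable from baseline
        means = (base, base * 1.001, base * 1.002)
    hmm = default_truth_params(pi=pi, alpha=alpha, r=2, state_means=means)
    return SimConfig(
        chrom_windows=dict(_CORPUS_WINDOWS),
        hmm=hmm,
        control_mean=rng.uniform(3.0, 5.0),
        seed=int(rng.integers(2**31)),
    )


def _discretize_case(config: SimConfig) -> QCFeatures:
    sim = simulate(config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        profile = discretize(sim.counts, max_iter=40)
    return extract_features(profile.fit, sim.counts)


def _nonreplicate_case(config_a: SimConfig, config_b: SimConfig) -> QCFeatures:
    """Two profiles enriched at unrelated target sets passed off as replicates."""
    sim_a = simulate(config_a)
    sim_b = simulate(config_b)
    counts = sim_a.counts
    mixed = counts.counts.copy()
    mixed[:, counts.chip_columns[1]] = sim_b.counts.counts[:, sim_b.counts.chip_columns[0]]
    cm = CountMatrix(
        grid=counts.grid, counts=mixed, roles=list(counts.roles)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        profile = discretize(cm, max_iter=40)
    return extract_features(profile.fit, cm)


def build_training_corpus(
    n_positive: int = 200,
    n_negative: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Labeled QC feature table from simulated discretizations.

    Positives are replicated profiles with true enrichment; negatives
    alternate between (a) enrichment-free profiles treated as ChIP and
    (b) non-replicate pairs treated as replicates.  Failed cases are
    dropped with a log message and the classes rebalanced by truncation.
    Fully deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for label, kind, count in (
        (1, "positive", n_positive),
        (0, "negative", n_negative),
    ):
        made = 0
        neg_kind_toggle = 0
        while made < count:
            try:
                if label == 1:
                    feats = _discretize_case(_case_config(rng, enriched=True))
                    subtype = "replicated"
                elif neg_kind_toggle == 0:
                    feats = _discretize_case(_case_config(rng, enriched=False))
                    subtype = "no_enrichment"
                else:
                    feats = _nonreplicate_case(
                        _case_config(rng, enriched=True),
                        _case_config(rng, enriched=True),
                    )
                    subtype = "nonreplicate"
            except (ValueError, FloatingPointError) as exc:
                logger.warning("corpus case dropped (%s): %s", kind, exc)
                continue
            finally:
                if label == 0:
                    neg_kind_toggle ^= 1
            row = {f: getattr(feats, f) for f in FEATURE_NAMES}
            row["label"] = label
            row["kind"] = subtype
            rows.append(row)
            made += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Training and prediction
# ---------------------------------------------------------------------------

DEFAULT_GRID = {
    "svc__C": [0.1, 1.0, 10.0, 100.0],
    "svc__gamma": [0.01, 0.1, 1.0, "scale"],
}


def train_qc(table: pd.DataFrame, grid=None, folds: int = 10, seed: int = 0):
    """Grid-searched RBF-SVM under stratified k-fold CV.

    Returns ``(QCModel, cv_accuracy)`` where ``cv_accuracy`` is the mean
    held-out accuracy at the selected hyperparameters; the model itself
    is refit on the full table.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = table[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = table["label"].to_numpy(dtype=int)
    counts = np.bincount(y, minlength=2)
    if np.any(counts < 2 * folds):
        raise ValueError("need at least 2 examples per class per fold")
    pipe = Pipeline([("scale", StandardScaler()), ("svc", SVC(kernel="rbf"))])
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    search = GridSearchCV(pipe, grid or DEFAULT_GRID, cv=cv, scoring="accuracy")
    search.fit(X, y)
    best = search.best_estimator_
    svc: SVC = best.named_steps["svc"]
    scaler: StandardScaler = best.named_steps["scale"]
    # sklearn's decision_function is positive for classes_[1]; flip the
    # stored coefficients if "accept" (label 1) is not that class.
    sign = 1.0 if svc.classes_[1] == 1 else -1.0
    model = QCModel(
        scaler_mean=scaler.mean_.copy(),
        scaler_scale=scaler.scale_.copy(),
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=sign * svc.dual_coef_[0].copy(),
        intercept=sign * float(svc.intercept_[0]),
        gamma=float(svc._gamma),
        C=float(svc.C),
        meta={
            "trained_on": "synthetic simulator corpus",
            "n_examples": int(len(y)),
            "cv_folds": folds,
            "cv_accuracy": float(search.best_score_),
        },
    )
    return model, float(search.best_score_)


def classify(model: QCModel, features: QCFeatures) -> QCVerdict:
    """Deterministic accept/reject verdict for the whole profile."""
    x = features.to_array()
    if not np.all(np.isfinite(x)):
        bad = FEATURE_NAMES[int(np.flatnonzero(~np.isfinite(x))[0])]
        raise ValueError(f"non-finite QC feature: {bad}")
    value = model.decision_value(x)
    return QCVerdict(accepted=value > 0, decision_value=value, features=features)
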