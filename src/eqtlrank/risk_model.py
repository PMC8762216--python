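"""Regularized logistic risk models, CV ensembles, AUC, and a reference PRS.

The predictor is a penalized logistic regression over the (filtered,
standardized) feature matrix.  Hyperparameters are tuned by repeated
stratified k-fold cross-validation maximizing out-of-fold AUC; the 50 fold
models of the winning grid point (5 repeats x 10 folds by default) form the
ensemble used for contribution-stability analysis.  A conventional polygenic
risk score (sum of GWAS log-odds times effect-allele dosage) is provided for
comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import rankdata
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import RepeatedStratifiedKFold

from .errors import DataError, PipelineError, ValidationError
from .feature_filter import filter_features
from .feature_matrix import FeatureMatrix

logger = logging.getLogger(__name__)

_SOLVER_TOL = 1e-8
_MAX_ITER = 10_000


# ---------------------------------------------------------------------------
# Hyperparameters and fitted models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HyperParams:
    """Penalty family and strength for the logistic predictor.

    ``strength`` is scikit-learn's inverse-regularization ``C`` (> 0, smaller
    = stronger penalty); ``l1_ratio`` applies to ``elastic_net`` only.
    """

    penalty: str
    strength: float
    l1_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.penalty not in ("l1", "l2", "elastic_net"):
            raise ValidationError(f"unknown penalty {self.penalty!r}")
        if not (self.strength > 0):
            raise ValidationError("regularization strength must be > 0")
        if self.penalty == "elastic_net":
            if self.l1_ratio is None or not (0.0 <= self.l1_ratio <= 1.0):
                raise ValidationError("elastic_net needs l1_ratio in [0, 1]")

    def to_dict(self) -> dict:
        return {"penalty": self.penalty, "strength": self.strength,
                "l1_ratio": self.l1_ratio}

    @classmethod
    def from_dict(cls, d: dict) -> "HyperParams":
        return cls(d["penalty"], d["strength"], d.get("l1_ratio"))


def default_grid() -> list[HyperParams]:
    """Elastic-net grid: l1_ratio {0.25, 0.5, 0.75, 1.0} x 13 strengths 1e-4..1e2."""
    return [
        HyperParams("elastic_net", float(c), r)
        for r in (0.25, 0.5, 0.75, 1.0)
        for c in np.logspace(-4, 2, 13)
    ]


def fast_grid() -> list[HyperParams]:
    """Reduced 10-point grid for desk-scale runs (pipeline default)."""
    return [
        HyperParams("elastic_net", float(c), r)
        for r in (0.5, 1.0)
        for c in np.logspace(-3, 1, 5)
    ]


@dataclass
class FittedRiskModel:
    """A fitted logistic predictor with everything needed to replay it."""

    intercept: float
    coefficients: dict[str, float]
    hyperparams: HyperParams
    train_auc: float
    feature_order: list[str]
    replay_stats: dict | None = None

    def __post_init__(self) -> None:
        if set(self.coefficients) != set(self.feature_order):
            raise ValidationError("coefficient keys must equal feature_order")

    @property
    def coef_vector(self) -> np.ndarray:
        return np.array([self.coefficients[f] for f in self.feature_order])

    @property
    def nonzero_features(self) -> list[str]:
        return [f for f in self.feature_order if self.coefficients[f] != 0.0]

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "hyperparams": self.hyperparams.to_dict(),
            "train_auc": self.train_auc,
            "feature_order": self.feature_order,
            "replay_stats": self.replay_stats,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedRiskModel":
        return cls(
            intercept=float(d["intercept"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            hyperparams=HyperParams.from_dict(d["hyperparams"]),
            train_auc=float(d["train_auc"]),
            feature_order=list(d["feature_order"]),
            replay_stats=d.get("replay_stats"),
        )


@dataclass
class ModelEnsemble:
    """The fold models of one repeated-CV run plus their out-of-fold AUCs.

    ``fold_scores`` keeps each fold's test indices and predicted scores so
    the mean/sd can be recomputed from first principles.
    """

    models: list[FittedRiskModel]
    fold_aucs: list[float]
    fold_scores: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.fold_aucs, ddof=1)) if len(self.fold_aucs) > 1 else 0.0

    def auc_range(self, lo: float = 2.5, hi: float = 97.5) -> tuple[float, float]:
        return (float(np.percentile(self.fold_aucs, lo)),
                float(np.percentile(self.fold_aucs, hi)))

    def to_dict(self) -> dict:
        return {
            "fold_aucs": [float(a) for a in self.fold_aucs],
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "models": [m.to_dict() for m in self.models],
        }


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def auc(scores, labels) -> float:
    """AUC by the rank / Mann-Whitney identity ``AUC = U / (n1 * n0)``.

    Ties contribute one half, so constant scores give exactly 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise DataError("auc: need both classes")
    ranks = rankdata(scores)
    u1 = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u1 / (n1 * n0))


def evaluate_auc(
    scores,
    labels,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """AUC with a 95% CI from a stratified bootstrap (``n_boot`` replicates).

    Cases and controls are resampled with replacement within class; the CI is
    the 2.5/97.5 percentile of the replicate AUCs.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    point = auc(scores, labels)
    s1 = scores[labels == 1]
    s0 = scores[labels == 0]
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    # chunked so the rank matrix stays modest even for large cohorts
    chunk = max(1, int(2e6 / (s1.size + s0.size)))
    y = np.concatenate([np.ones(s1.size, int), np.zeros(s0.size, int)])
    for start in range(0, n_boot, chunk):
        b = min(chunk, n_boot - start)
        rs1 = s1[rng.integers(0, s1.size, size=(b, s1.size))]
        rs0 = s0[rng.integers(0, s0.size, size=(b, s0.size))]
        allv = np.concatenate([rs1, rs0], axis=1)
        ranks = rankdata(allv, axis=1)
        u1 = ranks[:, : s1.size].sum(axis=1) - s1.size * (s1.size + 1) / 2.0
        boot[start:start + b] = u1 / (s1.size * s0.size)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return point, float(lo), float(hi)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _make_estimator(hp: HyperParams, seed: int) -> LogisticRegression:
    # scikit-learn >= 1.8 expresses the penalty family through l1_ratio
    if hp.penalty == "l2":
        return LogisticRegression(C=hp.strength, l1_ratio=0.0, solver="lbfgs",
                                  tol=_SOLVER_TOL, max_iter=_MAX_ITER)
    ratio = 1.0 if hp.penalty == "l1" else hp.l1_ratio
    return LogisticRegression(C=hp.strength, l1_ratio=ratio, solver="saga",
                              tol=_SOLVER_TOL, max_iter=_MAX_ITER,
                              random_state=seed)


def _trivial_model(labels: np.ndarray, hp: HyperParams,
                   replay_stats: dict | None) -> FittedRiskModel:
    """Intercept-only model (empty feature set or fully shrunk fit)."""
    n1 = max(int((labels == 1).sum()), 1)
    n0 = max(int((labels == 0).sum()), 1)
    return FittedRiskModel(
        intercept=float(np.log(n1 / n0)), coefficients={}, hyperparams=hp,
        train_auc=0.5, feature_order=[], replay_stats=replay_stats,
    )


def _fit(
    X: np.ndarray,
    y: np.ndarray,
    hp: HyperParams,
    feature_order: list[str],
    replay_stats: dict | None,
    seed: int,
    error_on_nonconvergence: bool,
) -> FittedRiskModel:
    if X.shape[1] == 0:
        return _trivial_model(y, hp, replay_stats)
    est = _make_estimator(hp, seed)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        est.fit(X, y)
    if any(issubclass(w.category, ConvergenceWarning) for w in caught):
        msg = (f"logistic fit did not converge at grid point {hp.to_dict()} "
               f"within {_MAX_ITER} iterations")
        if error_on_nonconvergence:
            raise PipelineError(msg)
        logger.warning(msg)
    coefs = est.coef_.ravel()
    model = FittedRiskModel(
        intercept=float(est.intercept_[0]),
        coefficients={f: float(c) for f, c in zip(feature_order, coefs)},
        hyperparams=hp,
        train_auc=auc(est.predict_proba(X)[:, 1], y),
        feature_order=list(feature_order),
        replay_stats=replay_stats,
    )
    return model


def cv_ensemble(
    fm: FeatureMatrix,
    hp: HyperParams,
    repeats: int = 5,
    folds: int = 10,
    seed: int = 0,
    filter_alpha: float | None = None,
) -> ModelEnsemble:
    """Fit ``repeats x folds`` stratified CV models at one grid point.

    Each split fits on the training fold and scores the held-out fold; the
    out-of-fold AUCs and per-fold scores are retained.  With ``filter_alpha``
    set, the Mann-Whitney/BY filter is re-run inside each training fold
    (leakage-free variant); by default the matrix is assumed pre-filtered on
    the full cohort, reproducing the standard order of operations.
    """
    X, y = fm.values, fm.labels
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise DataError("cv_ensemble: need both classes")
    if counts.min() < folds:
        raise DataError(
            f"cv_ensemble: smallest class ({counts.min()}) cannot stratify "
            f"into {folds} folds"
        )
    rskf = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats,
                                   random_state=seed % (2 ** 31))
    models: list[FittedRiskModel] = []
    fold_aucs: list[float] = []
    fold_scores: list[tuple[np.ndarray, np.ndarray]] = []
    for train_idx, test_idx in rskf.split(X, y):
        cols = np.arange(fm.n_features)
        Xtr, ytr = X[train_idx], y[train_idx]
        if filter_alpha is not None and fm.n_features:
            sub = FeatureMatrix(
                [fm.sample_ids[i] for i in train_idx], list(fm.descriptors),
                Xtr, ytr, fm.column_stats,
            )
            _, results = filter_features(sub, alpha=filter_alpha)
            cols = np.flatnonzero([r.kept for r in results])
            Xtr = Xtr[:, cols]
        order = [fm.feature_ids[j] for j in cols]
        stats = _subset_stats(fm.column_stats, cols)
        model = _fit(Xtr, ytr, hp, order, stats, seed,
                     error_on_nonconvergence=False)
        if model.feature_order:
            scores = expit(model.intercept + X[test_idx][:, cols] @ model.coef_vector)
        else:
            scores = np.full(test_idx.size, expit(model.intercept))
        models.append(model)
        fold_aucs.append(auc(scores, y[test_idx]))
        fold_scores.append((test_idx, scores))
    return ModelEnsemble(models, fold_aucs, fold_scores)


def _subset_stats(stats: dict | None, cols: np.ndarray) -> dict | None:
    if stats is None:
        return None
    return {k: [stats[k][j] for j in cols] for k in ("mean", "sd", "zero_variance")}


def tune_hyperparameters(
    fm: FeatureMatrix,
    grid: Sequence[HyperParams] | None = None,
    repeats: int = 5,
    folds: int = 10,
    seed: int = 0,
) -> tuple[HyperParams, ModelEnsemble]:
    """Pick the grid point maximizing mean out-of-fold AUC.

    Every grid point is evaluated on the *same* fold assignment (derived from
    ``seed``), so mean AUCs are directly comparable.  Ties break toward
    stronger regularization (smaller ``strength``, then larger ``l1_ratio``).
    Returns the winner and its 50-model (by default) ensemble.
    """
    if grid is None:
        grid = default_grid()
    grid = list(grid)
    if not grid:
        raise ValidationError("tune_hyperparameters: empty grid")
    results: list[tuple[float, HyperParams]] = []
    for hp in grid:
        ens = cv_ensemble(fm, hp, repeats=repeats, folds=folds, seed=seed)
        results.append((ens.mean_auc, hp))
        logger.info("tune: %s -> mean oof AUC %.4f", hp.to_dict(), ens.mean_auc)
    best_hp = sorted(
        results,
        key=lambda t: (-t[0], t[1].strength, -(t[1].l1_ratio or 0.0), t[1].penalty),
    )[0][1]
    # deterministic folds: rebuilding the winner reproduces its fold models
    best_ens = cv_ensemble(fm, best_hp, repeats=repeats, folds=folds, seed=seed)
    return best_hp, best_ens


def fit_final_model(
    fm: FeatureMatrix,
    hp: HyperParams,
    seed: int = 0,
) -> FittedRiskModel:
    """Deterministic fit on the full cohort (fixed tolerance and seed)."""
    if len(np.unique(fm.labels)) < 2:
        raise DataError("fit_final_model: need both classes")
    return _fit(fm.values, fm.labels, hp, fm.feature_ids, fm.column_stats,
                seed, error_on_nonconvergence=True)


# ---------------------------------------------------------------------------
# Scoring new cohorts
# ---------------------------------------------------------------------------

def predict_scores(
    model: FittedRiskModel,
    fm_new: FeatureMatrix,
    strict: bool = False,
) -> np.ndarray:
    """Per-sample risk scores in (0, 1) for a new cohort.

    Columns are aligned by feature id; model features absent from the cohort
    contribute a standardized value of zero (with a logged count).  The
    training-time standardization is replayed — the new cohort's statistics
    are never used.  More than 20% absent features is a warning, escalated to
    an error in ``strict`` mode.
    """
    if model.replay_stats is not None and fm_new.column_stats is not None:
        raise ValidationError(
            "predict_scores expects an unstandardized matrix; the model "
            "replays its own training statistics"
        )
    col_of = {f: j for j, f in enumerate(fm_new.feature_ids)}
    n = fm_new.n_samples
    X = np.zeros((n, len(model.feature_order)))
    missing = 0
    for k, fid in enumerate(model.feature_order):
        j = col_of.get(fid)
        if j is None:
            missing += 1
            continue
        col = fm_new.values[:, j]
        if model.replay_stats is not None:
            mean = model.replay_stats["mean"][k]
            sd = model.replay_stats["sd"][k]
            zero = model.replay_stats["zero_variance"][k]
            col = np.zeros(n) if (zero or sd == 0.0) else (col - mean) / sd
        X[:, k] = col
    if missing:
        frac = missing / max(len(model.feature_order), 1)
        msg = (f"predict_scores: {missing} of {len(model.feature_order)} model "
               f"features absent from cohort ({frac:.1%}); zero-filled")
        if frac > 0.2:
            if strict:
                raise DataError(msg)
            logger.warning(msg)
        else:
            logger.info(msg)
    if model.feature_order:
        return expit(model.intercept + X @ model.coef_vector)
    return np.full(n, expit(model.intercept))


# ---------------------------------------------------------------------------
# Conventional PRS for comparison
# ---------------------------------------------------------------------------

def compute_prs(
    gm,
    betas: Mapping[str, float],
    effect_alleles: Mapping[str, str] | None = None,
) -> np.ndarray:
    """Polygenic risk score: ``score_i = sum_s beta_s * dosage_{i,s}``.

    Dosages count the GWAS effect allele (flipped ``2 - d`` where the cohort
    counts the other declared allele); SNPs whose alleles cannot be matched
    are skipped with a log entry.  Missing dosages are mean-imputed.  No
    shrinkage and no p-value thresholding.
    """
    overlap = [s for s in gm.snp_ids if s in betas]
    if not overlap:
        raise DataError("compute_prs: no overlapping SNPs between betas and cohort")
    scores = np.zeros(gm.n_samples)
    skipped = []
    for snp in overlap:
        d = gm.snp_column(snp).copy()
        if np.isnan(d).all():
            skipped.append(snp)
            continue
        d[np.isnan(d)] = np.nanmean(d)
        if effect_alleles is not None:
            eff = effect_alleles[snp]
            if gm.counted_allele.get(snp) == eff:
                pass
            elif gm.other_allele.get(snp) == eff:
                d = 2.0 - d
            else:
                skipped.append(snp)
                continue
        scores += betas[snp] * d
    if skipped:
        logger.info("compute_prs: skipped %d SNPs (allele mismatch or all "
                    "missing)", len(skipped))
    return scores
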