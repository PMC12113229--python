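"""AUC-weighted ensemble species distribution modelling.

Three base learners — a maxent-like penalized logistic regression on a
linear + quadratic feature expansion, a random forest, and an RBF support
vector machine with Platt-scaled probabilities — are fitted on repeated
stratified 80/20 holdout rounds. Within each round the base models whose
test AUC exceeds the gate (default 0.8) are combined with weights
proportional to their AUC:

    W_i = r_i / sum_j r_j     over the gate-passing models,

and the per-round ensemble suitability rasters are averaged into the final
0-1 suitability map. Threshold-dependent metrics (TSS, kappa, omission
rate, proportion correct) are computed at the max-TSS threshold on the
evaluation set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import warnings

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .grid import EnvStack
from .synthetic import OccurrenceSet, generate_pseudo_absences

LEARNERS = ("maxent_like", "random_forest", "svm")

# layers that are plumbing, never covariates
_EXCLUDED = {"road_mask", "water_mask", "aspect"}


def model_layer_names(stack: EnvStack) -> tuple[list[str], list[str]]:
    """Default (continuous, categorical) covariate layers for modelling.

    The circular aspect layer enters through its eastness/southness
    components; binary feature masks are excluded (their distance rasters
    carry the information).
    """
    cont = [n for n in stack.continuous_names() if n not in _EXCLUDED]
    cat = [
        n
        for n in stack.names
        if stack.kinds.get(n) == "categorical" and n not in _EXCLUDED
    ]
    return cont, cat


class FeatureBuilder:
    """Maps layer-value tables to model design matrices.

    Continuous layers are standardized against their valid-grid mean/sd;
    categorical layers are one-hot encoded over their declared code lists.
    """

    def __init__(self, stack: EnvStack, continuous=None, categorical=None):
        cont_default, cat_default = model_layer_names(stack)
        self.continuous = list(continuous) if continuous is not None else cont_default
        self.categorical = list(categorical) if categorical is not None else cat_default
        self.codes = {
            n: list(stack.categories.get(n, sorted(np.unique(stack[n][stack.mask]))))
            for n in self.categorical
        }
        m = stack.mask
        self.center = {n: float(stack[n][m].mean()) for n in self.continuous}
        self.scale = {
            n: float(stack[n][m].std()) or 1.0 for n in self.continuous
        }

    @property
    def layer_names(self) -> list[str]:
        return self.continuous + self.categorical

    def matrix(self, values: pd.DataFrame) -> np.ndarray:
        """Design matrix from a table whose columns are layer values."""
        cols = []
        for n in self.continuous:
            cols.append((values[n].to_numpy(float) - self.center[n]) / self.scale[n])
        for n in self.categorical:
            v = values[n].to_numpy()
            for code in self.codes[n]:
                cols.append((v == code).astype(float))
        return np.column_stack(cols)

    def values_at_points(self, stack: EnvStack, df: pd.DataFrame) -> pd.DataFrame:
        vals = stack.values_at(
            df["x"].to_numpy(), df["y"].to_numpy(), names=self.layer_names
        )
        return pd.DataFrame(vals, columns=self.layer_names)

    def grid_values(self, stack: EnvStack) -> pd.DataFrame:
        m = stack.mask
        return pd.DataFrame(
            {n: stack[n][m] for n in self.layer_names}
        )


class _SquareExpand:
    """Appends squared columns (the quadratic features of the maxent-like
    learner); sklearn-compatible transformer."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return np.hstack([X, X ** 2])

    def get_params(self, deep=True):
        return {}

    def set_params(self, **kw):
        return self


@dataclass
class EvalMetrics:
    auc: float
    tss: float
    omission_rate: float
    prop_correct: float
    kappa: float
    threshold: float

    def as_dict(self) -> dict:
        return {
            "AUC": self.auc,
            "TSS": self.tss,
            "Omission.rate": self.omission_rate,
            "Prop.correct": self.prop_correct,
            "Kappa": self.kappa,
            "threshold": self.threshold,
        }


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> dict:
    """Threshold-dependent metrics from an explicit confusion matrix."""
    pos, neg = tp + fn, tn + fp
    if pos == 0 or neg == 0:
        raise ValueError("both classes must be present")
    sens = tp / pos
    spec = tn / neg
    n = pos + neg
    acc = (tp + tn) / n
    p_yes = ((tp + fp) / n) * (pos / n)
    p_no = ((fn + tn) / n) * (neg / n)
    pe = p_yes + p_no
    kappa = 0.0 if pe == 1.0 else (acc - pe) / (1.0 - pe)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "tss": sens + spec - 1.0,
        "omission_rate": 1.0 - sens,
        "prop_correct": acc,
        "kappa": kappa,
    }


def max_tss_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold (strict >) maximizing TSS on the given set; the lowest
    maximizing threshold wins ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    uniq = np.unique(scores)
    cands = np.concatenate(([uniq[0] - 1e-9], (uniq[:-1] + uniq[1:]) / 2.0))
    pos = labels == 1
    best_t, best_tss = cands[0], -np.inf
    for t in cands:
        pred = scores > t
        sens = (pred & pos).sum() / pos.sum()
        spec = (~pred & ~pos).sum() / (~pos).sum()
        tss = sens + spec - 1.0
        if tss > best_tss + 1e-12:
            best_tss, best_t = tss, t
    return float(best_t)


def evaluate(scores: np.ndarray, labels: np.ndarray,
             threshold: float | None = None) -> EvalMetrics:
    """Rank AUC plus max-TSS-threshold confusion metrics on a test set."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if len(np.unique(labels)) < 2:
        raise ValueError("test set must contain both classes")
    auc = float(roc_auc_score(labels, scores))
    t = max_tss_threshold(scores, labels) if threshold is None else threshold
    pred = scores > t
    pos = labels == 1
    tp = int((pred & pos).sum()); fn = int((~pred & pos).sum())
    tn = int((~pred & ~pos).sum()); fp = int((pred & ~pos).sum())
    cm = confusion_metrics(tp, fn, tn, fp)
    return EvalMetrics(
        auc=auc,
        tss=cm["tss"],
        omission_rate=cm["omission_rate"],
        prop_correct=cm["prop_correct"],
        kappa=cm["kappa"],
        threshold=float(t),
    )


def split_sample(labels: np.ndarray, train_fraction: float = 0.8,
                 n_rounds: int = 10, seed: int = 0):
    """Stratified random holdout splits, one per round.

    Yields (train_idx, test_idx) with the train fraction of each label
    class, independently resampled each round.
    """
    labels = np.asarray(labels, int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos < 5 or n_neg < 5:
        raise ValueError(
            f"need at least 5 records per class (got {n_pos} presences, "
            f"{n_neg} absences)"
        )
    splitter = StratifiedShuffleSplit(
        n_splits=n_rounds, train_size=train_fraction, random_state=seed
    )
    X_dummy = np.zeros((len(labels), 1))
    return list(splitter.split(X_dummy, labels))


def fit_base_model(kind: str, X: np.ndarray, y: np.ndarray, seed: int = 0):
    """Fit one base learner; returns an object with predict_prob(X)->[0,1]."""
    y = np.asarray(y, int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    if kind == "maxent_like":
        est = Pipeline([
            ("scale", StandardScaler()),
            ("quad", _SquareExpand()),
            ("lr", LogisticRegression(C=1.0, max_iter=2000)),
        ])
    elif kind == "random_forest":
        est = RandomForestClassifier(n_estimators=100, random_state=seed)
    elif kind == "svm":
        # Platt-scaled RBF SVM scores
        est = Pipeline([
            ("scale", StandardScaler()),
            ("svc", CalibratedClassifierCV(
                SVC(kernel="rbf", random_state=seed),
                method="sigmoid", ensemble=False,
            )),
        ])
    else:
        raise ValueError(f"unknown learner kind {kind!r}")
    est.fit(X, y)
    return _FittedBase(kind, est)


@dataclass
class _FittedBase:
    kind: str
    estimator: object

    def predict_prob(self, X: np.ndarray) -> np.ndarray:
        p = self.estimator.predict_proba(X)[:, 1]
        return np.clip(p, 0.0, 1.0)


def ensemble_weights(aucs, auc_gate: float = 0.8) -> np.ndarray:
    """Per-model weights W_i = r_i / sum r_j over models with r_i > gate;
    gated-out models get weight 0. Errors when no model passes."""
    r = np.asarray(list(aucs), float)
    if r.size == 0:
        raise ValueError("aucs is empty")
    passing = r > auc_gate
    if not passing.any():
        raise ValueError(
            f"no base model exceeds the AUC gate ({auc_gate}); max AUC was "
            f"{r.max():.3f} — consider more data or a richer covariate set"
        )
    w = np.where(passing, r, 0.0)
    return w / w.sum()


@dataclass
class RoundFit:
    round_index: int
    models: dict  # kind -> _FittedBase
    model_metrics: dict  # kind -> EvalMetrics
    weights: dict  # kind -> float (0 for gated-out models)
    ensemble_metrics: EvalMetrics

    def predict_prob(self, X: np.ndarray) -> np.ndarray:
        out = np.zeros(X.shape[0])
        for kind, w in self.weights.items():
            if w > 0:
                out += w * self.models[kind].predict_prob(X)
        return out


@dataclass
class SuitabilityMap:
    values: np.ndarray  # full grid, NaN off-mask
    spec: object  # GridSpec
    species: str
    provenance: str = "averaged"

    def valid_values(self, mask) -> np.ndarray:
        return self.values[mask]


@dataclass
class EnsembleConfig:
    learners: tuple = LEARNERS
    n_rounds: int = 10
    train_fraction: float = 0.8
    auc_gate: float = 0.8
    redraw_absences: bool = True
    with_replacement: bool = False  # bootstrap resampling instead of holdout
    seed: int = 0


@dataclass
class EnsembleFit:
    species: str
    builder: FeatureBuilder
    rounds: list
    reference_values: pd.Series  # presence-mean covariate row
    config: EnsembleConfig = field(default_factory=EnsembleConfig)

    def predict_prob(self, X: np.ndarray) -> np.ndarray:
        preds = [r.predict_prob(X) for r in self.rounds]
        return np.mean(preds, axis=0)

    def mean_metrics(self) -> EvalMetrics:
        ms = [r.ensemble_metrics for r in self.rounds]
        return EvalMetrics(
            auc=float(np.mean([m.auc for m in ms])),
            tss=float(np.mean([m.tss for m in ms])),
            omission_rate=float(np.mean([m.omission_rate for m in ms])),
            prop_correct=float(np.mean([m.prop_correct for m in ms])),
            kappa=float(np.mean([m.kappa for m in ms])),
            threshold=float(np.mean([m.threshold for m in ms])),
        )


def fit_ensemble(
    stack: EnvStack,
    presences: OccurrenceSet,
    config: EnsembleConfig | None = None,
    builder: FeatureBuilder | None = None,
    absences: OccurrenceSet | None = None,
) -> EnsembleFit:
    """Run the full multi-round ensemble fit for one species.

    Pseudo-absences are re-drawn each round by default (balanced with the
    presences); pass ``absences`` with ``redraw_absences=False`` for a fixed
    background set.
    """
    cfg = config or EnsembleConfig()
    builder = builder or FeatureBuilder(stack)
    pres_df = presences.presences()
    if len(pres_df) < 1:
        raise ValueError("no presence records supplied")
    species = str(pres_df.species.iloc[0])
    rng = np.random.default_rng(cfg.seed)
    pres_vals = builder.values_at_points(stack, pres_df)
    ref = pres_vals[builder.continuous].mean()
    for n in builder.categorical:
        ref[n] = pres_vals[n].mode().iloc[0]

    rounds = []
    for r in range(cfg.n_rounds):
        round_seed = int(rng.integers(0, 2**31 - 1))
        if absences is not None and not cfg.redraw_absences:
            abs_df = absences.absences()
        else:
            abs_df = generate_pseudo_absences(
                stack, presences, seed=round_seed
            ).absences()
        abs_vals = builder.values_at_points(stack, abs_df)
        values = pd.concat([pres_vals, abs_vals], ignore_index=True)
        y = np.concatenate([
            np.ones(len(pres_vals), int), np.zeros(len(abs_vals), int)
        ])
        X = builder.matrix(values)
        if cfg.with_replacement:
            idx = np.random.default_rng(round_seed).integers(0, len(y), len(y))
            tr, te = split_sample(y[idx], cfg.train_fraction, 1, round_seed)[0]
            tr, te = idx[tr], idx[te]
        else:
            tr, te = split_sample(y, cfg.train_fraction, 1, round_seed)[0]
        models, metrics = {}, {}
        for kind in cfg.learners:
            fit = fit_base_model(kind, X[tr], y[tr], seed=round_seed)
            models[kind] = fit
            metrics[kind] = evaluate(fit.predict_prob(X[te]), y[te])
        aucs = [metrics[k].auc for k in cfg.learners]
        try:
            w = ensemble_weights(aucs, cfg.auc_gate)
        except ValueError:
            # no learner cleared the gate on this holdout round: the round
            # contributes nothing to the ensemble (mirrors gating models
            # out of the weighted average) rather than aborting the fit
            warnings.warn(
                f"round {r}: no base model exceeds the AUC gate "
                f"({cfg.auc_gate}, max {max(aucs):.3f}); round excluded",
                stacklevel=2,
            )
            continue
        weights = dict(zip(cfg.learners, map(float, w)))
        ens_scores = np.zeros(len(te))
        for kind in cfg.learners:
            if weights[kind] > 0:
                ens_scores += weights[kind] * models[kind].predict_prob(X[te])
        rounds.append(
            RoundFit(
                round_index=r,
                models=models,
                model_metrics=metrics,
                weights=weights,
                ensemble_metrics=evaluate(ens_scores, y[te]),
            )
        )
    if not rounds:
        raise ValueError(
            f"no base model exceeds the AUC gate ({cfg.auc_gate}) in any of "
            f"{cfg.n_rounds} rounds; the ensemble cannot be built"
        )
    return EnsembleFit(
        species=species, builder=builder, rounds=rounds,
        reference_values=ref, config=cfg,
    )


def predict_ensemble(fit: EnsembleFit, stack: EnvStack) -> SuitabilityMap:
    """Averaged ensemble suitability over the whole grid."""
    missing = [n for n in fit.builder.layer_names if n not in stack]
    if missing:
        raise KeyError(f"stack is missing fitted covariates: {missing}")
    values = fit.builder.grid_values(stack)
    X = fit.builder.matrix(values)
    p = fit.predict_prob(X)
    out = np.full(stack.spec.shape, np.nan)
    out[stack.mask] = p
    return SuitabilityMap(values=out, spec=stack.spec, species=fit.species)


def variable_contribution(
    fit: EnsembleFit,
    stack: EnvStack,
    n_permutations: int = 5,
    seed: int = 0,
) -> pd.Series:
    """Permutation-based percentage contribution per reported factor.

    For each factor the layer values are permuted across valid cells, the
    ensemble map is recomputed, and the raw importance is
    1 - Pearson r(baseline map, permuted map), averaged over permutations.
    The eastness/southness pair is permuted jointly and reported as
    ``aspect``. Contributions are normalized to sum to 100.
    """
    rng = np.random.default_rng(seed)
    values = fit.builder.grid_values(stack)
    baseline = fit.predict_prob(fit.builder.matrix(values))
    if np.std(baseline) == 0:
        raise ValueError("constant prediction map; contributions undefined")

    pair = [n for n in ("eastness", "southness") if n in fit.builder.layer_names]
    factors: dict[str, list[str]] = {
        n: [n] for n in fit.builder.layer_names if n not in pair
    }
    if pair:
        factors["aspect"] = pair

    raw = {}
    n_cells = len(values)
    for name, cols in factors.items():
        acc = 0.0
        for _ in range(max(1, n_permutations)):
            perm = rng.permutation(n_cells)
            shuffled = values.copy()
            for c in cols:
                shuffled[c] = values[c].to_numpy()[perm]
            pred = fit.predict_prob(fit.builder.matrix(shuffled))
            if np.std(pred) == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(baseline, pred)[0, 1])
            acc += 1.0 - r
        raw[name] = acc / max(1, n_permutations)
    total = sum(raw.values())
    if total <= 0:
        raise ValueError("all permutation importances are zero")
    return pd.Series({k: 100.0 * v / total for k, v in raw.items()}).sort_values(
        ascending=False
    )


def response_curve(
    fit: EnsembleFit,
    stack: EnvStack,
    variable: str,
    n_points: int = 100,
) -> pd.DataFrame:
    """Ensemble occurrence probability along one continuous covariate.

    The focal variable is swept over its observed range (reported both raw
    and normalized to 0-1); every other covariate is held at its mean over
    presence cells (mode for categorical layers).
    """
    if variable not in fit.builder.continuous:
        raise KeyError(
            f"{variable!r} is not a continuous model covariate "
            f"(have {fit.builder.continuous})"
        )
    v = stack[variable][stack.mask]
    lo, hi = float(v.min()), float(v.max())
    sweep = np.linspace(lo, hi, n_points)
    table = pd.DataFrame(
        {n: np.full(n_points, fit.reference_values[n])
         for n in fit.builder.layer_names}
    )
    table[variable] = sweep
    prob = fit.predict_prob(fit.builder.matrix(table))
    norm = (sweep - lo) / (hi - lo) if hi > lo else np.zeros(n_points)
    return pd.DataFrame(
        {"value": sweep, "value_norm": norm, "probability": prob}
    )
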