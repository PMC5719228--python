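"""Evaluation metrics and the prediction-horizon experiment harness.

Metrics: auROC as the Mann-Whitney statistic (the probability a random case
outscores a random control, ties counted one half), DeLong
structural-component variance for confidence intervals and paired model
comparison, specificity at the operating point giving 80% sensitivity, and
the PPV implied by an operating point at a fixed prevalence,

    PPV = sens * p / (sens * p + (1 - spec) * (1 - p)).

Experiments mirror the study designs: single/additive/ablation feature-set
tables at one horizon, per-horizon train-and-evaluate sweeps over 1-16 h,
and the cross-horizon grid where every trained model is scored at every
horizon.  The cohort is split temporally (default 75/25 by event time,
emulating a train-on-earlier-years / evaluate-on-the-final-year design);
the feature vocabulary is fit on training instances only and frozen for
evaluation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from . import features as F
from . import models as M

logger = logging.getLogger(__name__)

DEFAULT_PREVALENCE = 0.013
DEFAULT_HP = M.ModelHyperparams(a1=0.001, a2=0.01)


@dataclass
class ROCResult:
    auroc: float
    ci95: tuple[float, float]
    spec_at_sens80: float
    ppv_at_sens80: float
    threshold: float
    n_cases: int
    n_controls: int


# ---------------------------------------------------------------------------
# Metrics


def auroc(scores_cases, scores_controls) -> float:
    """Mann-Whitney auROC: mean over case-control pairs of
    1[case > control] + 0.5 * 1[tie]."""
    cases = np.asarray(scores_cases, dtype=float)
    controls = np.asarray(scores_controls, dtype=float)
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both score groups must be nonempty")
    m, n = len(cases), len(controls)
    ranks = rankdata(np.concatenate([cases, controls]))
    return float((ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n))


def _delong_components(cases: np.ndarray, controls: np.ndarray):
    """auROC plus its per-case (V10) and per-control (V01) structural
    components."""
    m, n = len(cases), len(controls)
    tz = rankdata(np.concatenate([cases, controls]))
    tx = rankdata(cases)
    ty = rankdata(controls)
    v10 = (tz[:m] - tx) / n          # per-case components
    v01 = 1.0 - (tz[m:] - ty) / m    # per-control components
    auc = float(v10.mean())
    return auc, v10, v01


def delong_se(scores_cases, scores_controls) -> float:
    """DeLong standard error of the auROC estimate."""
    cases = np.asarray(scores_cases, dtype=float)
    controls = np.asarray(scores_controls, dtype=float)
    _, v10, v01 = _delong_components(cases, controls)
    var = (np.var(v10, ddof=1) / len(v10) if len(v10) > 1 else 0.0) + \
          (np.var(v01, ddof=1) / len(v01) if len(v01) > 1 else 0.0)
    return float(np.sqrt(var))


def delong_ci(scores_cases, scores_controls,
              level: float = 0.95) -> tuple[float, float]:
    """DeLong confidence interval, truncated to [0, 1].

    Degenerate zero-variance inputs collapse the interval to the point
    estimate (flagged with a warning).
    """
    a = auroc(scores_cases, scores_controls)
    se = delong_se(scores_cases, scores_controls)
    if se == 0.0:
        warnings.warn("zero DeLong variance; interval collapses to the "
                      "point estimate")
        return (a, a)
    z = norm.ppf(0.5 + level / 2.0)
    return (float(max(0.0, a - z * se)), float(min(1.0, a + z * se)))


def delong_test(cases_a, controls_a, cases_b, controls_b) -> tuple[float, float]:
    """Paired DeLong test for the auROC difference of two models scored on
    the same instances (cases/controls in identical order).

    Returns (auc_a - auc_b, two-sided p).  A model compared against itself
    gives difference 0 and p = 1.
    """
    cases_a = np.asarray(cases_a, dtype=float)
    controls_a = np.asarray(controls_a, dtype=float)
    cases_b = np.asarray(cases_b, dtype=float)
    controls_b = np.asarray(controls_b, dtype=float)
    if len(cases_a) != len(cases_b) or len(controls_a) != len(controls_b):
        raise ValueError("paired test requires identical instance sets")
    auc_a, v10_a, v01_a = _delong_components(cases_a, controls_a)
    auc_b, v10_b, v01_b = _delong_components(cases_b, controls_b)
    delta = auc_a - auc_b
    d10 = v10_a - v10_b
    d01 = v01_a - v01_b
    var = (np.var(d10, ddof=1) / len(d10) if len(d10) > 1 else 0.0) + \
          (np.var(d01, ddof=1) / len(d01) if len(d01) > 1 else 0.0)
    if var == 0.0:
        return (float(delta), 1.0 if delta == 0.0 else 0.0)
    z = delta / np.sqrt(var)
    return (float(delta), float(2.0 * norm.sf(abs(z))))


def spec_at_sensitivity(scores_cases, scores_controls,
                        target_sens: float = 0.80) -> tuple[float, float]:
    """Specificity at the largest cutoff whose sensitivity meets the target.

    Classification is positive at or above the cutoff; the cutoff is the
    largest value (over +inf and the observed case scores) with sensitivity
    >= ``target_sens``.  Returns (specificity, threshold).
    """
    cases = np.asarray(scores_cases, dtype=float)
    controls = np.asarray(scores_controls, dtype=float)
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both score groups must be nonempty")
    thresholds = np.concatenate([[np.inf], np.sort(np.unique(cases))[::-1]])
    for thr in thresholds:
        sens = float(np.mean(cases >= thr))
        if sens >= target_sens:
            spec = float(np.mean(controls < thr))
            return spec, float(thr)
    raise AssertionError("unreachable: the smallest case score gives "
                         "sensitivity 1")  # pragma: no cover


def estimated_ppv(sens: float, spec: float, prevalence: float) -> float:
    """PPV implied by an operating point at a given prevalence."""
    for name, v in (("sens", sens), ("spec", spec),
                    ("prevalence", prevalence)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    num = sens * prevalence
    if num == 0.0:
        return 0.0
    return num / (num + (1.0 - spec) * (1.0 - prevalence))


def evaluate_scores(scores_cases, scores_controls,
                    prevalence: float = DEFAULT_PREVALENCE,
                    target_sens: float = 0.80) -> ROCResult:
    spec, thr = spec_at_sensitivity(scores_cases, scores_controls,
                                    target_sens)
    sens = float(np.mean(np.asarray(scores_cases) >= thr))
    return ROCResult(
        auroc=auroc(scores_cases, scores_controls),
        ci95=delong_ci(scores_cases, scores_controls),
        spec_at_sens80=spec,
        ppv_at_sens80=estimated_ppv(sens, spec, prevalence),
        threshold=thr,
        n_cases=len(scores_cases),
        n_controls=len(scores_controls))


# ---------------------------------------------------------------------------
# Experiment harness


def temporal_split(cohort: pd.DataFrame,
                   frac: float = 0.75) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split the cohort by event time: the earliest ``frac`` of records
    train, the remainder evaluate."""
    cut = cohort["event_time"].quantile(frac)
    train = cohort[cohort["event_time"] <= cut]
    test = cohort[cohort["event_time"] > cut]
    return train.reset_index(drop=True), test.reset_index(drop=True)


def _instances_from_pairs(pairs, feature_sets) -> list[F.Instance]:
    return [F.Instance(encounter_id=p.encounter_id, y=p.y,
                       horizon_hours=p.horizon_hours,
                       prediction_time=p.prediction_time,
                       features=F.merge_fragments(frags, feature_sets))
            for p, frags in pairs]


def _fit_and_score(train_instances, test_instances, hp, prevalence):
    vocab = F.FeatureVocabulary.fit(train_instances)
    X_train = vocab.transform(train_instances)
    y_train = F.labels(train_instances)
    model = M.train(X_train, y_train, hp, feature_names=vocab.names,
                    vocabulary_checksum=vocab.checksum())
    X_test = vocab.transform(test_instances)
    y_test = F.labels(test_instances)
    scores = model.predict_proba(X_test)
    result = evaluate_scores(scores[y_test == 1], scores[y_test == 0],
                             prevalence=prevalence)
    return model, vocab, result


def _result_row(result: ROCResult, **extra) -> dict:
    return {**extra, "auroc": result.auroc, "ci_lo": result.ci95[0],
            "ci_hi": result.ci95[1], "spec80": result.spec_at_sens80,
            "ppv80": result.ppv_at_sens80, "n_case": result.n_cases,
            "n_control": result.n_controls}


def run_feature_set_experiments(cohort: pd.DataFrame, events,
                                horizon_hours: float = 6.0,
                                hp: M.ModelHyperparams | None = None,
                                seed: int = 0,
                                prevalence: float = DEFAULT_PREVALENCE,
                                split_frac: float = 0.75,
                                spec: F.WindowSpec | None = None,
                                binning=None) -> pd.DataFrame:
    """Single-type, additive, and ablation feature-set experiments at one
    horizon, all with shared splits and seeds."""
    hp = replace(hp or DEFAULT_HP, seed=seed)
    index = events if isinstance(events, F.EventIndex) else F.EventIndex(events)
    train_c, test_c = temporal_split(cohort, split_frac)
    pairs_train = F.featurize_cohort(train_c, index, horizon_hours, spec,
                                     binning)
    pairs_test = F.featurize_cohort(test_c, index, horizon_hours, spec,
                                    binning)

    configs: list[tuple[str, tuple[str, ...]]] = []
    for fs in F.FEATURE_SETS:                       # single-type models
        configs.append((fs, (fs,)))
    for i in range(1, len(F.FEATURE_SETS) + 1):     # additive order
        subset = F.FEATURE_SETS[:i]
        configs.append(("+".join(subset), subset))
    configs.append(("all", F.FEATURE_SETS))
    for fs in F.FEATURE_SETS:                       # ablations
        subset = tuple(s for s in F.FEATURE_SETS if s != fs)
        configs.append((f"all-{fs}", subset))

    rows = []
    for name, subset in configs:
        train_inst = _instances_from_pairs(pairs_train, subset)
        test_inst = _instances_from_pairs(pairs_test, subset)
        _, _, result = _fit_and_score(train_inst, test_inst, hp, prevalence)
        rows.append(_result_row(result, feature_set=name,
                                horizon_train=horizon_hours,
                                horizon_eval=horizon_hours))
    return pd.DataFrame(rows)


def horizon_sweep(cohort: pd.DataFrame, events, horizons=range(1, 17),
                  hp: M.ModelHyperparams | None = None, seed: int = 0,
                  prevalence: float = DEFAULT_PREVALENCE,
                  split_frac: float = 0.75,
                  spec: F.WindowSpec | None = None,
                  binning=None,
                  feature_sets=F.FEATURE_SETS) -> pd.DataFrame:
    """Train and evaluate one model per prediction horizon."""
    hp = replace(hp or DEFAULT_HP, seed=seed)
    index = events if isinstance(events, F.EventIndex) else F.EventIndex(events)
    train_c, test_c = temporal_split(cohort, split_frac)
    rows = []
    for h in horizons:
        train_inst = F.build_instances(train_c, index, float(h), spec,
                                       binning, feature_sets)
        test_inst = F.build_instances(test_c, index, float(h), spec, binning,
                                      feature_sets)
        _, _, result = _fit_and_score(train_inst, test_inst, hp, prevalence)
        rows.append(_result_row(result, feature_set="+".join(feature_sets),
                                horizon_train=float(h), horizon_eval=float(h)))
    return pd.DataFrame(rows)


def cross_horizon(cohort: pd.DataFrame, events, horizons=range(1, 17),
                  hp: M.ModelHyperparams | None = None, seed: int = 0,
                  split_frac: float = 0.75,
                  spec: F.WindowSpec | None = None,
                  binning=None) -> pd.DataFrame:
    """Evaluate every per-horizon model at every horizon.

    Returns a long-format frame (train_horizon, eval_horizon, auroc,
    n_case, n_control); the diagonal reproduces the horizon sweep.
    """
    hp = replace(hp or DEFAULT_HP, seed=seed)
    horizons = [float(h) for h in horizons]
    index = events if isinstance(events, F.EventIndex) else F.EventIndex(events)
    train_c, test_c = temporal_split(cohort, split_frac)
    train_by_h = {h: F.build_instances(train_c, index, h, spec, binning)
                  for h in horizons}
    test_by_h = {h: F.build_instances(test_c, index, h, spec, binning)
                 for h in horizons}
    rows = []
    for h_train in horizons:
        train_inst = train_by_h[h_train]
        vocab = F.FeatureVocabulary.fit(train_inst)
        model = M.train(vocab.transform(train_inst), F.labels(train_inst),
                        hp, feature_names=vocab.names)
        for h_eval in horizons:
            test_inst = test_by_h[h_eval]
            X = vocab.transform(test_inst)
            y = F.labels(test_inst)
            scores = model.predict_proba(X)
            rows.append({"train_horizon": h_train, "eval_horizon": h_eval,
                         "auroc": auroc(scores[y == 1], scores[y == 0]),
                         "n_case": int((y == 1).sum()),
                         "n_control": int((y == 0).sum())})
    return pd.DataFrame(rows)


def grid_diagonal_contrast(grid: pd.DataFrame) -> tuple[float, float]:
    """(mean diagonal auROC, mean off-diagonal auROC) of a cross-horizon
    grid."""
    diag = grid[grid["train_horizon"] == grid["eval_horizon"]]["auroc"]
    off = grid[grid["train_horizon"] != grid["eval_horizon"]]["auroc"]
    return float(diag.mean()), float(off.mean())
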