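"""Model training and the evaluation battery: CV/test AUC, sensitivity at
fixed specificity, continuous NRI with bootstrap CIs, paired model comparison.

Protocol: the cohort is split into 11 near-equal patient-level parts; part 0
is the untouched holdout test set and parts 1-10 drive 10-fold
cross-validation (fit on nine parts, score the tenth).  Code embeddings are
retrained on each fold's training patients (and on all ten CV parts for the
holdout model), so no information flows from evaluation patients into the
machine-learned features.

Models: logistic regression (standardized inputs) and gradient boosting.  The
gradient-boosting family is backed by scikit-learn's histogram-based
implementation — the modern GBM in that library and the only one tractable at
the grid's problem sizes on a single core; the classic exact-split tree
variant remains selectable via ``params={"implementation": "exact"}``.  The
tuned variant uses learning_rate 0.01, max_depth 8 and 1000 boosting rounds.
The LACE baseline is a univariate logistic model on the integer LACE score.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier, HistGradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "ModelSpec",
    "EvalReport",
    "NriResult",
    "default_grid",
    "make_model",
    "auc",
    "sensitivity_at_specificity",
    "nri",
    "compare_models",
    "cross_validate",
    "group_mask_for",
    "run_matrix",
    "MatrixResult",
]

VALID_GROUPS = {"manual", "embedding", "lace"}


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """One grid row: model family x feature-group combination."""

    name: str
    family: str  # "logistic" | "gradient_boosting"
    feature_groups: tuple[str, ...]
    params: tuple = ()  # hashable (key, value) pairs
    seed: int = 0

    def __post_init__(self):
        if self.family not in {"logistic", "gradient_boosting"}:
            raise ValueError(f"unknown model family {self.family!r}")
        bad = set(self.feature_groups) - VALID_GROUPS
        if bad:
            raise ValueError(f"unknown feature groups {sorted(bad)}")
        if not self.feature_groups:
            raise ValueError("at least one feature group required")

    @property
    def params_dict(self) -> dict:
        return dict(self.params)


TUNED_GBM_PARAMS = (("learning_rate", 0.01), ("max_depth", 8), ("n_estimators", 1000))


def default_grid(seed: int = 0) -> list[ModelSpec]:
    """The 8-row evaluation grid: LR and GBM over {manual, embedding, both},
    tuned GBM on both, and the LACE-only LR baseline."""
    return [
        ModelSpec("lr_manual", "logistic", ("manual",), seed=seed),
        ModelSpec("lr_w2v", "logistic", ("embedding",), seed=seed),
        ModelSpec("lr_combined", "logistic", ("manual", "embedding"), seed=seed),
        ModelSpec("gbm_manual", "gradient_boosting", ("manual",), seed=seed),
        ModelSpec("gbm_w2v", "gradient_boosting", ("embedding",), seed=seed),
        ModelSpec("gbm_combined", "gradient_boosting", ("manual", "embedding"),
                  seed=seed),
        ModelSpec("gbm_tuned_combined", "gradient_boosting",
                  ("manual", "embedding"), params=TUNED_GBM_PARAMS, seed=seed),
        ModelSpec("lr_lace", "logistic", ("lace",), seed=seed),
    ]


def make_model(spec: ModelSpec):
    if spec.family == "logistic":
        return make_pipeline(
            StandardScaler(),
            LogisticRegression(max_iter=2000, random_state=spec.seed),
        )
    params = spec.params_dict
    if params.pop("implementation", "hist") == "exact":
        return GradientBoostingClassifier(random_state=spec.seed, **params)
    if "n_estimators" in params:  # classic name -> histogram-GBM name
        params["max_iter"] = params.pop("n_estimators")
    return HistGradientBoostingClassifier(
        random_state=spec.seed, early_stopping=False, **params
    )


def _check_two_classes(labels):
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class")
    return labels


def auc(scores, labels) -> float:
    """Area under the ROC curve (rank statistic; ties count one half)."""
    labels = _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def sensitivity_at_specificity(scores, labels, target_specificity=0.75) -> float:
    """Largest sensitivity attainable while specificity stays >= target.

    Conservative threshold convention: the operating point is an actual
    threshold of the score distribution (no ROC interpolation).
    """
    labels = _check_two_classes(labels)
    fpr, tpr, _ = roc_curve(labels, np.asarray(scores, dtype=float))
    ok = (1.0 - fpr) >= target_specificity
    return float(tpr[ok].max()) if ok.any() else 0.0


@dataclasses.dataclass
class NriResult:
    overall: float
    events: float
    nonevents: float
    ci_overall: tuple[float, float]
    ci_events: tuple[float, float]
    ci_nonevents: tuple[float, float]

    def to_dict(self):
        return dataclasses.asdict(self)


def _nri_point(diff_sign, y):
    ev = diff_sign[y == 1]
    ne = diff_sign[y == 0]
    events = float(np.mean(ev)) if len(ev) else 0.0
    nonevents = float(-np.mean(ne)) if len(ne) else 0.0
    return events + nonevents, events, nonevents


def nri(scores_old, scores_new, labels, n_bootstrap=1000, seed=0) -> NriResult:
    """Category-free (continuous) net reclassification improvement.

    events component = P(new > old | event) - P(new < old | event);
    non-events component = P(new < old | non-event) - P(new > old | non-event);
    overall = sum.  95% CIs by patient-level bootstrap percentiles.
    """
    old = np.asarray(scores_old, dtype=float)
    new = np.asarray(scores_new, dtype=float)
    if old.shape != new.shape:
        raise ValueError("score vectors differ in length")
    y = _check_two_classes(labels)
    sign = np.sign(new - old)
    overall, events, nonevents = _nri_point(sign, y)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_bootstrap, 3))
    n = len(y)
    for b in range(n_bootstrap):
        ix = rng.integers(0, n, n)
        boots[b] = _nri_point(sign[ix], y[ix])
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    return NriResult(
        overall=overall, events=events, nonevents=nonevents,
        ci_overall=(float(lo[0]), float(hi[0])),
        ci_events=(float(lo[1]), float(hi[1])),
        ci_nonevents=(float(lo[2]), float(hi[2])),
    )


def compare_models(fold_aucs: dict[str, list[float]]) -> dict[tuple[str, str], float]:
    """Bonferroni-adjusted two-sided paired t-tests on aligned fold AUCs.

    Degenerate zero-variance differences: p = 1 when the fold AUCs are
    identical, p = 0 when they differ by a nonzero constant.
    """
    names = list(fold_aucs)
    lengths = {len(v) for v in fold_aucs.values()}
    if len(lengths) != 1:
        raise ValueError("fold AUC lists must be aligned")
    if lengths.pop() < 2:
        raise ValueError("need at least 2 folds")
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    out = {}
    for a, b in pairs:
        d = np.asarray(fold_aucs[a]) - np.asarray(fold_aucs[b])
        if np.allclose(d.std(ddof=1), 0.0):
            p = 1.0 if np.allclose(d, 0.0) else 0.0
        else:
            p = float(stats.ttest_rel(fold_aucs[a], fold_aucs[b]).pvalue)
        out[(a, b)] = min(1.0, m * p)
    return out


@dataclasses.dataclass
class EvalReport:
    """Evaluation summary for one grid row."""

    name: str
    family: str
    feature_groups: tuple[str, ...]
    fold_aucs: list[float]
    cv_auc_mean: float
    cv_auc_sd: float
    test_auc: float
    sensitivity_at_spec: float
    target_specificity: float

    def to_dict(self):
        d = dataclasses.asdict(self)
        d["feature_groups"] = list(self.feature_groups)
        return d


@dataclasses.dataclass
class MatrixResult:
    reports: list[EvalReport]
    pvalues: dict[tuple[str, str], float]
    nris: dict[str, NriResult]
    holdout_scores: dict[str, np.ndarray]
    holdout_labels: np.ndarray

    def report_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "model": r.family,
                    "features": "+".join(r.feature_groups),
                    "name": r.name,
                    "cv_auc_mean": r.cv_auc_mean,
                    "cv_auc_sd": r.cv_auc_sd,
                    "test_auc": r.test_auc,
                    "sensitivity_at_spec": r.sensitivity_at_spec,
                }
                for r in self.reports
            ]
        )


def group_mask_for(spec: ModelSpec, encoder) -> np.ndarray:
    """Mask over encoded manual-matrix columns selected by the spec's groups.

    The ``manual`` group includes the raw index-admission features; the
    ``embedding`` group lives in a separate dense block and is not part of
    the encoded manual matrix.
    """
    groups = set(spec.feature_groups) & {"manual", "lace"}
    if "manual" in groups:
        groups.add("raw")
    if not groups:
        return np.zeros(len(encoder.encoded_columns_), dtype=bool)
    return encoder.group_mask(groups)


def cross_validate(
    x, y, parts, spec: ModelSpec, emb_blocks=None, manual_mask=None
) -> list[float]:
    """One AUC per CV fold (parts 1..max); the model sees only the other folds.

    ``x`` is the encoded manual design matrix; ``emb_blocks`` maps fold id to
    the embedding feature block trained without that fold (required when the
    spec uses embedding features).  ``manual_mask`` restricts the manual
    columns to the spec's groups (default: all columns).
    """
    y = np.asarray(y).astype(int)
    parts = np.asarray(parts)
    fold_ids = sorted(p for p in np.unique(parts) if p != 0)
    use_emb = "embedding" in spec.feature_groups
    if manual_mask is None:
        manual_mask = (
            np.ones(x.shape[1], dtype=bool) if not use_emb
            else np.zeros(x.shape[1], dtype=bool)
        )
    aucs = []
    for f in fold_ids:
        train = np.flatnonzero((parts != 0) & (parts != f))
        test = np.flatnonzero(parts == f)
        if len(np.unique(y[test])) < 2 or len(np.unique(y[train])) < 2:
            raise ValueError(f"fold {f} has a single outcome class")
        block = emb_blocks[f] if use_emb else None
        xtr = _stack(x, manual_mask, block, train)
        xte = _stack(x, manual_mask, block, test)
        model = make_model(spec)
        model.fit(xtr, y[train])
        aucs.append(auc(model.predict_proba(xte)[:, 1], y[test]))
    return aucs


def _stack(x, mask, emb_block, rows):
    parts = []
    if mask is not None and mask.any():
        parts.append(x[np.ix_(rows, np.flatnonzero(mask))])
    if emb_block is not None:
        parts.append(emb_block[rows])
    if not parts:
        raise ValueError("model spec selects no feature columns")
    return np.hstack(parts)


def run_matrix(
    x_manual: np.ndarray,
    encoder,
    y: np.ndarray,
    parts: np.ndarray,
    specs: list[ModelSpec],
    emb_blocks: dict[int, np.ndarray] | None = None,
    emb_block_full: np.ndarray | None = None,
    target_specificity: float = 0.75,
    nri_pairs: tuple[tuple[str, str], ...] = (
        ("gbm_manual", "gbm_combined"),
        ("lr_combined", "gbm_combined"),
    ),
    nri_bootstrap: int = 1000,
    nri_seed: int = 0,
) -> MatrixResult:
    """Evaluate every spec with the shared CV/holdout protocol.

    ``emb_blocks[f]`` is the per-patient embedding feature block built from an
    embedding trained without fold ``f`` (and never on part 0);
    ``emb_block_full`` comes from an embedding trained on all ten CV parts and
    serves the holdout evaluation.
    """
    y = np.asarray(y).astype(int)
    parts = np.asarray(parts)
    needs_emb = any("embedding" in s.feature_groups for s in specs)
    if needs_emb and (emb_blocks is None or emb_block_full is None):
        raise ValueError("embedding feature blocks required for this grid")
    holdout = np.flatnonzero(parts == 0)
    train_all = np.flatnonzero(parts != 0)
    fold_aucs: dict[str, list[float]] = {}
    reports, holdout_scores = [], {}
    for spec in specs:
        mask = group_mask_for(spec, encoder)
        aucs = cross_validate(x_manual, y, parts, spec, emb_blocks, manual_mask=mask)
        use_emb = "embedding" in spec.feature_groups
        block = emb_block_full if use_emb else None
        model = make_model(spec)
        model.fit(_stack(x_manual, mask, block, train_all), y[train_all])
        s = model.predict_proba(_stack(x_manual, mask, block, holdout))[:, 1]
        holdout_scores[spec.name] = s
        fold_aucs[spec.name] = aucs
        reports.append(
            EvalReport(
                name=spec.name,
                family=spec.family,
                feature_groups=spec.feature_groups,
                fold_aucs=[float(a) for a in aucs],
                cv_auc_mean=float(np.mean(aucs)),
                cv_auc_sd=float(np.std(aucs, ddof=1)),
                test_auc=auc(s, y[holdout]),
                sensitivity_at_spec=sensitivity_at_specificity(
                    s, y[holdout], target_specificity
                ),
                target_specificity=target_specificity,
            )
        )
    pvalues = compare_models(fold_aucs) if len(specs) > 1 else {}
    nris = {}
    for old, new in nri_pairs:
        if old in holdout_scores and new in holdout_scores:
            nris[f"{old}->{new}"] = nri(
                holdout_scores[old], holdout_scores[new], y[holdout],
                n_bootstrap=nri_bootstrap, seed=nri_seed,
            )
    return MatrixResult(
        reports=reports,
        pvalues=pvalues,
        nris=nris,
        holdout_scores=holdout_scores,
        holdout_labels=y[holdout],
    )
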