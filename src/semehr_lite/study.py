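"""Study layer: post-filter rules and mention-count patient classification.

A *study* consumes the annotated corpus for one clinical question.  It keeps
its own store (:class:`StudyKG`): the validated concept query, a list of
post-filter rules that remove or re-contextualize unwanted mentions (by
surface string or surrounding text), the selected cohort, and exported
feature tables.

The classification task mirrors the patient-level integration experiment:
the number of *positive* mentions of the search concepts in a patient's
record is the single feature, and either a Gaussian naive Bayes model or a
one-column decision table (a count threshold) predicts whether the patient
has the disease.  Evaluation is seeded, stratified k-fold cross-validation
reporting per-class precision/recall/F-measure and the weighted average.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold

from .annotator import ConceptMention
from .ontology import ConceptQuery

__all__ = [
    "FilterRule",
    "apply_rules",
    "CountClassifier",
    "fit_classifier",
    "cross_validate",
    "CVResult",
    "StudyKG",
    "VARIANCE_FLOOR",
    "analytic_bayes_threshold",
]

VARIANCE_FLOOR = 1e-6

Action = Literal["remove", "set_negated", "set_other_experiencer", "scale_confidence"]


@dataclass(frozen=True)
class FilterRule:
    """One post-filter rule over annotated mentions.

    ``target`` chooses what the pattern is matched against: the mention's
    exact surface string, or a context window of ``window`` characters
    either side of the mention in the note text.  The regex is compiled at
    construction, so an invalid pattern fails at load time, never at apply
    time.
    """

    rule_id: str
    target: Literal["surface", "context_window"]
    pattern: str
    action: Action
    window: int = 0
    argument: float = 1.0

    def __post_init__(self) -> None:
        if self.window < 0:
            raise ValueError(f"rule {self.rule_id}: window must be >= 0")
        if self.target not in ("surface", "context_window"):
            raise ValueError(f"rule {self.rule_id}: unknown target {self.target!r}")
        if self.action not in (
            "remove", "set_negated", "set_other_experiencer", "scale_confidence",
        ):
            raise ValueError(f"rule {self.rule_id}: unknown action {self.action!r}")
        try:
            object.__setattr__(self, "_compiled", re.compile(self.pattern))
        except re.error as exc:
            raise ValueError(f"rule {self.rule_id}: invalid regex: {exc}") from exc

    def matches(self, mention: ConceptMention, text: str) -> bool:
        if self.target == "surface":
            return self._compiled.search(mention.surface) is not None
        lo = max(0, mention.start - self.window)
        hi = min(len(text), mention.end + self.window)
        return self._compiled.search(text[lo:hi]) is not None

    def to_dict(self) -> dict:
        return {
            "rule_id": self.rule_id,
            "target": self.target,
            "pattern": self.pattern,
            "action": self.action,
            "window": self.window,
            "argument": self.argument,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FilterRule":
        return cls(**d)


def apply_rules(
    mentions: Sequence[ConceptMention],
    rules: Sequence[FilterRule],
    note_texts: Mapping[str, str],
) -> list[ConceptMention]:
    """Apply filter rules in list order; returns the surviving mentions.

    ``remove`` drops the mention; the ``set_*`` actions rewrite a context
    dimension (the mention's category changes accordingly downstream);
    ``scale_confidence`` multiplies confidence by the rule argument.
    Remove-only rule sets are idempotent.
    """
    out: list[ConceptMention] = []
    for m in mentions:
        text = note_texts.get(m.note_id, "")
        keep = True
        for rule in rules:
            if not rule.matches(m, text):
                continue
            if rule.action == "remove":
                keep = False
                break
            if rule.action == "set_negated":
                m = replace(m, negation="negated")
            elif rule.action == "set_other_experiencer":
                m = replace(m, experiencer="other")
            elif rule.action == "scale_confidence":
                m = replace(m, confidence=m.confidence * rule.argument)
        if keep:
            out.append(m)
    return out


# ---------------------------------------------------------------------------
# single-feature patient classification
# ---------------------------------------------------------------------------

@dataclass
class CountClassifier:
    """A classifier over the single feature ``n_positive``.

    ``naive_bayes``: per-class Gaussian with a variance floor, priors from
    class frequencies.  ``decision_table``: the integer count threshold that
    maximizes training accuracy (predict the high-count class at or above
    the threshold); ties resolve to the smaller threshold.  Binary only for
    the decision table; naive Bayes accepts any number of classes.
    """

    model_kind: Literal["naive_bayes", "decision_table"]
    classes: list[str]
    class_prior: dict[str, float]
    # naive_bayes parameters
    means: dict[str, float] = field(default_factory=dict)
    variances: dict[str, float] = field(default_factory=dict)
    # decision_table parameters
    threshold: int | None = None
    high_class: str | None = None
    low_class: str | None = None

    def predict(self, counts: Iterable[float]) -> list[str]:
        counts = list(counts)
        if self.model_kind == "decision_table":
            return [
                self.high_class if c >= self.threshold else self.low_class
                for c in counts
            ]
        out = []
        for c in counts:
            best, best_ll = None, -np.inf
            for cls in self.classes:  # sorted order breaks ties deterministically
                var = self.variances[cls]
                ll = (
                    np.log(self.class_prior[cls])
                    - 0.5 * np.log(2 * np.pi * var)
                    - (c - self.means[cls]) ** 2 / (2 * var)
                )
                if ll > best_ll:
                    best, best_ll = cls, ll
            out.append(best)
        return out


def fit_classifier(
    rows: Sequence[tuple[float, str]],
    model_kind: Literal["naive_bayes", "decision_table"],
) -> CountClassifier:
    """Fit a :class:`CountClassifier` on (n_positive, label) rows."""
    if not rows:
        raise ValueError("no training rows")
    counts = np.asarray([r[0] for r in rows], dtype=float)
    labels = np.asarray([r[1] for r in rows], dtype=object)
    if np.any(counts < 0):
        raise ValueError("mention counts must be non-negative")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to fit a classifier")
    prior = {c: float(np.mean(labels == c)) for c in classes}
    clf = CountClassifier(model_kind=model_kind, classes=classes, class_prior=prior)
    if model_kind == "naive_bayes":
        for c in classes:
            x = counts[labels == c]
            clf.means[c] = float(np.mean(x))
            clf.variances[c] = max(float(np.var(x)), VARIANCE_FLOOR)
        return clf
    if model_kind == "decision_table":
        if len(classes) != 2:
            raise ValueError("decision_table supports exactly 2 classes")
        mean_by_class = {c: float(np.mean(counts[labels == c])) for c in classes}
        # the class with the larger mean count sits above the threshold;
        # sorted order breaks an exact mean tie deterministically
        high = max(classes, key=lambda c: (mean_by_class[c], c))
        low = classes[0] if high == classes[1] else classes[1]
        best_t, best_acc = 0, -1.0
        for t in range(0, int(counts.max()) + 2):
            pred_high = counts >= t
            acc = float(np.mean(np.where(pred_high, high, low) == labels))
            if acc > best_acc:  # strict: ties keep the smaller threshold
                best_t, best_acc = t, acc
        clf.threshold = best_t
        clf.high_class = high
        clf.low_class = low
        return clf
    raise ValueError(f"unknown model_kind {model_kind!r}")


@dataclass
class CVResult:
    """Cross-validation metrics, shaped like a per-class P/R/F table."""

    table: pd.DataFrame  # columns: class, precision, recall, f_measure, support
    predictions: pd.DataFrame  # columns: n_positive, label, predicted, fold

    @property
    def weighted_f(self) -> float:
        return float(
            self.table.loc[self.table["class"] == "Weighted avg.", "f_measure"].iloc[0]
        )


def cross_validate(
    rows: Sequence[tuple[float, str]],
    model_kind: Literal["naive_bayes", "decision_table"],
    k: int = 10,
    seed: int = 0,
) -> CVResult:
    """Seeded, stratified k-fold cross-validation of the count classifier.

    Predictions are pooled across folds and per-class precision, recall and
    F-measure (harmonic mean) plus the support-weighted average are
    reported.  Zero-division cases score 0 with a warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(rows) < k:
        raise ValueError("need at least k rows")
    counts = np.asarray([r[0] for r in rows], dtype=float)
    labels = np.asarray([r[1] for r in rows], dtype=object)
    classes = sorted(set(labels))
    class_n = {c: int(np.sum(labels == c)) for c in classes}
    if min(class_n.values()) < k:
        # a class thinner than k cannot appear in every training fold
        if min(class_n.values()) < 2:
            raise ValueError(
                f"class absent from training folds: {min(class_n, key=class_n.get)}"
            )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pred = np.empty(len(rows), dtype=object)
    fold_of = np.empty(len(rows), dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for fold, (train, test) in enumerate(skf.split(counts.reshape(-1, 1), labels)):
            if len(set(labels[train])) < 2:
                raise ValueError(f"a class is absent from training fold {fold}")
            clf = fit_classifier(list(zip(counts[train], labels[train])), model_kind)
            pred[test] = clf.predict(counts[test])
            fold_of[test] = fold
    prec, rec, f1, support = precision_recall_fscore_support(
        labels, pred, labels=classes, zero_division=0
    )
    if np.any((prec == 0) | (rec == 0)):
        warnings.warn("zero precision or recall in some class; scored as 0")
    records = [
        {
            "class": c,
            "precision": float(p),
            "recall": float(r),
            "f_measure": float(f),
            "support": int(s),
        }
        for c, p, r, f, s in zip(classes, prec, rec, f1, support)
    ]
    w = support / support.sum()
    records.append(
        {
            "class": "Weighted avg.",
            "precision": float(np.sum(prec * w)),
            "recall": float(np.sum(rec * w)),
            "f_measure": float(np.sum(f1 * w)),
            "support": int(support.sum()),
        }
    )
    table = pd.DataFrame(records, columns=["class", "precision", "recall", "f_measure", "support"])
    predictions = pd.DataFrame(
        {"n_positive": counts, "label": labels, "predicted": pred, "fold": fold_of}
    )
    return CVResult(table=table, predictions=predictions)


def analytic_bayes_threshold(
    lambda_control: float,
    lambda_case: float,
    prior_case: float,
    t_max: int = 200,
) -> int:
    """Accuracy-optimal integer count threshold for a two-Poisson mixture.

    Exhaustive scan over thresholds t: predict "case" at count >= t; the
    expected accuracy is prior_control*P(X0 < t) + prior_case*P(X1 >= t)
    under the true class-conditional Poisson densities.  Ties resolve to
    the smaller threshold.
    """
    from scipy.stats import poisson

    pi0 = 1.0 - prior_case
    best_t, best_acc = 0, -1.0
    for t in range(0, t_max + 1):
        acc = pi0 * poisson.cdf(t - 1, lambda_control) + prior_case * poisson.sf(
            t - 1, lambda_case
        )
        if acc > best_acc:
            best_t, best_acc = t, acc
    return best_t


# ---------------------------------------------------------------------------
# study knowledge store
# ---------------------------------------------------------------------------

@dataclass
class StudyKG:
    """Per-study storage: query, rules, cohort and exported features."""

    study_id: str
    concept_query: ConceptQuery = field(default_factory=ConceptQuery)
    rules: list[FilterRule] = field(default_factory=list)
    cohort: list[str] = field(default_factory=list)
    exports: dict[str, list[dict]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "study_id": self.study_id,
            "concept_query": {
                "included_cuis": list(self.concept_query.included_cuis),
                "excluded_cuis": sorted(self.concept_query.excluded_cuis),
                "origin_terms": list(self.concept_query.origin_terms),
                "validation_state": dict(sorted(self.concept_query.validation_state.items())),
            },
            "rules": [r.to_dict() for r in self.rules],
            "cohort": list(self.cohort),
            "exports": self.exports,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "StudyKG":
        d = json.loads(Path(path).read_text())
        cq = d["concept_query"]
        return cls(
            study_id=d["study_id"],
            concept_query=ConceptQuery(
                included_cuis=list(cq["included_cuis"]),
                excluded_cuis=set(cq["excluded_cuis"]),
                origin_terms=list(cq["origin_terms"]),
                validation_state=dict(cq["validation_state"]),
            ),
            rules=[FilterRule.from_dict(r) for r in d["rules"]],
            cohort=list(d["cohort"]),
            exports=dict(d["exports"]),
        )
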