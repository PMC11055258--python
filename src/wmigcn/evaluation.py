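"""Model evaluation: class filtering, stratified CV, metrics and the ablation.

The evaluation protocol mirrors the study design: rhythm classes rarer than
2% of the total are excluded, models are assessed with stratified 4-fold
cross-validation, every record is predicted by the model whose test fold
contains it (out-of-fold prediction), and the three adjacency variants
(WMI / MI / identity) are compared pairwise with independent two-sample
t-tests on the fold accuracies.

Per-class performance uses the one-vs-rest dichotomy:

    sensitivity = TP / (TP + FN)      precision = TP / (TP + FP)
    specificity = TN / (FP + TN)      accuracy  = (TP + TN) / Total

Undefined ratios (0/0) are reported as NaN markers and excluded from macro
averages.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .gcn import GCNClassifier, GCNConfig, GCNResults, GraphSample, build_samples
from .io import DatasetManifest, ECGRecord
from .structure import Variant, mi_matrix

METRIC_NAMES = ("sensitivity", "precision", "specificity", "accuracy")


@dataclass
class ConfusionMatrix:
    """Rows = true class, columns = predicted class."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        c = len(self.classes)
        if self.counts.shape != (c, c):
            raise ValueError("counts must be C x C for C classes")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        self.classes = tuple(self.classes)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @staticmethod
    def from_predictions(
        y_true: Sequence[str], y_pred: Sequence[str], classes: Sequence[str]
    ) -> "ConfusionMatrix":
        classes = tuple(classes)
        lut = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
        for t, p in zip(y_true, y_pred):
            counts[lut[t], lut[p]] += 1
        return ConfusionMatrix(counts=counts, classes=classes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


@dataclass
class MetricReport:
    """Per-class and macro-averaged one-vs-rest metrics (proportions)."""

    per_class: dict[str, dict[str, float]]
    overall: dict[str, float]
    fold_values: Optional[pd.DataFrame] = None  # one row per fold

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.per_class).T
        frame.loc["overall (macro)"] = pd.Series(self.overall)
        return frame[list(METRIC_NAMES)]


@dataclass
class ComparisonResult:
    """Pairwise independent t-tests on fold accuracies."""

    pairs: dict[tuple[str, str], dict[str, float]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"variant_a": a, "variant_b": b, **stats}
            for (a, b), stats in self.pairs.items()
        ]
        return pd.DataFrame(rows)


def filter_classes(
    manifest: DatasetManifest, min_fraction: float = 0.02
) -> DatasetManifest:
    """Drop classes rarer than ``min_fraction`` of the pre-filter total.

    The boundary is strict: a class at exactly the threshold is kept.
    """
    if not (0 < min_fraction < 0.5):
        raise ValueError("min_fraction must lie in (0, 0.5)")
    if len(manifest.class_counts) < 2:
        raise ValueError("need at least 2 classes before filtering")
    total = len(manifest)
    keep = {
        label
        for label, count in manifest.class_counts.items()
        if count / total >= min_fraction
    }
    if not keep:
        raise ValueError("class filtering removed every class")
    rows = [r for r in manifest.records if r[2] in keep]
    return DatasetManifest(records=rows)


def make_folds(
    manifest: DatasetManifest, k: int = 4, seed: int = 0
) -> list[tuple[list[str], list[str]]]:
    """Stratified k-fold split of record ids, deterministic per seed."""
    if k < 2:
        raise ValueError("k must be >= 2")
    for label, count in manifest.class_counts.items():
        if count < k:
            raise ValueError(
                f"class {label!r} has only {count} records; needs >= {k}"
            )
    ids = np.array(manifest.record_ids)
    labels = np.array(manifest.labels)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        (list(ids[tr]), list(ids[te])) for tr, te in skf.split(ids, labels)
    ]


def _one_vs_rest(counts: np.ndarray, i: int) -> tuple[int, int, int, int]:
    tp = counts[i, i]
    fn = counts[i].sum() - tp
    fp = counts[:, i].sum() - tp
    tn = counts.sum() - tp - fn - fp
    return int(tp), int(fn), int(fp), int(tn)


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricReport:
    """The four one-vs-rest metrics per class, macro-averaged overall."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    per_class: dict[str, dict[str, float]] = {}
    for i, cls in enumerate(cm.classes):
        tp, fn, fp, tn = _one_vs_rest(cm.counts, i)
        per_class[cls] = {
            "sensitivity": _ratio(tp, tp + fn),
            "precision": _ratio(tp, tp + fp),
            "specificity": _ratio(tn, fp + tn),
            "accuracy": (tp + tn) / cm.total,
        }
    overall = {
        name: float(np.nanmean([m[name] for m in per_class.values()]))
        for name in METRIC_NAMES
    }
    return MetricReport(per_class=per_class, overall=overall)


def independent_ttest(a: Sequence[float], b: Sequence[float]) -> dict[str, float]:
    """Equal-variance two-sample t-test (pooled variance, df = n_a + n_b - 2).

    Degenerate zero-variance groups: identical means give t = 0, p = 1;
    different means give an infinite-t marker with p = 0.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 observations per group")
    diff = a.mean() - b.mean()
    df = na + nb - 2
    pooled = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    se = math.sqrt(pooled * (1 / na + 1 / nb))
    if se == 0:
        if diff == 0:
            t, p = 0.0, 1.0
        else:
            t, p = math.copysign(math.inf, diff), 0.0
    else:
        from scipy.stats import t as t_dist

        t = diff / se
        p = 2 * t_dist.sf(abs(t), df)
    return {"mean_diff": float(diff), "t": float(t), "p": float(p), "df": float(df)}


@dataclass
class FoldOutcome:
    fold: int
    results: GCNResults
    test_ids: list[str]
    y_true: list[str]
    y_pred: list[str]

    @property
    def accuracy(self) -> float:
        return float(np.mean([t == p for t, p in zip(self.y_true, self.y_pred)]))


def predict_all(
    fold_outcomes: Sequence[FoldOutcome], manifest: DatasetManifest
) -> ConfusionMatrix:
    """Out-of-fold confusion matrix over every record in the manifest."""
    classes = tuple(sorted(manifest.class_counts))
    covered = set(itertools.chain.from_iterable(f.test_ids for f in fold_outcomes))
    missing = set(manifest.record_ids) - covered
    if missing:
        raise ValueError(f"records never assigned to a test fold: {sorted(missing)[:5]}")
    y_true = list(itertools.chain.from_iterable(f.y_true for f in fold_outcomes))
    y_pred = list(itertools.chain.from_iterable(f.y_pred for f in fold_outcomes))
    return ConfusionMatrix.from_predictions(y_true, y_pred, classes)


@dataclass
class VariantOutcome:
    variant: Variant
    confusion: ConfusionMatrix
    report: MetricReport
    fold_accuracies: list[float]


@dataclass
class AblationResult:
    """Cross-validated comparison of the three adjacency variants."""

    variants: dict[Variant, VariantOutcome]
    comparisons: ComparisonResult
    k: int
    seed: int

    def accuracy(self, variant: Variant | str) -> float:
        return float(np.mean(self.variants[Variant(variant)].fold_accuracies))

    def summary(self) -> str:
        lines = [
            f"Adjacency-variant ablation ({self.k}-fold CV, seed {self.seed})",
            "=" * 54,
            f"{'variant':<10}{'acc mean':>10}{'acc sd':>9}  per-fold accuracies",
        ]
        for variant, out in self.variants.items():
            accs = np.array(out.fold_accuracies)
            lines.append(
                f"{variant.value:<10}{accs.mean():>10.4f}{accs.std(ddof=1):>9.4f}  "
                + " ".join(f"{a:.3f}" for a in accs)
            )
        lines.append("")
        lines.append("pairwise independent t-tests on fold accuracies:")
        for (a, b), stats in self.comparisons.pairs.items():
            lines.append(
                f"  {a} vs {b}: mean diff {stats['mean_diff']:+.4f}, "
                f"t = {stats['t']:.3f}, p = {stats['p']:.4f} (df {stats['df']:.0f})"
            )
        return "\n".join(lines)


class AblationStudy:
    """Train and compare GCNs with WMI, MI and identity adjacencies.

    MI matrices are estimated once per record and shared across variants;
    folds and seeds are identical across variants so the comparison isolates
    the adjacency structure.
    """

    def __init__(
        self,
        records: Sequence[ECGRecord],
        config: Optional[GCNConfig] = None,
        variants: Sequence[Variant | str] = (Variant.WMI, Variant.MI, Variant.IDENTITY),
        n_bins: int = 16,
        normalize: str = "dataset",
        zero_diagonal: bool = True,
    ):
        if any(rec.label is None for rec in records):
            raise ValueError("every record needs a label")
        self.records = {rec.record_id: rec for rec in records}
        self.manifest = DatasetManifest(
            records=[(rec.record_id, None, rec.label) for rec in records]
        )
        if len(self.manifest.class_counts) < 2:
            raise ValueError("need at least 2 classes")
        self.config = config or GCNConfig()
        self.variants = [Variant(v) for v in variants]
        self.n_bins = n_bins
        self.normalize = normalize
        self.zero_diagonal = zero_diagonal

    def _samples(self, variant: Variant) -> dict[str, GraphSample]:
        if not hasattr(self, "_mi_cache"):
            self._mi_cache = {
                rid: mi_matrix(rec, self.n_bins)
                for rid, rec in self.records.items()
            }
        samples = build_samples(
            list(self.records.values()),
            variant,
            self.config.node_feature_length,
            self.n_bins,
            self.normalize,
            zero_diagonal=self.zero_diagonal,
            mi_cache=self._mi_cache,
        )
        return {s.record_id: s for s in samples}

    def run(self, k: int = 4, seed: int = 0) -> AblationResult:
        folds = make_folds(self.manifest, k=k, seed=seed)
        classes = tuple(sorted(self.manifest.class_counts))
        outcomes: dict[Variant, VariantOutcome] = {}
        for variant in self.variants:
            samples = self._samples(variant)
            fold_outcomes: list[FoldOutcome] = []
            for fi, (train_ids, test_ids) in enumerate(folds):
                cfg = self.config
                model = GCNClassifier(
                    [samples[r] for r in train_ids],
                    [self.records[r].label for r in train_ids],
                    config=cfg,
                    classes=classes,
                )
                res = model.fit(
                    [samples[r] for r in test_ids],
                    [self.records[r].label for r in test_ids],
                )
                preds = res.predict([samples[r] for r in test_ids])
                fold_outcomes.append(
                    FoldOutcome(
                        fold=fi,
                        results=res,
                        test_ids=list(test_ids),
                        y_true=[self.records[r].label for r in test_ids],
                        y_pred=preds,
                    )
                )
            cm = predict_all(fold_outcomes, self.manifest)
            report = metrics_from_confusion(cm)
            report.fold_values = pd.DataFrame(
                [
                    {
                        "fold": f.fold,
                        "accuracy": f.accuracy,
                        "n_test": len(f.test_ids),
                    }
                    for f in fold_outcomes
                ]
            )
            outcomes[variant] = VariantOutcome(
                variant=variant,
                confusion=cm,
                report=report,
                fold_accuracies=[f.accuracy for f in fold_outcomes],
            )
        pairs = {
            (a.value, b.value): independent_ttest(
                outcomes[a].fold_accuracies, outcomes[b].fold_accuracies
            )
            for a, b in itertools.combinations(self.variants, 2)
        }
        return AblationResult(
            variants=outcomes,
            comparisons=ComparisonResult(pairs=pairs),
            k=k,
            seed=seed,
        )


def run_ablation(
    records: Sequence[ECGRecord],
    config: Optional[GCNConfig] = None,
    variants: Sequence[Variant | str] = (Variant.WMI, Variant.MI, Variant.IDENTITY),
    k: int = 4,
    seed: int = 0,
    **kwargs,
) -> AblationResult:
    """Functional wrapper around :class:`AblationStudy`."""
    return AblationStudy(records, config=config, variants=variants, **kwargs).run(
        k=k, seed=seed
    )
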