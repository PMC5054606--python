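"""TSS-proximal-region classifier: features, training set, CV, genome scan.

Positive examples are the -1 kb..+0.5 kb regions around expressed lincRNA
TSSs; negatives are unannotated 1,500 bp windows sampled within +-10 kb of
those TSSs.  Each region is described by 336 k-mer frequencies, CpG o/e,
CGI and repeat coverage, motif presence flags, mean CAGE signal, and mean
chromatin-mark signal (PolII, H3K4me3, H3K9ac, H3K27ac).  The classifier
is an RBF SVM with gamma = 1 and cost = 2; gamma is applied to the
dimension-averaged squared distance of the standardized features so that
the stated hyperparameters keep their meaning for every feature subset
(see docs/methods.md).  Evaluation is stratified 10-fold CV with the usual
confusion-matrix metrics plus ROC/PRC areas.

Genome-wide prediction tiles each chromosome with 1,500 bp windows stepped
by 300 bp, drops windows overlapping annotated exons, and keeps windows the
SVM scores positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import (
    ExpressionTable,
    GenomeInterval,
    IntervalIndex,
    PipelineConfig,
    SignalTrack,
    TranscriptModel,
    reverse_complement,
    tss_proximal_region,
)
from .seqfeatures import (
    Pwm,
    _COMP_CODE_ORDER,
    _distribution,
    coverage_fraction,
    cpg_oe,
    encode_sequence,
    kmer_names,
    kmer_vector,
    merge_intervals,
    pwm_scan,
    scaled_scores,
)

CHROMATIN_FEATURES = ("PolII", "H3K4me3", "H3K9ac", "H3K27ac")

REPEAT_EXCLUDED_CLASSES = ("simple_repeat", "low_complexity", "satellite")


def filter_repeats(repeats: Iterable[GenomeInterval]) -> list[GenomeInterval]:
    """Drop simple repeats, low-complexity and satellite repeat classes."""
    return [
        r
        for r in repeats
        if not any(cls in r.name.lower() for cls in REPEAT_EXCLUDED_CLASSES)
    ]


@dataclass
class FeatureInputs:
    """Everything region featurization needs, bundled."""

    genome: Mapping[str, str]
    chromatin: Mapping[str, SignalTrack]   # must cover CHROMATIN_FEATURES
    cage: SignalTrack
    cgi: Sequence[GenomeInterval]
    repeats: Sequence[GenomeInterval]
    pwms: Sequence[Pwm]


def feature_names(pwms: Sequence[Pwm]) -> list[str]:
    return (
        kmer_names()
        + ["cpg_oe", "cgi_cov", "repeat_cov"]
        + [f"motif_{p.id}" for p in pwms]
        + ["CAGE"]
        + list(CHROMATIN_FEATURES)
    )


def feature_groups(pwms: Sequence[Pwm]) -> dict[str, list[str]]:
    """The ablation groups mirroring the per-category classifier comparison."""
    return {
        "kmer": kmer_names(),
        "histone": list(CHROMATIN_FEATURES),
        "CAGE": ["CAGE"],
        "motif": [f"motif_{p.id}" for p in pwms],
        "cgi_cpg": ["cgi_cov", "cpg_oe"],
        "repeat": ["repeat_cov"],
    }


def region_features(
    regions: Sequence[GenomeInterval],
    inputs: FeatureInputs,
    cfg: PipelineConfig | None = None,
    ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Feature matrix for arbitrary regions (minus-strand sequences are
    reverse-complemented so sequence features are promoter-oriented)."""
    cfg = cfg or PipelineConfig()
    repeats = filter_repeats(inputs.repeats)
    cgi_index = list(inputs.cgi)
    rows = []
    for region in regions:
        seq = inputs.genome[region.chrom][region.start : region.end]
        if region.strand == "-":
            seq = reverse_complement(seq)
        row = list(kmer_vector(seq))
        row.append(cpg_oe(seq))
        row.append(coverage_fraction(region, cgi_index))
        row.append(coverage_fraction(region, repeats))
        for pwm in inputs.pwms:
            row.append(
                float(pwm_scan(seq, pwm, cfg.motif_presence_p).present)
            )
        row.append(inputs.cage.mean(region.chrom, region.start, region.end))
        for mark in CHROMATIN_FEATURES:
            row.append(
                inputs.chromatin[mark].mean(region.chrom, region.start, region.end)
            )
        rows.append(row)
    index = list(ids) if ids is not None else [
        f"{r.chrom}:{r.start}-{r.end}({r.strand})" for r in regions
    ]
    return pd.DataFrame(rows, index=index, columns=feature_names(inputs.pwms))


class WindowScanner:
    """Vectorized featurization of scan windows (plus-orientation).

    Precomputes, per chromosome: k-mer id arrays, base/CpG indicator
    cumsums, merged CGI/repeat coverage cumsums and per-position best
    motif scores (both strands), so that each window costs a few slices.
    Feature values agree exactly with :func:`region_features` on
    plus-strand, N-free windows.
    """

    def __init__(self, inputs: FeatureInputs, cfg: PipelineConfig | None = None):
        self.inputs = inputs
        self.cfg = cfg or PipelineConfig()
        self._cache: dict[str, dict] = {}
        self._dists = [_distribution(p) for p in inputs.pwms]
        self._thresholds = []
        for dist in self._dists:
            sf = dist._sf
            idx = np.flatnonzero(sf <= self.cfg.motif_presence_p)
            self._thresholds.append(int(idx[0]) if idx.size else sf.size)

    def _chrom_cache(self, chrom: str) -> dict:
        if chrom in self._cache:
            return self._cache[chrom]
        seq = self.inputs.genome[chrom]
        codes = encode_sequence(seq)
        n = codes.size
        cache: dict = {"codes": codes, "n": n}
        for k in (2, 3, 4):
            m = n - k + 1
            ids = np.zeros(m, dtype=np.int64)
            valid = np.ones(m, dtype=bool)
            for j in range(k):
                c = codes[j : j + m]
                valid &= c < 4
                ids = ids * 4 + np.where(c < 4, c, 0)
            ids = np.where(valid, ids, -1)
            cache[f"ids{k}"] = ids
        is_c = (codes == 1).astype(np.int64)
        is_g = (codes == 2).astype(np.int64)
        is_cg = np.zeros(n, dtype=np.int64)
        is_cg[:-1] = (codes[:-1] == 1) & (codes[1:] == 2)
        for name, ind in (("c", is_c), ("g", is_g), ("cg", is_cg)):
            cache[f"cum_{name}"] = np.concatenate(([0], np.cumsum(ind)))
        for name, intervals in (
            ("cgi", self.inputs.cgi),
            ("repeat", filter_repeats(self.inputs.repeats)),
        ):
            ind = np.zeros(n, dtype=np.int64)
            for s, e in merge_intervals(
                (iv.start, iv.end) for iv in intervals if iv.chrom == chrom
            ):
                ind[max(0, s) : min(n, e)] = 1
            cache[f"cum_{name}"] = np.concatenate(([0], np.cumsum(ind)))
        best_scores = []
        for dist in self._dists:
            scaled = dist._scaled
            rc = scaled[_COMP_CODE_ORDER][:, ::-1]
            fwd = scaled_scores(codes, scaled)
            rev = scaled_scores(codes, rc)
            best_scores.append((np.maximum(fwd, rev), scaled.shape[1]))
        cache["motif_best"] = best_scores
        return self._cache.setdefault(chrom, cache)

    def window_features(self, chrom: str, starts: np.ndarray) -> pd.DataFrame:
        cfg = self.cfg
        cache = self._chrom_cache(chrom)
        w = cfg.scan_window
        n_win = starts.size
        blocks = []
        for k in (2, 3, 4):
            ids = cache[f"ids{k}"]
            block = np.empty((n_win, 4**k))
            for i, s in enumerate(starts):
                window_ids = ids[s : s + w - k + 1]
                window_ids = window_ids[window_ids >= 0]
                counts = np.bincount(window_ids, minlength=4**k)
                total = counts.sum()
                block[i] = counts / total if total else counts
            blocks.append(block)
        ends = starts + w
        n_c = cache["cum_c"][ends] - cache["cum_c"][starts]
        n_g = cache["cum_g"][ends] - cache["cum_g"][starts]
        n_cg = cache["cum_cg"][ends - 1] - cache["cum_cg"][starts]
        denom = n_c * n_g
        oe = np.where(denom > 0, n_cg * w / np.maximum(denom, 1), 0.0)
        cgi_cov = (cache["cum_cgi"][ends] - cache["cum_cgi"][starts]) / w
        rep_cov = (cache["cum_repeat"][ends] - cache["cum_repeat"][starts]) / w
        motif_cols = []
        for (best, width), thr in zip(cache["motif_best"], self._thresholds):
            col = np.empty(n_win)
            for i, s in enumerate(starts):
                sub = best[s : min(s + w - width + 1, best.size)]
                col[i] = float(sub.max() >= thr) if sub.size else 0.0
            motif_cols.append(col)
        cage = np.array(
            [self.inputs.cage.mean(chrom, s, s + w) for s in starts]
        )
        marks = [
            np.array(
                [
                    self.inputs.chromatin[mark].mean(chrom, s, s + w)
                    for s in starts
                ]
            )
            for mark in CHROMATIN_FEATURES
        ]
        data = np.column_stack(
            blocks + [oe, cgi_cov, rep_cov] + motif_cols + [cage] + marks
        )
        index = [f"{chrom}:{s}-{s + w}(+)" for s in starts]
        return pd.DataFrame(data, index=index, columns=feature_names(self.inputs.pwms))


# ---------------------------------------------------------------------------
# Training set


@dataclass
class TrainingSet:
    regions: list[GenomeInterval]
    features: pd.DataFrame
    labels: np.ndarray
    n_pos: int
    n_neg: int

    @property
    def ratio(self) -> float:
        return self.n_neg / self.n_pos


def expressed_lincs(
    lincs: Sequence[TranscriptModel],
    expression: ExpressionTable,
    min_fpkm: float,
) -> list[TranscriptModel]:
    return [
        tx for tx in lincs if tx.id in expression and expression.mean_fpkm(tx.id) >= min_fpkm
    ]


def build_training_set(
    lincs: Sequence[TranscriptModel],
    annotation: Sequence[TranscriptModel],
    inputs: FeatureInputs,
    expression: ExpressionTable | None = None,
    cfg: PipelineConfig | None = None,
    seed: int = 0,
    max_tries: int = 200,
) -> TrainingSet:
    """Positive TSS proximal regions plus sampled unannotated negatives.

    ``lincs`` are the reference lincRNAs (filtered to mean FPKM >=
    cfg.min_fpkm_known when ``expression`` is given).  Negatives are
    1,500 bp windows drawn uniformly (seeded) within +-10 kb of each
    positive TSS that overlap no annotated exon and no positive region;
    a TSS with no valid negative after ``max_tries`` draws is dropped.
    """
    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(seed)
    if expression is not None:
        lincs = expressed_lincs(lincs, expression, cfg.min_fpkm_known)
    positives = [
        tss_proximal_region(tx.chrom, tx.tss, tx.strand, cfg.tss_up, cfg.tss_down)
        for tx in lincs
    ]
    exon_index = IntervalIndex(e for tx in annotation for e in tx.exons)
    pos_index = IntervalIndex(positives)
    regions: list[GenomeInterval] = []
    labels: list[bool] = []
    ids: list[str] = []
    n_neg = 0
    for tx, pos in zip(lincs, positives):
        chrom_len = len(inputs.genome[tx.chrom])
        negs: list[GenomeInterval] = []
        lo = max(0, tx.tss - cfg.neg_zone)
        hi = min(chrom_len, tx.tss + cfg.neg_zone) - cfg.scan_window
        for _ in range(max_tries):
            if len(negs) == cfg.neg_per_pos:
                break
            start = int(rng.integers(lo, hi + 1))
            cand = GenomeInterval(tx.chrom, start, start + cfg.scan_window, tx.strand)
            if exon_index.any_overlap(cand) or pos_index.any_overlap(cand):
                continue
            if any(cand.overlaps(n) for n in negs):
                continue
            negs.append(cand)
        if len(negs) < cfg.neg_per_pos:
            warnings.warn(f"no valid negative window for TSS of {tx.id}; dropped")
            continue
        regions.append(pos)
        labels.append(True)
        ids.append(f"pos_{tx.id}")
        for j, neg in enumerate(negs):
            regions.append(neg)
            labels.append(False)
            ids.append(f"neg_{tx.id}_{j}")
        n_neg += len(negs)
    features = region_features(regions, inputs, cfg, ids=ids)
    return TrainingSet(
        regions=regions,
        features=features,
        labels=np.asarray(labels, dtype=bool),
        n_pos=int(np.sum(labels)),
        n_neg=n_neg,
    )


# ---------------------------------------------------------------------------
# Model and cross-validation


@dataclass
class CvReport:
    """10-fold CV metrics: the confusion-matrix panel plus ROC/PRC areas."""

    accuracy: float
    error_rate: float
    sensitivity: float
    specificity: float
    precision: float
    auroc: float
    auprc: float
    per_fold: pd.DataFrame
    roc_curve: pd.DataFrame
    prc_curve: pd.DataFrame
    n_pos: int
    n_neg: int

    def summary(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "error_rate": self.error_rate,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "auroc": self.auroc,
            "auprc": self.auprc,
        }


@dataclass
class TssModel:
    """A fitted scaler+SVM over a fixed, named feature schema."""

    pipeline: Pipeline
    feature_names: list[str]

    def decision(self, features: pd.DataFrame) -> np.ndarray:
        return self.pipeline.decision_function(features[self.feature_names])

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return self.decision(features) > 0


def _make_pipeline(n_features: int, cfg: PipelineConfig) -> Pipeline:
    # gamma acts on the dimension-averaged squared distance: gamma/n_features
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "svm",
                SVC(
                    kernel="rbf",
                    gamma=cfg.svm_gamma / n_features,
                    C=cfg.svm_cost,
                ),
            ),
        ]
    )


def train_and_cv(
    features: pd.DataFrame,
    labels: np.ndarray,
    columns: Sequence[str] | None = None,
    cfg: PipelineConfig | None = None,
    seed: int = 0,
) -> tuple[CvReport, TssModel]:
    """Stratified k-fold CV (standardization fit inside folds), then a final
    fit on all data.  ``columns`` restricts to a feature group."""
    cfg = cfg or PipelineConfig()
    labels = np.asarray(labels, dtype=bool)
    X = features if columns is None else features[list(columns)]
    names = list(X.columns)
    counts = np.bincount(labels.astype(int), minlength=2)
    if counts.min() < cfg.cv_folds:
        raise ValueError(
            f"need >= {cfg.cv_folds} examples per class, got {counts.tolist()}"
        )
    skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=seed)
    scores = np.empty(len(labels))
    fold_rows = []
    for fold, (train, test) in enumerate(skf.split(X, labels)):
        pipe = _make_pipeline(len(names), cfg)
        pipe.fit(X.iloc[train], labels[train])
        s = pipe.decision_function(X.iloc[test])
        scores[test] = s
        pred = s > 0
        truth = labels[test]
        tp = int((pred & truth).sum())
        tn = int((~pred & ~truth).sum())
        fp = int((pred & ~truth).sum())
        fn = int((~pred & truth).sum())
        fold_rows.append(
            {
                "fold": fold,
                "accuracy": (tp + tn) / truth.size,
                "sensitivity": tp / max(tp + fn, 1),
                "specificity": tn / max(tn + fp, 1),
                "precision": tp / max(tp + fp, 1),
                "auroc": roc_auc_score(truth, s) if 0 < truth.sum() < truth.size else np.nan,
            }
        )
    pred = scores > 0
    tp = int((pred & labels).sum())
    tn = int((~pred & ~labels).sum())
    fp = int((pred & ~labels).sum())
    fn = int((~pred & labels).sum())
    accuracy = (tp + tn) / labels.size
    fpr, tpr, _ = roc_curve(labels, scores)
    prec_c, rec_c, _ = precision_recall_curve(labels, scores)
    report = CvReport(
        accuracy=accuracy,
        error_rate=1.0 - accuracy,
        sensitivity=tp / max(tp + fn, 1),
        specificity=tn / max(tn + fp, 1),
        precision=tp / max(tp + fp, 1),
        auroc=float(roc_auc_score(labels, scores)),
        auprc=float(average_precision_score(labels, scores)),
        per_fold=pd.DataFrame(fold_rows),
        roc_curve=pd.DataFrame({"fpr": fpr, "tpr": tpr}),
        prc_curve=pd.DataFrame({"recall": rec_c, "precision": prec_c}),
        n_pos=int(labels.sum()),
        n_neg=int((~labels).sum()),
    )
    final = _make_pipeline(len(names), cfg)
    final.fit(X, labels)
    return report, TssModel(pipeline=final, feature_names=names)


def ablation(
    features: pd.DataFrame,
    labels: np.ndarray,
    pwms: Sequence[Pwm],
    cfg: PipelineConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """One CV row per feature group plus the all-features model."""
    rows = []
    for group, cols in feature_groups(pwms).items():
        report, _ = train_and_cv(features, labels, cols, cfg, seed)
        rows.append({"features": group, **report.summary()})
    report, _ = train_and_cv(features, labels, None, cfg, seed)
    rows.append({"features": "all", **report.summary()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Genome-wide scan


@dataclass
class PredictedRegionSet:
    """Scan windows classified as TSS proximal regions, with SVM scores."""

    regions: list[GenomeInterval]
    scores: np.ndarray

    def __len__(self) -> int:
        return len(self.regions)

    def merged(self) -> list[GenomeInterval]:
        out = []
        by_chrom: dict[str, list[GenomeInterval]] = {}
        for r in self.regions:
            by_chrom.setdefault(r.chrom, []).append(r)
        for chrom in sorted(by_chrom):
            for s, e in merge_intervals((r.start, r.end) for r in by_chrom[chrom]):
                out.append(GenomeInterval(chrom, s, e, "."))
        return out


def candidate_windows(
    chrom_len: int, chrom: str, annotation_exons: IntervalIndex, cfg: PipelineConfig
) -> np.ndarray:
    """Window starts on the step lattice, excluding annotated-exon overlap."""
    if chrom_len < cfg.scan_window:
        warnings.warn(f"{chrom}: shorter than one scan window; skipped")
        return np.empty(0, dtype=np.int64)
    starts = np.arange(0, chrom_len - cfg.scan_window + 1, cfg.scan_step)
    keep = [
        s
        for s in starts
        if not annotation_exons.any_overlap(
            GenomeInterval(chrom, int(s), int(s) + cfg.scan_window)
        )
    ]
    return np.asarray(keep, dtype=np.int64)


def genome_scan(
    model: TssModel,
    inputs: FeatureInputs,
    annotation: Sequence[TranscriptModel],
    cfg: PipelineConfig | None = None,
) -> PredictedRegionSet:
    """Classify every unannotated scan window; keep the positives."""
    cfg = cfg or PipelineConfig()
    exon_index = IntervalIndex(e for tx in annotation for e in tx.exons)
    scanner = WindowScanner(inputs, cfg)
    regions: list[GenomeInterval] = []
    scores: list[float] = []
    for chrom in sorted(inputs.genome):
        starts = candidate_windows(len(inputs.genome[chrom]), chrom, exon_index, cfg)
        if starts.size == 0:
            continue
        feats = scanner.window_features(chrom, starts)
        s = model.decision(feats)
        for start, val in zip(starts, s):
            if val > 0:
                regions.append(
                    GenomeInterval(chrom, int(start), int(start) + cfg.scan_window, ".")
                )
                scores.append(float(val))
    return PredictedRegionSet(regions=regions, scores=np.asarray(scores))
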