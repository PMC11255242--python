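"""Classification of R-loop-prone regions from (GC skew, G%, T%).

An RBF support-vector machine (logistic regression as a deterministic
fallback) separates T-run-associated peak regions from random gene
regions; the trained model can scan a genome gene-by-gene for predicted
prone regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .genome import GenomeBundle
from .seqfeat import base_pct, find_t_runs, gc_skew

FEATURE_NAMES = ("gc_skew", "g_pct", "t_pct")


@dataclass
class ClassifierSpec:
    kind: str = "svm_rbf"  # or "logistic"
    C: float = 1.0
    n_folds: int = 5


@dataclass
class TrainedClassifier:
    kind: str
    means: np.ndarray
    sds: np.ndarray
    cv_accuracy: float
    roc: pd.DataFrame  # fpr, tpr
    auc: float
    seed: int
    # svm_rbf parameters
    gamma: float = 0.0
    support_vectors: np.ndarray | None = None
    dual_coef: np.ndarray | None = None
    intercept: float = 0.0
    # logistic parameters
    coef: np.ndarray | None = None

    def _standardize(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.means) / self.sds

    def decision_function(self, x: np.ndarray) -> np.ndarray:
        """Signed decision scores; > 0 predicts the positive class."""
        z = self._standardize(np.atleast_2d(x))
        if self.kind == "svm_rbf":
            d2 = (
                np.sum(z**2, axis=1)[:, None]
                + np.sum(self.support_vectors**2, axis=1)[None, :]
                - 2.0 * z @ self.support_vectors.T
            )
            k = np.exp(-self.gamma * np.maximum(d2, 0.0))
            return k @ self.dual_coef + self.intercept
        return z @ self.coef + self.intercept

    def predict(self, x: np.ndarray) -> np.ndarray:
        return (self.decision_function(x) > 0).astype(int)

    # ------------------------------------------------------------- text I/O

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"kind\t{self.kind}\n")
            fh.write("means\t" + "\t".join(f"{v:.17g}" for v in self.means) + "\n")
            fh.write("sds\t" + "\t".join(f"{v:.17g}" for v in self.sds) + "\n")
            fh.write(f"cv_accuracy\t{self.cv_accuracy:.17g}\n")
            fh.write(f"auc\t{self.auc:.17g}\n")
            fh.write(f"seed\t{self.seed}\n")
            fh.write(f"intercept\t{self.intercept:.17g}\n")
            if self.kind == "svm_rbf":
                fh.write(f"gamma\t{self.gamma:.17g}\n")
                fh.write(f"n_sv\t{len(self.dual_coef)}\n")
                for sv, a in zip(self.support_vectors, self.dual_coef):
                    fh.write(
                        "sv\t" + "\t".join(f"{v:.17g}" for v in sv) + f"\t{a:.17g}\n"
                    )
            else:
                fh.write("coef\t" + "\t".join(f"{v:.17g}" for v in self.coef) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "TrainedClassifier":
        fields: dict[str, list[list[str]]] = {}
        with open(path) as fh:
            for line in fh:
                key, *vals = line.rstrip("\n").split("\t")
                fields.setdefault(key, []).append(vals)
        kind = fields["kind"][0][0]
        model = cls(
            kind=kind,
            means=np.array([float(v) for v in fields["means"][0]]),
            sds=np.array([float(v) for v in fields["sds"][0]]),
            cv_accuracy=float(fields["cv_accuracy"][0][0]),
            roc=pd.DataFrame(columns=["fpr", "tpr"]),
            auc=float(fields["auc"][0][0]),
            seed=int(fields["seed"][0][0]),
            intercept=float(fields["intercept"][0][0]),
        )
        if kind == "svm_rbf":
            model.gamma = float(fields["gamma"][0][0])
            rows = fields["sv"]
            model.support_vectors = np.array(
                [[float(v) for v in r[:-1]] for r in rows]
            )
            model.dual_coef = np.array([float(r[-1]) for r in rows])
        else:
            model.coef = np.array([float(v) for v in fields["coef"][0]])
        return model


# --------------------------------------------------------------------------
# ROC / AUC (own implementation; cross-checked against the U statistic)


def roc_curve_points(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """(FPR, TPR) swept over every distinct decision threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    order = np.argsort(-scores, kind="mergesort")
    labels = labels[order]
    scores_sorted = scores[order]
    tp = np.cumsum(labels)
    fp = np.cumsum(1 - labels)
    # keep the last point of every tied-score block
    keep = np.concatenate([np.diff(scores_sorted) != 0, [True]])
    tpr = np.concatenate([[0.0], tp[keep] / max(1, labels.sum())])
    fpr = np.concatenate([[0.0], fp[keep] / max(1, (1 - labels).sum())])
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def auc_trapezoid(roc: pd.DataFrame) -> float:
    return float(np.trapezoid(roc["tpr"].to_numpy(), roc["fpr"].to_numpy()))


# --------------------------------------------------------------------------
# training


def _fit_once(
    x: np.ndarray, y: np.ndarray, spec: ClassifierSpec, gamma: float, seed: int
):
    if spec.kind == "svm_rbf":
        clf = SVC(C=spec.C, kernel="rbf", gamma=gamma, random_state=seed)
    elif spec.kind == "logistic":
        clf = LogisticRegression(C=spec.C, max_iter=1000)
    else:
        raise ValueError(f"unknown classifier kind {spec.kind!r}")
    clf.fit(x, y)
    return clf


def train_classifier(
    pos: np.ndarray,
    neg: np.ndarray,
    spec: ClassifierSpec | None = None,
    seed: int = 0,
) -> TrainedClassifier:
    """Train on positive/negative feature rows (columns: gc_skew, g_pct, t_pct).

    Features are standardized with training statistics; the RBF bandwidth is
    1 / (3 * pooled feature variance) after standardization. Stratified
    k-fold CV accuracy and an ROC/AUC from out-of-fold decision scores are
    recorded on the model.
    """
    spec = spec or ClassifierSpec()
    pos = np.atleast_2d(np.asarray(pos, dtype=float))
    neg = np.atleast_2d(np.asarray(neg, dtype=float))
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be non-empty")
    if len(pos) < 20 or len(neg) < 20:
        raise ValueError("need >= 20 examples per class")

    x = np.vstack([pos, neg])
    y = np.concatenate([np.ones(len(pos), dtype=int), np.zeros(len(neg), dtype=int)])
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=0)
    sds[sds == 0] = 1.0
    z = (x - means) / sds
    pooled_var = float(z.var(axis=0, ddof=0).mean())
    gamma = 1.0 / (3.0 * pooled_var) if pooled_var > 0 else 1.0

    cv = StratifiedKFold(n_splits=spec.n_folds, shuffle=True, random_state=seed)
    oof_scores = np.zeros(len(y))
    correct = 0
    for train_idx, test_idx in cv.split(z, y):
        clf = _fit_once(z[train_idx], y[train_idx], spec, gamma, seed)
        s = clf.decision_function(z[test_idx])
        oof_scores[test_idx] = s
        correct += int(np.sum((s > 0).astype(int) == y[test_idx]))
    cv_accuracy = correct / len(y)
    roc = roc_curve_points(oof_scores, y)
    auc = auc_trapezoid(roc)

    final = _fit_once(z, y, spec, gamma, seed)
    model = TrainedClassifier(
        kind=spec.kind,
        means=means,
        sds=sds,
        cv_accuracy=cv_accuracy,
        roc=roc,
        auc=auc,
        seed=seed,
    )
    if spec.kind == "svm_rbf":
        model.gamma = gamma
        model.support_vectors = final.support_vectors_
        model.dual_coef = final.dual_coef_.ravel()
        model.intercept = float(final.intercept_[0])
    else:
        model.coef = final.coef_.ravel()
        model.intercept = float(final.intercept_[0])
    return model


def evaluate(model: TrainedClassifier, x: np.ndarray, y: np.ndarray) -> dict:
    """Accuracy at threshold 0, ROC, trapezoid AUC, confusion counts."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y).astype(int)
    if len(x) == 0:
        raise ValueError("empty test set")
    scores = model.decision_function(x)
    pred = (scores > 0).astype(int)
    roc = roc_curve_points(scores, y)
    return {
        "accuracy": float(np.mean(pred == y)),
        "roc": roc,
        "auc": auc_trapezoid(roc),
        "tp": int(np.sum((pred == 1) & (y == 1))),
        "fp": int(np.sum((pred == 1) & (y == 0))),
        "tn": int(np.sum((pred == 0) & (y == 0))),
        "fn": int(np.sum((pred == 0) & (y == 1))),
        "scores": scores,
    }


# --------------------------------------------------------------------------
# genome scanning


@dataclass
class ScanHit:
    chrom: str
    strand: str
    start: int
    end: int
    score: float  # mean decision score of merged windows
    max_trun: int


def window_features(seq: str) -> tuple[float, float, float]:
    return gc_skew(seq), base_pct(seq, "G"), base_pct(seq, "T")


def scan_genome(
    model: TrainedClassifier,
    bundle: GenomeBundle,
    window: int = 300,
    step: int = 50,
    min_trun: int = 5,
) -> list[ScanHit]:
    """Slide windows along each gene's sense strand; classify windows whose
    tail half holds a T-run >= min_trun; merge overlapping positive windows."""
    t_probe = "T" * min_trun
    hits: list[ScanHit] = []
    for gene in bundle.genes:
        chrom_len = bundle.chrom_length(gene.chrom)
        if window > chrom_len:
            continue
        span_start, span_end = gene.start, min(gene.end, chrom_len)
        if span_end - span_start < window:
            continue
        gene_seq = bundle.fetch(gene.chrom, span_start, span_end, gene.strand)
        n = len(gene_seq)
        candidates = []  # (sense offset, features, max_trun)
        for off in range(0, n - window + 1, step):
            wseq = gene_seq[off : off + window]
            tail = wseq[window // 2 :]
            if t_probe not in tail:
                continue
            runs = find_t_runs(wseq, min_trun)
            candidates.append((off, window_features(wseq), max(r.length for r in runs) if runs else 0))
        if not candidates:
            continue
        feats = np.array([c[1] for c in candidates])
        scores = model.decision_function(feats)
        positives = [
            (c[0], s, c[2]) for c, s in zip(candidates, scores) if s > 0
        ]
        if not positives:
            continue
        # sense offsets -> genomic intervals
        intervals = []
        for off, s, mt in positives:
            if gene.strand == "+":
                gstart = span_start + off
            else:
                gstart = span_end - off - window
            intervals.append((gstart, gstart + window, s, mt))
        intervals.sort()
        cur = list(intervals[0]) + [1]
        for iv in intervals[1:]:
            if iv[0] <= cur[1]:
                cur[1] = max(cur[1], iv[1])
                cur[2] += iv[2]
                cur[3] = max(cur[3], iv[3])
                cur[4] += 1
            else:
                hits.append(
                    ScanHit(gene.chrom, gene.strand, cur[0], cur[1], cur[2] / cur[4], cur[3])
                )
                cur = list(iv) + [1]
        hits.append(
            ScanHit(gene.chrom, gene.strand, cur[0], cur[1], cur[2] / cur[4], cur[3])
        )
    return hits


def count_hits_per_gene(hits: list[ScanHit], bundle: GenomeBundle) -> pd.Series:
    """Hits assigned to the gene whose span contains the hit midpoint."""
    counts = {g.gene_id: 0 for g in bundle.genes}
    for hit in hits:
        mid = (hit.start + hit.end) // 2
        for g in bundle.genes:
            if (
                g.chrom == hit.chrom
                and g.strand == hit.strand
                and g.start <= mid < g.end
            ):
                counts[g.gene_id] += 1
                break
    return pd.Series(counts, name="n_hits")


def write_hits_bed(hits: list[ScanHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\tmax_trun\n")
        for i, h in enumerate(hits, 1):
            fh.write(
                f"{h.chrom}\t{h.start}\t{h.end}\thit_{i}\t{h.score:.4f}\t"
                f"{h.strand}\t{h.max_trun}\n"
            )
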