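"""Identification and verification metrics.

Identification: a K-class confusion matrix and macro-averaged one-vs-rest
accuracy / precision / recall / specificity (percentages) with the F1 score
computed from the macro precision and recall. Verification: FAR / FRR at a
threshold, threshold sweeps, ROC and DET curves with trapezoidal AUC and an
interpolated EER, and an empirical chance level obtained by retraining the
classifier on label-shuffled training data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class ConfusionMatrix:
    counts: np.ndarray              # (K, K); rows true, columns predicted
    class_labels: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricReport:
    """Macro metrics; accuracy/precision/recall/specificity are percentages,
    f1 is unitless in [0, 1]. ``overall_accuracy`` is the plain fraction of
    correctly classified segments (in [0, 1])."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    specificity: float
    overall_accuracy: float
    per_class: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class ErrorRates:
    far: float
    frr: float
    eer: float | None = None
    curve: list[tuple[float, float, float]] = field(default_factory=list)


def confusion_matrix(true_labels, predicted_labels, k: int,
                     class_labels=None) -> ConfusionMatrix:
    """counts[i, j] = number of samples with true class i predicted as j."""
    if class_labels is None:
        class_labels = np.arange(1, k + 1)
    class_labels = np.asarray(class_labels)
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("true and predicted labels must have equal length")
    lut = {lab: i for i, lab in enumerate(class_labels.tolist())}
    counts = np.zeros((k, k), dtype=int)
    for ti, pi in zip(t.tolist(), p.tolist()):
        if ti not in lut or pi not in lut:
            raise ValueError(f"label pair ({ti}, {pi}) outside the class set")
        counts[lut[ti], lut[pi]] += 1
    return ConfusionMatrix(counts=counts, class_labels=class_labels)


def macro_metrics(cm: ConfusionMatrix, f1_per_class: bool = False) -> MetricReport:
    """Macro one-vs-rest metrics from a confusion matrix.

    Per class k: TP = counts[k,k]; FN = row k minus TP; FP = column k minus
    TP; TN = the rest. Macro values are unweighted means over classes whose
    ratios are defined (empty classes are excluded with a warning).
    F1 = 2PR/(P+R) from the macro precision and recall; ``f1_per_class=True``
    instead averages per-class F1 values.
    """
    c = cm.counts.astype(float)
    total = c.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(c)
    fn = c.sum(axis=1) - tp
    fp = c.sum(axis=0) - tp
    tn = total - tp - fn - fp

    present = (tp + fn) > 0
    if not present.all():
        warnings.warn("classes with no true samples excluded from macro "
                      "recall/accuracy", stacklevel=2)

    def _safe(num, den):
        with np.errstate(invalid="ignore", divide="ignore"):
            r = num / den
        return r

    acc_k = _safe(tp + tn, tp + tn + fp + fn)
    prec_k = _safe(tp, tp + fp)
    rec_k = _safe(tp, tp + fn)
    spec_k = _safe(tn, tn + fp)

    def _macro(vals, mask=None):
        v = vals if mask is None else vals[mask]
        v = v[np.isfinite(v)]
        return float(v.mean()) if v.size else float("nan")

    precision = _macro(prec_k)
    recall = _macro(rec_k, present)
    if f1_per_class:
        with np.errstate(invalid="ignore", divide="ignore"):
            f1_k = 2 * rec_k * prec_k / (rec_k + prec_k)
        f1 = _macro(f1_k, present)
    else:
        f1 = (2 * recall * precision / (recall + precision)
              if (recall + precision) > 0 else 0.0)
    return MetricReport(
        accuracy=100.0 * _macro(acc_k, present),
        precision=100.0 * precision,
        recall=100.0 * recall,
        f1=f1,
        specificity=100.0 * _macro(spec_k),
        overall_accuracy=float(tp.sum() / total),
        per_class={"accuracy": acc_k, "precision": prec_k, "recall": rec_k,
                   "specificity": spec_k, "tp": tp, "tn": tn, "fp": fp, "fn": fn},
    )


def far_frr(decisions, is_genuine, pooled_attempts: bool = False) -> ErrorRates:
    """FAR and FRR of a set of decided attempts.

    Default convention: FAR = false accepts / imposter attempts and FRR =
    false rejects / genuine attempts. ``pooled_attempts=True`` divides both
    counts by the total number of attempts instead.
    """
    genuine = np.asarray(is_genuine, dtype=bool)
    accepted = np.asarray([d.verdict == "genuine" for d in decisions])
    if genuine.shape != accepted.shape:
        raise ValueError("decisions and is_genuine must align")
    n_gen = int(genuine.sum())
    n_imp = int((~genuine).sum())
    if n_gen == 0 or n_imp == 0:
        raise ValueError("need at least one genuine and one imposter attempt")
    fa = int((accepted & ~genuine).sum())
    fr = int((~accepted & genuine).sum())
    if pooled_attempts:
        total = n_gen + n_imp
        return ErrorRates(far=fa / total, frr=fr / total)
    return ErrorRates(far=fa / n_imp, frr=fr / n_gen)


def far_frr_curve(scores, is_genuine, thetas) -> ErrorRates:
    """Sweep acceptance thresholds over the score set (accept iff score >=
    theta) and report the (theta, FAR, FRR) curve plus the interpolated EER."""
    s = np.asarray(scores, dtype=float)
    g = np.asarray(is_genuine, dtype=bool)
    n_gen, n_imp = int(g.sum()), int((~g).sum())
    if n_gen == 0 or n_imp == 0:
        raise ValueError("need both genuine and imposter scores")
    curve = []
    for th in thetas:
        accept = s >= th
        far = float((accept & ~g).sum() / n_imp)
        frr = float((~accept & g).sum() / n_gen)
        curve.append((float(th), far, frr))
    eer = _interp_eer([(c[1], c[2]) for c in curve])
    last = curve[-1]
    return ErrorRates(far=last[1], frr=last[2], eer=eer, curve=curve)


def _interp_eer(far_frr_pairs) -> float | None:
    """Linear interpolation of the FAR = FRR crossing along the sweep."""
    diffs = [far - frr for far, frr in far_frr_pairs]
    for i in range(len(diffs) - 1):
        d0, d1 = diffs[i], diffs[i + 1]
        if d0 == 0:
            return far_frr_pairs[i][0]
        if d0 * d1 < 0:
            w = d0 / (d0 - d1)
            far = far_frr_pairs[i][0] + w * (far_frr_pairs[i + 1][0] - far_frr_pairs[i][0])
            return float(far)
    if diffs and diffs[-1] == 0:
        return far_frr_pairs[-1][0]
    return None


def roc_det_curves(beta_scores) -> dict:
    """ROC and DET curves from (score, is_genuine) pairs.

    Thresholds sweep the unique scores (accept iff score >= t), from strict
    to permissive, giving ROC points (FPR, TPR) from (0,0) to (1,1) and DET
    points (FPR, FNR). AUC is trapezoidal over the ROC; EER is linearly
    interpolated where FPR crosses FNR.
    """
    pairs = list(beta_scores)
    s = np.asarray([p[0] for p in pairs], dtype=float)
    g = np.asarray([p[1] for p in pairs], dtype=bool)
    n_gen, n_imp = int(g.sum()), int((~g).sum())
    if n_gen == 0 or n_imp == 0:
        raise ValueError("need both genuine and imposter scores")
    thresholds = np.unique(s)[::-1]
    fpr = [0.0]
    tpr = [0.0]
    for t in thresholds:
        accept = s >= t
        fpr.append(float((accept & ~g).sum() / n_imp))
        tpr.append(float((accept & g).sum() / n_gen))
    fpr.append(1.0)
    tpr.append(1.0)
    fpr_arr, tpr_arr = np.asarray(fpr), np.asarray(tpr)
    auc = float(np.trapezoid(tpr_arr, fpr_arr))
    fnr_arr = 1.0 - tpr_arr
    eer = _interp_eer(list(zip(fpr_arr, fnr_arr)))
    return {
        "roc": list(zip(fpr_arr.tolist(), tpr_arr.tolist())),
        "det": list(zip(fpr_arr.tolist(), fnr_arr.tolist())),
        "auc": auc,
        "eer": eer,
    }


def chance_level(train_values, train_labels, test_values, test_labels,
                 config=None, n_shuffles: int = 100, seed: int = 0,
                 fast_epochs: int | None = None) -> dict:
    """Empirical chance level by label-shuffled retraining.

    For each shuffle the *training* labels are permuted (the test set is
    untouched), the network is retrained with the given recipe, and plain
    accuracy on the test set is recorded. ``fast_epochs`` optionally reduces
    the epoch count — an approximation for constrained runtimes.
    """
    import dataclasses as _dc

    from .classify import FfnnConfig, predict, train_ffnn

    config = config or FfnnConfig()
    if fast_epochs is not None:
        config = _dc.replace(config, epochs=fast_epochs)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))
    test_labels = np.asarray(test_labels)
    test_before = np.array(test_values, copy=True)
    accs = []
    for i in range(n_shuffles):
        shuffled = rng.permutation(np.asarray(train_labels))
        cfg = _dc.replace(config, seed=int(rng.integers(0, 2**31 - 1)))
        model = train_ffnn(train_values, shuffled, cfg)
        preds = predict(model, test_values)
        accs.append(float(np.mean(preds.predicted_labels == test_labels)))
    assert np.array_equal(test_before, np.asarray(test_values)), \
        "test set must not be mutated by the shuffle procedure"
    accs_arr = np.asarray(accs)
    return {"mean": float(accs_arr.mean()),
            "sd": float(accs_arr.std(ddof=1)) if n_shuffles > 1 else 0.0,
            "accuracies": accs}
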