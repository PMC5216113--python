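"""Precision/recall scoring, threshold sweeps and the leave-one-subject-out
(LOSO) harness comparing SVM-only detection with SVM + HMM refinement.

Scoring is per breathing cycle: TP = swallow cycles classified swallow,
FP = normal cycles classified swallow, P = annotated swallow cycles.
Precision = TP/(TP+FP), Recall = TP/P; empty denominators yield NaN
(with a warning) rather than 0, so averages stay honest. Cycles flagged
as drinking are excluded before counting.

In the LOSO protocol each subject's sessions are held out in turn while
all other subjects train the SVM, the posterior sigmoid and the HMM
matrices — the fold-clean analogue of training on five subjects and
testing on the sixth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .features import CycleFeaturizer
from .hmm import SwallowHMM
from .io import AnnotationTrack, RawSignal, label_cycles
from .segmentation import CycleSegmenter
from .simulate import SimulationConfig, simulate_session
from .svm import SwallowSVM

__all__ = [
    "DetectionMetrics",
    "SweepResult",
    "score",
    "sweep_thresholds",
    "prepare_session",
    "simulate_subjects",
    "loso_evaluate",
    "run_pipeline",
]

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.1, 0.91, 0.1), 10))


@dataclass
class DetectionMetrics:
    """Cycle-level detection counts and ratios."""

    tp: int
    fp: int
    p: int
    precision: float
    recall: float

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "p": self.p,
                "precision": self.precision, "recall": self.recall}


@dataclass
class SweepResult:
    """Per-threshold SVM-only metrics plus the single SVM+HMM point."""

    thresholds: tuple
    svm: list  # DetectionMetrics per threshold
    svm_hmm: DetectionMetrics | None = None
    subject: str = ""
    n_cycles: int = 0


def score(predicted, true, excluded=None) -> DetectionMetrics:
    """Score aligned per-cycle label sequences (1 swallow / 0 normal).

    ``excluded`` marks cycles removed from counting (drink cycles).
    """
    pred = np.asarray(predicted).astype(int)
    truth = np.asarray(true).astype(int)
    pred = np.where(pred > 0, 1, 0)  # accept ±1 coding
    truth = np.where(truth > 0, 1, 0)
    if pred.shape != truth.shape:
        raise ValueError("predicted and true label sequences must align")
    if excluded is not None:
        keep = ~np.asarray(excluded, dtype=bool)
        pred, truth = pred[keep], truth[keep]
    tp = int(((pred == 1) & (truth == 1)).sum())
    fp = int(((pred == 1) & (truth == 0)).sum())
    p = int((truth == 1).sum())
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        warnings.warn("no detections: precision undefined (NaN)", stacklevel=2)
        precision = float("nan")
    if p > 0:
        recall = tp / p
    else:
        warnings.warn("no relevant swallows: recall undefined (NaN)", stacklevel=2)
        recall = float("nan")
    return DetectionMetrics(tp, fp, p, precision, recall)


def sweep_thresholds(posteriors, true, thresholds=DEFAULT_THRESHOLDS,
                     excluded=None) -> list[DetectionMetrics]:
    """SVM-only metrics for each posterior threshold Pth."""
    posteriors = np.asarray(posteriors, dtype=float)
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for pth in thresholds:
            out.append(score((posteriors >= pth).astype(int), true, excluded))
    return out


def cycle_recovery(truth, cycles, tol: float = 0.25) -> tuple[int, int]:
    """How many true cycles the segmenter recovered.

    A true cycle (consecutive ground-truth boundaries) counts as
    recovered iff some detected cycle matches both its start and end
    valley within ``tol`` seconds — so a split or merged cycle is a
    miss. Returns (recovered, total).
    """
    starts = np.array([c.start_time for c in cycles])
    ends = np.array([c.end_time for c in cycles])
    tb = np.asarray(truth.cycle_boundaries, dtype=float)
    ok = sum(
        int(((np.abs(starts - s) <= tol) & (np.abs(ends - e) <= tol)).any())
        if len(starts) else 0
        for s, e in zip(tb[:-1], tb[1:])
    )
    return ok, len(tb) - 1


def prepare_session(signal: RawSignal, annotations: AnnotationTrack,
                    segmenter: CycleSegmenter | None = None):
    """Segment, featurize and label one session.

    Returns (features DataFrame, labels 0/1, excluded mask) with one row
    per detected breathing cycle.
    """
    segmenter = segmenter or CycleSegmenter()
    cycles = segmenter.transform(signal)
    features = CycleFeaturizer().transform(cycles)
    labels, excluded = label_cycles(cycles, annotations)
    return features, labels, excluded


def simulate_subjects(n_subjects: int, seed: int,
                      config_overrides: dict | None = None,
                      sessions_per_subject: int = 1) -> dict:
    """Simulated cohort: per-subject lists of (RawSignal, AnnotationTrack).

    Subject/session seeds are derived deterministically from ``seed``.
    """
    overrides = dict(config_overrides or {})
    cohort: dict[str, list] = {}
    for s in range(n_subjects):
        sessions = []
        for j in range(sessions_per_subject):
            cfg = SimulationConfig(**overrides,
                                   seed=(seed * 1009 + s * 131 + j) % (2 ** 31))
            signal, truth = simulate_session(cfg)
            signal.subject_id = f"subject{s + 1}"
            sessions.append((signal,
                             AnnotationTrack(truth.swallow_times, source="simulator")))
        cohort[f"subject{s + 1}"] = sessions
    return cohort


def _aggregate(metrics: list[DetectionMetrics]) -> dict:
    """Macro-average precision/recall, skipping NaN entries with the
    convention that undefined metrics do not enter the mean."""
    prec = [m.precision for m in metrics if np.isfinite(m.precision)]
    rec = [m.recall for m in metrics if np.isfinite(m.recall)]
    return {
        "precision": float(np.mean(prec)) if prec else float("nan"),
        "recall": float(np.mean(rec)) if rec else float("nan"),
    }


def loso_evaluate(subject_sessions: dict, segmenter: CycleSegmenter | None = None,
                  svm_kwargs: dict | None = None, hmm_kwargs: dict | None = None,
                  thresholds=DEFAULT_THRESHOLDS,
                  pth: float = 0.5) -> dict:
    """Leave-one-subject-out comparison of SVM-only and SVM + HMM.

    For each held-out subject the SVM (with its posterior sigmoid) and
    the HMM matrices are fitted on the remaining subjects; the held-out
    subject's sessions are then swept over Pth for SVM-only detection
    and decoded by the HMM. Returns per-subject :class:`SweepResult`
    records, macro-averages, and pooled counts at the reference Pth.
    """
    subjects = list(subject_sessions)
    if len(subjects) < 2:
        raise ValueError("LOSO evaluation requires at least 2 subjects")
    segmenter = segmenter or CycleSegmenter()
    svm_kwargs = dict(svm_kwargs or {})
    hmm_kwargs = dict(hmm_kwargs or {})

    # segment + featurize every session once
    prepared: dict[str, list] = {
        subj: [prepare_session(sig, ann, segmenter) for sig, ann in sessions]
        for subj, sessions in subject_sessions.items()
    }

    results: list[SweepResult] = []
    pooled = {"svm": np.zeros(3, int), "hmm": np.zeros(3, int)}  # tp, fp, p
    for held_out in subjects:
        train = [prepared[s] for s in subjects if s != held_out]
        sess_X, sess_y = [], []
        for sess in train:
            for f, lab, exc in sess:
                k = ~exc
                sess_X.append(f.to_numpy()[k])
                sess_y.append(lab[k])
        X_tr = np.vstack(sess_X)
        y_tr = np.concatenate(sess_y)
        if len(np.unique(y_tr)) < 2:
            raise ValueError("training folds must contain both cycle classes")

        model = SwallowSVM(**svm_kwargs).fit(X_tr, np.where(y_tr == 1, 1, -1))

        # HMM matrices from training subjects only (fold-clean); emissions
        # are estimated from out-of-fold posteriors so B reflects the
        # spread the model shows on unseen cycles
        post_oof = model.oof_posterior()
        bounds = np.cumsum([0] + [len(s) for s in sess_y])
        train_posts = [post_oof[a:b] for a, b in zip(bounds[:-1], bounds[1:])]
        hmm = SwallowHMM(**hmm_kwargs).fit(sess_y, train_posts)

        sweep_counts = np.zeros((len(thresholds), 3), int)
        hmm_counts = np.zeros(3, int)
        n_cycles = 0
        for f, lab, exc in prepared[held_out]:
            k = ~exc
            f_np, lab_k = f.to_numpy()[k], lab[k]
            n_cycles += len(lab_k)
            post = model.posterior(f_np)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for ti, th in enumerate(thresholds):
                    m = score((post >= th).astype(int), lab_k)
                    sweep_counts[ti] += (m.tp, m.fp, m.p)
                m = score(hmm.predict(post), lab_k)
            hmm_counts += (m.tp, m.fp, m.p)

        def _metrics(c):
            tp, fp, p = map(int, c)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                prec = tp / (tp + fp) if tp + fp else float("nan")
                rec = tp / p if p else float("nan")
            return DetectionMetrics(tp, fp, p, prec, rec)

        res = SweepResult(tuple(thresholds),
                          [_metrics(c) for c in sweep_counts],
                          _metrics(hmm_counts), subject=held_out,
                          n_cycles=n_cycles)
        if res.svm_hmm.p == 0:
            warnings.warn(f"{held_out}: no swallow cycles; excluded from "
                          "recall averaging", stacklevel=2)
        results.append(res)
        ref = int(np.argmin(np.abs(np.asarray(thresholds) - pth)))
        pooled["svm"] += sweep_counts[ref]
        pooled["hmm"] += hmm_counts

    ref = int(np.argmin(np.abs(np.asarray(thresholds) - pth)))
    avg_svm = _aggregate([r.svm[ref] for r in results])
    avg_hmm = _aggregate([r.svm_hmm for r in results])

    def _pooled(c):
        tp, fp, p = map(int, c)
        return {"tp": tp, "fp": fp, "p": p,
                "precision": tp / (tp + fp) if tp + fp else float("nan"),
                "recall": tp / p if p else float("nan")}

    return {
        "per_subject": results,
        "reference_pth": float(pth),
        "average_svm": avg_svm,
        "average_svm_hmm": avg_hmm,
        "pooled_svm": _pooled(pooled["svm"]),
        "pooled_svm_hmm": _pooled(pooled["hmm"]),
    }


DEFAULT_PIPELINE_CONFIG = {
    "seed": 0,
    "n_subjects": 3,
    "sessions_per_subject": 1,
    "simulation": {},        # SimulationConfig overrides
    "segmentation": {},      # CycleSegmenter kwargs
    "svm": {},               # SwallowSVM kwargs
    "hmm": {},               # SwallowHMM kwargs
    "pth": 0.5,
}


def run_pipeline(config: dict | None = None) -> dict:
    """End-to-end run: simulate cohort → segment → featurize → train →
    detect → refine → score; returns a JSON-serializable report.

    The report logs every stage with its parameters and seeds and
    contains, per subject, the full SVM-only Pth sweep and the single
    SVM + HMM operating point.
    """
    cfg = dict(DEFAULT_PIPELINE_CONFIG)
    cfg.update(config or {})
    stages = []
    try:
        cohort = simulate_subjects(cfg["n_subjects"], cfg["seed"],
                                   cfg["simulation"], cfg["sessions_per_subject"])
        stages.append({"stage": "simulate", "n_subjects": cfg["n_subjects"],
                       "seed": cfg["seed"], "overrides": cfg["simulation"]})
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'simulate' failed: {exc}") from exc
    try:
        segmenter = CycleSegmenter(**cfg["segmentation"])
        out = loso_evaluate(cohort, segmenter, cfg["svm"], cfg["hmm"],
                            pth=cfg["pth"])
        stages.append({"stage": "loso_evaluate", "segmentation": cfg["segmentation"],
                       "svm": cfg["svm"], "hmm": cfg["hmm"], "pth": cfg["pth"]})
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'loso_evaluate' failed: {exc}") from exc

    report = {
        "config": cfg,
        "stages": stages,
        "reference_pth": out["reference_pth"],
        "average_svm": out["average_svm"],
        "average_svm_hmm": out["average_svm_hmm"],
        "pooled_svm": out["pooled_svm"],
        "pooled_svm_hmm": out["pooled_svm_hmm"],
        "per_subject": [
            {
                "subject": r.subject,
                "n_cycles": r.n_cycles,
                "svm_sweep": [{"pth": float(t), **m.as_dict()}
                              for t, m in zip(r.thresholds, r.svm)],
                "svm_hmm": r.svm_hmm.as_dict(),
            }
            for r in out["per_subject"]
        ],
    }
    validate_report(report)
    return report


REPORT_REQUIRED_KEYS = ("config", "stages", "reference_pth", "average_svm",
                        "average_svm_hmm", "per_subject")


def validate_report(report: dict) -> None:
    """Schema check for pipeline reports."""
    for key in REPORT_REQUIRED_KEYS:
        if key not in report:
            raise ValueError(f"report missing key {key!r}")
    for subj in report["per_subject"]:
        if "svm_sweep" not in subj or "svm_hmm" not in subj:
            raise ValueError("per-subject entries need both the SVM sweep "
                             "and the SVM+HMM point")
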