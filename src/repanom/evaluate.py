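"""Event-level anomaly evaluation and the hidden-Markov-model baseline.

Detection uses two thresholds: one on the phase-fluctuation score, one shared
by all scaled reconstruction-error channels (their absolute values).  A
sample is flagged when either detector fires.  Evaluation is event-level: a
labeled anomaly counts as detected (TP) if at least one of its samples is
flagged, and a normal period (a segmented period overlapping no labeled
event) counts as a false positive if any of its samples is flagged.  Sweeping
a grid over both thresholds yields a cloud of (FPR, TPR) points; its
upper-left Pareto frontier, anchored at (0,0) and (1,1), is the ROC curve and
the trapezoid rule gives the AUC.  The operating point maximizing F1 is also
reported.

The baseline scores a sliding 30-frame window (1 s at 30 fps) of the
11-dimensional normalized features with the length-normalized negative
log-likelihood under a Gaussian-mixture-emission HMM (10 states, 5 mixtures,
unrestricted covariances), thresholded the same event-level way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cdtw import Segment
from .features import FeatureSequence, project_sequence
from .pipeline import PipelineConfig, fit_exercise_model, run_pipeline

__all__ = [
    "flag",
    "EventConfusion",
    "event_confusion",
    "RocResult",
    "roc_and_auc",
    "SessionScores",
    "session_scores",
    "crossval",
    "CrossvalResult",
    "fit_hmm_baseline",
    "hmm_score",
]


def flag(
    phase_score: np.ndarray,
    recon_scores: np.ndarray | None,
    theta_phase: float,
    theta_recon: float,
) -> np.ndarray:
    """Per-sample anomaly flags: phase score above its threshold OR any
    channel's |scaled reconstruction error| above the shared threshold."""
    if theta_phase < 0 or theta_recon < 0:
        raise ValueError("thresholds must be non-negative")
    flags = np.asarray(phase_score, dtype=float) > theta_phase
    if recon_scores is not None:
        flags = flags | (np.max(np.abs(recon_scores), axis=1) > theta_recon)
    return flags


def _check_events(events, n_samples):
    evs = sorted(events, key=lambda e: e[0])
    for (s0, e0, *_), (s1, e1, *_) in zip(evs, evs[1:]):
        if e0 > s1:
            raise ValueError("labeled anomaly events overlap")
    for s, e, *_ in evs:
        if s < 0 or e > n_samples or s >= e:
            raise ValueError("event outside sequence bounds")
    return evs


def normal_periods(segments: list[Segment], events) -> list[Segment]:
    """Full (non-partial) periods overlapping no labeled event."""
    out = []
    for seg in segments:
        if seg.partial:
            continue
        if any(s < seg.end and e > seg.start for s, e, *_ in events):
            continue
        out.append(seg)
    return out


@dataclass(frozen=True)
class EventConfusion:
    tp: int
    fn: int
    fp: int
    n_events: int
    n_normal_periods: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    @property
    def fpr(self) -> float:
        return self.fp / self.n_normal_periods if self.n_normal_periods else 0.0


def event_confusion(
    flags: np.ndarray, events, segments: list[Segment]
) -> EventConfusion:
    """Event-level counts from per-sample flags.

    TP: events with >= 1 flagged sample.  FP: normal periods with >= 1
    flagged sample.  Precision/recall/F1 use the 0-convention on empty
    denominators.
    """
    flags = np.asarray(flags, dtype=bool)
    evs = _check_events(events, flags.size)
    tp = sum(bool(flags[s:e].any()) for s, e, *_ in evs)
    normals = normal_periods(segments, evs)
    fp = sum(bool(flags[seg.start : seg.end].any()) for seg in normals)
    return EventConfusion(tp, len(evs) - tp, fp, len(evs), len(normals))


# ---------------------------------------------------------------------------
# Two-threshold ROC over pooled sessions
# ---------------------------------------------------------------------------


@dataclass
class SessionScores:
    """Event/period score maxima of one scored session — sufficient
    statistics for the event-level ROC."""

    event_phase_max: np.ndarray  # (n_events,)
    event_recon_max: np.ndarray
    period_phase_max: np.ndarray  # (n_normal_periods,)
    period_recon_max: np.ndarray


def session_scores(
    phase_score: np.ndarray,
    recon_scores: np.ndarray | None,
    events,
    segments: list[Segment],
) -> SessionScores:
    phase_score = np.asarray(phase_score, dtype=float)
    evs = _check_events(events, phase_score.size)
    rmax = (
        np.max(np.abs(recon_scores), axis=1)
        if recon_scores is not None
        else np.full_like(phase_score, -np.inf)
    )
    ep = np.array([phase_score[s:e].max() for s, e, *_ in evs])
    er = np.array([rmax[s:e].max() for s, e, *_ in evs])
    normals = normal_periods(segments, evs)
    pp = np.array([phase_score[g.start : g.end].max() for g in normals])
    pr = np.array([rmax[g.start : g.end].max() for g in normals])
    return SessionScores(ep, er, pp, pr)


@dataclass
class RocResult:
    points: np.ndarray  # (G, 4): theta_phase, theta_recon, TPR, FPR
    frontier: np.ndarray  # (K, 2): FPR, TPR including (0,0) and (1,1)
    auc: float
    best: dict  # F1-optimal operating point

    def __repr__(self):
        b = self.best
        return (
            f"RocResult(auc={self.auc:.4f}, best_f1={b['f1']:.4f} "
            f"@ theta_phase={b['theta_phase']:.3g}, theta_recon={b['theta_recon']:.3g})"
        )


def _quantile_grid(values: np.ndarray, size: int) -> np.ndarray:
    values = values[np.isfinite(values)]
    if values.size == 0:
        return np.array([np.inf])
    qs = np.quantile(values, np.linspace(0.0, 1.0, size))
    grid = np.unique(qs)
    # endpoints: below the minimum (flag everything) and +inf (flag nothing)
    lo = grid[0] - 1e-9 - abs(grid[0]) * 1e-9
    return np.concatenate([[max(lo, 0.0)], grid, [np.inf]])


def roc_and_auc(
    pooled: list[SessionScores],
    grid_phase: np.ndarray | None = None,
    grid_recon: np.ndarray | None = None,
    grid_size: int = 50,
) -> RocResult:
    """ROC/AUC from a grid over the two thresholds (OR-combined detectors).

    Grids default to quantile spacing over the observed event/period maxima.
    The point cloud is reduced to its upper-left Pareto frontier, anchored at
    (0,0) and (1,1); AUC is the trapezoid area under the frontier.  Ties on
    best F1 resolve toward lower FPR.
    """
    ep = np.concatenate([s.event_phase_max for s in pooled])
    er = np.concatenate([s.event_recon_max for s in pooled])
    pp = np.concatenate([s.period_phase_max for s in pooled])
    pr = np.concatenate([s.period_recon_max for s in pooled])
    n_events, n_normals = ep.size, pp.size
    if n_events == 0:
        raise ValueError("cannot build an ROC without labeled events")
    if grid_phase is None:
        grid_phase = _quantile_grid(np.concatenate([ep, pp]), grid_size)
    if grid_recon is None:
        grid_recon = _quantile_grid(np.concatenate([er, pr]), grid_size)

    gp = np.asarray(grid_phase, dtype=float)
    gr = np.asarray(grid_recon, dtype=float)
    # detection matrices over the grid: (n_units, |gp|, |gr|)
    det_e = (ep[:, None, None] > gp[None, :, None]) | (er[:, None, None] > gr[None, None, :])
    det_p = (pp[:, None, None] > gp[None, :, None]) | (pr[:, None, None] > gr[None, None, :])
    tp = det_e.sum(axis=0).astype(float)
    fp = det_p.sum(axis=0).astype(float)
    tpr = tp / n_events
    fpr = fp / n_normals if n_normals else np.zeros_like(fp)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        rec = tpr
        f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)

    P, R = np.meshgrid(gp, gr, indexing="ij")
    points = np.stack([P.ravel(), R.ravel(), tpr.ravel(), fpr.ravel()], axis=1)

    # upper-left Pareto frontier of the (FPR, TPR) cloud
    order = np.lexsort((-tpr.ravel(), fpr.ravel()))
    frontier = [(0.0, 0.0)]
    best_tpr = 0.0
    for k in order:
        x, y = fpr.ravel()[k], tpr.ravel()[k]
        if y > best_tpr:
            frontier.append((x, y))
            best_tpr = y
    frontier.append((1.0, 1.0))
    F = np.array(frontier)
    auc = float(np.trapezoid(F[:, 1], F[:, 0]))

    flat_f1 = f1.ravel()
    cand = np.lexsort((points[:, 3], -flat_f1))[0]
    besti = np.unravel_index(cand, f1.shape)
    best = {
        "theta_phase": float(gp[besti[0]]),
        "theta_recon": float(gr[besti[1]]),
        "precision": float(prec[besti]),
        "recall": float(rec[besti]),
        "f1": float(f1[besti]),
        "tpr": float(tpr[besti]),
        "fpr": float(fpr[besti]),
    }
    return RocResult(points, F, auc, best)


# ---------------------------------------------------------------------------
# HMM baseline
# ---------------------------------------------------------------------------


def fit_hmm_baseline(
    training_arrays: list[np.ndarray],
    n_states: int = 10,
    n_mix: int = 5,
    max_iter: int = 1000,
    seed: int = 0,
):
    """Gaussian-mixture-emission HMM on the normalized 11-dim features.

    EM failures (degenerate covariances) trigger one refit with a stronger
    covariance prior.
    """
    from hmmlearn.hmm import GMMHMM

    X = np.concatenate(training_arrays, axis=0)
    lengths = [a.shape[0] for a in training_arrays]

    def _floor_covars(model, floor=1e-6):
        # EM with many mixture components can collapse a covariance onto a
        # few samples; floor the eigenvalues to restore positive definiteness
        C = model.covars_
        for s in range(C.shape[0]):
            for k in range(C.shape[1]):
                A = 0.5 * (C[s, k] + C[s, k].T)
                w, V = np.linalg.eigh(A)
                C[s, k] = (V * np.maximum(w, floor)) @ V.T
        model.covars_ = C

    def _fit(floor):
        model = GMMHMM(
            n_components=n_states,
            n_mix=n_mix,
            covariance_type="full",
            n_iter=max_iter,
            random_state=int(seed),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X, lengths)
            _floor_covars(model, floor)
            if not np.all(np.isfinite(model.score(X[:50]))):
                raise ValueError("non-finite likelihood")
        return model

    try:
        return _fit(1e-6)
    except Exception:
        warnings.warn("HMM EM produced a degenerate fit; refitting with a stronger covariance floor")
        return _fit(1e-3)


def hmm_score(model, features_flat: np.ndarray, window: int = 30, stride: int = 1) -> np.ndarray:
    """Per-sample anomaly score from sliding-window likelihood.

    Score = negative length-normalized log-likelihood of the window, aligned
    to the window center; edge samples copy the nearest scored value and
    samples between strides take the previous scored value.
    """
    X = np.asarray(features_flat, dtype=float)
    T = X.shape[0]
    if T < window:
        raise ValueError(f"sequence of length {T} shorter than window {window}")
    starts = np.arange(0, T - window + 1, stride)
    try:
        # emission log-likelihoods once per session, then a batched forward
        # pass over all windows (equivalent to per-window model.score)
        from scipy.special import logsumexp

        fll = model._compute_log_likelihood(X)  # (T, n_states)
        with np.errstate(divide="ignore"):
            logA = np.log(model.transmat_)
            logpi = np.log(model.startprob_)
        alpha = logpi[None, :] + fll[starts]
        for t in range(1, window):
            alpha = logsumexp(alpha[:, :, None] + logA[None, :, :], axis=1)
            alpha += fll[starts + t]
        scores = -logsumexp(alpha, axis=1) / window
    except AttributeError:  # private API moved: fall back to per-window scoring
        scores = np.array([-model.score(X[s : s + window]) / window for s in starts])
    centers = starts + window // 2
    out = np.empty(T)
    out[: centers[0] + 1] = scores[0]
    for k in range(1, centers.size):
        out[centers[k - 1] + 1 : centers[k] + 1] = scores[k]
    out[centers[-1] + 1 :] = scores[-1]
    return out


# ---------------------------------------------------------------------------
# Leave-subjects-out cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CrossvalResult:
    pooled: RocResult
    per_fold: list[RocResult]
    fold_subjects: list[list[str]]
    hmm_pooled: RocResult | None = None
    hmm_per_fold: list[RocResult] = field(default_factory=list)


def crossval(
    cohort: list[dict],
    k_folds: int,
    config: PipelineConfig = PipelineConfig(),
    seed: int = 0,
    include_hmm: bool = True,
) -> CrossvalResult:
    """Leave-subjects-out cross-validation on a cohort.

    ``cohort`` entries: {"subject_id", "train": [sessions], "test":
    [(features, events)] or [LabeledSession]}.  Folds partition the subjects
    (each subject tested exactly once); models are built on the normal
    sessions of the training subjects and applied to the held-out subjects'
    mixture sessions.  Test scores are pooled across folds for the final ROC;
    per-fold curves are also returned.
    """
    n_subjects = len(cohort)
    if k_folds < 2:
        raise ValueError("need at least 2 folds")
    if n_subjects < k_folds:
        raise ValueError("fewer subjects than folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_subjects)
    folds = [sorted(order[i::k_folds].tolist()) for i in range(k_folds)]

    pooled_scores: list[SessionScores] = []
    pooled_hmm: list[SessionScores] = []
    per_fold, hmm_per_fold, fold_subjects = [], [], []
    for fold in folds:
        test_idx = set(fold)
        train_sessions = []
        for i, subj in enumerate(cohort):
            if i not in test_idx:
                for s in subj["train"]:
                    train_sessions.append(_features_of(s))
        model = fit_exercise_model(train_sessions, config, seed)
        if include_hmm:
            flats = [
                model.phase_net.standardize(project_sequence(s, model.projections))
                for s in train_sessions
            ]
            hmm = fit_hmm_baseline(
                flats, config.hmm_states, config.hmm_mixtures, config.hmm_max_iter, seed
            )
        fold_scores, fold_hmm = [], []
        for i in fold:
            subj = cohort[i]
            for sess in subj["test"]:
                feats, events = _features_of(sess), _events_of(sess)
                report = run_pipeline(feats, model)
                sc = session_scores(
                    report.phase_score, report.recon_scores, events, report.segments
                )
                fold_scores.append(sc)
                if include_hmm:
                    flat = model.phase_net.standardize(
                        project_sequence(feats, model.projections)
                    )
                    hscore = hmm_score(hmm, flat, config.hmm_window, config.hmm_stride)
                    fold_hmm.append(
                        session_scores(hscore, None, events, report.segments)
                    )
        fold_subjects.append([cohort[i]["subject_id"] for i in fold])
        per_fold.append(roc_and_auc(fold_scores, grid_size=config.grid_size))
        pooled_scores.extend(fold_scores)
        if include_hmm:
            hmm_per_fold.append(roc_and_auc(fold_hmm, grid_size=config.grid_size))
            pooled_hmm.extend(fold_hmm)
    pooled = roc_and_auc(pooled_scores, grid_size=config.grid_size)
    hmm_pooled = roc_and_auc(pooled_hmm, grid_size=config.grid_size) if include_hmm else None
    return CrossvalResult(pooled, per_fold, fold_subjects, hmm_pooled, hmm_per_fold)


def _features_of(session) -> FeatureSequence:
    return session.features if hasattr(session, "features") else session


def _events_of(session):
    return session.anomaly_events if hasattr(session, "anomaly_events") else []
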