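"""Majority-vote verification (probability assessment) and the LOPO protocol.

An authentication *attempt* is a set of per-segment predicted labels from
one user's run. The labels are tallied into vote counts V(j), the majority
label v = argmax_j V(j) (ties toward the smaller label) and its count Nv are
found, and the majority probability beta = Nv / Nseg is compared with a
threshold theta. By default the verdict is *genuine* only when the majority
label also equals the claimed identity; thresholding beta alone (so that a
consistent misclassification toward some other enrolled user could pass) is
available as ``require_claimed_match=False``.

The leave-one-participant-out (LOPO) evaluation trains the full pipeline on
all users but one; the held-out user — who cannot be a class of the trained
softmax — supplies imposter attempts against every enrolled identity, while
each enrolled user's own test runs supply genuine attempts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass(frozen=True)
class AuthAttempt:
    claimed_label: int
    predicted_labels: np.ndarray
    theta: float = 0.5
    n_labels: int | None = None     # N; inferred as max label when None

    def __post_init__(self) -> None:
        labels = np.asarray(self.predicted_labels, dtype=int)
        if labels.size < 1:
            raise ValueError("an attempt needs at least one segment")
        if not (0 < self.theta <= 1):
            raise ValueError("theta must be in (0, 1]")
        object.__setattr__(self, "predicted_labels", labels)


@dataclass(frozen=True)
class AuthDecision:
    vote_counts: np.ndarray         # V(j), j = 1..N
    majority_label: int             # v
    majority_count: int             # Nv
    beta: float
    theta: float
    claimed_label: int
    claimed_match: bool             # v == claimed
    verdict: str                    # "genuine" | "imposter"


def vote_counts(predicted_labels: np.ndarray, n_labels: int) -> np.ndarray:
    """V(j) = number of segments predicted as label j, for j = 1..N."""
    labels = np.asarray(predicted_labels, dtype=int)
    if labels.size and (labels.min() < 1 or labels.max() > n_labels):
        bad = labels[(labels < 1) | (labels > n_labels)][0]
        raise ValueError(f"predicted label {bad} outside 1..{n_labels}")
    return np.bincount(labels, minlength=n_labels + 1)[1:]


def majority(v: np.ndarray) -> tuple[int, int]:
    """Majority label and its count; ties go to the smallest label index."""
    v = np.asarray(v)
    if v.sum() < 1:
        raise ValueError("vote counts are empty")
    j = int(np.argmax(v))  # argmax returns the first (smallest) maximiser
    return j + 1, int(v[j])


def majority_probability(nv: int, nseg: int) -> float:
    """beta = Nv / Nseg, the majority label's share of the attempt."""
    if nseg <= 0:
        raise ValueError("Nseg must be positive")
    if not (1 <= nv <= nseg):
        raise ValueError("need 1 <= Nv <= Nseg")
    return nv / nseg


def decide(attempt: AuthAttempt, require_claimed_match: bool = True) -> AuthDecision:
    """Full probability assessment for one attempt.

    verdict = genuine iff beta >= theta and (by default) the majority label
    equals the claimed one.
    """
    n = attempt.n_labels or max(int(attempt.predicted_labels.max()),
                                attempt.claimed_label)
    v = vote_counts(attempt.predicted_labels, n)
    maj, nv = majority(v)
    beta = majority_probability(nv, attempt.predicted_labels.size)
    match = maj == attempt.claimed_label
    accept = beta >= attempt.theta and (match or not require_claimed_match)
    return AuthDecision(vote_counts=v, majority_label=maj, majority_count=nv,
                        beta=beta, theta=attempt.theta,
                        claimed_label=attempt.claimed_label,
                        claimed_match=match,
                        verdict="genuine" if accept else "imposter")


@dataclass
class AuthTrial:
    """One scored LOPO trial: an AuthDecision plus its ground truth."""

    fold: int                       # held-out user
    claimed_label: int
    true_user: int
    run_index: int
    is_genuine: bool                # ground truth of the claim
    decision: AuthDecision

    @property
    def score(self) -> float:
        """Claim-aware acceptance score: beta when the majority backs the
        claim, else 0 (matches the default decision rule for any theta>0)."""
        return self.decision.beta if self.decision.claimed_match else 0.0


def lopo_evaluate(dataset, config=None, theta: float = 0.5,
                  require_claimed_match: bool = True) -> list[AuthTrial]:
    """Leave-one-participant-out authentication evaluation.

    For each held-out user u the pipeline (preprocessing, feature
    extraction, MI selection, scaler, classifier) is refitted on the other
    users' training runs. Genuine trials: every enrolled user's test runs,
    claiming their own identity. Imposter trials: u's test runs, claiming
    each enrolled identity in turn.
    """
    from .pipeline import PipelineConfig, fit_pipeline, predict_segments

    config = config or PipelineConfig()
    users = sorted({r.user_id for r in dataset.recordings})
    if len(users) < 3:
        raise ValueError("LOPO needs at least 3 users (>= 2 enrolled per fold)")
    n_train = config.n_train_runs
    trials: list[AuthTrial] = []
    for held_out in users:
        enrolled = [u for u in users if u != held_out]
        train_recs = [r for r in dataset.recordings
                      if r.user_id != held_out and r.run_index <= n_train]
        model = fit_pipeline(train_recs, config)
        test_recs = [r for r in dataset.recordings if r.run_index > n_train]
        for rec in test_recs:
            preds = predict_segments(model, [rec])
            labels = preds.predicted_labels
            if rec.user_id == held_out:
                claims = enrolled          # imposter claims every identity
            else:
                claims = [rec.user_id]     # genuine self-claim
            for claimed in claims:
                attempt = AuthAttempt(claimed_label=claimed,
                                      predicted_labels=labels, theta=theta,
                                      n_labels=max(users))
                dec = decide(attempt, require_claimed_match=require_claimed_match)
                trials.append(AuthTrial(
                    fold=held_out, claimed_label=claimed, true_user=rec.user_id,
                    run_index=rec.run_index,
                    is_genuine=rec.user_id == claimed, decision=dec))
    return trials


def trials_at_theta(trials: list[AuthTrial], theta: float,
                    require_claimed_match: bool = True) -> list[AuthTrial]:
    """Re-threshold existing trials without re-running the pipeline."""
    out = []
    for t in trials:
        accept = (t.decision.beta >= theta
                  and (t.decision.claimed_match or not require_claimed_match))
        dec = replace(t.decision, theta=theta,
                      verdict="genuine" if accept else "imposter")
        out.append(replace_trial(t, dec))
    return out


def replace_trial(trial: AuthTrial, decision: AuthDecision) -> AuthTrial:
    return AuthTrial(fold=trial.fold, claimed_label=trial.claimed_label,
                     true_user=trial.true_user, run_index=trial.run_index,
                     is_genuine=trial.is_genuine, decision=decision)
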