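"""Cumulative-window population decoding of stimulus class from spike counts.

Spikes of each trial are binned into 100 ms windows from stimulus onset to a
5 s horizon (50 evaluation bins).  At evaluation bin ``b`` the feature vector
of a trial is the concatenation of the per-unit counts of bins ``1..b``, so
with ``C`` units the dimensionality grows from ``C`` to ``50*C``.  A
maximum-margin classifier (SVM, polynomial kernel of degree 3 by default) is
scored by stratified 5-fold cross-validation (each fold = 20% held-out test
data), re-randomizing fold membership over Monte-Carlo repeats; accuracies are
reported as mean +/- SEM per bin.  The empirical chance level is obtained by
re-running the identical procedure on randomly permuted trial labels.

Feature standardization is fit on the training folds only, so no test-set
statistics leak into training.  No class reweighting is applied; with
imbalanced classes the permutation chance level sits slightly above 50%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import SpikeSession


class DecodingError(ValueError):
    pass


@dataclass
class FeatureSet:
    """Post-stimulus bin counts (trials, bins, units) plus binary labels."""

    counts: np.ndarray                  # (n_trials, n_bins, n_units)
    labels: np.ndarray                  # (n_trials,) in {0, 1}
    classes: tuple[str, str]
    bin_size_s: float
    units: list[str]
    session_id: str = ""

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def n_units(self) -> int:
        return self.counts.shape[2]

    def features_at(self, b: int) -> np.ndarray:
        """Cumulative features at evaluation bin ``b`` (1-based), dim ``b*C``."""
        if not 1 <= b <= self.n_bins:
            raise DecodingError(f"evaluation bin {b} outside 1..{self.n_bins}")
        return self.counts[:, :b, :].reshape(self.n_trials, b * self.n_units)


@dataclass
class DecodingResult:
    """Per-bin cross-validated accuracy (mean +/- SEM over MC repeats)."""

    accuracy_mean: np.ndarray           # (n_bins,)
    accuracy_sem: np.ndarray            # (n_bins,)
    max_accuracy: float
    classes: tuple[str, str]
    n_units: int
    n_trials_per_class: tuple[int, int]
    bin_size_s: float
    session_id: str = ""
    chance_mean: np.ndarray | None = None


def build_cumulative_features(session: SpikeSession, bin_size_s: float = 0.1,
                              horizon_s: float = 5.0,
                              classes: tuple[str, str] | None = None) -> FeatureSet:
    """Bin post-stimulus spikes into per-trial cumulative count features."""
    present = [s for s in ("NS", "LS", "HS")
               if (session.trials["stimulus"] == s).any()]
    if classes is None:
        if len(present) != 2:
            raise DecodingError(
                f"binary decoder needs exactly two stimulus classes, found {present}")
        classes = (present[0], present[1])
    n_bins = horizon_s / bin_size_s
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise DecodingError(f"bin size {bin_size_s} does not divide horizon {horizon_s}")
    n_bins = int(round(n_bins))
    if session.n_units < 1:
        raise DecodingError("session has no units")

    trials = session.trials[session.trials["stimulus"].isin(classes)]
    if len(trials) < 2:
        raise DecodingError("need at least two trials")
    trial_ids = trials["trial_id"].to_numpy()
    labels = (trials["stimulus"] == classes[1]).to_numpy().astype(int)
    if labels.min() == labels.max():
        raise DecodingError("only one stimulus class present")

    u_index = {u: i for i, u in enumerate(session.units)}
    t_index = {t: i for i, t in enumerate(trial_ids)}
    counts = np.zeros((len(trial_ids), n_bins, session.n_units), dtype=np.int64)
    sp = session.spikes
    mask = sp["trial_id"].isin(t_index) & (sp["t_s"] >= 0) & (sp["t_s"] < horizon_s)
    sp = sp[mask]
    if len(sp):
        b = np.minimum(np.floor(sp["t_s"].to_numpy(float) / bin_size_s).astype(np.int64),
                       n_bins - 1)
        ti = sp["trial_id"].map(t_index).to_numpy(np.int64)
        ui = sp["unit_id"].map(u_index).to_numpy(np.int64)
        np.add.at(counts, (ti, b, ui), 1)
    return FeatureSet(counts=counts, labels=labels, classes=classes,
                      bin_size_s=bin_size_s, units=list(session.units),
                      session_id=session.session_id)


def _make_classifier(kernel: str, degree: int, coef0: float, c: float) -> SVC:
    if kernel == "poly":
        return SVC(kernel="poly", degree=degree, coef0=coef0, C=c, gamma="scale")
    if kernel == "linear":
        return SVC(kernel="linear", C=c)
    raise DecodingError("kernel must be 'poly' or 'linear'")


def _cv_accuracy_per_bin(features: FeatureSet, labels: np.ndarray, folds: int,
                         rng_seed: int, kernel: str, degree: int, coef0: float,
                         c: float) -> np.ndarray:
    """One stratified K-fold pass; returns pooled accuracy per evaluation bin."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rng_seed)
    n_bins = features.n_bins
    correct = np.zeros(n_bins)
    total = np.zeros(n_bins)
    splits = list(skf.split(np.zeros(len(labels)), labels))
    for train_ix, test_ix in splits:
        y_tr, y_te = labels[train_ix], labels[test_ix]
        for b in range(1, n_bins + 1):
            X = features.features_at(b)
            scaler = StandardScaler().fit(X[train_ix])
            clf = _make_classifier(kernel, degree, coef0, c)
            clf.fit(scaler.transform(X[train_ix]), y_tr)
            pred = clf.predict(scaler.transform(X[test_ix]))
            correct[b - 1] += (pred == y_te).sum()
            total[b - 1] += len(y_te)
    return correct / total


def evaluate_decoder(features: FeatureSet, folds: int = 5, mc_repeats: int = 100,
                     seed: int | None = 0, kernel: str = "poly", degree: int = 3,
                     coef0: float = 1.0, c: float = 1.0) -> DecodingResult:
    """Cross-validated cumulative decoding accuracy, mean +/- SEM per bin.

    Fold membership is reshuffled with a fresh child seed on every
    Monte-Carlo repeat.
    """
    labels = features.labels
    n0, n1 = int((labels == 0).sum()), int((labels == 1).sum())
    if n0 == 0 or n1 == 0:
        raise DecodingError("both classes must be present")
    if min(n0, n1) < folds:
        raise DecodingError(
            f"each class needs >= {folds} trials for {folds}-fold CV (have {n0}, {n1})")
    if mc_repeats < 1:
        raise DecodingError("mc_repeats must be >= 1")

    seeds = np.random.SeedSequence(seed).spawn(mc_repeats)
    acc = np.empty((mc_repeats, features.n_bins))
    for r, child in enumerate(seeds):
        acc[r] = _cv_accuracy_per_bin(
            features, labels, folds, int(child.generate_state(1)[0] % (2**31)),
            kernel, degree, coef0, c)
    mean = acc.mean(axis=0)
    sem = acc.std(axis=0, ddof=1) / np.sqrt(mc_repeats) if mc_repeats > 1 \
        else np.zeros(features.n_bins)
    return DecodingResult(accuracy_mean=mean, accuracy_sem=sem,
                          max_accuracy=float(mean.max()), classes=features.classes,
                          n_units=features.n_units, n_trials_per_class=(n0, n1),
                          bin_size_s=features.bin_size_s, session_id=features.session_id)


def permutation_chance(features: FeatureSet, n_permutations: int = 500,
                       folds: int = 5, seed: int | None = 0, kernel: str = "poly",
                       degree: int = 3, coef0: float = 1.0, c: float = 1.0
                       ) -> np.ndarray:
    """Mean decoding accuracy per bin after random label permutation.

    Each permutation shuffles the trial labels and re-runs the full
    cross-validated decoding; the returned curve is the average over
    permutations (the empirical chance level).
    """
    if n_permutations < 1:
        raise DecodingError("n_permutations must be >= 1")
    labels = features.labels
    if min((labels == 0).sum(), (labels == 1).sum()) < folds:
        raise DecodingError("each class needs at least `folds` trials")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    fold_seeds = ss.spawn(n_permutations)
    acc = np.empty((n_permutations, features.n_bins))
    for p in range(n_permutations):
        perm = rng.permutation(labels)
        acc[p] = _cv_accuracy_per_bin(
            features, perm, folds, int(fold_seeds[p].generate_state(1)[0] % (2**31)),
            kernel, degree, coef0, c)
    return acc.mean(axis=0)


def aggregate_sessions(results: list[DecodingResult], min_units: int = 5) -> dict:
    """Cohort summary over sessions with at least ``min_units`` units.

    Returns mean +/- SEM of the per-session maximum accuracy and the
    bin-wise mean curve.
    """
    if not results:
        raise DecodingError("no session results to aggregate")
    kept = [r for r in results if r.n_units >= min_units]
    dropped = [r.session_id for r in results if r.n_units < min_units]
    if not kept:
        raise DecodingError(
            f"all sessions dropped by the min_units={min_units} session filter")
    maxima = np.array([r.max_accuracy for r in kept])
    n_bins = {r.accuracy_mean.shape[0] for r in kept}
    curve = (np.mean([r.accuracy_mean for r in kept], axis=0)
             if len(n_bins) == 1 else None)
    sem = float(maxima.std(ddof=1) / np.sqrt(len(maxima))) if len(maxima) > 1 else 0.0
    return {
        "n_sessions": len(kept),
        "session_ids": [r.session_id for r in kept],
        "excluded_sessions": dropped,
        "max_accuracy_mean": float(maxima.mean()),
        "max_accuracy_sem": sem,
        "per_session_max": maxima.tolist(),
        "mean_curve": None if curve is None else curve.tolist(),
    }
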