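"""Classifiers for oddball ERP decoding.

Two classifiers are provided:

* :class:`MDM` — minimum distance to mean on the SPD manifold.  Training
  computes one geometric-mean covariance per class,

      Cbar_k = GeometricMean( C_i | l_i = k ),

  and an unlabeled covariance is assigned the class of the nearest mean
  under the affine-invariant Riemannian distance,

      l_hat = argmin_k delta_R(Cbar_k, C).

* :class:`SWLDA` — stepwise linear discriminant analysis, the conventional
  P300 baseline: forward-stepwise ordinary least squares on +/-1 labels
  with partial-F entry/removal tests, operating on decimated epoch
  amplitudes.

Both support K-command selection: in an oddball round, exactly one feature
per stimulus code is scored and the command with the most target-like
score wins (smallest code on ties).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .geometry import check_spd, geometric_mean, riemannian_distance
from .preprocessing import NONTARGET, TARGET

__all__ = [
    "MDM",
    "SWLDA",
    "CommandDecision",
    "mdm_fit",
    "mdm_predict",
    "command_select",
    "swlda_fit",
    "swlda_predict",
    "swlda_command_select",
    "decimate_epochs",
]


@dataclass
class CommandDecision:
    """Scores per stimulus code 1..K and the decided command (argmax score).

    Ties are broken deterministically in favor of the smallest code.
    """

    scores: np.ndarray  # index c holds the score of code c+1
    decided_command: int


def _stack_covs(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 3 or X.shape[1] != X.shape[2]:
        raise ValueError(f"X must be (n, d, d) SPD matrices, got shape {X.shape}")
    return X


class MDM(ClassifierMixin, BaseEstimator):
    """Minimum-distance-to-mean classifier on SPD covariance features.

    Parameters
    ----------
    tol, max_iterations : stopping rule of the per-class Karcher mean.

    Attributes
    ----------
    classes_ : sorted unique training labels.
    covmeans_ : (n_classes, d, d) geometric-mean covariance per class.
    counts_ : trials per class used in each mean.
    """

    def __init__(self, tol: float = 1e-8, max_iterations: int = 50):
        self.tol = tol
        self.max_iterations = max_iterations

    def fit(self, X, y):
        X = _stack_covs(X)
        y = np.asarray(y, dtype=int)
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("MDM requires at least two classes in y")
        means, counts = [], []
        for k in self.classes_:
            members = X[y == k]
            means.append(
                geometric_mean(members, tol=self.tol, max_iterations=self.max_iterations)
            )
            counts.append(len(members))
        self.covmeans_ = np.stack(means)
        self.counts_ = np.asarray(counts)
        return self

    def transform(self, X) -> np.ndarray:
        """Riemannian distance of each covariance to every class mean."""
        check_is_fitted(self, "covmeans_")
        X = _stack_covs(X)
        if X.shape[1] != self.covmeans_.shape[1]:
            raise ValueError(
                f"dimension mismatch: covariances are {X.shape[1]}x{X.shape[2]}, "
                f"class means are {self.covmeans_.shape[1]}x{self.covmeans_.shape[2]}"
            )
        return np.array(
            [[riemannian_distance(m, c) for m in self.covmeans_] for c in X]
        )

    def predict(self, X) -> np.ndarray:
        """Label of the nearest class mean; exact ties go to the smaller label."""
        dist = self.transform(X)
        # classes_ is sorted, so argmin's first-hit rule is the tie rule
        return self.classes_[np.argmin(dist, axis=1)]


def mdm_fit(covs, labels, tol: float = 1e-8, max_iterations: int = 50) -> MDM:
    """Fit per-class geometric-mean covariances (thin wrapper over MDM)."""
    return MDM(tol=tol, max_iterations=max_iterations).fit(np.asarray(covs), labels)


def mdm_predict(cov: np.ndarray, model: MDM) -> int:
    """Classify one SPD covariance by minimum distance to the class means."""
    return int(model.predict(np.asarray(cov)[None])[0])


def command_select(trial_covs: dict[int, np.ndarray], model: MDM) -> CommandDecision:
    """Decide the attended command from one covariance per stimulus code.

    score(code) = delta_R(C_code, Cbar_nontarget) - delta_R(C_code, Cbar_target);
    the decided command attains the maximal score (a covariance much closer
    to the target mean than to the non-target mean is most target-like).
    Requires exactly the codes 1..K; smallest code wins ties.
    """
    check_is_fitted(model, "covmeans_")
    k = len(trial_covs)
    expected = set(range(1, k + 1))
    if set(trial_covs) != expected:
        raise ValueError(f"expected one covariance per code {sorted(expected)}, got {sorted(trial_covs)}")
    cls = list(model.classes_)
    if TARGET not in cls or NONTARGET not in cls:
        raise ValueError("MDM model must be trained on target/non-target labels (1, 2)")
    i_t, i_nt = cls.index(TARGET), cls.index(NONTARGET)
    covs = np.stack([check_spd(trial_covs[c], f"code {c}") for c in range(1, k + 1)])
    dist = model.transform(covs)
    scores = dist[:, i_nt] - dist[:, i_t]
    decided = int(np.argmax(scores)) + 1  # argmax first-hit = smallest code on tie
    return CommandDecision(scores=scores, decided_command=decided)


# --------------------------------------------------------------------------
# SWLDA


def decimate_epochs(epochs: np.ndarray, fs: float, bin_ms: float = 20.0) -> np.ndarray:
    """Epoch amplitudes averaged in time bins, channels concatenated.

    Each channel of each (N, M) epoch is reduced to ``floor(M / bin)``
    means over consecutive ``bin_ms`` windows and the channels are
    concatenated, giving the decimated feature vector SWLDA selects from
    (N x 50 features for a 1000 ms epoch at 20 ms bins).
    """
    epochs = np.asarray(epochs, dtype=float)
    single = epochs.ndim == 2
    if single:
        epochs = epochs[None]
    n, n_ch, m = epochs.shape
    step = max(int(round(fs * bin_ms / 1000.0)), 1)
    n_bins = m // step
    binned = epochs[:, :, : n_bins * step].reshape(n, n_ch, n_bins, step).mean(axis=3)
    out = binned.reshape(n, n_ch * n_bins)
    return out[0] if single else out


class SWLDA(ClassifierMixin, BaseEstimator):
    """Stepwise linear discriminant analysis (forward OLS with removal).

    Regression of +/-1 class labels on the feature columns.  At each step
    the candidate with the smallest partial-F p-value enters if it is
    below ``p_enter``; after every addition, any included feature whose
    p-value has risen above ``p_remove`` is removed.  Selection stops when
    no candidate can enter or ``max_features`` is reached.  If nothing
    enters, the model is intercept-only and predicts the majority class.

    Attributes
    ----------
    selected_features_ : indices into the feature vector, in entry order.
    weights_ : OLS weight per selected feature.
    intercept_ : OLS intercept.
    classes_ : [1, 2] (target, non-target).
    """

    def __init__(self, p_enter: float = 0.10, p_remove: float = 0.15, max_features: int = 60):
        self.p_enter = p_enter
        self.p_remove = p_remove
        self.max_features = max_features

    @staticmethod
    def _encode(y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=int)
        if not np.isin(y, [TARGET, NONTARGET]).all():
            raise ValueError("labels must be 1 (target) or 2 (non-target)")
        return np.where(y == TARGET, 1.0, -1.0)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (trials x features)")
        z = self._encode(y)
        if len(z) != len(X):
            raise ValueError("X and y length mismatch")
        if len(np.unique(z)) < 2:
            raise ValueError("both classes must be present in y")
        n, n_feat = X.shape
        # constant columns can never explain label variance; skip, not fatal
        usable = np.ptp(X, axis=0) > 0

        selected: list[int] = []
        while len(selected) < min(self.max_features, n_feat):
            df_new = n - len(selected) - 2  # residual dof if one more enters
            if df_new <= 0:
                break
            q, _ = np.linalg.qr(np.column_stack([np.ones(n), X[:, selected]]))
            r_y = z - q @ (q.T @ z)
            rss_old = float(r_y @ r_y)
            if rss_old <= 1e-12:
                break
            cand = np.array(
                [j for j in range(n_feat) if usable[j] and j not in selected], dtype=int
            )
            if len(cand) == 0:
                break
            r_x = X[:, cand] - q @ (q.T @ X[:, cand])
            norms = np.einsum("ij,ij->j", r_x, r_x)
            ok = norms > 1e-12 * n
            if not ok.any():
                break
            cand, r_x, norms = cand[ok], r_x[:, ok], norms[ok]
            proj = r_x.T @ r_y
            rss_new = np.maximum(rss_old - proj**2 / norms, 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                f_stat = (rss_old - rss_new) / (rss_new / df_new)
            p_vals = stats.f.sf(f_stat, 1, df_new)
            p_vals = np.where(np.isfinite(p_vals), p_vals, 0.0)
            best = int(np.argmin(p_vals))
            if p_vals[best] >= self.p_enter:
                break
            selected.append(int(cand[best]))
            selected = self._backward_pass(X, z, selected)

        self.selected_features_ = np.array(selected, dtype=int)
        if selected:
            design = np.column_stack([np.ones(n), X[:, selected]])
            beta, *_ = np.linalg.lstsq(design, z, rcond=None)
            self.intercept_ = float(beta[0])
            self.weights_ = beta[1:]
        else:
            self.intercept_ = float(z.mean())  # majority-class fallback
            self.weights_ = np.zeros(0)
        self.n_features_in_ = n_feat
        self.classes_ = np.array([TARGET, NONTARGET])
        return self

    def _backward_pass(self, X, z, selected: list[int]) -> list[int]:
        """Drop included features whose coefficient p-value exceeds p_remove."""
        n = len(z)
        while selected:
            df = n - len(selected) - 1
            if df <= 0:  # saturated; let the forward loop terminate
                break
            design = np.column_stack([np.ones(n), X[:, selected]])
            beta, *_ = np.linalg.lstsq(design, z, rcond=None)
            resid = z - design @ beta
            sigma2 = float(resid @ resid) / df
            cov = sigma2 * np.linalg.pinv(design.T @ design)
            se = np.sqrt(np.maximum(np.diag(cov), 1e-300))
            t_vals = beta / se
            p_vals = 2 * stats.t.sf(np.abs(t_vals), df)
            worst = int(np.argmax(p_vals[1:]))  # never test the intercept
            if p_vals[1:][worst] <= self.p_remove:
                break
            del selected[worst]
        return selected

    def decision_function(self, X) -> np.ndarray:
        """Linear score w.x + intercept; positive means target-like."""
        check_is_fitted(self, "selected_features_")
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        if single:
            X = X[None]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature length {X.shape[1]} != training length {self.n_features_in_}"
            )
        scores = X[:, self.selected_features_] @ self.weights_ + self.intercept_
        return scores[0] if single else scores

    def predict(self, X) -> np.ndarray:
        """Target iff score > 0; a score of exactly 0 is non-target."""
        scores = np.atleast_1d(self.decision_function(X))
        out = np.where(scores > 0, TARGET, NONTARGET)
        return out if np.asarray(X).ndim > 1 else out[0]


def swlda_fit(features, labels, **kwargs) -> SWLDA:
    """Fit the stepwise discriminant (thin wrapper over SWLDA)."""
    return SWLDA(**kwargs).fit(features, labels)


def swlda_predict(features, model: SWLDA):
    """Class label(s) for decimated feature vector(s)."""
    return model.predict(features)


def swlda_command_select(features_by_code: dict[int, np.ndarray], model: SWLDA) -> CommandDecision:
    """Decide the attended command from one feature vector per stimulus code.

    The command whose feature vector earns the highest (most target-like)
    linear score wins; smallest code on ties.
    """
    k = len(features_by_code)
    expected = set(range(1, k + 1))
    if set(features_by_code) != expected:
        raise ValueError(
            f"expected one feature vector per code {sorted(expected)}, got {sorted(features_by_code)}"
        )
    feats = np.stack([features_by_code[c] for c in range(1, k + 1)])
    scores = model.decision_function(feats)
    return CommandDecision(scores=scores, decided_command=int(np.argmax(scores)) + 1)
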