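"""Dirichlet-multinomial mixture (DMM) enterotyping and switch analysis.

Gut communities cluster into a small number of compositional types
(enterotypes). The DMM model treats each sample's genus-level count vector as
multinomial with a Dirichlet-distributed composition whose parameters depend
on a latent community type::

    x_i | z_i = k  ~  DirichletMultinomial(n_i, alpha_k),   z_i ~ Categorical(pi)

Fitting is by expectation-maximisation: the E-step computes posterior
responsibilities from the component Dirichlet-multinomial likelihoods, the
M-step re-estimates the mixture weights and the component Dirichlet parameters
by a monotone fixed-point iteration on the weighted likelihood. The number of
components is selected by the Laplace approximation of the model evidence
(BIC offered as a fallback). Components are labelled by their dominant genus
(largest fitted alpha proportion), and longitudinal enterotype switching is
summarised with Fisher exact tests.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp, polygamma, psi
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = [
    "DirichletMultinomialMixture",
    "fit_dmm",
    "select_k",
    "assign_and_label",
    "switch_analysis",
    "counts_from_relative",
]


def counts_from_relative(table: pd.DataFrame, depth: int) -> pd.DataFrame:
    """Convert relative abundances to integer counts at a nominal depth.

    Values are scaled by ``depth`` and rounded half-to-even; logged because
    the DMM likelihood is only exact for true counts.
    """
    logger.info("converting relative abundances to counts at depth %d (round half-to-even)", depth)
    return pd.DataFrame(
        np.rint(table.to_numpy() * depth).astype(np.int64),
        index=table.index, columns=table.columns,
    )


def _dm_component_loglik(X: np.ndarray, alpha: np.ndarray, log_coef: np.ndarray) -> np.ndarray:
    """log DM(x_i | alpha) for every sample, including the multinomial coefficient."""
    n = X.sum(axis=1)
    A = alpha.sum()
    return (
        log_coef
        + gammaln(A)
        - gammaln(n + A)
        + (gammaln(X + alpha) - gammaln(alpha)).sum(axis=1)
    )


def _fixed_point_alpha(
    X: np.ndarray, r: np.ndarray, alpha: np.ndarray,
    floor: float, tol: float = 1e-10, max_iter: int = 100,
) -> np.ndarray:
    """Weighted Dirichlet-multinomial MLE by the standard fixed-point update.

    alpha_j <- alpha_j * sum_i r_i [psi(x_ij + a_j) - psi(a_j)]
                       / sum_i r_i [psi(n_i + A)  - psi(A)]

    Each update is an ascent step on the weighted log-likelihood.
    """
    n = X.sum(axis=1)
    for _ in range(max_iter):
        A = alpha.sum()
        num = (r[:, None] * (psi(X + alpha) - psi(alpha))).sum(axis=0)
        den = (r * (psi(n + A) - psi(A))).sum()
        if den <= 0:
            break
        new = np.maximum(alpha * num / den, floor)
        if np.max(np.abs(new - alpha) / np.maximum(alpha, floor)) < tol:
            alpha = new
            break
        alpha = new
    return alpha


class DirichletMultinomialMixture(BaseEstimator):
    """Mixture of Dirichlet-multinomial components fitted by EM.

    Parameters
    ----------
    n_components : int
        Number of mixture components K.
    n_restarts : int
        Independent EM runs (k-means-on-proportions initialisation); the run
        with the highest log-likelihood is kept.
    tol : float
        EM convergence: relative change of the log-likelihood.
    max_iter : int
        EM iteration cap; hitting it sets ``converged_ = False`` (flagged,
        never silent).
    alpha_floor : float
        Lower bound applied to every Dirichlet parameter.
    random_state : int or None
        Seed for initialisation.

    Attributes
    ----------
    weights_ : (K,) mixture weights.
    alphas_ : (K, J) Dirichlet parameter vectors.
    responsibilities_ : (n, K) posterior component probabilities.
    labels_ : (n,) max-responsibility component per training sample.
    log_likelihood_ : float, at the kept optimum.
    log_likelihood_trace_ : per-EM-iteration log-likelihoods of the kept run.
    laplace_ : Laplace-approximation negative log evidence (lower is better).
    bic_ : Bayesian information criterion (lower is better).
    converged_ : bool.
    feature_names_ : column names when X is a DataFrame.
    dominant_genus_ : per-component dominant feature label (if names known).
    """

    def __init__(self, n_components: int = 2, n_restarts: int = 5, tol: float = 1e-6,
                 max_iter: int = 200, alpha_floor: float = 1e-10,
                 random_state: int | None = None):
        self.n_components = n_components
        self.n_restarts = n_restarts
        self.tol = tol
        self.max_iter = max_iter
        self.alpha_floor = alpha_floor
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    def _validate(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            self.feature_names_ = list(X.columns)
            X = X.to_numpy()
        else:
            X = np.asarray(X)
            self.feature_names_ = getattr(self, "feature_names_", None)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x genera)")
        if not np.issubdtype(X.dtype, np.integer):
            if not np.allclose(X, np.rint(X)):
                raise ValueError(
                    "X must hold integer counts; convert relative abundances "
                    "with counts_from_relative()"
                )
            X = np.rint(X).astype(np.int64)
        if (X < 0).any():
            raise ValueError("counts must be non-negative")
        return X

    def _em_once(self, X: np.ndarray, rng: np.random.Generator):
        n, J = X.shape
        K = self.n_components
        props = X / X.sum(axis=1, keepdims=True)
        if K == 1:
            assign = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=K, n_init=1,
                        random_state=int(rng.integers(2**31 - 1)))
            assign = km.fit_predict(props)
        alphas = np.empty((K, J))
        for k in range(K):
            mask = assign == k
            mean = props[mask].mean(axis=0) if mask.any() else props.mean(axis=0)
            alphas[k] = np.maximum(mean * 10.0, self.alpha_floor)
        weights = np.maximum(np.bincount(assign, minlength=K) / n, 1e-3)
        weights /= weights.sum()

        log_coef = gammaln(X.sum(axis=1) + 1) - gammaln(X + 1).sum(axis=1)
        trace = []
        prev = -np.inf
        converged = False
        for _ in range(self.max_iter):
            # E-step
            log_p = np.stack([
                np.log(weights[k]) + _dm_component_loglik(X, alphas[k], log_coef)
                for k in range(K)
            ], axis=1)
            norm = logsumexp(log_p, axis=1)
            ll = norm.sum()
            trace.append(ll)
            resp = np.exp(log_p - norm[:, None])
            if np.isfinite(prev) and abs(ll - prev) <= self.tol * abs(prev):
                converged = True
                break
            prev = ll
            # M-step
            weights = np.maximum(resp.mean(axis=0), 1e-12)
            weights /= weights.sum()
            for k in range(K):
                alphas[k] = _fixed_point_alpha(X, resp[:, k], alphas[k], self.alpha_floor)
        return ll, weights, alphas, resp, trace, converged

    def _laplace(self, X: np.ndarray) -> float:
        """Negative log evidence by Laplace approximation over log-alpha.

        The Hessian of the weighted component likelihood w.r.t. log alpha is
        diagonal plus rank one, so its determinant is analytic; a component
        whose Hessian is not negative definite falls back to a BIC-style
        penalty on its effective sample size.
        """
        n, J = X.shape
        counts_n = X.sum(axis=1)
        penalty = 0.0
        for k in range(self.n_components):
            r = self.responsibilities_[:, k]
            a = self.alphas_[k]
            A = a.sum()
            D = (r[:, None] * (polygamma(1, X + a) - polygamma(1, a))).sum(axis=0)
            u = (r * (polygamma(1, A) - polygamma(1, counts_n + A))).sum()
            neg_diag = -(a ** 2) * D  # diagonal of -H in log space
            if (neg_diag <= 0).any():
                penalty += 0.5 * J * np.log(max(r.sum(), 2.0))
                continue
            det_factor = 1.0 + u * (1.0 / D).sum()
            if det_factor <= 0:
                penalty += 0.5 * J * np.log(max(r.sum(), 2.0))
                continue
            penalty += 0.5 * (np.log(neg_diag).sum() + np.log(det_factor))
        K = self.n_components
        if K > 1:
            # weights: observed information on the simplex has determinant
            # n^(K-1) / prod(pi_k); near-empty components are penalised hard
            pi = np.maximum(self.weights_, 1e-12)
            penalty += 0.5 * ((K - 1) * np.log(n) - np.log(pi).sum()
                              - (K - 1) * np.log(2 * np.pi))
        return float(-self.log_likelihood_ - 0.5 * K * J * np.log(2 * np.pi) + penalty)

    # -- API ---------------------------------------------------------------
    def fit(self, X, y=None):
        X = self._validate(X)
        n, J = X.shape
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.n_components > n:
            raise ValueError(f"n_components={self.n_components} exceeds n_samples={n}")
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(max(1, self.n_restarts)):
            result = self._em_once(X, rng)
            if best is None or result[0] > best[0]:
                best = result
        ll, weights, alphas, resp, trace, converged = best
        if not converged:
            logger.warning("DMM EM did not converge in %d iterations (K=%d)",
                           self.max_iter, self.n_components)
        self.weights_ = weights
        self.alphas_ = alphas
        self.responsibilities_ = resp
        self.labels_ = resp.argmax(axis=1)
        self.log_likelihood_ = float(ll)
        self.log_likelihood_trace_ = list(trace)
        self.converged_ = bool(converged)
        p = self.n_components * J + (self.n_components - 1)
        self.bic_ = float(-2 * ll + p * np.log(n))
        self.laplace_ = self._laplace(X)
        if self.feature_names_ is not None:
            props = alphas / alphas.sum(axis=1, keepdims=True)
            self.dominant_genus_ = [self.feature_names_[j] for j in props.argmax(axis=1)]
        else:
            self.dominant_genus_ = None
        return self

    def predict_proba(self, X) -> np.ndarray:
        names = getattr(self, "feature_names_", None)
        X = self._validate(X)
        if names is not None:
            self.feature_names_ = names
        log_coef = gammaln(X.sum(axis=1) + 1) - gammaln(X + 1).sum(axis=1)
        log_p = np.stack([
            np.log(self.weights_[k]) + _dm_component_loglik(X, self.alphas_[k], log_coef)
            for k in range(self.n_components)
        ], axis=1)
        return np.exp(log_p - logsumexp(log_p, axis=1)[:, None])

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)


def fit_dmm(counts: pd.DataFrame, k: int, seed: int = 0, n_restarts: int = 5,
            tol: float = 1e-6) -> DirichletMultinomialMixture:
    """Fit a K-component DMM to a genus x sample integer count table."""
    model = DirichletMultinomialMixture(
        n_components=k, n_restarts=n_restarts, tol=tol, random_state=seed
    )
    return model.fit(counts.T)


def select_k(counts: pd.DataFrame, k_range, criterion: str = "laplace",
             seed: int = 0, n_restarts: int = 5) -> tuple[int, pd.DataFrame, dict]:
    """Fit DMMs over ``k_range`` and pick the criterion-minimising K."""
    if criterion not in ("laplace", "bic"):
        raise ValueError("criterion must be 'laplace' or 'bic'")
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must be non-empty")
    rows, models = [], {}
    for k in k_range:
        m = fit_dmm(counts, k, seed=seed, n_restarts=n_restarts)
        models[k] = m
        rows.append({"K": k, "log_likelihood": m.log_likelihood_,
                     "laplace": m.laplace_, "bic": m.bic_,
                     "converged": m.converged_})
    table = pd.DataFrame(rows).set_index("K")
    best_k = int(table[criterion].idxmin())
    return best_k, table, models


def assign_and_label(model: DirichletMultinomialMixture, counts: pd.DataFrame) -> pd.Series:
    """Assign each sample to its max-responsibility component, labelled by the
    component's dominant genus (ties on responsibility -> lowest index)."""
    proba = model.predict_proba(counts.T)
    comp = proba.argmax(axis=1)
    if model.dominant_genus_ is not None:
        names = list(model.dominant_genus_)
        # disambiguate if two components share a dominant genus
        if len(set(names)) < len(names):
            names = [f"{g}_{k}" for k, g in enumerate(names)]
    else:
        names = [f"component_{k}" for k in range(model.n_components)]
    return pd.Series([names[c] for c in comp], index=counts.columns, name="enterotype")


def switch_analysis(
    labels_t0: pd.Series,
    labels_t12: pd.Series,
    arms: pd.Series | None = None,
    reference_enterotype: str = "Bacteroides",
) -> dict:
    """Longitudinal enterotype switching summary with Fisher exact tests.

    Inputs are indexed by subject. Returns the per-subject switch table, the
    overall switch proportion, and 2x2 Fisher exact contrasts of switching by
    baseline enterotype (reference vs other) and, when ``arms`` is given, by
    intervention arm.
    """
    common = labels_t0.index.intersection(labels_t12.index)
    if len(common) == 0:
        raise ValueError("no paired subjects")
    table = pd.DataFrame({
        "enterotype_t0": labels_t0.loc[common],
        "enterotype_t12": labels_t12.loc[common],
    })
    table["switched"] = table["enterotype_t0"] != table["enterotype_t12"]
    out: dict = {"table": table, "overall_switch_prop": table["switched"].mean()}

    is_ref = table["enterotype_t0"] == reference_enterotype
    ct = np.array([
        [int((is_ref & table["switched"]).sum()), int((is_ref & ~table["switched"]).sum())],
        [int((~is_ref & table["switched"]).sum()), int((~is_ref & ~table["switched"]).sum())],
    ])
    out["by_baseline_enterotype"] = {
        "table": ct,
        "switch_prop_reference": ct[0, 0] / ct[0].sum() if ct[0].sum() else np.nan,
        "switch_prop_other": ct[1, 0] / ct[1].sum() if ct[1].sum() else np.nan,
        "fisher_p": stats.fisher_exact(ct, alternative="two-sided")[1],
    }
    if arms is not None:
        arms = arms.loc[common]
        arm_names = sorted(arms.unique())
        ct2 = np.array([
            [int((table["switched"] & (arms == a)).sum()),
             int((~table["switched"] & (arms == a)).sum())]
            for a in arm_names
        ])
        out["by_arm"] = {
            "arms": arm_names,
            "table": ct2,
            "switch_props": {a: ct2[i, 0] / ct2[i].sum() for i, a in enumerate(arm_names)},
            "fisher_p": stats.fisher_exact(ct2, alternative="two-sided")[1]
            if len(arm_names) == 2 else np.nan,
        }
    return out
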