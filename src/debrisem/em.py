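"""Semi-supervised multinomial mixture model fit by EM.

The model: droplet count vectors x_i (total u_i) are multinomial draws whose
gene probabilities alpha_k depend on a latent component z_i in {0..K}, with
mixing weights pi. Component 0 is the ambient-debris component; the K others
are cell types. The observed-data log-likelihood is

    log P(X) = sum_i log( sum_k pi_k Mult(x_i | alpha_k, u_i) ).

Semi-supervision: droplets whose total count falls below a threshold are
assumed to contain ambient RNA, and their latent labels are held fixed at the
debris component throughout EM. This anchors the debris profile to the long
tail of near-empty droplets while the remaining ("test set") droplets are
free to move between components.

The multinomial coefficient depends on x_i only and cancels in every
posterior ratio, so component-score computations omit it by default; pass
``include_coefficient=True`` where an absolute likelihood is wanted.
Reported log-likelihoods are therefore comparable only within a run unless
the coefficient is included.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import gammaln, logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "MixtureParams",
    "PosteriorMatrix",
    "EMResult",
    "multinomial_log_prob",
    "e_step",
    "m_step",
    "run_em",
    "assign_clusters",
    "observed_log_likelihood",
]


@dataclass
class MixtureParams:
    """Parameters of the (K+1)-component multinomial mixture.

    ``alpha`` is (K+1) x G with each row a gene-probability vector;
    ``pi`` is the length-(K+1) mixing weight vector. ``debris_index`` is the
    component whose label is fixed for low-count droplets (0 by convention).
    """

    alpha: np.ndarray
    pi: np.ndarray
    debris_index: int = 0

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.alpha.ndim != 2 or self.pi.shape != (self.alpha.shape[0],):
            raise ValueError("alpha must be (K+1) x G with pi of length K+1")
        if not (0 <= self.debris_index < self.alpha.shape[0]):
            raise ValueError("debris_index out of range")

    @property
    def n_components(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_genes(self) -> int:
        return self.alpha.shape[1]

    def validate(self, atol: float = 1e-10) -> None:
        if np.any(self.alpha <= 0):
            raise ValueError("alpha entries must be > 0 (pseudocount expected)")
        if np.max(np.abs(self.alpha.sum(axis=1) - 1.0)) > atol:
            raise ValueError("alpha rows must sum to 1")
        if np.any(self.pi < 0) or abs(self.pi.sum() - 1.0) > atol:
            raise ValueError("pi must be nonnegative and sum to 1")


@dataclass
class PosteriorMatrix:
    """Per-droplet component membership probabilities.

    Rows of ``probs`` (N x (K+1)) sum to one; rows where ``fixed_mask`` is
    True are exactly one-hot at the debris component.
    """

    probs: np.ndarray
    fixed_mask: np.ndarray

    @property
    def n_droplets(self) -> int:
        return self.probs.shape[0]


@dataclass
class EMResult:
    params: MixtureParams
    posteriors: PosteriorMatrix
    trace: pd.DataFrame  # columns: iteration, log_likelihood, max_param_change
    converged: bool
    n_iter: int


def multinomial_log_prob(
    x: np.ndarray, alpha_k: np.ndarray, include_coefficient: bool = False
) -> float:
    """Log multinomial pmf of count vector ``x`` under gene probabilities
    ``alpha_k``, up to the count-only coefficient unless requested.

    A zero alpha entry with a positive count yields -inf (permitted; the
    pseudocount in fitted parameters precludes it there).
    """
    x = np.asarray(x, dtype=float)
    a = np.asarray(alpha_k, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(x > 0, x * np.log(a), 0.0)
    out = float(terms.sum())
    if include_coefficient:
        out += float(gammaln(x.sum() + 1) - gammaln(x + 1).sum())
    return out


def _component_scores(counts: sp.spmatrix, params: MixtureParams) -> np.ndarray:
    """N x (K+1) matrix of log pi_k + sum_g x_gi log alpha_kg."""
    with np.errstate(divide="ignore"):
        log_alpha = np.log(params.alpha)  # (K+1, G)
        log_pi = np.log(params.pi)
    # sparse (N x G) @ dense (G x (K+1)); only stored x>0 entries multiply,
    # so -inf log-alphas propagate exactly where a count is positive
    s = counts.T @ log_alpha.T
    s = np.asarray(s)
    return s + log_pi[None, :]


def _posteriors_and_loglik(
    counts: sp.spmatrix, params: MixtureParams, fixed_mask: np.ndarray | None
) -> tuple[np.ndarray, float]:
    """E-step work-horse.

    Returns responsibilities (fixed rows one-hot) and the semi-supervised
    observed-data log-likelihood: free droplets contribute the log mixture
    density, fixed droplets the log of their (debris-component) joint term.
    """
    scores = _component_scores(counts, params)
    n, m = scores.shape
    row_lse = logsumexp(scores, axis=1)
    if np.any(np.isneginf(row_lse)):
        raise FloatingPointError("droplet with -inf likelihood in every component")
    probs = np.exp(scores - row_lse[:, None])
    ll_terms = row_lse
    if fixed_mask is not None and fixed_mask.any():
        fixed_mask = np.asarray(fixed_mask, dtype=bool)
        probs[fixed_mask, :] = 0.0
        probs[fixed_mask, params.debris_index] = 1.0
        ll_terms = np.where(fixed_mask, scores[:, params.debris_index], row_lse)
    return probs, float(ll_terms.sum())


def e_step(
    counts: sp.spmatrix,
    params: MixtureParams,
    fixed_mask: np.ndarray | None = None,
) -> PosteriorMatrix:
    """Posterior membership probabilities, computed in log space.

    ``counts`` is the gene x droplet sparse matrix. Droplets flagged in
    ``fixed_mask`` have their posterior overwritten with a one-hot vector at
    the debris component, realizing the fixed latent labels of the
    semi-supervised scheme.
    """
    if fixed_mask is None:
        fixed_mask = np.zeros(counts.shape[1], dtype=bool)
    probs, _ = _posteriors_and_loglik(counts, params, fixed_mask)
    return PosteriorMatrix(probs=probs, fixed_mask=np.asarray(fixed_mask, dtype=bool))


def m_step(
    counts: sp.spmatrix,
    posteriors: PosteriorMatrix,
    pseudocount: float = 1e-10,
) -> MixtureParams:
    """Maximum-likelihood parameter update from responsibilities.

    alpha_k is the responsibility-weighted mean of droplet counts plus a
    pseudocount per gene (to keep every probability strictly positive),
    renormalized; pi_k is the mean responsibility.
    """
    r = posteriors.probs  # N x (K+1)
    weighted = np.asarray(counts @ r)  # G x (K+1)
    mass = r.sum(axis=0)
    empty = mass <= 1e-8 * r.shape[0]
    if empty.any():
        logger.warning(
            "component(s) %s have ~zero posterior mass; pseudocount keeps them "
            "at the uniform distribution",
            np.flatnonzero(empty).tolist(),
        )
    alpha = weighted.T + pseudocount
    alpha /= alpha.sum(axis=1, keepdims=True)
    pi = mass / r.shape[0]
    return MixtureParams(alpha=alpha, pi=pi, debris_index=0)


def run_em(
    counts: sp.spmatrix,
    init_params: MixtureParams,
    fixed_mask: np.ndarray | None = None,
    eps: float = 1e-4,
    max_iter: int = 1000,
    pseudocount: float = 1e-10,
) -> EMResult:
    """Alternate E and M steps until the parameters stop moving.

    Convergence is declared when the maximum absolute change across all
    alpha and pi entries falls below ``eps``. The trace records, for each
    iteration, the observed-data log-likelihood evaluated at the pre-update
    parameters; by the EM ascent property it is nondecreasing (up to the
    tiny perturbation the pseudocount introduces).
    """
    counts = sp.csc_matrix(counts)
    if fixed_mask is None:
        fixed_mask = np.zeros(counts.shape[1], dtype=bool)
    fixed_mask = np.asarray(fixed_mask, dtype=bool)
    params = init_params
    rows = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        probs, ll = _posteriors_and_loglik(counts, params, fixed_mask)
        new_params = m_step(counts, PosteriorMatrix(probs, fixed_mask), pseudocount)
        delta = max(
            float(np.max(np.abs(new_params.alpha - params.alpha))),
            float(np.max(np.abs(new_params.pi - params.pi))),
        )
        rows.append((it, ll, delta))
        params = new_params
        if delta < eps:
            converged = True
            break
    if not converged:
        logger.warning("EM reached max_iter=%d without converging", max_iter)
    trace = pd.DataFrame(rows, columns=["iteration", "log_likelihood", "max_param_change"])
    posteriors = e_step(counts, params, fixed_mask)
    return EMResult(params=params, posteriors=posteriors, trace=trace,
                    converged=converged, n_iter=it)


def assign_clusters(posteriors: PosteriorMatrix) -> np.ndarray:
    """Hard labels by maximum posterior; ties go to the lowest component
    index (so an exact tie with the debris component yields debris)."""
    return np.argmax(posteriors.probs, axis=1)


def observed_log_likelihood(
    counts: sp.spmatrix,
    params: MixtureParams,
    fixed_mask: np.ndarray | None = None,
    include_coefficient: bool = False,
) -> float:
    """Observed-data log-likelihood of the mixture.

    Without ``fixed_mask`` this is sum_i log sum_k pi_k Mult(x_i|alpha_k);
    with it, fixed droplets contribute their debris-component joint term
    (the quantity EM with fixed labels actually ascends). Uses the same
    coefficient convention as :func:`multinomial_log_prob`.
    """
    counts = sp.csc_matrix(counts)
    _, ll = _posteriors_and_loglik(counts, params, fixed_mask)
    if include_coefficient:
        x = counts.toarray().astype(float)
        ll += float(
            gammaln(x.sum(axis=0) + 1).sum() - gammaln(x + 1).sum()
        )
    return ll
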