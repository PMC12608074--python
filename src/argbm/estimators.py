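"""Likelihood and maximum-likelihood estimates of root locations and dispersal.

Model: sample locations arise from Brownian motion with per-generation
dispersal rate σ² (1D) or dispersal matrix Σ (2D) run forward down the ARG
from independent, fixed root locations, conditioned on both parental
lineages meeting at every recombination node.  With the path-tip vector
``Lp ~ N(Rμ, σ² Sp)`` this gives the generalized-least-squares estimates

    μ̂  = (R^T Sp^g- R)^{-1} R^T Sp^g- P ℓ*
    σ̂² = (P ℓ* - R μ̂)^T Sp^g- (P ℓ* - R μ̂) / ns

(applied columnwise over habitat dimensions; in 2D the quadratic form is the
2x2 dispersal matrix).  On a tree these collapse to the classic phylogenetic
Brownian-motion GLS estimates.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._linalg import psd_pinv, solve_spd
from .arg import ARG, locations_array
from .paths import PathBasis, enumerate_minimal_paths, sample_matrix, shared_times


@dataclass
class SpatialFit:
    """Result of a spatial maximum-likelihood fit.

    ``mu_hat`` is an ``(nr, d)`` matrix of root locations (habitat units);
    ``dispersal`` is a scalar σ̂² in 1D or a 2x2 symmetric PSD matrix Σ̂ in 2D,
    per generation.
    """

    mu_hat: np.ndarray
    dispersal: float | np.ndarray
    loglik: float
    n_roots: int
    n_samples: int
    n_paths: int
    roots: np.ndarray
    samples: np.ndarray

    @property
    def dims(self) -> int:
        return self.mu_hat.shape[1]

    def dispersal_matrix(self) -> np.ndarray:
        """Dispersal as a (d, d) matrix regardless of habitat dimension."""
        if np.ndim(self.dispersal) == 0:
            return np.array([[float(self.dispersal)]])
        return np.asarray(self.dispersal)


def _effective_shared_times(
    Sp: np.ndarray, R: np.ndarray, root_variance: float
) -> np.ndarray:
    # optional relaxation of the fixed-root assumption: a scalar prior
    # variance (in units of shared time) between pairs of paths from the
    # same root; default 0 keeps root locations fixed
    if root_variance:
        return Sp + root_variance * (R @ R.T)
    return Sp


def mle_root_locations(
    locations: np.ndarray, basis: PathBasis, Sp: np.ndarray
) -> np.ndarray:
    """GLS/ML root locations, ``(nr, d)``."""
    loc = np.atleast_2d(np.asarray(locations, dtype=float))
    if loc.shape[0] == 1 and len(basis.samples) == 1:
        loc = loc.reshape(1, -1)
    elif loc.shape[0] != len(basis.samples):
        loc = loc.T
    g, _, _ = psd_pinv(Sp)
    a = basis.R.T @ g @ basis.R
    b = basis.R.T @ g @ basis.P @ loc
    return solve_spd(a, b, what="R^T Sp^g- R")


def mle_dispersal(
    locations: np.ndarray,
    basis: PathBasis,
    Sp: np.ndarray,
    mu_hat: np.ndarray,
) -> float | np.ndarray:
    """ML dispersal rate: scalar σ̂² in 1D, 2x2 matrix Σ̂ in 2D.

    Denominator is ``ns`` (maximum likelihood, no degrees-of-freedom
    correction for the estimated roots).
    """
    loc = locations_like(locations, basis)
    g, _, _ = psd_pinv(Sp)
    resid = basis.P @ loc - basis.R @ np.atleast_2d(mu_hat)
    q = resid.T @ g @ resid / len(basis.samples)
    q = (q + q.T) / 2.0
    # PSD up to roundoff by construction of the pseudo-inverse
    assert np.all(np.linalg.eigvalsh(q) > -1e-9 * max(1.0, abs(q).max()))
    if q.shape == (1, 1):
        return max(float(q[0, 0]), 0.0)
    return q


def locations_like(locations, basis: PathBasis) -> np.ndarray:
    loc = np.asarray(locations, dtype=float)
    if loc.ndim == 1:
        loc = loc[:, None]
    if loc.shape[0] != len(basis.samples):
        raise ValueError("locations do not match the basis samples")
    return loc


def log_likelihood(
    locations: np.ndarray,
    basis: PathBasis,
    Sp: np.ndarray,
    mu: np.ndarray,
    dispersal: float | np.ndarray,
) -> float:
    """Log-likelihood of the observed sample locations.

    Evaluates the Gaussian ``N(m, dispersal ⊗ S)`` for the sample-location
    vector, where ``S = (P^T Sp^g- P)^{-1}`` and the mean ``m`` is the
    conditional mean of the sample locations given the root locations
    (``m = S P^T Sp^g- R μ``; equal to ``μ1`` for a single root).  This is
    the path-form density on its constraint support up to a parameter-free
    constant whenever every recombination loop closes under a single root,
    and reduces exactly to the classic Brownian-motion tree likelihood when
    the ARG is a tree.  See :func:`path_log_likelihood` for the path form.
    """
    loc = locations_like(locations, basis)
    d = loc.shape[1]
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    if mu.shape[0] != basis.R.shape[1]:
        mu = mu.T
    g, _, _ = psd_pinv(Sp)
    s = sample_matrix(Sp, basis.P)
    mean = s @ (basis.P.T @ g @ basis.R @ mu)
    disp = np.atleast_2d(np.asarray(dispersal, dtype=float))
    if disp.shape != (d, d):
        raise ValueError("dispersal has wrong dimension for the locations")
    sign, logdet_s = np.linalg.slogdet(s)
    if sign <= 0:
        raise np.linalg.LinAlgError("sample matrix is not positive definite")
    sign_d, logdet_disp = np.linalg.slogdet(disp)
    if sign_d <= 0:
        raise np.linalg.LinAlgError("dispersal is not positive definite")
    resid = loc - mean
    q = resid.T @ np.linalg.solve(s, resid)
    ns = len(basis.samples)
    return float(
        -0.5
        * (
            d * ns * np.log(2 * np.pi)
            + ns * logdet_disp
            + d * logdet_s
            + np.trace(np.linalg.solve(disp, q))
        )
    )


def path_log_likelihood(
    locations: np.ndarray,
    basis: PathBasis,
    Sp: np.ndarray,
    mu: np.ndarray,
    dispersal: float | np.ndarray,
) -> float:
    """Log-density of the path-tip Gaussian ``Lp ~ N(Rμ, dispersal ⊗ Sp)``
    evaluated at ``Pℓ*``, with pseudo-inverse and pseudo-determinant on the
    support when ``Sp`` is singular (redundant path sets).

    For a tree this coincides with :func:`log_likelihood`; for a minimal
    basis of a loopy ARG the two differ by a normalization that is
    parameter-free whenever every loop closes under a single root.  The
    root-location estimate of the model is the exact maximizer of this
    objective over μ at any fixed dispersal.
    """
    loc = locations_like(locations, basis)
    d = loc.shape[1]
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    if mu.shape[0] != basis.R.shape[1]:
        mu = mu.T
    g, rank, logpdet = psd_pinv(Sp)
    disp = np.atleast_2d(np.asarray(dispersal, dtype=float))
    _, logdet_disp = np.linalg.slogdet(disp)
    resid = basis.P @ loc - basis.R @ mu
    q = resid.T @ g @ resid
    return float(
        -0.5
        * (
            d * rank * np.log(2 * np.pi)
            + rank * logdet_disp
            + d * logpdet
            + np.trace(np.linalg.solve(disp, q))
        )
    )


def fit(
    arg: ARG,
    locations,
    cutoff: float | None = None,
    root_variance: float = 0.0,
) -> SpatialFit:
    """End-to-end fit: (chop ->) minimal paths -> shared times -> MLEs."""
    model = BrownianDispersal(cutoff=cutoff, root_variance=root_variance)
    model.fit(arg, locations)
    return model.result_


class BrownianDispersal:
    """Maximum-likelihood dispersal and root locations from an ARG.

    scikit-learn-style estimator: configure with constructor parameters,
    call :meth:`fit` with an ARG and sample coordinates, then read fitted
    attributes (``dispersal_``, ``root_locations_``, ``log_likelihood_``)
    or query ancestor locations via :meth:`locate` / :meth:`predict`.

    Parameters
    ----------
    cutoff : float, optional
        Chop the ARG at this many generations in the past before fitting;
        each truncated lineage gets an independent root at the cutoff.
    root_variance : float, default 0
        Optional scalar prior variance on root locations, expressed in
        shared-time units added between pairs of paths from the same root;
        0 fixes the roots (the default model).
    """

    def __init__(self, cutoff: float | None = None, root_variance: float = 0.0):
        self.cutoff = cutoff
        self.root_variance = root_variance

    # minimal get/set_params so the estimator plays with sklearn tooling
    def get_params(self, deep: bool = True) -> dict:
        return {"cutoff": self.cutoff, "root_variance": self.root_variance}

    def set_params(self, **params) -> "BrownianDispersal":
        for k, v in params.items():
            if k not in ("cutoff", "root_variance"):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, arg: ARG, locations) -> "BrownianDispersal":
        if not isinstance(arg, ARG):
            arg = ARG(arg)
        if self.cutoff is not None:
            arg = arg.chop(self.cutoff)
        self.arg_ = arg
        loc = locations_array(arg, locations)
        self.basis_ = enumerate_minimal_paths(arg)
        sp = shared_times(arg, self.basis_)
        self.shared_times_ = _effective_shared_times(
            sp, self.basis_.R, self.root_variance
        )
        self.root_locations_ = mle_root_locations(loc, self.basis_, self.shared_times_)
        self.dispersal_ = mle_dispersal(
            loc, self.basis_, self.shared_times_, self.root_locations_
        )
        disp = self.dispersal_
        if np.ndim(disp) == 0:
            disp = np.array([[float(disp)]])
        self.log_likelihood_ = (
            log_likelihood(
                loc, self.basis_, self.shared_times_, self.root_locations_, disp
            )
            if np.all(np.linalg.eigvalsh(disp) > 0)
            else -np.inf
        )
        self.locations_ = loc
        self.n_samples_ = arg.num_samples
        self.n_paths_ = len(self.basis_)
        self.n_roots_ = len(arg.roots)
        self.result_ = SpatialFit(
            mu_hat=self.root_locations_,
            dispersal=self.dispersal_,
            loglik=self.log_likelihood_,
            n_roots=self.n_roots_,
            n_samples=self.n_samples_,
            n_paths=self.n_paths_,
            roots=arg.roots.copy(),
            samples=arg.samples.copy(),
        )
        return self

    def _check_fitted(self):
        if not hasattr(self, "result_"):
            raise RuntimeError("estimator is not fitted; call fit() first")

    def locate(self, sample_id: int, position: float, time: float,
               level: float = 0.95, dispersal=None):
        """Location distribution of the ancestor of ``sample_id`` at
        ``position`` bp and ``time`` generations (see :mod:`argbm.ancestors`)."""
        from .ancestors import AncestorQuery, locate

        self._check_fitted()
        return locate(
            self.arg_, self.locations_, self,
            AncestorQuery(sample_id=sample_id, position=position, time=time),
            level=level, dispersal=dispersal,
        )

    def locate_track(self, sample_id: int, position: float, times,
                     level: float = 0.95, dispersal=None):
        from .ancestors import locate_track

        self._check_fitted()
        return locate_track(
            self.arg_, self.locations_, self, sample_id, position, times,
            level=level, dispersal=dispersal,
        )

    def predict(self, queries) -> np.ndarray:
        """Mean ancestor locations for an iterable of
        ``(sample_id, position, time)`` queries, shape ``(n_queries, d)``."""
        self._check_fitted()
        return np.array(
            [self.locate(s, p, t).mean for s, p, t in queries]
        )
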