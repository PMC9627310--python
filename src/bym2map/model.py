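"""BYM2 Poisson model: scaled ICAR structure, PC priors, joint log-density.

The model for area counts is

    O_i ~ Poisson(E_i * exp(mu + b_i)),
    b_i = sigma * (sqrt(1 - phi) * v_i + sqrt(phi) * u*_i),

where v is i.i.d. standard normal, u* is the intrinsic CAR (ICAR) field
scaled so the geometric mean of its constrained marginal variances is one,
phi in [0, 1] splits the latent variance between the unstructured and
spatially structured components, and sigma is the overall marginal standard
deviation. The ICAR precision is Q = D - A on the contiguity graph, improper
with one null direction per connected component; identification comes from a
per-component sum-to-zero constraint. Islands (degree-0 areas) carry no
structured effect: u*_i = 0 there, so their latent variance is
sigma^2 * (1 - phi).

Hyperpriors are penalized-complexity (PC) priors: an exponential prior on
sigma calibrated by P(sigma > U_sigma) = alpha_sigma, and a PC prior on phi
built from the Kullback-Leibler distance between the BYM2 field at mixing
phi and the unstructured base model (phi = 0), calibrated by
P(phi < U_phi) = alpha_phi.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import brentq
from scipy.special import gammaln

from .geometry import AdjacencyGraph

__all__ = [
    "HyperPriors",
    "ScaledStructure",
    "BYM2Spec",
    "LatentState",
    "icar_precision",
    "scaling_factor",
    "scaled_structure",
    "pc_prior_sigma_logpdf",
    "pc_prior_sigma_rate",
    "PCMixingPrior",
    "log_joint",
    "make_spec",
]

_EIG_TOL = 1e-9


@dataclass(frozen=True)
class HyperPriors:
    """PC-prior hyperparameters: P(phi < U_phi) = alpha_phi, P(sigma > U_sigma) = alpha_sigma."""

    U_phi: float = 0.5
    alpha_phi: float = 2.0 / 3.0
    U_sigma: float = 0.2 / 0.31
    alpha_sigma: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.U_phi < 1 and 0 < self.alpha_phi < 1):
            raise ValueError("U_phi and alpha_phi must lie in (0, 1)")
        if not (self.U_sigma > 0 and 0 < self.alpha_sigma < 1):
            raise ValueError("U_sigma must be > 0 and alpha_sigma in (0, 1)")


def icar_precision(graph: AdjacencyGraph) -> sparse.csr_matrix:
    """ICAR precision Q = diag(degree) - adjacency over all nodes.

    Island rows/columns are identically zero; Q is symmetric with zero row
    sums and positive semi-definite, its null space spanned by the indicator
    vectors of the connected components.
    """
    adj = graph.adjacency_matrix().tocsr()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    return (sparse.diags(deg) - adj).tocsr()


def _component_eig(Q: sparse.csr_matrix, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Dense eigendecomposition of a component submatrix of Q."""
    sub = Q[np.ix_(idx, idx)].toarray()
    lam, vec = np.linalg.eigh(sub)
    return lam, vec


def scaling_factor(lam: np.ndarray, vec: np.ndarray) -> float:
    """Geometric-mean marginal variance of the sum-to-zero-constrained ICAR.

    For a connected component the constrained covariance equals the
    Moore-Penrose pseudo-inverse of the component precision; kappa is the
    geometric mean of its diagonal. Dividing the field by sqrt(kappa) gives
    geometric-mean marginal variance one.
    """
    pos = lam > _EIG_TOL * max(1.0, lam[-1])
    if pos.sum() != len(lam) - 1:
        raise ValueError("component precision must have a 1-dimensional null space")
    marg = (vec[:, pos] ** 2 / lam[pos]).sum(axis=1)
    return float(np.exp(np.mean(np.log(marg))))


@dataclass
class ScaledStructure:
    """Scaled ICAR structure over a contiguity graph.

    Holds the sparse precision, the per-component node index sets with their
    eigendecompositions and scaling factors, and the eigenvalue spectrum of
    the scaled structured covariance used by the PC mixing prior (one zero
    entry per island, reflecting the absent structured effect there).
    """

    Q: sparse.csr_matrix
    components: list[np.ndarray]          # non-singleton components (node indices)
    islands: np.ndarray                   # island node indices
    kappa: list[float]                    # scaling factor per non-singleton component
    eigvals: list[np.ndarray]             # raw ICAR eigenvalues per component
    eigvecs: list[np.ndarray]
    gamma: np.ndarray = field(init=False)  # scaled structured-covariance spectrum

    def __post_init__(self) -> None:
        # spectrum of the scaled structured covariance on the constrained
        # subspace; islands carry no structured field and do not contribute
        gammas = [np.empty(0)]
        for lam, kap in zip(self.eigvals, self.kappa):
            pos = lam > _EIG_TOL * max(1.0, lam[-1])
            gammas.append(1.0 / (kap * lam[pos]))
        self.gamma = np.concatenate(gammas)

    @property
    def n(self) -> int:
        return self.Q.shape[0]

    def sqrt_kappa_per_node(self) -> np.ndarray:
        """sqrt(kappa) of each node's component (1 for islands, unused there)."""
        s = np.ones(self.n)
        for idx, kap in zip(self.components, self.kappa):
            s[idx] = math.sqrt(kap)
        return s


def scaled_structure(graph: AdjacencyGraph) -> ScaledStructure:
    """Build and scale the ICAR structure per connected component."""
    Q = icar_precision(graph)
    labels = graph.component_id
    comps, kappas, lams, vecs = [], [], [], []
    islands = np.flatnonzero(graph.is_island)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) == 1:
            continue  # singleton = island: no structured effect, no scaling
        lam, vec = _component_eig(Q, idx)
        comps.append(idx)
        lams.append(lam)
        vecs.append(vec)
        kappas.append(scaling_factor(lam, vec))
    return ScaledStructure(
        Q=Q, components=comps, islands=islands, kappa=kappas, eigvals=lams, eigvecs=vecs
    )


# ---------------------------------------------------------------------------
# PC prior on sigma: exponential with rate -ln(alpha)/U

def pc_prior_sigma_rate(U_sigma: float, alpha_sigma: float) -> float:
    if U_sigma <= 0 or not (0 < alpha_sigma < 1):
        raise ValueError("need U_sigma > 0 and 0 < alpha_sigma < 1")
    return -math.log(alpha_sigma) / U_sigma


def pc_prior_sigma_logpdf(sigma: float, U_sigma: float, alpha_sigma: float) -> float:
    """Log-density of the PC prior on the marginal standard deviation.

    Exponential with rate lambda = -ln(alpha)/U, which gives exactly
    P(sigma > U) = alpha.
    """
    if sigma <= 0:
        return -np.inf
    lam = pc_prior_sigma_rate(U_sigma, alpha_sigma)
    return math.log(lam) - lam * sigma


# ---------------------------------------------------------------------------
# PC prior on phi

class PCMixingPrior:
    """PC prior on the BYM2 mixing parameter phi.

    The distance from the base model (phi = 0, purely unstructured field) is
    d(phi) = sqrt(2 * KLD(phi)) where KLD is the Kullback-Leibler divergence
    of N(0, (1-phi) I + phi * Sigma*) from N(0, I), evaluated through the
    positive eigenvalues gamma_j of the scaled structured covariance Sigma*
    on the constrained subspace (islands carry no structured field and do
    not enter the distance). An exponential density with rate ``rate`` is
    placed on d, truncated to the attainable range [0, d(1)], and ``rate``
    is solved so that P(phi < U) = alpha.
    """

    _PHI_MAX = 1.0 - 1e-12

    def __init__(self, structure: ScaledStructure, U_phi: float = 0.5,
                 alpha_phi: float = 2.0 / 3.0):
        if not (0 < U_phi < 1 and 0 < alpha_phi < 1):
            raise ValueError("U_phi and alpha_phi must lie in (0, 1)")
        g = structure.gamma
        if len(g) == 0:
            raise ValueError(
                "no non-singleton component: the mixing parameter has no "
                "structured field to weight"
            )
        self.gm1 = g - 1.0          # gamma_j - 1
        self.U_phi = U_phi
        self.alpha_phi = alpha_phi
        self.d_max = self._d(self._PHI_MAX)
        self.rate = self._solve_rate()
        self._log_norm = self._log1mexp(self.rate * self.d_max) - math.log(self.rate) \
            if self.rate > 0 else None

    # -- distance and derivatives (all analytic) --
    def _kld(self, phi: float) -> float:
        t = phi * self.gm1
        return float(0.5 * np.sum(t - np.log1p(t)))

    def _kld_d1(self, phi: float) -> float:
        s = 1.0 + phi * self.gm1
        return float(0.5 * np.sum(self.gm1**2 * phi / s))

    def _kld_d2(self, phi: float) -> float:
        s = 1.0 + phi * self.gm1
        return float(0.5 * np.sum(self.gm1**2 / s**2))

    def _d(self, phi: float) -> float:
        return math.sqrt(2.0 * self._kld(phi))

    def _d_d1(self, phi: float) -> float:
        d = self._d(phi)
        if d < 1e-8:
            return math.sqrt(self._kld_d2(0.0))  # limit as phi -> 0
        return self._kld_d1(phi) / d

    @staticmethod
    def _log1mexp(x: float) -> float:
        """log(1 - exp(-x)) for x > 0, stable."""
        if x <= 0:
            raise ValueError("x must be > 0")
        return math.log(-math.expm1(-x)) if x < 0.693 else math.log1p(-math.exp(-x))

    # -- calibration --
    def cdf_given_rate(self, phi: float, rate: float) -> float:
        """P(phi' < phi) under an exponential(rate) on d truncated to [0, d_max]."""
        dphi = self._d(min(phi, self._PHI_MAX))
        if abs(rate) < 1e-12:
            return dphi / self.d_max
        return float(math.expm1(-rate * dphi) / math.expm1(-rate * self.d_max))

    def _solve_rate(self) -> float:
        f = lambda lam: self.cdf_given_rate(self.U_phi, lam) - self.alpha_phi
        lo, hi = 1e-8, 1.0
        for _ in range(60):
            if f(hi) > 0:
                break
            hi *= 2.0
        else:
            raise RuntimeError(
                "PC mixing prior: could not bracket the rate; "
                f"CDF(U) at rate {hi:g} is {self.cdf_given_rate(self.U_phi, hi):.4f} "
                f"< alpha = {self.alpha_phi:.4f}"
            )
        if f(lo) > 0:
            raise RuntimeError(
                "PC mixing prior: alpha below the rate->0 limit "
                f"{self._d(self.U_phi) / self.d_max:.4f}; no positive rate satisfies "
                "the tail condition"
            )
        return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))

    # -- density --
    def logpdf(self, phi: float) -> float:
        if not (0.0 < phi < 1.0):
            return -np.inf
        phi = min(phi, self._PHI_MAX)
        return (
            math.log(self.rate)
            - self.rate * self._d(phi)
            + math.log(self._d_d1(phi))
            - self._log1mexp(self.rate * self.d_max)
        )

    def dlogpdf_dphi(self, phi: float) -> float:
        phi = min(max(phi, 1e-12), self._PHI_MAX)
        d = self._d(phi)
        d1 = self._d_d1(phi)
        if d < 1e-8:
            d2 = 0.0  # d'' -> 0 as phi -> 0
        else:
            d2 = self._kld_d2(phi) / d - self._kld_d1(phi) ** 2 / d**3
        return -self.rate * d1 + d2 / d1

    def cdf(self, phi: float) -> float:
        return self.cdf_given_rate(phi, self.rate)


class UniformMixingPrior:
    """Flat prior on phi, used when the graph has no structured field at all."""

    rate = None

    def logpdf(self, phi: float) -> float:
        return 0.0 if 0.0 < phi < 1.0 else -np.inf

    def dlogpdf_dphi(self, phi: float) -> float:
        return 0.0

    def cdf(self, phi: float) -> float:
        return min(max(phi, 0.0), 1.0)


# ---------------------------------------------------------------------------
# Model spec and joint density

@dataclass
class BYM2Spec:
    """Complete BYM2 model definition for a set of areas."""

    observed: np.ndarray
    expected: np.ndarray
    graph: AdjacencyGraph
    structure: ScaledStructure
    hyperpriors: HyperPriors
    intercept_prior_sd: float = 5.0
    phi_prior: PCMixingPrior = field(init=False)

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        self.expected = np.asarray(self.expected, dtype=float)
        n = self.graph.n
        if self.observed.shape != (n,) or self.expected.shape != (n,):
            raise ValueError("observed/expected length must match the graph")
        if (self.expected <= 0).any():
            raise ValueError(
                "expected counts must be positive; drop zero-E areas before "
                "building the model spec"
            )
        if (self.observed < 0).any():
            raise ValueError("negative observed counts")
        if self.structure.components:
            self.phi_prior = PCMixingPrior(
                self.structure, self.hyperpriors.U_phi, self.hyperpriors.alpha_phi
            )
        else:
            # no structured field anywhere (all areas are islands): phi only
            # rescales the unstructured term, so a flat prior is used
            self.phi_prior = UniformMixingPrior()

    @property
    def n(self) -> int:
        return self.graph.n


def make_spec(
    observed: np.ndarray,
    expected: np.ndarray,
    graph: AdjacencyGraph,
    hyperpriors: HyperPriors | None = None,
    intercept_prior_sd: float = 5.0,
) -> BYM2Spec:
    """Convenience constructor: builds and scales the ICAR structure."""
    return BYM2Spec(
        observed=observed,
        expected=expected,
        graph=graph,
        structure=scaled_structure(graph),
        hyperpriors=hyperpriors or HyperPriors(),
        intercept_prior_sd=intercept_prior_sd,
    )


@dataclass
class LatentState:
    """One point in the latent space: intercept, hyperparameters, effects."""

    mu: float
    phi: float
    sigma: float
    v: np.ndarray
    u_star: np.ndarray

    def combined_effect(self) -> np.ndarray:
        return self.sigma * (
            math.sqrt(1.0 - self.phi) * self.v + math.sqrt(self.phi) * self.u_star
        )


def poisson_loglik(state: LatentState, spec: BYM2Spec) -> float:
    """Poisson log-likelihood with offsets, including all constants."""
    eta = state.mu + state.combined_effect()
    lam_log = np.log(spec.expected) + eta
    return float(
        np.sum(spec.observed * lam_log - np.exp(lam_log) - gammaln(spec.observed + 1.0))
    )


def _u_star_logpdf(u_star: np.ndarray, spec: BYM2Spec, tol: float = 1e-6) -> float:
    """Constrained scaled-ICAR log-density of u* (islands must be 0)."""
    st = spec.structure
    if len(st.islands) and np.abs(u_star[st.islands]).max() > tol:
        raise ValueError("structured effect must be 0 on islands")
    total = 0.0
    for idx, lam, kap in zip(st.components, st.eigvals, st.kappa):
        u = u_star[idx]
        if abs(u.sum()) > tol * max(1.0, np.abs(u).max()) * len(u):
            raise ValueError("structured effect violates the sum-to-zero constraint")
        pos = lam > _EIG_TOL * max(1.0, lam[-1])
        m = len(idx)
        quad = kap * float(u @ (st.Q[np.ix_(idx, idx)] @ u))
        logdet = float(np.sum(np.log(kap * lam[pos])))
        total += 0.5 * logdet - 0.5 * (m - 1) * math.log(2 * math.pi) - 0.5 * quad
    return total


def log_joint(state: LatentState, spec: BYM2Spec) -> float:
    """Joint log-density: likelihood + effect priors + hyperpriors + intercept.

    Raises ``ValueError`` naming the offending term on a non-finite result.
    """
    hp = spec.hyperpriors
    terms = {
        "poisson_loglik": poisson_loglik(state, spec),
        "v_prior": float(
            -0.5 * state.v @ state.v - 0.5 * len(state.v) * math.log(2 * math.pi)
        ),
        "u_star_prior": _u_star_logpdf(state.u_star, spec),
        "sigma_prior": pc_prior_sigma_logpdf(state.sigma, hp.U_sigma, hp.alpha_sigma),
        "phi_prior": spec.phi_prior.logpdf(state.phi),
        "intercept_prior": float(
            -0.5 * (state.mu / spec.intercept_prior_sd) ** 2
            - math.log(spec.intercept_prior_sd)
            - 0.5 * math.log(2 * math.pi)
        ),
    }
    for name, val in terms.items():
        if not np.isfinite(val):
            raise ValueError(f"non-finite log-density term: {name} = {val}")
    return float(sum(terms.values()))
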