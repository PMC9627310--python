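"""Posterior sampling for the BYM2 model.

The model is sampled on an unconstrained parameterization
theta = (mu, log sigma, logit phi, v, z) with a fully non-centered latent
field. The structured component is parameterized spectrally: z is standard
normal in the positive-eigenvalue eigenbasis of each component's ICAR
precision, and u* = V diag(1/sqrt(kappa * lambda)) z, which reproduces the
sum-to-zero-constrained scaled ICAR distribution exactly — the constraint
and the island zeros hold by construction, and the prior on every sampled
coordinate is unit normal, which keeps the posterior well conditioned for
a diagonal mass matrix. The combined effect is
b = sigma * (sqrt(1-phi) v + sqrt(phi) u*).

Sampling uses the No-U-Turn Sampler (multinomial variant, Stan-style) with
dual-averaging step-size adaptation and a diagonal mass matrix estimated
during warmup. Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .model import BYM2Spec, pc_prior_sigma_rate

__all__ = [
    "FitConfig",
    "PosteriorSamples",
    "BYM2Posterior",
    "fit_bym2",
    "convergence_diagnostics",
    "nuts_sample",
]

_DIVERGENCE_ENERGY = 1000.0


@dataclass(frozen=True)
class FitConfig:
    chains: int = 4
    warmup: int = 1000
    samples: int = 1000
    seed: int = 0
    target_accept: float = 0.9
    max_treedepth: int = 10


@dataclass
class PosteriorSamples:
    """Posterior draws indexed (chain, draw[, area]) with sampler metadata."""

    mu: np.ndarray
    phi: np.ndarray
    sigma: np.ndarray
    v: np.ndarray
    u_star: np.ndarray
    divergences: np.ndarray            # (chain, draw) bool
    step_size: np.ndarray              # per chain
    config: FitConfig
    warnings: list[str] = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return self.mu.shape[0]

    @property
    def n_draws(self) -> int:
        return self.mu.shape[1]

    @property
    def n_areas(self) -> int:
        return self.v.shape[2]

    def combined_effect(self) -> np.ndarray:
        """(chain, draw, area) array of b = sigma(sqrt(1-phi) v + sqrt(phi) u*)."""
        s = self.sigma[..., None]
        return s * (
            np.sqrt(1.0 - self.phi)[..., None] * self.v
            + np.sqrt(self.phi)[..., None] * self.u_star
        )

    def rr(self) -> np.ndarray:
        """(chain, draw, area) relative risks exp(mu + b)."""
        return np.exp(self.mu[..., None] + self.combined_effect())

    @staticmethod
    def flat(arr: np.ndarray) -> np.ndarray:
        """Merge the chain axis: (chain, draw, ...) -> (chain*draw, ...)."""
        return arr.reshape(-1, *arr.shape[2:])

    def divergence_rate(self) -> float:
        return float(self.divergences.mean())

    def to_inference_data(self):
        """ArviZ ``InferenceData`` view (chain x draw x variable) of the draws."""
        import arviz as az

        return az.from_dict(
            posterior={
                "mu": self.mu, "phi": self.phi, "sigma": self.sigma,
                "v": self.v, "u_star": self.u_star, "rr": self.rr(),
            },
            sample_stats={"diverging": self.divergences},
        )

    def save(self, path) -> None:
        """Persist draws (.npz, chain x draw x variable) + JSON metadata sidecar."""
        import json
        from dataclasses import asdict
        from pathlib import Path

        path = Path(path)
        np.savez_compressed(
            path,
            mu=self.mu, phi=self.phi, sigma=self.sigma, v=self.v,
            u_star=self.u_star, divergences=self.divergences,
            step_size=self.step_size,
        )
        sidecar = path.with_suffix(".json")
        with open(sidecar, "w") as fh:
            json.dump(
                {"config": asdict(self.config), "warnings": self.warnings,
                 "layout": "chain x draw x variable"},
                fh, indent=1,
            )

    @classmethod
    def load(cls, path) -> "PosteriorSamples":
        import json
        from pathlib import Path

        path = Path(path)
        with np.load(path.with_suffix(".npz")) as z:
            arrs = {k: z[k] for k in z.files}
        with open(path.with_suffix(".json")) as fh:
            meta = json.load(fh)
        return cls(config=FitConfig(**meta["config"]),
                   warnings=list(meta["warnings"]), **arrs)


class BYM2Posterior:
    """Log-posterior and gradient of the BYM2 model on unconstrained parameters.

    Parameter vector layout: [mu, log_sigma, logit_phi, v (n), z (m)] where m
    is the total count of positive ICAR eigenvalues (n minus islands minus
    one per non-singleton component). ``likelihood=False`` switches the data
    term off (prior-only sampling); ``likelihood_mask`` multiplies per-area
    likelihood contributions (0/1), used by exact leave-one-out refits.
    """

    def __init__(
        self,
        spec: BYM2Spec,
        likelihood: bool = True,
        likelihood_mask: np.ndarray | None = None,
    ):
        self.spec = spec
        st = spec.structure
        self.n = spec.n
        # spectral map A: u* = A z with z ~ N(0, I); A is (n, m) block-diagonal
        blocks = []
        for idx, lam, vec, kap in zip(st.components, st.eigvals, st.eigvecs, st.kappa):
            pos = lam > 1e-9 * max(1.0, lam[-1])
            W = vec[:, pos] / np.sqrt(kap * lam[pos])[None, :]
            blocks.append((idx, W))
        self.m = sum(W.shape[1] for _, W in blocks)
        self.dim = 3 + self.n + self.m
        self._A = np.zeros((self.n, self.m))
        col = 0
        for idx, W in blocks:
            self._A[idx, col : col + W.shape[1]] = W
            col += W.shape[1]
        self.likelihood = likelihood
        if likelihood_mask is None:
            self.mask = np.ones(self.n)
        else:
            self.mask = np.asarray(likelihood_mask, dtype=float)
        self._lam_sigma = pc_prior_sigma_rate(
            spec.hyperpriors.U_sigma, spec.hyperpriors.alpha_sigma
        )

    # -- packing helpers --
    def unpack(self, theta: np.ndarray):
        mu = theta[0]
        sigma = math.exp(theta[1])
        phi = float(expit(theta[2]))
        v = theta[3 : 3 + self.n]
        z = theta[3 + self.n :]
        return mu, sigma, phi, v, z

    def u_star_full(self, z: np.ndarray) -> np.ndarray:
        """Scaled, constrained structured field u* from spectral coordinates."""
        return self._A @ z

    def logp_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        mu, sigma, phi, v, z = self.unpack(theta)
        phi = min(max(phi, 1e-12), 1.0 - 1e-12)
        sp, spc = self.spec, self.spec.phi_prior
        sq1mphi = math.sqrt(1.0 - phi)
        sqphi = math.sqrt(phi)
        u_star = self._A @ z
        b = sigma * (sq1mphi * v + sqphi * u_star)
        grad = np.zeros_like(theta)
        logp = 0.0

        if self.likelihood:
            eta = mu + b
            lam = sp.expected * np.exp(np.clip(eta, -500, 500))
            logp += float(np.sum(self.mask * (sp.observed * eta - lam)))
            r = self.mask * (sp.observed - lam)  # d loglik / d eta
        else:
            r = np.zeros(self.n)
        # mu
        grad[0] += r.sum() - mu / sp.intercept_prior_sd**2
        logp += -0.5 * (mu / sp.intercept_prior_sd) ** 2
        # v (non-centered standard normal)
        grad[3 : 3 + self.n] += sigma * sq1mphi * r - v
        logp += -0.5 * float(v @ v)
        # z: standard normal in the ICAR eigenbasis
        grad[3 + self.n :] += sigma * sqphi * (r @ self._A) - z
        logp += -0.5 * float(z @ z)
        # log sigma: db/dlog(sigma) = b; exponential PC prior + Jacobian
        grad[1] += float(r @ b) - self._lam_sigma * sigma + 1.0
        logp += -self._lam_sigma * sigma + theta[1]
        # logit phi
        db_dphi = sigma * (u_star / (2.0 * sqphi) - v / (2.0 * sq1mphi))
        dll_dphi = float(r @ db_dphi)
        dprior_dphi = spc.dlogpdf_dphi(phi)
        grad[2] += (dll_dphi + dprior_dphi) * phi * (1.0 - phi) + (1.0 - 2.0 * phi)
        logp += spc.logpdf(phi) + math.log(phi) + math.log1p(-phi)
        return logp, grad


# ---------------------------------------------------------------------------
# NUTS

def _leapfrog(logp_grad, theta, p, grad, eps, inv_mass):
    p = p + 0.5 * eps * grad
    theta = theta + eps * inv_mass * p
    logp, grad = logp_grad(theta)
    p = p + 0.5 * eps * grad
    return theta, p, logp, grad


def _kinetic(p, inv_mass):
    return 0.5 * float(p @ (inv_mass * p))


def _uturn(rho, p_minus, p_plus, inv_mass) -> bool:
    return (rho @ (inv_mass * p_minus)) <= 0 or (rho @ (inv_mass * p_plus)) <= 0


class _Tree:
    """State of one NUTS subtree: both ends, a multinomial proposal, weights."""

    __slots__ = ("tm", "pm", "gm", "tp", "pp", "gp", "prop", "prop_logp",
                 "prop_grad", "log_w", "rho", "stop", "a_sum", "a_n")

    def __init__(self, tm, pm, gm, tp, pp, gp, prop, prop_logp, prop_grad,
                 log_w, rho, stop, a_sum, a_n):
        self.tm, self.pm, self.gm = tm, pm, gm
        self.tp, self.pp, self.gp = tp, pp, gp
        self.prop, self.prop_logp, self.prop_grad = prop, prop_logp, prop_grad
        self.log_w, self.rho, self.stop = log_w, rho, stop
        self.a_sum, self.a_n = a_sum, a_n


def _build_tree(logp_grad, theta, p, grad, direction, depth, eps, inv_mass,
                joint0, rng) -> _Tree:
    if depth == 0:
        t1, p1, logp1, g1 = _leapfrog(logp_grad, theta, p, grad,
                                      direction * eps, inv_mass)
        joint1 = logp1 - _kinetic(p1, inv_mass) if np.isfinite(logp1) else -np.inf
        diverged = (not np.isfinite(joint1)) or (joint0 - joint1 > _DIVERGENCE_ENERGY)
        log_w = -np.inf if diverged else joint1 - joint0
        a = 0.0 if diverged else math.exp(min(0.0, joint1 - joint0))
        return _Tree(t1, p1, g1, t1, p1, g1, t1, logp1, g1, log_w, p1.copy(),
                     diverged, a, 1)
    first = _build_tree(logp_grad, theta, p, grad, direction, depth - 1, eps,
                        inv_mass, joint0, rng)
    if first.stop:
        return first
    if direction > 0:
        second = _build_tree(logp_grad, first.tp, first.pp, first.gp,
                             direction, depth - 1, eps, inv_mass, joint0, rng)
        first.tp, first.pp, first.gp = second.tp, second.pp, second.gp
    else:
        second = _build_tree(logp_grad, first.tm, first.pm, first.gm,
                             direction, depth - 1, eps, inv_mass, joint0, rng)
        first.tm, first.pm, first.gm = second.tm, second.pm, second.gm
    log_w = np.logaddexp(first.log_w, second.log_w)
    if np.isfinite(second.log_w) and rng.random() < math.exp(second.log_w - log_w):
        first.prop = second.prop
        first.prop_logp, first.prop_grad = second.prop_logp, second.prop_grad
    first.rho = first.rho + second.rho
    first.log_w = log_w
    first.a_sum += second.a_sum
    first.a_n += second.a_n
    first.stop = second.stop or _uturn(first.rho, first.pm, first.pp, inv_mass)
    return first


def nuts_sample(
    logp_grad,
    theta0: np.ndarray,
    n_warmup: int,
    n_samples: int,
    rng: np.random.Generator,
    target_accept: float = 0.9,
    max_treedepth: int = 10,
):
    """Multinomial No-U-Turn sampler with dual averaging and diagonal mass.

    ``logp_grad(theta) -> (logp, grad)``. Returns ``(draws, divergent,
    step_size)``. The diagonal mass matrix is estimated from the middle half
    of warmup (Welford), after which the step size is re-adapted.
    """
    theta = np.asarray(theta0, dtype=float).copy()
    dim = len(theta)
    inv_mass = np.ones(dim)
    logp, grad = logp_grad(theta)

    eps = _find_reasonable_eps(logp_grad, theta, grad, logp, inv_mass, rng)
    mu_da = math.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa_da = 0.05, 10.0, 0.75
    da_iter = 0

    mass_lo, mass_hi = int(0.25 * n_warmup), int(0.80 * n_warmup)
    w_mean = np.zeros(dim)
    w_m2 = np.zeros(dim)
    w_n = 0

    draws = np.empty((n_samples, dim))
    divergent = np.zeros(n_samples, dtype=bool)

    for it in range(n_warmup + n_samples):
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        joint0 = logp - _kinetic(p0, inv_mass)
        tree = _Tree(theta, p0, grad, theta, p0, grad, theta, logp, grad,
                     0.0, p0.copy(), False, 0.0, 0)
        diverged = False
        for depth in range(max_treedepth):
            direction = 1 if rng.random() < 0.5 else -1
            if direction > 0:
                sub = _build_tree(logp_grad, tree.tp, tree.pp, tree.gp, 1,
                                  depth, eps, inv_mass, joint0, rng)
                tree.tp, tree.pp, tree.gp = sub.tp, sub.pp, sub.gp
            else:
                sub = _build_tree(logp_grad, tree.tm, tree.pm, tree.gm, -1,
                                  depth, eps, inv_mass, joint0, rng)
                tree.tm, tree.pm, tree.gm = sub.tm, sub.pm, sub.gm
            tree.a_sum += sub.a_sum
            tree.a_n += sub.a_n
            if sub.stop:
                diverged = diverged or (sub.a_n == 0 or not np.isfinite(sub.log_w))
                break
            # progressive biased sampling between the old tree and new subtree
            if rng.random() < math.exp(min(0.0, sub.log_w - tree.log_w)):
                tree.prop = sub.prop
                tree.prop_logp, tree.prop_grad = sub.prop_logp, sub.prop_grad
            tree.log_w = np.logaddexp(tree.log_w, sub.log_w)
            tree.rho = tree.rho + sub.rho
            if _uturn(tree.rho, tree.pm, tree.pp, inv_mass):
                break
        theta, logp, grad = tree.prop, tree.prop_logp, tree.prop_grad
        accept_stat = tree.a_sum / max(tree.a_n, 1)

        if it < n_warmup:
            da_iter += 1
            h_bar = (1 - 1 / (da_iter + t0)) * h_bar + (
                target_accept - accept_stat
            ) / (da_iter + t0)
            log_eps = mu_da - math.sqrt(da_iter) / gamma * h_bar
            w = da_iter ** (-kappa_da)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = math.exp(log_eps)
            if mass_lo <= it < mass_hi:
                w_n += 1
                delta = theta - w_mean
                w_mean += delta / w_n
                w_m2 += delta * (theta - w_mean)
            if it == mass_hi - 1 and w_n > 10:
                var = w_m2 / (w_n - 1)
                var = (w_n / (w_n + 5.0)) * var + 1e-3 * (5.0 / (w_n + 5.0))
                inv_mass = var
                eps = _find_reasonable_eps(logp_grad, theta, grad, logp,
                                           inv_mass, rng)
                mu_da = math.log(10.0 * eps)
                log_eps_bar, h_bar, da_iter = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = math.exp(log_eps_bar)
        else:
            draws[it - n_warmup] = theta
            divergent[it - n_warmup] = diverged
    return draws, divergent, eps


def _find_reasonable_eps(logp_grad, theta, grad, logp, inv_mass, rng) -> float:
    eps = 0.1
    p = rng.standard_normal(len(theta)) / np.sqrt(inv_mass)
    joint0 = logp - _kinetic(p, inv_mass)

    def delta(e: float) -> float:
        _, p1, logp1, _ = _leapfrog(logp_grad, theta, p, grad, e, inv_mass)
        j1 = logp1 - _kinetic(p1, inv_mass) if np.isfinite(logp1) else -np.inf
        return j1 - joint0 if np.isfinite(j1) else -1000.0

    direction = 1.0 if delta(eps) > math.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        if direction * (delta(eps) - math.log(0.5)) < 0:
            break
    return float(min(max(eps, 1e-8), 10.0))


# ---------------------------------------------------------------------------
# Public fitting API

def fit_bym2(
    spec: BYM2Spec,
    config: FitConfig | None = None,
    likelihood: bool = True,
    likelihood_mask: np.ndarray | None = None,
) -> PosteriorSamples:
    """Sample the BYM2 posterior (or the prior, with ``likelihood=False``).

    Runs ``config.chains`` independent NUTS chains (deterministic given
    ``config.seed``) and attaches warnings when the divergence rate exceeds
    1% or any scalar R-hat exceeds 1.01.
    """
    config = config or FitConfig()
    if config.chains < 2:
        raise ValueError("at least 2 chains required")
    post = BYM2Posterior(spec, likelihood=likelihood, likelihood_mask=likelihood_mask)
    n = post.n
    ss = np.random.SeedSequence(config.seed)
    chain_seeds = ss.spawn(config.chains)
    mu_all = np.empty((config.chains, config.samples))
    phi_all = np.empty_like(mu_all)
    sigma_all = np.empty_like(mu_all)
    v_all = np.empty((config.chains, config.samples, n))
    us_all = np.empty((config.chains, config.samples, n))
    div_all = np.zeros((config.chains, config.samples), dtype=bool)
    eps_all = np.empty(config.chains)

    crude = (
        math.log(max(spec.observed.sum(), 1.0) / spec.expected.sum())
        if likelihood
        else 0.0
    )
    for c in range(config.chains):
        rng = np.random.default_rng(chain_seeds[c])
        theta0 = np.zeros(post.dim)
        theta0[0] = crude + 0.1 * rng.standard_normal()
        theta0[1] = math.log(0.3) + 0.1 * rng.standard_normal()
        theta0[2] = 0.2 * rng.standard_normal()
        theta0[3:] = 0.1 * rng.standard_normal(post.dim - 3)
        draws, divergent, eps = nuts_sample(
            post.logp_and_grad,
            theta0,
            config.warmup,
            config.samples,
            rng,
            target_accept=config.target_accept,
            max_treedepth=config.max_treedepth,
        )
        mu_all[c] = draws[:, 0]
        sigma_all[c] = np.exp(draws[:, 1])
        phi_all[c] = expit(draws[:, 2])
        v_all[c] = draws[:, 3 : 3 + n]
        us_all[c] = draws[:, 3 + n :] @ post._A.T
        div_all[c] = divergent
        eps_all[c] = eps

    samples = PosteriorSamples(
        mu=mu_all, phi=phi_all, sigma=sigma_all, v=v_all, u_star=us_all,
        divergences=div_all, step_size=eps_all, config=config,
    )
    dr = samples.divergence_rate()
    if dr > 0.01:
        samples.warnings.append(f"divergence rate {dr:.1%} exceeds 1%")
    diag = convergence_diagnostics(samples, include_areas=False)
    worst = diag["r_hat"].max()
    if worst > 1.01:
        samples.warnings.append(
            f"R-hat {worst:.3f} on {diag['r_hat'].idxmax()} exceeds 1.01"
        )
    return samples


def convergence_diagnostics(
    samples: PosteriorSamples, include_areas: bool = True
) -> pd.DataFrame:
    """Rank-normalized split R-hat and bulk/tail ESS per scalar quantity.

    Covers mu, phi, sigma and (optionally) each area's relative risk.
    """
    import arviz as az

    qty: dict[str, np.ndarray] = {
        "mu": samples.mu,
        "phi": samples.phi,
        "sigma": samples.sigma,
    }
    if include_areas:
        rr = samples.rr()
        for i in range(samples.n_areas):
            qty[f"rr[{i}]"] = rr[:, :, i]
    rows = []
    for name, arr in qty.items():
        rows.append(
            {
                "param": name,
                "r_hat": float(az.rhat(arr)),
                "ess_bulk": float(az.ess(arr, method="bulk")),
                "ess_tail": float(az.ess(arr, method="tail")),
            }
        )
    return pd.DataFrame(rows).set_index("param")
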