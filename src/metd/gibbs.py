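"""Blocked conjugate Gibbs sampling for Gaussian linear models with optional
nested random intercepts.

The sampler targets

    y = X beta + sum_k Z_k u_k + e,    e ~ N(0, sigma^2 I)

with independent priors per fixed coefficient — Normal(m_j, s_j^2) or
Student-t(nu_j, m_j, s_j) written as a scale mixture of normals
(beta_j | lam_j ~ N(m_j, s_j^2 lam_j), lam_j ~ InvGamma(nu/2, nu/2)) — and
half-t(nu, A) priors on the residual scale and on each random-intercept
standard deviation via the Huang–Wand inverse-gamma augmentation
(tau^2 | a ~ InvGamma(nu/2, nu/a), a ~ InvGamma(1/2, 1/A^2)).

All location parameters (beta and every u_k jointly) are drawn in one
multivariate-normal block per iteration, so the posterior correlation
between an intercept and the means of its random-effect blocks — severe in
small nested designs — does not slow mixing.  Variances are standard
inverse-gamma draws.  The dense joint update is cubic in (p + total levels),
which is the right trade-off for the small-sample designs this package
targets.  Chain c of a run uses seed ``base_seed + c``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CoefPrior", "RandomBlock", "sample_linear_model"]


@dataclass(frozen=True)
class CoefPrior:
    """Prior for one fixed coefficient."""

    family: str = "normal"  # "normal" | "student_t"
    location: float = 0.0
    scale: float = 10.0
    df: float = 3.0

    def __post_init__(self) -> None:
        if self.family not in ("normal", "student_t"):
            raise ValueError(f"unknown prior family {self.family!r}")
        if self.scale <= 0:
            raise ValueError("prior scale must be > 0")


@dataclass(frozen=True)
class RandomBlock:
    """One random-intercept block: integer level codes per observation."""

    name: str
    codes: np.ndarray  # shape (n,), values 0..n_levels-1
    scale: float = 10.0  # half-t scale on the block SD
    df: float = 3.0

    @property
    def n_levels(self) -> int:
        return int(np.max(self.codes)) + 1


def _inv_gamma(rng, shape: float, rate: float) -> float:
    return rate / rng.gamma(shape, 1.0)


def sample_linear_model(y, X, coef_priors, random_blocks=(), *,
                        sigma_scale: float | None = None, sigma_df: float = 3.0,
                        chains: int = 4, warmup: int = 1000, draws: int = 1000,
                        seed: int = 0, keep_random_effects: bool = False):
    """Run Gibbs chains; return draws keyed by parameter name.

    Returns a dict mapping parameter name to an array of shape
    (chains, draws): ``beta[j]`` for fixed coefficients, ``sigma`` for the
    residual SD and ``sd_<block>`` for random-intercept SDs.  With
    ``keep_random_effects`` the per-level intercepts ``u_<block>`` are kept
    as (chains, draws, n_levels).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if len(coef_priors) != p:
        raise ValueError("one prior per column of X is required")
    if sigma_scale is None:
        sigma_scale = 2.5 * max(np.std(y, ddof=1), 1e-3)

    blocks = list(random_blocks)
    # joint design: fixed effects then one-hot indicators per block
    parts = [X]
    slices: list[slice] = []
    start = p
    for b in blocks:
        q = b.n_levels
        Z = np.zeros((n, q))
        Z[np.arange(n), b.codes] = 1.0
        parts.append(Z)
        slices.append(slice(start, start + q))
        start += q
    W = np.hstack(parts)
    m = W.shape[1]
    WtW = W.T @ W
    Wty = W.T @ y

    prior_loc = np.array([pr.location for pr in coef_priors])
    prior_scale = np.array([pr.scale for pr in coef_priors])
    prior_df = np.array([pr.df for pr in coef_priors])
    is_t = np.array([pr.family == "student_t" for pr in coef_priors])

    full_loc = np.zeros(m)
    full_loc[:p] = prior_loc

    out = {f"beta[{j}]": np.empty((chains, draws)) for j in range(p)}
    out["sigma"] = np.empty((chains, draws))
    for b in blocks:
        out[f"sd_{b.name}"] = np.empty((chains, draws))
        if keep_random_effects:
            out[f"u_{b.name}"] = np.empty((chains, draws, b.n_levels))

    for c in range(chains):
        rng = np.random.default_rng(seed + c)
        lam = np.ones(p)
        sigma2 = max(float(np.var(y, ddof=1)) if n > 1 else 1.0, 1e-6)
        sigma2 *= float(np.exp(rng.normal(0, 0.2)))
        a_sigma = _inv_gamma(rng, 0.5, 1.0 / sigma_scale**2)
        tau2 = [float(b.scale**2) * float(np.exp(rng.normal(0, 0.2)))
                for b in blocks]
        a_tau = [_inv_gamma(rng, 0.5, 1.0 / b.scale**2) for b in blocks]

        for it in range(warmup + draws):
            # joint (beta, u) | variances: one multivariate-normal block
            prec_diag = np.empty(m)
            prec_diag[:p] = 1.0 / (prior_scale**2 * lam)
            for k, sl in enumerate(slices):
                prec_diag[sl] = 1.0 / tau2[k]
            P = WtW / sigma2 + np.diag(prec_diag)
            rhs = Wty / sigma2 + full_loc * prec_diag
            try:
                L = np.linalg.cholesky(P)
            except np.linalg.LinAlgError:
                P = P + np.eye(m) * 1e-8 * np.trace(P) / m
                L = np.linalg.cholesky(P)
            mean = np.linalg.solve(P, rhs)
            theta = mean + np.linalg.solve(L.T, rng.standard_normal(m))
            beta = theta[:p]

            # latent t-prior scales for fixed effects
            if is_t.any():
                z = (beta - prior_loc) / prior_scale
                for j in np.flatnonzero(is_t):
                    lam[j] = _inv_gamma(rng, (prior_df[j] + 1) / 2,
                                        (prior_df[j] + z[j]**2) / 2)

            # variance components (half-t via inverse-gamma augmentation).
            # The (variance, auxiliary) pair is iterated a few times per
            # scan: it is a cheap inner chain and the extra sweeps remove
            # the autocorrelation the augmentation introduces when the
            # likelihood is weak (few levels, or near-zero residuals).
            for k, b in enumerate(blocks):
                u_k = theta[slices[k]]
                ssq = 0.5 * np.sum(u_k**2)
                for _ in range(4):
                    tau2[k] = max(_inv_gamma(rng, (b.df + b.n_levels) / 2,
                                             b.df / a_tau[k] + ssq),
                                  (1e-4 * b.scale)**2)
                    a_tau[k] = _inv_gamma(rng, (b.df + 1) / 2,
                                          b.df / tau2[k] + 1.0 / b.scale**2)

            # residual variance with half-t(nu, sigma_scale) prior
            rss = float(np.sum((y - W @ theta)**2))
            # floored below: on exactly-degenerate data (zero residuals) the
            # scale posterior is improper at zero; the floor pins it there
            for _ in range(4):
                sigma2 = max(_inv_gamma(rng, (sigma_df + n) / 2,
                                        sigma_df / a_sigma + 0.5 * rss),
                             (1e-4 * sigma_scale)**2)
                a_sigma = _inv_gamma(rng, (sigma_df + 1) / 2,
                                     sigma_df / sigma2 + 1.0 / sigma_scale**2)

            if it >= warmup:
                d = it - warmup
                for j in range(p):
                    out[f"beta[{j}]"][c, d] = beta[j]
                out["sigma"][c, d] = np.sqrt(sigma2)
                for k, b in enumerate(blocks):
                    out[f"sd_{b.name}"][c, d] = np.sqrt(tau2[k])
                    if keep_random_effects:
                        out[f"u_{b.name}"][c, d] = theta[slices[k]]
    return out
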