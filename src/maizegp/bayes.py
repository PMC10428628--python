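"""Bayesian linear mixed models for genomic prediction, via Gibbs sampling.

Three model families are implemented:

* :func:`fit_mcmc_mixed` — a uni-/multi-trait animal-model Gibbs sampler for
  one environment: ``y_i = X_i b_i + Z_i u_i + e_i`` with
  ``u ~ N(0, G0 (x) A)`` and ``e ~ N(0, R0 (x) I)``; G0 and R0 receive
  inverse-Wishart updates.  With the (co)variances held fixed its posterior
  mean solves the standard mixed-model equations, for which
  :func:`blup_oracle` provides the exact direct solution.

* :func:`fit_bgge` — a genomic G x E model over records stacked across
  environments.  Each random effect has covariance ``sigma2_k K_k`` for a
  kernel ``K_k``; sampling is done in the kernel eigenbasis where the
  likelihood diagonalizes (transformed data d = U'y, effect coordinates
  b_i with prior variance sigma2 * s_i), with scaled inverse-chi-squared
  conjugate updates for the variances.  Kernels come from
  :func:`build_ge_kernels`: one main genotype kernel plus one
  environment-specific block kernel per environment.

* :func:`fit_bmtme` — the matrix-variate multi-trait multi-environment
  model ``Y = X B + Z1 b1 + Z2 b2 + E`` with ``b1 ~ MN(0, G, St)``,
  ``b2 ~ MN(0, Se (x) G, St)`` and residual rows iid ``N(0, Re)``; St, Se
  and Re receive inverse-Wishart updates.

:func:`adjust_phenotypes` fits the phenotypic pre-adjustment model
(replicate and block-within-replicate fixed, line random) per environment
and trait, returning one adjusted value per line.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import invwishart

from .panel import KinshipMatrix, validate_phenotypes

logger = logging.getLogger(__name__)


class DegenerateDataError(ValueError):
    """The response carries no usable variation."""


@dataclass
class MCMCSettings:
    """Chain length controls.  Defaults follow the full-scale analysis
    (100,000 iterations, 10,000 burn-in, thinning 5); :meth:`short` returns
    the scaled-down chain used by the test suite."""

    n_iterations: int = 100_000
    burn_in: int = 10_000
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_draws(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin

    @classmethod
    def short(cls, seed: int = 0) -> "MCMCSettings":
        return cls(n_iterations=5_000, burn_in=1_000, thin=2, seed=seed)

    @classmethod
    def tiny(cls, seed: int = 0) -> "MCMCSettings":
        return cls(n_iterations=1_500, burn_in=400, thin=2, seed=seed)


@dataclass
class BGGEPriors:
    """Scaled inverse-chi-squared hyperparameters for the G x E model."""

    nu_u: float = 5.0
    nu_e: float = 5.0
    sc_u: float | None = None  # default: half the data variance split across kernels
    sc_e: float | None = None  # default: half the data variance


@dataclass
class PosteriorSamples:
    """Thinned post-burn-in draws from one of the samplers."""

    model: str
    draws: dict
    line_ids: list[str]
    trait_names: list[str]
    meta: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    def mean(self, name: str) -> np.ndarray:
        return self.draws[name].mean(axis=0)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _prepare_kinship(values: np.ndarray, jitter: float = 1e-8):
    """Symmetrize, add one shot of jitter scaled to the diagonal, eigh."""
    A = (values + values.T) / 2.0
    A = A + jitter * np.mean(np.diag(A)) * np.eye(A.shape[0])
    d, V = np.linalg.eigh(A)
    if d.min() < -1e-6 * max(1.0, d.max()):
        raise ValueError("kinship not positive definite after jitter")
    d = np.clip(d, 1e-10, None)
    return d, V


def split_rhat(chain: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one scalar chain."""
    x = np.asarray(chain, dtype=float)
    m = x.size // 2
    if m < 2:
        return np.nan
    halves = np.stack([x[:m], x[m : 2 * m]])
    w = halves.var(axis=1, ddof=1).mean()
    b = m * halves.mean(axis=1).var(ddof=1)
    if w <= 0:
        return np.nan
    return float(np.sqrt((m - 1) / m + b / (w * m)))


def _check_convergence(trace: np.ndarray, label: str) -> None:
    r = split_rhat(trace)
    if np.isfinite(r) and r > 1.1:
        logger.warning("split-Rhat %.3f > 1.1 for %s", r, label)


def _records_to_wide(records: pd.DataFrame, traits, environment=None) -> pd.DataFrame:
    rec = validate_phenotypes(records)
    envs = rec["environment"].unique()
    if environment is not None:
        rec = rec[rec["environment"] == environment]
        if rec.empty:
            raise ValueError(f"no records for environment {environment!r}")
    elif len(envs) > 1:
        raise ValueError("records span several environments; pass environment=")
    rec = rec[rec["trait"].isin(traits)]
    missing = set(traits) - set(rec["trait"])
    if missing:
        raise ValueError(f"unknown trait(s) {sorted(missing)}")
    if rec.duplicated(subset=["line", "trait"]).any():
        raise ValueError("multiple records per line/trait; adjust phenotypes first")
    wide = rec.pivot(index="line", columns="trait", values="value")[list(traits)]
    return wide.dropna(axis=0)


# ---------------------------------------------------------------------------
# multi-trait MCMC mixed model
# ---------------------------------------------------------------------------

def fit_mcmc_mixed(
    records: pd.DataFrame,
    kinship: KinshipMatrix,
    traits: list[str],
    settings: MCMCSettings | None = None,
    priors: dict | None = None,
    environment: str | None = None,
    fix_variance: tuple[np.ndarray, np.ndarray] | None = None,
) -> PosteriorSamples:
    """Gibbs sampler for the (multi-)trait animal model in one environment.

    ``fix_variance=(G0, R0)`` freezes the (co)variance components, in which
    case the posterior mean of the random effects equals the direct
    mixed-model-equation solution up to Monte-Carlo error.
    """
    settings = settings or MCMCSettings.short()
    wide = _records_to_wide(records, traits, environment)
    lines = list(wide.index)
    Y = wide.to_numpy(dtype=float)
    n, t = Y.shape
    if n < 3:
        raise ValueError("need at least 3 lines")
    vy = Y.var(axis=0, ddof=1)
    if np.any(vy < 1e-12):
        raise DegenerateDataError("a trait has (near-)zero variance")

    d, V = _prepare_kinship(kinship.align(lines))
    rng = np.random.default_rng(settings.seed)

    priors = priors or {}
    nu0 = priors.get("nu", t + 1)
    S0 = priors.get("scale", 0.1 * np.diag(vy))

    beta = Y.mean(axis=0)
    Ut = np.zeros((n, t))  # random effects in the eigenbasis of A
    if fix_variance is not None:
        G0 = np.atleast_2d(np.asarray(fix_variance[0], dtype=float))
        R0 = np.atleast_2d(np.asarray(fix_variance[1], dtype=float))
    else:
        G0 = 0.5 * np.diag(vy)
        R0 = 0.5 * np.diag(vy)

    keep_beta, keep_u, keep_g, keep_r = [], [], [], []
    eye_t = np.eye(t)
    for it in range(1, settings.n_iterations + 1):
        U = V @ Ut
        # fixed effects (per-trait intercepts)
        resid = Y - U
        mean_b = resid.mean(axis=0)
        Lb = np.linalg.cholesky(R0 / n)
        beta = mean_b + Lb @ rng.standard_normal(t)
        # random effects, rotated so lines decouple
        G0inv = np.linalg.inv(G0)
        R0inv = np.linalg.inv(R0)
        Yt = V.T @ (Y - beta)
        P = G0inv[None, :, :] / d[:, None, None] + R0inv[None, :, :]
        rhs = Yt @ R0inv
        m = np.linalg.solve(P, rhs[:, :, None])[:, :, 0]
        L = np.linalg.cholesky(P)
        z = rng.standard_normal((n, t, 1))
        Ut = m + np.linalg.solve(np.transpose(L, (0, 2, 1)), z)[:, :, 0]
        if fix_variance is None:
            Sg = Ut.T @ (Ut / d[:, None])
            G0 = invwishart.rvs(df=nu0 + n, scale=S0 + Sg, random_state=rng)
            G0 = np.atleast_2d(G0)
            E = Y - beta - V @ Ut
            R0 = np.atleast_2d(
                invwishart.rvs(df=nu0 + n, scale=S0 + E.T @ E, random_state=rng)
            )
        if it > settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            keep_beta.append(beta.copy())
            keep_u.append(V @ Ut)
            keep_g.append(G0.copy())
            keep_r.append(R0.copy())
        if it % 1000 == 0:
            logger.debug("mcmc_mixed iteration %d/%d", it, settings.n_iterations)

    draws = {
        "beta": np.stack(keep_beta),
        "u": np.stack(keep_u),
        "G0": np.stack(keep_g),
        "R0": np.stack(keep_r),
    }
    _check_convergence(draws["G0"][:, 0, 0], "G0[0,0]")
    return PosteriorSamples(
        model="mcmc_mixed",
        draws=draws,
        line_ids=lines,
        trait_names=list(traits),
        meta={"kinship_mean_diag": float(np.mean(np.diag(kinship.align(lines))))},
    )


def heritability(samples: PosteriorSamples, trait: str) -> tuple[float, tuple[float, float]]:
    """Posterior mean and 95% interval of narrow-sense heritability.

    The per-line genetic variance is sigma2_u * A_ii; for fully inbred lines
    the VanRaden diagonal averages 1+F (about 2), so the kinship's mean
    diagonal (stored at fit time) scales the genetic component:
    h2 = c*sigma2_u / (c*sigma2_u + sigma2_e)."""
    k = samples.trait_names.index(trait)
    c = samples.meta.get("kinship_mean_diag", 1.0)
    g = c * samples.draws["G0"][:, k, k]
    h = g / (g + samples.draws["R0"][:, k, k])
    return float(h.mean()), (float(np.quantile(h, 0.025)), float(np.quantile(h, 0.975)))


def genetic_correlation(
    samples: PosteriorSamples, trait_x: str, trait_y: str
) -> tuple[float, tuple[float, float]]:
    """Posterior mean and central 95% interval of the genetic correlation,
    computed per draw as sigma_Gxy / sqrt(sigma2_Gx * sigma2_Gy)."""
    names = samples.trait_names
    for tr in (trait_x, trait_y):
        if tr not in names:
            raise ValueError(f"trait {tr!r} absent from samples")
    i, j = names.index(trait_x), names.index(trait_y)
    key = "G0" if "G0" in samples.draws else "Sigma_t"
    G = samples.draws[key]
    r = G[:, i, j] / np.sqrt(G[:, i, i] * G[:, j, j])
    return float(r.mean()), (float(np.quantile(r, 0.025)), float(np.quantile(r, 0.975)))


# ---------------------------------------------------------------------------
# exact mixed-model-equation solver (closed-form oracle)
# ---------------------------------------------------------------------------

def blup_oracle(
    Y: np.ndarray,
    kinship_values: np.ndarray,
    var_components: tuple[np.ndarray, np.ndarray],
    fixed_design: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the mixed-model equations exactly for known (co)variances.

    Y is lines x traits; ``var_components = (G0, R0)``.  Returns
    (beta_hat (p x t), u_hat (n x t)) for the model with ``u ~ N(0, G0 (x) A)``
    and ``e ~ N(0, R0 (x) I)`` under trait-major stacking.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.ndim == 2 and Y.shape[0] == 1:
        Y = Y.T
    n, t = Y.shape
    X = np.ones((n, 1)) if fixed_design is None else np.asarray(fixed_design, dtype=float)
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        corr = np.corrcoef(X.T)
        bad = [
            (i, j)
            for i in range(p)
            for j in range(i + 1, p)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise np.linalg.LinAlgError(f"fixed design rank-deficient; confounded columns {bad}")
    G0 = np.atleast_2d(np.asarray(var_components[0], dtype=float))
    R0 = np.atleast_2d(np.asarray(var_components[1], dtype=float))
    A = np.asarray(kinship_values, dtype=float)
    A = (A + A.T) / 2.0 + 1e-10 * np.eye(n)

    Rinv = np.kron(np.linalg.inv(R0), np.eye(n))
    Ginv = np.kron(np.linalg.inv(G0), np.linalg.inv(A))
    Xf = np.kron(np.eye(t), X)
    Zf = np.eye(n * t)
    y = Y.T.reshape(-1)  # trait-major
    top = np.hstack([Xf.T @ Rinv @ Xf, Xf.T @ Rinv @ Zf])
    bot = np.hstack([Zf.T @ Rinv @ Xf, Zf.T @ Rinv @ Zf + Ginv])
    C = np.vstack([top, bot])
    rhs = np.concatenate([Xf.T @ Rinv @ y, Zf.T @ Rinv @ y])
    sol = np.linalg.solve(C, rhs)
    beta = sol[: p * t].reshape(t, p).T
    u = sol[p * t :].reshape(t, n).T
    return beta, u


# ---------------------------------------------------------------------------
# phenotypic adjustment (replicate/block fixed, line random)
# ---------------------------------------------------------------------------

def _gibbs_line_blup(
    y: np.ndarray,
    X: np.ndarray,
    line_idx: np.ndarray,
    n_lines: int,
    settings: MCMCSettings,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-trait Gibbs for y = Xb + u_line + e with u ~ N(0, sigma2_u I).

    Returns (posterior-mean fitted fixed part per record, posterior-mean line
    effect)."""
    n = y.size
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX + 1e-10 * np.eye(X.shape[1]))
    # prior scale from the design-adjusted variance so the chain (and the
    # adjusted values) are invariant to additive replicate/block offsets
    resid_ols = y - X @ (XtX_inv @ (X.T @ y))
    vy = float(np.var(resid_ols, ddof=1)) if n > 1 else 1.0
    if vy < 1e-12:
        return np.full(n, y.mean()), np.zeros(n_lines)
    counts = np.bincount(line_idx, minlength=n_lines).astype(float)
    nu, sc = 4.0, 0.5 * vy
    s2u, s2e = 0.5 * vy, 0.5 * vy
    u = np.zeros(n_lines)
    b = XtX_inv @ (X.T @ y)
    sum_fit, sum_u, kept = np.zeros(n), np.zeros(n_lines), 0
    Lx = np.linalg.cholesky(XtX_inv)
    for it in range(1, settings.n_iterations + 1):
        r = y - u[line_idx]
        b = XtX_inv @ (X.T @ r) + np.sqrt(s2e) * (Lx @ rng.standard_normal(X.shape[1]))
        r2 = y - X @ b
        prec = counts / s2e + 1.0 / s2u
        mean_u = (np.bincount(line_idx, weights=r2, minlength=n_lines) / s2e) / prec
        u = mean_u + rng.standard_normal(n_lines) / np.sqrt(prec)
        s2u = (nu * sc + np.sum(u**2)) / rng.chisquare(nu + n_lines)
        e = r2 - u[line_idx]
        s2e = (nu * sc + np.sum(e**2)) / rng.chisquare(nu + n)
        if it > settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            sum_fit += X @ b
            sum_u += u
            kept += 1
    return sum_fit / kept, sum_u / kept


def adjust_phenotypes(
    raw_records: pd.DataFrame, settings: MCMCSettings | None = None
) -> pd.DataFrame:
    """Adjust raw plot records to one value per line/environment/trait.

    Per environment and trait, fits replicate and block-within-replicate as
    fixed effects and line as a random effect via the Gibbs engine; the
    adjusted value is the grand fixed-effect mean plus the posterior-mean
    line effect.  Environments where every line has a single record are
    passed through unchanged (no design effects are estimable).
    """
    rec = validate_phenotypes(raw_records, require_design=True)
    settings = settings or MCMCSettings(n_iterations=2_000, burn_in=500, thin=2)
    out = []
    for (env, trait), sub in rec.groupby(["environment", "trait"], sort=True):
        lines = sorted(sub["line"].unique())
        if len(sub) == len(lines):
            adj = sub.set_index("line")["value"].reindex(lines).to_numpy()
        else:
            line_idx = sub["line"].map({l: i for i, l in enumerate(lines)}).to_numpy()
            design = pd.get_dummies(
                sub[["replicate", "block"]].astype(str).agg("|".join, axis=1),
                drop_first=True,
                dtype=float,
            )
            rep = pd.get_dummies(sub["replicate"].astype(str), drop_first=True, dtype=float)
            X = np.column_stack([np.ones(len(sub)), rep.to_numpy(), design.to_numpy()])
            # drop exactly collinear columns (block nested in replicate)
            q, r = np.linalg.qr(X)
            keep = np.abs(np.diag(r)) > 1e-8
            X = X[:, keep]
            rng = np.random.default_rng(
                settings.seed + zlib.crc32(f"{env}|{trait}".encode()) % 2**16
            )
            fit_fixed, u = _gibbs_line_blup(
                sub["value"].to_numpy(dtype=float), X, line_idx, len(lines), settings, rng
            )
            adj = fit_fixed.mean() + u
        out.append(
            pd.DataFrame(
                {
                    "line": lines,
                    "environment": env,
                    "replicate": 1,
                    "block": 1,
                    "trait": trait,
                    "value": adj,
                }
            )
        )
    adjusted = pd.concat(out, ignore_index=True)
    adjusted.attrs["adjusted"] = True
    return adjusted


# ---------------------------------------------------------------------------
# genomic G x E model in the kernel eigenbasis
# ---------------------------------------------------------------------------

@dataclass
class EigenKernel:
    """Eigendecomposed covariance kernel over stacked records.

    ``K = U diag(s) U'`` to numerical precision; negative eigenvalues are
    truncated at zero, and zero-eigenvalue directions carry no effect.
    """

    K: np.ndarray
    U: np.ndarray
    s: np.ndarray
    label: str


def build_ge_kernels(
    grm: KinshipMatrix, lines: list[str], environments: list[str]
) -> list[EigenKernel]:
    """Main-genotype kernel plus one env-specific block kernel per environment.

    ``lines`` and ``environments`` are per-record labels in the stacked
    (environment-ordered) record order used for the response vector.
    """
    lines = list(lines)
    environments = list(environments)
    if len(lines) != len(environments):
        raise ValueError("lines and environments must align per record")
    env_levels = sorted(set(environments))
    for env in env_levels:
        if environments.count(env) < 2:
            raise ValueError(f"environment {env!r} has a single record")
    K_lines = grm.align(sorted(set(lines)))
    order = {l: i for i, l in enumerate(sorted(set(lines)))}
    idx = np.array([order[l] for l in lines])
    K_main = K_lines[np.ix_(idx, idx)]

    def _eig(K: np.ndarray, label: str) -> EigenKernel:
        s, U = np.linalg.eigh((K + K.T) / 2.0)
        s = np.clip(s, 0.0, None)
        return EigenKernel(K=K, U=U, s=s, label=label)

    kernels = [_eig(K_main, "main-genotype")]
    env_arr = np.asarray(environments, dtype=object)
    for env in env_levels:
        ind = (env_arr == env).astype(float)
        kernels.append(_eig(K_main * np.outer(ind, ind), f"gxe:{env}"))
    return kernels


def fit_bgge(
    y: np.ndarray,
    kernels: list[EigenKernel],
    priors: BGGEPriors | None = None,
    settings: MCMCSettings | None = None,
    env_labels: list[str] | None = None,
    observed: np.ndarray | None = None,
    fix_variance: tuple[float, float] | None = None,
) -> PosteriorSamples:
    """Gibbs sampler for the additive-kernel G x E model.

    ``observed`` is a boolean mask; records marked False are treated as
    missing and data-augmented each sweep, so their posterior-mean fitted
    values are out-of-sample predictions.  ``fix_variance=(s2_u, s2_e)``
    freezes all variances (oracle-comparison mode).
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    settings = settings or MCMCSettings.short()
    priors = priors or BGGEPriors()
    obs = np.ones(n, dtype=bool) if observed is None else np.asarray(observed, dtype=bool)
    if obs.sum() < 3:
        raise ValueError("fewer than 3 observed records")
    vy = float(np.var(y[obs], ddof=1))
    sc_u = priors.sc_u if priors.sc_u is not None else 0.5 * vy / len(kernels)
    sc_e = priors.sc_e if priors.sc_e is not None else 0.5 * vy

    env = (
        np.asarray(env_labels, dtype=object)
        if env_labels is not None
        else np.asarray(["_all"] * n, dtype=object)
    )
    env_levels = sorted(set(env))
    env_groups = {e: np.flatnonzero(env == e) for e in env_levels}

    rng = np.random.default_rng(settings.seed)
    mu = {e: float(np.mean(y[obs & (env == e)])) if np.any(obs & (env == e)) else float(np.mean(y[obs])) for e in env_levels}
    u = [np.zeros(n) for _ in kernels]
    if fix_variance is not None:
        s2k = [float(fix_variance[0])] * len(kernels)
        s2e = float(fix_variance[1])
    else:
        s2k = [0.5 * vy / len(kernels)] * len(kernels)
        s2e = 0.5 * vy
    y_cur = y.copy()
    y_cur[~obs] = float(np.mean(y[obs]))

    fitted_sum = np.zeros(n)
    keep_s2k, keep_s2e, kept = [], [], 0
    xb = np.empty(n)
    for it in range(1, settings.n_iterations + 1):
        for e in env_levels:
            xb[env_groups[e]] = mu[e]
        total_u = np.sum(u, axis=0)
        fit = xb + total_u
        if (~obs).any():
            y_cur[~obs] = fit[~obs] + np.sqrt(s2e) * rng.standard_normal((~obs).sum())
        # fixed per-environment means
        for e in env_levels:
            g = env_groups[e]
            m = float(np.mean(y_cur[g] - total_u[g]))
            mu[e] = m + np.sqrt(s2e / g.size) * rng.standard_normal()
            xb[g] = mu[e]
        # kernel effects in their eigenbases
        for k, ker in enumerate(kernels):
            r = y_cur - xb - (np.sum(u, axis=0) - u[k])
            dvec = ker.U.T @ r
            s = ker.s
            nz = s > 1e-10
            b = np.zeros(n)
            lam = s[nz] * s2k[k]
            var_b = lam * s2e / (lam + s2e)
            mean_b = (lam / (lam + s2e)) * dvec[nz]
            b[nz] = mean_b + np.sqrt(var_b) * rng.standard_normal(nz.sum())
            u[k] = ker.U @ b
            if fix_variance is None:
                ssq = float(np.sum(b[nz] ** 2 / s[nz]))
                scale = priors.nu_u * sc_u + ssq
                if not np.isfinite(scale):
                    raise FloatingPointError(f"non-finite scale update at iteration {it}")
                s2k[k] = scale / rng.chisquare(priors.nu_u + nz.sum())
        if fix_variance is None:
            e_res = y_cur[obs] - xb[obs] - np.sum(u, axis=0)[obs]
            scale = priors.nu_e * sc_e + float(np.sum(e_res**2))
            if not np.isfinite(scale):
                raise FloatingPointError(f"non-finite scale update at iteration {it}")
            s2e = scale / rng.chisquare(priors.nu_e + obs.sum())
        if it > settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            fitted_sum += xb + np.sum(u, axis=0)
            keep_s2k.append(list(s2k))
            keep_s2e.append(s2e)
            kept += 1

    draws = {
        "sigma2_u": np.asarray(keep_s2k),
        "sigma2_e": np.asarray(keep_s2e)[:, None],
        "fitted_mean": (fitted_sum / kept)[None, :],
    }
    _check_convergence(draws["sigma2_e"][:, 0], "sigma2_e")
    return PosteriorSamples(
        model="bgge",
        draws=draws,
        line_ids=[],
        trait_names=[],
        meta={"kernel_labels": [k.label for k in kernels]},
    )


def bgge_predictions(samples: PosteriorSamples) -> np.ndarray:
    """Posterior-mean fitted value per stacked record."""
    return samples.draws["fitted_mean"][0]


# ---------------------------------------------------------------------------
# matrix-variate multi-trait multi-environment model
# ---------------------------------------------------------------------------

def _layout(records: pd.DataFrame, traits: list[str]):
    # NaN values are allowed here: they mark cells to predict (na_mode)
    rec = records.copy()
    validate_phenotypes(rec.dropna(subset=["value"]))
    if "replicate" not in rec.columns:
        rec["replicate"] = 1
    if rec.duplicated(subset=["line", "environment", "replicate", "trait"]).any():
        raise ValueError("duplicate phenotype keys")
    rec = rec[rec["trait"].isin(traits)]
    if rec.duplicated(subset=["line", "environment", "trait"]).any():
        raise ValueError("multiple records per line/environment/trait; adjust first")
    envs = sorted(rec["environment"].unique())
    lines = sorted(rec["line"].unique())
    wide = rec.pivot_table(
        index=["environment", "line"], columns="trait", values="value", dropna=False
    ).reindex(pd.MultiIndex.from_product([envs, lines], names=["environment", "line"]))
    wide = wide.reindex(columns=traits)
    return wide, envs, lines


def fit_bmtme(
    records: pd.DataFrame,
    grm: KinshipMatrix,
    settings: MCMCSettings | None = None,
    traits: list[str] | None = None,
    na_mode: bool = False,
    priors: dict | None = None,
) -> PosteriorSamples:
    """Gibbs sampler for the matrix-variate multi-trait multi-environment model.

    The response is laid out environment-major as an (e*g) x t matrix
    ``Y = X beta + Z1 b1 + Z2 b2 + E`` with ``b1 ~ MN(0, G, St)``,
    ``b2 ~ MN(0, Se (x) G, St)`` and residual rows iid ``N(0, Re)``.
    Because environment-constant components of b2 are indistinguishable from
    b1, b2 is parameterized on an orthonormal sum-to-zero contrast basis
    across environments (so Se is the (e-1) x (e-1) covariance of the
    interaction contrasts); genetic effects live in the column span of G,
    whose null directions are truncated.  With ``na_mode=True`` missing
    cells are data-augmented each sweep and their posterior-mean fitted
    values serve as predictions; otherwise an incomplete layout is an error
    listing the missing cells.
    """
    settings = settings or MCMCSettings.short()
    traits = traits or sorted(records["trait"].unique())
    wide, envs, lines = _layout(records, traits)
    Y = wide.to_numpy(dtype=float)
    e, g, t = len(envs), len(lines), len(traits)
    l = e * g
    miss = np.isnan(Y)
    if miss.any() and not na_mode:
        where = wide[wide.isna().any(axis=1)].index[:5].tolist()
        raise ValueError(f"incomplete layout (e.g. {where}); pass na_mode=True")
    vy = np.nanvar(Y, axis=0, ddof=1)
    if np.any(vy < 1e-12):
        raise DegenerateDataError("a trait has (near-)zero variance")

    dG_all, V_all = _prepare_kinship(grm.align(lines))
    keep = dG_all > 1e-8 * dG_all.max()
    dG, V = dG_all[keep], V_all[:, keep]
    nG = int(keep.sum())
    rng = np.random.default_rng(settings.seed)

    # orthonormal sum-to-zero contrasts across environments (Helmert-style)
    if e > 1:
        H = np.linalg.qr(np.eye(e) - 1.0 / e)[0][:, : e - 1]
        ec = e - 1
    else:
        H = np.zeros((1, 0))
        ec = 0

    priors = priors or {}
    nu_t = priors.get("nu_t", t + 1)
    S0t = priors.get("scale_t", 0.1 * np.diag(vy))
    nu_e = priors.get("nu_e", ec + 1)
    S0e = priors.get("scale_e", 0.1 * np.eye(max(ec, 1)))
    nu_r = priors.get("nu_r", t + 1)
    S0r = priors.get("scale_r", 0.1 * np.diag(vy))

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        beta = np.nanmean(Y.reshape(e, g, t), axis=1)  # e x t environment means
    grand = np.nanmean(Y, axis=0)
    beta = np.where(np.isnan(beta), grand[None, :], beta)
    B1t = np.zeros((nG, t))       # main genetic effects, eigenbasis of G
    B2c = np.zeros((ec * nG, t))  # interaction contrasts, (H (x) V) basis
    St = 0.25 * np.diag(vy)
    Se = 0.5 * np.eye(max(ec, 1))
    Re = 0.5 * np.diag(vy)

    Yc = Y.copy()
    col_means = np.nanmean(Y, axis=0)
    for k in range(t):
        Yc[miss[:, k], k] = col_means[k]

    def current_fit(beta, B1, B2):
        return np.repeat(beta, g, axis=0) + np.tile(B1, (e, 1)) + B2

    B1 = V @ B1t
    B2 = np.zeros((l, t))
    fitted_sum = np.zeros((l, t))
    keep_St, keep_Se, keep_Re, keep_B1, kept = [], [], [], [], 0
    for it in range(1, settings.n_iterations + 1):
        fit = current_fit(beta, B1, B2)
        # data augmentation of missing cells, residual rows iid N(0, Re)
        if miss.any():
            LRe = np.linalg.cholesky(Re)
            E_draw = (LRe @ rng.standard_normal((t, l))).T
            full_rows = miss.all(axis=1)
            Yc[full_rows] = fit[full_rows] + E_draw[full_rows]
            part_rows = np.flatnonzero(miss.any(axis=1) & ~full_rows)
            for i in part_rows:
                o = ~miss[i]
                mm = miss[i]
                Roo = Re[np.ix_(o, o)]
                Rmo = Re[np.ix_(mm, o)]
                cond_mean = fit[i, mm] + Rmo @ np.linalg.solve(Roo, Yc[i, o] - fit[i, o])
                cond_cov = Re[np.ix_(mm, mm)] - Rmo @ np.linalg.solve(Roo, Rmo.T)
                Yc[i, mm] = rng.multivariate_normal(cond_mean, cond_cov)
        Re_inv = np.linalg.inv(Re)
        St_inv = np.linalg.inv(St)
        # beta: per-environment trait means
        M = (Yc - np.tile(B1, (e, 1)) - B2).reshape(e, g, t).mean(axis=1)
        Lb = np.linalg.cholesky(Re / g)
        beta = M + (Lb @ rng.standard_normal((t, e))).T
        # an environment with no observed cells gives beta no information;
        # pin it to the grand mean rather than letting it random-walk
        unobs_env = miss.reshape(e, g, t).all(axis=(1, 2))
        if unobs_env.any():
            beta[unobs_env] = grand[None, :]
        # b1 in the retained eigenbasis of G (lines decouple)
        R1 = (Yc - np.repeat(beta, g, axis=0) - B2).reshape(e, g, t)
        R1sum = np.einsum("ji,ejt->it", V, R1)
        P = St_inv[None, :, :] / dG[:, None, None] + e * Re_inv[None, :, :]
        rhs = R1sum @ Re_inv
        m = np.linalg.solve(P, rhs[:, :, None])[:, :, 0]
        L = np.linalg.cholesky(P)
        z = rng.standard_normal((nG, t, 1))
        B1t = m + np.linalg.solve(np.transpose(L, (0, 2, 1)), z)[:, :, 0]
        B1 = V @ B1t
        S1 = B1t.T @ (B1t / dG[:, None])
        if ec > 0:
            # b2 on the contrast basis: columns of (H (x) V) are orthonormal
            dE, Ve = np.linalg.eigh((Se + Se.T) / 2.0)
            dE = np.clip(dE, 1e-12, None)
            HVe = H @ Ve  # e x ec, orthonormal columns
            R2 = (Yc - np.repeat(beta, g, axis=0) - np.tile(B1, (e, 1))).reshape(e, g, t)
            T = np.einsum("ea,ji,ejt->ait", HVe, V, R2).reshape(ec * nG, t)
            dprod = np.repeat(dE, nG) * np.tile(dG, ec)
            P2 = St_inv[None, :, :] / dprod[:, None, None] + Re_inv[None, :, :]
            rhs2 = T @ Re_inv
            m2 = np.linalg.solve(P2, rhs2[:, :, None])[:, :, 0]
            L2 = np.linalg.cholesky(P2)
            z2 = rng.standard_normal((ec * nG, t, 1))
            B2t = m2 + np.linalg.solve(np.transpose(L2, (0, 2, 1)), z2)[:, :, 0]
            B2 = np.einsum("ea,ji,ait->ejt", HVe, V, B2t.reshape(ec, nG, t)).reshape(l, t)
            S2 = B2t.T @ (B2t / dprod[:, None])
            n2 = ec * nG
        else:
            S2 = np.zeros((t, t))
            n2 = 0
        # trait covariance from both genetic terms
        St = np.atleast_2d(
            invwishart.rvs(df=nu_t + nG + n2, scale=S0t + S1 + S2, random_state=rng)
        )
        # contrast covariance of the interaction term
        if ec > 0:
            St_inv = np.linalg.inv(St)
            B2v = (B2t.reshape(ec, nG, t) / np.sqrt(dG)[None, :, None]) @ np.linalg.cholesky(St_inv)
            C2 = B2v.reshape(ec, nG * t)
            Se = np.atleast_2d(
                invwishart.rvs(df=nu_e + nG * t, scale=S0e + C2 @ C2.T, random_state=rng)
            )
        # residual covariance
        E = Yc - current_fit(beta, B1, B2)
        Re = np.atleast_2d(
            invwishart.rvs(df=nu_r + l, scale=S0r + E.T @ E, random_state=rng)
        )
        if it > settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            fitted_sum += current_fit(beta, B1, B2)
            keep_St.append(St.copy())
            keep_Se.append(Se.copy())
            keep_Re.append(Re.copy())
            keep_B1.append(B1.copy())
            kept += 1
        if it % 1000 == 0:
            logger.debug("bmtme iteration %d/%d", it, settings.n_iterations)

    draws = {
        "Sigma_t": np.stack(keep_St),
        "Sigma_e_contrast": np.stack(keep_Se),
        "Re": np.stack(keep_Re),
        "b1": np.stack(keep_B1),
        "fitted_mean": (fitted_sum / kept)[None, :, :],
    }
    _check_convergence(draws["Sigma_t"][:, 0, 0], "Sigma_t[0,0]")
    return PosteriorSamples(
        model="bmtme",
        draws=draws,
        line_ids=lines,
        trait_names=list(traits),
        meta={"environments": envs},
    )


def bmtme_predictions(samples: PosteriorSamples) -> pd.DataFrame:
    """Posterior-mean fitted values as a tidy (line, environment, trait) table."""
    envs = samples.meta["environments"]
    lines = samples.line_ids
    fitted = samples.draws["fitted_mean"][0].reshape(len(envs), len(lines), len(samples.trait_names))
    rows = []
    for a, env in enumerate(envs):
        for i, line in enumerate(lines):
            for k, trait in enumerate(samples.trait_names):
                rows.append((line, env, trait, fitted[a, i, k]))
    return pd.DataFrame(rows, columns=["line", "environment", "trait", "predicted"])


def gblup_extend(
    u_train: np.ndarray, kinship: KinshipMatrix, train_lines: list[str], new_lines: list[str]
) -> np.ndarray:
    """Extend estimated genetic values to unphenotyped lines.

    Uses the conditional mean of a Gaussian with covariance proportional to
    the kinship: u_new = K_nt K_tt^{-1} u_train (columns are traits)."""
    all_lines = list(train_lines) + [l for l in new_lines if l not in train_lines]
    K = kinship.align(all_lines)
    nt = len(train_lines)
    K_tt = K[:nt, :nt] + 1e-8 * np.eye(nt)
    idx = {l: i for i, l in enumerate(all_lines)}
    rows = np.array([idx[l] for l in new_lines])
    K_nt = K[rows][:, :nt]
    return K_nt @ np.linalg.solve(K_tt, u_train)
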