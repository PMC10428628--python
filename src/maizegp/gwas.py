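"""Mixed-linear-model association scan with structure correction, and the
Bayes-factor / posterior-probability-of-association pleiotropy statistic.

The scan fits ``y = S a + Q v + Z u + e`` per marker, with population
structure covariates Q (principal components of the dosage matrix), a
polygenic random effect with covariance proportional to the kinship K, and
variance components estimated once under the null model via the spectral
decomposition of K (the fast "population parameters previously determined"
mode).  Each marker is then tested by generalized least squares on the
whitened data with a Wald test.

For pleiotropy, a closed-form Bayes factor compares a bivariate-effect
model against the null under a conjugate matrix-normal-inverse-Wishart
prior, and PPA = BF*pi / ((1-pi) + BF*pi) converts it to a posterior
probability of association given prior probability pi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import multigammaln

from .panel import GenotypePanel, KinshipMatrix


@dataclass
class StructureCovariates:
    Q: np.ndarray  # lines x q component scores
    method: str = "PCA"
    explained_variance_ratio: np.ndarray | None = None


def structure_covariates(panel: GenotypePanel, n_components: int) -> StructureCovariates:
    """Top principal-component scores of the centered dosage matrix."""
    if np.isnan(panel.dosage).any():
        raise ValueError("panel must be complete; impute first")
    if n_components >= panel.n_lines:
        raise ValueError("n_components must be smaller than the number of lines")
    if n_components <= 0:
        return StructureCovariates(Q=np.empty((panel.n_lines, 0)))
    X = panel.dosage - panel.dosage.mean(axis=0)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :n_components] * s[:n_components]
    evr = (s**2 / np.sum(s**2))[:n_components]
    return StructureCovariates(Q=scores, explained_variance_ratio=evr)


def _null_variance_components(y, X0, K_values):
    """ML variance components under the null via the spectral decomposition."""
    n = y.size
    K = (K_values + K_values.T) / 2.0 + 1e-8 * np.mean(np.diag(K_values)) * np.eye(n)
    s, U = np.linalg.eigh(K)
    s = np.clip(s, 0.0, None)
    yr = U.T @ y
    Xr = U.T @ X0

    def negloglik(log_delta):
        delta = np.exp(log_delta)  # sigma2_e / sigma2_g
        w = s + delta
        Xw = Xr / w[:, None]
        beta = np.linalg.solve(Xr.T @ Xw, Xw.T @ yr)
        r = yr - Xr @ beta
        sigma2_g = float(np.sum(r**2 / w) / n)
        return 0.5 * (n * np.log(2 * np.pi * sigma2_g) + np.sum(np.log(w)) + n)

    res = optimize.minimize_scalar(negloglik, bounds=(-10.0, 10.0), method="bounded")
    delta = float(np.exp(res.x))
    w = s + delta
    Xw = Xr / w[:, None]
    beta = np.linalg.solve(Xr.T @ Xw, Xw.T @ yr)
    r = yr - Xr @ beta
    sigma2_g = float(np.sum(r**2 / w) / n)
    sigma2_e = sigma2_g * delta
    return sigma2_g, sigma2_e, s, U


def mlm_gwas(
    adjusted_values: pd.Series | np.ndarray,
    panel: GenotypePanel,
    Q: StructureCovariates | np.ndarray | None,
    K: KinshipMatrix,
) -> pd.DataFrame:
    """Q+K mixed-model scan of one adjusted phenotype vector.

    ``adjusted_values`` must align with ``panel.line_ids`` (a Series indexed
    by line id is re-ordered).  Returns one row per marker with effect,
    standard error, F statistic, p-value and PV% (variance explained); a
    marker collinear with the covariates is flagged NA and the scan
    continues.
    """
    if isinstance(adjusted_values, pd.Series):
        y = adjusted_values.reindex(panel.line_ids).to_numpy(dtype=float)
    else:
        y = np.asarray(adjusted_values, dtype=float)
    if y.size != panel.n_lines or np.isnan(y).any():
        raise ValueError("phenotype vector must cover every line in the panel")
    if np.isnan(panel.dosage).any():
        raise ValueError("panel must be complete; impute first")

    Qm = Q.Q if isinstance(Q, StructureCovariates) else (
        np.empty((y.size, 0)) if Q is None else np.asarray(Q, dtype=float)
    )
    X0 = np.column_stack([np.ones(y.size), Qm])
    sigma2_g, sigma2_e, s, U = _null_variance_components(y, X0, K.align(panel.line_ids))

    w = sigma2_g * s + sigma2_e
    sw = 1.0 / np.sqrt(w)
    yt = sw * (U.T @ y)
    X0t = sw[:, None] * (U.T @ X0)
    Mt = sw[:, None] * (U.T @ panel.dosage)

    # residualize on the null covariates (Frisch-Waugh)
    Xpinv = np.linalg.pinv(X0t)
    yr = yt - X0t @ (Xpinv @ yt)
    Mr = Mt - X0t @ (Xpinv @ Mt)

    mm = np.sum(Mr**2, axis=0)
    my = Mr.T @ yr
    df_resid = y.size - X0.shape[1] - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        effect = my / mm
        rss0 = float(yr @ yr)
        rss1 = rss0 - my**2 / mm
        sigma2 = rss1 / df_resid
        se = np.sqrt(sigma2 / mm)
        tstat = effect / se
        F = tstat**2
        p = 2.0 * stats.t.sf(np.abs(tstat), df_resid)
    collinear = mm < 1e-10 * np.max(mm) if mm.size else np.zeros(0, dtype=bool)
    effect[collinear] = np.nan
    se[collinear] = np.nan
    F[collinear] = np.nan
    p[collinear] = np.nan

    result = pd.DataFrame(
        {
            "marker": panel.marker_ids,
            "chromosome": panel.chromosome,
            "position_bp": panel.position_bp,
            "effect": effect,
            "se": se,
            "F": F,
            "p_value": np.clip(p, np.finfo(float).tiny, 1.0),
            "collinear": collinear,
        }
    )
    result["pv_percent"] = pv_explained(result, df_resid)
    result.attrs["sigma2_g"] = sigma2_g
    result.attrs["sigma2_e"] = sigma2_e
    result.attrs["df_resid"] = df_resid
    return result


def pv_explained(result: pd.DataFrame, df_resid: int | None = None) -> np.ndarray:
    """Percent phenotypic variance explained per marker, as partial R^2.

    For a 1-df marker term, partial R^2 = F / (F + df_resid), reported as a
    percentage.  NA statistics yield NA PV%.
    """
    if df_resid is None:
        df_resid = result.attrs["df_resid"]
    F = result["F"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        return 100.0 * F / (F + df_resid)


def genomic_control_lambda(p_values: np.ndarray) -> float:
    """Median-based genomic inflation factor of a scan's p-values."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


# ---------------------------------------------------------------------------
# multivariate Bayes factor and PPA
# ---------------------------------------------------------------------------

def _log_marginal_mniw(Y, X, Lambda0, nu0, S0):
    """Log marginal likelihood of Y = XB + E under the conjugate
    matrix-normal-inverse-Wishart prior B ~ MN(0, Lambda0^{-1}, Sigma),
    Sigma ~ IW(nu0, S0)."""
    n, q = Y.shape
    Lambda_n = Lambda0 + X.T @ X
    Bn = np.linalg.solve(Lambda_n, X.T @ Y)
    Sn = S0 + Y.T @ Y - Bn.T @ Lambda_n @ Bn
    nu_n = nu0 + n
    sign0, logdet_L0 = np.linalg.slogdet(Lambda0)
    signn, logdet_Ln = np.linalg.slogdet(Lambda_n)
    _, logdet_S0 = np.linalg.slogdet(S0)
    _, logdet_Sn = np.linalg.slogdet(Sn)
    return (
        -0.5 * n * q * np.log(np.pi)
        + 0.5 * q * (logdet_L0 - logdet_Ln)
        + 0.5 * nu0 * logdet_S0
        - 0.5 * nu_n * logdet_Sn
        + multigammaln(nu_n / 2.0, q)
        - multigammaln(nu0 / 2.0, q)
    )


def multivariate_bf(
    Y: np.ndarray, marker_dosage: np.ndarray, prior_scale: float = 1.0
) -> float:
    """Bayes factor for a joint marker effect on two (or more) traits.

    The alternative adds the centered marker with a unit-information-style
    prior: effect-row precision x'x / (n * prior_scale^2), so the prior
    effect variance scales with ``prior_scale`` and the BF tends to 1 as
    ``prior_scale`` tends to 0.  Both models share a vague intercept and the
    same inverse-Wishart residual prior, so their ratio is proper.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, q = Y.shape
    x = np.asarray(marker_dosage, dtype=float)
    if x.size != n:
        raise ValueError("marker and phenotypes must align")
    if np.std(x) < 1e-12:
        raise ValueError("constant marker: Bayes factor undefined")
    xc = (x - x.mean())[:, None]
    Yc = Y - Y.mean(axis=0)

    nu0 = q + 2
    S0 = np.diag(np.var(Yc, axis=0, ddof=1)) * (nu0 - q - 1)
    lam_int = 1e-6
    X_null = np.ones((n, 1))
    L0_null = np.array([[lam_int]])
    ll_null = _log_marginal_mniw(Yc, X_null, L0_null, nu0, S0)

    X_alt = np.hstack([X_null, xc])
    xtx = float((xc * xc).sum())
    lam_marker = xtx / (n * prior_scale**2) if prior_scale > 0 else np.inf
    if not np.isfinite(lam_marker):
        return 1.0
    L0_alt = np.diag([lam_int, lam_marker])
    ll_alt = _log_marginal_mniw(Yc, X_alt, L0_alt, nu0, S0)
    return float(np.exp(ll_alt - ll_null))


def log10_bf(Y, marker_dosage, prior_scale: float = 1.0) -> float:
    return float(np.log10(multivariate_bf(Y, marker_dosage, prior_scale)))


def compute_ppa(bf: float, pi: float) -> float:
    """Posterior probability of association from a Bayes factor and prior pi."""
    if not 0.0 < pi < 1.0:
        raise ValueError("pi must be in (0, 1)")
    if bf <= 0:
        raise ValueError("Bayes factor must be positive")
    return (bf * pi) / ((1.0 - pi) + bf * pi)


def candidate_window(
    marker_position: int, ld_decay_distance_bp: float
) -> tuple[int, int]:
    """Closed 1-based interval of twice the LD decay distance, SNP-centered.

    Returns [max(1, pos - d), pos + d]; the lower bound is clamped at the
    chromosome start.
    """
    if marker_position < 1:
        raise ValueError("position must be >= 1")
    if not ld_decay_distance_bp > 0:
        raise ValueError("decay distance must be positive")
    d = int(round(ld_decay_distance_bp))
    return max(1, marker_position - d), marker_position + d


def windows_to_bed(
    windows: list[tuple[str, int, int]], path: str, names: list[str] | None = None
) -> None:
    """Write (chrom, start_1based, end_1based) closed intervals as BED
    (0-based, half-open)."""
    with open(path, "w") as fh:
        for k, (chrom, start, end) in enumerate(windows):
            name = names[k] if names else f"window{k + 1}"
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")


def bed_to_windows(path: str) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end = line.split("\t")[:3]
            out.append((chrom, int(start) + 1, int(end)))
    return out
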