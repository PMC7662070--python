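"""Bayesian mixed models for genomic prediction via Gibbs sampling.

Two samplers share one engine style:

* ``gibbs_univariate`` — y = Xb + Zg + Wb + e with g ~ N(0, K sigma_g^2)
  for a relationship kernel K (pedigree A, VanRaden G or weighted G_w), an
  optional i.i.d. random effect (e.g. block within replicate) and
  scaled-inverse-chi-squared variance updates.

* ``gibbs_multitrait`` — Y = XB + a + e with vec(a) ~ N(0, Sigma_a (x) K)
  and vec(e) ~ N(0, Sigma_e (x) I), inverse-Wishart full conditionals for
  both covariance matrices.

Both work in the eigenbasis of the kernel, K = U D U', where the genetic
values decorrelate across individuals.  The multi-trait sampler
additionally diagonalizes the (Sigma_a, Sigma_e) pencil each iteration
(Sigma_e = L L', L^-1 Sigma_a L^-T = Q Lam Q'), so every breeding-value
coordinate has a scalar full conditional — exact, and vectorized over the
whole n x t array.  Missing phenotype cells are data-augmented, which is
what makes cross-validation masking exact: a masked individual's GEBV is
informed purely through relatedness.

Heritability and genetic correlations are computed *per retained sample*
(h2 = sigma_a^2/(sigma_a^2+sigma_e^2), r_G = sigma_axy/sqrt(sigma_ax^2
sigma_ay^2)) and then summarized, not computed from averaged components.
DIC uses the conditional deviance given the breeding values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular

from .relmat import RelMatrix, ensure_psd


@dataclass
class MCMCConfig:
    """Chain settings and inverse-Wishart prior hyperparameters.

    Defaults are desk-scale (20,000 iterations, 5,000 burn-in, thin 10);
    production-scale settings (e.g. 300,000/50,000/10) are plain overrides.
    Prior scale matrices default to an even split of the phenotypic
    variance: S_a = diag(s_a_frac * var_p) * (nu - t - 1) and likewise S_e,
    with nu = t + 2 — weakly informative, centered on s_a_frac/s_e_frac of
    the observed variance.
    """

    n_iter: int = 20_000
    burn_in: int = 5_000
    thin: int = 10
    seed: int = 0
    nu_a: float | None = None
    nu_e: float | None = None
    s_a_frac: float = 0.5
    s_e_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in + self.thin - 1) // self.thin


@dataclass
class PosteriorSummary:
    """Posterior summaries of one Gibbs run."""

    trait_names: list[str]
    Sigma_a_mean: np.ndarray
    Sigma_a_sd: np.ndarray
    Sigma_e_mean: np.ndarray
    Sigma_e_sd: np.ndarray
    h2_mean: np.ndarray
    h2_sd: np.ndarray
    h2_ci: np.ndarray        # (t, 2) central 95% interval
    rG_mean: np.ndarray
    rG_sd: np.ndarray
    rG_ci: np.ndarray        # (t, t, 2)
    gebv: pd.DataFrame       # posterior-mean breeding values
    dic: float
    p_d: float
    ess_h2: np.ndarray
    extra: dict = field(default_factory=dict)


def effective_sample_size(x: np.ndarray) -> float:
    """ESS by the initial-positive-sequence autocorrelation estimator."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1))
    acf = acf / acf[0]
    s = 0.0
    for k in range(1, n):
        if acf[k] <= 0:
            break
        s += acf[k]
    return float(n / (1.0 + 2.0 * s))


def gaussian_deviance(y: np.ndarray, mu: np.ndarray,
                      Sigma_e: np.ndarray) -> float:
    """-2 log N(y_obs; mu_obs, Sigma_e[obs, obs]) summed over rows.

    ``y`` may contain NaN cells; each row contributes the marginal normal
    density of its observed cells only.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    Sigma_e = np.atleast_2d(np.asarray(Sigma_e, dtype=float))
    dev = 0.0
    masks = ~np.isnan(y)
    for pattern in np.unique(masks, axis=0):
        if not pattern.any():
            continue
        rows = np.flatnonzero((masks == pattern).all(axis=1))
        o = np.flatnonzero(pattern)
        S = Sigma_e[np.ix_(o, o)]
        r = y[np.ix_(rows, o)] - mu[np.ix_(rows, o)]
        L = np.linalg.cholesky(S)
        z = solve_triangular(L, r.T, lower=True)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        dev += rows.size * (o.size * np.log(2 * np.pi) + logdet) \
            + float((z ** 2).sum())
    return dev


def _default_priors(varp: np.ndarray, t: int, config: MCMCConfig
                    ) -> tuple[float, float, np.ndarray, np.ndarray]:
    nu_a = config.nu_a if config.nu_a is not None else t + 2
    nu_e = config.nu_e if config.nu_e is not None else t + 2
    S_a = np.diag(config.s_a_frac * varp) * (nu_a - t - 1)
    S_e = np.diag(config.s_e_frac * varp) * (nu_e - t - 1)
    return float(nu_a), float(nu_e), S_a, S_e


def _missing_groups(mask: np.ndarray) -> list[tuple[np.ndarray, np.ndarray,
                                                    np.ndarray]]:
    """Group rows by missingness pattern: (rows, observed, missing)."""
    groups = []
    for pattern in np.unique(mask, axis=0):
        rows = np.flatnonzero((mask == pattern).all(axis=1))
        groups.append((rows, np.flatnonzero(~pattern),
                       np.flatnonzero(pattern)))
    return groups


def gibbs_multitrait(Y: pd.DataFrame, kernel: RelMatrix,
                     config: MCMCConfig | None = None,
                     X: np.ndarray | None = None,
                     keep_samples: bool = True) -> dict:
    """Run the multi-trait Gibbs sampler; returns the samples record.

    ``Y`` is an individuals x traits frame indexed by ids present in the
    kernel; NaN cells (including whole rows for unphenotyped individuals)
    are data-augmented.  Fixed effects default to trait-wise intercepts.
    Pass the result to :func:`summarize_posterior`.
    """
    config = config or MCMCConfig()
    ids = [str(i) for i in Y.index]
    K = ensure_psd(kernel.align(ids))
    Yobs = Y.to_numpy(dtype=float)
    n, t = Yobs.shape
    if t < 1:
        raise ValueError("no traits")
    if n - int(np.isnan(Yobs).all(axis=1).sum()) < 2:
        raise ValueError("fewer than 2 phenotyped individuals")

    d, U = np.linalg.eigh(K.values)
    d = np.clip(d, 1e-10, None)
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    Xt = U.T @ X
    XtX = Xt.T @ Xt
    Lx = np.linalg.cholesky(np.linalg.inv(XtX))

    varp = np.nanvar(Yobs, axis=0, ddof=1)
    varp = np.where(np.isfinite(varp) & (varp > 0), varp, 1.0)
    nu_a, nu_e, S_a, S_e = _default_priors(varp, t, config)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x6139]))
    mask = np.isnan(Yobs)
    groups = _missing_groups(mask)

    # initial state
    Sigma_a = np.diag(config.s_a_frac * varp)
    Sigma_e = np.diag(config.s_e_frac * varp)
    col_mean = np.nanmean(np.where(mask, np.nan, Yobs), axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    Yc = np.where(mask, col_mean, Yobs)
    B = np.zeros((p, t))
    B[0] = col_mean if (X[:, 0] == 1).all() else 0.0
    A_til = np.zeros((n, t))

    S = config.n_retained
    out = {
        "trait_names": list(Y.columns),
        "ids": ids,
        "Sigma_a": np.empty((S, t, t)),
        "Sigma_e": np.empty((S, t, t)),
        "beta": np.empty((S, p, t)),
        "deviance": np.empty(S),
        "kernel_kind": kernel.kind,
        "n_obs_cells": int((~mask).sum()),
    }
    gebv_sum = np.zeros((n, t))
    beta_sum = np.zeros((p, t))
    k_out = 0

    for it in range(config.n_iter):
        a = U @ A_til
        mu = X @ B + a
        # data augmentation of missing cells
        Le_full = np.linalg.cholesky(Sigma_e)
        for rows, o, m in groups:
            if m.size == 0:
                continue
            if o.size == 0:
                Yc[rows] = mu[rows] + \
                    rng.standard_normal((rows.size, t)) @ Le_full.T
                continue
            Soo = Sigma_e[np.ix_(o, o)]
            Smo = Sigma_e[np.ix_(m, o)]
            Smm = Sigma_e[np.ix_(m, m)]
            G = Smo @ np.linalg.inv(Soo)
            cond_cov = Smm - G @ Smo.T
            Lc = np.linalg.cholesky(cond_cov + 1e-12 * np.eye(m.size))
            resid_o = Yobs[np.ix_(rows, o)] - mu[np.ix_(rows, o)]
            cm = mu[np.ix_(rows, m)] + resid_o @ G.T
            Yc[np.ix_(rows, m)] = cm + \
                rng.standard_normal((rows.size, m.size)) @ Lc.T

        Yt = U.T @ Yc
        # fixed effects: matrix-normal full conditional (flat prior)
        R0 = Yt - A_til
        Bhat = np.linalg.solve(XtX, Xt.T @ R0)
        B = Bhat + Lx @ rng.standard_normal((p, t)) @ Le_full.T
        R = Yt - Xt @ B

        # breeding values via joint diagonalization of (Sigma_a, Sigma_e)
        Li = solve_triangular(Le_full, np.eye(t), lower=True)
        Bm = Li @ Sigma_a @ Li.T
        lam, Q = np.linalg.eigh((Bm + Bm.T) / 2.0)
        lam = np.clip(lam, 0.0, None)
        M = Le_full @ Q
        W = R @ Li.T @ Q                     # coords with unit residual cov
        v = d[:, None] * lam[None, :]
        post_var = v / (1.0 + v)
        Zs = post_var * W + np.sqrt(post_var) * rng.standard_normal((n, t))
        A_til = Zs @ M.T

        scat_a = A_til.T @ (A_til / d[:, None])
        Sigma_a = stats.invwishart.rvs(df=nu_a + n, scale=S_a + scat_a,
                                       random_state=rng).reshape(t, t)
        E = R - A_til
        Sigma_e = stats.invwishart.rvs(df=nu_e + n, scale=S_e + E.T @ E,
                                       random_state=rng).reshape(t, t)

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            a = U @ A_til
            out["Sigma_a"][k_out] = Sigma_a
            out["Sigma_e"][k_out] = Sigma_e
            out["beta"][k_out] = B
            out["deviance"][k_out] = gaussian_deviance(
                Yobs, X @ B + a, Sigma_e)
            gebv_sum += a
            beta_sum += B
            k_out += 1

    gebv = gebv_sum / k_out
    beta_mean = beta_sum / k_out
    out["gebv_mean"] = gebv
    out["beta_mean"] = beta_mean
    out["deviance_at_mean"] = gaussian_deviance(
        Yobs, X @ beta_mean + gebv, out["Sigma_e"].mean(axis=0))
    if not keep_samples:
        for key in ("beta",):
            out.pop(key, None)
    return out


def gibbs_univariate(y: pd.Series | np.ndarray, kernel: RelMatrix,
                     config: MCMCConfig | None = None,
                     X: np.ndarray | None = None,
                     individuals: list[str] | None = None,
                     block: np.ndarray | None = None) -> dict:
    """Single-trait sampler with an optional extra i.i.d. random effect.

    Observations map to kernel individuals through ``individuals`` (default:
    the index of ``y``); repeated labels (ramets) are allowed when every
    genotype has the same number of observations.  Missing responses are
    data-augmented so masked individuals still receive GEBVs.
    """
    config = config or MCMCConfig()
    if isinstance(y, pd.Series):
        if individuals is None:
            individuals = [str(i) for i in y.index]
        name = y.name or "trait"
        y = y.to_numpy(dtype=float)
    else:
        y = np.asarray(y, dtype=float)
        name = "trait"
        if individuals is None:
            raise ValueError("individuals mapping required for array input")
    individuals = [str(s) for s in individuals]
    ids = list(dict.fromkeys(individuals))
    K = ensure_psd(kernel.align(ids))
    idx = {s: i for i, s in enumerate(ids)}
    zmap = np.array([idx[s] for s in individuals])
    m_obs = y.size
    n = len(ids)
    counts = np.bincount(zmap, minlength=n).astype(float)
    if not np.all(counts == counts[0]):
        raise ValueError("unbalanced genotype replication is not supported; "
                         "aggregate or correct phenotypes first")
    c = float(counts[0])
    if (~np.isnan(y)).sum() < 2:
        raise ValueError("fewer than 2 non-missing records")

    d, U = np.linalg.eigh(K.values)
    d = np.clip(d, 1e-10, None)
    if X is None:
        X = np.ones((m_obs, 1))
    X = np.asarray(X, dtype=float)
    p = X.shape[1]

    has_block = block is not None
    if has_block:
        blk_codes, blk_levels = pd.factorize(np.asarray(block))
        nb = len(blk_levels)
        blk_counts = np.bincount(blk_codes, minlength=nb).astype(float)

    varp = float(np.nanvar(y, ddof=1))
    nu_g = float(config.nu_a) if config.nu_a is not None else 3.0
    nu_e = float(config.nu_e) if config.nu_e is not None else 3.0
    # scales chosen so the prior mean equals the requested variance fraction
    nuSg = (nu_g - 2.0) * config.s_a_frac * varp
    nuSe = (nu_e - 2.0) * config.s_e_frac * varp
    nuSb = 0.1 * varp

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x0417]))
    miss = np.isnan(y)
    sigma_g2 = config.s_a_frac * varp
    sigma_e2 = config.s_e_frac * varp
    sigma_b2 = 0.1 * varp
    beta = np.zeros(p)
    beta[0] = np.nanmean(y) if (X[:, 0] == 1).all() else 0.0
    g = np.zeros(n)
    b = np.zeros(nb) if has_block else None
    yc = np.where(miss, np.nanmean(y), y)

    XtXi = np.linalg.inv(X.T @ X)
    Lxb = np.linalg.cholesky(XtXi)

    S = config.n_retained
    out = {
        "trait_names": [str(name)],
        "ids": ids,
        "Sigma_a": np.empty((S, 1, 1)),
        "Sigma_e": np.empty((S, 1, 1)),
        "sigma_b2": np.empty(S) if has_block else None,
        "beta": np.empty((S, p, 1)),
        "deviance": np.empty(S),
        "kernel_kind": kernel.kind,
        "n_obs_cells": int((~miss).sum()),
    }
    gebv_sum = np.zeros(n)
    mu_sum = np.zeros(m_obs)
    se_sum = 0.0
    k_out = 0

    for it in range(config.n_iter):
        fixed = X @ beta
        blk_part = b[blk_codes] if has_block else 0.0
        mu = fixed + g[zmap] + blk_part
        yc = np.where(miss, mu + np.sqrt(sigma_e2) *
                      rng.standard_normal(m_obs), y)

        # fixed effects
        r = yc - g[zmap] - blk_part
        bhat = XtXi @ (X.T @ r)
        beta = bhat + np.sqrt(sigma_e2) * (Lxb @ rng.standard_normal(p))

        # genetic values in the kernel eigenbasis (balanced: Z'Z = c I)
        r = yc - X @ beta - blk_part
        zr = np.zeros(n)
        np.add.at(zr, zmap, r)
        rt = U.T @ zr
        post_var = 1.0 / (c / sigma_e2 + 1.0 / (d * sigma_g2))
        gamma = post_var * rt / sigma_e2 + \
            np.sqrt(post_var) * rng.standard_normal(n)
        g = U @ gamma

        if has_block:
            r = yc - X @ beta - g[zmap]
            wr = np.bincount(blk_codes, weights=r, minlength=nb)
            pv = 1.0 / (blk_counts / sigma_e2 + 1.0 / sigma_b2)
            b = pv * wr / sigma_e2 + np.sqrt(pv) * rng.standard_normal(nb)
            sigma_b2 = float(stats.invgamma.rvs(
                (3.0 + nb) / 2.0, scale=(nuSb + b @ b) / 2.0,
                random_state=rng))

        quad_g = float(gamma @ (gamma / d))
        sigma_g2 = float(stats.invgamma.rvs(
            (nu_g + n) / 2.0, scale=(nuSg + quad_g) / 2.0, random_state=rng))
        resid = yc - X @ beta - g[zmap] - (b[blk_codes] if has_block else 0.0)
        sigma_e2 = float(stats.invgamma.rvs(
            (nu_e + m_obs) / 2.0, scale=(nuSe + resid @ resid) / 2.0,
            random_state=rng))

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            out["Sigma_a"][k_out] = sigma_g2
            out["Sigma_e"][k_out] = sigma_e2
            out["beta"][k_out, :, 0] = beta
            if has_block:
                out["sigma_b2"][k_out] = sigma_b2
            mu = X @ beta + g[zmap] + (b[blk_codes] if has_block else 0.0)
            out["deviance"][k_out] = gaussian_deviance(
                y[~miss, None], mu[~miss, None], [[sigma_e2]])
            gebv_sum += g
            mu_sum += mu
            se_sum += sigma_e2
            k_out += 1

    out["gebv_mean"] = (gebv_sum / k_out)[:, None]
    out["deviance_at_mean"] = gaussian_deviance(
        y[~miss, None], (mu_sum / k_out)[~miss, None], [[se_sum / k_out]])
    return out


def compute_dic(samples: dict) -> tuple[float, float]:
    """(DIC, pD) from the stored conditional deviances.

    DIC = 2 * mean(D) - D(posterior mean); pD = mean(D) - D(posterior mean).
    """
    dbar = float(samples["deviance"].mean())
    dhat = float(samples["deviance_at_mean"])
    return 2.0 * dbar - dhat, dbar - dhat


def summarize_posterior(samples: dict, min_samples: int = 200,
                        ci: float = 0.95) -> PosteriorSummary:
    """Sample-wise h2 and r_G summaries, GEBVs, DIC, ESS diagnostics."""
    Sa = samples["Sigma_a"]
    Se = samples["Sigma_e"]
    S, t, _ = Sa.shape
    if S < min_samples:
        raise ValueError(f"only {S} retained samples (< {min_samples}); "
                         "lengthen the chain")
    va = np.einsum("sii->si", Sa)
    ve = np.einsum("sii->si", Se)
    h2 = va / (va + ve)
    sd_a = np.sqrt(va)
    rG = Sa / (sd_a[:, :, None] * sd_a[:, None, :])
    lo, hi = (1 - ci) / 2 * 100, (1 + ci) / 2 * 100
    dic, p_d = compute_dic(samples)
    ess = np.array([effective_sample_size(h2[:, j]) for j in range(t)])
    gebv = pd.DataFrame(samples["gebv_mean"], index=samples["ids"],
                        columns=samples["trait_names"])
    return PosteriorSummary(
        trait_names=list(samples["trait_names"]),
        Sigma_a_mean=Sa.mean(axis=0), Sigma_a_sd=Sa.std(axis=0, ddof=1),
        Sigma_e_mean=Se.mean(axis=0), Sigma_e_sd=Se.std(axis=0, ddof=1),
        h2_mean=h2.mean(axis=0), h2_sd=h2.std(axis=0, ddof=1),
        h2_ci=np.percentile(h2, [lo, hi], axis=0).T,
        rG_mean=rG.mean(axis=0), rG_sd=rG.std(axis=0, ddof=1),
        rG_ci=np.moveaxis(np.percentile(rG, [lo, hi], axis=0), 0, -1),
        gebv=gebv, dic=dic, p_d=p_d, ess_h2=ess,
        extra={"kernel_kind": samples.get("kernel_kind")},
    )


def correct_phenotypes(pheno, factors: list[str] | None = None,
                       mode: str = "residual_plus_intercept",
                       genotype_col: str | None = None) -> pd.DataFrame:
    """Pre-correct phenotypes for design effects by per-trait OLS.

    ``residual_plus_intercept`` fits y = Xb + e on the declared factors and
    returns intercept + residual per observation, averaged to one record
    per genotype.  ``genotype_blues`` additionally fits a genotype factor
    and returns its effects re-centered on the grand mean (best linear
    unbiased estimates under the fixed-genotype model).
    """
    df = pheno.data
    factors = list(factors) if factors is not None else list(pheno.factor_cols)
    if mode not in ("residual_plus_intercept", "genotype_blues"):
        raise ValueError(f"unknown mode {mode!r}")
    gcol = genotype_col or pheno.id_col
    ids_order = list(dict.fromkeys(df[gcol].astype(str)))

    out = {}
    for trait in pheno.trait_cols:
        yfull = df[trait].to_numpy(dtype=float)
        ok = ~np.isnan(yfull)
        if ok.sum() == 0:
            warnings.warn(f"trait {trait!r} entirely missing; skipped")
            continue
        sub = df.loc[ok]
        y = yfull[ok]
        design_cols = list(factors)
        if mode == "genotype_blues":
            design_cols = design_cols + [gcol]
        parts = [pd.Series(1.0, index=sub.index, name="intercept")]
        col_names = ["intercept"]
        for f in design_cols:
            dummies = pd.get_dummies(sub[f].astype(str), prefix=f,
                                     drop_first=True, dtype=float)
            parts.append(dummies)
            col_names.extend(dummies.columns)
        Xd = pd.concat(parts, axis=1).to_numpy(dtype=float)
        coef, _, rank, _ = np.linalg.lstsq(Xd, y, rcond=None)
        if rank < Xd.shape[1]:
            from scipy.linalg import qr

            _, _, piv = qr(Xd, pivoting=True, mode="economic")
            aliased = [col_names[j] for j in piv[rank:]]
            raise ValueError(
                f"rank-deficient design for trait {trait!r}; aliased "
                f"columns: {aliased[:5]}")
        if mode == "residual_plus_intercept":
            resid = y - Xd @ coef
            vals = coef[0] + resid
            s = pd.Series(vals, index=sub[gcol].astype(str))
            out[trait] = s.groupby(level=0).mean()
        else:
            # genotype effects: reference level absorbed in the intercept
            levels = sorted(set(sub[gcol].astype(str)))
            eff = {levels[0]: 0.0}
            for name_, c in zip(col_names, coef):
                if name_.startswith(f"{gcol}_"):
                    eff[name_[len(gcol) + 1:]] = c
            blues = pd.Series(eff)
            blues = blues - blues.mean() + y.mean()
            out[trait] = blues

    res = pd.DataFrame(out)
    return res.reindex([i for i in ids_order if i in res.index])
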