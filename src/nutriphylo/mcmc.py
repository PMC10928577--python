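"""Bayesian phylogenetic mixed models by Gibbs sampling.

The model for a species-level trait y (one row per observation) is

    y = X b + Z_p u_species + Z_s u_study [+ Z_o u_obs] + e

with u_species ~ N(0, s2_phylo * C) for the (unit-diagonal-scaled) Brownian
tip covariance C of the phylogeny, u_study ~ N(0, s2_study * I),
u_obs ~ N(0, s2_obs * I), e ~ N(0, s2_resid * I). Fixed effects get a
N(0, V_fixed) prior; each variance gets the univariate inverse-Wishart
prior with parameters (V, nu), i.e. inverse-gamma(shape nu/2, scale nu*V/2).
All full conditionals are conjugate, so the sampler is a plain Gibbs scheme.

Pagel's lambda is computed per retained sample as the phylogenetic fraction
of variance, s2_phylo / (s2_phylo + s2_resid) — the study (design) variance
is excluded from the denominator by default, with an option to include it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg

from .phylo import PhyloCovariance, gelman_rubin, hpd_interval, vcv_from_tree


@dataclass(frozen=True)
class VariancePrior:
    """Univariate inverse-Wishart (V, nu) = inverse-gamma(nu/2, nu*V/2)."""

    V: float = 1.0
    nu: float = 0.02

    def __post_init__(self) -> None:
        if self.V <= 0 or self.nu <= 0:
            raise ValueError("V and nu must be positive")


@dataclass(frozen=True)
class McmcConfig:
    """Chain settings and priors for the phylogenetic mixed model."""

    n_iter: int = 20000
    burn_in: int = 2000
    thin: int = 20
    fixed_prior_variance: float = 1.0
    species_prior: VariancePrior = field(default_factory=VariancePrior)
    study_prior: VariancePrior = field(default_factory=VariancePrior)
    observation_prior: VariancePrior = field(
        default_factory=lambda: VariancePrior(1.0, 0.002)
    )
    residual_prior: VariancePrior = field(
        default_factory=lambda: VariancePrior(1.0, 0.002)
    )
    n_chains: int = 2
    seed: int = 0
    lambda_includes_study: bool = False

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.fixed_prior_variance <= 0:
            raise ValueError("fixed_prior_variance must be positive")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class LambdaResult:
    """Posterior summary of the phylogenetic mixed model."""

    lambda_mean: float
    lambda_hpd: tuple[float, float]
    lambda_samples: np.ndarray
    chains: list[dict[str, np.ndarray]]
    rhat: dict[str, float | None]
    autocorr_lag1: dict[str, float]
    converged: bool | None
    notes: list[str]
    config: McmcConfig

    @property
    def n_retained_per_chain(self) -> int:
        return len(self.chains[0]["lambda"])


@dataclass
class SlopeResult:
    """Posterior summary of a fixed-effect slope."""

    slope_mean: float
    slope_hpd: tuple[float, float]
    slope_samples: np.ndarray
    lambda_result: LambdaResult


def _draw_inv_gamma(rng, shape: float, scale: float) -> float:
    return scale / rng.gamma(shape)


def _index_factor(values) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(pd.Series(values), sort=True)
    return codes.astype(int), len(uniques)


def _gibbs_chain(
    y: np.ndarray,
    X: np.ndarray | None,
    species_idx: np.ndarray | None,
    Cinv: np.ndarray | None,
    study_idx: np.ndarray | None,
    use_obs: bool,
    config: McmcConfig,
    seed: int,
) -> dict[str, np.ndarray]:
    """One Gibbs chain; returns retained samples of every component."""
    rng = np.random.default_rng(seed)
    n = len(y)
    p = 0 if X is None else X.shape[1]

    beta = np.zeros(p)
    u_p = np.zeros(0 if Cinv is None else len(Cinv))
    u_s = np.zeros(0)
    n_study = 0
    if study_idx is not None:
        n_study = int(study_idx.max()) + 1
        u_s = np.zeros(n_study)
    u_o = np.zeros(n if use_obs else 0)
    s2_p = s2_s = s2_o = 1.0
    s2_e = 1.0

    if species_idx is not None:
        counts_p = np.bincount(species_idx, minlength=len(Cinv)).astype(float)
    if study_idx is not None:
        counts_s = np.bincount(study_idx, minlength=n_study).astype(float)

    keep = config.n_retained
    out = {
        k: np.empty(keep)
        for k in ("sigma2_phylo", "sigma2_study", "sigma2_obs", "sigma2_resid", "lambda")
    }
    out_beta = np.empty((keep, p))
    j = 0

    for it in range(1, config.n_iter + 1):
        # fixed effects
        if p:
            r = y.copy()
            if species_idx is not None:
                r -= u_p[species_idx]
            if study_idx is not None:
                r -= u_s[study_idx]
            if use_obs:
                r -= u_o
            prec = X.T @ X / s2_e + np.eye(p) / config.fixed_prior_variance
            L = np.linalg.cholesky(prec)
            mean = linalg.cho_solve((L, True), X.T @ r / s2_e)
            beta = mean + linalg.solve_triangular(
                L.T, rng.standard_normal(p), lower=False
            )

        fixed_part = X @ beta if p else 0.0

        # species (phylogenetic) effects
        if species_idx is not None:
            r = y - fixed_part
            if study_idx is not None:
                r -= u_s[study_idx]
            if use_obs:
                r -= u_o
            prec = Cinv / s2_p + np.diag(counts_p / s2_e)
            L = np.linalg.cholesky(prec)
            rhs = np.bincount(species_idx, weights=r, minlength=len(Cinv)) / s2_e
            mean = linalg.cho_solve((L, True), rhs)
            u_p = mean + linalg.solve_triangular(
                L.T, rng.standard_normal(len(Cinv)), lower=False
            )
            q = len(Cinv)
            quad = float(u_p @ Cinv @ u_p)
            pr = config.species_prior
            s2_p = _draw_inv_gamma(rng, (pr.nu + q) / 2, (pr.nu * pr.V + quad) / 2)

        # study effects (iid)
        if study_idx is not None:
            r = y - fixed_part
            if species_idx is not None:
                r -= u_p[species_idx]
            if use_obs:
                r -= u_o
            var = 1.0 / (counts_s / s2_e + 1.0 / s2_s)
            mean = var * np.bincount(study_idx, weights=r, minlength=n_study) / s2_e
            u_s = mean + np.sqrt(var) * rng.standard_normal(n_study)
            pr = config.study_prior
            s2_s = _draw_inv_gamma(
                rng, (pr.nu + n_study) / 2, (pr.nu * pr.V + float(u_s @ u_s)) / 2
            )

        # observation-level effects (iid, one per row)
        if use_obs:
            r = y - fixed_part
            if species_idx is not None:
                r -= u_p[species_idx]
            if study_idx is not None:
                r -= u_s[study_idx]
            var = 1.0 / (1.0 / s2_e + 1.0 / s2_o)
            mean = var * r / s2_e
            u_o = mean + np.sqrt(var) * rng.standard_normal(n)
            pr = config.observation_prior
            s2_o = _draw_inv_gamma(
                rng, (pr.nu + n) / 2, (pr.nu * pr.V + float(u_o @ u_o)) / 2
            )

        # residual variance
        e = y - fixed_part
        if species_idx is not None:
            e -= u_p[species_idx]
        if study_idx is not None:
            e -= u_s[study_idx]
        if use_obs:
            e -= u_o
        pr = config.residual_prior
        s2_e = _draw_inv_gamma(rng, (pr.nu + n) / 2, (pr.nu * pr.V + float(e @ e)) / 2)

        if it > config.burn_in and (it - config.burn_in) % config.thin == 0:
            out["sigma2_phylo"][j] = s2_p if species_idx is not None else np.nan
            out["sigma2_study"][j] = s2_s if study_idx is not None else np.nan
            out["sigma2_obs"][j] = s2_o if use_obs else np.nan
            out["sigma2_resid"][j] = s2_e
            denom = s2_p + s2_e
            if config.lambda_includes_study and study_idx is not None:
                denom += s2_s
            out["lambda"][j] = s2_p / denom if species_idx is not None else np.nan
            out_beta[j] = beta
            j += 1
    out["beta"] = out_beta
    return out


def _lag1_autocorr(x: np.ndarray) -> float:
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0:
        return 0.0
    return float(x[:-1] @ x[1:]) / denom


def _prepare_inputs(
    traits: pd.DataFrame,
    tree: dendropy.Tree,
    trait: str | None,
    sex: str | None,
):
    df = traits.copy()
    if trait is not None and "trait" in df.columns:
        df = df[df["trait"] == trait]
    if sex is not None and "sex" in df.columns:
        df = df[df["sex"] == sex]
    if len(df) < 2:
        raise ValueError("need at least 2 observations")
    cov = vcv_from_tree(tree)
    offenders = sorted(set(df["species"]) - set(cov.labels))
    if offenders:
        raise ValueError(f"species absent from the tree: {offenders}")
    return df.reset_index(drop=True), cov


def _scaled_subcov(cov: PhyloCovariance, species: list[str]) -> np.ndarray:
    C = cov.submatrix(species).matrix
    C = C / np.max(np.diag(C))  # unit max diagonal: priors comparable across trees
    return C


def fit_phylo_mixed_model(
    traits: pd.DataFrame,
    tree: dendropy.Tree,
    config: McmcConfig | None = None,
    random_terms: tuple[str, ...] = ("species", "study"),
    trait: str | None = None,
    sex: str | None = None,
    predictor: str | None = None,
    include_intercept: bool = True,
) -> LambdaResult:
    """Fit the Gibbs-sampled phylogenetic mixed model and summarise lambda.

    ``traits`` needs columns species and value (plus study/sex/trait where
    used); ``trait``/``sex`` filter long tables. ``predictor`` names an
    extra column entering as a fixed-effect slope. A requested study term is
    dropped (with a note) when the table has fewer than two study levels.
    Chains are seeded deterministically from ``config.seed``.
    """
    config = config or McmcConfig()
    df, cov = _prepare_inputs(traits, tree, trait, sex)
    y = df["value"].to_numpy(float)
    notes: list[str] = []

    species_idx = Cinv = None
    if "species" in random_terms:
        species_idx, _ = _index_factor(df["species"])
        species_levels = sorted(df["species"].unique())
        C = _scaled_subcov(cov, species_levels)
        eigmin = float(np.linalg.eigvalsh(C).min())
        if eigmin < -1e-8:
            raise ValueError("phylogenetic covariance matrix is not PSD")
        Cinv = np.linalg.inv(C + 1e-10 * np.eye(len(C)))

    study_idx = None
    if "study" in random_terms:
        if "study" not in df.columns or df["study"].nunique() < 2:
            notes.append("study term dropped: fewer than two study levels")
        else:
            study_idx, _ = _index_factor(df["study"])

    use_obs = "observation" in random_terms

    cols = []
    if include_intercept:
        cols.append(np.ones(len(df)))
    if predictor is not None:
        x = df[predictor].to_numpy(float)
        if np.ptp(x) < 1e-12:
            raise ValueError(f"predictor '{predictor}' is constant; slope unidentifiable")
        cols.append(x)
    X = np.column_stack(cols) if cols else None

    chains = [
        _gibbs_chain(
            y, X, species_idx, Cinv, study_idx, use_obs, config, config.seed + k
        )
        for k in range(config.n_chains)
    ]

    lam_all = np.concatenate([c["lambda"] for c in chains])
    if species_idx is not None:
        lam_mean = float(lam_all.mean())
        lam_hpd = hpd_interval(lam_all, 0.95)
    else:
        lam_mean, lam_hpd = float("nan"), (float("nan"), float("nan"))

    tracked = ["lambda", "sigma2_resid"]
    if species_idx is not None:
        tracked.append("sigma2_phylo")
    if study_idx is not None:
        tracked.append("sigma2_study")
    rhat: dict[str, float | None] = {}
    for k in tracked:
        if config.n_chains >= 2:
            rhat[k] = gelman_rubin([c[k] for c in chains])
        else:
            rhat[k] = None
    autocorr = {k: float(np.mean([_lag1_autocorr(c[k]) for c in chains])) for k in tracked}
    converged = None
    if config.n_chains >= 2:
        converged = all(v is not None and v < 1.1 for v in rhat.values())
        if not converged:
            notes.append(f"convergence flag: R-hat >= 1.1 for some component: {rhat}")

    return LambdaResult(
        lambda_mean=lam_mean,
        lambda_hpd=lam_hpd,
        lambda_samples=lam_all,
        chains=chains,
        rhat=rhat,
        autocorr_lag1=autocorr,
        converged=converged,
        notes=notes,
        config=config,
    )


def prior_sensitivity(
    traits: pd.DataFrame,
    tree: dendropy.Tree,
    nu_values=(1e-6, 0.002, 0.02, 0.2),
    config: McmcConfig | None = None,
    **fit_kwargs,
) -> pd.DataFrame:
    """Refit the mixed model across a grid of nu values for the G-side priors.

    Returns one row per nu with the posterior mean of lambda and its 95% HPD.
    A zero-variance trait vector is flagged degenerate instead of crashing.
    """
    config = config or McmcConfig()
    rows = []
    y = traits["value"].to_numpy(float)
    degenerate = np.ptp(y) < 1e-12
    for nu in nu_values:
        if degenerate:
            rows.append(
                {"nu": nu, "lambda_mean": np.nan, "hpd_low": np.nan,
                 "hpd_high": np.nan, "flag": "degenerate: zero trait variance"}
            )
            continue
        cfg = replace(
            config,
            species_prior=replace(config.species_prior, nu=nu),
            study_prior=replace(config.study_prior, nu=nu),
        )
        res = fit_phylo_mixed_model(traits, tree, config=cfg, **fit_kwargs)
        rows.append(
            {"nu": nu, "lambda_mean": res.lambda_mean,
             "hpd_low": res.lambda_hpd[0], "hpd_high": res.lambda_hpd[1],
             "flag": ""}
        )
    return pd.DataFrame(rows)


def regress_optimal_on_selfregulated(
    table: pd.DataFrame,
    tree: dendropy.Tree,
    config: McmcConfig | None = None,
    response_trait: str = "optimal_pc_ratio",
    predictor_trait: str = "self_regulated_pc_ratio",
) -> SlopeResult:
    """Regress the optimal P:C ratio on the self-regulated P:C ratio.

    Pairs the two traits by (species, study, sex, within-group occurrence),
    then fits the mixed model with the predictor as a fixed slope and random
    effects for study, species (phylogenetic) and observation (row-level,
    prior V=1, nu=0.002 by default). Returns the posterior mean and 95% HPD
    of the slope.
    """
    config = config or McmcConfig()
    keys = [k for k in ("species", "study", "sex") if k in table.columns]
    resp = table[table["trait"] == response_trait].copy()
    pred = table[table["trait"] == predictor_trait].copy()
    if resp.empty or pred.empty:
        raise ValueError("both response and predictor traits must be present")
    for df in (resp, pred):
        df["_occ"] = df.groupby(keys).cumcount()
    merged = resp.merge(
        pred[keys + ["_occ", "value"]],
        on=keys + ["_occ"],
        suffixes=("", "_pred"),
    )
    if merged["species"].nunique() < 4:
        raise ValueError("need both traits for at least 4 species")
    data = merged.rename(columns={"value_pred": "predictor"})[
        keys + ["value", "predictor"]
    ]
    res = fit_phylo_mixed_model(
        data,
        tree,
        config=config,
        random_terms=("species", "study", "observation"),
        predictor="predictor",
    )
    slope = np.concatenate([c["beta"][:, 1] for c in res.chains])
    return SlopeResult(
        slope_mean=float(slope.mean()),
        slope_hpd=hpd_interval(slope, 0.95),
        slope_samples=slope,
        lambda_result=res,
    )
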