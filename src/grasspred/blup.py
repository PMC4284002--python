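"""Trait BLUPs, variance components, heritability and genetic correlations.

Replicated field-trial observations (randomized complete block design:
one replicate per genotype per block) are analysed with the mixed model

    y = mu + block (fixed) + genotype (random) + e

Variance components come from REML profiled over the ratio
``delta = s2_E / s2_G`` on the spectrum of the genotype design (see
:mod:`grasspred._reml`); genotype BLUPs solve the mixed-model equations at
the optimum.  Broad-sense heritability is reported on a clone-mean basis,

    H2 = s2_G / (s2_G + s2_E / n_reps)

with ``n_reps`` the harmonic-mean replicate count.

Genetic correlations between traits are available through two routes used
interchangeably in practice: rescaling the phenotypic correlation by
heritabilities (``r_G = r_P / sqrt(H2_x H2_y)``), or method-of-moments
genetic covariance from clone-mean cross-products for traits measured in
the same design.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._reml import fit_variance_ratio, gls_effects
from .exceptions import DataError, InvalidParameterError

__all__ = ["TraitBlupModel", "TraitBlupResults", "estimate_blups",
           "phenotypic_correlation", "genetic_correlation_h2",
           "genetic_correlation_cov", "write_blup_tsv", "read_blup_tsv"]


class TraitBlupModel:
    """Mixed model for one trait's replicated observations.

    Parameters
    ----------
    observations
        Long table with columns ``genotype_id``, ``block``, ``value`` (a
        ``trait`` column, if present, must be single-valued).
    trait
        Trait name recorded on the results.
    """

    def __init__(self, observations: pd.DataFrame, trait: str | None = None):
        obs = observations.copy()
        if "trait" in obs.columns:
            names = obs["trait"].unique()
            if trait is None:
                if len(names) != 1:
                    raise DataError(
                        f"observations contain several traits {list(names)}; "
                        "pass trait=")
                trait = str(names[0])
            else:
                obs = obs[obs["trait"] == trait]
        if trait is None:
            trait = "trait"
        required = {"genotype_id", "block", "value"}
        if not required.issubset(obs.columns):
            raise DataError(f"observations need columns {sorted(required)}")
        obs = obs.dropna(subset=["value"]).reset_index(drop=True)
        self.trait = trait
        self.observations = obs
        self.genotypes = sorted(obs["genotype_id"].astype(str).unique())
        self.blocks = sorted(obs["block"].astype(str).unique())
        if len(self.genotypes) < 2:
            raise DataError("need at least 2 genotypes with observations")
        if len(self.blocks) == 1 and len(obs) == len(self.genotypes):
            raise DataError(
                "single block with a single replicate per genotype: "
                "variance components are inestimable")

    def _design(self):
        obs = self.observations
        g_idx = pd.Categorical(obs["genotype_id"].astype(str),
                               categories=self.genotypes).codes
        b_idx = pd.Categorical(obs["block"].astype(str),
                               categories=self.blocks).codes
        n = len(obs)
        X = np.ones((n, len(self.blocks)))
        # intercept + block contrasts (first block is the reference)
        for j in range(1, len(self.blocks)):
            X[:, j] = (b_idx == j).astype(float)
        Z = np.zeros((n, len(self.genotypes)))
        Z[np.arange(n), g_idx] = 1.0
        return X, Z

    def fit(self) -> "TraitBlupResults":
        X, Z = self._design()
        y = self.observations["value"].to_numpy(dtype=float)
        K = Z @ Z.T
        vc, _ = fit_variance_ratio(y, X, K)
        beta, hinv_resid = gls_effects(y, X, K, vc.delta)
        u = Z.T @ hinv_resid  # BLUPs of genotype effects
        reps = self.observations.groupby("genotype_id").size()
        n_reps = stats.hmean(reps.to_numpy())
        h2 = vc.sigma2_g / (vc.sigma2_g + vc.sigma2_e / n_reps) \
            if vc.sigma2_g > 0 else 0.0
        return TraitBlupResults(
            trait=self.trait,
            blups=pd.Series(u, index=pd.Index(self.genotypes,
                                              name="genotype_id"),
                            name=self.trait),
            sigma2_g=vc.sigma2_g,
            sigma2_e=vc.sigma2_e,
            h2=float(h2),
            n_reps=float(n_reps),
            fixed_effects=pd.Series(
                beta, index=["intercept"] + [f"block[{b}]"
                                             for b in self.blocks[1:]]),
            loglik=vc.loglik,
            model=self,
        )


@dataclass
class TraitBlupResults:
    """Fitted variance components and genotype BLUPs for one trait."""

    trait: str
    blups: pd.Series
    sigma2_g: float
    sigma2_e: float
    h2: float
    n_reps: float
    fixed_effects: pd.Series
    loglik: float
    model: TraitBlupModel | None = None

    def summary(self) -> str:
        lines = [
            f"Trait BLUP results: {self.trait}",
            f"  genotypes            {len(self.blups)}",
            f"  harmonic-mean reps   {self.n_reps:.2f}",
            f"  sigma2_G             {self.sigma2_g:.4f}",
            f"  sigma2_E             {self.sigma2_e:.4f}",
            f"  H2 (clone-mean)      {self.h2:.3f}",
            f"  REML log-likelihood  {self.loglik:.3f}",
        ]
        return "\n".join(lines)


def estimate_blups(observations: pd.DataFrame,
                   trait: str | None = None) -> TraitBlupResults:
    """Convenience wrapper: fit :class:`TraitBlupModel` on ``observations``."""
    return TraitBlupModel(observations, trait=trait).fit()


def phenotypic_correlation(x: pd.Series | TraitBlupResults,
                           y: pd.Series | TraitBlupResults) -> float:
    """Pearson correlation of two per-genotype trait vectors on shared ids."""
    xs = x.blups if isinstance(x, TraitBlupResults) else x
    ys = y.blups if isinstance(y, TraitBlupResults) else y
    shared = xs.index.intersection(ys.index)
    if len(shared) < 3:
        raise DataError("fewer than 3 shared genotypes")
    a = xs.loc[shared].to_numpy(dtype=float)
    b = ys.loc[shared].to_numpy(dtype=float)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def genetic_correlation_h2(r_p: float, h2_x: float, h2_y: float) -> float:
    """Genetic correlation from the phenotypic one: r_P / sqrt(H2_x H2_y).

    Values outside [-1, 1] are clipped with a warning (never silently).
    """
    if h2_x <= 0 or h2_y <= 0:
        raise InvalidParameterError("heritabilities must be positive")
    r_g = r_p / np.sqrt(h2_x * h2_y)
    if abs(r_g) > 1:
        warnings.warn(
            f"genetic correlation {r_g:.3f} clipped to [-1, 1]",
            stacklevel=2)
        r_g = float(np.clip(r_g, -1.0, 1.0))
    return float(r_g)


def genetic_correlation_cov(observations_x: pd.DataFrame,
                            observations_y: pd.DataFrame) -> float:
    """Genetic correlation from method-of-moments genetic (co)variances.

    Both traits must be measured on the same genotypes in the same design.
    The genetic covariance is the covariance of clone means minus the
    residual cross-covariance divided by the replicate count; variances are
    estimated the same way.  Returns NaN with a warning when either genetic
    variance estimate is non-positive.
    """
    def _prep(obs):
        obs = obs.dropna(subset=["value"])
        return obs.set_index(["genotype_id", "block"])["value"]

    sx = _prep(observations_x)
    sy = _prep(observations_y)
    shared = sx.index.intersection(sy.index)
    if len(shared) < 4:
        raise DataError("too few shared genotype x block observations")
    df = pd.DataFrame({"x": sx.loc[shared], "y": sy.loc[shared]}).reset_index()
    means = df.groupby("genotype_id")[["x", "y"]].mean()
    counts = df.groupby("genotype_id").size()
    if len(means) < 3:
        raise DataError("fewer than 3 shared genotypes")
    n_reps = stats.hmean(counts.to_numpy())
    # within-genotype residual (co)variance
    resid = df.set_index("genotype_id")[["x", "y"]] - means
    n_resid_df = len(df) - len(means)
    if n_resid_df <= 0:
        raise DataError("no residual degrees of freedom (single replicate)")
    r = resid.to_numpy()
    cov_e = r.T @ r / n_resid_df
    cov_means = np.cov(means.to_numpy().T, ddof=1)
    cov_g = cov_means - cov_e / n_reps
    var_gx, var_gy, cov_gxy = cov_g[0, 0], cov_g[1, 1], cov_g[0, 1]
    if var_gx <= 0 or var_gy <= 0:
        warnings.warn(
            "non-positive genetic variance estimate; genetic correlation "
            "undefined", stacklevel=2)
        return float("nan")
    r_g = cov_gxy / np.sqrt(var_gx * var_gy)
    if abs(r_g) > 1:
        warnings.warn(
            f"genetic correlation {r_g:.3f} clipped to [-1, 1]", stacklevel=2)
        r_g = float(np.clip(r_g, -1.0, 1.0))
    return float(r_g)


def write_blup_tsv(results: TraitBlupResults, path, sidecar: bool = True) -> None:
    df = results.blups.rename("blup").reset_index()
    df.to_csv(path, sep="\t", index=False)
    if sidecar:
        meta = {"trait": results.trait, "sigma2_g": results.sigma2_g,
                "sigma2_e": results.sigma2_e, "h2": results.h2,
                "n_reps": results.n_reps}
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)


def read_blup_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={"genotype_id": str})
    return df.set_index("genotype_id")["blup"]
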