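"""Mixed-linear-model association scans (EMMAX-style) and MLMM selection.

The single-locus scan fits the null model ``y = X b + u + e`` with
``u ~ N(0, s2_g K)`` once by REML, then tests every marker by generalized
least squares with the covariance held fixed at the null fit — the EMMAX
approximation.  Computation is spectral: after rotating by the eigenvectors
of ``K`` the GLS per marker reduces to a weighted simple regression, so a
scan over tens of thousands of markers is a handful of matrix products.

Test statistics use the F/t distribution with ``n - q - 1`` residual
degrees of freedom rather than the asymptotic chi-square; at a hundred-odd
individuals this is the conservative choice and materially affects tail
p-values.

The multi-locus procedure (MLMM) alternates forward inclusion of the most
significant marker as a fixed cofactor (refitting variance components at
every step) with backward elimination, and selects the largest model whose
cofactors all pass the Bonferroni threshold ("multiple Bonferroni"
criterion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._reml import (SpectralCache, VarianceComponents, profile_delta,
                    spectral_projection)
from .blup import TraitBlupResults
from .exceptions import DataError, InvalidParameterError
from .genotypes import GenotypeTable, impute_mean
from .structure import KinshipMatrix, PCAResult, pca_genotypes

__all__ = ["EmmaxGWAS", "GWASResult", "MLMMPath", "emmax_scan", "naive_scan",
           "adjust_pvalues", "bonferroni_threshold", "mlmm_select",
           "genomic_inflation"]

_CHI2_MEDIAN = stats.chi2.ppf(0.5, 1)  # 0.4549...


def genomic_inflation(pvalues: np.ndarray) -> float:
    """Genomic inflation factor: median chi-square over its null median."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        return float("nan")
    chi2 = stats.chi2.isf(np.clip(p, 1e-300, 1.0), 1)
    return float(np.median(chi2) / _CHI2_MEDIAN)


@dataclass
class GWASResult:
    """Per-marker association results plus model-level diagnostics."""

    table: pd.DataFrame            # locus, chrom, pos, maf, n, beta, se, p
    method: str                    # "emmax" | "naive"
    delta: float | None            # s2_e / s2_g at the null fit
    lambda_gc: float
    covariates: list[str] = field(default_factory=list)
    n_individuals: int = 0

    @property
    def pvalues(self) -> pd.Series:
        return self.table.set_index("locus")["p"]

    def significant(self, threshold: float) -> pd.DataFrame:
        t = self.table
        return t[t["p"] < threshold].sort_values("p").reset_index(drop=True)

    def summary(self) -> str:
        tested = int(self.table["p"].notna().sum())
        lines = [
            f"GWAS scan ({self.method})",
            f"  individuals     {self.n_individuals}",
            f"  markers tested  {tested} / {len(self.table)}",
            f"  covariates      {', '.join(self.covariates) or 'intercept'}",
            f"  lambda_GC       {self.lambda_gc:.3f}",
        ]
        if self.delta is not None:
            lines.insert(4, f"  delta (s2e/s2g) {self.delta:.4g}")
        return "\n".join(lines)


def _align_phenotype(y, gt: GenotypeTable) -> tuple[np.ndarray, GenotypeTable]:
    """Restrict genotypes to phenotyped individuals, preserving gt order."""
    if isinstance(y, TraitBlupResults):
        y = y.blups
    if not isinstance(y, pd.Series):
        y = pd.Series(np.asarray(y, dtype=float), index=gt.ids)
    missing = [g for g in y.index if g not in set(gt.ids)]
    if missing:
        raise DataError(f"phenotyped ids absent from genotypes: {missing[:5]}"
                        + ("..." if len(missing) > 5 else ""))
    ids = [g for g in gt.ids if g in set(y.index)]
    if len(ids) < len(gt.ids):
        gt = gt.subset(individuals=ids)
    return y.loc[ids].to_numpy(dtype=float), gt


class EmmaxGWAS:
    """Mixed-model association scan for one trait.

    Parameters
    ----------
    y
        Per-genotype trait values (BLUPs), as a Series indexed by genotype
        id or a :class:`~grasspred.blup.TraitBlupResults`.
    gt
        Genotype table; the analysis uses the individuals present in both.
    kinship
        Relatedness matrix (IBS or GRM).  Required unless ``identity=True``.
    n_pcs
        Number of leading PCA axes added as fixed covariates (the usual
        structure correction is 2).
    pca
        Optional precomputed :class:`PCAResult`; computed from ``gt`` when
        PCs are requested without one.
    covariates
        Optional extra fixed covariates, DataFrame indexed by genotype id.
    """

    def __init__(self, y, gt: GenotypeTable,
                 kinship: KinshipMatrix | None = None,
                 n_pcs: int = 0, pca: PCAResult | None = None,
                 covariates: pd.DataFrame | None = None,
                 identity: bool = False):
        self.y, self.gt = _align_phenotype(y, gt)
        self.ids = list(self.gt.ids)
        n = len(self.ids)
        if identity:
            self.K = np.eye(n)
            self._kin_method = "identity"
        else:
            if kinship is None:
                raise DataError("a kinship matrix is required (or identity=True)")
            self.K = kinship.align(self.ids)
            self._kin_method = kinship.method
        w = np.linalg.eigvalsh(self.K)
        if w.min() < -1e-6 * max(1.0, w.max()):
            raise DataError("kinship matrix is not positive semi-definite")

        cols = [np.ones(n)]
        names = ["intercept"]
        if n_pcs > 0:
            if pca is None:
                pca = pca_genotypes(self.gt, max_axes=n_pcs)
            pos = {g: i for i, g in enumerate(pca.ids)}
            missing = [g for g in self.ids if g not in pos]
            if missing:
                raise DataError(f"ids absent from PCA: {missing[:5]}")
            rows = [pos[g] for g in self.ids]
            for a in range(n_pcs):
                cols.append(pca.scores[rows, a])
                names.append(f"PC{a + 1}")
        if covariates is not None:
            cov = covariates.loc[self.ids]
            for c in cov.columns:
                cols.append(cov[c].to_numpy(dtype=float))
                names.append(str(c))
        self.X = np.column_stack(cols)
        self.covariate_names = names
        if n < self.X.shape[1] + 2:
            raise DataError("too few individuals for the covariate set")

        self.G = impute_mean(self.gt)
        self._maf = np.minimum(self.gt.alt_allele_frequency(),
                               1 - self.gt.alt_allele_frequency())
        self._n_obs = (~np.isnan(self.gt.dosage)).sum(axis=0)
        d, U = np.linalg.eigh(self.K)
        self._eig = (np.clip(d, 0.0, None), U)
        self._proj: SpectralCache | None = None
        self._null: VarianceComponents | None = None

    # -- null model ------------------------------------------------------
    def fit_null(self) -> VarianceComponents:
        """REML variance components under the no-marker null model."""
        if self._proj is None:
            self._proj = spectral_projection(self.K, self.X)
        eta = self._proj.rotate(self.y)
        self._null = profile_delta(self._proj.xi, eta)
        if self._null.delta > 1e4:
            warnings.warn(
                "variance ratio is at the boundary (negligible genetic "
                "variance); the scan degenerates to covariate-adjusted OLS",
                stacklevel=2)
        return self._null

    @property
    def null_(self) -> VarianceComponents:
        if self._null is None:
            self.fit_null()
        return self._null

    # -- scans -----------------------------------------------------------
    def _gls_scan_core(self, y: np.ndarray, G: np.ndarray, delta: float,
                       X: np.ndarray | None = None):
        """Vectorised per-marker GLS with covariance K + delta I.

        Returns (beta, se, p, tested) arrays over the columns of G.
        """
        X = self.X if X is None else X
        d, U = self._eig
        w = 1.0 / (d + delta)
        ys = U.T @ y
        Xs = U.T @ X
        Gs = U.T @ G
        Xw = Xs * w[:, None]
        A = Xs.T @ Xw
        Ainv = np.linalg.inv(A)
        # residualise y and markers against covariates in the GLS metric
        yt = ys - Xs @ (Ainv @ (Xw.T @ ys))
        Gt = Gs - Xs @ (Ainv @ (Xw.T @ Gs))
        gwg = np.einsum("ij,ij->j", Gt * w[:, None], Gt)
        gwy = Gt.T @ (w * yt)
        ywy = float(yt @ (w * yt))
        n, q = X.shape
        df = n - q - 1
        if df < 1:
            raise DataError("no residual degrees of freedom")
        tested = gwg > 1e-10 * max(1.0, float(np.max(gwg, initial=0.0)))
        beta = np.full(G.shape[1], np.nan)
        se = np.full(G.shape[1], np.nan)
        p = np.full(G.shape[1], np.nan)
        g = gwg[tested]
        b = gwy[tested] / g
        rss = np.maximum(ywy - b * gwy[tested], 0.0)
        sigma2 = rss / df
        s = np.sqrt(np.maximum(sigma2 / g, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(s > 0, b / s, np.inf)
        beta[tested] = b
        se[tested] = s
        p[tested] = np.clip(2.0 * stats.t.sf(np.abs(tstat), df), 1e-300, 1.0)
        return beta, se, p, tested

    def scan(self) -> GWASResult:
        """Test every marker against the trait under the fitted null."""
        null = self.null_
        beta, se, p, tested = self._gls_scan_core(self.y, self.G, null.delta)
        table = pd.DataFrame({
            "locus": self.gt.loci["locus"].to_numpy(),
            "chrom": self.gt.loci["chrom"].to_numpy(),
            "pos": self.gt.loci["pos"].to_numpy(),
            "maf": self._maf,
            "n": self._n_obs,
            "beta": beta,
            "se": se,
            "p": p,
            "tested": tested,
        })
        return GWASResult(
            table=table,
            method=f"emmax[{self._kin_method}]",
            delta=null.delta,
            lambda_gc=genomic_inflation(p),
            covariates=list(self.covariate_names),
            n_individuals=len(self.ids),
        )

    def test_single_marker(self, y_new: np.ndarray, locus_index: int,
                           refit: bool = True) -> tuple[float, float]:
        """(beta, p) for one marker against a replacement phenotype.

        Refits the variance ratio for ``y_new`` on the cached spectral
        projection (the covariates are unchanged), then runs the single
        GLS test — the workhorse of the perturbation power study.
        """
        y_new = np.asarray(y_new, dtype=float)
        if refit:
            if self._proj is None:
                self._proj = spectral_projection(self.K, self.X)
            vc = profile_delta(self._proj.xi, self._proj.rotate(y_new))
            delta = vc.delta
        else:
            delta = self.null_.delta
        g = self.G[:, [locus_index]]
        beta, _, p, tested = self._gls_scan_core(y_new, g, delta)
        return float(beta[0]), float(p[0]) if tested[0] else float("nan")


def emmax_scan(y, gt: GenotypeTable, kinship: KinshipMatrix,
               n_pcs: int = 2, pca: PCAResult | None = None) -> GWASResult:
    """One-call mixed-model scan with kinship and PC covariates."""
    return EmmaxGWAS(y, gt, kinship=kinship, n_pcs=n_pcs, pca=pca).scan()


def naive_scan(y, gt: GenotypeTable) -> GWASResult:
    """Simple per-marker linear regression of the trait on dosage."""
    model = EmmaxGWAS(y, gt, identity=True)
    beta, se, p, tested = model._gls_scan_core(model.y, model.G, delta=1.0)
    table = pd.DataFrame({
        "locus": model.gt.loci["locus"].to_numpy(),
        "chrom": model.gt.loci["chrom"].to_numpy(),
        "pos": model.gt.loci["pos"].to_numpy(),
        "maf": model._maf,
        "n": model._n_obs,
        "beta": beta,
        "se": se,
        "p": p,
        "tested": tested,
    })
    return GWASResult(table=table, method="naive", delta=None,
                      lambda_gc=genomic_inflation(p),
                      covariates=["intercept"],
                      n_individuals=len(model.ids))


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / m."""
    if n_tests < 1:
        raise InvalidParameterError("n_tests must be >= 1")
    if not (0 < alpha < 1):
        raise InvalidParameterError("alpha must lie in (0, 1)")
    return alpha / n_tests


def adjust_pvalues(pvals, method: str = "bh", alpha: float = 0.05):
    """Multiple-testing control.

    ``method="bonferroni"`` returns the family-wise threshold ``alpha / m``;
    ``method="bh"`` returns Benjamini-Hochberg step-up adjusted values
    (monotone, never below the raw p); ``method="storey"`` additionally
    rescales by an estimate of the null proportion pi0 on a fixed lambda
    grid.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise DataError("empty p-value input")
    if np.nanmin(p) <= 0 or np.nanmax(p) > 1:
        raise DataError("p-values must lie in (0, 1]")
    if method == "bonferroni":
        return bonferroni_threshold(alpha, p.size)
    if method == "bh":
        from statsmodels.stats.multitest import multipletests
        return multipletests(p, method="fdr_bh")[1]
    if method == "storey":
        from statsmodels.stats.multitest import multipletests
        lam = np.arange(0.05, 0.96, 0.05)
        pi0 = np.array([(p > l).mean() / (1 - l) for l in lam])
        pi0_hat = min(1.0, float(pi0[-1]) if pi0[-1] > 0 else 1.0)
        return np.minimum(multipletests(p, method="fdr_bh")[1] * pi0_hat, 1.0)
    raise InvalidParameterError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Multi-locus mixed model
# ---------------------------------------------------------------------------

@dataclass
class MLMMPath:
    """Forward-backward cofactor path and the multiple-Bonferroni choice."""

    forward_order: list[str]                 # loci in order of inclusion
    models: list[list[str]]                  # every model visited
    cofactor_pvalues: list[dict[str, float]]  # per model, aligned with models
    selected: list[str]                      # largest all-Bonferroni model
    threshold: float
    max_steps: int

    def summary(self) -> str:
        lines = [f"MLMM path ({len(self.models)} models, "
                 f"Bonferroni threshold {self.threshold:.3g})"]
        for model, pv in zip(self.models, self.cofactor_pvalues):
            tag = " <- selected" if model == self.selected else ""
            desc = ", ".join(f"{l}({pv[l]:.2g})" for l in model) or "(null)"
            lines.append(f"  [{len(model)}] {desc}{tag}")
        return "\n".join(lines)


def mlmm_select(y, gt: GenotypeTable, kinship: KinshipMatrix,
                n_pcs: int = 0, pca: PCAResult | None = None,
                max_steps: int = 9, alpha: float = 0.05) -> MLMMPath:
    """Forward-backward multi-locus mixed-model selection.

    Each forward step adds the most significant marker as a fixed cofactor
    and refits variance components; backward steps from the largest model
    drop the least significant cofactor.  The selected model is the largest
    visited model whose cofactors all pass ``alpha / m`` with ``m`` the
    number of markers scanned.
    """
    if max_steps < 1:
        raise InvalidParameterError("max_steps must be >= 1")
    base = EmmaxGWAS(y, gt, kinship=kinship, n_pcs=n_pcs, pca=pca)
    loci = list(base.gt.loci["locus"])
    loc_index = {l: i for i, l in enumerate(loci)}
    m_tested = int((base.G.std(axis=0) > 0).sum())
    threshold = bonferroni_threshold(alpha, max(m_tested, 1))

    def _fit_with(cofactors: list[str]):
        """Null fit + scan with the given cofactors as fixed effects."""
        cols = [base.X] + [base.G[:, [loc_index[l]]] for l in cofactors]
        X = np.column_stack(cols) if len(cols) > 1 else base.X
        proj = spectral_projection(base.K, X)
        vc = profile_delta(proj.xi, proj.rotate(base.y))
        return X, vc

    def _cofactor_pvalues(cofactors: list[str]) -> dict[str, float]:
        if not cofactors:
            return {}
        out = {}
        for l in cofactors:
            others = [c for c in cofactors if c != l]
            X, vc = _fit_with(others)
            g = base.G[:, [loc_index[l]]]
            _, _, p, tested = base._gls_scan_core(base.y, g, vc.delta, X=X)
            out[l] = float(p[0]) if tested[0] else float("nan")
        return out

    models: list[list[str]] = [[]]
    forward_order: list[str] = []
    cofactors: list[str] = []
    for _ in range(max_steps):
        X, vc = _fit_with(cofactors)
        mask = np.ones(len(loci), dtype=bool)
        for l in cofactors:
            mask[loc_index[l]] = False
        _, _, p, tested = base._gls_scan_core(base.y, base.G[:, mask],
                                              vc.delta, X=X)
        p = np.where(tested, p, np.nan)
        if np.all(np.isnan(p)):
            break
        best_local = int(np.nanargmin(p))
        best = str([loci[i] for i in np.flatnonzero(mask)][best_local])
        cofactors = cofactors + [best]
        forward_order.append(best)
        models.append(list(cofactors))

    # backward elimination from the largest model
    current = list(cofactors)
    while len(current) > 1:
        pv = _cofactor_pvalues(current)
        worst = max(pv, key=lambda l: (np.inf if np.isnan(pv[l]) else pv[l]))
        current = [l for l in current if l != worst]
        if current not in models:
            models.append(list(current))

    cof_pvals = [_cofactor_pvalues(m) for m in models]
    selected: list[str] = []
    for model, pv in zip(models, cof_pvals):
        if model and all(np.isfinite(list(pv.values()))) \
                and all(v <= threshold for v in pv.values()):
            if len(model) > len(selected):
                selected = list(model)
    return MLMMPath(forward_order=forward_order, models=models,
                    cofactor_pvalues=cof_pvals, selected=selected,
                    threshold=threshold, max_steps=max_steps)
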