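"""Ridge-regression BLUP genome-wide prediction and cross-validation.

The predictor is ridge regression with a common marker-effect variance
(rrBLUP): ``y = mu + Z u + e`` with ``u ~ N(0, s2_u I)`` over centered
marker dosages.  The shrinkage parameter ``lambda = s2_e / s2_u`` is fitted
by REML on the spectrum of ``Z Z'`` (the same machinery as the mixed-model
scan), and effects solve ``u = Z'(Z Z' + lambda I)^{-1}(y - mu)`` — the
marker-effect dual of GBLUP, with identical predictions.

Performance measures follow genomic-selection convention: predictive
ability ``r`` (Pearson correlation of observed and predicted BLUPs on the
test set), accuracy ``Accu = r / sqrt(H2)``, and the intercept/slope
``(b0, b1)`` of regressing observed on predicted values, which are near
(0, 1) for a well-calibrated model.  Cross-validation designs cover random
k-fold schemes (optionally stratified by subpopulation), training-size and
marker-count sweeps, across-subpopulation splits with matched random
baselines, and marker pre-selection by GWAS p-value or ridge effect size
computed strictly within the training fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._reml import fit_variance_ratio
from .blup import TraitBlupResults
from .exceptions import DataError, InvalidParameterError
from .genotypes import GenotypeTable
from .structure import ibs_kinship

__all__ = ["RidgeBLUP", "RidgeBLUPResults", "CVResult", "accuracy",
           "cross_validate", "cross_validate_subpops", "select_markers",
           "fit_ridge_blup"]


def accuracy(r: float, h2: float) -> float:
    """Prediction accuracy: predictive ability over sqrt heritability."""
    if h2 <= 0 or h2 > 1:
        raise InvalidParameterError("h2 must lie in (0, 1]")
    return float(r / np.sqrt(h2))


def _training_matrix(dosage: np.ndarray):
    """Mean-impute and center columns; returns (Z, column means of observed)."""
    means = np.nanmean(dosage, axis=0)
    filled = np.where(np.isnan(dosage), means[None, :], dosage)
    return filled - means[None, :], means


class RidgeBLUP:
    """Ridge-regression BLUP model on a training population.

    Parameters
    ----------
    y
        Training phenotypes (BLUPs), Series indexed by genotype id or array
        aligned with ``gt.ids``.
    gt
        Training genotypes.
    shrinkage
        Fixed ridge parameter ``s2_e / s2_u``; fitted by REML when ``None``.
    """

    def __init__(self, y, gt: GenotypeTable, shrinkage: float | None = None):
        if isinstance(y, TraitBlupResults):
            y = y.blups
        if isinstance(y, pd.Series):
            ids = [g for g in gt.ids if g in set(y.index)]
            gt = gt.subset(individuals=ids) if len(ids) < gt.n_individuals else gt
            y = y.loc[gt.ids]
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != gt.n_individuals:
            raise DataError("phenotype length does not match genotypes")
        if gt.n_individuals < 10:
            raise DataError("need at least 10 training individuals")
        if np.std(y) == 0:
            raise DataError("zero-variance training phenotype")
        if shrinkage is not None and shrinkage <= 0:
            raise InvalidParameterError("shrinkage must be positive")
        self.y = y
        self.gt = gt
        self.shrinkage = shrinkage

    def fit(self) -> "RidgeBLUPResults":
        Z, means = _training_matrix(self.gt.dosage)
        n = len(self.y)
        K = Z @ Z.T
        X = np.ones((n, 1))
        if self.shrinkage is None:
            vc, _ = fit_variance_ratio(self.y, X, K)
            lam = vc.delta
            s2u, s2e = vc.sigma2_g, vc.sigma2_e
        else:
            lam = float(self.shrinkage)
            s2u = s2e = float("nan")
        H = K + lam * np.eye(n)
        hinv_y = np.linalg.solve(H, self.y)
        hinv_1 = np.linalg.solve(H, np.ones(n))
        mu = float(np.ones(n) @ hinv_y / (np.ones(n) @ hinv_1))
        resid = self.y - mu
        u = Z.T @ np.linalg.solve(H, resid)
        return RidgeBLUPResults(
            effects=pd.Series(u, index=pd.Index(self.gt.loci["locus"],
                                                name="locus")),
            intercept=mu,
            shrinkage=lam,
            sigma2_marker=s2u,
            sigma2_e=s2e,
            training_ids=list(self.gt.ids),
            marker_means=pd.Series(means, index=self.gt.loci["locus"]),
        )


@dataclass
class RidgeBLUPResults:
    """Fitted marker effects; ``predict`` applies them to new genotypes."""

    effects: pd.Series
    intercept: float
    shrinkage: float
    sigma2_marker: float
    sigma2_e: float
    training_ids: list[str]
    marker_means: pd.Series = field(repr=False, default=None)

    def predict(self, gt: GenotypeTable) -> pd.Series:
        """Predict genotypic values; markers centered by training means."""
        sub = gt.subset(loci=list(self.effects.index))
        means = self.marker_means.loc[sub.loci["locus"]].to_numpy()
        filled = np.where(np.isnan(sub.dosage), means[None, :], sub.dosage)
        z = filled - means[None, :]
        pred = self.intercept + z @ self.effects.to_numpy()
        return pd.Series(pred, index=pd.Index(sub.ids, name="genotype_id"))

    def summary(self) -> str:
        return (f"RidgeBLUP: {len(self.effects)} markers, "
                f"{len(self.training_ids)} training genotypes, "
                f"lambda={self.shrinkage:.4g}")


def fit_ridge_blup(y, gt: GenotypeTable,
                   shrinkage: float | None = None) -> RidgeBLUPResults:
    """Convenience wrapper around :class:`RidgeBLUP`."""
    return RidgeBLUP(y, gt, shrinkage=shrinkage).fit()


# ---------------------------------------------------------------------------
# Marker selection strategies
# ---------------------------------------------------------------------------

def select_markers(gt_train: GenotypeTable, y_train, strategy: str,
                   n_markers: int, seed: int = 0,
                   kinship=None, n_pcs: int = 0) -> list[str]:
    """Choose a marker subset using training data only (no leakage).

    ``"random"`` samples uniformly (seeded); ``"gwas_p"`` takes the lowest
    single-locus mixed-model p-values (kinship computed from the training
    genotypes when not supplied); ``"effect_size"`` takes the largest
    absolute ridge effects.  Ties keep the smaller locus index.
    """
    if n_markers < 1:
        raise InvalidParameterError("n_markers must be >= 1")
    loci = list(gt_train.loci["locus"])
    if n_markers >= len(loci):
        if n_markers > len(loci):
            warnings.warn("n_markers exceeds available loci; returning all",
                          stacklevel=2)
        return loci
    if strategy == "random":
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(loci), size=n_markers, replace=False))
        return [loci[i] for i in idx]
    if strategy == "gwas_p":
        from .gwas import EmmaxGWAS
        if kinship is None:
            kinship = ibs_kinship(gt_train)
        res = EmmaxGWAS(y_train, gt_train, kinship=kinship, n_pcs=n_pcs).scan()
        p = res.table["p"].to_numpy()
        order = np.lexsort((np.arange(len(p)), np.where(np.isnan(p), np.inf, p)))
        return [loci[i] for i in np.sort(order[:n_markers])]
    if strategy == "effect_size":
        fit = RidgeBLUP(y_train, gt_train).fit()
        eff = np.abs(fit.effects.to_numpy())
        order = np.lexsort((np.arange(len(eff)), -eff))
        return [loci[i] for i in np.sort(order[:n_markers])]
    raise InvalidParameterError(f"unknown strategy {strategy!r}")


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Per-repeat predictive performance for one cross-validation scheme."""

    scheme: dict
    per_repeat: pd.DataFrame  # repeat, r, accu, b0, b1

    def summary(self) -> dict:
        out = {"scheme": self.scheme, "n_repeats": len(self.per_repeat)}
        for c in ("r", "accu", "b0", "b1"):
            vals = self.per_repeat[c].to_numpy(dtype=float)
            out[f"mean_{c}"] = float(np.nanmean(vals))
            out[f"sd_{c}"] = float(np.nanstd(vals, ddof=1)) \
                if len(vals) > 1 else 0.0
        return out

    def summary_text(self) -> str:
        s = self.summary()
        return (f"CV {self.scheme}: r = {s['mean_r']:.3f} "
                f"({s['sd_r']:.3f}), Accu = {s['mean_accu']:.3f}, "
                f"b0 = {s['mean_b0']:.3f}, b1 = {s['mean_b1']:.3f}")


def _resolve_y_h2(blups, h2):
    if isinstance(blups, TraitBlupResults):
        if h2 is None:
            h2 = blups.h2
        return blups.blups, h2
    return blups, h2


def _calibration(observed: np.ndarray, predicted: np.ndarray):
    if np.std(predicted) == 0 or np.std(observed) == 0:
        return float("nan"), float("nan"), float("nan")
    res = stats.linregress(predicted, observed)
    r = float(np.corrcoef(observed, predicted)[0, 1])
    return r, float(res.intercept), float(res.slope)


def _fold_assignments(ids: list[str], folds: int, rng,
                      labels: pd.Series | None, stratify: bool) -> np.ndarray:
    n = len(ids)
    assign = np.empty(n, dtype=int)
    if labels is not None and stratify:
        lab = labels.loc[ids].to_numpy()
        for value in pd.unique(lab):
            idx = np.flatnonzero(lab == value)
            perm = rng.permutation(idx)
            assign[perm] = np.arange(len(perm)) % folds
    else:
        perm = rng.permutation(n)
        assign[perm] = np.arange(n) % folds
    return assign


def cross_validate(blups, gt: GenotypeTable, folds: int = 10,
                   repeats: int = 100, h2: float | None = None,
                   n_markers: int | None = None, strategy: str = "random",
                   train_fraction: float | None = None,
                   labels: pd.Series | None = None, stratify: bool = True,
                   seed: int = 0) -> CVResult:
    """Repeated random cross-validation of ridge-BLUP prediction.

    Per repeat, genotypes are split into ``folds`` folds (or a single
    train/test split when ``train_fraction`` is given); the model is fitted
    on training individuals only — including any marker pre-selection — and
    held-out predictions are pooled before computing r, Accu and (b0, b1).
    Per-repeat seeds derive from ``seed``.
    """
    y, h2 = _resolve_y_h2(blups, h2)
    ids = [g for g in gt.ids if g in set(y.index)]
    if len(ids) < gt.n_individuals:
        gt = gt.subset(individuals=ids)
    y = y.loc[ids]
    n = len(ids)
    if train_fraction is None and not (2 <= folds <= n):
        raise DataError(f"fold count must lie in [2, {n}]")
    rows = []
    for rep in range(repeats):
        rng = np.random.default_rng([seed, rep])
        observed = np.full(n, np.nan)
        predicted = np.full(n, np.nan)
        if train_fraction is not None:
            n_train = int(round(train_fraction * n))
            if n_train < 10 or n_train >= n:
                raise DataError("train_fraction leaves too few individuals")
            perm = rng.permutation(n)
            fold_sets = [perm[n_train:]]
            train_sets = [perm[:n_train]]
        else:
            assign = _fold_assignments(ids, folds, rng, labels, stratify)
            fold_sets = [np.flatnonzero(assign == f) for f in range(folds)]
            train_sets = [np.flatnonzero(assign != f) for f in range(folds)]
        for test_idx, train_idx in zip(fold_sets, train_sets):
            gt_train = gt.subset(individuals=[ids[i] for i in train_idx])
            gt_test = gt.subset(individuals=[ids[i] for i in test_idx])
            if n_markers is not None:
                chosen = select_markers(
                    gt_train, y.iloc[train_idx], strategy, n_markers,
                    seed=int(rng.integers(2 ** 31)))
                gt_train = gt_train.subset(loci=chosen)
                gt_test = gt_test.subset(loci=chosen)
            fit = RidgeBLUP(y.iloc[train_idx], gt_train).fit()
            pred = fit.predict(gt_test)
            predicted[test_idx] = pred.to_numpy()
            observed[test_idx] = y.iloc[test_idx].to_numpy()
        ok = np.isfinite(predicted) & np.isfinite(observed)
        r, b0, b1 = _calibration(observed[ok], predicted[ok])
        accu = accuracy(r, h2) if h2 else float("nan")
        rows.append({"repeat": rep, "r": r, "accu": accu, "b0": b0, "b1": b1})
    scheme = {"folds": folds if train_fraction is None else None,
              "train_fraction": train_fraction, "repeats": repeats,
              "n_markers": n_markers,
              "strategy": strategy if n_markers else None,
              "n_individuals": n, "stratified": bool(labels is not None
                                                     and stratify)}
    return CVResult(scheme=scheme, per_repeat=pd.DataFrame(rows))


def cross_validate_subpops(blups, gt: GenotypeTable, labels: pd.Series,
                           train_label: str, test_label: str,
                           repeats: int = 100, h2: float | None = None,
                           seed: int = 0) -> tuple[CVResult, CVResult]:
    """Across-subpopulation prediction plus a matched random baseline.

    One deterministic evaluation trains on every individual labelled
    ``train_label`` and tests on ``test_label``; the baseline repeats the
    same training/test sizes with individuals drawn at random from the whole
    panel.
    """
    y, h2 = _resolve_y_h2(blups, h2)
    ids = [g for g in gt.ids if g in set(y.index)]
    gt = gt.subset(individuals=ids) if len(ids) < gt.n_individuals else gt
    y = y.loc[ids]
    lab = labels.loc[ids]
    for value in (train_label, test_label):
        if value not in set(lab):
            raise DataError(f"unknown subpopulation label {value!r}")
    train_ids = [g for g in ids if lab[g] == train_label]
    test_ids = [g for g in ids if lab[g] == test_label]
    if len(train_ids) < 10:
        raise DataError("training subpopulation too small")
    fit = RidgeBLUP(y.loc[train_ids], gt.subset(individuals=train_ids)).fit()
    pred = fit.predict(gt.subset(individuals=test_ids))
    r, b0, b1 = _calibration(y.loc[test_ids].to_numpy(), pred.to_numpy())
    across = CVResult(
        scheme={"design": "across-subpop", "train": train_label,
                "test": test_label, "n_train": len(train_ids),
                "n_test": len(test_ids)},
        per_repeat=pd.DataFrame([{
            "repeat": 0, "r": r,
            "accu": accuracy(r, h2) if h2 else float("nan"),
            "b0": b0, "b1": b1}]),
    )
    rows = []
    for rep in range(repeats):
        rng = np.random.default_rng([seed, rep])
        perm = rng.permutation(len(ids))
        tr = [ids[i] for i in perm[:len(train_ids)]]
        te = [ids[i] for i in perm[len(train_ids):len(train_ids) + len(test_ids)]]
        fit = RidgeBLUP(y.loc[tr], gt.subset(individuals=tr)).fit()
        pred = fit.predict(gt.subset(individuals=te))
        r, b0, b1 = _calibration(y.loc[te].to_numpy(), pred.to_numpy())
        rows.append({"repeat": rep, "r": r,
                     "accu": accuracy(r, h2) if h2 else float("nan"),
                     "b0": b0, "b1": b1})
    baseline = CVResult(
        scheme={"design": "random-baseline", "n_train": len(train_ids),
                "n_test": len(test_ids), "repeats": repeats},
        per_repeat=pd.DataFrame(rows),
    )
    return across, baseline
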