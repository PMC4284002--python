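"""SNV quality filtering, per-locus statistics, LD and windowed pruning.

Two named filter profiles mirror the stringent/liberal filtering commonly
applied to reduced-representation SNV data:

* ``STRINGENT`` — variant quality Q >= 15, per-call depth >= 14, <= 10%
  missing calls, |F_IS| <= 0.25, heterozygous calls require >= 5% of reads
  on the minor allele, biallelic only.
* ``LIBERAL`` — per-call depth >= 3, mean depth >= 6, <= 20% missing,
  >= 3 copies of the minor allele, biallelic only.

``F_IS = 1 - Ho/He`` measures departure of genotype frequencies from
Hardy-Weinberg expectations (He computed as ``2p(1-p)`` without small-sample
correction).  Pairwise LD is the squared Pearson correlation of dosage
vectors ("genotypic correlation"); pruning is greedy within sliding windows
in the style of PLINK ``--indep-pairwise``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError, InvalidParameterError
from .genotypes import GenotypeTable

__all__ = ["FilterProfile", "STRINGENT", "LIBERAL", "LocusStats",
           "locus_stats", "locus_stats_table", "apply_filter_profile",
           "ld_r2", "ld_prune"]


@dataclass(frozen=True)
class FilterProfile:
    """Thresholds of a locus-level SNV filter; ``None`` disables a criterion.

    ``min_depth`` and ``min_het_read_fraction`` act per call (failing calls
    are set missing before locus statistics are computed); the remaining
    criteria act per locus.
    """

    name: str = "custom"
    min_qual: float | None = None
    min_depth: float | None = None
    min_ave_depth: float | None = None
    max_missing_pct: float | None = None
    min_minor_allele_copies: int | None = None
    max_abs_fis: float | None = None
    min_het_read_fraction: float | None = None
    required_n_alleles: int = 2
    #: if True the het-read criterion drops the whole locus instead of
    #: masking individual calls
    het_read_drops_locus: bool = False

    def __post_init__(self) -> None:
        for fname in ("min_qual", "min_depth", "min_ave_depth",
                      "min_minor_allele_copies", "max_abs_fis",
                      "min_het_read_fraction"):
            v = getattr(self, fname)
            if v is not None and v < 0:
                raise InvalidParameterError(f"{fname} must be non-negative")
        if self.max_missing_pct is not None and not (
                0 <= self.max_missing_pct <= 100):
            raise InvalidParameterError("max_missing_pct must lie in [0, 100]")

    def with_(self, **kwargs) -> "FilterProfile":
        return replace(self, **kwargs)


STRINGENT = FilterProfile(
    name="stringent", min_qual=15, min_depth=14, max_missing_pct=10,
    max_abs_fis=0.25, min_het_read_fraction=0.05, required_n_alleles=2)

LIBERAL = FilterProfile(
    name="liberal", min_depth=3, min_ave_depth=6, max_missing_pct=20,
    min_minor_allele_copies=3, required_n_alleles=2)

PROFILES = {"stringent": STRINGENT, "liberal": LIBERAL}


@dataclass(frozen=True)
class LocusStats:
    """Observed-call summary statistics for one locus."""

    locus: str
    maf: float
    ho: float                 # observed heterozygosity
    he: float                 # expected heterozygosity 2p(1-p)
    fis: float                # 1 - Ho/He; NaN when He == 0
    missing_pct: float
    mean_depth: float
    minor_allele_copies: int
    n_obs: int


def locus_stats_table(gt: GenotypeTable) -> pd.DataFrame:
    """Vectorised per-locus statistics over observed calls only."""
    dosage = gt.dosage
    observed = ~np.isnan(dosage)
    n_obs = observed.sum(axis=0)
    if (n_obs == 0).any():
        bad = gt.loci["locus"].iloc[int(np.argmin(n_obs))]
        raise DataError(f"locus {bad!r} has no observed calls")
    alt_copies = np.nansum(dosage, axis=0)
    p = alt_copies / (2 * n_obs)
    maf = np.minimum(p, 1 - p)
    minor_copies = np.minimum(alt_copies, 2 * n_obs - alt_copies)
    ho = (dosage == 1).sum(axis=0) / n_obs
    he = 2 * p * (1 - p)
    with np.errstate(divide="ignore", invalid="ignore"):
        fis = np.where(he > 0, 1.0 - ho / he, np.nan)
    missing_pct = 100.0 * (1.0 - n_obs / gt.n_individuals)
    if gt.depth is not None:
        with np.errstate(invalid="ignore"):
            mean_depth = np.nanmean(np.where(observed, gt.depth, np.nan), axis=0)
    else:
        mean_depth = np.full(gt.n_loci, np.nan)
    return pd.DataFrame({
        "locus": gt.loci["locus"].to_numpy(),
        "maf": maf,
        "ho": ho,
        "he": he,
        "fis": fis,
        "missing_pct": missing_pct,
        "mean_depth": mean_depth,
        "minor_allele_copies": minor_copies.astype(int),
        "n_obs": n_obs,
    })


def locus_stats(gt: GenotypeTable, locus: str) -> LocusStats:
    """Statistics for a single locus (see :func:`locus_stats_table`)."""
    sub = gt.subset(loci=[locus])
    row = locus_stats_table(sub).iloc[0]
    return LocusStats(**row.to_dict())


def _mask_low_confidence_calls(gt: GenotypeTable,
                               profile: FilterProfile) -> GenotypeTable:
    """Apply the per-call criteria (min depth, het read balance)."""
    out = gt.copy()
    if profile.min_depth is not None:
        if out.depth is None:
            raise ConfigurationError(
                "profile sets min_depth but the table has no depth field")
        low = out.depth < profile.min_depth
        out.dosage[low] = np.nan
    if profile.min_het_read_fraction is not None and not profile.het_read_drops_locus:
        if out.ref_depth is None or out.alt_depth is None:
            raise ConfigurationError(
                "profile sets min_het_read_fraction but the table has no "
                "allelic depth fields")
        frac = out.minor_read_fraction()
        bad = (out.dosage == 1) & (frac < profile.min_het_read_fraction)
        out.dosage[bad] = np.nan
    return out


def apply_filter_profile(gt: GenotypeTable, profile: FilterProfile
                         ) -> tuple[GenotypeTable, pd.DataFrame]:
    """Filter loci by every configured criterion of ``profile``.

    Per-call criteria mask calls first; locus statistics (missingness, MAF,
    F_IS) are then recomputed on the masked table.  Returns the filtered
    table and a per-locus report with the first failed criterion (checked in
    the order n_alleles, qual, het_reads, ave_depth, missing, minor_alleles,
    fis) for every removed locus.
    """
    if profile.min_qual is not None and gt.loci["qual"].isna().all():
        raise ConfigurationError(
            "profile sets min_qual but the table has no quality scores")
    masked = _mask_low_confidence_calls(gt, profile)
    # a masked locus may end up with zero observed calls: treat as 100% missing
    n_obs = (~np.isnan(masked.dosage)).sum(axis=0)
    fully_masked = n_obs == 0
    if fully_masked.any():
        # reinstate one dummy observed call to keep the stats table defined;
        # the missingness criterion removes such loci regardless
        masked.dosage[0, fully_masked] = 0.0
    stats = locus_stats_table(masked)
    stats.loc[fully_masked, "missing_pct"] = 100.0

    failures = pd.Series("", index=stats.index, dtype=object)

    def _flag(mask: np.ndarray, label: str) -> None:
        mask = np.asarray(mask) & (failures == "").to_numpy()
        failures.iloc[np.flatnonzero(mask)] = label

    _flag(gt.loci["n_alleles"].to_numpy() != profile.required_n_alleles,
          "n_alleles")
    if profile.min_qual is not None:
        qual = gt.loci["qual"].to_numpy(dtype=float)
        _flag(~(qual >= profile.min_qual), "qual")
    if profile.min_het_read_fraction is not None and profile.het_read_drops_locus:
        frac = gt.minor_read_fraction()
        bad = np.nansum((gt.dosage == 1) & (frac < profile.min_het_read_fraction),
                        axis=0) > 0
        _flag(bad, "het_reads")
    if profile.min_ave_depth is not None:
        if masked.depth is None:
            raise ConfigurationError(
                "profile sets min_ave_depth but the table has no depth field")
        _flag(~(stats["mean_depth"].to_numpy() >= profile.min_ave_depth),
              "ave_depth")
    if profile.max_missing_pct is not None:
        _flag(stats["missing_pct"].to_numpy() > profile.max_missing_pct,
              "missing")
    if profile.min_minor_allele_copies is not None:
        _flag(stats["minor_allele_copies"].to_numpy()
              < profile.min_minor_allele_copies, "minor_alleles")
    if profile.max_abs_fis is not None:
        fis = stats["fis"].to_numpy()
        _flag(np.abs(np.nan_to_num(fis)) > profile.max_abs_fis, "fis")

    keep = (failures == "").to_numpy()
    if fully_masked.any():
        masked.dosage[0, fully_masked] = np.nan
    report = pd.DataFrame({
        "locus": stats["locus"],
        "passed": keep,
        "failed_criterion": failures.where(failures != "", other=pd.NA),
    })
    filtered = masked.subset(loci=list(keep))
    return filtered, report


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_r2(gt: GenotypeTable, locus_a: str, locus_b: str) -> float:
    """Squared genotypic correlation over jointly observed individuals.

    Returns NaN (undefined) when either locus has zero variance among the
    jointly observed calls.
    """
    sub = gt.subset(loci=[locus_a, locus_b])
    a, b = sub.dosage[:, 0], sub.dosage[:, 1]
    both = ~np.isnan(a) & ~np.isnan(b)
    if both.sum() < 2:
        raise DataError(
            f"fewer than 2 jointly observed calls for {locus_a!r}/{locus_b!r}")
    a, b = a[both], b[both]
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _pairwise_r2(dosage: np.ndarray) -> np.ndarray:
    """All-pairs r^2 of dosage columns using pairwise-complete observations."""
    m = dosage.shape[1]
    mask = ~np.isnan(dosage)
    x = np.nan_to_num(dosage)
    n = mask.T.astype(float) @ mask
    sx = x.T @ mask
    sxx = (x * x).T @ mask
    sxy = x.T @ x
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sx.T / n
        var_a = sxx - sx ** 2 / n
        r2 = cov ** 2 / (var_a * var_a.T)
    r2[n < 2] = np.nan
    np.fill_diagonal(r2, 1.0)
    return r2


def ld_prune(gt: GenotypeTable, window: int = 50, step: int = 5,
             r2_threshold: float = 0.2) -> list[str]:
    """Greedy windowed LD pruning (PLINK ``--indep-pairwise`` style).

    Loci must be sorted by (chrom, pos).  Within every ``window``-locus
    window (slid by ``step``, per chromosome) the member with the lower MAF
    of the worst-correlated retained pair is dropped until no retained pair
    exceeds ``r2_threshold``; MAF ties drop the larger index.  Returns the
    retained locus ids in input order.
    """
    if window < 2:
        raise InvalidParameterError("window must be >= 2")
    if step < 1:
        raise InvalidParameterError("step must be >= 1")
    loci = gt.loci
    order_key = loci[["chrom", "pos"]].astype({"pos": float})
    if not (order_key.sort_values(["chrom", "pos"]).index
            == order_key.index).all():
        raise DataError("loci must be sorted by (chrom, pos) before pruning")
    stats = locus_stats_table(gt)
    maf = stats["maf"].to_numpy()
    retained = np.ones(gt.n_loci, dtype=bool)
    for chrom in loci["chrom"].unique():
        idx = np.flatnonzero((loci["chrom"] == chrom).to_numpy())
        for start in range(0, len(idx), step):
            win = idx[start:start + window]
            if len(win) < 2:
                continue
            active = win[retained[win]]
            if len(active) < 2:
                continue
            r2 = _pairwise_r2(gt.dosage[:, active])
            np.fill_diagonal(r2, np.nan)
            alive = np.ones(len(active), dtype=bool)
            while True:
                sub = np.where(np.outer(alive, alive), r2, np.nan)
                if np.all(np.isnan(sub)) or np.nanmax(sub) <= r2_threshold:
                    break
                i, j = np.unravel_index(np.nanargmax(sub), sub.shape)
                a, b = active[i], active[j]
                if maf[a] < maf[b] or (maf[a] == maf[b] and a > b):
                    drop_local, drop_global = i, a
                else:
                    drop_local, drop_global = j, b
                alive[drop_local] = False
                retained[drop_global] = False
            if start + window >= len(idx):
                break
    return list(loci["locus"].iloc[np.flatnonzero(retained)])
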