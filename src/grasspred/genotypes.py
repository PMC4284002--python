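"""Genotype container and file I/O.

The central in-memory object is :class:`GenotypeTable`: an individuals x loci
alternate-allele dosage matrix (0/1/2, ``NaN`` for missing) together with
per-locus metadata (chromosome, position, alleles, variant quality) and
optional per-call read support (total depth, allelic depths, genotype
quality).  Dosage counts copies of the first ALT allele; calls involving a
third allele are representable (the locus is flagged via ``n_alleles``) but
their dosage is treated as missing until multi-allelic loci are filtered out.

VCF reading is delegated to :mod:`cyvcf2`; writing emits plain VCF 4.2 text
with ``GT:DP:AD:GQ`` per-call fields so that tables round-trip exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError

__all__ = ["GenotypeTable", "read_vcf", "write_vcf", "impute_mean",
           "read_dosage_tsv", "write_dosage_tsv"]

LOCUS_COLUMNS = ["locus", "chrom", "pos", "ref", "alt", "n_alleles", "qual"]


@dataclass
class GenotypeTable:
    """Individuals x loci dosage matrix with per-call read support.

    Parameters
    ----------
    ids
        Ordered, unique individual identifiers.
    loci
        One row per locus with columns ``locus`` (identifier), ``chrom``,
        ``pos`` (1-based), ``ref``, ``alt``, ``n_alleles`` and ``qual``
        (Phred-like variant quality, NaN if unknown).
    dosage
        Float array of shape ``(n_individuals, n_loci)`` with entries in
        ``{0, 1, 2}`` and ``NaN`` for missing calls.
    depth, ref_depth, alt_depth, gq
        Optional per-call annotations with the same shape as ``dosage``.
    metadata
        Optional per-individual table (``genotype_id``, ``subpop``, ``lat``,
        ``lon``, ``alt``).
    """

    ids: list[str]
    loci: pd.DataFrame
    dosage: np.ndarray
    depth: np.ndarray | None = None
    ref_depth: np.ndarray | None = None
    alt_depth: np.ndarray | None = None
    gq: np.ndarray | None = None
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise DataError(f"duplicated individual ids: {dupes}")
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.ids), len(self.loci)):
            raise DataError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.ids)} individuals x {len(self.loci)} loci"
            )
        observed = self.dosage[~np.isnan(self.dosage)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise DataError("dosage entries must be 0, 1, 2 or NaN")
        self.loci = self.loci.reset_index(drop=True)
        if (pd.to_numeric(self.loci["pos"]) <= 0).any():
            raise DataError("locus positions must be strictly positive")
        if self.loci["locus"].duplicated().any():
            raise DataError("duplicated locus ids")

    # -- basic geometry -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def shape(self) -> tuple[int, int]:
        return self.dosage.shape

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    # -- derived per-call statistics ------------------------------------
    def minor_read_fraction(self) -> np.ndarray:
        """Fraction of reads supporting the less frequent allele per call.

        Defined wherever allelic depths are present and total allelic depth
        is positive; ``NaN`` elsewhere.
        """
        if self.ref_depth is None or self.alt_depth is None:
            raise DataError("allelic depths not available")
        total = self.ref_depth + self.alt_depth
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.minimum(self.ref_depth, self.alt_depth) / total
        frac = np.where(total > 0, frac, np.nan)
        frac[np.isnan(self.dosage)] = np.nan
        return frac

    def alt_allele_frequency(self) -> np.ndarray:
        """Observed ALT-allele frequency per locus (missing calls ignored)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    # -- subsetting -----------------------------------------------------
    def _take(self, arr: np.ndarray | None, rows, cols) -> np.ndarray | None:
        if arr is None:
            return None
        return arr[np.ix_(rows, cols)]

    def subset(self, individuals=None, loci=None) -> "GenotypeTable":
        """Return a new table restricted to the given individuals/loci.

        Both arguments accept identifiers (order respected) or boolean masks.
        """
        if individuals is None:
            rows = np.arange(self.n_individuals)
        else:
            individuals = list(individuals)
            if individuals and isinstance(individuals[0], (bool, np.bool_)):
                rows = np.flatnonzero(individuals)
            else:
                index = {g: i for i, g in enumerate(self.ids)}
                missing = [g for g in individuals if g not in index]
                if missing:
                    raise DataError(f"unknown individual ids: {missing}")
                rows = np.array([index[g] for g in individuals], dtype=int)
        if loci is None:
            cols = np.arange(self.n_loci)
        else:
            loci = list(loci)
            if loci and isinstance(loci[0], (bool, np.bool_)):
                cols = np.flatnonzero(loci)
            else:
                index = {l: i for i, l in enumerate(self.loci["locus"])}
                missing = [l for l in loci if l not in index]
                if missing:
                    raise DataError(f"unknown locus ids: {missing}")
                cols = np.array([index[l] for l in loci], dtype=int)
        meta = None
        if self.metadata is not None:
            meta = (self.metadata.set_index("genotype_id")
                    .loc[[self.ids[r] for r in rows]].reset_index())
        return GenotypeTable(
            ids=[self.ids[r] for r in rows],
            loci=self.loci.iloc[cols],
            dosage=self.dosage[np.ix_(rows, cols)],
            depth=self._take(self.depth, rows, cols),
            ref_depth=self._take(self.ref_depth, rows, cols),
            alt_depth=self._take(self.alt_depth, rows, cols),
            gq=self._take(self.gq, rows, cols),
            metadata=meta,
        )

    def copy(self) -> "GenotypeTable":
        return GenotypeTable(
            ids=list(self.ids),
            loci=self.loci.copy(),
            dosage=self.dosage.copy(),
            depth=None if self.depth is None else self.depth.copy(),
            ref_depth=None if self.ref_depth is None else self.ref_depth.copy(),
            alt_depth=None if self.alt_depth is None else self.alt_depth.copy(),
            gq=None if self.gq is None else self.gq.copy(),
            metadata=None if self.metadata is None else self.metadata.copy(),
        )

    replace = dataclasses.replace


def impute_mean(gt: GenotypeTable) -> np.ndarray:
    """Replace missing calls by the locus mean dosage of observed calls.

    Returns a dense float matrix; observed entries are unchanged.  Raises
    :class:`DataError` naming the first locus with no observed calls.
    """
    dosage = gt.dosage.copy()
    observed = ~np.isnan(dosage)
    n_obs = observed.sum(axis=0)
    if (n_obs == 0).any():
        bad = gt.loci["locus"].iloc[int(np.argmin(n_obs))]
        raise DataError(f"locus {bad!r} has no observed calls; cannot impute")
    means = np.nanmean(dosage, axis=0)
    idx = np.where(~observed)
    dosage[idx] = means[idx[1]]
    return dosage


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def _fmt_call(dos, dp, rd, ad, gq) -> str:
    if np.isnan(dos):
        gt_field = "./."
    else:
        d = int(dos)
        gt_field = {0: "0/0", 1: "0/1", 2: "1/1"}[d]
    parts = [gt_field]
    parts.append("." if dp is None or np.isnan(dp) else str(int(dp)))
    if rd is None or ad is None or np.isnan(rd) or np.isnan(ad):
        parts.append(".")
    else:
        parts.append(f"{int(rd)},{int(ad)}")
    parts.append("." if gq is None or np.isnan(gq) else str(int(gq)))
    return ":".join(parts)


def write_vcf(gt: GenotypeTable, path) -> None:
    """Write the table as uncompressed VCF 4.2 with GT:DP:AD:GQ calls."""
    chroms = list(dict.fromkeys(gt.loci["chrom"].astype(str)))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=grasspred\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER",
                  "INFO", "FORMAT"] + list(gt.ids)
        fh.write("\t".join(header) + "\n")
        dp = gt.depth
        rd = gt.ref_depth
        ad = gt.alt_depth
        gq = gt.gq
        for j, row in gt.loci.iterrows():
            qual = "." if pd.isna(row["qual"]) else f"{float(row['qual']):g}"
            fields = [str(row["chrom"]), str(int(row["pos"])), str(row["locus"]),
                      str(row["ref"]), str(row["alt"]), qual, ".", ".",
                      "GT:DP:AD:GQ"]
            for i in range(gt.n_individuals):
                fields.append(_fmt_call(
                    gt.dosage[i, j],
                    None if dp is None else dp[i, j],
                    None if rd is None else rd[i, j],
                    None if ad is None else ad[i, j],
                    None if gq is None else gq[i, j],
                ))
            fh.write("\t".join(fields) + "\n")


def read_vcf(path) -> GenotypeTable:
    """Read a VCF into a :class:`GenotypeTable`.

    Biallelic records map GT to ALT dosage; ``./.`` becomes missing.
    Multi-allelic records are preserved and flagged through ``n_alleles``
    so they can be removed by the allele-count filter; calls carrying an
    allele beyond the first ALT are stored as missing dosage.  DP/AD/GQ are
    captured when present.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise DataError("duplicated sample id in VCF header")
    loci_rows = []
    dosages, depths, refds, altds, gqs = [], [], [], [], []
    any_dp = any_ad = any_gq = False
    for var in vcf:
        alts = var.ALT if var.ALT else ["."]
        n_alleles = 1 + len([a for a in alts if a != "."])
        gts = var.genotypes  # [[a1, a2, phased], ...]
        dos = np.full(len(samples), np.nan)
        for i, g in enumerate(gts):
            a = [x for x in g[:-1] if x is not None]
            if len(a) < 2 or min(a) < 0:
                continue
            if max(a) > 1:
                continue  # third allele: dosage undefined, locus stays flagged
            dos[i] = float(a[0] + a[1])
        dosages.append(dos)

        def _field(name):
            try:
                arr = var.format(name)
            except KeyError:
                return None
            return arr

        dp = _field("DP")
        if dp is not None:
            dp = dp.astype(float).reshape(len(samples), -1)[:, 0]
            dp[dp < 0] = np.nan
            any_dp = True
        depths.append(dp)
        ad = _field("AD")
        if ad is not None and ad.shape[1] >= 2:
            ad = ad.astype(float)
            ad[ad < 0] = np.nan
            refds.append(ad[:, 0])
            altds.append(ad[:, 1])
            any_ad = True
        else:
            refds.append(None)
            altds.append(None)
        gq = _field("GQ")
        if gq is not None:
            gq = gq.astype(float).reshape(len(samples), -1)[:, 0]
            gq[gq < 0] = np.nan
            any_gq = True
        gqs.append(gq)
        loci_rows.append({
            "locus": var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}",
            "chrom": var.CHROM,
            "pos": var.POS,
            "ref": var.REF,
            "alt": ",".join(alts),
            "n_alleles": n_alleles,
            "qual": np.nan if var.QUAL is None else float(var.QUAL),
        })
    vcf.close()
    m = len(loci_rows)
    n = len(samples)

    def _stack(cols, present):
        if not present:
            return None
        out = np.full((n, m), np.nan)
        for j, col in enumerate(cols):
            if col is not None:
                out[:, j] = col
        return out

    loci = pd.DataFrame(loci_rows, columns=LOCUS_COLUMNS)
    dosage = (np.vstack(dosages).T if m else np.empty((n, 0)))
    return GenotypeTable(
        ids=samples,
        loci=loci,
        dosage=dosage,
        depth=_stack(depths, any_dp),
        ref_depth=_stack(refds, any_ad),
        alt_depth=_stack(altds, any_ad),
        gq=_stack(gqs, any_gq),
    )


# ---------------------------------------------------------------------------
# Dosage matrix TSV (rows = individuals, columns = loci, NA = missing)
# ---------------------------------------------------------------------------

def write_dosage_tsv(gt: GenotypeTable, path) -> None:
    df = pd.DataFrame(gt.dosage, index=gt.ids, columns=gt.loci["locus"])
    df.index.name = "genotype_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_dosage_tsv(path) -> GenotypeTable:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
    loci = pd.DataFrame({
        "locus": df.columns,
        "chrom": "NA",
        "pos": np.arange(1, df.shape[1] + 1),
        "ref": "N",
        "alt": "N",
        "n_alleles": 2,
        "qual": np.nan,
    })
    return GenotypeTable(ids=list(df.index.astype(str)), loci=loci,
                         dosage=df.to_numpy(dtype=float))
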