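"""SNP and Gene Expression Marker (GEM) scoring from raw matrices.

Two marker classes are produced for association mapping in an inbred wheat
panel:

* **SNPs** are called from per-accession allele read depths.  A noise
  threshold (default 0.15) is applied at two levels: panel-wide, an allele
  is only treated as real if it carries at least that fraction of the
  pooled reads at the site (sites with more than two real alleles, or
  fewer than two, are excluded); within an accession, a call is made for
  the majority allele only when the minority fraction is below the same
  threshold — a mixed signal in a fully inbred line is scored missing.
  Genotypes are coded as minor-allele dosage in {0, 2} (homozygous lines).

* **GEMs** are per-unigene transcript abundances expressed as RPKM
  (reads per kilobase of transcript per million aligned reads),
  RPKM_ij = 1e9 * c_ij / (N_i * l_j).  Unigenes whose abundance across
  accessions falls below 0.4 RPKM are removed before use as markers.

Markers below 5 % minor allele frequency are excluded from association
(strict inequality: MAF exactly 0.05 is retained).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ALLELES",
    "AlleleDepthTensor",
    "GenotypeMatrix",
    "ExpressionMatrix",
    "call_snps",
    "filter_maf",
    "compute_rpkm",
    "filter_gems",
]

ALLELES = ("A", "C", "G", "T")
_ALLELE_INDEX = {a: i for i, a in enumerate(ALLELES)}


@dataclass
class AlleleDepthTensor:
    """Read depth per accession x SNP site x allele.

    ``counts`` has shape (n_accessions, n_sites, 4) over the DNA alphabet
    in ``ALLELES`` order.  ``site_info`` (indexed by site id) carries at
    least the unigene each site lies in and its offset within it.
    """

    counts: np.ndarray
    accessions: pd.Index
    sites: pd.Index
    site_info: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3 or self.counts.shape[2] != len(ALLELES):
            raise ValueError("counts must have shape (n_accessions, n_sites, 4)")
        if np.any(self.counts < 0):
            raise ValueError("read counts must be non-negative")
        self.accessions = pd.Index(self.accessions)
        self.sites = pd.Index(self.sites)
        if self.counts.shape[:2] != (len(self.accessions), len(self.sites)):
            raise ValueError("counts shape inconsistent with accession/site ids")
        if self.site_info is None:
            self.site_info = pd.DataFrame(index=self.sites)

    def to_long(self) -> pd.DataFrame:
        """Long-format table (accession, site, allele, count), zero rows omitted."""
        acc_i, site_i, all_i = np.nonzero(self.counts)
        return pd.DataFrame(
            {
                "accession": self.accessions[acc_i],
                "site": self.sites[site_i],
                "allele": [ALLELES[k] for k in all_i],
                "count": self.counts[acc_i, site_i, all_i],
            }
        )

    @classmethod
    def from_long(
        cls,
        long: pd.DataFrame,
        accessions=None,
        sites=None,
        site_info: pd.DataFrame | None = None,
    ) -> "AlleleDepthTensor":
        if long.empty and accessions is None:
            raise ValueError("empty depth table")
        accessions = pd.Index(
            accessions if accessions is not None else sorted(long["accession"].unique())
        )
        sites = pd.Index(sites if sites is not None else sorted(long["site"].unique()))
        counts = np.zeros((len(accessions), len(sites), len(ALLELES)), dtype=np.int64)
        ai = accessions.get_indexer(long["accession"])
        si = sites.get_indexer(long["site"])
        ki = long["allele"].map(_ALLELE_INDEX).to_numpy()
        if np.any(ai < 0) or np.any(si < 0):
            raise ValueError("long table contains ids not in the provided indexes")
        np.add.at(counts, (ai, si, ki), long["count"].to_numpy())
        return cls(counts, accessions, sites, site_info)


@dataclass
class GenotypeMatrix:
    """Accessions x markers of minor-allele dosage in {0, 2}, NaN missing.

    ``info`` (indexed by marker id) records the dosage-counted allele
    (``allele_minor``), the other allele (``allele_major``), the minor
    allele frequency among called accessions, and the unigene the marker
    lies in.
    """

    calls: pd.DataFrame
    info: pd.DataFrame

    def __post_init__(self):
        vals = self.calls.to_numpy(float)
        ok = np.isnan(vals) | (vals == 0.0) | (vals == 2.0)
        if not ok.all():
            raise ValueError("genotype calls must be 0, 2 or missing")
        if not self.calls.columns.equals(self.info.index):
            raise ValueError("marker info index must match call columns")

    @property
    def accessions(self) -> pd.Index:
        return self.calls.index

    @property
    def markers(self) -> pd.Index:
        return self.calls.columns

    def maf(self) -> pd.Series:
        """Minor-allele frequency per marker over non-missing calls."""
        vals = self.calls.to_numpy(float)
        called = np.isfinite(vals)
        with np.errstate(invalid="ignore"):
            freq = np.nansum(vals, axis=0) / (2.0 * called.sum(axis=0))
        freq = np.minimum(freq, 1.0 - freq)
        return pd.Series(freq, index=self.markers, name="maf")


@dataclass
class ExpressionMatrix:
    """Accessions x unigenes RPKM, with unigene lengths and library totals."""

    rpkm: pd.DataFrame
    lengths: pd.Series
    totals: pd.Series

    def __post_init__(self):
        if not self.rpkm.columns.equals(pd.Index(self.lengths.index)):
            raise ValueError("unigene lengths must be indexed like rpkm columns")
        if not self.rpkm.index.equals(pd.Index(self.totals.index)):
            raise ValueError("totals must be indexed like rpkm rows")
        if (self.rpkm.to_numpy() < 0).any():
            raise ValueError("RPKM values must be non-negative")

    @property
    def accessions(self) -> pd.Index:
        return self.rpkm.index

    @property
    def unigenes(self) -> pd.Index:
        return self.rpkm.columns


def call_snps(
    depths: AlleleDepthTensor,
    noise_threshold: float = 0.15,
    min_depth: int = 4,
) -> GenotypeMatrix:
    """Call biallelic homozygous SNP genotypes from allele read depths.

    Panel level: an allele is *real* at a site when its pooled read
    fraction across all accessions is >= ``noise_threshold``.  Sites with
    more than two real alleles (ambiguous, likely paralogous) or fewer
    than two (monomorphic) are excluded.

    Accession level: accessions with total site depth < ``min_depth`` are
    missing.  Otherwise the minority fraction among the two real alleles
    must be < ``noise_threshold`` for a homozygous majority call; a larger
    minority signal in an inbred line is scored missing.

    Dosage counts the panel-wide minor allele, so calls are 0 or 2.
    """
    if depths.counts.size == 0:
        raise ValueError("empty allele-depth tensor")
    if not 0 < noise_threshold < 0.5:
        raise ValueError("noise threshold must be in (0, 0.5)")

    counts = depths.counts.astype(float)
    pooled = counts.sum(axis=0)  # (sites, 4)
    site_tot = pooled.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(site_tot[:, None] > 0, pooled / site_tot[:, None], 0.0)
    real = frac >= noise_threshold  # (sites, 4)
    n_real = real.sum(axis=1)
    keep = n_real == 2

    calls = {}
    info_rows = []
    for s in np.nonzero(keep)[0]:
        a_idx, b_idx = np.nonzero(real[s])[0]
        # orient so the dosage-counted allele is the panel-wide rarer one
        if pooled[s, a_idx] < pooled[s, b_idx]:
            minor_i, major_i = a_idx, b_idx
        else:
            minor_i, major_i = b_idx, a_idx
        dep = counts[:, s, :]
        total = dep.sum(axis=1)
        two = dep[:, [major_i, minor_i]]
        two_tot = two.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            minority = np.where(
                two_tot > 0, np.min(two, axis=1) / two_tot, np.nan
            )
        g = np.full(len(depths.accessions), np.nan)
        callable_ = (total >= min_depth) & (two_tot > 0) & (
            minority < noise_threshold
        )
        major_wins = dep[:, major_i] >= dep[:, minor_i]
        g[callable_ & major_wins] = 0.0
        g[callable_ & ~major_wins] = 2.0
        site = depths.sites[s]
        calls[site] = g
        row = {
            "allele_minor": ALLELES[minor_i],
            "allele_major": ALLELES[major_i],
        }
        if depths.site_info is not None and "unigene" in depths.site_info.columns:
            row["unigene"] = depths.site_info.loc[site, "unigene"]
        info_rows.append((site, row))

    call_df = pd.DataFrame(calls, index=depths.accessions)
    info = pd.DataFrame(
        [r for _, r in info_rows], index=pd.Index([s for s, _ in info_rows])
    )
    if call_df.empty:
        call_df = pd.DataFrame(index=depths.accessions)
        info = pd.DataFrame(columns=["allele_minor", "allele_major"])
    gm = GenotypeMatrix(call_df, info)
    gm.info["maf"] = gm.maf()
    return gm


def filter_maf(genotypes: GenotypeMatrix, min_maf: float = 0.05) -> GenotypeMatrix:
    """Remove markers with minor allele frequency below ``min_maf``.

    MAF is computed on non-missing calls only (dosage sum over twice the
    called count).  The rule is a strict inequality: MAF exactly at the
    threshold is retained.  Markers whose stored coding no longer counts
    the rarer allele are re-oriented (dosage flipped, allele labels
    swapped).  All-missing markers are removed with a warning.
    """
    calls = genotypes.calls.copy()
    info = genotypes.info.copy()
    vals = calls.to_numpy(float)
    called = np.isfinite(vals).sum(axis=0)
    if np.any(called == 0):
        warnings.warn(
            f"{int((called == 0).sum())} marker(s) with no called accessions removed"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.nansum(vals, axis=0) / (2.0 * called)
    # re-orient markers where the stored "minor" allele is actually major
    flip = freq > 0.5
    if flip.any():
        cols = calls.columns[flip]
        calls[cols] = 2.0 - calls[cols]
        if {"allele_minor", "allele_major"} <= set(info.columns):
            minor = info.loc[cols, "allele_minor"].copy()
            info.loc[cols, "allele_minor"] = info.loc[cols, "allele_major"]
            info.loc[cols, "allele_major"] = minor
        freq = np.where(flip, 1.0 - freq, freq)
    keep = (called > 0) & (freq >= min_maf) & (freq > 0.0)
    out = GenotypeMatrix(calls.loc[:, calls.columns[keep]], info.loc[calls.columns[keep]])
    out.info["maf"] = out.maf()
    return out


def compute_rpkm(
    counts: pd.DataFrame, lengths: pd.Series, totals: pd.Series | None = None
) -> ExpressionMatrix:
    """Reads per kilobase per million aligned reads from raw counts.

    RPKM_ij = 1e9 * c_ij / (N_i * l_j) with N_i the accession's total
    aligned reads (row sums of ``counts`` when not supplied) and l_j the
    unigene length in bases.
    """
    counts = counts.astype(float)
    lengths = lengths.reindex(counts.columns)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every unigene needs a positive length")
    if totals is None:
        totals = counts.sum(axis=1)
    totals = totals.reindex(counts.index)
    zero = totals[(totals.isna()) | (totals <= 0)]
    if len(zero):
        raise ValueError(
            f"zero or missing total aligned reads for accession(s): {list(zero.index)}"
        )
    rpkm = 1e9 * counts.div(totals, axis=0).div(lengths, axis=1)
    return ExpressionMatrix(rpkm=rpkm, lengths=lengths, totals=totals)


def filter_gems(
    expr: ExpressionMatrix, min_mean_rpkm: float = 0.4, statistic: str = "mean"
) -> ExpressionMatrix:
    """Remove unigenes with low abundance across accessions.

    A unigene is removed when its across-accession summary (mean by
    default; ``statistic='max'`` available) of RPKM is below
    ``min_mean_rpkm`` — strict inequality, the boundary is retained.
    """
    if statistic == "mean":
        summary = expr.rpkm.mean(axis=0)
    elif statistic == "max":
        summary = expr.rpkm.max(axis=0)
    else:
        raise ValueError("statistic must be 'mean' or 'max'")
    keep = summary >= min_mean_rpkm
    return ExpressionMatrix(
        rpkm=expr.rpkm.loc[:, keep[keep].index],
        lengths=expr.lengths[keep[keep].index],
        totals=expr.totals,
    )
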