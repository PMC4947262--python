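"""Stem material-strength traits from three-point bend tests.

A dried internode section rests on two supports a span ``L`` apart and is
loaded centrally (half-span ``a = L/2``).  The instrument records ``Fmax``,
the peak force at failure, and ``F/V``, the slope of the load curve during
the elastic phase.  Cross-section image analysis supplies the whole-stem
and hollow (lumen) areas, from which equivalent circular diameters and the
annular second moment of area ``I`` follow.  Material strength is then

    I   = pi * (D2**4 - D1a**4) / 64
    MOR = Fmax * a * D2 / I
    MOE = (F/V) * (a**2 / 12) * (3*L - 4*a) / I

``F/V`` is consumed in the instrument's recorded units exactly as logged
(with a constant probe speed the time-slope is proportional to the
deflection-slope), so MOE values stay on the conventional reporting scale
for this assay; no unit conversion is applied.

Replicate records from multiple harvest years are combined into per-accession
predicted means by an additive accession + year least-squares fit, and a
pairwise Pearson correlation table summarises the trait relationships.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "diameter_from_area",
    "second_moment",
    "modulus_of_rupture",
    "modulus_of_elasticity",
    "breakage_score",
    "derive_traits",
    "predicted_means",
    "correlation_table",
    "CorrelationTable",
]

#: Columns a replicate-level specimen table must carry for trait derivation.
SPECIMEN_COLUMNS = (
    "accession",
    "year",
    "replicate",
    "Fmax",
    "FoverV",
    "span_L",
    "half_span_a",
    "whole_stem_area",
    "hollow_area",
)


def diameter_from_area(area):
    """Equivalent circular diameter (mm) from a cross-section area (mm^2).

    Inverts A = pi * D**2 / 4.  Accepts scalars or arrays; negative areas
    raise ``ValueError``.
    """
    area = np.asarray(area, dtype=float)
    if np.any(area < 0):
        raise ValueError("cross-section area must be non-negative")
    d = 2.0 * np.sqrt(area / np.pi)
    return float(d) if d.ndim == 0 else d


def second_moment(D2, D1a):
    """Second moment of area I (mm^4) of an annulus: pi*(D2^4 - D1a^4)/64.

    ``D2`` is the outer (whole stem) diameter, ``D1a`` the hollow diameter.
    ``D1a > D2`` describes an impossible annulus and raises ``ValueError``.
    """
    D2 = np.asarray(D2, dtype=float)
    D1a = np.asarray(D1a, dtype=float)
    if np.any(D1a < 0) or np.any(D2 < 0):
        raise ValueError("diameters must be non-negative")
    if np.any(D1a > D2):
        raise ValueError("hollow diameter D1a exceeds whole-stem diameter D2")
    i = np.pi * (D2**4 - D1a**4) / 64.0
    return float(i) if i.ndim == 0 else i


def modulus_of_rupture(Fmax, a, D2, I):
    """Modulus of rupture MOR (N mm^-2) = Fmax * a * D2 / I.

    Requires I > 0 (a degenerate section has no defined material stress).
    """
    Fmax = np.asarray(Fmax, dtype=float)
    I = np.asarray(I, dtype=float)
    if np.any(I <= 0):
        raise ValueError("second moment of area must be positive")
    out = Fmax * np.asarray(a, float) * np.asarray(D2, float) / I
    return float(out) if out.ndim == 0 else out


def modulus_of_elasticity(FoverV, a, L, I):
    """Modulus of elasticity MOE = (F/V) * (a^2/12) * (3L - 4a) / I.

    With the standard central-load geometry a = L/2 this reduces to
    (F/V) * L^3 / (48 I).  ``F/V`` is used in its recorded instrument units.
    """
    FoverV = np.asarray(FoverV, dtype=float)
    a = np.asarray(a, dtype=float)
    L = np.asarray(L, dtype=float)
    I = np.asarray(I, dtype=float)
    if np.any(I <= 0):
        raise ValueError("second moment of area must be positive")
    out = FoverV * (a**2 / 12.0) * (3.0 * L - 4.0 * a) / I
    return float(out) if out.ndim == 0 else out


def breakage_score(flags) -> float:
    """Mean of 0/1 stem-failure flags over the plants tested for one accession."""
    flags = np.asarray(flags, dtype=float)
    if flags.size == 0:
        raise ValueError("breakage score needs at least one flag")
    if not np.all(np.isin(flags[~np.isnan(flags)], (0.0, 1.0))):
        raise ValueError("breakage flags must be 0 or 1")
    return float(np.nanmean(flags))


def derive_traits(specimens: pd.DataFrame) -> pd.DataFrame:
    """Append D2, D1a, I, MOR and MOE columns to a replicate-level table.

    The input must carry the raw measurement columns listed in
    ``SPECIMEN_COLUMNS``.  Geometry is taken per specimen — each plant's own
    cross-section feeds its own moduli.
    """
    missing = [c for c in SPECIMEN_COLUMNS if c not in specimens.columns]
    if missing:
        raise ValueError(f"specimen table lacks columns: {missing}")
    a = specimens["half_span_a"].to_numpy(float)
    L = specimens["span_L"].to_numpy(float)
    if np.any(np.abs(a - L / 2.0) > 1e-9 * np.maximum(L, 1.0)):
        raise ValueError("half-span a must equal L/2")

    out = specimens.copy()
    out["D2"] = diameter_from_area(out["whole_stem_area"].to_numpy(float))
    out["D1a"] = diameter_from_area(out["hollow_area"].to_numpy(float))
    out["I"] = second_moment(out["D2"].to_numpy(), out["D1a"].to_numpy())
    out["MOR"] = modulus_of_rupture(
        out["Fmax"].to_numpy(), a, out["D2"].to_numpy(), out["I"].to_numpy()
    )
    out["MOE"] = modulus_of_elasticity(
        out["FoverV"].to_numpy(), a, L, out["I"].to_numpy()
    )
    return out


def predicted_means(
    long_table: pd.DataFrame,
    traits: list[str] | None = None,
    accession_col: str = "accession",
    year_col: str = "year",
) -> pd.DataFrame:
    """Per-accession predicted trait means, adjusted for year effects.

    Fits the additive fixed-effects model

        value = mu + genotype_i + year_t + error

    by least squares with a sum-to-zero constraint on the year effects, and
    returns ``mu + genotype_i`` per accession (on balanced data this equals
    the plain arithmetic mean; with a single year it reduces to it exactly).
    Accessions with no records for a trait get NaN with a warning.
    """
    if traits is None:
        traits = [
            c
            for c in long_table.columns
            if c not in (accession_col, year_col, "replicate")
            and pd.api.types.is_numeric_dtype(long_table[c])
        ]
    accessions = pd.Index(sorted(long_table[accession_col].unique()))
    result = pd.DataFrame(index=accessions, columns=traits, dtype=float)
    result.index.name = accession_col

    for trait in traits:
        sub = long_table[[accession_col, year_col, trait]].dropna()
        if sub.empty:
            warnings.warn(f"trait {trait!r}: no records at all")
            continue
        acc_codes, acc_levels = pd.factorize(sub[accession_col], sort=True)
        yr_codes, yr_levels = pd.factorize(sub[year_col], sort=True)
        n, g, t = len(sub), len(acc_levels), len(yr_levels)
        # design: accession one-hot (absorbs mu) + sum-coded year contrasts
        X = np.zeros((n, g + max(t - 1, 0)))
        X[np.arange(n), acc_codes] = 1.0
        for j in range(t - 1):
            X[yr_codes == j, g + j] = 1.0
            X[yr_codes == t - 1, g + j] = -1.0
        beta, *_ = np.linalg.lstsq(X, sub[trait].to_numpy(float), rcond=None)
        result.loc[acc_levels, trait] = beta[:g]
        absent = accessions.difference(acc_levels)
        if len(absent):
            warnings.warn(
                f"trait {trait!r}: no records for {len(absent)} accession(s); NaN means"
            )
    return result


@dataclass
class CorrelationTable:
    """Pairwise Pearson correlations between trait means.

    ``r``, ``r2`` and ``p`` are square symmetric DataFrames; ``stars`` holds
    the conventional significance codes ('***' P<=0.001, '**' P<=0.01,
    '*' P<=0.05, '' otherwise); ``n`` counts complete pairs.
    """

    r: pd.DataFrame
    r2: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    n: pd.DataFrame


def _star_code(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def correlation_table(trait_means: pd.DataFrame) -> CorrelationTable:
    """Pairwise-complete Pearson correlation of a trait-means matrix.

    The P value tests r against zero via t = r*sqrt((n-2)/(1-r^2)) with
    n-2 degrees of freedom, two-sided.  Constant traits give NaN with a
    warning; pairs with fewer than 3 complete observations give NaN.
    """
    cols = list(trait_means.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    nmat = np.zeros((k, k), dtype=int)
    X = trait_means.to_numpy(float)
    for i in range(k):
        for j in range(i, k):
            mask = np.isfinite(X[:, i]) & np.isfinite(X[:, j])
            n = int(mask.sum())
            nmat[i, j] = nmat[j, i] = n
            if n < 3:
                continue
            xi, xj = X[mask, i], X[mask, j]
            if np.std(xi) == 0 or np.std(xj) == 0:
                warnings.warn(
                    f"constant trait in pair ({cols[i]!r}, {cols[j]!r}); NaN correlation"
                )
                continue
            if i == j:
                r[i, j], p[i, j] = 1.0, 0.0
                continue
            rij = float(np.corrcoef(xi, xj)[0, 1])
            rij = min(1.0, max(-1.0, rij))
            if abs(rij) == 1.0:
                pij = 0.0
            else:
                t = rij * np.sqrt((n - 2) / (1.0 - rij * rij))
                pij = 2.0 * stats.t.sf(abs(t), df=n - 2)
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    rdf = pd.DataFrame(r, index=cols, columns=cols)
    pdf = pd.DataFrame(p, index=cols, columns=cols)
    stars = pdf.map(_star_code)
    return CorrelationTable(
        r=rdf,
        r2=rdf**2,
        p=pdf,
        stars=stars,
        n=pd.DataFrame(nmat, index=cols, columns=cols),
    )
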