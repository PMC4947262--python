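"""Directional validation of discovery-panel markers in a test panel.

A marker found associated in the discovery panel predicts which allele
("the increasing allele") should raise the trait.  Validation genotypes an
independent panel at the chosen loci, selects a subset of accessions on
genotype alone — covering the allele-class combinations so trait prediction
is unbiased — phenotypes them, and asks the one-directional question:
do carriers of the increasing allele show a higher mean trait value?

The test is a two-sample pooled-variance Student t-test, one-sided in the
predicted direction (Welch's correction and a two-sided variant are
available by flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

__all__ = ["ValidationResult", "select_test_accessions", "segregation_test"]


@dataclass
class ValidationResult:
    """One marker's directional segregation test."""

    marker: str
    increasing_class: str
    other_class: str
    n_increasing: int
    n_other: int
    mean_increasing: float
    mean_other: float
    sd_increasing: float
    sd_other: float
    t: float
    df: float
    p_one_sided: float
    two_sided: bool = False

    @property
    def significance_band(self) -> str:
        p = self.p_one_sided
        if p <= 0.001:
            return "P<=0.001"
        if p <= 0.01:
            return "P<=0.01"
        if p <= 0.05:
            return "P<=0.05"
        return "ns"

    def to_row(self) -> dict:
        d = self.__dict__.copy()
        d["significance"] = self.significance_band
        return d


def select_test_accessions(
    genotypes: pd.DataFrame, n_target: int = 30
) -> pd.Index:
    """Pick accessions covering the allele-class combinations at target loci.

    ``genotypes`` is accessions x target markers (any hashable call
    labels; NaN = missing).  Monomorphic markers are excluded from the
    combination cross with a warning (they cannot segregate in this
    panel); if every marker is monomorphic the selection is impossible.
    Selection is greedy round-robin over the observed combination classes
    in sorted order, taking accessions in input order within each class,
    so the result is deterministic.  Every observed combination is
    represented whenever ``n_target`` allows.
    """
    informative = []
    for col in genotypes.columns:
        vals = genotypes[col].dropna().unique()
        if len(vals) >= 2:
            informative.append(col)
        else:
            warnings.warn(f"marker {col!r} monomorphic in the test panel; not used")
    if not informative:
        raise ValueError("monomorphic panel: no marker segregates at the target loci")
    if n_target >= len(genotypes):
        return genotypes.index

    combos: dict[tuple, list] = {}
    for acc, row in genotypes[informative].iterrows():
        key = tuple(row.fillna("NA"))
        combos.setdefault(key, []).append(acc)
    ordered_keys = sorted(combos, key=lambda k: tuple(map(str, k)))
    selected: list = []
    exhausted = False
    while len(selected) < n_target and not exhausted:
        exhausted = True
        for key in ordered_keys:
            if combos[key]:
                selected.append(combos[key].pop(0))
                exhausted = False
                if len(selected) >= n_target:
                    break
    return pd.Index(selected)


def segregation_test(
    trait: pd.Series,
    allele_classes: pd.Series,
    increasing_label,
    marker: str = "",
    welch: bool = False,
    two_sided: bool = False,
) -> ValidationResult:
    """Directional two-sample t-test of trait means across allele classes.

    Tests whether accessions carrying ``increasing_label`` have a higher
    mean trait value than the rest (one-sided by default).  Pooled-variance
    Student t unless ``welch``.  Both classes need n >= 2; two identical
    constant classes give P = 0.5 by convention (no evidence either way).
    """
    df_in = pd.DataFrame({"y": trait, "cls": allele_classes}).dropna()
    inc = df_in.loc[df_in["cls"] == increasing_label, "y"].to_numpy(float)
    oth = df_in.loc[df_in["cls"] != increasing_label, "y"].to_numpy(float)
    if len(inc) < 2 or len(oth) < 2:
        raise ValueError("each allele class needs at least 2 observations")
    other_labels = sorted(df_in.loc[df_in["cls"] != increasing_label, "cls"].unique())

    if inc.var(ddof=1) == 0 and oth.var(ddof=1) == 0 and inc.mean() == oth.mean():
        t_stat, dof, p_one = 0.0, float(len(inc) + len(oth) - 2), 0.5
    else:
        res = stats.ttest_ind(
            inc,
            oth,
            equal_var=not welch,
            alternative="two-sided" if two_sided else "greater",
        )
        t_stat = float(res.statistic)
        dof = float(res.df)
        p_one = float(res.pvalue)
    return ValidationResult(
        marker=marker,
        increasing_class=str(increasing_label),
        other_class="/".join(map(str, other_labels)),
        n_increasing=len(inc),
        n_other=len(oth),
        mean_increasing=float(inc.mean()),
        mean_other=float(oth.mean()),
        sd_increasing=float(inc.std(ddof=1)),
        sd_other=float(oth.std(ddof=1)),
        t=t_stat,
        df=dof,
        p_one_sided=p_one,
        two_sided=two_sided,
    )
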