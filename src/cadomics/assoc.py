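"""Per-SNP case-control association and candidate selection.

Each biallelic SNP gets an allelic (2×2 allele-count) Pearson chi-square test
of CAD cases versus controls, an odds ratio with 95% Wald CI
(Haldane–Anscombe 0.5 correction when a cell is empty), and a Bonferroni
adjusted p over the SNPs actually tested.  Candidates are SNPs with adjusted
p below 1e-7 and OR > 1 or < 0.5.  A pooled two-proportion z-test serves the
haplotype-panel frequency comparisons, and an optional covariate-adjusted
logistic regression (Wald p) stands alongside the chi-square for users who
want population-structure-style covariate control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import HET, HOM_ALT, HOM_REF, GenotypeMatrix, log



_CHROM_SPECIAL = {"X": 23.0, "Y": 24.0, "MT": 25.0, "M": 25.0}


def chrom_sort_key(col: pd.Series) -> pd.Series:
    """Numeric chromosome ordering (1..22, X, Y, MT) robust to string labels."""
    num = pd.to_numeric(col, errors="coerce")
    special = col.astype(str).str.upper().map(_CHROM_SPECIAL)
    return num.fillna(special).fillna(1000.0)


@dataclass
class AssociationResult:
    """Per-SNP allelic association table (one row per SNP)."""

    table: pd.DataFrame
    n_tests: int

    def to_frame(self) -> pd.DataFrame:
        return self.table.sort_values(
            ["chrom", "pos"], key=lambda c: chrom_sort_key(c) if c.name == "chrom" else c
        )


@dataclass(frozen=True)
class SignificanceThreshold:
    alpha: float
    n_candidates: int

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.n_candidates < 1:
            raise ValueError("alpha must be positive and n_candidates >= 1")

    @property
    def threshold(self) -> float:
        return self.alpha / self.n_candidates


def bonferroni_threshold(alpha: float, n_candidates: int) -> SignificanceThreshold:
    return SignificanceThreshold(alpha, n_candidates)


def _allele_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Alt and ref allele counts per SNP, missing calls excluded."""
    alt = 2 * (calls == HOM_ALT).sum(axis=0) + (calls == HET).sum(axis=0)
    ref = 2 * (calls == HOM_REF).sum(axis=0) + (calls == HET).sum(axis=0)
    return alt, ref


def chi_square_2x2(a: float, b: float, c: float, d: float) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) for a 2×2 table."""
    n = a + b + c + d
    row1, row2, col1, col2 = a + b, c + d, a + c, b + d
    if min(row1, row2, col1, col2) == 0 or n == 0:
        return 0.0, 1.0
    chi2 = n * (a * d - b * c) ** 2 / (row1 * row2 * col1 * col2)
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def odds_ratio(a: float, b: float, c: float, d: float) -> tuple[float, float, float]:
    """OR = ad/bc with Haldane–Anscombe correction and 95% Wald CI."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.975)
    return float(or_), float(or_ * np.exp(-z * se)), float(or_ * np.exp(z * se))


def allelic_chi_square(
    g: GenotypeMatrix, cases: pd.Index | list[str], controls: pd.Index | list[str]
) -> AssociationResult:
    """Allelic 2×2 association of every SNP, Bonferroni over SNPs tested."""
    cases, controls = pd.Index(cases), pd.Index(controls)
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both groups must be non-empty")
    case_alt, case_ref = _allele_counts(g.calls.loc[cases].to_numpy())
    ctrl_alt, ctrl_ref = _allele_counts(g.calls.loc[controls].to_numpy())

    rows = []
    for j, snp in enumerate(g.calls.columns):
        a, b = int(case_alt[j]), int(case_ref[j])
        c, d = int(ctrl_alt[j]), int(ctrl_ref[j])
        monomorphic = (a + c == 0) or (b + d == 0)
        if monomorphic:
            chi2, p = 0.0, 1.0
            or_, lo, hi = np.nan, np.nan, np.nan
        else:
            chi2, p = chi_square_2x2(a, b, c, d)
            or_, lo, hi = odds_ratio(a, b, c, d)
        rows.append((a, b, c, d, chi2, p, or_, lo, hi, monomorphic))
    m = len(rows)
    table = pd.DataFrame(
        rows,
        index=g.calls.columns,
        columns=[
            "case_alt", "case_ref", "ctrl_alt", "ctrl_ref",
            "chi2", "p", "odds_ratio", "or_ci_low", "or_ci_high", "or_undefined",
        ],
    )
    table["p_adj"] = np.minimum(table["p"] * m, 1.0)
    table["chrom"] = g.snps["chrom"]
    table["pos"] = g.snps["pos"]
    table["candidate"] = (table["p_adj"] < 1e-7) & (
        (table["odds_ratio"] > 1) | (table["odds_ratio"] < 0.5)
    )
    log.info("allelic_chi_square snps=%d cases=%d controls=%d", m, len(cases), len(controls))
    return AssociationResult(table, m)


def select_candidates(
    results: AssociationResult, adj_p_max: float = 1e-7, or_rule: str = "gt1_or_lt0.5"
) -> list[str]:
    """SNPs passing the adjusted-p and odds-ratio rule, ordered by position.

    ``or_rule`` "gt1_or_lt0.5" applies the printed asymmetric rule; "symmetric"
    requires OR > 2 or < 0.5.
    """
    t = results.table
    if or_rule == "gt1_or_lt0.5":
        or_ok = (t["odds_ratio"] > 1) | (t["odds_ratio"] < 0.5)
    elif or_rule == "symmetric":
        or_ok = (t["odds_ratio"] > 2) | (t["odds_ratio"] < 0.5)
    else:
        raise ValueError(f"unknown or_rule {or_rule!r}")
    sel = t[(t["p_adj"] < adj_p_max) & or_ok & ~t["or_undefined"]]
    return sel.sort_values(
        ["chrom", "pos"], key=lambda c: chrom_sort_key(c) if c.name == "chrom" else c
    ).index.tolist()


def proportion_test(
    counts_a: tuple[int, int], counts_b: tuple[int, int]
) -> tuple[float, float]:
    """Two-proportion z-test with pooled variance, two-sided."""
    (xa, na), (xb, nb) = counts_a, counts_b
    if na <= 0 or nb <= 0:
        raise ValueError("sample sizes must be positive")
    p_pool = (xa + xb) / (na + nb)
    se = np.sqrt(p_pool * (1 - p_pool) * (1 / na + 1 / nb))
    if se == 0:
        return 0.0, 1.0
    z = (xa / na - xb / nb) / se
    return float(z), float(2 * stats.norm.sf(abs(z)))


def covariate_adjusted_logistic(
    g: GenotypeMatrix,
    snp: str,
    labels: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> dict:
    """Logistic regression of case status on the 0/0.5/1 genotype plus covariates.

    A plain fixed-effects stand-in for mixed-model association; reported beside
    the chi-square so discrepancies are visible.
    """
    import statsmodels.api as sm

    from .preprocess import encode_and_impute

    enc = encode_and_impute(g.subset([snp]))[snp]
    X = enc.to_frame("genotype")
    if covariates is not None:
        X = pd.concat([X, covariates.loc[X.index]], axis=1)
    X = sm.add_constant(X.astype(float))
    fit = sm.Logit(labels.loc[X.index].astype(int), X).fit(disp=0)
    return {
        "beta": float(fit.params["genotype"]),
        "or": float(np.exp(fit.params["genotype"])),
        "p": float(fit.pvalues["genotype"]),
    }


def manhattan_table(results: AssociationResult, p_floor: float = 1e-300) -> pd.DataFrame:
    """Plot-ready table: chrom, pos, −log10(p), candidate flag, genome coordinate."""
    t = results.table.sort_values(
        ["chrom", "pos"], key=lambda c: chrom_sort_key(c) if c.name == "chrom" else c
    ).copy()
    capped = t["p"] < p_floor
    t["neg_log10_p"] = -np.log10(t["p"].clip(lower=p_floor))
    t["p_capped"] = capped
    offset, offsets = 0, {}
    for chrom, sub in t.groupby("chrom", sort=False):
        offsets[chrom] = offset
        offset += int(sub["pos"].max()) + 1
    t["genome_coord"] = t["pos"] + t["chrom"].map(offsets)
    return t[["chrom", "pos", "neg_log10_p", "candidate", "p_capped", "genome_coord"]]
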