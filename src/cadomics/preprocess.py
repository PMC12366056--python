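"""Metabolite normalization and SNP quality control / numeric encoding.

Two metabolite transforms are provided.  ``normalize_metabolites`` is the
median/log2 scheme used before clustering: per metabolite, missing values are
imputed with the median of the observed values, exact zeros are replaced by
0.001 so the log is defined, each value is divided by the metabolite's median
(recomputed after imputation and zero substitution) and log2-transformed.
``unit_variance_scale`` is the centering + unit-variance scaling used before
OPLS-DA.

SNP QC applies three sequential filters — minor allele frequency < 0.01,
Hardy-Weinberg disequilibrium in the controls (chi-square goodness of fit,
1 df, p < 1e-6), missing rate > 10% — attributing each removed SNP to the
first filter it fails.  Retained genotypes are encoded 0 / 0.5 / 1
(hom-ref / het / hom-alt) and missing cells imputed with the per-SNP median
of the encoded values, snapped to the nearest legal code (ties → 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix, MetaboliteMatrix, log

ZERO_REPLACEMENT = 0.001


@dataclass
class NormalizedMatrix:
    """Subjects × features matrix after a named transform, with its constants."""

    values: pd.DataFrame
    transform: str  # "median_log2" | "unit_variance"
    scale: pd.Series  # per-feature median or standard deviation
    center: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("normalized matrix may not contain missing values")
        if (self.scale <= 0).any():
            raise ValueError("scaling constants must be strictly positive")


def normalize_metabolites(m: MetaboliteMatrix) -> NormalizedMatrix:
    """Median/log2 normalization (see module docstring for the step order)."""
    vals = m.values.astype(float).copy()
    if vals.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    entirely_missing = vals.isna().all(axis=0)
    if entirely_missing.any():
        raise ValueError(
            f"metabolite(s) entirely missing: {vals.columns[entirely_missing].tolist()[:5]}"
        )
    vals = vals.fillna(vals.median(axis=0))
    vals = vals.mask(vals == 0.0, ZERO_REPLACEMENT)
    medians = vals.median(axis=0)
    assert (medians > 0).all(), "median must be positive after zero substitution"
    out = np.log2(vals / medians)
    log.info("normalize_metabolites subjects=%d metabolites=%d", *vals.shape)
    return NormalizedMatrix(out, "median_log2", scale=medians)


def unit_variance_scale(m: MetaboliteMatrix | pd.DataFrame, ddof: int = 1) -> NormalizedMatrix:
    """Center each metabolite and divide by its sample standard deviation."""
    vals = (m.values if isinstance(m, MetaboliteMatrix) else m).astype(float)
    if vals.isna().any().any():
        raise ValueError("unit-variance scaling requires a complete matrix")
    sd = vals.std(axis=0, ddof=ddof)
    zero_var = sd <= 0
    if zero_var.any():
        raise ValueError(f"zero-variance feature(s): {vals.columns[zero_var].tolist()[:5]}")
    mean = vals.mean(axis=0)
    return NormalizedMatrix((vals - mean) / sd, "unit_variance", scale=sd, center=mean)


# ---------------------------------------------------------------- SNP QC


@dataclass
class SnpQcReport:
    """Per-SNP QC metrics and sequential pass/fail attribution."""

    table: pd.DataFrame  # columns: maf, hwe_p, missing_rate, status
    n_input: int
    n_removed: dict[str, int]
    n_retained: int

    def __post_init__(self) -> None:
        assert self.n_input == self.n_retained + sum(self.n_removed.values())

    def to_frame(self) -> pd.DataFrame:
        return self.table


def hwe_chi_square(n_hom_ref: int, n_het: int, n_hom_alt: int) -> tuple[float, float]:
    """Hardy-Weinberg goodness-of-fit chi-square (1 df) on genotype counts.

    Expected counts are n·p², n·2pq, n·q² with q the observed alt-allele
    frequency.  Monomorphic sites fit exactly (statistic 0, p = 1).
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 0.0, 1.0
    q = (2 * n_hom_alt + n_het) / (2 * n)
    p = 1.0 - q
    expected = np.array([n * p * p, n * 2 * p * q, n * q * q])
    observed = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    nz = expected > 0
    chi2 = float(((observed[nz] - expected[nz]) ** 2 / expected[nz]).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def _genotype_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return (
        (calls == HOM_REF).sum(axis=0),
        (calls == HET).sum(axis=0),
        (calls == HOM_ALT).sum(axis=0),
    )


def snp_qc(
    g: GenotypeMatrix,
    controls: pd.Index | list[str],
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-6,
    missing_max: float = 0.10,
) -> tuple[GenotypeMatrix, SnpQcReport]:
    """Sequential SNP filtering: MAF, then HWE in controls, then missing rate.

    MAF uses observed (non-missing) allele counts over the whole cohort; the
    HWE test uses genotype counts in the control subjects only.
    """
    controls = pd.Index(controls)
    if len(controls) == 0:
        raise ValueError("control subset is empty")
    missing_controls = controls.difference(g.subjects)
    if len(missing_controls):
        raise ValueError(f"controls not in genotype matrix: {missing_controls[:3].tolist()}")

    calls = g.calls.to_numpy()
    n_rr, n_ra, n_aa = _genotype_counts(calls)
    n_obs = n_rr + n_ra + n_aa
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.where(n_obs > 0, (2 * n_aa + n_ra) / (2 * np.maximum(n_obs, 1)), 0.0)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    missing_rate = (calls == MISSING).mean(axis=0)

    ctrl_calls = g.calls.loc[controls].to_numpy()
    c_rr, c_ra, c_aa = _genotype_counts(ctrl_calls)
    hwe_p = np.array(
        [hwe_chi_square(int(a), int(b), int(c))[1] for a, b, c in zip(c_rr, c_ra, c_aa)]
    )

    status = np.full(g.calls.shape[1], "pass", dtype=object)
    status[np.where(maf < maf_min)[0]] = "maf"
    hwe_fail = (hwe_p < hwe_p_min) & (status == "pass")
    status[hwe_fail] = "hwe"
    miss_fail = (missing_rate > missing_max) & (status == "pass")
    status[miss_fail] = "missing_rate"

    table = pd.DataFrame(
        {"maf": maf, "hwe_p": hwe_p, "missing_rate": missing_rate, "status": status},
        index=g.calls.columns,
    )
    keep = table.index[status == "pass"]
    n_removed = {
        reason: int((status == reason).sum()) for reason in ("maf", "hwe", "missing_rate")
    }
    report = SnpQcReport(table, g.calls.shape[1], n_removed, len(keep))
    if len(keep) == 0:
        log.warning("snp_qc removed every SNP")
    log.info(
        "snp_qc n_input=%d retained=%d removed=%s", report.n_input, report.n_retained, n_removed
    )
    return g.subset(keep), report


ENCODING = {HOM_REF: 0.0, HET: 0.5, HOM_ALT: 1.0}
_LEGAL = np.array([0.0, 0.5, 1.0])


def _snap(x: float) -> float:
    """Nearest legal code; exact ties snap to 0.5."""
    d = np.abs(_LEGAL - x)
    best = d.min()
    hits = _LEGAL[np.isclose(d, best)]
    return 0.5 if len(hits) > 1 else float(hits[0])


def encode_and_impute(g: GenotypeMatrix) -> pd.DataFrame:
    """Encode genotypes 0/0.5/1 and median-impute missing cells per SNP."""
    calls = g.calls.to_numpy().astype(float)
    enc = np.where(calls == MISSING, np.nan, calls / 2.0)
    zero_obs = np.isnan(enc).all(axis=0)
    if zero_obs.any():
        raise ValueError(
            f"SNP(s) with no observed calls: {g.calls.columns[zero_obs].tolist()[:5]}"
        )
    col_median = np.nanmedian(enc, axis=0)
    fill = np.array([_snap(m) for m in col_median])
    rows, cols = np.where(np.isnan(enc))
    enc[rows, cols] = fill[cols]
    return pd.DataFrame(enc, index=g.calls.index, columns=g.calls.columns)
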