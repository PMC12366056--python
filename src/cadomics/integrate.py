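"""Intersection of the two cluster solutions into genetic–metabolic subtypes,
cross-layer enrichment testing, and the rule-based five-SNP haplotype caller.

The haplotype classes are diplotype rules over the LPCAT1 panel
(rs36993, rs9799949, rs10475026, rs1032751, rs1032752):

* haplotype 3 — homozygous alternate at all five SNPs;
* haplotype 2 — homozygous reference at rs1032752, rs1032751, rs10475026 and
  rs9799949, combined with homozygous alternate at rs36993;
* haplotype 1 — every other combination (wild type).  A missing call anywhere
  in the panel conservatively yields haplotype 1 with a missing-data flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GROUPS, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix, check_aligned, log
from .assoc import chi_square_2x2
from .cluster import ClusterSolution

HAPLOTYPE_PANEL = ("rs36993", "rs9799949", "rs10475026", "rs1032751", "rs1032752")
#: SNPs that are hom-ref under the haplotype-2 rule (the fifth, rs36993, is hom-alt).
_HAP2_HOM_REF = ("rs1032752", "rs1032751", "rs10475026", "rs9799949")


# ---------------------------------------------------------------- enrichment


@dataclass
class EnrichmentResult:
    crosstab: pd.DataFrame
    pair_tests: pd.DataFrame  # per tested hypothesis: chi2, p, p_adj

    def to_frame(self) -> pd.DataFrame:
        return self.pair_tests


def pearson_chi_square(table: np.ndarray) -> tuple[float, float, int]:
    """Classical Pearson chi-square for an r×c contingency table."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    nz = expected > 0
    chi2 = float(((table[nz] - expected[nz]) ** 2 / expected[nz]).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return chi2, float(stats.chi2.sf(chi2, df=df)), df


def crosstab_enrichment(
    a: ClusterSolution,
    b: ClusterSolution,
    hypotheses: list[tuple[int, tuple[int, ...]]] | None = None,
) -> EnrichmentResult:
    """Cross-tabulate two partitions and test 2×2 collapses for enrichment.

    Each hypothesis is (cluster of ``a``, set of clusters of ``b``); the 2×2
    collapse counts subjects in/out of each margin.  By default every
    (a-cluster, single b-cluster) pair is tested; p-values are Bonferroni
    adjusted over the hypotheses tested.
    """
    check_aligned(a.assignments.index, b.assignments.index)
    ct = pd.crosstab(a.assignments, b.assignments)
    if hypotheses is None:
        hypotheses = [(i, (j,)) for i in ct.index for j in ct.columns]
    rows = []
    for a_label, b_set in hypotheses:
        in_a = a.assignments == a_label
        in_b = b.assignments.isin(b_set)
        t11 = int((in_a & in_b).sum())
        t12 = int((in_a & ~in_b).sum())
        t21 = int((~in_a & in_b).sum())
        t22 = int((~in_a & ~in_b).sum())
        chi2, p = chi_square_2x2(t11, t12, t21, t22)
        rows.append((a_label, "+".join(map(str, b_set)), t11, t12, t21, t22, chi2, p))
    tests = pd.DataFrame(
        rows, columns=["cluster_a", "clusters_b", "n11", "n12", "n21", "n22", "chi2", "p"]
    )
    tests["p_adj"] = np.minimum(tests["p"] * len(tests), 1.0)
    return EnrichmentResult(ct, tests)


def derive_subtype_rules(
    a: ClusterSolution,
    b: ClusterSolution,
    target_clusters: tuple[int, int],
    residual_min: float = 2.0,
) -> dict[str, tuple[int, tuple[int, ...]]]:
    """For each targeted a-cluster, pick the b-clusters with standardized
    Pearson residuals above ``residual_min`` in the cross-tab.

    Automates the pairing of metabolomic clusters with their enriched genetic
    clusters; cluster labels are fit-specific, so the rules are data, not
    constants.
    """
    check_aligned(a.assignments.index, b.assignments.index)
    ct = pd.crosstab(a.assignments, b.assignments).astype(float)
    n = ct.to_numpy().sum()
    rowp = ct.sum(axis=1) / n
    colp = ct.sum(axis=0) / n
    expected = np.outer(rowp, colp) * n
    denom = np.sqrt(expected * np.outer(1 - rowp, 1 - colp))
    resid = (ct.to_numpy() - expected) / denom
    rules = {}
    for name, a_label in zip(("Subtype-I", "Subtype-II"), target_clusters):
        i = list(ct.index).index(a_label)
        enriched = tuple(ct.columns[np.where(resid[i] > residual_min)[0]])
        rules[name] = (a_label, enriched)
    return rules


# ---------------------------------------------------------------- subtypes


@dataclass
class SubtypeAssignment:
    table: pd.DataFrame  # columns: metabolomic_cluster, genetic_cluster, subtype
    rules: dict[str, tuple[int, tuple[int, ...]]]

    def counts(self) -> pd.Series:
        return self.table["subtype"].value_counts()

    def to_frame(self) -> pd.DataFrame:
        return self.table


def assign_subtypes(
    a: ClusterSolution,
    b: ClusterSolution,
    rules: dict[str, tuple[int, tuple[int, ...]]],
) -> SubtypeAssignment:
    """Map each subject's (metabolomic, genetic) cluster pair to a subtype.

    ``rules`` maps subtype name -> (a-cluster, set of b-clusters); rules must
    not overlap; unmatched subjects are "unassigned".
    """
    check_aligned(a.assignments.index, b.assignments.index)
    seen: set[tuple[int, int]] = set()
    for name, (a_label, b_set) in rules.items():
        pairs = {(a_label, bl) for bl in b_set}
        if pairs & seen:
            raise ValueError(f"overlapping subtype rules at {name!r}")
        seen |= pairs
    subtype = pd.Series("unassigned", index=a.assignments.index, name="subtype")
    for name, (a_label, b_set) in rules.items():
        mask = (a.assignments == a_label) & b.assignments.isin(b_set)
        subtype[mask] = name
    table = pd.DataFrame(
        {
            "metabolomic_cluster": a.assignments,
            "genetic_cluster": b.assignments,
            "subtype": subtype,
        }
    )
    return SubtypeAssignment(table, rules)


# ---------------------------------------------------------------- haplotypes


@dataclass
class HaplotypeCall:
    haplotype: pd.Series  # 1 | 2 | 3 per subject
    genotypes: pd.DataFrame  # the five calls consumed
    missing_flag: pd.Series

    def to_frame(self) -> pd.DataFrame:
        out = self.genotypes.copy()
        out["haplotype"] = self.haplotype
        out["missing_flag"] = self.missing_flag
        return out


def classify_panel_genotypes(calls: np.ndarray, panel: tuple[str, ...]) -> int:
    """Classify one subject's five panel genotypes into haplotype 1/2/3."""
    if (calls == MISSING).any():
        return 1
    if (calls == HOM_ALT).all():
        return 3
    hap2 = np.full(5, HOM_REF, dtype=calls.dtype)
    hap2[list(panel).index("rs36993")] = HOM_ALT
    if (calls == hap2).all():
        return 2
    return 1


def call_haplotypes(
    g: GenotypeMatrix, panel: tuple[str, ...] = HAPLOTYPE_PANEL
) -> HaplotypeCall:
    """Apply the diplotype rules over the five-SNP panel to every subject."""
    missing_snps = [s for s in panel if s not in g.calls.columns]
    if missing_snps:
        raise ValueError(f"panel SNP(s) absent from genotype matrix: {missing_snps}")
    sub = g.calls[list(panel)]
    arr = sub.to_numpy()
    missing_flag = (arr == MISSING).any(axis=1)
    hap3 = (arr == HOM_ALT).all(axis=1) & ~missing_flag
    hap2_pat = np.full(5, HOM_REF, dtype=arr.dtype)
    hap2_pat[list(panel).index("rs36993")] = HOM_ALT
    hap2 = (arr == hap2_pat).all(axis=1) & ~missing_flag
    hap = np.where(hap3, 3, np.where(hap2, 2, 1)).astype(np.int8)
    log.info(
        "call_haplotypes n=%d hap1=%d hap2=%d hap3=%d",
        len(hap), int((hap == 1).sum()), int((hap == 2).sum()), int((hap == 3).sum()),
    )
    return HaplotypeCall(
        pd.Series(hap, index=sub.index, name="haplotype"),
        sub,
        pd.Series(missing_flag, index=sub.index, name="missing_flag"),
    )


def haplotype_group_frequencies(
    calls: HaplotypeCall, cohort: pd.DataFrame
) -> dict[str, pd.DataFrame | float]:
    """Haplotype frequencies per group, the reverse conditioning, and the
    haplotype × group chi-square."""
    check_aligned(calls.haplotype.index, cohort.index)
    groups = cohort["group"]
    for gname in GROUPS:
        if (groups == gname).sum() == 0:
            raise ValueError(f"empty group {gname!r}")
    ct = pd.crosstab(calls.haplotype, groups).reindex(columns=list(GROUPS), fill_value=0)
    freq_in_group = ct / ct.sum(axis=0)  # per group, shares over haplotypes
    group_share = ct.div(ct.sum(axis=1), axis=0)  # per haplotype, shares over groups
    if (ct.to_numpy().sum(axis=1) > 0).sum() < 2:
        chi2, p = 0.0, 1.0
    else:
        nonzero = ct[ct.sum(axis=1) > 0]
        chi2, p, _ = pearson_chi_square(nonzero.to_numpy())
    return {
        "counts": ct,
        "frequency_by_group": freq_in_group,
        "group_share_by_haplotype": group_share,
        "chi2": chi2,
        "p": p,
    }
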