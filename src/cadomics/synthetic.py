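"""Synthetic cohort generator.

Emulates the structure the downstream analysis assumes: three clinical groups
(control / high-risk / CAD), a genome-wide biallelic SNP matrix containing a
five-SNP haplotype block whose all-alt-homozygous diplotype rises in frequency
across groups, a targeted metabolite panel with latent subject clusters coupled
across the two omics layers, a subset of group-informative metabolites, and
realistic missingness/zeros.  Every stage draws from its own child stream of a
single root seed, so e.g. adding SNPs does not perturb the metabolite draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    GROUPS,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    GenotypeMatrix,
    MetaboliteMatrix,
    validate_cohort,
    write_vcf,
)

#: The five-SNP panel with ref>alt alleles; block sits on chromosome 5.
DEFAULT_HAPLOTYPE_BLOCK = ("rs36993", "rs9799949", "rs10475026", "rs1032751", "rs1032752")
_BLOCK_ALLELES = {
    "rs36993": ("A", "G"),
    "rs9799949": ("C", "T"),
    "rs10475026": ("A", "C"),
    "rs1032751": ("T", "C"),
    "rs1032752": ("G", "A"),
}

#: Group-wise clinical parameter defaults (mean, sd) / Bernoulli rates,
#: matching the study cohort's descriptive statistics.
_AGE = ((56.3, 14.4), (65.7, 10.6), (63.8, 10.1))
_BMI = ((23.55, 4.06), (27.37, 3.65), (27.62, 4.13))
_MALE_FRAC = (0.354, 0.416, 0.741)
_MEDICATIONS = {
    "statin": (0.066, 0.237, 0.714),
    "fibrate": (0.000, 0.028, 0.027),
    "ccb": (0.004, 0.196, 0.211),
    "beta_blocker": (0.074, 0.127, 0.320),
    "arb": (0.015, 0.251, 0.293),
    "diuretics": (0.018, 0.061, 0.109),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the generated cohort.

    ``hap3_frequency`` is the per-group target frequency of the
    all-alt-homozygous diplotype over the five block SNPs; ``effect_size`` is
    the standardized (log-scale, noise-sd units) metabolite mean shift per
    control→high-risk→CAD step for informative features, and also scales the
    separation of the latent metabolite clusters; ``coupling_strength`` is the
    probability that a subject's metabolomic latent cluster copies its genetic
    latent cluster.
    """

    n_per_group: tuple[int, int, int] = (271, 363, 147)
    n_snps: int = 300
    n_metabolites: int = 143
    haplotype_block: tuple[str, str, str, str, str] = DEFAULT_HAPLOTYPE_BLOCK
    hap3_frequency: tuple[float, float, float] = (0.1333, 0.1928, 0.2721)
    hap2_frequency: tuple[float, float, float] = (0.08, 0.03, 0.01)
    n_informative_features: int = 10
    effect_size: float = 1.0
    metabolite_missing_rate: float = 0.02
    zero_rate: float = 0.01
    genotype_missing_rate: float = 0.01
    coupling_strength: float = 0.9
    n_latent_clusters: int = 5
    n_cluster_snps: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.haplotype_block) != 5:
            raise ValueError("haplotype block must list exactly 5 SNP ids")
        if any(n <= 0 for n in self.n_per_group):
            raise ValueError("group sizes must be positive")
        if self.n_informative_features > self.n_metabolites:
            raise ValueError("n_informative_features exceeds n_metabolites")
        if self.n_informative_features < 0:
            raise ValueError("n_informative_features must be non-negative")
        fracs = (
            *self.hap3_frequency,
            *self.hap2_frequency,
            self.metabolite_missing_rate,
            self.zero_rate,
            self.genotype_missing_rate,
            self.coupling_strength,
        )
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("all fractions must lie in [0, 1]")
        for f2, f3 in zip(self.hap2_frequency, self.hap3_frequency):
            if f2 + f3 > 1.0:
                raise ValueError("hap2 + hap3 frequency exceeds 1 in a group")
        if self.n_snps < 5 + self.n_cluster_snps:
            raise ValueError("n_snps must cover the block plus cluster-informative SNPs")


@dataclass
class GroundTruth:
    """What was planted: latent clusters per layer, haplotype class, features."""

    genetic_cluster: pd.Series
    metabolomic_cluster: pd.Series
    haplotype: pd.Series
    informative_features: list[str]


@dataclass
class SyntheticCohort:
    cohort: pd.DataFrame
    genotypes: GenotypeMatrix
    metabolites: MetaboliteMatrix
    truth: GroundTruth


def _child_rngs(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _draw_hwe_genotypes(rng: np.random.Generator, n: int, p_alt: float) -> np.ndarray:
    alt = rng.binomial(2, p_alt, size=n)
    return np.array((HOM_REF, HET, HOM_ALT), dtype=np.int8)[alt]


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort; identical config+seed → identical output."""
    rngs = _child_rngs(
        config.seed,
        ("phenotype", "latent", "block", "cluster_snps", "null_snps", "metabolites", "missing"),
    )
    n = sum(config.n_per_group)
    group_idx = np.repeat(np.arange(3), config.n_per_group)
    subjects = pd.Index([f"S{i + 1:05d}" for i in range(n)], name="subject_id")

    cohort = _make_phenotypes(rngs["phenotype"], subjects, group_idx)
    gen_cluster, met_cluster = _make_latent_clusters(rngs["latent"], config, n)
    genotypes, haplotype = _make_genotypes(rngs, config, subjects, group_idx, gen_cluster)
    metabolites, informative = _make_metabolites(
        rngs["metabolites"], rngs["missing"], config, subjects, group_idx, met_cluster
    )
    truth = GroundTruth(
        genetic_cluster=pd.Series(gen_cluster + 1, index=subjects, name="genetic_cluster"),
        metabolomic_cluster=pd.Series(met_cluster + 1, index=subjects, name="metabolomic_cluster"),
        haplotype=haplotype,
        informative_features=informative,
    )
    return SyntheticCohort(cohort, genotypes, metabolites, truth)


def _make_phenotypes(rng, subjects, group_idx) -> pd.DataFrame:
    n = len(subjects)
    age = np.empty(n)
    bmi = np.empty(n)
    male = np.empty(n, dtype=bool)
    for gi in range(3):
        mask = group_idx == gi
        m = mask.sum()
        age[mask] = rng.normal(*_AGE[gi], size=m)
        bmi[mask] = rng.normal(*_BMI[gi], size=m)
        male[mask] = rng.random(m) < _MALE_FRAC[gi]
    df = pd.DataFrame(
        {
            "group": np.array(GROUPS)[group_idx],
            "sex": np.where(male, "male", "female"),
            "age": np.clip(age, 20, 95).round(1),
            "bmi": np.clip(bmi, 14, 50).round(2),
        },
        index=subjects,
    )
    for med, rates in _MEDICATIONS.items():
        flags = np.empty(n, dtype=bool)
        for gi in range(3):
            mask = group_idx == gi
            flags[mask] = rng.random(mask.sum()) < rates[gi]
        df[med] = flags
    return validate_cohort(df)


def _make_latent_clusters(rng, config, n):
    k = config.n_latent_clusters
    gen = rng.integers(0, k, size=n)
    copy = rng.random(n) < config.coupling_strength
    met = np.where(copy, gen, rng.integers(0, k, size=n))
    return gen, met


def _block_patterns(block: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Genotype vectors defining haplotype 3 and haplotype 2 over the panel."""
    hap3 = np.full(5, HOM_ALT, dtype=np.int8)
    hap2 = np.full(5, HOM_REF, dtype=np.int8)
    hap2[list(block).index("rs36993")] = HOM_ALT
    return hap3, hap2


def _make_genotypes(rngs, config, subjects, group_idx, gen_cluster):
    n = len(subjects)
    block = list(config.haplotype_block)
    hap3_pat, hap2_pat = _block_patterns(config.haplotype_block)

    # --- haplotype block: draw the diplotype class per subject, then render
    rng = rngs["block"]
    u = rng.random(n)
    f3 = np.asarray(config.hap3_frequency)[group_idx]
    f2 = np.asarray(config.hap2_frequency)[group_idx]
    hap = np.where(u < f3, 3, np.where(u < f3 + f2, 2, 1)).astype(np.int8)
    block_calls = np.empty((n, 5), dtype=np.int8)
    block_calls[hap == 3] = hap3_pat
    block_calls[hap == 2] = hap2_pat
    other = np.flatnonzero(hap == 1)
    block_maf = rng.uniform(0.2, 0.4, size=5)
    draws = np.column_stack(
        [_draw_hwe_genotypes(rng, len(other), block_maf[j]) for j in range(5)]
    )
    # redraw any "other" subject that collides with a planted pattern
    for _ in range(100):
        collide = np.flatnonzero(
            (draws == hap3_pat).all(axis=1) | (draws == hap2_pat).all(axis=1)
        )
        if collide.size == 0:
            break
        draws[collide] = np.column_stack(
            [_draw_hwe_genotypes(rng, collide.size, block_maf[j]) for j in range(5)]
        )
    block_calls[other] = draws

    # --- cluster-informative SNPs: allele frequency depends on the latent cluster
    rng = rngs["cluster_snps"]
    n_cs = config.n_cluster_snps
    k = config.n_latent_clusters
    freq = np.clip(rng.beta(0.5, 0.5, size=(n_cs, k)), 0.05, 0.95)
    cluster_calls = np.empty((n, n_cs), dtype=np.int8)
    for c in range(k):
        mask = gen_cluster == c
        for j in range(n_cs):
            cluster_calls[mask, j] = _draw_hwe_genotypes(rng, mask.sum(), freq[j, c])

    # --- remaining null SNPs: independent random MAFs
    rng = rngs["null_snps"]
    n_null = config.n_snps - 5 - n_cs
    null_maf = rng.uniform(0.05, 0.5, size=n_null)
    null_calls = np.empty((n, n_null), dtype=np.int8)
    for j in range(n_null):
        null_calls[:, j] = _draw_hwe_genotypes(rng, n, null_maf[j])

    # --- missingness outside the block (the five-SNP panel stays complete)
    non_block = np.concatenate([cluster_calls, null_calls], axis=1)
    if config.genotype_missing_rate > 0:
        miss = rng.random(non_block.shape) < config.genotype_missing_rate
        non_block[miss] = MISSING

    calls = np.concatenate([block_calls, non_block], axis=1)
    ids = block + [f"snp{j + 1:05d}" for j in range(n_cs + n_null)]
    chrom = ["5"] * 5 + [str(1 + j % 22) for j in range(n_cs + n_null)]
    pos = list(range(1_461_000, 1_461_000 + 5 * 500, 500)) + [
        10_000 + 137 * (j // 22 + 1) for j in range(n_cs + n_null)
    ]
    ref = [_BLOCK_ALLELES.get(i, ("A", "G"))[0] for i in ids]
    alt = [_BLOCK_ALLELES.get(i, ("A", "G"))[1] for i in ids]
    snps = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt},
        index=pd.Index(ids, name="snp_id"),
    )
    g = GenotypeMatrix(pd.DataFrame(calls, index=subjects, columns=ids), snps)
    return g, pd.Series(hap, index=subjects, name="haplotype")


def _make_metabolites(rng, rng_missing, config, subjects, group_idx, met_cluster):
    n, p = len(subjects), config.n_metabolites
    names = [f"met{j + 1:03d}" for j in range(p)]
    informative = names[: config.n_informative_features]

    base = rng.normal(np.log(50.0), 1.0, size=p)  # per-metabolite log-abundance
    # latent-cluster offsets: per (metabolite, cluster) a ± effect_size/2 shift
    signs = rng.choice((-0.5, 0.5), size=(p, config.n_latent_clusters))
    cluster_shift = config.effect_size * signs[:, met_cluster].T  # n × p
    group_shift = np.zeros((n, p))
    group_shift[:, : config.n_informative_features] = (
        config.effect_size * group_idx[:, None]
    )
    logval = base[None, :] + cluster_shift + group_shift + rng.normal(0.0, 1.0, (n, p))
    conc = np.exp(logval)

    u = rng_missing.random((n, p))
    conc[u < config.zero_rate] = 0.0
    conc[(u >= config.zero_rate) & (u < config.zero_rate + config.metabolite_missing_rate)] = np.nan

    values = pd.DataFrame(conc, index=subjects, columns=names)
    return MetaboliteMatrix(values), informative


# ---------------------------------------------------------------- persistence


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write the cohort to disk: TSV tables plus a VCF (and TSV mirror) of genotypes.

    Returns a manifest mapping logical names to file paths; the files round-trip
    through the ``cadomics.io`` readers.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest = {
        "phenotype": d / "phenotype.tsv",
        "metabolites": d / "metabolites.tsv",
        "genotypes_vcf": d / "genotypes.vcf",
        "genotypes_tsv": d / "genotypes.tsv",
        "snp_metadata": d / "snp_metadata.tsv",
        "ground_truth": d / "ground_truth.tsv",
    }
    cohort.cohort.to_csv(manifest["phenotype"], sep="\t")
    cohort.metabolites.values.to_csv(manifest["metabolites"], sep="\t")
    write_vcf(cohort.genotypes, manifest["genotypes_vcf"])
    cohort.genotypes.calls.to_csv(manifest["genotypes_tsv"], sep="\t")
    cohort.genotypes.snps.to_csv(manifest["snp_metadata"], sep="\t")
    truth = pd.concat(
        [cohort.truth.genetic_cluster, cohort.truth.metabolomic_cluster, cohort.truth.haplotype],
        axis=1,
    )
    truth["informative"] = ",".join(cohort.truth.informative_features)
    truth.to_csv(manifest["ground_truth"], sep="\t")
    return manifest
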