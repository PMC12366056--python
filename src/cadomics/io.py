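"""Readers, writers and core containers for the pipeline's file formats.

Genotypes travel as VCF 4.2 (GT-only) or a mirrored TSV matrix; phenotype,
metabolite and result tables as TSV/CSV with a header row.  Coordinates are
1-based throughout, as in VCF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("cadomics")

# ---------------------------------------------------------------- constants

#: Ordered disease groups; every CohortTable group column uses these labels.
GROUPS = ("control", "high-risk", "CAD")

#: Integer genotype codes used throughout (int8 matrices).
HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

#: Medication flags carried by the phenotype table.
MEDICATION_FLAGS = ("statin", "fibrate", "ccb", "beta_blocker", "arb", "diuretics")

_NUCLEOTIDES = frozenset("ACGT")


def configure_logging(verbose: bool = False) -> None:
    """One structured line per pipeline stage; quiet by default."""
    level = logging.INFO if verbose else logging.WARNING
    logging.basicConfig(format="%(name)s %(levelname)s %(message)s")
    log.setLevel(level)


# ---------------------------------------------------------------- containers


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Check the phenotype-table contract: unique subject index, known groups.

    The table is indexed by ``subject_id`` and must carry ``group``, ``sex``
    and ``age`` columns; clinical covariates and medication flags are free-form
    extra columns.
    """
    if not cohort.index.is_unique:
        dupes = cohort.index[cohort.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate subject_id: {dupes[:5]}")
    for col in ("group", "sex", "age"):
        if col not in cohort.columns:
            raise ValueError(f"phenotype table lacks required column {col!r}")
    if cohort["group"].isna().any():
        raise ValueError("group labels may not be missing")
    bad = set(cohort["group"].unique()) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group labels {sorted(bad)}; expected {GROUPS}")
    return cohort


@dataclass
class GenotypeMatrix:
    """Subjects × SNPs categorical calls with per-SNP allele metadata.

    ``calls`` holds int8 codes (HOM_REF/HET/HOM_ALT/MISSING); ``snps`` is
    indexed by SNP id with columns chrom, pos, ref, alt.
    """

    calls: pd.DataFrame
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.snps.index.is_unique:
            raise ValueError("duplicate SNP ids")
        if list(self.calls.columns) != list(self.snps.index):
            raise ValueError("calls columns and SNP metadata index disagree")
        for col in ("chrom", "pos", "ref", "alt"):
            if col not in self.snps.columns:
                raise ValueError(f"SNP metadata lacks column {col!r}")
        for col in ("ref", "alt"):
            bad = ~self.snps[col].isin(list(_NUCLEOTIDES))
            if bad.any():
                raise ValueError(
                    f"non-nucleotide {col} allele at {self.snps.index[bad][:3].tolist()}"
                )
        vals = self.calls.to_numpy()
        ok = np.isin(vals, (HOM_REF, HET, HOM_ALT, MISSING))
        if not ok.all():
            raise ValueError("genotype codes must be in {0,1,2,-1}")

    @property
    def subjects(self) -> pd.Index:
        return self.calls.index

    def subset(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(self.calls[list(snp_ids)], self.snps.loc[list(snp_ids)])


@dataclass
class MetaboliteMatrix:
    """Subjects × metabolites concentrations (µM); NaN marks missing."""

    values: pd.DataFrame
    classes: pd.Series | None = None  # metabolite -> panel class

    def __post_init__(self) -> None:
        if not self.values.columns.is_unique:
            raise ValueError("duplicate metabolite names")
        arr = self.values.to_numpy(dtype=float)
        finite = np.isfinite(arr) | np.isnan(arr)
        if not finite.all():
            raise ValueError("metabolite values must be finite or missing")
        with np.errstate(invalid="ignore"):
            if np.nanmin(arr) < 0:
                raise ValueError("negative metabolite concentration")

    @property
    def subjects(self) -> pd.Index:
        return self.values.index


def check_aligned(*indexes: pd.Index) -> None:
    """Fail loudly on subject-index mismatch instead of silently intersecting."""
    first = indexes[0]
    for other in indexes[1:]:
        if len(other) != len(first) or not (other == first).all():
            raise ValueError("subject indices are not aligned")


# ---------------------------------------------------------------- VCF


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a biallelic GT-only VCF into a GenotypeMatrix.

    Phasing separators are ignored (1|0 and 0/1 are both het); ./. maps to
    missing.  Multiallelic records and duplicate ids are rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, rows, meta = [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multiallelic record {var.ID or f'{var.CHROM}:{var.POS}'} not supported"
            )
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        if vid in set(ids):
            raise ValueError(f"duplicate SNP id {vid}")
        codes = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                codes[i] = MISSING
            else:
                if a > 1 or b > 1:
                    raise ValueError(f"multiallelic genotype at record {vid}")
                codes[i] = (HOM_REF, HET, HOM_ALT)[a + b]
        ids.append(vid)
        rows.append(codes)
        meta.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
    calls = pd.DataFrame(
        np.array(rows, dtype=np.int8).T if rows else np.empty((len(samples), 0), np.int8),
        index=pd.Index(samples, name="subject_id"),
        columns=ids,
    )
    snps = pd.DataFrame(meta, index=pd.Index(ids, name="snp_id"),
                        columns=["chrom", "pos", "ref", "alt"])
    log.info("read_vcf path=%s subjects=%d snps=%d", path, calls.shape[0], calls.shape[1])
    return GenotypeMatrix(calls, snps)


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 (GT only) mirroring ``read_vcf``."""
    code_to_gt = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
    order = g.snps.sort_values(["chrom", "pos"]).index
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(g.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(map(str, g.subjects)) + "\n")
        for sid in order:
            row = g.snps.loc[sid]
            gts = "\t".join(code_to_gt[c] for c in g.calls[sid])
            fh.write(f"{row.chrom}\t{row.pos}\t{sid}\t{row.ref}\t{row.alt}\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------- tables

#: read_table schemas: required columns and dtypes.
PHENOTYPE_SCHEMA = {"required": ("subject_id", "group", "sex", "age")}


def _delimiter(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_phenotype_table(path: str | Path) -> pd.DataFrame:
    """Read a phenotype TSV/CSV into a validated CohortTable."""
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter(path))
    missing = [c for c in PHENOTYPE_SCHEMA["required"] if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table lacks required column(s) {missing}")
    df = df.set_index("subject_id")
    return validate_cohort(df)


def read_metabolite_table(path: str | Path) -> MetaboliteMatrix:
    """Read a metabolite TSV/CSV (subjects × metabolites); empty cells → missing."""
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter(path), index_col=0)
    df.index.name = "subject_id"
    return MetaboliteMatrix(df.astype(float))


def read_genotype_table(path: str | Path, snp_meta_path: str | Path) -> GenotypeMatrix:
    """Read the TSV mirror of the genotype matrix plus its SNP metadata table."""
    path, mpath = Path(path), Path(snp_meta_path)
    calls = pd.read_csv(path, sep=_delimiter(path), index_col=0).astype(np.int8)
    calls.index.name = "subject_id"
    snps = pd.read_csv(mpath, sep=_delimiter(mpath), index_col=0)
    return GenotypeMatrix(calls, snps)


def write_results(obj, path: str | Path) -> Path:
    """Serialize a result object or DataFrame to TSV with a documented header.

    Anything exposing ``to_frame()`` (the result dataclasses in this package)
    or a DataFrame/Series is accepted; row order is the object's declared
    deterministic order.
    """
    path = Path(path)
    if hasattr(obj, "to_frame") and not isinstance(obj, pd.Series):
        frame = obj.to_frame()
    elif isinstance(obj, pd.Series):
        frame = obj.to_frame()
    elif isinstance(obj, pd.DataFrame):
        frame = obj
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")
    frame.to_csv(path, sep="\t")
    return path


# ---------------------------------------------------------------- config


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(cfg: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)
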