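"""Readers and writers for the standard formats the pipeline touches.

One internal data model is shared by every stage:

* :class:`GenotypeDataset` — samples x variants counted-allele dosage
  matrix (int8; ``-1`` marks a missing genotype) with per-sample phenotype
  and sex, and per-variant metadata.
* :class:`GeneRegion` — 1-based inclusive gene boundaries (UTRs included).
* :class:`GeneSetCollection` — named gene sets (GMT).
* :class:`CountsMatrix` — genes x samples expression counts with a paired
  pre/post-treatment design.

Readers are deliberately "dumb": the counted allele is whatever the file
declares (PLINK A1 or VCF ALT); minor-allele orientation happens in the QC
stage. Internal coordinates are 1-based inclusive everywhere; BED is
converted at the boundary. Multiallelic and non-SNP records are dropped at
read time with counts logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = np.int8(-1)

#: phenotype codes
CASE, CONTROL, PHENO_MISSING = np.int8(1), np.int8(0), np.int8(-9)
#: sex codes (PLINK convention)
MALE, FEMALE, SEX_UNKNOWN = np.int8(1), np.int8(2), np.int8(0)

_PLINK_MAGIC = b"\x6c\x1b\x01"


class FormatError(ValueError):
    """A file does not conform to its declared format."""


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNP; dosage counts copies of ``counted_allele``."""

    id: str
    chromosome: str
    position: int  # 1-based
    counted_allele: str
    other_allele: str

    def __post_init__(self):
        if self.position <= 0:
            raise ValueError(f"variant {self.id}: position must be positive")
        if self.counted_allele == self.other_allele:
            raise ValueError(f"variant {self.id}: alleles must differ")


@dataclass(frozen=True)
class GeneRegion:
    """Gene boundaries, 1-based inclusive, UTRs included."""

    gene_id: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


@dataclass
class GeneSetCollection:
    """Named sets of gene ids with optional descriptions."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)


VARIANT_COLUMNS = ["id", "chromosome", "position", "counted_allele", "other_allele"]


@dataclass
class GenotypeDataset:
    """Samples x variants dosage matrix with phenotype/sex and metadata.

    ``dosage[i, j]`` is the number of copies of variant j's counted allele
    carried by sample i, in {0, 1, 2}, or -1 for missing.
    """

    sample_ids: list[str]
    phenotype: np.ndarray  # int8: 1 case, 0 control, -9 missing
    sex: np.ndarray  # int8: 1 male, 2 female, 0 unknown
    variants: pd.DataFrame  # columns VARIANT_COLUMNS
    dosage: np.ndarray  # int8, shape (n_samples, n_variants)

    def __post_init__(self):
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        self.sex = np.asarray(self.sex, dtype=np.int8)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n, m = len(self.sample_ids), len(self.variants)
        if self.dosage.shape != (n, m):
            raise ValueError(
                f"dosage shape {self.dosage.shape} != (samples={n}, variants={m})"
            )
        if self.phenotype.shape != (n,) or self.sex.shape != (n,):
            raise ValueError("phenotype/sex length must equal sample count")
        bad = ~np.isin(self.dosage, [-1, 0, 1, 2])
        if bad.any():
            raise ValueError("dosage entries must be in {0,1,2} or -1 (missing)")
        if list(self.variants.columns) != VARIANT_COLUMNS:
            raise ValueError(f"variants must have columns {VARIANT_COLUMNS}")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def variant_records(self) -> list[VariantRecord]:
        return [VariantRecord(*row) for row in self.variants.itertuples(index=False)]

    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypeDataset":
        """Return a copy restricted to the given positional indices."""
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypeDataset(
            sample_ids=[self.sample_ids[i] for i in si],
            phenotype=self.phenotype[si].copy(),
            sex=self.sex[si].copy(),
            variants=self.variants.iloc[vi].reset_index(drop=True),
            dosage=self.dosage[np.ix_(si, vi)].copy(),
        )

    def dosage_float(self) -> np.ndarray:
        """Dosage as float64 with NaN for missing."""
        x = self.dosage.astype(np.float64)
        x[self.dosage == MISSING] = np.nan
        return x

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and np.array_equal(self.phenotype, other.phenotype)
            and np.array_equal(self.sex, other.sex)
            and self.variants.equals(other.variants)
            and np.array_equal(self.dosage, other.dosage)
        )


@dataclass
class CountsMatrix:
    """Genes x samples expression counts for a paired pre/post design."""

    gene_ids: list[str]
    sample_ids: list[str]
    condition: np.ndarray  # 'pre' / 'post' per sample
    pairing: np.ndarray  # cell-line id per sample
    counts: np.ndarray  # int64, genes x samples, >= 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be integral")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("counts shape must be genes x samples")
        self.condition = np.asarray(self.condition, dtype=object)
        self.pairing = np.asarray(self.pairing, dtype=object)
        bad = set(self.condition) - {"pre", "post"}
        if bad:
            raise ValueError(f"conditions must be 'pre'/'post', got {sorted(bad)}")
        for line in set(self.pairing):
            conds = set(self.condition[self.pairing == line])
            if conds != {"pre", "post"}:
                raise ValueError(f"pairing id {line!r} lacks a pre/post pair")

    @property
    def n_pairs(self) -> int:
        return len(set(self.pairing))


# ---------------------------------------------------------------------------
# PLINK 1 bed/bim/fam
# ---------------------------------------------------------------------------

# 2-bit codes in a SNP-major v1 .bed, least significant pair first:
#   00 -> two copies of A1, 01 -> missing, 10 -> het, 11 -> zero copies of A1
_BED_DECODE = np.array([2, -1, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, -1: 0b01, 1: 0b10, 0: 0b11}


def read_plink(prefix: str) -> GenotypeDataset:
    """Read a PLINK 1 bed/bim/fam fileset.

    Dosages count the .bim A1 allele. FAM phenotype 2 maps to case, 1 to
    control, 0/-9 to missing; sex 1 male, 2 female, other unknown.
    """
    fam = pd.read_csv(
        f"{prefix}.fam", sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype=str,
    )
    bim = pd.read_csv(
        f"{prefix}.bim", sep=r"\s+", header=None,
        names=["chromosome", "id", "cm", "position", "a1", "a2"],
        dtype={"chromosome": str, "id": str, "a1": str, "a2": str},
    )
    n, m = len(fam), len(bim)

    sex = np.full(n, SEX_UNKNOWN, dtype=np.int8)
    sex[fam["sex"].values == "1"] = MALE
    sex[fam["sex"].values == "2"] = FEMALE
    pheno = np.full(n, PHENO_MISSING, dtype=np.int8)
    pheno[fam["pheno"].values == "2"] = CASE
    pheno[fam["pheno"].values == "1"] = CONTROL

    with open(f"{prefix}.bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _PLINK_MAGIC:
            raise FormatError(
                f"{prefix}.bed: bad magic {magic!r}; not a SNP-major PLINK 1 bed"
            )
        payload = np.frombuffer(fh.read(), dtype=np.uint8)

    bytes_per_snp = (n + 3) // 4
    if payload.size != bytes_per_snp * m:
        raise FormatError(
            f"{prefix}.bed payload is {payload.size} bytes; expected "
            f"{bytes_per_snp * m} for {n} samples x {m} variants"
        )
    blocks = payload.reshape(m, bytes_per_snp)
    # unpack 2-bit pairs, least significant first
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (blocks >> (2 * k)) & 0b11
    dosage = _BED_DECODE[codes[:, :n]].T.copy()

    variants = pd.DataFrame({
        "id": bim["id"].astype(str),
        "chromosome": bim["chromosome"].astype(str),
        "position": bim["position"].astype(int),
        "counted_allele": bim["a1"].astype(str),
        "other_allele": bim["a2"].astype(str),
    })
    return GenotypeDataset(
        sample_ids=list(fam["iid"].astype(str)),
        phenotype=pheno, sex=sex, variants=variants, dosage=dosage,
    )


def write_plink(ds: GenotypeDataset, prefix: str) -> None:
    """Write a GenotypeDataset as PLINK 1 bed/bim/fam (SNP-major)."""
    n, m = ds.n_samples, ds.n_variants
    fam_pheno = np.where(
        ds.phenotype == CASE, "2", np.where(ds.phenotype == CONTROL, "1", "-9")
    )
    fam = pd.DataFrame({
        "fid": ds.sample_ids, "iid": ds.sample_ids, "pat": "0", "mat": "0",
        "sex": ds.sex.astype(int).astype(str), "pheno": fam_pheno,
    })
    fam.to_csv(f"{prefix}.fam", sep="\t", header=False, index=False)
    bim = pd.DataFrame({
        "chromosome": ds.variants["chromosome"], "id": ds.variants["id"],
        "cm": 0, "position": ds.variants["position"],
        "a1": ds.variants["counted_allele"], "a2": ds.variants["other_allele"],
    })
    bim.to_csv(f"{prefix}.bim", sep="\t", header=False, index=False)

    bytes_per_snp = (n + 3) // 4
    enc = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    lut = np.zeros(4, dtype=np.uint8)
    for d, c in _BED_ENCODE.items():
        lut[d] = c  # index by dosage value (-1 wraps to 3)
    enc[:, :n] = lut[ds.dosage.T]
    blocks = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        blocks |= enc[:, k::4] << (2 * k)
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_PLINK_MAGIC)
        fh.write(blocks.tobytes())


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str, phenotype_table: str | None = None) -> GenotypeDataset:
    """Read genotypes from a VCF via cyvcf2; counted allele = ALT.

    Multiallelic and non-SNP records are skipped with a logged warning
    count. ``phenotype_table`` optionally points to a TSV with columns
    ``sample``, ``phenotype`` (case/control/1/0), ``sex`` (male/female/1/2);
    without it phenotype and sex are missing/unknown.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    n = len(samples)
    rows, dosage_cols = [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        gt = var.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        col = np.select(
            [gt == 0, gt == 1, gt == 3], [np.int8(0), np.int8(1), np.int8(2)],
            default=MISSING,
        ).astype(np.int8)
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        rows.append((vid, str(var.CHROM), int(var.POS), var.ALT[0], var.REF))
        dosage_cols.append(col)
    if n_skipped:
        logger.warning("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)

    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dosage = (
        np.stack(dosage_cols, axis=1) if dosage_cols
        else np.zeros((n, 0), dtype=np.int8)
    )
    pheno = np.full(n, PHENO_MISSING, dtype=np.int8)
    sex = np.full(n, SEX_UNKNOWN, dtype=np.int8)
    if phenotype_table is not None:
        tab = pd.read_csv(phenotype_table, sep="\t", dtype=str).set_index("sample")
        for i, s in enumerate(samples):
            if s in tab.index:
                p = str(tab.loc[s, "phenotype"]).lower()
                pheno[i] = CASE if p in ("case", "1") else (
                    CONTROL if p in ("control", "0") else PHENO_MISSING)
                x = str(tab.loc[s, "sex"]).lower() if "sex" in tab.columns else ""
                sex[i] = MALE if x in ("male", "1") else (
                    FEMALE if x in ("female", "2") else SEX_UNKNOWN)
    ds = GenotypeDataset(samples, pheno, sex, variants, dosage)
    ds.n_skipped_records = n_skipped
    return ds


def write_vcf(ds: GenotypeDataset, path: str) -> None:
    """Write a minimal VCF 4.2 with GT only; REF = other allele, ALT = counted."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = ds.variants["chromosome"].unique()
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ds.sample_ids) + "\n"
        )
        for j, v in enumerate(ds.variants.itertuples(index=False)):
            gts = "\t".join(gt_map[int(d)] for d in ds.dosage[:, j])
            fh.write(
                f"{v.chromosome}\t{v.position}\t{v.id}\t{v.other_allele}\t"
                f"{v.counted_allele}\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# BED gene regions, GMT, counts
# ---------------------------------------------------------------------------

def read_gene_regions(path: str) -> list[GeneRegion]:
    """Read BED4 (0-based half-open) gene regions into 1-based inclusive form."""
    regions: list[GeneRegion] = []
    seen: dict[str, tuple] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: BED4 needs 4 columns")
            chrom, start_s, end_s, gene_id = parts[:4]
            start0, end0 = int(start_s), int(end_s)
            if start0 >= end0:
                raise FormatError(
                    f"{path}:{lineno}: start >= end for gene {gene_id}"
                )
            key = (chrom, start0, end0)
            if gene_id in seen and seen[gene_id] != key:
                raise FormatError(
                    f"{path}:{lineno}: gene {gene_id} duplicated with "
                    "different coordinates"
                )
            if gene_id in seen:
                continue
            seen[gene_id] = key
            regions.append(GeneRegion(gene_id, chrom, start0 + 1, end0))
    return regions


def write_gene_regions(regions: list[GeneRegion], path: str) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chromosome}\t{r.start - 1}\t{r.end}\t{r.gene_id}\n")


def read_gmt(path: str) -> GeneSetCollection:
    """Read a GMT file: name, description, members... (tab-separated)."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name, desc, members = parts[0], parts[1], parts[2:]
            members = [m for m in members if m]
            uniq = set(members)
            if len(uniq) < len(members):
                logger.warning(
                    "read_gmt: set %s has duplicate members; de-duplicated", name
                )
            sets[name] = uniq
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc] + sorted(members)) + "\n")


def read_counts(counts_path: str, design_path: str) -> CountsMatrix:
    """Read a genes x samples counts TSV plus a sample/condition/pairing design."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t", dtype=str)
    for col in ("sample", "condition", "pairing"):
        if col not in design.columns:
            raise FormatError(f"{design_path}: design needs a '{col}' column")
    design = design.set_index("sample")
    missing = [s for s in counts.columns if s not in design.index]
    if missing:
        raise FormatError(
            f"samples in counts but absent from design: {missing}"
        )
    design = design.loc[list(counts.columns)]

    arr = counts.values
    frac = arr != np.floor(arr)
    if frac.any():
        g, s = np.argwhere(frac)[0]
        raise FormatError(
            f"non-integer count for gene {counts.index[g]} in sample "
            f"{counts.columns[s]}"
        )
    return CountsMatrix(
        gene_ids=list(counts.index.astype(str)),
        sample_ids=list(counts.columns.astype(str)),
        condition=design["condition"].values,
        pairing=design["pairing"].values,
        counts=arr.astype(np.int64),
    )


def write_counts(cm: CountsMatrix, counts_path: str, design_path: str) -> None:
    pd.DataFrame(cm.counts, index=cm.gene_ids, columns=cm.sample_ids).to_csv(
        counts_path, sep="\t", index_label="gene_id"
    )
    pd.DataFrame({
        "sample": cm.sample_ids, "condition": cm.condition, "pairing": cm.pairing,
    }).to_csv(design_path, sep="\t", index=False)
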