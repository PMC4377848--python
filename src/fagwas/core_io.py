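"""Core data model and readers/writers.

The pipeline's in-memory containers are deliberately thin: a genotype dataset
is a sample list, a variant table and a dosage matrix; phenotypes, genes and
gene sets are validated pandas structures.  All genomic coordinates are held
1-based (VCF convention); BED input, which is 0-based half-open, is converted
on read so that SNP-in-gene tests never mix conventions.

Dosages count copies of ``allele2`` (the allele whose frequency enters the
genomic relationship matrix) and take values 0, 1, 2 or NaN — NaN is the one
and only missing-genotype sentinel.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: the missing-dosage sentinel; never a numeric code mixed with real dosages
MISSING = np.nan

VARIANT_COLUMNS = ["chrom", "pos", "allele1", "allele2", "id"]


class ParseError(ValueError):
    """Raised when an input file does not parse in its declared dialect."""


def _chrom_key(label: str):
    """Sort key putting numeric chromosome labels in numeric order."""
    s = str(label)
    m = re.fullmatch(r"(?:chr)?(\d+)", s, flags=re.IGNORECASE)
    return (0, int(m.group(1)), "") if m else (1, 0, s)


@dataclass
class GenotypeDataset:
    """Samples x variants dosage matrix plus variant metadata.

    Variants are stored sorted by (chromosome, position); construction applies
    the sort to both the variant table and the dosage columns.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self):
        self.samples = list(self.samples)
        self.variants = self.variants.reset_index(drop=True)
        missing_cols = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing_cols:
            raise ValueError(f"variant table lacks columns {missing_cols}")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} != "
                f"({len(self.samples)}, {len(self.variants)})"
            )
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.unique(self.dosages[~ok])
            raise ValueError(f"dosage entries outside {{0,1,2,missing}}: {bad[:5]}")
        if self.variants["id"].duplicated().any():
            dups = self.variants["id"][self.variants["id"].duplicated()].tolist()
            raise ValueError(f"duplicate marker IDs: {dups[:5]}")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs")
        self._sort_genome_order()

    def _sort_genome_order(self):
        keys = [
            (_chrom_key(c), p)
            for c, p in zip(self.variants["chrom"], self.variants["pos"])
        ]
        order = np.array(sorted(range(len(keys)), key=keys.__getitem__), dtype=int)
        if not np.array_equal(order, np.arange(len(keys))):
            self.variants = self.variants.iloc[order].reset_index(drop=True)
            self.dosages = self.dosages[:, order]
        for chrom, sub in self.variants.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if (np.diff(pos) <= 0).any():
                raise ValueError(f"non-increasing positions on chromosome {chrom}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def allele2_freq(self) -> np.ndarray:
        """Frequency of allele2 per variant from non-missing dosages."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele2_freq()
        return np.minimum(p, 1.0 - p)

    def sample_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def locus_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypeDataset":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypeDataset(
            samples=[self.samples[i] for i in si],
            variants=self.variants.iloc[vi],
            dosages=self.dosages[np.ix_(si, vi)],
        )

    def flip_alleles(self, variant_idx) -> "GenotypeDataset":
        """Swap allele1/allele2 (dosage d -> 2-d) at the given variants."""
        vi = np.asarray(variant_idx)
        variants = self.variants.copy()
        a1 = variants.loc[vi, "allele1"].copy()
        variants.loc[vi, "allele1"] = variants.loc[vi, "allele2"].values
        variants.loc[vi, "allele2"] = a1.values
        dos = self.dosages.copy()
        dos[:, vi] = 2.0 - dos[:, vi]
        return GenotypeDataset(self.samples, variants, dos)


@dataclass
class PhenotypeTable:
    """Per-animal fixed-effect covariates and named trait values.

    ``data`` holds one row per animal with columns ``animal``, ``herd``,
    ``parity`` (1-3), ``dim`` (days in milk, positive), then trait columns.
    """

    data: pd.DataFrame

    RESERVED = ("animal", "herd", "parity", "dim")

    def __post_init__(self):
        df = self.data.reset_index(drop=True)
        for c in self.RESERVED:
            if c not in df.columns:
                raise ValueError(f"phenotype table lacks column {c!r}")
        if df["animal"].duplicated().any():
            raise ValueError("duplicate animal IDs in phenotype table")
        if not df["parity"].isin([1, 2, 3]).all():
            raise ValueError("parity must be in {1,2,3}")
        if not (df["dim"] > 0).all():
            raise ValueError("DIM must be positive")
        self.data = df

    @property
    def trait_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.RESERVED]

    def trait(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)


@dataclass
class GeneTable:
    """Gene intervals, 1-based inclusive coordinates."""

    data: pd.DataFrame  # columns: gene, chrom, start, end

    def __post_init__(self):
        df = self.data.reset_index(drop=True)
        for c in ("gene", "chrom", "start", "end"):
            if c not in df.columns:
                raise ValueError(f"gene table lacks column {c!r}")
        if (df["start"] >= df["end"]).any():
            raise ValueError("gene start must be < end")
        if df["gene"].duplicated().any():
            raise ValueError("duplicate gene IDs")
        self.data = df


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. KEGG pathways) as id -> member gene list."""

    sets: dict[str, list[str]]

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise ValueError(f"duplicate gene within set {name!r}")

    def __len__(self):
        return len(self.sets)


# ---------------------------------------------------------------------------
# genotype I/O


def read_genotypes(path, format: str = "vcf") -> GenotypeDataset:
    """Read genotypes from a VCF or PLINK-style text fileset.

    ``format='plink-text'`` expects ``path`` to be the ``.ped`` file or the
    common prefix of a ``.ped``/``.map`` pair.  Non-biallelic variants are
    rejected with a count.  Output is genome-sorted; missing genotypes are NaN.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "plink-text":
        return _read_plink_text(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path) -> GenotypeDataset:
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    rows, cols = [], []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        rows.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0],
                     rec.ID or f"{rec.CHROM}:{rec.POS}"))
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = rec.gt_types
        col = np.choose(gt, [0.0, 1.0, np.nan, 2.0])
        cols.append(col)
    if n_multi:
        raise ParseError(f"{path}: {n_multi} non-biallelic variant(s) rejected")
    if not rows:
        raise ParseError(f"{path}: no biallelic variants found")
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    return GenotypeDataset(samples, variants, np.column_stack(cols))


def write_vcf(genos: GenotypeDataset, path) -> None:
    """Write a minimal VCFv4.2 with GT-only genotypes (unphased)."""
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(genos.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genos.samples) + "\n")
        for j, row in genos.variants.iterrows():
            gts = [code.get(d, "./.") for d in genos.dosages[:, j]]
            fh.write(f"{row.chrom}\t{row.pos}\t{row.id}\t{row.allele1}\t"
                     f"{row.allele2}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n")


def _plink_pair(path):
    p = Path(path)
    if p.suffix == ".ped":
        return p, p.with_suffix(".map")
    if p.suffix == ".map":
        return p.with_suffix(".ped"), p
    return p.with_suffix(".ped"), p.with_suffix(".map")


def _read_plink_text(path) -> GenotypeDataset:
    ped_path, map_path = _plink_pair(path)
    if not ped_path.exists() or not map_path.exists():
        raise FileNotFoundError(f"need {ped_path} and {map_path}")
    vmeta = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(f"{map_path}:{ln}: expected 4 fields, got {len(parts)}")
            vmeta.append((parts[0], parts[1], int(parts[3])))
    m = len(vmeta)
    samples, geno_rows = [], []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise ParseError(
                    f"{ped_path}:{ln}: expected {6 + 2 * m} fields, got {len(parts)}")
            samples.append(parts[1])
            geno_rows.append(parts[6:])
    alleles_per_locus = []
    for i in range(m):
        seen = set()
        for row in geno_rows:
            seen.update((row[2 * i], row[2 * i + 1]))
        seen.discard("0")
        if len(seen) > 2:
            raise ParseError(
                f"{ped_path}: locus {vmeta[i][1]} has {len(seen)} alleles (1 rejected)")
        srt = sorted(seen)  # alphabetical: allele1 < allele2
        if len(srt) == 0:
            srt = ["N", "N2"]
        elif len(srt) == 1:
            srt = [srt[0], "0"]
        alleles_per_locus.append(tuple(srt))
    dos = np.empty((len(samples), m))
    for k, row in enumerate(geno_rows):
        for i, (a1, a2) in enumerate(alleles_per_locus):
            x, y = row[2 * i], row[2 * i + 1]
            if x == "0" or y == "0":
                dos[k, i] = MISSING
            else:
                dos[k, i] = (x == a2) + (y == a2)
    variants = pd.DataFrame(
        [(c, p, a[0], a[1], i) for (c, i, p), a in zip(vmeta, alleles_per_locus)],
        columns=["chrom", "pos", "allele1", "allele2", "id"],
    )[VARIANT_COLUMNS]
    return GenotypeDataset(samples, variants, dos)


def write_plink_text(genos: GenotypeDataset, prefix) -> None:
    ped_path, map_path = _plink_pair(Path(str(prefix) + ".ped"))
    with open(map_path, "w") as fh:
        for _, row in genos.variants.iterrows():
            fh.write(f"{row.chrom}\t{row.id}\t0\t{row.pos}\n")
    with open(ped_path, "w") as fh:
        for k, sample in enumerate(genos.samples):
            fields = [sample, sample, "0", "0", "0", "-9"]
            for j, row in genos.variants.iterrows():
                d = genos.dosages[k, j]
                if np.isnan(d):
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [row.allele1, row.allele1]
                elif d == 1:
                    fields += [row.allele1, row.allele2]
                else:
                    fields += [row.allele2, row.allele2]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# gene / gene-set / phenotype I/O


def read_genes(path) -> GeneTable:
    """Read gene intervals from BED3+ (0-based half-open -> 1-based inclusive)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{ln}: BED needs >=3 fields")
            name = parts[3] if len(parts) > 3 else f"gene{ln}"
            rows.append((name, parts[0], int(parts[1]) + 1, int(parts[2])))
    if not rows:
        raise ParseError(f"{path}: empty BED file")
    return GeneTable(pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"]))


def write_genes(genes: GeneTable, path) -> None:
    with open(path, "w") as fh:
        for _, r in genes.data.iterrows():
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.gene}\n")


def read_gene_sets(path) -> GeneSetCollection:
    """Read GMT: one set per line — name, description, then member genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{ln}: GMT line needs >=3 tab-separated fields")
            name, members = parts[0], list(dict.fromkeys(g for g in parts[2:] if g))
            sets[name] = members
    if not sets:
        raise ParseError(f"{path}: no gene sets found")
    return GeneSetCollection(sets)


def write_gene_sets(sets: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.sets.items():
            fh.write("\t".join([name, "na"] + list(members)) + "\n")


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t")
    df["animal"] = df["animal"].astype(str)
    return PhenotypeTable(df)


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# derived fatty-acid traits

#: desaturation / CLA indices: name -> (product, substrate); index =
#: product / (product + substrate) x 100
INDEX_DEFS = {
    "C14 index": ("C14:1", "C14:0"),
    "C16 index": ("C16:1", "C16:0"),
    "C18 index": ("C18:1c9", "C18:0"),
    "CLA index": ("CLA", "C18:1t11"),
}

#: group traits sum even-chain saturated FA only
GROUP_DEFS = {
    "C6-C10": ["C6:0", "C8:0", "C10:0"],
    "C6-C12": ["C6:0", "C8:0", "C10:0", "C12:0"],
    "C12-C14": ["C12:0", "C14:0"],
}


def compute_index_traits(pheno: PhenotypeTable) -> PhenotypeTable:
    """Add desaturation-index and even-chain group-sum columns.

    An index for a zero denominator is set missing with a logged warning.
    Indices/groups whose constituent columns are absent are skipped.
    """
    df = pheno.data.copy()
    for name, (num, den) in INDEX_DEFS.items():
        if num in df.columns and den in df.columns:
            denom = df[num] + df[den]
            zero = denom == 0
            if zero.any():
                log.warning("%s: %d animal(s) with zero denominator set missing",
                            name, int(zero.sum()))
            with np.errstate(invalid="ignore", divide="ignore"):
                vals = np.where(zero, np.nan, df[num] / denom * 100.0)
            df[name] = vals
    for name, members in GROUP_DEFS.items():
        if all(c in df.columns for c in members):
            df[name] = df[members].sum(axis=1)
    return PhenotypeTable(df)
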