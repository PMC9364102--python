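"""Genotype containers, PLINK PED/MAP and VCF readers, and QC filters.

Genotypes are stored as a dense ``int8`` matrix of per-sample, per-SNP codes:

====================  =====
code                  value
====================  =====
homozygous major/ref  0
heterozygous          1
homozygous minor/alt  2
missing               -1
====================  =====

Coordinates are 1-based and inclusive throughout (the PLINK MAP convention);
every run interval detected downstream inherits this frame.  Only autosomes
are retained: non-autosomal map entries are dropped with a warning because
all genome-wide summaries (including the autosomal length used by F_ROH)
are defined over autosomes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HOM_MAJOR: int = 0
HET: int = 1
HOM_MINOR: int = 2
MISSING: int = -1

_VALID_ALLELES = frozenset("ACGT0")


class ParseError(ValueError):
    """A genotype file could not be parsed."""


class DimensionError(ValueError):
    """PED and MAP (or calls and map) dimensions disagree."""


class EmptyPanelError(ValueError):
    """A filter removed every SNP."""


@dataclass(frozen=True)
class GenomicMap:
    """SNP map: identifier, chromosome label and 1-based physical position.

    Positions must be strictly increasing within a chromosome and SNP ids
    unique; both are validated at construction.
    """

    table: pd.DataFrame  # columns: snp_id, chrom, pos

    def __post_init__(self) -> None:
        t = self.table
        required = {"snp_id", "chrom", "pos"}
        if not required.issubset(t.columns):
            raise ValueError(f"map table needs columns {sorted(required)}")
        if t["snp_id"].duplicated().any():
            dups = t.loc[t["snp_id"].duplicated(), "snp_id"].head(3).tolist()
            raise ValueError(f"duplicate snp_id in map: {dups}")
        if (t["pos"] < 0).any():
            raise ValueError("negative positions in map")
        for chrom, grp in t.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    @property
    def n_snps(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    def positions(self, chrom: str) -> np.ndarray:
        return self.table.loc[self.table["chrom"] == chrom, "pos"].to_numpy()

    def chrom_slice(self, chrom: str) -> np.ndarray:
        """Integer indices of the SNPs on ``chrom``, in map order."""
        return np.flatnonzero((self.table["chrom"] == chrom).to_numpy())


@dataclass
class GenotypeMatrix:
    """Samples x SNPs genotype codes together with their genomic map.

    ``alleles`` keeps the observed (major, minor) base per SNP so that a
    matrix can be written back to PED without losing allele labels.
    """

    samples: list[str]
    breeds: list[str]
    gmap: GenomicMap
    calls: np.ndarray  # int8, shape (n_samples, n_snps)
    alleles: np.ndarray | None = None  # shape (n_snps, 2), dtype '<U1'

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), self.gmap.n_snps):
            raise DimensionError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.samples)} samples, {self.gmap.n_snps} snps)"
            )
        if len(self.breeds) != len(self.samples):
            raise DimensionError("breeds and samples length mismatch")
        bad = ~np.isin(self.calls, (HOM_MAJOR, HET, HOM_MINOR, MISSING))
        if bad.any():
            raise ValueError("genotype codes outside {0,1,2,-1}")
        if self.alleles is None:
            self.alleles = np.tile(np.array(["A", "C"]), (self.gmap.n_snps, 1))

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return self.gmap.n_snps

    def minor_allele_freq(self) -> np.ndarray:
        """Per-SNP minor allele frequency over non-missing calls.

        SNPs with no non-missing call get NaN.
        """
        calls = self.calls
        valid = calls != MISSING
        n_valid = valid.sum(axis=0)
        minor_count = np.where(valid, calls, 0).sum(axis=0)  # minor dosage
        with np.errstate(invalid="ignore", divide="ignore"):
            p = minor_count / (2.0 * n_valid)
        p = np.where(n_valid > 0, p, np.nan)
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=0)

    def het_rate(self) -> float:
        """Mean heterozygosity: fraction of non-missing calls that are het."""
        valid = self.calls != MISSING
        n = valid.sum()
        if n == 0:
            raise ValueError("no non-missing calls")
        return float((self.calls == HET).sum() / n)

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            samples=list(self.samples),
            breeds=list(self.breeds),
            gmap=GenomicMap(self.gmap.table.iloc[keep].reset_index(drop=True)),
            calls=self.calls[:, keep].copy(),
            alleles=self.alleles[keep].copy(),
        )

    def subset_samples(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in keep],
            breeds=[self.breeds[i] for i in keep],
            gmap=self.gmap,
            calls=self.calls[keep].copy(),
            alleles=self.alleles.copy(),
        )

    def reorient_by_frequency(self) -> "GenotypeMatrix":
        """Flip codes so that code 0 is the most frequent allele per SNP.

        Ties are broken by allele lexicographic order (the smaller base is
        the major allele).  This is the orientation ``read_plink`` produces,
        so a reoriented matrix round-trips bit-identically through PED.
        """
        calls = self.calls.copy()
        alleles = self.alleles.copy()
        valid = calls != MISSING
        # dosage of the current "minor" allele
        minor_count = np.where(valid, calls, 0).sum(axis=0)
        total = 2 * valid.sum(axis=0)
        major_count = total - minor_count
        flip = minor_count > major_count
        tie = (minor_count == major_count) & (alleles[:, 1] < alleles[:, 0])
        flip |= tie
        for j in np.flatnonzero(flip):
            col = calls[:, j]
            swapped = col.copy()
            swapped[col == HOM_MAJOR] = HOM_MINOR
            swapped[col == HOM_MINOR] = HOM_MAJOR
            calls[:, j] = swapped
            alleles[j] = alleles[j, ::-1]
        return replace(self, calls=calls, alleles=alleles)


def _is_autosome(label: str) -> bool:
    try:
        return int(label) >= 1
    except ValueError:
        return False


def _drop_non_autosomes(table: pd.DataFrame) -> pd.DataFrame:
    auto = table["chrom"].map(_is_autosome)
    n_drop = int((~auto).sum())
    if n_drop:
        warnings.warn(
            f"dropping {n_drop} non-autosomal map entries", stacklevel=3
        )
    return table.loc[auto].reset_index(drop=True)


def read_plink(ped_path, map_path) -> GenotypeMatrix:
    """Read a text PLINK PED/MAP pair into a :class:`GenotypeMatrix`.

    Allele pairs ``0 0`` become missing; per-SNP major/minor orientation is
    fixed by allele frequency with lexicographic tie-break.  The PED family
    ID column is used as the breed label.
    """
    map_df = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos"],
        dtype={"chrom": str, "snp_id": str},
    )
    if map_df.shape[1] != 4:
        raise ParseError(f"{map_path}: MAP must have 4 columns")
    map_df = _drop_non_autosomes(
        map_df.rename(columns={"pos": "pos"})[["snp_id", "chrom", "pos", "cm"]]
    )
    n_all = None
    samples: list[str] = []
    breeds: list[str] = []
    rows: list[np.ndarray] = []
    allele_rows: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if n_all is None:
                n_all = len(fields)
            if len(fields) != n_all or (len(fields) - 6) % 2 != 0:
                raise ParseError(
                    f"{ped_path}: ragged PED line {lineno} "
                    f"({len(fields)} fields, expected {n_all})"
                )
            breeds.append(fields[0])
            samples.append(fields[1])
            pairs = fields[6:]
            bad = set(pairs) - _VALID_ALLELES
            if bad:
                raise ParseError(
                    f"{ped_path}: line {lineno}: invalid alleles {sorted(bad)}"
                )
            allele_rows.append(list(zip(pairs[0::2], pairs[1::2])))
    if n_all is None:
        raise ParseError(f"{ped_path}: empty PED file")
    n_snps_ped = (n_all - 6) // 2
    # the MAP row count must match PED *before* autosome filtering only if
    # nothing was dropped; track the original count separately
    orig_map = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos"], dtype={"chrom": str},
    )
    if n_snps_ped != len(orig_map):
        raise DimensionError(
            f"PED has {n_snps_ped} SNPs but MAP has {len(orig_map)} rows"
        )
    keep_idx = orig_map.index[orig_map["chrom"].map(_is_autosome)].to_numpy()

    n_samples = len(samples)
    a1 = np.empty((n_samples, n_snps_ped), dtype="<U1")
    a2 = np.empty((n_samples, n_snps_ped), dtype="<U1")
    for i, row in enumerate(allele_rows):
        for j, (x, y) in enumerate(row):
            a1[i, j], a2[i, j] = x, y
    a1, a2 = a1[:, keep_idx], a2[:, keep_idx]

    n_snps = len(keep_idx)
    calls = np.full((n_samples, n_snps), MISSING, dtype=np.int8)
    alleles_out = np.empty((n_snps, 2), dtype="<U1")
    for j in range(n_snps):
        c1, c2 = a1[:, j], a2[:, j]
        miss = (c1 == "0") | (c2 == "0")
        obs = np.concatenate([c1[~miss], c2[~miss]])
        uniq, counts = np.unique(obs, return_counts=True) if obs.size else (
            np.array(["A"]), np.array([0]))
        if len(uniq) > 2:
            raise ParseError(
                f"SNP {map_df['snp_id'].iloc[j]} has >2 alleles: {list(uniq)}"
            )
        # major = most frequent; lexicographic tie-break
        order = np.lexsort((uniq, -counts))
        major = uniq[order[0]]
        minor = uniq[order[1]] if len(uniq) == 2 else (
            "C" if major == "A" else "A")
        alleles_out[j] = (major, minor)
        dosage = (c1 == minor).astype(np.int8) + (c2 == minor).astype(np.int8)
        calls[:, j] = np.where(miss, MISSING, dosage)

    gmap = GenomicMap(map_df[["snp_id", "chrom", "pos"]].reset_index(drop=True))
    return GenotypeMatrix(samples, breeds, gmap, calls, alleles_out)


def write_plink(g: GenotypeMatrix, ped_path, map_path) -> None:
    """Write a text PLINK PED/MAP pair."""
    with open(map_path, "w") as fh:
        for _, row in g.gmap.table.iterrows():
            fh.write(f"{row['chrom']}\t{row['snp_id']}\t0\t{row['pos']}\n")
    code_to_pair = {
        HOM_MAJOR: (0, 0),
        HET: (0, 1),
        HOM_MINOR: (1, 1),
    }
    with open(ped_path, "w") as fh:
        for i, sample in enumerate(g.samples):
            out = [g.breeds[i], sample, "0", "0", "0", "-9"]
            for j in range(g.n_snps):
                c = int(g.calls[i, j])
                if c == MISSING:
                    out += ["0", "0"]
                else:
                    k1, k2 = code_to_pair[c]
                    out += [g.alleles[j, k1], g.alleles[j, k2]]
            fh.write(" ".join(out) + "\n")


def read_vcf_biallelic(vcf_path) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a REF/ALT-oriented matrix.

    Multi-allelic records are skipped with a logged count; half-calls and
    ``./.`` become missing.  Code 0 is homozygous REF, 2 homozygous ALT.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    rows = []
    snp_ids, chroms, poss, alleles = [], [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        if var.format("GT") is None and var.gt_types is None:
            raise ParseError(f"{vcf_path}: record without GT at {var.POS}")
        codes = np.full(len(samples), MISSING, dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                continue  # half-call or missing
            codes[i] = a + b
        rows.append(codes)
        snp_ids.append(var.ID if var.ID not in (None, ".") else
                       f"{var.CHROM}_{var.POS}")
        chroms.append(str(var.CHROM))
        poss.append(var.POS)
        alleles.append((var.REF, var.ALT[0]))
    vcf.close()
    if n_multi:
        logger.info("skipped %d multi-allelic records", n_multi)
    if not rows:
        raise ParseError(f"{vcf_path}: no biallelic records")
    table = _drop_non_autosomes(
        pd.DataFrame({"snp_id": snp_ids, "chrom": chroms, "pos": poss})
    )
    keep = [i for i, c in enumerate(chroms) if _is_autosome(c)]
    calls = np.stack([rows[i] for i in keep], axis=1)
    allele_arr = np.array([alleles[i] for i in keep], dtype="<U20")
    gmap = GenomicMap(table)
    return GenotypeMatrix(samples, ["NA"] * len(samples), gmap, calls,
                          allele_arr)


def write_vcf(g: GenotypeMatrix, vcf_path) -> None:
    """Write a plain-text VCF (GT only), REF/ALT from the allele table."""
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in g.gmap.chromosomes:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.samples) + "\n")
        gt_map = {HOM_MAJOR: "0/0", HET: "0/1", HOM_MINOR: "1/1",
                  MISSING: "./."}
        table = g.gmap.table
        for j in range(g.n_snps):
            ref, alt = g.alleles[j]
            gts = "\t".join(gt_map[int(c)] for c in g.calls[:, j])
            fh.write(
                f"{table['chrom'].iloc[j]}\t{table['pos'].iloc[j]}\t"
                f"{table['snp_id'].iloc[j]}\t{ref}\t{alt}\t.\t.\t.\tGT\t{gts}\n"
            )


@dataclass(frozen=True)
class QcReport:
    n_input: int
    n_removed_call_rate: int
    n_removed_maf: int
    n_kept: int


def qc_filter(
    g: GenotypeMatrix,
    min_call_rate: float = 0.90,
    min_maf: float = 0.01,
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop SNPs with call rate or minor allele frequency below threshold.

    A SNP is removed when its call rate is *less than* ``min_call_rate`` or
    its MAF (computed over non-missing calls) is *less than* ``min_maf``.
    The sample set is unchanged.  Idempotent: a second application with the
    same thresholds removes nothing.
    """
    if not (0 <= min_call_rate <= 1 and 0 <= min_maf <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    cr = g.call_rate()
    maf = g.minor_allele_freq()
    fail_cr = cr < min_call_rate
    fail_maf = np.isnan(maf) | (maf < min_maf)
    keep = ~(fail_cr | fail_maf)
    if not keep.any():
        raise EmptyPanelError("QC removed every SNP")
    report = QcReport(
        n_input=g.n_snps,
        n_removed_call_rate=int(fail_cr.sum()),
        n_removed_maf=int(fail_maf.sum()),
        n_kept=int(keep.sum()),
    )
    return g.subset_snps(keep), report
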