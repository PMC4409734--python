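"""Readers, writers and marker QC for SNP-array data on a pedigreed population.

Genotypes are held as 0/1/2 counts of ``allele_b`` with ``-1`` for missing
calls (never imputed).  Map coordinates are 1-based inclusive base pairs, the
VCF convention; interval *outputs* elsewhere in the package are BED-style
half-open 0-based and say so in their headers.  Alleles are taken exactly as
written in the input — array data are assumed strand-harmonised upstream.

Supported formats: VCF (plain or bgzipped, via pysam) and PED/MAP text for
genotypes, phased VCF for haplotypes, and header-carrying TSV for pedigree,
trait (PTA) and ancestral-allele tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger("herdsweep")

MISSING = -1  #: genotype / haplotype sentinel for a missing call

#: autosome labels accepted after QC (cattle: BTA1..BTA29)
AUTOSOMES = tuple(range(1, 30))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class MarkerMap:
    """Per-SNP map: id, chromosome, physical position and allele labels.

    ``ancestral`` codes which of the two alleles is ancestral at each SNP:
    ``0`` = allele_a, ``1`` = allele_b, ``-1`` = unknown.
    """

    snp_id: np.ndarray
    chromosome: np.ndarray
    position_bp: np.ndarray
    allele_a: np.ndarray
    allele_b: np.ndarray
    ancestral: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=np.int64)
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        self.allele_a = np.asarray(self.allele_a, dtype=object)
        self.allele_b = np.asarray(self.allele_b, dtype=object)
        if self.ancestral is None:
            self.ancestral = np.full(len(self.snp_id), MISSING, dtype=np.int8)
        else:
            self.ancestral = np.asarray(self.ancestral, dtype=np.int8)
        self.validate()

    def validate(self) -> None:
        n = len(self.snp_id)
        for name in ("chromosome", "position_bp", "allele_a", "allele_b", "ancestral"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"marker map field {name!r} length mismatch")
        for c in np.unique(self.chromosome):
            pos = self.position_bp[self.chromosome == c]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {c}"
                )

    def __len__(self) -> int:
        return len(self.snp_id)

    @property
    def n_snps(self) -> int:
        return len(self.snp_id)

    def chromosomes(self) -> np.ndarray:
        """Chromosome labels in map order (first occurrence)."""
        _, idx = np.unique(self.chromosome, return_index=True)
        return self.chromosome[np.sort(idx)]

    def chrom_slice(self, chrom: int) -> slice:
        """Contiguous index slice of SNPs on ``chrom`` (map is chromosome-sorted)."""
        idx = np.flatnonzero(self.chromosome == chrom)
        if idx.size == 0:
            return slice(0, 0)
        if not np.array_equal(idx, np.arange(idx[0], idx[-1] + 1)):
            raise ValueError(f"chromosome {chrom} SNPs are not contiguous in the map")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def subset(self, index: np.ndarray) -> "MarkerMap":
        return MarkerMap(
            snp_id=self.snp_id[index],
            chromosome=self.chromosome[index],
            position_bp=self.position_bp[index],
            allele_a=self.allele_a[index],
            allele_b=self.allele_b[index],
            ancestral=self.ancestral[index],
        )

    def to_frame(self) -> pd.DataFrame:
        anc = np.where(
            self.ancestral == 0,
            self.allele_a,
            np.where(self.ancestral == 1, self.allele_b, "unknown"),
        )
        return pd.DataFrame(
            {
                "snp_id": self.snp_id,
                "chromosome": self.chromosome,
                "position_bp": self.position_bp,
                "allele_a": self.allele_a,
                "allele_b": self.allele_b,
                "ancestral_allele": anc,
            }
        )


@dataclass
class GenotypeMatrix:
    """animals x SNPs diploid genotypes, coded as counts of allele_b."""

    animals: list[str]
    markers: MarkerMap
    codes: np.ndarray  # int8 (n_animals, n_snps); 0/1/2 or MISSING

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.animals), self.markers.n_snps):
            raise ValueError(
                f"genotype matrix shape {self.codes.shape} inconsistent with "
                f"{len(self.animals)} animals x {self.markers.n_snps} SNPs"
            )

    @property
    def n_animals(self) -> int:
        return len(self.animals)

    @property
    def n_snps(self) -> int:
        return self.markers.n_snps

    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per SNP."""
        return (self.codes != MISSING).mean(axis=0)

    def allele_b_frequency(self) -> np.ndarray:
        """Frequency of allele_b among non-missing calls per SNP (NaN if none)."""
        called = self.codes != MISSING
        n = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(called, self.codes, 0).sum(axis=0) / (2.0 * n)

    def maf(self) -> np.ndarray:
        p = self.allele_b_frequency()
        return np.minimum(p, 1.0 - p)

    def subset_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            animals=list(self.animals),
            markers=self.markers.subset(index),
            codes=self.codes[:, index],
        )


@dataclass
class PedigreeTable:
    """Animal, sire, dam, birth year.  Unknown parents are ``None``."""

    df: pd.DataFrame  # columns animal_id, sire_id, dam_id, birth_year

    def __post_init__(self) -> None:
        required = {"animal_id", "sire_id", "dam_id", "birth_year"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"pedigree requires columns {sorted(required)}")
        if self.df["animal_id"].duplicated().any():
            dup = self.df.loc[self.df["animal_id"].duplicated(), "animal_id"].iloc[0]
            raise ValueError(f"duplicate animal id {dup!r} in pedigree")
        self._check_acyclic()
        self._check_birth_years()

    def _parent_of(self) -> dict:
        return {
            row.animal_id: (row.sire_id, row.dam_id)
            for row in self.df.itertuples(index=False)
        }

    def _check_acyclic(self) -> None:
        parents = self._parent_of()
        state: dict = {}  # 1 = in progress, 2 = done

        for start in parents:
            if state.get(start):
                continue
            stack = [(start, iter(p for p in parents.get(start, ()) if p is not None))]
            state[start] = 1
            path = [start]
            while stack:
                node, it = stack[-1]
                advanced = False
                for parent in it:
                    if parent not in parents:
                        continue
                    if state.get(parent) == 1:
                        cycle = path[path.index(parent):] + [parent]
                        raise ValueError(
                            "pedigree cycle: " + " -> ".join(map(str, cycle))
                        )
                    if state.get(parent) != 2:
                        state[parent] = 1
                        path.append(parent)
                        stack.append(
                            (parent, iter(p for p in parents[parent] if p is not None))
                        )
                        advanced = True
                        break
                if not advanced:
                    state[node] = 2
                    path.pop()
                    stack.pop()

    def _check_birth_years(self) -> None:
        year = dict(zip(self.df["animal_id"], self.df["birth_year"]))
        for row in self.df.itertuples(index=False):
            for parent in (row.sire_id, row.dam_id):
                if parent is not None and parent in year:
                    if row.birth_year < year[parent]:
                        raise ValueError(
                            f"animal {row.animal_id!r} born {row.birth_year} before "
                            f"parent {parent!r} ({year[parent]})"
                        )

    def birth_years(self, animals: list[str]) -> np.ndarray:
        """Birth year per requested animal; NaN where unrecorded."""
        year = dict(zip(self.df["animal_id"], self.df["birth_year"]))
        return np.array([float(year.get(a, np.nan)) for a in animals])


@dataclass
class TraitTable:
    """Long-format PTA table: one value per animal x trait."""

    df: pd.DataFrame  # columns animal_id, trait, pta_value

    TRAITS = ("milk", "fat", "protein")

    def __post_init__(self) -> None:
        required = {"animal_id", "trait", "pta_value"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"trait table requires columns {sorted(required)}")
        if self.df.duplicated(["animal_id", "trait"]).any():
            raise ValueError("more than one PTA for an animal x trait pair")

    def values_for(self, animals: list[str], trait: str) -> np.ndarray:
        sub = self.df[self.df["trait"] == trait]
        lookup = dict(zip(sub["animal_id"], sub["pta_value"]))
        return np.array([float(lookup.get(a, np.nan)) for a in animals])


@dataclass
class HaplotypePanel:
    """Phased haplotypes: two allele sequences (0 = allele_a, 1 = allele_b) per animal."""

    animals: list[str]
    markers: MarkerMap
    haps: np.ndarray  # int8 (n_animals, 2, n_snps)

    def __post_init__(self) -> None:
        self.haps = np.asarray(self.haps, dtype=np.int8)
        if self.haps.shape != (len(self.animals), 2, self.markers.n_snps):
            raise ValueError("haplotype panel shape inconsistent with animals/map")

    @property
    def n_animals(self) -> int:
        return len(self.animals)

    def hap_matrix(self) -> np.ndarray:
        """(2 * n_animals, n_snps) view, animal-major (hap 0 then hap 1)."""
        return self.haps.reshape(2 * len(self.animals), self.markers.n_snps)

    def collapse(self) -> GenotypeMatrix:
        """Unphase: genotype code = sum of the two alleles; missing if either is."""
        codes = self.haps.sum(axis=1, dtype=np.int8)
        codes[np.any(self.haps == MISSING, axis=1)] = MISSING
        return GenotypeMatrix(list(self.animals), self.markers, codes)

    def allele_b_frequency(self) -> np.ndarray:
        h = self.hap_matrix()
        ok = h != MISSING
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(ok, h, 0).sum(axis=0) / ok.sum(axis=0)


# ---------------------------------------------------------------------------
# VCF genotypes
# ---------------------------------------------------------------------------


def _parse_vcf(path: str | Path, require_phase: bool):
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    snp_id, chrom, pos, ref, alt = [], [], [], [], []
    hap_rows = []
    n_rejected = 0
    for rec in vf:
        alts = rec.alts or ()
        if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
            n_rejected += 1
            continue
        row = np.full((len(samples), 2), MISSING, dtype=np.int8)
        for i, s in enumerate(samples):
            sd = rec.samples[s]
            gt = sd.get("GT")
            if gt is None or len(gt) != 2:
                raise ValueError(
                    f"{path}: non-diploid GT for sample {s} at {rec.chrom}:{rec.pos}"
                )
            if require_phase and not sd.phased and not all(
                a is None or a == gt[0] for a in gt
            ):
                raise ValueError(
                    f"{path}: unphased heterozygote for sample {s} at "
                    f"{rec.chrom}:{rec.pos}; a phased VCF ('|' separators) is required"
                )
            for k, a in enumerate(gt):
                if a is not None:
                    row[i, k] = a
        hap_rows.append(row)
        snp_id.append(rec.id if rec.id not in (None, ".") else f"{rec.chrom}_{rec.pos}")
        chrom.append(int(str(rec.chrom).removeprefix("chr")))
        pos.append(rec.pos)
        ref.append(rec.ref)
        alt.append(alts[0])
    vf.close()
    if n_rejected:
        logger.info("%s: rejected %d multi-allelic/non-SNP records", path, n_rejected)
    if not snp_id:
        raise ValueError(f"{path}: no biallelic SNP records")
    markers = MarkerMap(snp_id, chrom, pos, ref, alt)
    haps = np.stack(hap_rows, axis=2)  # (n_animals, 2, n_snps)
    return samples, markers, haps


def read_genotypes(
    path: str | Path, format: str = "vcf", map_path: str | Path | None = None
) -> GenotypeMatrix:
    """Read diploid genotypes from a VCF or a PED/MAP pair.

    For ``format="ped_map"``, ``path`` is the .ped file; ``map_path`` defaults
    to the same stem with a .map suffix.
    """
    if format == "vcf":
        samples, markers, haps = _parse_vcf(path, require_phase=False)
        codes = haps.sum(axis=1, dtype=np.int8)
        codes[np.any(haps == MISSING, axis=1)] = MISSING
        return GenotypeMatrix(samples, markers, codes)
    if format == "ped_map":
        return _read_ped_map(path, map_path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(g: GenotypeMatrix, path: str | Path) -> None:
    """Write genotypes as an uncompressed VCF (unphased GT)."""
    _write_vcf(path, g.animals, g.markers, codes=g.codes)


def _write_vcf(
    path: str | Path,
    animals: list[str],
    markers: MarkerMap,
    codes: np.ndarray | None = None,
    haps: np.ndarray | None = None,
) -> None:
    sep = "|" if haps is not None else "/"
    gt_strings = {MISSING: f".{sep}.", 0: f"0{sep}0", 1: f"0{sep}1", 2: f"1{sep}1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=herdsweep\n")
        for c in markers.chromosomes():
            length = int(markers.position_bp[markers.chromosome == c].max()) + 1
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, animals))
            + "\n"
        )
        for j in range(markers.n_snps):
            if haps is not None:
                col = [
                    f".{sep}." if MISSING in (a0 := haps[i, 0, j], a1 := haps[i, 1, j])
                    else f"{a0}{sep}{a1}"
                    for i in range(len(animals))
                ]
            else:
                col = [gt_strings[int(c)] for c in codes[:, j]]
            fh.write(
                f"{markers.chromosome[j]}\t{markers.position_bp[j]}\t"
                f"{markers.snp_id[j]}\t{markers.allele_a[j]}\t{markers.allele_b[j]}"
                f"\t.\t.\t.\tGT\t" + "\t".join(col) + "\n"
            )


def _read_ped_map(path: str | Path, map_path: str | Path | None) -> GenotypeMatrix:
    path = Path(path)
    if map_path is None:
        map_path = path.with_suffix(".map")
    mp = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chromosome", "snp_id", "cm", "position_bp"],
        dtype={"chromosome": int, "snp_id": str, "position_bp": int},
    )
    n_snps = len(mp)
    animals: list[str] = []
    rows = []
    allele_a = np.array([None] * n_snps, dtype=object)
    allele_b = np.array([None] * n_snps, dtype=object)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_snps:
                raise ValueError(
                    f"{path}:{lineno}: expected {6 + 2 * n_snps} fields, "
                    f"got {len(fields)}"
                )
            animals.append(fields[1])
            alleles = fields[6:]
            row = np.empty(n_snps, dtype=np.int8)
            for j in range(n_snps):
                a1, a2 = alleles[2 * j], alleles[2 * j + 1]
                code = 0
                for a in (a1, a2):
                    if a == "0":
                        code = MISSING
                        break
                    if allele_a[j] is None:
                        allele_a[j] = a
                    elif a != allele_a[j] and allele_b[j] is None:
                        allele_b[j] = a
                    if a == allele_a[j]:
                        pass
                    elif a == allele_b[j]:
                        code += 1
                    else:
                        raise ValueError(
                            f"{path}:{lineno}: third allele {a!r} at SNP "
                            f"{mp['snp_id'][j]}"
                        )
                row[j] = code
            rows.append(row)
    # monomorphic SNPs never reveal a second allele; give them a placeholder
    allele_b[[b is None for b in allele_b]] = "N"
    allele_a[[a is None for a in allele_a]] = "N"
    markers = MarkerMap(
        mp["snp_id"].to_numpy(object),
        mp["chromosome"].to_numpy(),
        mp["position_bp"].to_numpy(),
        allele_a,
        allele_b,
    )
    return GenotypeMatrix(animals, markers, np.array(rows, dtype=np.int8))


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def qc_filter(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    call_rate_min: float = 0.8,
    autosomes_only: bool = True,
) -> GenotypeMatrix:
    """Marker QC: keep autosomal SNPs with MAF > maf_min and call rate > call_rate_min.

    Both thresholds are strict inequalities.  MAF is computed on non-missing
    calls only.  Retained SNPs keep their map order, so the filter is
    idempotent and never reorders the panel.
    """
    if not 0 <= maf_min < 0.5:
        raise ValueError("maf_min must lie in [0, 0.5)")
    if not 0 < call_rate_min <= 1:
        raise ValueError("call_rate_min must lie in (0, 1]")
    keep = (g.call_rate() > call_rate_min) & (np.nan_to_num(g.maf()) > maf_min)
    if autosomes_only:
        keep &= np.isin(g.markers.chromosome, AUTOSOMES)
    if not keep.any():
        raise ValueError("QC removed every SNP: no markers survive the filter")
    logger.info(
        "QC retained %d of %d SNPs (maf > %g, call rate > %g)",
        int(keep.sum()),
        g.n_snps,
        maf_min,
        call_rate_min,
    )
    return g.subset_snps(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# pedigree / trait / ancestral-allele / haplotype tables
# ---------------------------------------------------------------------------


def read_pedigree(path: str | Path) -> PedigreeTable:
    """Read a whitespace/tab-delimited pedigree with header; unknown parents are '0'."""
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    df.columns = [c.lower() for c in df.columns]
    df = df.rename(columns={"animal": "animal_id", "sire": "sire_id", "dam": "dam_id"})
    df["birth_year"] = df["birth_year"].astype(int)
    for col in ("sire_id", "dam_id"):
        df[col] = df[col].where(df[col] != "0", None)
    return PedigreeTable(df[["animal_id", "sire_id", "dam_id", "birth_year"]])


def write_pedigree(ped: PedigreeTable, path: str | Path) -> None:
    df = ped.df.fillna("0")
    df.to_csv(path, sep="\t", index=False)


def read_traits(path: str | Path) -> TraitTable:
    df = pd.read_csv(path, sep=r"\s+", dtype={"animal_id": str})
    df["pta_value"] = df["pta_value"].astype(float)
    return TraitTable(df[["animal_id", "trait", "pta_value"]])


def write_traits(traits: TraitTable, path: str | Path) -> None:
    traits.df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_haplotypes(path: str | Path) -> HaplotypePanel:
    """Read phased haplotypes from a phased VCF ('|' genotype separators)."""
    samples, markers, haps = _parse_vcf(path, require_phase=True)
    return HaplotypePanel(samples, markers, haps)


def write_haplotypes(hp: HaplotypePanel, path: str | Path) -> None:
    _write_vcf(path, hp.animals, hp.markers, haps=hp.haps)


def read_ancestral_alleles(path: str | Path, markers: MarkerMap) -> MarkerMap:
    """Attach an ancestral-allele TSV (snp_id, ancestral_allele) to a map.

    Rows whose base matches neither declared allele (or are absent) stay unknown.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    lookup = dict(zip(df["snp_id"], df["ancestral_allele"]))
    anc = np.full(markers.n_snps, MISSING, dtype=np.int8)
    for j in range(markers.n_snps):
        base = lookup.get(markers.snp_id[j])
        if base == markers.allele_a[j]:
            anc[j] = 0
        elif base == markers.allele_b[j]:
            anc[j] = 1
    out = markers.subset(np.arange(markers.n_snps))
    out.ancestral = anc
    return out


def write_ancestral_alleles(markers: MarkerMap, path: str | Path) -> None:
    df = markers.to_frame()[["snp_id", "ancestral_allele"]]
    df.to_csv(path, sep="\t", index=False)
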