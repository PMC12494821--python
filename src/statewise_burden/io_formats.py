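"""Readers/writers for the formats every pipeline stage consumes.

Coordinate conventions used throughout the package:

* VCF records are 1-based inclusive.
* BED intervals are 0-based half-open.
* Window spans in reports are 1-based inclusive (``chr11:64,859,972-64,869,939``
  style).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "VariantRecord",
    "SampleRecord",
    "IntervalTrack",
    "GenotypeMatrix",
    "AssocResult",
    "read_vcf",
    "write_vcf",
    "read_bed_track",
    "write_bed_track",
    "read_samples_tsv",
    "write_samples_tsv",
    "write_results",
    "read_results",
    "compute_maf_mac",
]

#: cohort labels recognised in sample tables
COHORTS = ("internal_case_BD", "internal_case_SZ", "internal_control", "external_control")

RESULT_COLUMNS = [
    "unit",
    "kind",
    "estimate",
    "odds_ratio",
    "p",
    "direction",
    "n_variants",
    "model",
    "flag",
]


@dataclass
class VariantRecord:
    """One bi-allelic site and its annotations.

    ``maf``/``mac`` always refer to the *minor* allele in the analysis sample
    set, which may be either REF or ALT.  ``annotations`` maps a track name
    (``state``, ``repeat``, ``gene``, ``ptv``, ``excluded``) to its label.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    maf: float = 0.0
    mac: int = 0
    is_snv: bool = True
    annotations: dict = field(default_factory=dict)

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class SampleRecord:
    """One individual with phenotype, batch, and sequencing QC metrics."""

    sample_id: str
    cohort: str
    sex: str  # genetically inferred karyotype, "XX" or "XY"
    reported_sex: str
    batch: str
    metrics: dict = field(default_factory=dict)
    relatedness_group: int = -1

    @property
    def is_case(self) -> bool:
        return self.cohort in ("internal_case_BD", "internal_case_SZ")


@dataclass
class IntervalTrack:
    """A named set of labelled genomic intervals (BED semantics).

    ``multi_label`` tracks (e.g. repeat classes) may contain overlapping
    intervals with different labels; single-label tracks (e.g. chromatin
    state partitions) must not overlap at all.
    """

    name: str
    intervals: list  # of (chrom, start, end, label); 0-based half-open
    multi_label: bool = False

    def __post_init__(self) -> None:
        for chrom, start, end, _label in self.intervals:
            if start >= end:
                raise ValueError(f"{self.name}: empty interval {chrom}:{start}-{end}")
        self.intervals.sort(key=lambda iv: (iv[0], iv[1], iv[2]))
        if not self.multi_label:
            prev = {}
            for chrom, start, end, label in self.intervals:
                if chrom in prev and start < prev[chrom]:
                    raise ValueError(
                        f"{self.name}: overlapping intervals in single-label track "
                        f"near {chrom}:{start}"
                    )
                prev[chrom] = end
        self._trees: dict[str, IntervalTree] | None = None

    def _ensure_trees(self) -> dict:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for chrom, start, end, label in self.intervals:
                trees.setdefault(chrom, IntervalTree()).addi(start, end, label)
            self._trees = trees
        return self._trees

    def labels_at(self, chrom: str, pos: int) -> list:
        """Labels overlapping a 1-based point position."""
        tree = self._ensure_trees().get(chrom)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.at(pos - 1))

    def label_at(self, chrom: str, pos: int):
        """Single label at a 1-based position, or None (single-label tracks)."""
        labels = self.labels_at(chrom, pos)
        return labels[0] if labels else None

    @property
    def label_set(self) -> list:
        return sorted({iv[3] for iv in self.intervals})


@dataclass
class GenotypeMatrix:
    """samples x variants matrix of non-reference allele counts (0/1/2).

    Stored dense ``int8``; a value of -1 marks a missing genotype.  Burden
    construction treats missing as homozygous reference; single-variant MAC
    computation excludes missing calls.
    """

    data: np.ndarray  # (n_samples, n_variants) int8
    sample_ids: list

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.ndim != 2:
            raise ValueError("genotype matrix must be 2-D")
        if self.data.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match matrix rows")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_variants(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(self.data[idx], [self.sample_ids[i] for i in idx])

    def dosage(self, fill_missing: int = 0) -> np.ndarray:
        """Non-reference dosage with missing genotypes imputed to ``fill_missing``."""
        out = self.data.astype(np.float32)
        out[self.data < 0] = fill_missing
        return out


@dataclass
class AssocResult:
    """One association test result."""

    unit: str
    kind: str  # state | repeat | gene | gene_set | window | variant
    estimate: float
    p: float
    n_variants: int = 0
    model: str = "base"
    flag: str = ""

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.estimate))

    @property
    def direction(self) -> int:
        return int(np.sign(self.estimate))


def compute_maf_mac(genotypes: np.ndarray) -> tuple:
    """Minor allele frequency and count per variant column.

    Missing genotypes (coded ``-1``) are excluded from the denominator.  The
    minor allele may be REF: for an ALT frequency of 0.98 the MAF is 0.02.
    Returns ``(maf, mac, alt_af)`` arrays.
    """
    g = np.asarray(genotypes)
    miss = g < 0
    called = g.shape[0] - miss.sum(axis=0)
    alt_count = np.where(miss, 0, g).sum(axis=0, dtype=np.int64)
    total = 2 * called
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_af = np.where(total > 0, alt_count / np.maximum(total, 1), 0.0)
    mac = np.minimum(alt_count, total - alt_count).astype(np.int64)
    maf = np.minimum(alt_af, 1.0 - alt_af)
    maf = np.where(total > 0, maf, 0.0)
    return maf, mac, alt_af


def read_vcf(path: str, sample_subset: Iterable[str] | None = None):
    """Read a bi-allelic VCF into (variants, GenotypeMatrix).

    MAF/MAC are computed on the provided sample subset (all samples when
    ``sample_subset`` is None).  Multi-allelic records and malformed GT
    fields raise ``ValueError`` naming the site.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    all_samples = list(vcf.samples)
    if sample_subset is not None:
        subset = list(sample_subset)
        missing = set(subset) - set(all_samples)
        if missing:
            raise ValueError(f"samples not in VCF: {sorted(missing)}")
        col_idx = np.array([all_samples.index(s) for s in subset])
        samples = subset
    else:
        col_idx = np.arange(len(all_samples))
        samples = all_samples

    variants: list[VariantRecord] = []
    rows = []
    for rec in vcf:
        site = f"{rec.CHROM}:{rec.POS}:{rec.REF}"
        if len(rec.ALT) != 1:
            raise ValueError(f"multi-allelic record at {site} (ALT={rec.ALT})")
        alt = rec.ALT[0]
        # genotype array: columns 0,1 allele indices, column 2 phased flag
        garr = rec.genotype.array()
        a = garr[col_idx, 0]
        b = garr[col_idx, 1]
        if np.any(a > 1) or np.any(b > 1):
            raise ValueError(f"multi-allelic GT at {site}")
        g = np.where((a < 0) | (b < 0), -1, a + b).astype(np.int8)
        rows.append(g)
        variants.append(
            VariantRecord(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=alt,
                is_snv=len(rec.REF) == 1 and len(alt) == 1,
            )
        )
    vcf.close()
    if rows:
        data = np.stack(rows, axis=1)
    else:
        data = np.zeros((len(samples), 0), dtype=np.int8)
    gm = GenotypeMatrix(data, samples)
    maf, mac, _ = compute_maf_mac(gm.data)
    for i, v in enumerate(variants):
        v.maf = float(maf[i])
        v.mac = int(mac[i])
    seen = set()
    for v in variants:
        if v.key in seen:
            raise ValueError(f"duplicate record {v.key}")
        seen.add(v.key)
    return variants, gm


def write_vcf(path: str, variants: Sequence[VariantRecord], genotypes: GenotypeMatrix) -> None:
    """Write a minimal VCF 4.2 with GT-only genotype fields."""
    order = np.lexsort(
        (
            [v.alt for v in variants],
            [v.ref for v in variants],
            [v.pos for v in variants],
            [v.chrom for v in variants],
        )
    )
    chroms = []
    for v in variants:
        if v.chrom not in chroms:
            chroms.append(v.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted(chroms):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.sample_ids)
            + "\n"
        )
        gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
        for j in order:
            v = variants[j]
            col = genotypes.data[:, j]
            gts = "\t".join(gt_strings[int(g)] for g in col)
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_bed_track(path: str, name: str, multi_label: bool = False) -> IntervalTrack:
    """Read a 4+ column BED (0-based half-open) into an IntervalTrack."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 BED columns")
            chrom, start, end, label = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            intervals.append((chrom, start, end, label))
    return IntervalTrack(name=name, intervals=intervals, multi_label=multi_label)


def write_bed_track(path: str, track: IntervalTrack) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, label in track.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")


def _sample_frame(samples: Sequence[SampleRecord]) -> pd.DataFrame:
    metric_names = sorted({m for s in samples for m in s.metrics})
    rows = []
    for s in samples:
        row = {
            "sample_id": s.sample_id,
            "cohort": s.cohort,
            "sex": s.sex,
            "reported_sex": s.reported_sex,
            "batch": s.batch,
            "relatedness_group": s.relatedness_group,
        }
        for m in metric_names:
            row[m] = s.metrics.get(m, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def write_samples_tsv(path: str, samples: Sequence[SampleRecord]) -> None:
    _sample_frame(samples).to_csv(path, sep="\t", index=False)


def read_samples_tsv(path: str) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "batch": str})
    core = {"sample_id", "cohort", "sex", "reported_sex", "batch", "relatedness_group"}
    samples = []
    for _, row in df.iterrows():
        metrics = {c: float(row[c]) for c in df.columns if c not in core}
        samples.append(
            SampleRecord(
                sample_id=row["sample_id"],
                cohort=row["cohort"],
                sex=row["sex"],
                reported_sex=row["reported_sex"],
                batch=str(row["batch"]),
                metrics=metrics,
                relatedness_group=int(row.get("relatedness_group", -1)),
            )
        )
    return samples


def write_results(results: Sequence[AssocResult], path: str) -> None:
    """Write association results as TSV with a fixed column order.

    P-values are written in scientific notation at full double precision so a
    round-trip through disk is lossless.
    """
    rows = []
    for r in results:
        rows.append(
            {
                "unit": r.unit,
                "kind": r.kind,
                "estimate": repr(float(r.estimate)),
                "odds_ratio": repr(float(r.odds_ratio)),
                "p": f"{float(r.p):.17e}",
                "direction": r.direction,
                "n_variants": r.n_variants,
                "model": r.model,
                "flag": r.flag,
            }
        )
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_results(path: str) -> list:
    # numeric columns parsed via Python float() for exact repr round-trips
    df = pd.read_csv(
        path, sep="\t", keep_default_na=False, dtype={"estimate": str, "odds_ratio": str, "p": str}
    )
    out = []
    for _, row in df.iterrows():
        out.append(
            AssocResult(
                unit=str(row["unit"]),
                kind=str(row["kind"]),
                estimate=float(row["estimate"]),
                p=float(row["p"]),
                n_variants=int(row["n_variants"]),
                model=str(row["model"]),
                flag=str(row["flag"]),
            )
        )
    return out
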