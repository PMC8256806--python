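"""PLINK 1 binary genotype I/O, quality control and per-population allele frequencies.

Dosages count copies of allele2 (the .bim column-6 allele), stored as int8
with ``MISSING`` (-1) as the missing sentinel.  Coordinates follow .bim:
1-based inclusive base-pair positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Missing-genotype sentinel.  A dedicated negative value: 0 is a legal homozygote.
MISSING: int = -1

_BED_MAGIC = b"\x6c\x1b"
_BED_SNP_MAJOR = b"\x01"

# 2-bit PLINK genotype codes -> allele2 dosage.
# 00 -> hom allele1 (0), 01 -> missing, 10 -> het (1), 11 -> hom allele2 (2)
_CODE_TO_DOSAGE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_DOSAGE_TO_CODE = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}


class PlinkFormatError(ValueError):
    """Raised when a .bed/.bim/.fam trio violates the PLINK 1 binary layout."""


@dataclass(frozen=True)
class SNPRecord:
    """One marker row of a .bim file (1-based inclusive position)."""

    snp_id: str
    chrom: str
    pos_bp: int
    allele1: str
    allele2: str

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise ValueError(f"pos_bp must be >= 1, got {self.pos_bp} for {self.snp_id}")
        if self.allele1 == self.allele2:
            raise ValueError(f"alleles must differ for SNP {self.snp_id}")


@dataclass
class GenotypeDataset:
    """Samples x SNPs diploid dosage matrix with sample and marker metadata.

    ``dosages[i, j]`` is the number of copies of ``snps[j].allele2`` carried by
    sample ``i`` (0, 1, 2) or ``MISSING``.
    """

    sample_ids: list[str]
    populations: list[str]
    snps: list[SNPRecord]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.validate()

    # -- invariants -------------------------------------------------------

    def validate(self) -> None:
        n, m = len(self.sample_ids), len(self.snps)
        if len(self.populations) != n:
            raise ValueError("populations length must match sample_ids")
        if self.dosages.shape != (n, m):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} != ({n}, {m})"
            )
        if any(not p for p in self.populations):
            raise ValueError("population labels must be non-empty")
        bad = ~np.isin(self.dosages, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError(f"{bad.sum()} dosage values outside {{0,1,2,MISSING}}")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("snp_ids are not unique")

    # -- convenience ------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def population_labels(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def subset(
        self,
        sample_idx: np.ndarray | Sequence[int] | None = None,
        snp_idx: np.ndarray | Sequence[int] | None = None,
    ) -> "GenotypeDataset":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeDataset(
            sample_ids=[self.sample_ids[i] for i in si],
            populations=[self.populations[i] for i in si],
            snps=[self.snps[j] for j in vi],
            dosages=self.dosages[np.ix_(si, vi)],
        )

    def sort_snps(self) -> "GenotypeDataset":
        """Return a copy with SNPs sorted by (chrom, pos_bp); chrom numerically when possible."""
        order = sorted(
            range(self.n_snps),
            key=lambda j: (_chrom_sort_key(self.snps[j].chrom), self.snps[j].pos_bp),
        )
        return self.subset(snp_idx=order)

    def with_populations(self, mapping: dict[str, str]) -> "GenotypeDataset":
        """Relabel populations from a sample_id -> population mapping."""
        pops = [mapping.get(s, p) for s, p in zip(self.sample_ids, self.populations)]
        return GenotypeDataset(self.sample_ids, pops, self.snps, self.dosages.copy())


def _chrom_sort_key(chrom: str) -> tuple[int, int | str]:
    try:
        return (0, int(chrom))
    except ValueError:
        return (1, chrom)


@dataclass
class PopAlleleFreqs:
    """Per-population allele2 frequencies and haploid (2 x genotyped) counts.

    ``freqs[k, j]`` is NaN wherever ``n_hap[k, j] == 0`` (no callable genotype).
    """

    populations: list[str]
    freqs: np.ndarray
    n_hap: np.ndarray
    snps: list[SNPRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.n_hap = np.asarray(self.n_hap, dtype=np.int64)
        if self.freqs.shape != self.n_hap.shape:
            raise ValueError("freqs and n_hap shapes differ")
        if self.freqs.shape[0] != len(self.populations):
            raise ValueError("row count must match number of populations")
        if (self.n_hap % 2 != 0).any() or (self.n_hap < 0).any():
            raise ValueError("n_hap must be even and non-negative")
        defined = self.n_hap > 0
        vals = self.freqs[defined]
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("frequencies outside [0, 1]")
        if not np.isnan(self.freqs[~defined]).all():
            raise ValueError("freq must be NaN where n_hap == 0")

    def index_of(self, population: str) -> int:
        try:
            return self.populations.index(population)
        except ValueError:
            raise KeyError(f"unknown population {population!r}") from None

    @property
    def n_snps(self) -> int:
        return self.freqs.shape[1]


@dataclass
class QCReport:
    n_snps_in: int
    n_snps_out: int
    n_samples_in: int
    n_samples_out: int
    genotyping_rate: float
    removed_snps_call_rate: int = 0
    removed_samples_call_rate: int = 0
    removed_snps_maf: int = 0

    def __post_init__(self) -> None:
        if self.n_snps_out > self.n_snps_in or self.n_samples_out > self.n_samples_in:
            raise ValueError("output counts cannot exceed input counts")
        if not 0.0 <= self.genotyping_rate <= 1.0:
            raise ValueError("genotyping_rate outside [0, 1]")

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            ("n_snps_in", self.n_snps_in),
            ("n_snps_out", self.n_snps_out),
            ("n_samples_in", self.n_samples_in),
            ("n_samples_out", self.n_samples_out),
            ("removed_snps_call_rate", self.removed_snps_call_rate),
            ("removed_samples_call_rate", self.removed_samples_call_rate),
            ("removed_snps_maf", self.removed_snps_maf),
            ("genotyping_rate", f"{self.genotyping_rate:.6f}"),
        ]
        Path(path).write_text("\n".join(f"{k}\t{v}" for k, v in rows) + "\n")


# ---------------------------------------------------------------------------
# PLINK binary trio
# ---------------------------------------------------------------------------


def read_plink(
    prefix: str | Path,
    population_map: dict[str, str] | None = None,
    sort_snps: bool = True,
) -> GenotypeDataset:
    """Read a PLINK 1 binary trio ``prefix``.bed/.bim/.fam into a dataset.

    The population label of each sample is the .fam family-ID column, unless
    overridden through ``population_map`` (sample_id -> population).  SNPs are
    sorted by (chrom, pos) after loading unless ``sort_snps`` is False.
    """
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(".bed")
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")

    sample_ids: list[str] = []
    populations: list[str] = []
    for ln, line in enumerate(fam_path.read_text().splitlines(), start=1):
        parts = line.split()
        if len(parts) < 2:
            raise PlinkFormatError(f"{fam_path}:{ln}: expected >= 2 columns")
        populations.append(parts[0])
        sample_ids.append(parts[1])

    snps: list[SNPRecord] = []
    for ln, line in enumerate(bim_path.read_text().splitlines(), start=1):
        parts = line.split()
        if len(parts) != 6:
            raise PlinkFormatError(f"{bim_path}:{ln}: expected 6 columns, got {len(parts)}")
        chrom, snp_id, _cm, pos, a1, a2 = parts
        snps.append(SNPRecord(snp_id=snp_id, chrom=chrom, pos_bp=int(pos), allele1=a1, allele2=a2))

    raw = bed_path.read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise PlinkFormatError(
            f"{bed_path}: bad magic bytes at offset 0-1: expected 6c 1b, "
            f"got {raw[:2].hex(' ') if len(raw) >= 2 else '<truncated>'}"
        )
    if raw[2:3] != _BED_SNP_MAJOR:
        raise PlinkFormatError(
            f"{bed_path}: byte offset 2 must be 01 (SNP-major), got {raw[2:3].hex()}"
        )

    n, m = len(sample_ids), len(snps)
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if len(raw) != expected:
        raise PlinkFormatError(
            f"{bed_path}: size mismatch: expected {expected} bytes "
            f"(3 + ceil({n}/4) x {m} = 3 + {bytes_per_snp} x {m}), got {len(raw)}"
        )

    packed = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    # unpack 2-bit codes, low bits first within each byte
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (packed >> (2 * k)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T  # samples x snps

    ds = GenotypeDataset(sample_ids, populations, snps, np.ascontiguousarray(dosages))
    if population_map:
        ds = ds.with_populations(population_map)
    return ds.sort_snps() if sort_snps else ds


def write_plink(dataset: GenotypeDataset, prefix: str | Path) -> None:
    """Write the dataset as a PLINK 1 binary trio (SNP-major, zero-padded)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    with open(prefix.with_suffix(".fam"), "w") as fh:
        for pop, sid in zip(dataset.populations, dataset.sample_ids):
            fh.write(f"{pop} {sid} 0 0 0 -9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for s in dataset.snps:
            fh.write(f"{s.chrom}\t{s.snp_id}\t0\t{s.pos_bp}\t{s.allele1}\t{s.allele2}\n")

    n, m = dataset.n_samples, dataset.n_snps
    bytes_per_snp = (n + 3) // 4
    codes = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)  # pad bits are 00
    dos = dataset.dosages.T  # snps x samples
    for dosage, code in _DOSAGE_TO_CODE.items():
        codes[:, :n][dos == dosage] = code
    packed = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        packed |= codes[:, k::4].astype(np.uint8) << (2 * k)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + _BED_SNP_MAJOR)
        fh.write(packed.tobytes())


def read_population_map(path: str | Path) -> dict[str, str]:
    """Read a two-column sample_id <tab> population TSV (no header)."""
    mapping: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{ln}: expected 2 tab-separated columns")
        mapping[parts[0]] = parts[1]
    return mapping


# ---------------------------------------------------------------------------
# QC and allele frequencies
# ---------------------------------------------------------------------------


def autosomal_filter(dataset: GenotypeDataset) -> GenotypeDataset:
    """Drop SNPs on non-numeric chromosomes (sex/mito/scaffolds), logging the count."""
    keep = [j for j, s in enumerate(dataset.snps) if s.chrom.isdigit()]
    dropped = dataset.n_snps - len(keep)
    if dropped:
        logger.info("dropped %d non-autosomal SNPs", dropped)
    return dataset.subset(snp_idx=keep)


def qc_filter(
    dataset: GenotypeDataset,
    min_snp_call_rate: float = 0.90,
    min_sample_call_rate: float = 0.90,
    min_maf: float = 0.01,
) -> tuple[GenotypeDataset, QCReport]:
    """Filter SNPs by call rate, then samples by call rate, then SNPs by MAF.

    The three steps are iterated to a fixed point (each removal can change the
    other axes' rates), which makes the filter idempotent; the report
    accumulates removals per filter across rounds.  The genotyping rate is the
    non-missing fraction of the final matrix.  Raises if no SNP survives.
    """
    for name, v in (
        ("min_snp_call_rate", min_snp_call_rate),
        ("min_sample_call_rate", min_sample_call_rate),
        ("min_maf", min_maf),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")

    n_in, m_in = dataset.n_samples, dataset.n_snps
    ds = dataset
    removed_snps_cr = removed_samples = removed_maf = 0

    while True:
        if ds.n_snps == 0:
            raise ValueError("QC removed every SNP; relax the thresholds")
        called = ds.dosages != MISSING

        snp_cr = called.mean(axis=0) if ds.n_samples else np.zeros(ds.n_snps)
        keep_snps = np.flatnonzero(snp_cr >= min_snp_call_rate)
        removed_snps_cr += ds.n_snps - keep_snps.size

        called = called[:, keep_snps]
        sample_cr = called.mean(axis=1) if keep_snps.size else np.ones(ds.n_samples)
        keep_samples = np.flatnonzero(sample_cr >= min_sample_call_rate)
        removed_samples += ds.n_samples - keep_samples.size

        changed = keep_snps.size < ds.n_snps or keep_samples.size < ds.n_samples
        ds = ds.subset(sample_idx=keep_samples, snp_idx=keep_snps)

        # MAF on the surviving set
        dos = np.ma.masked_equal(ds.dosages, MISSING)
        n_hap = 2 * dos.count(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(n_hap > 0, dos.sum(axis=0).filled(0) / np.maximum(n_hap, 1), np.nan)
        maf = np.minimum(freq, 1.0 - freq)
        keep_maf = np.flatnonzero(np.nan_to_num(maf, nan=-1.0) >= min_maf)
        removed_maf += ds.n_snps - keep_maf.size
        changed = changed or keep_maf.size < ds.n_snps
        ds = ds.subset(snp_idx=keep_maf)
        if not changed:
            break

    if ds.n_snps == 0:
        raise ValueError("QC removed every SNP; relax the thresholds")

    total = ds.n_samples * ds.n_snps
    rate = float((ds.dosages != MISSING).sum() / total) if total else 0.0
    report = QCReport(
        n_snps_in=m_in,
        n_snps_out=ds.n_snps,
        n_samples_in=n_in,
        n_samples_out=ds.n_samples,
        genotyping_rate=rate,
        removed_snps_call_rate=removed_snps_cr,
        removed_samples_call_rate=removed_samples,
        removed_snps_maf=removed_maf,
    )
    return ds, report


def allele_frequencies(
    dataset: GenotypeDataset, group_by: dict[str, str] | None = None
) -> PopAlleleFreqs:
    """Per-population allele2 frequencies and haploid counts.

    ``group_by`` optionally maps population labels onto coarser group labels
    (e.g. farm -> old/new) before counting.  Frequencies are NaN where a group
    has no callable genotype at a SNP.
    """
    labels = [group_by.get(p, p) if group_by else p for p in dataset.populations]
    pops: list[str] = []
    for p in labels:
        if p not in pops:
            pops.append(p)

    n_pops, m = len(pops), dataset.n_snps
    freqs = np.full((n_pops, m), np.nan)
    n_hap = np.zeros((n_pops, m), dtype=np.int64)
    lab_arr = np.asarray(labels)
    for k, pop in enumerate(pops):
        rows = dataset.dosages[lab_arr == pop]
        if rows.shape[0] == 0:
            raise ValueError(f"population {pop!r} has no samples")
        called = rows != MISSING
        cnt = 2 * called.sum(axis=0)
        alt = np.where(called, rows, 0).sum(axis=0)
        n_hap[k] = cnt
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[k] = np.where(cnt > 0, alt / np.maximum(cnt, 1), np.nan)
    return PopAlleleFreqs(populations=pops, freqs=freqs, n_hap=n_hap, snps=list(dataset.snps))
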