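"""Bias-corrected f2 and outgroup-f3 statistics with block-jackknife errors.

Per-SNP contributions use Patterson-style finite-sample corrections with
haploid counts:

    f2(A, B)     = (pA - pB)^2 - pA(1-pA)/(nA-1) - pB(1-pB)/(nB-1)
    f3(O; A, B)  = (pO - pA)(pO - pB) - pO(1-pO)/(nO-1)

Standard errors come from a weighted delete-one-block jackknife over
contiguous SNP blocks that never span chromosomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from driftscan.genotype_io import PopAlleleFreqs, SNPRecord

logger = logging.getLogger(__name__)


@dataclass
class FStatRow:
    pop_a: str
    pop_b: str
    estimate: float
    std_error: float
    z_score: float
    p_value: float
    n_blocks: int

    def __post_init__(self) -> None:
        if np.isfinite(self.z_score) and self.std_error > 0:
            if abs(self.z_score - self.estimate / self.std_error) > 1e-8 * max(
                1.0, abs(self.z_score)
            ):
                raise ValueError("z_score inconsistent with estimate / std_error")
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p_value outside [0, 1]")


def _usable(freqs: PopAlleleFreqs, pop_indices: Sequence[int]) -> np.ndarray:
    """SNPs where every requested population has a defined frequency and n >= 2."""
    f = freqs.freqs[list(pop_indices)]
    n = freqs.n_hap[list(pop_indices)]
    return ~np.isnan(f).any(axis=0) & (n >= 2).all(axis=0)


def f2(
    freqs: PopAlleleFreqs, pop_a: str, pop_b: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP bias-corrected f2 contributions.

    Returns ``(contributions, used)`` where ``used`` marks SNPs entering the
    statistic; skipped SNPs (undefined frequency or haploid count < 2 in either
    population) are counted in the log.
    """
    ia, ib = freqs.index_of(pop_a), freqs.index_of(pop_b)
    used = _usable(freqs, [ia, ib])
    n_skip = int((~used).sum())
    if n_skip:
        logger.info("f2(%s,%s): skipped %d SNPs", pop_a, pop_b, n_skip)
    pa, pb = freqs.freqs[ia, used], freqs.freqs[ib, used]
    na, nb = freqs.n_hap[ia, used], freqs.n_hap[ib, used]
    contrib = (pa - pb) ** 2 - pa * (1 - pa) / (na - 1) - pb * (1 - pb) / (nb - 1)
    return contrib, used


def f3_outgroup(
    freqs: PopAlleleFreqs, outgroup: str, pop_a: str, pop_b: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP outgroup-f3 contributions (pO-pA)(pO-pB) - pO(1-pO)/(nO-1)."""
    if outgroup in (pop_a, pop_b):
        raise ValueError("outgroup must differ from the focal pair")
    io_, ia, ib = (freqs.index_of(p) for p in (outgroup, pop_a, pop_b))
    used = _usable(freqs, [io_, ia, ib])
    n_skip = int((~used).sum())
    if n_skip:
        logger.info("f3(%s;%s,%s): skipped %d SNPs", outgroup, pop_a, pop_b, n_skip)
    po, pa, pb = freqs.freqs[io_, used], freqs.freqs[ia, used], freqs.freqs[ib, used]
    no = freqs.n_hap[io_, used]
    contrib = (po - pa) * (po - pb) - po * (1 - po) / (no - 1)
    return contrib, used


def make_blocks(
    snps: Sequence[SNPRecord], used: np.ndarray, block_size_snps: int = 500
) -> np.ndarray:
    """Assign each used SNP to a contiguous block; blocks never span chromosomes.

    Returns an integer block id per used SNP (in the order of the contribution
    vector).
    """
    chroms = np.asarray([s.chrom for s in snps])[np.asarray(used, dtype=bool)]
    block_ids = np.empty(chroms.size, dtype=np.int64)
    next_block = 0
    i = 0
    while i < chroms.size:
        j = i
        while j < chroms.size and chroms[j] == chroms[i]:
            j += 1
        for start in range(i, j, block_size_snps):
            stop = min(start + block_size_snps, j)
            block_ids[start:stop] = next_block
            next_block += 1
        i = j
    return block_ids


def block_jackknife(
    contributions: np.ndarray, block_ids: np.ndarray
) -> tuple[float, float, float, float]:
    """Weighted delete-one-block jackknife over per-SNP contributions.

    Uses the Busing weighted-jackknife variance, which reduces to the classic
    delete-one formula when blocks are equal-sized.  Returns
    ``(estimate, std_error, z, p)``; a zero SE yields ``z = p = nan`` rather
    than an infinity.
    """
    contributions = np.asarray(contributions, dtype=float)
    block_ids = np.asarray(block_ids)
    if contributions.shape != block_ids.shape:
        raise ValueError("contributions and block_ids must align")
    blocks, counts = np.unique(block_ids, return_counts=True)
    m = blocks.size
    if m < 2:
        raise ValueError("need >= 2 non-empty blocks; reduce block size or add data")

    n = contributions.size
    total = contributions.sum()
    estimate = total / n

    block_sums = np.zeros(m)
    for k, b in enumerate(blocks):
        block_sums[k] = contributions[block_ids == b].sum()
    theta_minus = (total - block_sums) / (n - counts)

    h = n / counts
    theta_j = m * estimate - np.sum((1.0 - counts / n) * theta_minus)
    tau = h * estimate - (h - 1.0) * theta_minus  # pseudovalues
    var = np.sum((tau - theta_j) ** 2 / (h - 1.0)) / m
    se = float(np.sqrt(var))

    if se == 0.0:
        return float(estimate), 0.0, float("nan"), float("nan")
    z = float(estimate / se)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(estimate), se, z, p


def f3_table(
    freqs: PopAlleleFreqs,
    outgroup: str,
    block_size_snps: int = 500,
) -> list[FStatRow]:
    """Outgroup-f3 rows for every unordered non-outgroup pair, sorted descending."""
    pops = [p for p in freqs.populations if p != outgroup]
    if outgroup not in freqs.populations:
        raise KeyError(f"outgroup {outgroup!r} not among populations")
    rows = []
    for a, b in combinations(pops, 2):
        contrib, used = f3_outgroup(freqs, outgroup, a, b)
        blocks = make_blocks(freqs.snps, used, block_size_snps)
        est, se, z, p = block_jackknife(contrib, blocks)
        rows.append(
            FStatRow(a, b, est, se, z, p, n_blocks=int(np.unique(blocks).size))
        )
    rows.sort(key=lambda r: r.estimate, reverse=True)
    return rows


def write_f3_table(rows: Sequence[FStatRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("A\tB\tf3_estimate\tstd_error\tz_score\tp_value\tn_blocks\n")
        for r in rows:
            fh.write(
                f"{r.pop_a}\t{r.pop_b}\t{r.estimate:.6f}\t{r.std_error:.6e}\t"
                f"{r.z_score:.4f}\t{r.p_value:.4e}\t{r.n_blocks}\n"
            )
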