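"""Selection-signature scanning: per-SNP FST, window smoothing, region calling,
the kinship-corrected FLK differentiation test, and Storey q-value FDR control.

FST uses the Weir-Cockerham variance-components estimator by default (computed
from per-population allele frequencies and haploid counts), with an
uncorrected variance-ratio option.  FLK models the per-SNP frequency vector as
multivariate normal around an ancestral frequency with covariance
``p0 (1 - p0) F`` for a between-population kinship matrix F derived from a
neighbor-joining tree on Reynolds distances, rooted on an outgroup; the
statistic is chi-square with (n_populations - 1) degrees of freedom under
neutral drift.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from skbio import DistanceMatrix
from skbio.tree import nj

from driftscan.genotype_io import GenotypeDataset, PopAlleleFreqs, SNPRecord, allele_frequencies

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# FST
# ---------------------------------------------------------------------------


def _wc_components(P: np.ndarray, N: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weir-Cockerham between/within variance components (a, b) per SNP.

    Computed from population allele frequencies and haploid sample sizes
    (the average-heterozygosity term is zero in this parameterization).
    """
    r = P.shape[0]
    nbar = N.mean(axis=0)
    nc = (N.sum(axis=0) - (N**2).sum(axis=0) / N.sum(axis=0)) / (r - 1)
    pbar = (N * P).sum(axis=0) / N.sum(axis=0)
    s2 = (N * (P - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    inner = pbar * (1.0 - pbar) - s2 * (r - 1) / r
    a = (nbar / nc) * (s2 - inner / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * inner
    return a, b


def global_fst(freqs: PopAlleleFreqs, estimator: str = "wc") -> float:
    """Multi-locus FST: the ratio of summed variance components over SNPs.

    For ``"wc"`` this is sum(a) / sum(a + b), the standard genome-wide
    Weir-Cockerham estimate; for ``"plain"`` the summed between-population
    variance over the summed total.  Undefined SNPs are excluded.
    """
    if len(freqs.populations) < 2:
        raise ValueError("FST needs at least 2 populations")
    P = freqs.freqs
    N = freqs.n_hap.astype(float)
    defined = ~np.isnan(P).any(axis=0) & (N > 0).all(axis=0)
    P, N = P[:, defined], N[:, defined]
    if estimator == "wc":
        a, b = _wc_components(P, N)
        pbar = (N * P).sum(axis=0) / N.sum(axis=0)
        poly = (pbar > 0) & (pbar < 1)
        return float(a[poly].sum() / (a[poly] + b[poly]).sum())
    if estimator == "plain":
        pbar = P.mean(axis=0)
        var = P.var(axis=0)
        denom = pbar * (1.0 - pbar)
        ok = denom > 0
        return float(var[ok].sum() / denom[ok].sum())
    raise ValueError(f"unknown estimator {estimator!r}")


def per_snp_fst(freqs: PopAlleleFreqs, estimator: str = "wc") -> np.ndarray:
    """Per-SNP FST across all populations in ``freqs``.

    ``estimator="wc"`` is the Weir-Cockerham theta from allele frequencies and
    haploid sample sizes; ``estimator="plain"`` is the uncorrected ratio
    Var(p) / (pbar (1 - pbar)).  Monomorphic or undefined SNPs yield NaN.
    Negative WC estimates are returned as-is (clamping is a display concern).
    """
    if len(freqs.populations) < 2:
        raise ValueError("FST needs at least 2 populations")
    P = freqs.freqs
    N = freqs.n_hap.astype(float)
    defined = ~np.isnan(P).any(axis=0) & (N > 0).all(axis=0)

    out = np.full(P.shape[1], np.nan)
    if estimator == "plain":
        pbar = P[:, defined].mean(axis=0)
        var = P[:, defined].var(axis=0)  # ddof=0 across populations
        denom = pbar * (1.0 - pbar)
        vals = np.full(denom.shape, np.nan)
        ok = denom > 0
        vals[ok] = var[ok] / denom[ok]
        out[defined] = vals
        return out
    if estimator != "wc":
        raise ValueError(f"unknown estimator {estimator!r}")

    n = N[:, defined]
    p = P[:, defined]
    a, b = _wc_components(p, n)
    pbar = (n * p).sum(axis=0) / n.sum(axis=0)
    denom = a + b
    vals = np.full(denom.shape, np.nan)
    ok = np.abs(denom) > 0
    vals[ok] = a[ok] / denom[ok]
    # pooled-monomorphic SNPs carry no differentiation information
    poly = (pbar > 0) & (pbar < 1)
    vals[~poly] = np.nan
    out[defined] = vals
    return out


def smooth_fst(
    values: np.ndarray, snps: Sequence[SNPRecord], window_snps: int = 9, step: int = 1
) -> np.ndarray:
    """Centered sliding mean of ``values`` over ``window_snps`` SNPs per chromosome.

    Windows truncate at chromosome edges; NaN entries are ignored within a
    window (NaN results only where a whole window is NaN).  ``step`` thins the
    output grid: positions off the step grid get NaN.  Input must be sorted by
    (chrom, pos); unsorted input raises rather than silently re-sorting.
    """
    if window_snps < 1 or window_snps % 2 == 0:
        raise ValueError("window_snps must be odd and >= 1")
    values = np.asarray(values, dtype=float)
    if values.size != len(snps):
        raise ValueError("values and snps must align")
    _check_sorted(snps)

    half = window_snps // 2
    out = np.full(values.size, np.nan)
    for lo, hi in _chrom_runs(snps):
        v = values[lo:hi]
        finite = np.isfinite(v)
        x = np.where(finite, v, 0.0)
        csum = np.concatenate([[0.0], np.cumsum(x)])
        ccnt = np.concatenate([[0], np.cumsum(finite)])
        idx = np.arange(hi - lo)
        a = np.maximum(idx - half, 0)
        b = np.minimum(idx + half + 1, hi - lo)
        cnt = ccnt[b] - ccnt[a]
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(cnt > 0, (csum[b] - csum[a]) / cnt, np.nan)
        out[lo:hi] = means
    if step > 1:
        mask = np.ones(values.size, dtype=bool)
        mask[::step] = False
        out[mask] = np.nan
    return out


def _check_sorted(snps: Sequence[SNPRecord]) -> None:
    prev_chrom, prev_pos, seen = None, -1, set()
    for s in snps:
        if s.chrom != prev_chrom:
            if s.chrom in seen:
                raise ValueError("SNPs not sorted by (chrom, pos); sort before smoothing")
            seen.add(s.chrom)
            prev_chrom, prev_pos = s.chrom, -1
        if s.pos_bp < prev_pos:
            raise ValueError("SNPs not sorted by (chrom, pos); sort before smoothing")
        prev_pos = s.pos_bp


def _chrom_runs(snps: Sequence[SNPRecord]):
    lo = 0
    for i in range(1, len(snps) + 1):
        if i == len(snps) or snps[i].chrom != snps[lo].chrom:
            yield lo, i
            lo = i


@dataclass
class SelectedRegion:
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    peak_stat: float
    method: str  # "FST" or "FLK"

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp must be <= end_bp")
        if self.n_snps < 1:
            raise ValueError("region must contain >= 1 SNP")


def _merge_flagged(
    snps: Sequence[SNPRecord],
    flagged: np.ndarray,
    stat: np.ndarray,
    max_gap_snps: int,
    method: str,
) -> list[SelectedRegion]:
    regions: list[SelectedRegion] = []
    for lo, hi in _chrom_runs(snps):
        idx = [j for j in range(lo, hi) if flagged[j]]
        if not idx:
            continue
        group = [idx[0]]
        for j in idx[1:]:
            if j - group[-1] - 1 <= max_gap_snps:
                group.append(j)
            else:
                regions.append(_region_from(snps, group, stat, method))
                group = [j]
        regions.append(_region_from(snps, group, stat, method))
    return regions


def _region_from(snps, members, stat, method) -> SelectedRegion:
    vals = [stat[j] for j in members if np.isfinite(stat[j])]
    return SelectedRegion(
        chrom=snps[members[0]].chrom,
        start_bp=snps[members[0]].pos_bp,
        end_bp=snps[members[-1]].pos_bp,
        n_snps=len(members),
        peak_stat=float(max(vals)) if vals else float("nan"),
        method=method,
    )


def call_fst_regions(
    snps: Sequence[SNPRecord],
    smoothed: np.ndarray,
    quantile: float = 0.95,
    max_gap_snps: int = 0,
) -> tuple[list[SelectedRegion], float]:
    """Flag SNPs strictly above the empirical ``quantile`` of smoothed FST and
    merge them into regions (gaps of up to ``max_gap_snps`` unflagged SNPs are
    bridged within a chromosome).  Returns ``(regions, threshold)``.
    """
    smoothed = np.asarray(smoothed, dtype=float)
    finite = np.isfinite(smoothed)
    if finite.sum() < 20:
        warnings.warn("fewer than 20 SNPs: the empirical quantile is unstable")
    if not finite.any():
        return [], float("nan")
    threshold = float(np.quantile(smoothed[finite], quantile))  # type-7 interpolation
    flagged = finite & (smoothed > threshold)
    return _merge_flagged(snps, flagged, smoothed, max_gap_snps, "FST"), threshold


# ---------------------------------------------------------------------------
# Kinship and FLK
# ---------------------------------------------------------------------------


@dataclass
class KinshipF:
    """Between-population drift covariance matrix (outgroup excluded)."""

    populations: list[str]
    F: np.ndarray
    tree_newick: str = ""

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        k = len(self.populations)
        if self.F.shape != (k, k):
            raise ValueError("F shape must match populations")
        if not np.allclose(self.F, self.F.T, atol=1e-10):
            raise ValueError("F must be symmetric")
        if (np.diag(self.F) <= 0).any():
            raise ValueError("F diagonal must be positive")


def reynolds_distances(freqs: PopAlleleFreqs) -> np.ndarray:
    """Pairwise Reynolds-type drift distances (ratio of sums over SNPs).

    Numerator per SNP is the bias-corrected squared frequency difference (the
    f2 contribution); the denominator ``pi(1-pj) + pj(1-pi)`` is unbiased for
    its population value because samples are independent across populations.
    """
    P, N = freqs.freqs, freqs.n_hap.astype(float)
    k = P.shape[0]
    D = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            ok = ~np.isnan(P[i]) & ~np.isnan(P[j]) & (N[i] >= 2) & (N[j] >= 2)
            pi, pj = P[i, ok], P[j, ok]
            num = (
                (pi - pj) ** 2
                - pi * (1 - pi) / (N[i, ok] - 1)
                - pj * (1 - pj) / (N[j, ok] - 1)
            )
            den = pi * (1 - pj) + pj * (1 - pi)
            usable = den.sum()
            if usable <= 0:
                raise ValueError(f"no usable SNPs between populations {i} and {j}")
            D[i, j] = D[j, i] = max(num.sum() / usable, 0.0)
    return D


def build_kinship(freqs: PopAlleleFreqs, outgroup: str) -> KinshipF:
    """Kinship matrix F from a neighbor-joining tree on Reynolds distances.

    The NJ tree is rooted at the outgroup attachment node and the outgroup is
    dropped; F_ij is the shared root-to-divergence branch length of the pair
    and F_ii the root-to-leaf length.  Reynolds distances approximate half the
    additive drift distance, so fitted branch lengths are doubled to express F
    on the drift-variance scale Var(p) = F p0 (1 - p0).  Negative NJ branch
    lengths are clamped to zero; if F is not positive definite it is jittered
    by 1e-8 on the diagonal with a warning.
    """
    if outgroup not in freqs.populations:
        raise KeyError(f"outgroup {outgroup!r} not among populations")
    if len(freqs.populations) < 3:
        raise ValueError("kinship needs >= 3 populations including the outgroup")

    D = reynolds_distances(freqs)
    dm = DistanceMatrix(D, ids=freqs.populations)
    tree = nj(dm)

    og = tree.find(outgroup)
    rooted = tree.root_at(og.parent) if og.parent is not None else tree
    og = rooted.find(outgroup)

    clamped = 0
    for node in rooted.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    if clamped:
        warnings.warn(f"clamped {clamped} negative NJ branch lengths to 0")

    pops = [p for p in freqs.populations if p != outgroup]
    k = len(pops)
    F = np.zeros((k, k))
    root = rooted.root()
    tips = {p: rooted.find(p) for p in pops}

    def path_to_root(node) -> list:
        out = []
        while node is not root and node is not None:
            out.append(node)
            node = node.parent
        return list(reversed(out))

    paths = {p: path_to_root(tips[p]) for p in pops}
    for a in range(k):
        for b in range(a, k):
            pa, pb = paths[pops[a]], paths[pops[b]]
            if a == b:
                shared = pa
            else:
                shared = [x for x, y in zip(pa, pb) if x is y]
            F[a, b] = F[b, a] = 2.0 * sum((n.length or 0.0) for n in shared)

    eigmin = np.linalg.eigvalsh(F).min() if k else 0.0
    if eigmin <= 0:
        warnings.warn("kinship matrix not positive definite; jittering diagonal by 1e-8")
        F = F + (1e-8 - min(eigmin, 0.0)) * np.eye(k)
    newick = io.StringIO()
    rooted.write(newick)
    return KinshipF(populations=pops, F=F, tree_newick=newick.getvalue().strip())


def flk(
    freqs: PopAlleleFreqs, kinship: KinshipF, sampling_correction: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """FLK statistic and chi-square p-value per SNP.

    With frequency vector p over the kinship populations, the ancestral
    frequency is the generalized-least-squares estimate
    p0 = (1' V^-1 p) / (1' V^-1 1) and

        FLK = (p - p0 1)' [p0 (1 - p0) V]^-1 (p - p0 1)  ~  chi2(n_pops - 1),

    where V = F by default under the drift model.  Observed frequencies carry
    binomial sampling noise on top of drift, Var(p_hat_i) =
    p0(1-p0) [F_ii + (1 - F_ii)/n_i] for haploid count n_i, so with
    ``sampling_correction`` (the default) V = F + diag((1 - F_ii)/n_i) using
    each SNP's haploid counts; without it the test is anti-conservative for
    modest sample sizes.  SNPs with undefined frequencies or p0 outside (0, 1)
    yield NaN.
    """
    idx = [freqs.index_of(p) for p in kinship.populations]
    P = freqs.freqs[idx]
    N = freqs.n_hap[idx]
    r = len(idx)
    if r < 2:
        raise ValueError("FLK needs >= 2 populations")

    m = P.shape[1]
    stat = np.full(m, np.nan)
    pval = np.full(m, np.nan)
    ok = ~np.isnan(P).any(axis=0) & (N > 0).all(axis=0)

    one = np.ones(r)
    fdiag = np.diag(kinship.F)
    p0 = np.full(m, np.nan)
    quad = np.full(m, np.nan)

    if sampling_correction:
        # SNPs sharing a haploid-count vector share V; invert once per group
        _, group_ids = np.unique(N[:, ok], axis=1, return_inverse=True)
        cols = np.flatnonzero(ok)
        for g in np.unique(group_ids):
            js = cols[group_ids == g]
            V = kinship.F + np.diag((1.0 - fdiag) / N[:, js[0]])
            Vinv = np.linalg.inv(V)
            w = Vinv @ one
            p0[js] = (w @ P[:, js]) / (one @ w)
            inner = js[(p0[js] > 0.0) & (p0[js] < 1.0)]
            resid = P[:, inner] - p0[inner]
            quad[inner] = np.einsum("is,ij,js->s", resid, Vinv, resid)
    else:
        Finv = np.linalg.inv(kinship.F)
        w = Finv @ one
        denom = one @ w
        cols = np.flatnonzero(ok)
        p0[cols] = (w @ P[:, cols]) / denom
        inner = (p0 > 0.0) & (p0 < 1.0) & ok
        resid = P[:, inner] - p0[inner]
        quad[inner] = np.einsum("is,ij,js->s", resid, Finv, resid)

    ok &= (p0 > 0.0) & (p0 < 1.0)
    stat[ok] = quad[ok] / (p0[ok] * (1.0 - p0[ok]))
    pval[ok] = stats.chi2.sf(stat[ok], df=r - 1)
    n_excl = int((~ok).sum())
    if n_excl:
        logger.info("FLK: excluded %d SNPs (undefined freq or ancestral estimate at 0/1)", n_excl)
    return stat, pval


# ---------------------------------------------------------------------------
# q-values
# ---------------------------------------------------------------------------


def estimate_pi0(p_values: np.ndarray, method: str = "smoother") -> float:
    """Storey's null-proportion estimate.

    ``"smoother"`` fits a cubic polynomial to pi0(lambda) on the grid
    0.05..0.95 and extrapolates to lambda = 1; ``"fixed"`` uses lambda = 0.5.
    The estimate is capped into (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if method == "fixed":
        pi0 = (p > 0.5).sum() / (m * 0.5)
    elif method == "smoother":
        lams = np.arange(0.05, 0.96, 0.05)
        pi0s = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lams])
        coeffs = np.polyfit(lams, pi0s, deg=3)
        pi0 = float(np.polyval(coeffs, 1.0))
    else:
        raise ValueError(f"unknown pi0 method {method!r}")
    return float(min(max(pi0, 1.0 / m), 1.0))


def qvalues(
    p_values: np.ndarray, pi0_method: str = "smoother", pi0: float | None = None
) -> np.ndarray:
    """Storey q-values: q(p_(i)) = min_{t >= p_(i)} pi0 * m * t / rank(t).

    ``pi0`` overrides estimation when given.  Output is monotone in p and
    capped at 1; NaN p-values yield NaN q-values.
    """
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    if not finite.any():
        raise ValueError("no finite p-values")
    vals = p[finite]
    if (vals <= 0).any() or (vals > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(vals, method=pi0_method)

    m = vals.size
    order = np.argsort(vals, kind="stable")
    ranked = vals[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]  # step-up minima
    q = np.clip(q, 0.0, 1.0)
    out = np.full(p.shape, np.nan)
    out_idx = np.flatnonzero(finite)[order]
    out[out_idx] = q
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


@dataclass
class ScanConfig:
    window_snps: int = 9
    quantile: float = 0.95
    max_gap_snps: int = 2
    fdr: float = 0.15
    fst_estimator: str = "wc"
    pi0_method: str = "smoother"


@dataclass
class ScanResult:
    table: pd.DataFrame
    fst_regions: list[SelectedRegion]
    flk_regions: list[SelectedRegion]
    fst_threshold: float
    kinship: KinshipF | None
    config: ScanConfig
    fst_flagged: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))
    flk_flagged: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))

    @property
    def both_flagged(self) -> np.ndarray:
        return self.fst_flagged & self.flk_flagged

    def write(self, out_dir: str | Path, stem: str = "scan") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / f"{stem}_table.tsv", sep="\t", index=False)
        regions = self.fst_regions + self.flk_regions
        with open(out / f"{stem}_regions.tsv", "w") as fh:
            fh.write("method\tchrom\tstart_bp\tend_bp\tn_snps\tpeak_stat\n")
            for r in regions:
                fh.write(
                    f"{r.method}\t{r.chrom}\t{r.start_bp}\t{r.end_bp}\t{r.n_snps}\t"
                    f"{r.peak_stat:.6g}\n"
                )
        manh = self.table[["chrom", "pos_bp"]].copy()
        with np.errstate(divide="ignore"):
            manh["neglog10_p"] = -np.log10(self.table["flk_p"])
        manh.to_csv(out / f"{stem}_manhattan.tsv", sep="\t", index=False)


def run_scan(
    dataset: GenotypeDataset,
    groups: dict[str, str] | None = None,
    outgroup: str | None = None,
    config: ScanConfig | None = None,
) -> ScanResult:
    """FST + FLK scan over a grouping of the dataset's populations.

    ``groups`` maps population labels onto analysis groups (identity when
    None).  The outgroup group, when given, is used only to root the kinship
    tree: it is excluded from FST and from the FLK quadratic form.  FLK is
    skipped (NaN columns) when no outgroup is given or fewer than three groups
    exist.
    """
    config = config or ScanConfig()
    try:
        freqs = allele_frequencies(dataset, group_by=groups)
    except ValueError as exc:
        raise RuntimeError(f"[frequencies] {exc}") from exc
    n_groups = len(freqs.populations)
    focal = [p for p in freqs.populations if p != outgroup]
    if len(focal) < 2:
        raise RuntimeError("[grouping] need >= 2 non-outgroup groups")

    focal_idx = [freqs.index_of(p) for p in focal]
    focal_freqs = PopAlleleFreqs(
        populations=focal,
        freqs=freqs.freqs[focal_idx],
        n_hap=freqs.n_hap[focal_idx],
        snps=freqs.snps,
    )

    try:
        fst_raw = per_snp_fst(focal_freqs, estimator=config.fst_estimator)
        smoothed = smooth_fst(fst_raw, dataset.snps, window_snps=config.window_snps)
        fst_regions, threshold = call_fst_regions(
            dataset.snps, smoothed, quantile=config.quantile, max_gap_snps=config.max_gap_snps
        )
    except ValueError as exc:
        raise RuntimeError(f"[fst] {exc}") from exc
    fst_flagged = np.isfinite(smoothed) & (smoothed > threshold)

    kinship = None
    flk_stat = np.full(dataset.n_snps, np.nan)
    flk_p = np.full(dataset.n_snps, np.nan)
    flk_q = np.full(dataset.n_snps, np.nan)
    flk_flagged = np.zeros(dataset.n_snps, dtype=bool)
    flk_regions: list[SelectedRegion] = []
    if outgroup is not None and n_groups >= 3:
        try:
            kinship = build_kinship(freqs, outgroup)
            flk_stat, flk_p = flk(freqs, kinship)
            flk_q = qvalues(flk_p, pi0_method=config.pi0_method)
        except (ValueError, KeyError, np.linalg.LinAlgError) as exc:
            raise RuntimeError(f"[flk] {exc}") from exc
        flk_flagged = np.nan_to_num(flk_q, nan=1.0) <= config.fdr
        flk_regions = _merge_flagged(
            dataset.snps, flk_flagged, flk_stat, config.max_gap_snps, "FLK"
        )

    table = pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in dataset.snps],
            "chrom": [s.chrom for s in dataset.snps],
            "pos_bp": [s.pos_bp for s in dataset.snps],
            "fst": np.clip(fst_raw, 0.0, None),
            "fst_raw": fst_raw,
            "smoothed_fst": smoothed,
            "flk": flk_stat,
            "flk_p": flk_p,
            "flk_q": flk_q,
        }
    )
    return ScanResult(
        table=table,
        fst_regions=fst_regions,
        flk_regions=flk_regions,
        fst_threshold=threshold,
        kinship=kinship,
        config=config,
        fst_flagged=fst_flagged,
        flk_flagged=flk_flagged,
    )


def run_one_vs_rest(
    dataset: GenotypeDataset,
    populations: Sequence[str] | None = None,
    outgroup: str | None = None,
    config: ScanConfig | None = None,
) -> dict[str, ScanResult]:
    """One scan per focal population, comparing it to the rest combined."""
    pops = list(populations) if populations else dataset.population_labels
    pops = [p for p in pops if p != outgroup]
    results = {}
    for pop in pops:
        groups = {
            q: (pop if q == pop else ("rest" if q in pops else q))
            for q in dataset.population_labels
        }
        results[pop] = run_scan(dataset, groups=groups, outgroup=outgroup, config=config)
    return results
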