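"""Interval overlap of called regions with gene/QTL tables and Fisher-exact
category enrichment.

Internal coordinates are 1-based inclusive; BED input (0-based half-open) is
converted on read.  Overlap uses closed-interval intersection (>= 1 shared
base pair) via a sorted sweep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from driftscan.selection_scan import SelectedRegion

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Feature:
    chrom: str
    start_bp: int  # 1-based inclusive
    end_bp: int
    name: str
    category: str = ""

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"feature {self.name}: start > end after normalization")


@dataclass
class FeatureSet:
    intervals: list[Feature]
    source_format: str  # "bed" or "tsv"

    def __post_init__(self) -> None:
        names = [f.name for f in self.intervals]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique within a source")

    def __len__(self) -> int:
        return len(self.intervals)


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def read_features(path: str | Path, format: str = "bed") -> FeatureSet:
    """Read a BED (0-based half-open) or TSV (1-based inclusive) interval table.

    Columns: chrom, start, end, name[, category].  Malformed lines raise with
    their line number.  Chromosome names are normalized by stripping a leading
    ``chr``.
    """
    if format not in ("bed", "tsv"):
        raise ValueError(f"unrecognized format {format!r}")
    feats: list[Feature] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 4:
            raise ValueError(f"{path}:{ln}: expected >= 4 tab-separated columns")
        chrom, start_s, end_s, name = parts[:4]
        category = parts[4] if len(parts) > 4 else ""
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ValueError(f"{path}:{ln}: non-integer coordinates") from None
        if format == "bed":
            start, end = start + 1, end  # 0-based half-open -> 1-based inclusive
        if start > end:
            raise ValueError(f"{path}:{ln}: empty interval (start > end after normalization)")
        feats.append(Feature(_norm_chrom(chrom), start, end, name, category))
    return FeatureSet(intervals=feats, source_format=format)


def write_features_bed(features: FeatureSet, path: str | Path) -> None:
    """Write intervals back to BED (0-based half-open); inverse of bed reading."""
    with open(path, "w") as fh:
        for f in features.intervals:
            fields = [f.chrom, str(f.start_bp - 1), str(f.end_bp), f.name]
            if f.category:
                fields.append(f.category)
            fh.write("\t".join(fields) + "\n")


@dataclass(frozen=True)
class OverlapHit:
    region: SelectedRegion
    feature: Feature
    overlap_bp: int


def overlap(
    regions: Sequence[SelectedRegion], features: FeatureSet | Sequence[Feature]
) -> list[OverlapHit]:
    """All (region, feature) pairs sharing >= 1 bp, by a per-chromosome sorted sweep."""
    feats = features.intervals if isinstance(features, FeatureSet) else list(features)
    by_chrom: dict[str, list[Feature]] = {}
    for f in feats:
        by_chrom.setdefault(f.chrom, []).append(f)
    for fl in by_chrom.values():
        fl.sort(key=lambda f: f.start_bp)

    hits: list[OverlapHit] = []
    for region in sorted(regions, key=lambda r: (_norm_chrom(r.chrom), r.start_bp)):
        chrom = _norm_chrom(region.chrom)
        for f in by_chrom.get(chrom, []):
            if f.start_bp > region.end_bp:
                break  # sorted by start: nothing later can overlap
            lo = max(region.start_bp, f.start_bp)
            hi = min(region.end_bp, f.end_bp)
            if lo <= hi:
                hits.append(OverlapHit(region=region, feature=f, overlap_bp=hi - lo + 1))
    return hits


@dataclass
class EnrichmentRow:
    category: str
    observed: int
    expected: float
    fold_enrichment: float
    raw_p: float

    def __post_init__(self) -> None:
        if not 0.0 < self.raw_p <= 1.0:
            raise ValueError("raw_p must lie in (0, 1]")
        if self.expected > 0:
            fold = self.observed / self.expected
            if abs(fold - self.fold_enrichment) > 1e-9 * max(1.0, fold):
                raise ValueError("fold_enrichment inconsistent with observed/expected")


def fisher_enrichment(
    hit_names: Iterable[str],
    background_names: Iterable[str],
    category_map: dict[str, str | Sequence[str]],
    alternative: str = "greater",
) -> list[EnrichmentRow]:
    """Per-category Fisher exact enrichment of ``hit_names`` within ``background_names``.

    One-sided (over-representation) by default via the hypergeometric tail;
    ``expected = len(hits) * category_frequency_in_background``.  Rows are
    sorted by raw p-value.  Names may map to one category or a sequence of
    categories.
    """
    hits = set(hit_names)
    background = set(background_names)
    if not background:
        raise ValueError("background gene set is empty")
    if not hits <= background:
        raise ValueError("hit_names must be a subset of background_names")

    def cats_of(name: str) -> list[str]:
        c = category_map.get(name, [])
        return [c] if isinstance(c, str) else list(c)

    categories = sorted({c for n in background for c in cats_of(n) if c})
    n_list, n_bg = len(hits), len(background)
    rows: list[EnrichmentRow] = []
    for cat in categories:
        in_cat = {n for n in background if cat in cats_of(n)}
        k = len(hits & in_cat)
        K = len(in_cat)
        table = np.array([[k, n_list - k], [K - k, n_bg - n_list - (K - k)]])
        p = float(stats.fisher_exact(table, alternative=alternative)[1])
        expected = n_list * K / n_bg
        fold = k / expected if expected > 0 else float("nan")
        rows.append(
            EnrichmentRow(
                category=cat,
                observed=k,
                expected=expected,
                fold_enrichment=fold,
                raw_p=min(max(p, np.nextafter(0, 1)), 1.0),
            )
        )
    rows.sort(key=lambda r: r.raw_p)
    return rows


def write_enrichment(rows: Sequence[EnrichmentRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("category\tobserved\texpected\tfold_enrichment\traw_p\n")
        for r in rows:
            fh.write(
                f"{r.category}\t{r.observed}\t{r.expected:.4f}\t"
                f"{r.fold_enrichment:.4f}\t{r.raw_p:.4e}\n"
            )
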