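"""Genomic feature annotation and regulatory-domain gene assignment.

Regions (2 kb DhMR bins) are classified into one feature category at their
midpoint with the priority promoter-TSS > TTS > 5'UTR > 3'UTR > exon >
intron > intergenic, using HOMER-style windows (promoter-TSS = TSS-1 kb to
TSS+100 b, TTS = TES-100 b to TES+1 kb, strand-aware).  Category enrichment
of a region set against the genome-composition background uses a one-sided
binomial test.  Gene assignment follows GREAT's basal-plus-extension rule
(basal 5 kb upstream / 1 kb downstream of the TSS, extension up to 1 Mb
stopping at neighboring genes' basal domains).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import binom as _binom

from .stats import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "RegulatoryDomain",
    "FeatureAnnotation",
    "GeneModels",
    "CATEGORIES",
    "classify_region",
    "classify_regions",
    "feature_enrichment",
    "regulatory_domains",
    "assign_genes",
    "read_gene_models",
]

CATEGORIES = ("promoter-TSS", "TTS", "5UTR", "3UTR", "exon", "intron", "intergenic")

PROMOTER_UP = 1000    # upstream of TSS
PROMOTER_DOWN = 100   # downstream of TSS
TTS_UP = 100
TTS_DOWN = 1000


@dataclass(frozen=True)
class GeneModel:
    gene: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]
    utr5: tuple[int, int] | None = None
    utr3: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene}: bad strand {self.strand!r}")
        if len(self.exon_starts) != len(self.exon_ends):
            raise ValueError(f"{self.gene}: exon start/end length mismatch")
        for s, e in zip(self.exon_starts, self.exon_ends):
            if e <= s:
                raise ValueError(f"{self.gene}: empty exon [{s},{e})")

    @property
    def span(self) -> tuple[int, int]:
        return min(self.tss, self.tes), max(self.tss, self.tes)

    def promoter_window(self) -> tuple[int, int]:
        if self.strand == "+":
            return self.tss - PROMOTER_UP, self.tss + PROMOTER_DOWN
        return self.tss - PROMOTER_DOWN, self.tss + PROMOTER_UP

    def tts_window(self) -> tuple[int, int]:
        if self.strand == "+":
            return self.tes - TTS_UP, self.tes + TTS_DOWN
        return self.tes - TTS_DOWN, self.tes + TTS_UP


@dataclass(frozen=True)
class RegulatoryDomain:
    gene: str
    chrom: str
    basal: tuple[int, int]
    extended: tuple[int, int]

    def __post_init__(self) -> None:
        bs, be = self.basal
        es, ee = self.extended
        if not (es <= bs and be <= ee):
            raise ValueError(f"{self.gene}: basal not contained in extended domain")


@dataclass(frozen=True)
class FeatureAnnotation:
    chrom: str
    start: int
    end: int
    category: str
    gene: str | None
    distance_to_tss: int | None


class GeneModels:
    """Indexed gene models: per-chromosome interval trees per feature kind."""

    def __init__(self, models: list[GeneModel]):
        self.models = list(models)
        self._trees: dict[str, dict[str, IntervalTree]] = {}
        self._tss: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
        by_chrom: dict[str, list[GeneModel]] = {}
        for m in models:
            by_chrom.setdefault(m.chrom, []).append(m)
        for chrom, ms in by_chrom.items():
            trees = {k: IntervalTree() for k in ("promoter", "tts", "utr5", "utr3", "exon", "body")}
            for m in ms:
                s, e = m.promoter_window()
                trees["promoter"].addi(s, e, m)
                s, e = m.tts_window()
                trees["tts"].addi(s, e, m)
                if m.utr5:
                    trees["utr5"].addi(*m.utr5, m)
                if m.utr3:
                    trees["utr3"].addi(*m.utr3, m)
                for s, e in zip(m.exon_starts, m.exon_ends):
                    trees["exon"].addi(s, e, m)
                trees["body"].addi(*m.span, m)
            self._trees[chrom] = trees
            ms_sorted = sorted(ms, key=lambda m: m.tss)
            self._tss[chrom] = (np.array([m.tss for m in ms_sorted]), ms_sorted)

    def nearest_tss(self, chrom: str, pos: int) -> GeneModel | None:
        if chrom not in self._tss:
            return None
        tss, ms = self._tss[chrom]
        i = int(np.argmin(np.abs(tss - pos)))
        return ms[i]

    def hits(self, chrom: str, kind: str, pos: int) -> list[GeneModel]:
        if chrom not in self._trees:
            return []
        return [iv.data for iv in self._trees[chrom][kind][pos]]


def classify_region(region, models: GeneModels) -> FeatureAnnotation:
    """One category per region, decided at the region midpoint."""
    chrom, start, end = region[0], int(region[1]), int(region[2])
    mid = (start + end) // 2
    if chrom not in models._trees:
        logger.warning("region on unknown chromosome %s -> intergenic", chrom)
        return FeatureAnnotation(chrom, start, end, "intergenic", None, None)

    order = (
        ("promoter-TSS", "promoter"),
        ("TTS", "tts"),
        ("5UTR", "utr5"),
        ("3UTR", "utr3"),
        ("exon", "exon"),
        ("intron", "body"),
    )
    category = "intergenic"
    candidates: list[GeneModel] = []
    for cat, kind in order:
        hit = models.hits(chrom, kind, mid)
        if hit:
            category, candidates = cat, hit
            break
    if candidates:
        gene = min(candidates, key=lambda m: abs(m.tss - mid))
    else:
        gene = models.nearest_tss(chrom, mid)
    return FeatureAnnotation(
        chrom, start, end, category,
        gene.gene if gene else None,
        abs(gene.tss - mid) if gene else None,
    )


def classify_regions(regions: pd.DataFrame, models: GeneModels) -> pd.DataFrame:
    rows = [
        classify_region((c, s, e), models)
        for c, s, e in zip(regions["chrom"], regions["start"], regions["end"])
    ]
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in rows],
            "start": [r.start for r in rows],
            "end": [r.end for r in rows],
            "category": [r.category for r in rows],
            "gene": [r.gene for r in rows],
            "distance_to_tss": [r.distance_to_tss for r in rows],
        }
    )


def feature_enrichment(category_counts: dict[str, int], background_fracs: dict[str, float]) -> pd.DataFrame:
    """Per-category log2 enrichment over the background composition with a
    one-sided binomial p and BH q across categories.

    ``background_fracs`` must sum to 1 (the genome-wide bin composition);
    categories absent from the background are dropped with a warning.
    """
    n = sum(category_counts.values())
    if n <= 0:
        raise ValueError("empty region set")
    tot_bg = sum(background_fracs.values())
    if not np.isclose(tot_bg, 1.0, atol=1e-6):
        raise ValueError(f"background fractions sum to {tot_bg}, expected 1")
    rows = []
    for cat in CATEGORIES:
        if cat not in category_counts and cat not in background_fracs:
            continue
        k = int(category_counts.get(cat, 0))
        pbg = background_fracs.get(cat, 0.0)
        if pbg <= 0:
            if k:
                logger.warning("category %s absent from background; excluded", cat)
            continue
        frac = k / n
        log2e = np.log2(frac / pbg) if frac > 0 else -np.inf
        p = float(_binom.sf(k - 1, n, pbg))  # P(X >= k)
        rows.append((cat, k, frac, pbg, log2e, p))
    df = pd.DataFrame(rows, columns=["category", "count", "fraction", "background", "log2_enrichment", "p"])
    df["q"] = bh_fdr(df["p"].to_numpy())
    return df


def regulatory_domains(
    models: list[GeneModel] | GeneModels,
    chrom_sizes: dict[str, int],
    basal_up: int = 5000,
    basal_down: int = 1000,
    max_ext: int = 1_000_000,
) -> list[RegulatoryDomain]:
    """GREAT basal-plus-extension regulatory domains.

    The basal domain (strand-aware TSS-basal_up .. TSS+basal_down) is
    assigned regardless of neighbors; each side is then extended to the
    nearer of ``max_ext`` from the TSS or the closest neighboring basal
    domain edge, never shrinking below the gene's own basal domain, and
    clipped to the chromosome.
    """
    if isinstance(models, GeneModels):
        models = models.models
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    out: list[RegulatoryDomain] = []
    for chrom, ms in by_chrom.items():
        size = chrom_sizes[chrom]

        def _basal(m: GeneModel) -> tuple[int, int]:
            if m.strand == "+":
                s, e = m.tss - basal_up, m.tss + basal_down
            else:
                s, e = m.tss - basal_down, m.tss + basal_up
            return max(0, s), min(size, e)

        basals = {m.gene: _basal(m) for m in ms}
        for m in ms:
            bs, be = basals[m.gene]
            left_limit = max(m.tss - max_ext, 0)
            right_limit = min(m.tss + max_ext, size)
            for other in ms:
                if other.gene == m.gene:
                    continue
                os_, oe = basals[other.gene]
                if oe <= bs:
                    left_limit = max(left_limit, oe)
                if os_ >= be:
                    right_limit = min(right_limit, os_)
            ext = (min(left_limit, bs), max(right_limit, be))
            out.append(RegulatoryDomain(m.gene, chrom, (bs, be), ext))
    return out


def assign_genes(regions: pd.DataFrame, domains: list[RegulatoryDomain]) -> list[list[str]]:
    """Every gene whose extended domain overlaps the region by >= 1 bp."""
    trees: dict[str, IntervalTree] = {}
    for d in domains:
        trees.setdefault(d.chrom, IntervalTree()).addi(d.extended[0], d.extended[1], d.gene)
    out = []
    for chrom, start, end in zip(regions["chrom"], regions["start"], regions["end"]):
        if chrom not in trees:
            out.append([])
            continue
        out.append(sorted(iv.data for iv in trees[chrom][int(start): int(end)]))
    return out


def read_gene_models(path) -> list[GeneModel]:
    """Gene model TSV: gene, chrom, strand, tss, tes, exon_starts, exon_ends
    (comma-separated block coordinates)."""
    return read_gene_models_from_frame(pd.read_csv(path, sep="\t"))


def read_gene_models_from_frame(df: pd.DataFrame) -> list[GeneModel]:
    models = []
    for r in df.itertuples():
        models.append(
            GeneModel(
                gene=str(r.gene),
                chrom=str(r.chrom),
                strand=str(r.strand),
                tss=int(r.tss),
                tes=int(r.tes),
                exon_starts=tuple(int(v) for v in str(r.exon_starts).split(",") if v),
                exon_ends=tuple(int(v) for v in str(r.exon_ends).split(",") if v),
            )
        )
    return models
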