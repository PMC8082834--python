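"""Stepwise DhMR -> chromatin -> expression integration.

The funnel that nominates directly regulated target genes: DhMRs bound by
two factors (e.g. TET1 and NANOG ChIP peaks, each required to overlap the
DhMR by >= 1 bp independently), restricted to promoter-TSS bins, then joined
with the differential-expression table to keep genes whose expression change
is concordant with the promoter's 5hmC direction (gain with up, loss with
down).  Each step's output is a subset of its input.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

__all__ = ["TargetGeneRecord", "bound_dhmrs", "promoter_subset", "concordant_genes"]


@dataclass(frozen=True)
class TargetGeneRecord:
    gene: str
    chrom: str
    start: int
    end: int
    dhmr_call: str          # gain | loss
    expr_log2fc: float | None
    expr_q: float | None
    klass: str              # concordant-up | concordant-down | discordant | untested


def _tree(peaks: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in zip(peaks["chrom"], peaks["start"], peaks["end"]):
        if int(end) > int(start):
            trees.setdefault(chrom, IntervalTree()).addi(int(start), int(end))
    return trees


def _overlaps(trees: dict[str, IntervalTree], chrom: str, start: int, end: int) -> bool:
    return chrom in trees and bool(trees[chrom][int(start): int(end)])


def bound_dhmrs(dhmrs: pd.DataFrame, peaks_a: pd.DataFrame, peaks_b: pd.DataFrame) -> pd.DataFrame:
    """DhMRs overlapping >= 1 bp of BOTH peak sets (sequential intersectBed)."""
    ta, tb = _tree(peaks_a), _tree(peaks_b)
    keep = [
        _overlaps(ta, c, s, e) and _overlaps(tb, c, s, e)
        for c, s, e in zip(dhmrs["chrom"], dhmrs["start"], dhmrs["end"])
    ]
    return dhmrs.loc[keep].reset_index(drop=True)


def promoter_subset(bound: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Keep promoter-TSS DhMRs, each carrying its annotated gene.

    ``annotations`` is the classify_regions table; every DhMR must appear in
    it (keyed by chrom/start/end).
    """
    key = annotations.set_index(["chrom", "start", "end"])
    rows = []
    for _, r in bound.iterrows():
        k = (r["chrom"], r["start"], r["end"])
        if k not in key.index:
            raise KeyError(f"DhMR {k} missing from annotation table")
        ann = key.loc[k]
        if ann["category"] == "promoter-TSS":
            row = dict(r)
            row["gene"] = ann["gene"]
            rows.append(row)
    if not rows:
        return bound.iloc[0:0].assign(gene=pd.Series(dtype=object))
    return pd.DataFrame(rows).reset_index(drop=True)


def concordant_genes(
    promoter_dhmrs: pd.DataFrame, de_table: pd.DataFrame, q_threshold: float = 0.05
) -> list[TargetGeneRecord]:
    """Classify each promoter DhMR's gene against differential expression.

    de_table is keyed by gene with columns log2FC and q.  Concordant-up:
    gain DhMR and significant up-regulation; concordant-down: loss and
    significant down; significant opposite sign: discordant; gene absent or
    not significant: untested.
    """
    de = de_table.set_index("gene") if "gene" in de_table.columns else de_table
    records: list[TargetGeneRecord] = []
    for _, r in promoter_dhmrs.iterrows():
        gene = r["gene"]
        call = r["call"] if "call" in r else r["dhmr_call"]
        lfc = q = None
        klass = "untested"
        if gene in de.index:
            lfc = float(de.loc[gene, "log2FC"])
            q = float(de.loc[gene, "q"])
            if q < q_threshold:
                up = lfc > 0
                if (call == "gain") == up and lfc != 0:
                    klass = "concordant-up" if up else "concordant-down"
                elif lfc != 0:
                    klass = "discordant"
        records.append(
            TargetGeneRecord(
                gene=str(gene),
                chrom=str(r["chrom"]),
                start=int(r["start"]),
                end=int(r["end"]),
                dhmr_call=str(call),
                expr_log2fc=lfc,
                expr_q=q,
                klass=klass,
            )
        )
    return records


def target_gene_table(records: list[TargetGeneRecord]) -> pd.DataFrame:
    """Unique genes with supporting-DhMR counts, sorted by class then q.

    A gene supported by both gain and loss promoter DhMRs appears once per
    stratum with a conflict flag (the region count can exceed the unique
    gene count)."""
    df = pd.DataFrame([r.__dict__ for r in records])
    if df.empty:
        return df
    grouped = (
        df.groupby(["gene", "dhmr_call", "klass"], dropna=False)
        .agg(n_dhmrs=("chrom", "size"), expr_log2fc=("expr_log2fc", "first"), expr_q=("expr_q", "first"))
        .reset_index()
    )
    conflicted = df.groupby("gene")["dhmr_call"].nunique() > 1
    grouped["conflict"] = grouped["gene"].map(conflicted).fillna(False)
    order = {"concordant-up": 0, "concordant-down": 1, "discordant": 2, "untested": 3}
    grouped["_k"] = grouped["klass"].map(order)
    grouped = grouped.sort_values(["_k", "expr_q", "gene"], na_position="last").drop(columns="_k")
    return grouped.reset_index(drop=True)
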