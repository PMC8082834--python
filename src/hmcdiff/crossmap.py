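"""Chain-file liftover and cross-species DhMR comparison.

Implements UCSC chain parsing, base-level interval liftover (minimum-match
semantics like the UCSC liftOver tool), conservation-rate computation, and
the Fisher-based overlap statistics used to compare human and mouse
gain-of-5hmC region and gene sets.

Chain convention: the chain's first (``t``) genome is the *source* the
regions live in, the second (``q``) genome is the *destination*.  Source
strand is always ``+``; a ``-`` destination strand stores coordinates in
reverse-complement space per the UCSC convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bins import BinGrid
from .stats import fisher_exact

__all__ = [
    "ChainAlignment",
    "ChainFormatError",
    "LiftoverParams",
    "LiftoverResult",
    "parse_chain",
    "invert_chain",
    "liftover",
    "conservation_rate",
    "region_overlap_test",
    "ortholog_overlap",
]


class ChainFormatError(ValueError):
    pass


@dataclass(frozen=True)
class LiftoverParams:
    """min_ratio: minimum fraction of region bases that must map (0.95, the
    UCSC tool's minMatch default)."""

    min_ratio: float = 0.95
    require_single_target: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_ratio <= 1:
            raise ValueError("min_ratio must be in (0, 1]")


@dataclass
class ChainAlignment:
    score: float
    src_chrom: str
    src_size: int
    src_start: int
    src_end: int
    dst_chrom: str
    dst_size: int
    dst_strand: str
    dst_start: int   # strand coordinates (UCSC convention)
    dst_end: int
    blocks: list[tuple[int, int, int]]   # (size, src_gap, dst_gap); last gaps 0
    chain_id: str = "0"
    # absolute block coordinates, derived once
    _src_s: np.ndarray = field(init=False, repr=False)
    _src_e: np.ndarray = field(init=False, repr=False)
    _dst_q: np.ndarray = field(init=False, repr=False)   # strand-coord block starts

    def __post_init__(self) -> None:
        s, q = self.src_start, self.dst_start
        ss, se, qq = [], [], []
        for size, dt, dq in self.blocks:
            ss.append(s)
            se.append(s + size)
            qq.append(q)
            s += size + dt
            q += size + dq
        if s - self.blocks[-1][1] != self.src_end or q - self.blocks[-1][2] != self.dst_end:
            raise ChainFormatError(
                f"chain {self.chain_id}: block arithmetic does not match header extents"
            )
        self._src_s = np.array(ss)
        self._src_e = np.array(se)
        self._dst_q = np.array(qq)

    def dst_forward(self, q_start: int, q_end: int) -> tuple[int, int]:
        """Convert a strand-coordinate destination interval to forward coords."""
        if self.dst_strand == "+":
            return q_start, q_end
        return self.dst_size - q_end, self.dst_size - q_start

    def segments(self) -> pd.DataFrame:
        """Aligned blocks with destination intervals in forward coordinates."""
        rows = []
        for s, e, q in zip(self._src_s, self._src_e, self._dst_q):
            fs, fe = self.dst_forward(int(q), int(q) + int(e - s))
            rows.append((self.src_chrom, int(s), int(e), self.dst_chrom, fs, fe, self.dst_strand))
        return pd.DataFrame(
            rows,
            columns=["src_chrom", "src_start", "src_end", "dst_chrom", "dst_start", "dst_end", "strand"],
        )


def parse_chain(text: str) -> list[ChainAlignment]:
    """Parse UCSC chain format; malformed arithmetic raises with line numbers."""
    chains: list[ChainAlignment] = []
    header = None
    blocks: list[tuple[int, int, int]] = []
    header_line = 0

    def _finish():
        nonlocal header, blocks
        if header is None:
            return
        if not blocks or blocks[-1][1] != 0 or blocks[-1][2] != 0:
            raise ChainFormatError(f"line {header_line}: chain has no terminal gapless block")
        (score, t, tsize, tstrand, ts, te, qn, qsize, qstrand, qs, qe, cid) = header
        if tstrand != "+":
            raise ChainFormatError(f"line {header_line}: source strand must be '+'")
        chains.append(
            ChainAlignment(
                score=score, src_chrom=t, src_size=tsize, src_start=ts, src_end=te,
                dst_chrom=qn, dst_size=qsize, dst_strand=qstrand, dst_start=qs,
                dst_end=qe, blocks=blocks, chain_id=cid,
            )
        )
        header, blocks = None, []

    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("chain"):
            _finish()
            parts = line.split()
            if len(parts) not in (12, 13):
                raise ChainFormatError(f"line {ln}: malformed chain header")
            cid = parts[12] if len(parts) == 13 else "0"
            try:
                header = (
                    float(parts[1]), parts[2], int(parts[3]), parts[4], int(parts[5]),
                    int(parts[6]), parts[7], int(parts[8]), parts[9], int(parts[10]),
                    int(parts[11]), cid,
                )
            except ValueError as err:
                raise ChainFormatError(f"line {ln}: {err}") from None
            header_line = ln
        else:
            if header is None:
                raise ChainFormatError(f"line {ln}: alignment block outside a chain")
            parts = line.split()
            try:
                if len(parts) == 3:
                    blocks.append((int(parts[0]), int(parts[1]), int(parts[2])))
                elif len(parts) == 1:
                    blocks.append((int(parts[0]), 0, 0))
                else:
                    raise ValueError("expected 1 or 3 integers")
            except ValueError as err:
                raise ChainFormatError(f"line {ln}: {err}") from None
    _finish()
    if not chains:
        raise ChainFormatError("no chains found")
    return chains


def invert_chain(chain: ChainAlignment) -> ChainAlignment:
    """Chain mapping destination back to source (round-trip companion)."""
    seg = chain.segments().sort_values("dst_start", kind="stable").reset_index(drop=True)
    sizes = (seg.dst_end - seg.dst_start).to_list()
    if chain.dst_strand == "+":
        q = seg.src_start.to_list()
        qstrand = "+"
        q_start, q_end = q[0], q[-1] + sizes[-1]
    else:
        # destination forward ascending corresponds to source descending:
        # the new query (the old source) is on the minus strand
        q = [chain.src_size - e for e in seg.src_end]
        qstrand = "-"
        q_start, q_end = q[0], q[-1] + sizes[-1]
    blocks = []
    for k in range(len(sizes)):
        if k + 1 < len(sizes):
            dt = int(seg.dst_start[k + 1] - seg.dst_end[k])
            dq = int(q[k + 1] - (q[k] + sizes[k]))
        else:
            dt = dq = 0
        blocks.append((int(sizes[k]), dt, dq))
    return ChainAlignment(
        score=chain.score,
        src_chrom=chain.dst_chrom,
        src_size=chain.dst_size,
        src_start=int(seg.dst_start[0]),
        src_end=int(seg.dst_end[len(seg) - 1]),
        dst_chrom=chain.src_chrom,
        dst_size=chain.src_size,
        dst_strand=qstrand,
        dst_start=int(q_start),
        dst_end=int(q_end),
        blocks=blocks,
        chain_id=chain.chain_id,
    )


@dataclass(frozen=True)
class LiftoverResult:
    mapped: tuple[str, int, int, str] | None   # (chrom, start, end, strand), forward coords
    reason: str | None                         # None on success; deleted/partial/split/none
    fraction: float                            # fraction of bases mapped by the chain used

    @property
    def ok(self) -> bool:
        return self.mapped is not None


def _map_through(chain: ChainAlignment, start: int, end: int):
    """Mapped base count and strand-coordinate hull through one chain."""
    s0, e0, q0 = chain._src_s, chain._src_e, chain._dst_q
    os = np.maximum(s0, start)
    oe = np.minimum(e0, end)
    ov = oe - os
    hit = ov > 0
    if not hit.any():
        return 0, None
    qs = q0[hit] + (os[hit] - s0[hit])
    qe = qs + ov[hit]
    return int(ov[hit].sum()), (int(qs.min()), int(qe.max()))


def liftover(region, chains: list[ChainAlignment], params: LiftoverParams | None = None) -> LiftoverResult:
    """Map one region (chrom, start, end) through the highest-scoring
    overlapping chain.

    Success requires >= ``min_ratio`` of bases mapped through a single chain
    (hence one destination chromosome and strand, colinear); the result is
    the [min, max) hull of mapped destination positions in forward
    coordinates.  Failure is a value with a reason: ``none`` (no chain for
    the chromosome), ``deleted`` (chains exist but no base maps), ``split``
    (only a combination of chains would reach min_ratio), ``partial``.
    """
    params = params or LiftoverParams()
    chrom, start, end = region[0], int(region[1]), int(region[2])
    if end <= start:
        raise ValueError("empty region")
    mine = [c for c in chains if c.src_chrom == chrom]
    if not mine:
        return LiftoverResult(None, "none", 0.0)
    length = end - start
    best_frac, best = 0.0, None
    per_chain = []
    for c in sorted(mine, key=lambda c: -c.score):
        n, hull = _map_through(c, start, end)
        frac = n / length
        per_chain.append(frac)
        if frac > best_frac:
            best_frac, best = frac, (c, hull)
        if frac >= params.min_ratio:
            fs, fe = c.dst_forward(hull[0], hull[1])
            return LiftoverResult((c.dst_chrom, fs, fe, c.dst_strand), None, frac)
    if best_frac == 0.0:
        return LiftoverResult(None, "deleted", 0.0)
    if sum(per_chain) >= params.min_ratio and len([f for f in per_chain if f > 0]) > 1:
        return LiftoverResult(None, "split", best_frac)
    return LiftoverResult(None, "partial", best_frac)


def conservation_rate(
    regions: pd.DataFrame, chains: list[ChainAlignment], params: LiftoverParams | None = None
) -> tuple[float, pd.DataFrame]:
    """Fraction of regions that lift over, with a per-region outcome report."""
    if len(regions) == 0:
        raise ValueError("empty region set")
    rows = []
    n_ok = 0
    for chrom, start, end in zip(regions["chrom"], regions["start"], regions["end"]):
        res = liftover((chrom, start, end), chains, params)
        n_ok += res.ok
        if res.ok:
            mc, ms, me, mstrand = res.mapped
            rows.append((chrom, start, end, "mapped", mc, ms, me, mstrand, res.fraction))
        else:
            rows.append((chrom, start, end, res.reason, "", "", "", "", res.fraction))
    report = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "status", "dst_chrom", "dst_start", "dst_end",
                 "dst_strand", "fraction"],
    )
    return n_ok / len(regions), report


def _bins_of(regions: pd.DataFrame, grid: BinGrid) -> set[int]:
    out: set[int] = set()
    for chrom, start, end in zip(regions["chrom"], regions["start"], regions["end"]):
        if chrom in grid.chroms:
            out.update(map(int, grid.overlapping_bins(chrom, int(start), int(end))))
    return out


def region_overlap_test(set_a: pd.DataFrame, set_b: pd.DataFrame, universe: BinGrid):
    """Overlap of two region sets on the bin-grid universe.

    Regions mark every grid bin they overlap by >= 1 bp (intersectBed
    semantics).  Returns ``(n_overlap, percent_of_A_in_B, p, odds_ratio)``
    with a one-sided (greater) Fisher exact test on the 2x2 bin table.
    """
    if len(universe) == 0:
        raise ValueError("empty universe")
    a = _bins_of(set_a, universe)
    b = _bins_of(set_b, universe)
    n = len(universe)
    ab = len(a & b)
    a_only = len(a - b)
    b_only = len(b - a)
    neither = n - ab - a_only - b_only
    p, odds = fisher_exact([[ab, a_only], [b_only, neither]], alternative="greater")
    percent = 100.0 * ab / len(a) if a else float("nan")
    return ab, percent, p, odds


def ortholog_overlap(genes_a, ortholog_map: pd.DataFrame, genes_b):
    """Classify species-A genes as no_ortholog / ortholog_only / common.

    ``ortholog_map`` has columns (gene_a, gene_b); one-to-many entries are
    collapsed to the first pair in file order.  The overlap percentage is
    100 * common / (common + ortholog_only), NA if no gene has an ortholog.
    Mirrors the human-to-mouse gain-of-5hmC gene comparison.
    """
    amap: dict[str, str] = {}
    for ga, gb in zip(ortholog_map["gene_a"], ortholog_map["gene_b"]):
        amap.setdefault(str(ga), str(gb))
    bset = set(map(str, genes_b))
    counts = {"no_ortholog": 0, "ortholog_only": 0, "common": 0}
    for g in sorted(set(map(str, genes_a))):
        if g not in amap:
            counts["no_ortholog"] += 1
        elif amap[g] in bset:
            counts["common"] += 1
        else:
            counts["ortholog_only"] += 1
    with_orth = counts["common"] + counts["ortholog_only"]
    percent = 100.0 * counts["common"] / with_orth if with_orth else float("nan")
    return counts, percent
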