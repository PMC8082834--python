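"""Synthetic hMe-seal study generator with recorded ground truth.

Emulates the data structure of a two-group (tumor vs normal cerebellum)
5hmC pulldown study so every downstream stage can be scored against known
truth without any external download:

* binned pulldown counts with negative-binomial noise, where every sample is
  renormalized to the same expected depth — a genome-wide difference in
  absolute 5hmC abundance is therefore *invisible* in the counts and is
  carried only by the simulated mass-spec table (the situation the
  calibration step exists to fix);
* planted whole-bin regional gain/loss effects of known log2 magnitude;
* a mass-spec nucleoside table reporting each sample's true global level
  with multiplicative lognormal noise;
* gene models whose TSS sit at bin midpoints, a controlled subset of planted
  bins placed at promoters, and an expression count matrix in which linked
  genes change concordantly with their promoter's 5hmC direction;
* ChIP peak sets for two factors jointly covering a controlled fraction of
  the planted bins;
* a shadow genome plus UCSC chain file (per-chromosome offsets, unaligned
  gaps, one minus-strand chromosome) with the true coordinate map recorded;
* a survival table whose exponential hazard decreases with the relative
  5hmC level.

All randomness flows from the single integer seed in :class:`SimConfig`
through ``numpy.random.default_rng``; identical config + seed gives
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .bins import BinGrid, make_bins

__all__ = ["SimConfig", "SimTruth", "SimBundle", "SizingError", "simulate_dataset", "emit_fragments"]


class SizingError(ValueError):
    """Genome too small to host the requested genes / planted regions."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults follow the human study arm: 16 tumors vs 6 normal cerebella,
    2 kb bins on a 10 Mb toy genome at ~100 expected fragments per bin,
    NB dispersion 0.05, and a true tumor global 5hmC level of 0.44-fold
    relative to normal.
    """

    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 4_000_000, "chr2": 3_600_000, "chr3": 2_400_000}
    )
    binsize: int = 2000
    n_tumor: int = 16
    n_normal: int = 6
    depth: int = 500_000          # expected fragments per sample
    dispersion: float = 0.05      # NB alpha, var = mu + alpha mu^2
    global_level_tumor: float = 0.44
    n_gain: int = 100
    n_loss: int = 100
    dhmr_log2fc: float = 4.0
    chip_overlap_frac: float = 0.8
    expr_link_prob: float = 0.8
    survival_beta: float = 2.0
    masspec_cv: float = 0.1
    seed: int = 0
    # generative texture
    intensity_sigma: float = 0.5   # lognormal sd of latent bin intensities
    zero_inflation: float = 0.02   # fraction of unmappable-like (zero) bins
    level_cv: float = 0.2          # biological spread of per-tumor global levels
    normal_level_cv: float = 0.08
    normal_fraction: float = 0.007  # 5hmC per total cytosine in normal cerebellum
    frag_len: int = 200
    n_genes: int = 300
    promoter_dhmr_frac: float = 0.5
    expr_log2fc: float = 2.0
    expr_dispersion: float = 0.05
    n_background_peaks: int = 50
    peak_len: int = 600
    baseline_hazard: float = 0.05  # per week
    censor_horizon: float = 120.0  # weeks

    def __post_init__(self) -> None:
        if self.n_tumor < 1 or self.n_normal < 1:
            raise ValueError("need at least one sample per group")
        if self.global_level_tumor <= 0:
            raise ValueError("global_level_tumor must be > 0")
        if self.dispersion < 0 or self.expr_dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for name in ("chip_overlap_frac", "expr_link_prob", "zero_inflation", "promoter_dhmr_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.dhmr_log2fc <= 0:
            raise ValueError("dhmr_log2fc must be > 0")


@dataclass
class SimTruth:
    """Everything needed to score the pipeline against the generator."""

    planted_gain: pd.DataFrame     # chrom, start, end, bin_id, log2fc
    planted_loss: pd.DataFrame
    true_global_levels: pd.DataFrame  # sample, group, fraction, fold
    chain_segments: pd.DataFrame   # src/dst intervals (forward coords), strand
    true_de_genes: dict[str, float]
    chip_covered: set[str]         # bin ids of planted DhMRs covered by both factors
    survival_params: dict[str, float]

    def planted_bins(self) -> pd.DataFrame:
        return pd.concat([self.planted_gain, self.planted_loss], ignore_index=True)

    def mappable_fraction(self, regions: pd.DataFrame, min_ratio: float = 0.95) -> float:
        """Fraction of regions whose bases map through the true alignment at
        >= ``min_ratio`` (the quantity a liftover run should reproduce)."""
        ok = 0
        for chrom, start, end in zip(regions["chrom"], regions["start"], regions["end"]):
            seg = self.chain_segments[self.chain_segments.src_chrom == chrom]
            mapped = 0
            for s, e in zip(seg.src_start, seg.src_end):
                mapped += max(0, min(int(e), int(end)) - max(int(s), int(start)))
            if mapped / (int(end) - int(start)) >= min_ratio:
                ok += 1
        return ok / len(regions)


@dataclass
class SimBundle:
    config: SimConfig
    grid: BinGrid
    genes: pd.DataFrame
    counts: pd.DataFrame
    samples: pd.DataFrame
    masspec: pd.DataFrame
    peaks_a: pd.DataFrame
    peaks_b: pd.DataFrame
    expression: pd.DataFrame
    chain_text: str
    survival: pd.DataFrame
    truth: SimTruth

    def write(self, outdir) -> None:
        """Write the whole bundle as plain-text files (TSV/BED/chain/YAML)."""
        import pathlib
        import yaml

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
        self.counts.to_csv(out / "counts.tsv", sep="\t", index_label="bin")
        self.samples.to_csv(out / "samples.tsv", sep="\t", index=False)
        self.masspec.to_csv(out / "masspec.tsv", sep="\t", index=False)
        self.expression.to_csv(out / "expression.tsv", sep="\t", index_label="gene")
        self.survival.to_csv(out / "survival.tsv", sep="\t", index=False)
        for name, df in (("peaks_factorA.bed", self.peaks_a), ("peaks_factorB.bed", self.peaks_b)):
            df.to_csv(out / name, sep="\t", index=False, header=False)
        (out / "shadow.chain").write_text(self.chain_text)
        sizes = pd.DataFrame(
            {"chrom": list(self.grid.chrom_sizes), "size": list(self.grid.chrom_sizes.values())}
        )
        sizes.to_csv(out / "chrom_sizes.tsv", sep="\t", index=False)
        self.truth.planted_gain.to_csv(out / "truth_gain.tsv", sep="\t", index=False)
        self.truth.planted_loss.to_csv(out / "truth_loss.tsv", sep="\t", index=False)
        self.truth.true_global_levels.to_csv(out / "truth_levels.tsv", sep="\t", index=False)
        self.truth.chain_segments.to_csv(out / "truth_chain.tsv", sep="\t", index=False)
        de = pd.DataFrame(
            sorted(self.truth.true_de_genes.items()), columns=["gene", "log2fc"]
        )
        de.to_csv(out / "truth_de_genes.tsv", sep="\t", index=False)
        cfg = asdict(self.config)
        (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _pick_spaced(rng, candidates: np.ndarray, n: int, taken: list[int], min_gap: int, what: str):
    """Pick n bin indices from candidates, each >= min_gap bins from every
    already-taken index and from each other."""
    picked: list[int] = []
    occupied = sorted(taken)
    order = rng.permutation(candidates)
    for b in order:
        if len(picked) == n:
            break
        i = np.searchsorted(occupied, b)
        if i > 0 and b - occupied[i - 1] < min_gap:
            continue
        if i < len(occupied) and occupied[i] - b < min_gap:
            continue
        occupied.insert(i, int(b))
        picked.append(int(b))
    if len(picked) < n:
        raise SizingError(
            f"genome too small: requested {n} {what} but only {len(picked)} "
            f"spaced bins available"
        )
    return picked


def _nb_sample(rng, mean: np.ndarray, alpha: float) -> np.ndarray:
    mean = np.maximum(mean, 0.0)
    if alpha <= 0:
        return rng.poisson(mean)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, alpha * mean)
    return rng.poisson(lam)


def _lognoise(rng, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with unit mean and given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma2 = np.log(1.0 + cv**2)
    return rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size)


# ---------------------------------------------------------------------------
# chain construction
# ---------------------------------------------------------------------------

def _build_chain(config: SimConfig, grid: BinGrid):
    """Shadow-genome chain: per-chrom offsets, two unaligned source gaps and
    one target insertion per chromosome, and the last chromosome mapped to
    the minus strand.  Returns (chain_text, segments DataFrame)."""
    lines: list[str] = []
    segs: list[tuple] = []
    chroms = list(grid.chroms)
    for ci, chrom in enumerate(chroms):
        L = grid.chrom_sizes[chrom]
        dst = "chr" + chr(ord("A") + ci)
        offset = 10_000 * (ci + 1)
        gap_len = max(grid.binsize * 10, L // 40)
        g1 = (L // 3) // grid.binsize * grid.binsize
        g2 = (2 * L // 3) // grid.binsize * grid.binsize
        ins_len = 5_000
        minus = ci == len(chroms) - 1

        # source blocks: [0,g1) [g1+gap,g2) [g2+gap,L), with a dq insertion
        # between the first and second block
        blocks = [
            (0, g1),
            (g1 + gap_len, g2),
            (g2 + gap_len, L),
        ]
        sizes = [e - s for s, e in blocks]
        dts = [blocks[1][0] - blocks[0][1], blocks[2][0] - blocks[1][1]]
        dqs = [ins_len, 0]

        aligned = sum(sizes)
        dst_size = offset + aligned + sum(dqs) + 8_000
        strand = "-" if minus else "+"

        # walk in target strand coordinates (monotone)
        q = offset
        qstart = q
        for k, (s, e) in enumerate(blocks):
            if minus:
                # forward interval of this block on dst
                fs, fe = dst_size - (q + sizes[k]), dst_size - q
            else:
                fs, fe = q, q + sizes[k]
            segs.append((chrom, s, e, dst, fs, fe, strand))
            q += sizes[k]
            if k < len(dts):
                q += dqs[k]
        qend = q

        score = 1000 * (ci + 1)
        header = (
            f"chain {score} {chrom} {L} + 0 {L} {dst} {dst_size} {strand} "
            f"{qstart} {qend} {ci + 1}"
        )
        lines.append(header)
        for k in range(len(sizes)):
            if k < len(dts):
                lines.append(f"{sizes[k]} {dts[k]} {dqs[k]}")
            else:
                lines.append(f"{sizes[k]}")
        lines.append("")
    seg_df = pd.DataFrame(
        segs,
        columns=["src_chrom", "src_start", "src_end", "dst_chrom", "dst_start", "dst_end", "strand"],
    )
    return "\n".join(lines) + "\n", seg_df


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig) -> SimBundle:
    """Generate a complete, internally consistent dataset with truth."""
    rng = np.random.default_rng(config.seed)
    grid = make_bins(config.chrom_sizes, config.binsize)
    B = len(grid)
    iv = grid.intervals()
    bin_ids = np.array(grid.feature_ids())

    # --- genes at bin midpoints -------------------------------------------
    all_bins = np.arange(B)
    gene_bins = _pick_spaced(rng, all_bins, config.n_genes, [], 3, "gene TSS bins")
    genes = []
    for gi, b in enumerate(gene_bins):
        chrom, bs, be = grid.bin_interval(b)
        tss = (bs + be) // 2
        strand = "+" if rng.random() < 0.5 else "-"
        glen = int(rng.integers(5_000, 40_000))
        size = grid.chrom_sizes[chrom]
        if strand == "+":
            tes = min(tss + glen, size - 1)
            lo, hi = tss, tes
        else:
            tes = max(tss - glen, 1)
            lo, hi = tes, tss
        n_ex = int(rng.integers(2, 6))
        cuts = np.sort(rng.choice(np.arange(lo + 1, hi), size=2 * n_ex - 2, replace=False))
        bounds = np.concatenate([[lo], cuts, [hi]])
        ex_s = bounds[0::2][:n_ex]
        ex_e = bounds[1::2][:n_ex]
        genes.append(
            {
                "gene": f"G{gi:04d}",
                "chrom": chrom,
                "strand": strand,
                "tss": int(tss),
                "tes": int(tes),
                "exon_starts": ",".join(str(int(v)) for v in ex_s),
                "exon_ends": ",".join(str(int(v)) for v in ex_e),
                "length": int((ex_e - ex_s).sum()),
            }
        )
    genes_df = pd.DataFrame(genes)

    # --- planted DhMR bins -------------------------------------------------
    pg = int(round(config.promoter_dhmr_frac * config.n_gain))
    pl = int(round(config.promoter_dhmr_frac * config.n_loss))
    if pg + pl > config.n_genes:
        raise SizingError("more promoter DhMRs requested than genes available")
    prom = rng.choice(np.array(gene_bins), size=pg + pl, replace=False) if pg + pl else np.array([], int)
    gain_bins = list(map(int, prom[:pg]))
    loss_bins = list(map(int, prom[pg : pg + pl]))
    remaining = np.setdiff1d(all_bins, np.array(sorted(gene_bins)))
    extra = _pick_spaced(
        rng,
        remaining,
        (config.n_gain - pg) + (config.n_loss - pl),
        gene_bins + gain_bins + loss_bins,
        3,
        "planted DhMR bins",
    )
    gain_bins += extra[: config.n_gain - pg]
    loss_bins += extra[config.n_gain - pg :]
    gain_bins, loss_bins = sorted(gain_bins), sorted(loss_bins)

    effect = np.zeros(B)
    effect[gain_bins] = config.dhmr_log2fc
    effect[loss_bins] = -config.dhmr_log2fc

    def _bins_df(idx, lfc):
        rows = iv.iloc[idx].copy().reset_index(drop=True)
        rows["bin_id"] = bin_ids[idx]
        rows["log2fc"] = lfc
        return rows

    planted_gain = _bins_df(gain_bins, config.dhmr_log2fc)
    planted_loss = _bins_df(loss_bins, -config.dhmr_log2fc)

    # --- latent intensities and counts ------------------------------------
    lam = rng.lognormal(0.0, config.intensity_sigma, B) if config.intensity_sigma > 0 else np.ones(B)
    protected = set(gene_bins) | set(gain_bins) | set(loss_bins)
    if config.zero_inflation > 0:
        free = np.array(sorted(set(range(B)) - protected))
        n_zero = int(round(config.zero_inflation * B))
        if n_zero > 0 and free.size:
            zero_idx = rng.choice(free, size=min(n_zero, free.size), replace=False)
            lam[zero_idx] = 0.0

    tumor_samples = [f"MB{i + 1:02d}" for i in range(config.n_tumor)]
    normal_samples = [f"NC{i + 1:02d}" for i in range(config.n_normal)]
    samples = tumor_samples + normal_samples
    groups = ["tumor"] * config.n_tumor + ["normal"] * config.n_normal

    prof_normal = lam / lam.sum()
    lam_t = lam * np.exp2(effect) * config.global_level_tumor
    prof_tumor = lam_t / lam_t.sum()  # renormalized: global level invisible

    counts = np.empty((B, len(samples)), dtype=np.int64)
    for j, g in enumerate(groups):
        prof = prof_tumor if g == "tumor" else prof_normal
        counts[:, j] = _nb_sample(rng, config.depth * prof, config.dispersion)
    counts_df = pd.DataFrame(counts, index=bin_ids, columns=samples)
    samples_df = pd.DataFrame({"sample": samples, "group": groups})

    # --- per-sample true global levels and the mass-spec table ------------
    fold_t = config.global_level_tumor * _lognoise(rng, config.level_cv, config.n_tumor)
    fold_n = 1.0 * _lognoise(rng, config.normal_level_cv, config.n_normal)
    folds = np.concatenate([fold_t, fold_n])
    fractions = config.normal_fraction * folds
    obs = fractions * _lognoise(rng, config.masspec_cv, len(samples))
    dC = np.full(len(samples), 100.0)
    hmdC = obs / (1.0 - obs) * dC
    masspec = pd.DataFrame(
        {"sample": samples, "group": groups, "amount_5hmdC": hmdC, "amount_dC": dC}
    )
    levels = pd.DataFrame(
        {"sample": samples, "group": groups, "fraction": fractions, "fold": folds}
    )

    # --- ChIP peaks jointly covering a fraction of planted bins -----------
    planted_all = gain_bins + loss_bins
    covered_mask = rng.random(len(planted_all)) < config.chip_overlap_frac
    chip_covered = {bin_ids[b] for b, c in zip(planted_all, covered_mask) if c}

    def _peak_rows(which: int):
        rows = []
        for b, cov in zip(planted_all, covered_mask):
            if not cov:
                continue
            chrom, bs, be = grid.bin_interval(b)
            mid = (bs + be) // 2
            jitter = int(rng.integers(-config.peak_len // 3, config.peak_len // 3 + 1))
            s = max(0, mid + jitter - config.peak_len // 2)
            e = min(grid.chrom_sizes[chrom], s + config.peak_len)
            rows.append((chrom, s, e))
        # background peaks away from planted bins
        bg_candidates = np.setdiff1d(all_bins, np.array(sorted(protected)))
        n_bg = min(config.n_background_peaks, bg_candidates.size)
        for b in rng.choice(bg_candidates, size=n_bg, replace=False):
            chrom, bs, be = grid.bin_interval(int(b))
            s = bs + int(rng.integers(0, max(1, (be - bs) - config.peak_len)))
            e = min(grid.chrom_sizes[chrom], s + config.peak_len)
            rows.append((chrom, s, e))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        df["name"] = [f"peak{which}_{i}" for i in range(len(df))]
        df["score"] = 0
        df["strand"] = "."
        return df

    peaks_a = _peak_rows(1)
    peaks_b = _peak_rows(2)

    # --- expression linked to promoter DhMRs -------------------------------
    bin_to_gene = {b: genes_df.gene.iloc[k] for k, b in enumerate(gene_bins)}
    true_de: dict[str, float] = {}
    for b in gain_bins:
        if b in bin_to_gene and rng.random() < config.expr_link_prob:
            true_de[bin_to_gene[b]] = config.expr_log2fc
    for b in loss_bins:
        if b in bin_to_gene and rng.random() < config.expr_link_prob:
            true_de[bin_to_gene[b]] = -config.expr_log2fc

    base = np.maximum(rng.lognormal(np.log(150.0), 0.8, config.n_genes), 30.0)
    lfc_expr = np.array([true_de.get(g, 0.0) for g in genes_df.gene])
    expr = np.empty((config.n_genes, len(samples)), dtype=np.int64)
    for j, g in enumerate(groups):
        mean = base * np.exp2(lfc_expr) if g == "tumor" else base
        expr[:, j] = _nb_sample(rng, mean, config.expr_dispersion)
    expr_df = pd.DataFrame(expr, index=genes_df.gene.to_numpy(), columns=samples)

    # --- chain -------------------------------------------------------------
    chain_text, chain_segments = _build_chain(config, grid)

    # --- survival -----------------------------------------------------------
    hazard = config.baseline_hazard * np.exp(-config.survival_beta * fold_t)
    t_raw = rng.exponential(1.0 / hazard)
    event = (t_raw <= config.censor_horizon).astype(int)
    time = np.minimum(t_raw, config.censor_horizon)
    med = float(np.median(fold_t))
    surv_group = np.where(fold_t < med, "low_5hmC", "high_5hmC")
    survival = pd.DataFrame(
        {
            "subject": tumor_samples,
            "time": np.round(time, 3),
            "event": event,
            "group": surv_group,
        }
    )

    truth = SimTruth(
        planted_gain=planted_gain,
        planted_loss=planted_loss,
        true_global_levels=levels,
        chain_segments=chain_segments,
        true_de_genes=true_de,
        chip_covered=chip_covered,
        survival_params={"beta": config.survival_beta, "baseline_hazard": config.baseline_hazard},
    )
    return SimBundle(
        config=config,
        grid=grid,
        genes=genes_df,
        counts=counts_df,
        samples=samples_df,
        masspec=masspec,
        peaks_a=peaks_a,
        peaks_b=peaks_b,
        expression=expr_df,
        chain_text=chain_text,
        survival=survival,
        truth=truth,
    )


def emit_fragments(bundle: SimBundle, sample: str) -> pd.DataFrame:
    """BED3 fragments whose midpoint-bin histogram equals the bundle's count
    column for ``sample`` exactly (the counting round-trip oracle)."""
    if sample not in bundle.counts.columns:
        raise KeyError(f"unknown sample {sample!r}")
    j = list(bundle.counts.columns).index(sample)
    rng = np.random.default_rng([bundle.config.seed, 7919, j])
    grid = bundle.grid
    col = bundle.counts[sample].to_numpy()
    half = bundle.config.frag_len // 2
    rows = []
    for b, c in enumerate(col):
        if c == 0:
            continue
        chrom, bs, be = grid.bin_interval(b)
        size = grid.chrom_sizes[chrom]
        mids = rng.integers(bs, be, size=int(c))
        for m in mids:
            k = int(min(half, m, size - m))
            if k == 0:
                rows.append((chrom, int(m), int(m) + 1))
            else:
                rows.append((chrom, int(m) - k, int(m) + k))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
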