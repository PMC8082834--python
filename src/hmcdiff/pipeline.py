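"""End-to-end pipeline orchestration on files.

Runs quantify -> dhmr -> annotate -> crossmap -> expression DE -> integrate
-> survival stats on a directory of plain-text inputs (the layout written by
:meth:`hmcdiff.simulate.SimBundle.write`) and writes every artifact plus a
MANIFEST of sha256 checksums, so a rerun with the same config is verifiably
identical.
"""

from __future__ import annotations

import json
import logging
import pathlib
from dataclasses import dataclass, field

import pandas as pd

from . import annotate as _annotate
from . import crossmap as _crossmap
from . import integrate as _integrate
from . import quantify as _quantify
from . import stats as _stats
from .bins import make_bins
from .dhmr import DhmrParams, run_dhmr
from .io import atomic_write, parse_feature_id, read_chrom_sizes, read_matrix, sha256_file, write_bed

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths and parameters for a full run (all inputs under ``indir``)."""

    indir: str
    outdir: str
    binsize: int = 2000
    reference_group: str = "normal"
    test_group: str = "tumor"
    dhmr_params: DhmrParams = field(default_factory=DhmrParams)
    de_params: DhmrParams = field(
        default_factory=lambda: DhmrParams(lfc_threshold=1.0, fdr_threshold=0.05, calibration="off")
    )
    liftover: _crossmap.LiftoverParams = field(default_factory=_crossmap.LiftoverParams)
    basal_up: int = 5000
    basal_down: int = 1000
    max_ext: int = 1_000_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(pathlib.Path(path).read_text())
        dp = raw.pop("dhmr_params", None)
        ep = raw.pop("de_params", None)
        lp = raw.pop("liftover", None)
        cfg = cls(**raw)
        if dp:
            cfg.dhmr_params = DhmrParams(**dp)
        if ep:
            cfg.de_params = DhmrParams(**ep)
        if lp:
            cfg.liftover = _crossmap.LiftoverParams(**lp)
        return cfg

    def validate(self) -> None:
        indir = pathlib.Path(self.indir)
        required = [
            "counts.tsv", "samples.tsv", "masspec.tsv", "genes.tsv", "chrom_sizes.tsv",
            "expression.tsv", "peaks_factorA.bed", "peaks_factorB.bed", "shadow.chain",
            "survival.tsv",
        ]
        missing = [f for f in required if not (indir / f).exists()]
        if missing:
            raise FileNotFoundError(f"missing inputs in {indir}: {missing}")


def _regions_from_calls(dhmr_table: pd.DataFrame, call: str) -> pd.DataFrame:
    sel = dhmr_table[dhmr_table["call"] == call]
    coords = [parse_feature_id(f) for f in sel.index]
    return pd.DataFrame(coords, columns=["chrom", "start", "end"])


def run_pipeline(config: RunConfig) -> pathlib.Path:
    config.validate()
    indir = pathlib.Path(config.indir)
    out = pathlib.Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline start: indir=%s outdir=%s seed=%d", indir, out, config.seed)
    artifacts: list[pathlib.Path] = []

    def _save_tsv(df: pd.DataFrame, name: str, **kw):
        p = out / name
        with atomic_write(p) as fh:
            df.to_csv(fh, sep="\t", **kw)
        artifacts.append(p)
        return p

    stage = "quantify"
    try:
        records = _quantify.read_masspec(indir / "masspec.tsv")
        qt = _quantify.quantify_table(records, reference_group=config.reference_group)
        _save_tsv(qt, "quantify.tsv")
        folds = {
            s: (1.0 if qt.loc[s, "group"] == config.reference_group
                else float(qt.loc[s, "calibration_factor"]))
            for s in qt.index
        }

        stage = "dhmr"
        counts = read_matrix(indir / "counts.tsv")
        samples = pd.read_csv(indir / "samples.tsv", sep="\t")
        samples["calibration_fold"] = samples["sample"].map(folds)
        dhmr_table = run_dhmr(
            counts, samples, config.dhmr_params,
            test_group=config.test_group, reference_group=config.reference_group,
        )
        _save_tsv(dhmr_table, "dhmr.tsv", index_label="bin")
        gain = _regions_from_calls(dhmr_table, "gain")
        loss = _regions_from_calls(dhmr_table, "loss")
        for name, df in (("gain.bed", gain), ("loss.bed", loss)):
            p = out / name
            write_bed(df, p)
            artifacts.append(p)

        stage = "annotate"
        models = _annotate.read_gene_models(indir / "genes.tsv")
        gm = _annotate.GeneModels(models)
        chrom_sizes = read_chrom_sizes(indir / "chrom_sizes.tsv")
        grid = make_bins(chrom_sizes, config.binsize)
        background = _annotate.classify_regions(grid.intervals(), gm)
        bg_fracs = (background["category"].value_counts() / len(background)).to_dict()
        for name, regions in (("gain", gain), ("loss", loss)):
            if len(regions) == 0:
                continue
            ann = _annotate.classify_regions(regions, gm)
            _save_tsv(ann, f"annotation_{name}.tsv", index=False)
            enr = _annotate.feature_enrichment(
                ann["category"].value_counts().to_dict(), bg_fracs
            )
            _save_tsv(enr, f"enrichment_{name}.tsv", index=False)
        domains = _annotate.regulatory_domains(
            gm, chrom_sizes, config.basal_up, config.basal_down, config.max_ext
        )
        if len(gain):
            genes_near_gain = sorted({g for gl in _annotate.assign_genes(gain, domains) for g in gl})
            _save_tsv(pd.DataFrame({"gene": genes_near_gain}), "genes_near_gain.tsv", index=False)

        stage = "crossmap"
        chains = _crossmap.parse_chain((indir / "shadow.chain").read_text())
        if len(gain):
            rate, report = _crossmap.conservation_rate(gain, chains, config.liftover)
            _save_tsv(report, "liftover_report.tsv", index=False)
            mapped = report[report.status == "mapped"]
            write_bed(
                mapped.rename(columns={"dst_chrom": "chrom"})[["chrom", "dst_start", "dst_end"]]
                .rename(columns={"dst_start": "start", "dst_end": "end"}),
                out / "gain_mapped.bed",
            )
            artifacts.append(out / "gain_mapped.bed")
        else:
            rate = float("nan")

        stage = "expression"
        expr = read_matrix(indir / "expression.tsv")
        de = run_dhmr(
            expr, samples[["sample", "group"]].assign(calibration_fold=1.0),
            config.de_params,
            test_group=config.test_group, reference_group=config.reference_group,
        )
        de.index.name = "gene"
        _save_tsv(de, "de.tsv")

        stage = "integrate"
        from .io import read_bed

        peaks_a = read_bed(indir / "peaks_factorA.bed")
        peaks_b = read_bed(indir / "peaks_factorB.bed")
        dhmr_regions = pd.concat(
            [gain.assign(call="gain"), loss.assign(call="loss")], ignore_index=True
        )
        bound = _integrate.bound_dhmrs(dhmr_regions, peaks_a, peaks_b)
        ann_bound = _annotate.classify_regions(bound, gm) if len(bound) else bound
        prom = _integrate.promoter_subset(bound, ann_bound) if len(bound) else bound
        de_named = de.reset_index()
        targets = _integrate.concordant_genes(prom, de_named) if len(prom) else []
        _save_tsv(_integrate.target_gene_table(targets), "targets.tsv", index=False)

        stage = "survival"
        surv = pd.read_csv(indir / "survival.tsv", sep="\t")
        summary: dict[str, object] = {"n_gain": int(len(gain)), "n_loss": int(len(loss)),
                                      "conservation_rate": rate}
        if surv["group"].nunique() == 2:
            recs = [
                _stats.SurvivalRecord(str(r.subject), float(r.time), int(r.event), str(r.group))
                for r in surv.itertuples()
            ]
            curves, chi2, p = _stats.km_logrank(recs)
            summary["logrank_chi2"] = chi2
            summary["logrank_p"] = p
            summary["median_survival"] = {g: c.median for g, c in curves.items()}
        p_sum = out / "summary.json"
        with atomic_write(p_sum) as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        artifacts.append(p_sum)
    except Exception as err:  # preserve partial outputs, name the stage
        raise PipelineError(stage, err) from err

    manifest = out / "MANIFEST"
    with atomic_write(manifest) as fh:
        for p in sorted(artifacts):
            fh.write(f"{sha256_file(p)}  {p.name}\n")
    logger.info("pipeline done: %d artifacts", len(artifacts))
    return out
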