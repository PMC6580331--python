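"""End-to-end orchestration: ingest or simulate, score, call, compare.

One run takes per-sample annotated variants plus a dose table (or a
simulation parameter set), computes per-gene and combined GVB, assigns
star-allele diplotypes and metabolizer phenotypes, derives DIP, and
produces the full diagnostic comparison between the two predictors at
every configured DIP threshold: 2x2 tables, accuracy metrics, AUROCs
with DeLong confidence intervals, a paired DeLong test, rank-based
group tests, the Youden-optimal GVB cutpoint and McNemar comparisons.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .diagnostics import (
    DEFAULT_DIP_THRESHOLDS,
    PHENOTYPE_ORDINAL,
    ContingencyTable,
    build_contingency,
    compute_dip,
    delong_test,
    group_tests,
    mcnemar_test,
    metrics,
    roc_auc,
    youden_cutpoint,
)
from .gvb import DEFAULT_INDEL_SCORE, DEFAULT_RISK_CUTOFF, DEFAULT_SIFT_CUTOFF, combined_gvb, gene_gvb
from .io import read_dose_table, read_variant_tsv, read_vcf
from .simulate import CohortSimParams, simulate_cohort
from .star import Phenotype, call_diplotype, load_allele_table, worst_phenotype
from .variants import AnnotatedVariant

logger = logging.getLogger(__name__)


class PipelineConfigError(Exception):
    """Invalid run configuration (exit code 2 in the CLI)."""


class PipelineDataError(Exception):
    """Inconsistent or unusable input data (exit code 1 in the CLI)."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input source must be given: file paths (``vcf`` or
    ``variant_tsv``, plus ``dose_table``) or simulation parameters
    (``sim``).
    """

    vcf: Optional[str] = None
    variant_tsv: Optional[str] = None
    dose_table: Optional[str] = None
    allele_table: Optional[str] = None
    sim: Optional[CohortSimParams] = None
    sift_cutoff: float = DEFAULT_SIFT_CUTOFF
    indel_score: float = DEFAULT_INDEL_SCORE
    gvb_risk_cutoff: float = DEFAULT_RISK_CUTOFF
    dip_thresholds: Tuple[float, ...] = DEFAULT_DIP_THRESHOLDS
    primary_dip_threshold: float = 25.0
    uncertain_policy: str = "normal"
    exclude_multigene_carriers: bool = False
    phased: Optional[bool] = None  # None = auto-detect per sample/gene
    seed: int = 0

    def validate(self) -> None:
        has_files = self.vcf is not None or self.variant_tsv is not None
        if has_files == (self.sim is not None):
            raise PipelineConfigError(
                "exactly one of file inputs (vcf/variant_tsv + dose_table) "
                "or simulation parameters must be supplied"
            )
        if has_files and self.dose_table is None:
            raise PipelineConfigError("file input requires a dose_table")
        if self.vcf is not None and self.variant_tsv is not None:
            raise PipelineConfigError("supply either a VCF or a variant TSV, not both")
        if self.primary_dip_threshold not in self.dip_thresholds:
            raise PipelineConfigError(
                f"primary_dip_threshold {self.primary_dip_threshold} is not "
                f"among dip_thresholds {self.dip_thresholds}"
            )

    def echo(self) -> Dict[str, object]:
        """All result-affecting settings, for the report."""
        d = dataclasses.asdict(self)
        if self.sim is not None:
            sim = dataclasses.asdict(self.sim)
            sim["mild_dip_alleles"] = sorted(map(list, self.sim.mild_dip_alleles))
            sim["sift_map"] = {":".join(map(str, k)): v for k, v in self.sim.sift_map.items()}
            sim["dip_model"] = {p.value: list(v) for p, v in self.sim.dip_model.items()}
            sim["novel_variant"] = [self.sim.novel_variant[0], list(self.sim.novel_variant[1])]
            d["sim"] = sim
        return d


@dataclass
class ThresholdResult:
    """Both predictors' diagnostic results at one DIP threshold."""

    threshold: float
    n_events: int
    star_table: ContingencyTable
    gvb_table: ContingencyTable
    star_metrics: Dict[str, Optional[float]]
    gvb_metrics: Dict[str, Optional[float]]
    star_auroc: Optional[Tuple[float, Tuple[float, float]]]
    gvb_auroc: Optional[Tuple[float, Tuple[float, float]]]
    delong_p: Optional[float]


@dataclass
class ReportBundle:
    config: Dict[str, object]
    genes: List[str]
    patients: pd.DataFrame
    thresholds: Dict[float, ThresholdResult]
    group_tests: Dict[str, Dict[str, Tuple[float, float]]]
    mcnemar: Dict[str, float]
    youden_gvb_cutpoint: Optional[float]
    warnings: List[str]


def _load_inputs(config: RunConfig):
    if config.sim is not None:
        sim = dataclasses.replace(config.sim)
        cohort = simulate_cohort(sim)
        return cohort.variants, cohort.dose
    if config.vcf is not None:
        variants = read_vcf(config.vcf)
        strict = True
    else:
        variants = read_variant_tsv(config.variant_tsv)
        strict = False
    dose = read_dose_table(config.dose_table)
    v_samples = set(variants)
    d_samples = set(dose["sample"])
    extra_v = sorted(v_samples - d_samples)
    extra_d = sorted(d_samples - v_samples)
    if extra_v or (strict and extra_d):
        raise PipelineDataError(
            "sample-ID mismatch between variant and dose inputs: "
            f"variants-only={extra_v}, dose-only={extra_d}"
        )
    return variants, dose


def _is_phased(calls: Sequence[AnnotatedVariant]) -> bool:
    from .variants import Zygosity

    return all(v.phase is not None for v in calls if v.zygosity is Zygosity.HET)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute one full run and return the diagnostic report bundle."""
    config.validate()
    defs = load_allele_table(config.allele_table)
    genes = sorted({d.gene for d in defs})
    variants, dose = _load_inputs(config)
    if len(dose) == 0:
        raise PipelineDataError("empty cohort: no samples in the dose table")

    run_warnings: List[str] = []
    rows = []
    for rec in dose.itertuples(index=False):
        sample = rec.sample
        calls = variants.get(sample, [])
        dip = compute_dip(rec.actual_dose, rec.planned_dose)
        row: Dict[str, object] = {"sample": sample, "dip": dip}
        per_gene_gvb: Dict[str, float] = {}
        phenos: List[Phenotype] = []
        for gene in genes:
            gene_calls = [v for v in calls if v.gene == gene]
            gb = gene_gvb(
                gene_calls,
                sift_cutoff=config.sift_cutoff,
                indel_score=config.indel_score,
                gene=gene,
            )
            per_gene_gvb[gene] = gb.gvb
            phased = _is_phased(gene_calls) if config.phased is None else config.phased
            call = call_diplotype(
                gene_calls, defs, phased=phased, uncertain_policy=config.uncertain_policy
            )
            if call.unmatched_variants:
                run_warnings.append(
                    f"{sample}/{gene}: novel haplotype with "
                    f"{len(call.unmatched_variants)} unmatched variant(s)"
                )
            phenos.append(call.phenotype)
            row[f"gvb_{gene}"] = gb.gvb
            row[f"diplotype_{gene}"] = call.diplotype
            row[f"phenotype_{gene}"] = call.phenotype.value
        combined = combined_gvb(per_gene_gvb).combined
        pheno = worst_phenotype(phenos)
        row["combined_gvb"] = combined
        row["phenotype"] = pheno.value
        row["star_high_risk"] = pheno is not Phenotype.NM
        row["gvb_high_risk"] = combined <= config.gvb_risk_cutoff
        rows.append(row)
    patients = pd.DataFrame(rows)

    if config.exclude_multigene_carriers:
        non_nm = sum(
            (patients[f"phenotype_{g}"] != Phenotype.NM.value).astype(int) for g in genes
        )
        dropped = patients.loc[non_nm >= 2, "sample"].tolist()
        if dropped:
            run_warnings.append(f"excluded multi-gene variant carriers: {dropped}")
        patients = patients[non_nm < 2].reset_index(drop=True)
        if len(patients) == 0:
            raise PipelineDataError("no patients left after multi-gene carrier exclusion")

    dips = patients["dip"].to_numpy()
    star_pred = patients["star_high_risk"].to_numpy()
    gvb_pred = patients["gvb_high_risk"].to_numpy()
    star_scores = patients["phenotype"].map(PHENOTYPE_ORDINAL).to_numpy(dtype=float)
    gvb_scores = patients["combined_gvb"].to_numpy(dtype=float)

    thresholds: Dict[float, ThresholdResult] = {}
    for t in config.dip_thresholds:
        events = dips <= t
        star_tab = build_contingency(star_pred.tolist(), events.tolist())
        gvb_tab = build_contingency(gvb_pred.tolist(), events.tolist())
        if events.any() and not events.all():
            star_roc = roc_auc(star_scores, events, higher_score_means_event=True)
            gvb_roc = roc_auc(gvb_scores, events, higher_score_means_event=False)
            dl = delong_test(-gvb_scores, star_scores, events, higher_score_means_event=True)
        else:
            run_warnings.append(f"DIP threshold {t}: single outcome class, ROC skipped")
            star_roc = gvb_roc = None
            dl = None
        thresholds[float(t)] = ThresholdResult(
            threshold=float(t),
            n_events=int(events.sum()),
            star_table=star_tab,
            gvb_table=gvb_tab,
            star_metrics=metrics(star_tab).as_dict(),
            gvb_metrics=metrics(gvb_tab).as_dict(),
            star_auroc=star_roc,
            gvb_auroc=gvb_roc,
            delong_p=dl,
        )

    gt: Dict[str, Dict[str, Tuple[float, float]]] = {}
    for gene in genes:
        groups = patients[f"phenotype_{gene}"]
        if groups.nunique() >= 2:
            res = group_tests(dips, groups)
            gt[f"dip_by_phenotype_{gene}"] = {
                k: (r.statistic, r.pvalue) for k, r in res.items()
            }
    gvb_bins = np.round(gvb_scores, 6)
    if len(np.unique(gvb_bins)) >= 2:
        res = group_tests(dips, gvb_bins)
        gt["dip_by_combined_gvb_bin"] = {k: (r.statistic, r.pvalue) for k, r in res.items()}

    primary_events = dips <= config.primary_dip_threshold
    mc: Dict[str, float] = {}
    if len(patients) > 0:
        star_correct = star_pred == primary_events
        gvb_correct = gvb_pred == primary_events
        mc["overall"] = mcnemar_test(star_correct, gvb_correct)
        if primary_events.any():
            mc["sensitivity"] = mcnemar_test(
                star_correct[primary_events], gvb_correct[primary_events]
            )
        if (~primary_events).any():
            mc["specificity"] = mcnemar_test(
                star_correct[~primary_events], gvb_correct[~primary_events]
            )

    youden = None
    if primary_events.any() and not primary_events.all():
        youden = youden_cutpoint(gvb_scores, primary_events, higher_score_means_event=False)

    return ReportBundle(
        config=config.echo(),
        genes=genes,
        patients=patients,
        thresholds=thresholds,
        group_tests=gt,
        mcnemar=mc,
        youden_gvb_cutpoint=youden,
        warnings=run_warnings,
    )


# ---------------------------------------------------------------------------
# Rendering


def _bundle_dict(bundle: ReportBundle) -> Dict[str, object]:
    def tab(t: ContingencyTable) -> Dict[str, int]:
        return {"tp": t.tp, "fp": t.fp, "fn": t.fn, "tn": t.tn}

    def roc(r):
        if r is None:
            return None
        auc, (lo, hi) = r
        return {"auroc": auc, "ci95": [lo, hi]}

    return {
        "software": {"name": "thioburden", "version": __version__},
        "config": bundle.config,
        "genes": bundle.genes,
        "n_patients": int(len(bundle.patients)),
        "thresholds": {
            str(t): {
                "n_events": res.n_events,
                "star": {"table": tab(res.star_table), "metrics": res.star_metrics},
                "gvb": {"table": tab(res.gvb_table), "metrics": res.gvb_metrics},
                "star_auroc": roc(res.star_auroc),
                "gvb_auroc": roc(res.gvb_auroc),
                "delong_p": res.delong_p,
            }
            for t, res in bundle.thresholds.items()
        },
        "group_tests": {
            name: {k: {"statistic": s, "pvalue": p} for k, (s, p) in tests.items()}
            for name, tests in bundle.group_tests.items()
        },
        "mcnemar": bundle.mcnemar,
        "youden_gvb_cutpoint": bundle.youden_gvb_cutpoint,
        "warnings": bundle.warnings,
    }


def _round2(x: Optional[float]) -> str:
    # round-half-even to 2 decimals for percent reporting
    return "NA" if x is None else format(round(x, 2), ".2f")


def _markdown_table(name: str, res: ThresholdResult) -> str:
    t = res.threshold
    lines = [
        f"### {name} at DIP threshold {t:g}%",
        "",
        f"| Predictor | <= {t:g} | > {t:g} | Total |",
        "|---|---|---|---|",
    ]
    st, gt_ = res.star_table, res.gvb_table
    lines += [
        f"| PM + IM | {st.tp} | {st.fp} | {st.tp + st.fp} |",
        f"| NM | {st.fn} | {st.tn} | {st.fn + st.tn} |",
        f"| GVB <= cutoff | {gt_.tp} | {gt_.fp} | {gt_.tp + gt_.fp} |",
        f"| GVB > cutoff | {gt_.fn} | {gt_.tn} | {gt_.fn + gt_.tn} |",
        "",
        "| Metric | Star | GVB |",
        "|---|---|---|",
    ]
    for m in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
        lines.append(
            f"| {m} (%) | {_round2(res.star_metrics[m])} | {_round2(res.gvb_metrics[m])} |"
        )
    return "\n".join(lines)


def render_report(bundle: ReportBundle, fmt: str, out_dir: str) -> List[str]:
    """Write the report bundle in one of ``tsv``, ``json``, ``markdown``.

    Always also writes the per-patient calls TSV and a run log carrying
    the config echo and software version (timestamps live only there).
    """
    if fmt not in ("tsv", "json", "markdown"):
        raise PipelineConfigError(f"unknown report format {fmt!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: List[str] = []

    patients_path = str(out / "patients.tsv")
    bundle.patients.to_csv(patients_path, sep="\t", index=False)
    written.append(patients_path)

    if fmt == "json":
        path = str(out / "report.json")
        with open(path, "w") as fh:
            json.dump(_bundle_dict(bundle), fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(path)
    elif fmt == "tsv":
        rows = []
        for t, res in bundle.thresholds.items():
            for predictor, tab_, mets in (
                ("star", res.star_table, res.star_metrics),
                ("gvb", res.gvb_table, res.gvb_metrics),
            ):
                rows.append(
                    {
                        "dip_threshold": t,
                        "predictor": predictor,
                        "tp": tab_.tp,
                        "fp": tab_.fp,
                        "fn": tab_.fn,
                        "tn": tab_.tn,
                        **{k: (np.nan if v is None else round(v, 2)) for k, v in mets.items()},
                    }
                )
        path = str(out / "accuracy_tables.tsv")
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        written.append(path)
    else:
        parts = ["# Diagnostic accuracy report", ""]
        for t in sorted(bundle.thresholds):
            parts.append(_markdown_table("Accuracy", bundle.thresholds[t]))
            parts.append("")
        path = str(out / "report.md")
        Path(path).write_text("\n".join(parts))
        written.append(path)

    import datetime

    log_path = str(out / "run_log.txt")
    with open(log_path, "w") as fh:
        fh.write(f"thioburden {__version__}\n")
        fh.write(f"timestamp: {datetime.datetime.now().isoformat()}\n")
        fh.write("config:\n")
        fh.write(json.dumps(bundle.config, indent=2, sort_keys=True, default=str))
        fh.write("\nwarnings:\n")
        for w in bundle.warnings:
            fh.write(f"  - {w}\n")
    written.append(log_path)
    return written
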