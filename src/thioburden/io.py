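"""Reading and writing the pipeline's file formats.

Variant input is either a multi-sample VCF 4.x carrying per-variant
deleteriousness annotations in INFO (keys configurable; defaults SIFT,
CADD, GENE) and per-sample GT fields, or a flat TSV with one row per
sample-variant. Multi-allelic VCF records are split into biallelic
calls before scoring. Dose input is a TSV with planned and actual
last-cycle doses in mg/m2/day.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import pysam

from .gvb import GeneBurden
from .variants import AnnotatedVariant, Zygosity

logger = logging.getLogger(__name__)

#: gene -> (chrom, start, end), 1-based inclusive; used when the VCF has
#: no per-record gene annotation.
GeneRegions = Mapping[str, Tuple[str, int, int]]


def _gene_for_record(
    rec, gene_key: str, regions: Optional[GeneRegions]
) -> Optional[str]:
    gene = rec.info.get(gene_key) if gene_key in rec.info else None
    if isinstance(gene, (tuple, list)):
        gene = gene[0]
    if gene is not None:
        return str(gene)
    if regions:
        for g, (chrom, start, end) in regions.items():
            if rec.chrom == chrom and start <= rec.pos <= end:
                return g
    return None


def _info_scalar(rec, key: str, alt_index: int) -> Optional[float]:
    if key not in rec.info:
        return None
    val = rec.info[key]
    if isinstance(val, (tuple, list)):
        # per-ALT annotation (Number=A) or a single shared value
        val = val[alt_index] if len(val) > alt_index else val[0]
    if val is None:
        return None
    # htslib stores INFO floats as float32; round away the representation
    # noise (SIFT/CADD are printed to far fewer decimals than 6).
    return round(float(val), 6)


def read_vcf(
    path: str,
    sift_key: str = "SIFT",
    cadd_key: str = "CADD",
    gene_key: str = "GENE",
    regions: Optional[GeneRegions] = None,
) -> Dict[str, List[AnnotatedVariant]]:
    """Read per-sample annotated variants from a multi-sample VCF.

    Returns a mapping sample -> list of :class:`AnnotatedVariant` (only
    samples' non-reference calls). Records with no resolvable gene are
    skipped with a warning. Multi-allelic records are split; zygosity is
    evaluated per alternate allele.
    """
    out: Dict[str, List[AnnotatedVariant]] = {}
    with pysam.VariantFile(path) as vf:
        for sample in vf.header.samples:
            out[sample] = []
        for rec in vf:
            gene = _gene_for_record(rec, gene_key, regions)
            if gene is None:
                logger.warning(
                    "no gene for record %s:%d; skipped (set %s INFO or pass regions)",
                    rec.chrom, rec.pos, gene_key,
                )
                continue
            for ai, alt in enumerate(rec.alts or ()):
                sift = _info_scalar(rec, sift_key, ai)
                cadd = _info_scalar(rec, cadd_key, ai)
                allele_idx = ai + 1
                for sample in vf.header.samples:
                    call = rec.samples[sample]
                    gt = call.get("GT")
                    if gt is None or all(a in (None, 0) for a in gt):
                        continue
                    count = sum(1 for a in gt if a == allele_idx)
                    if count == 0:
                        continue
                    zyg = Zygosity.HOM if count >= 2 else Zygosity.HET
                    phase = None
                    if zyg is Zygosity.HET and call.phased:
                        phase = next(i for i, a in enumerate(gt) if a == allele_idx)
                    out[sample].append(
                        AnnotatedVariant.make(
                            gene=gene,
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            zygosity=zyg,
                            sift=sift,
                            cadd=cadd,
                            phase=phase,
                        )
                    )
    return out


TSV_COLUMNS = ["sample", "gene", "chrom", "pos", "ref", "alt", "class", "zygosity", "sift"]


def read_variant_tsv(path: str) -> Dict[str, List[AnnotatedVariant]]:
    """Read per-sample variants from a flat TSV (columns: sample, gene,
    chrom, pos, ref, alt, class, zygosity, sift; sift may be empty)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant TSV {path} lacks columns {missing}")
    out: Dict[str, List[AnnotatedVariant]] = {}
    for row in df.itertuples(index=False):
        sift = None if pd.isna(row.sift) else float(row.sift)
        v = AnnotatedVariant.make(
            gene=row.gene,
            chrom=str(row.chrom),
            pos=int(row.pos),
            ref=row.ref,
            alt=row.alt,
            zygosity=Zygosity(row.zygosity),
            sift=sift,
        )
        out.setdefault(row.sample, []).append(v)
    return out


def read_dose_table(path: str) -> pd.DataFrame:
    """Dose TSV with columns sample, planned_dose, actual_dose (mg/m2/day)."""
    df = pd.read_csv(path, sep="\t")
    required = ["sample", "planned_dose", "actual_dose"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"dose table {path} lacks columns {missing}")
    if (df["planned_dose"] <= 0).any():
        bad = df.loc[df["planned_dose"] <= 0, "sample"].tolist()
        raise ValueError(f"non-positive planned_dose for samples {bad}")
    return df


def burden_frame(burdens: Mapping[str, Mapping[str, GeneBurden]]) -> pd.DataFrame:
    """Per-sample per-gene burden table (sample, gene, n_qualifying, gvb)."""
    rows = [
        {
            "sample": sample,
            "gene": gene,
            "n_qualifying": len(gb.qualifying),
            "gvb": gb.gvb,
        }
        for sample, per_gene in burdens.items()
        for gene, gb in sorted(per_gene.items())
    ]
    return pd.DataFrame(rows, columns=["sample", "gene", "n_qualifying", "gvb"])


def write_tsv(df: pd.DataFrame, path: str) -> str:
    df.to_csv(path, sep="\t", index=False)
    return path
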