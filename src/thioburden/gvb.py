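"""Gene-wise variant burden (GVB) scoring.

GVB summarizes the deleterious coding-variant load of one gene in one
individual as a single number in [0, 1]. Qualifying variants are those
with a SIFT score below a cutoff (default 0.7) plus all InDels, which
SIFT cannot score and which receive a fixed substitute score (default
1e-8, i.e. maximally damaging). Each qualifying variant contributes a
zygosity-adjusted score: the square root of its base score when
heterozygous (one intact copy halves the log-scale burden), the base
score itself when homozygous. The gene's GVB is the geometric mean of
the adjusted scores, or 1 when no variant qualifies (no deleterious
burden). Multi-gene burdens combine per-gene GVBs by geometric mean.

Low GVB means high predicted functional impairment; a combined
NUDT15/TPMT GVB at or below 0.3 flags a patient as high-risk for
thiopurine intolerance.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

from .variants import AnnotatedVariant, Zygosity

logger = logging.getLogger(__name__)

#: Default SIFT cutoff: only variants with SIFT strictly below qualify.
DEFAULT_SIFT_CUTOFF = 0.7
#: Substitute base score for InDels, which SIFT does not score.
DEFAULT_INDEL_SCORE = 1e-8
#: Combined-GVB decision threshold for the high-risk class (inclusive).
DEFAULT_RISK_CUTOFF = 0.3


class RiskClass(str, enum.Enum):
    HIGH = "high_risk"
    LOW = "low_risk"


class MissingSiftError(ValueError):
    """A qualifying SNV carries no SIFT score and cannot be scored."""


@dataclass(frozen=True)
class GeneBurden:
    """Per-gene qualifying set, adjusted scores and the GVB value."""

    gene: str
    qualifying: Tuple[AnnotatedVariant, ...]
    adjusted_scores: Tuple[float, ...]
    gvb: float

    def __post_init__(self) -> None:
        if len(self.qualifying) != len(self.adjusted_scores):
            raise ValueError("adjusted_scores must align with qualifying variants")
        if not 0.0 <= self.gvb <= 1.0:
            raise ValueError(f"GVB {self.gvb} outside [0, 1]")


@dataclass(frozen=True)
class CombinedBurden:
    """Multi-gene burden: geometric mean of per-gene GVB values."""

    genes: Tuple[str, ...]
    per_gene: Mapping[str, float]
    combined: float


def geometric_mean(values: Sequence[float]) -> float:
    """Geometric mean computed in log space, with an explicit zero guard.

    Any exact zero short-circuits to 0.0 instead of propagating -inf
    through the log sum.
    """
    if not values:
        raise ValueError("geometric mean of an empty sequence")
    for v in values:
        if v < 0:
            raise ValueError(f"geometric mean undefined for negative value {v}")
    if any(v == 0.0 for v in values):
        return 0.0
    return math.exp(math.fsum(math.log(v) for v in values) / len(values))


def qualifying_variants(
    variants: Iterable[AnnotatedVariant],
    sift_cutoff: float = DEFAULT_SIFT_CUTOFF,
    *,
    missing_sift: str = "warn",
) -> List[AnnotatedVariant]:
    """Select the qualifying variant set of one gene.

    A variant qualifies if it is an InDel, or if it is an SNV with a SIFT
    score strictly below ``sift_cutoff``. SNVs without a SIFT score are
    unscoreable: with ``missing_sift="warn"`` (default) they are dropped
    with a logged warning, with ``"error"`` a :class:`MissingSiftError`
    is raised. Input order is preserved.
    """
    if missing_sift not in ("warn", "error"):
        raise ValueError(f"missing_sift must be 'warn' or 'error', got {missing_sift!r}")
    out: List[AnnotatedVariant] = []
    for v in variants:
        if v.is_indel:
            out.append(v)
        elif v.sift is None:
            msg = f"SNV {v.chrom}:{v.pos} {v.ref}>{v.alt} in {v.gene} has no SIFT score; excluded"
            if missing_sift == "error":
                raise MissingSiftError(msg)
            logger.warning(msg)
        elif v.sift < sift_cutoff:
            out.append(v)
    return out


def adjusted_score(
    variant: AnnotatedVariant,
    indel_score: float = DEFAULT_INDEL_SCORE,
    *,
    zygosity_adjust_indels: bool = True,
) -> float:
    """Zygosity-adjusted deleteriousness of one qualifying variant.

    The base score is ``indel_score`` for insertions/deletions and the
    SIFT score otherwise. Heterozygotes contribute the square root of the
    base score, homozygotes the base score itself. By default the
    zygosity adjustment also applies to InDels (a heterozygous InDel
    scores ``indel_score ** 0.5``); set ``zygosity_adjust_indels=False``
    to pin InDels at the substitute score regardless of zygosity.
    """
    if variant.is_indel:
        base = indel_score
        if not zygosity_adjust_indels:
            return base
    else:
        if variant.sift is None:
            raise MissingSiftError(
                f"cannot score SNV {variant.chrom}:{variant.pos} without SIFT"
            )
        base = variant.sift
    if variant.zygosity is Zygosity.HET:
        return math.sqrt(base)
    return base


def gene_gvb(
    variants: Iterable[AnnotatedVariant],
    sift_cutoff: float = DEFAULT_SIFT_CUTOFF,
    indel_score: float = DEFAULT_INDEL_SCORE,
    *,
    missing_sift: str = "warn",
    zygosity_adjust_indels: bool = True,
    gene: str | None = None,
) -> GeneBurden:
    """GVB of one gene for one individual.

    Returns 1 when no variant qualifies. An adjusted score of exactly 0
    (SIFT 0 homozygote) makes the GVB 0, with a logged warning.
    """
    variants = list(variants)
    genes = {v.gene for v in variants}
    if len(genes) > 1:
        raise ValueError(f"gene_gvb expects variants of one gene, got {sorted(genes)}")
    if gene is None:
        gene = genes.pop() if genes else ""
    qual = qualifying_variants(variants, sift_cutoff, missing_sift=missing_sift)
    if not qual:
        return GeneBurden(gene=gene, qualifying=(), adjusted_scores=(), gvb=1.0)
    scores = tuple(
        adjusted_score(v, indel_score, zygosity_adjust_indels=zygosity_adjust_indels)
        for v in qual
    )
    if any(s == 0.0 for s in scores):
        logger.warning("adjusted score of exactly 0 in %s; GVB set to 0", gene)
    return GeneBurden(gene=gene, qualifying=tuple(qual), adjusted_scores=scores, gvb=geometric_mean(scores))


def combined_gvb(per_gene: Mapping[str, float]) -> CombinedBurden:
    """Geometric mean of per-gene GVB values (k >= 1 genes)."""
    if not per_gene:
        raise ValueError("combined_gvb requires at least one gene")
    for g, v in per_gene.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"GVB for {g} is {v}, outside [0, 1]")
    genes = tuple(sorted(per_gene))
    return CombinedBurden(
        genes=genes,
        per_gene=dict(per_gene),
        combined=geometric_mean([per_gene[g] for g in genes]),
    )


def classify_risk(gvb: float, cutoff: float = DEFAULT_RISK_CUTOFF) -> RiskClass:
    """High-risk iff GVB <= cutoff (inclusive boundary)."""
    if not 0.0 <= gvb <= 1.0:
        raise ValueError(f"GVB {gvb} outside [0, 1]")
    return RiskClass.HIGH if gvb <= cutoff else RiskClass.LOW
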