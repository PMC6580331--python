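"""Star-allele diplotype assignment and metabolizer phenotype translation.

A star allele is a named haplotype of a pharmacogene defined by an exact
set of variants; the reference allele (*1) is defined by the empty set.
Given one sample's genotype for one gene, the matcher assigns the pair
of star alleles (the diplotype) and translates their function categories
into a metabolizer phenotype (PM / IM / NM).

Haplotype inference is deterministic: phased genotypes are matched
haplotype by haplotype; unphased genotypes are resolved by exhaustively
partitioning the heterozygous sites over the two haplotypes (homozygous
sites sit on both) and keeping the partition that explains the genotype
best. With the small defining-variant sets of NUDT15 and TPMT alleles
this search is exact. Haplotypes matching no defined allele are labeled
``"novel"``; by default they count as normal function for phenotype
translation, mirroring how star-allele nomenclature handles variants it
does not know about.
"""

from __future__ import annotations

import enum
import itertools
import logging
import math
import re
from dataclasses import dataclass
from importlib import resources
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from .variants import AnnotatedVariant, VariantKey, Zygosity, normalize_variant

logger = logging.getLogger(__name__)

NOVEL_LABEL = "novel"

#: Cap on heterozygous defining sites in the unphased 2^h partition search.
MAX_UNPHASED_HET_SITES = 12


class AlleleFunction(str, enum.Enum):
    NORMAL = "normal"
    DECREASED = "decreased"
    NO_FUNCTION = "no_function"
    UNCERTAIN = "uncertain"


class Phenotype(str, enum.Enum):
    PM = "PM"
    IM = "IM"
    NM = "NM"
    INDETERMINATE = "indeterminate"


#: Activity contributed by one allele; a diplotype's summed activity maps
#: to the phenotype (0 -> PM, 2 -> NM, anything between -> IM).
_ACTIVITY = {
    AlleleFunction.NORMAL: 1.0,
    AlleleFunction.DECREASED: 0.5,
    AlleleFunction.NO_FUNCTION: 0.0,
}

#: Ordinal risk ranking used when combining phenotypes across genes.
PHENOTYPE_RISK_ORDER = {Phenotype.PM: 2, Phenotype.IM: 1, Phenotype.NM: 0, Phenotype.INDETERMINATE: 0}


@dataclass(frozen=True)
class AlleleDefinition:
    gene: str
    name: str
    defining_variants: FrozenSet[VariantKey]
    function: AlleleFunction


@dataclass(frozen=True)
class DiplotypeCall:
    gene: str
    allele1: str
    allele2: str
    phenotype: Phenotype
    unmatched_variants: FrozenSet[VariantKey]

    @property
    def diplotype(self) -> str:
        return f"{self.allele1}/{self.allele2}"


def star_sort_key(name: str) -> Tuple[float, str]:
    """Canonical ordering of star-allele labels: *1 < *1S < *2 < ... < novel."""
    m = re.match(r"\*(\d+)(.*)", name)
    if m:
        return (int(m.group(1)), m.group(2))
    return (math.inf, name)


def _parse_variant_token(token: str) -> VariantKey:
    parts = token.strip().split(":")
    if len(parts) != 4:
        raise ValueError(f"malformed variant token {token!r} (want chrom:pos:ref:alt)")
    chrom, pos, ref, alt = parts
    if not pos.isdigit():
        raise ValueError(f"malformed position in variant token {token!r}")
    return normalize_variant(chrom, int(pos), ref, alt)


def default_allele_table_path() -> str:
    """Path to the shipped NUDT15/TPMT allele-definition table."""
    return str(resources.files("thioburden").joinpath("data/allele_definitions.tsv"))


def load_allele_table(path: Optional[str] = None) -> List[AlleleDefinition]:
    """Load and validate an allele-definition TSV.

    Expected columns: gene, allele, variants (semicolon-separated
    ``chrom:pos:ref:alt`` tokens, ``.`` for the reference allele),
    function. When ``path`` is None the shipped default table (NUDT15
    *1-*6, TPMT *1/*1S/*3C/*6) is loaded.
    """
    if path is None:
        path = default_allele_table_path()
    defs: List[AlleleDefinition] = []
    seen_names: Set[Tuple[str, str]] = set()
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"allele table {path} is empty")
        cols = header.rstrip("\n").split("\t")
        required = ["gene", "allele", "variants", "function"]
        if cols[: len(required)] != required:
            raise ValueError(f"allele table header must start with {required}, got {cols}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            gene, name, var_field, func = fields[:4]
            if (gene, name) in seen_names:
                raise ValueError(f"{path}:{lineno}: duplicate allele {gene} {name}")
            seen_names.add((gene, name))
            try:
                function = AlleleFunction(func)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: unknown function label {func!r}") from None
            if var_field.strip() in (".", ""):
                variants: FrozenSet[VariantKey] = frozenset()
            else:
                variants = frozenset(_parse_variant_token(t) for t in var_field.split(";"))
            defs.append(AlleleDefinition(gene=gene, name=name, defining_variants=variants, function=function))
    if not defs:
        raise ValueError(f"allele table {path} contains no definitions")
    # within a gene, defining-variant sets must be unique
    by_gene: Dict[str, Dict[FrozenSet[VariantKey], str]] = {}
    for d in defs:
        sets = by_gene.setdefault(d.gene, {})
        if d.defining_variants in sets:
            raise ValueError(
                f"alleles {sets[d.defining_variants]} and {d.name} of {d.gene} "
                "share an identical defining-variant set"
            )
        sets[d.defining_variants] = d.name
    return defs


def _reference_allele(defs: Sequence[AlleleDefinition]) -> str:
    for d in defs:
        if not d.defining_variants:
            return d.name
    return "*1"


def match_haplotype(
    hap_variants: Iterable[VariantKey], defs: Sequence[AlleleDefinition]
) -> str:
    """Match one haplotype's variant set against the definitions.

    Exact set equality after normalization; the empty set matches the
    reference allele; anything else is ``"novel"``.
    """
    hap = frozenset(normalize_variant(*k) for k in hap_variants)
    if not hap:
        return _reference_allele(defs)
    for d in defs:
        if d.defining_variants == hap:
            return d.name
    return NOVEL_LABEL


def translate_phenotype(
    func1: AlleleFunction,
    func2: AlleleFunction,
    *,
    uncertain_policy: str = "normal",
) -> Phenotype:
    """Translate two allele function categories into a metabolizer phenotype.

    no_function + no_function -> PM; normal + normal -> NM; any mixture
    with partial activity -> IM. Uncertain-function alleles count as
    normal by default (``uncertain_policy="normal"``); with
    ``"indeterminate"`` any uncertain allele yields an indeterminate
    phenotype.
    """
    if uncertain_policy not in ("normal", "indeterminate"):
        raise ValueError(f"unknown uncertain_policy {uncertain_policy!r}")
    funcs = (func1, func2)
    if AlleleFunction.UNCERTAIN in funcs:
        if uncertain_policy == "indeterminate":
            return Phenotype.INDETERMINATE
        funcs = tuple(
            AlleleFunction.NORMAL if f is AlleleFunction.UNCERTAIN else f for f in funcs
        )
    activity = _ACTIVITY[funcs[0]] + _ACTIVITY[funcs[1]]
    if activity == 0.0:
        return Phenotype.PM
    if activity >= 2.0:
        return Phenotype.NM
    return Phenotype.IM


def _allele_function(name: str, defs: Sequence[AlleleDefinition]) -> AlleleFunction:
    if name == NOVEL_LABEL:
        return AlleleFunction.UNCERTAIN
    for d in defs:
        if d.name == name:
            return d.function
    raise KeyError(f"allele {name} not in definition table")


def call_diplotype(
    genotype: Sequence[AnnotatedVariant],
    defs: Sequence[AlleleDefinition],
    phased: bool = False,
    *,
    uncertain_policy: str = "normal",
) -> DiplotypeCall:
    """Assign a star-allele diplotype for one sample and one gene.

    Phased genotypes (every het call carrying a ``phase``) are matched
    haplotype by haplotype. Unphased genotypes are resolved by trying
    every assignment of het sites to the two haplotypes and keeping the
    partition that (1) maximizes the number of non-novel alleles, then
    (2) maximizes the number of variants explained by defined alleles,
    then (3) has the lowest star-number pair. Variants on haplotypes
    that match no defined allele are reported in ``unmatched_variants``.
    """
    genes = {v.gene for v in genotype}
    if len(genes) > 1:
        raise ValueError(f"call_diplotype expects one gene, got {sorted(genes)}")
    gene = genes.pop() if genes else (defs[0].gene if defs else "")
    gene_defs = [d for d in defs if d.gene == gene] or list(defs)

    # collapse to unique normalized sites, checking zygosity consistency
    zyg: Dict[VariantKey, Zygosity] = {}
    phase_of: Dict[VariantKey, Optional[int]] = {}
    for v in genotype:
        k = v.normalized_key
        if k in zyg and zyg[k] != v.zygosity:
            raise ValueError(
                f"site {k} reported both {zyg[k].value} and {v.zygosity.value}"
            )
        zyg[k] = v.zygosity
        phase_of[k] = v.phase

    hom = [k for k, z in zyg.items() if z is Zygosity.HOM]
    het = sorted((k for k, z in zyg.items() if z is Zygosity.HET), key=lambda k: (k[0], k[1], k[2], k[3]))

    if phased:
        haps: Tuple[Set[VariantKey], Set[VariantKey]] = (set(hom), set(hom))
        for k in het:
            p = phase_of[k]
            if p is None:
                raise ValueError(f"phased call requested but site {k} carries no phase")
            haps[p].add(k)
        partitions = [(frozenset(haps[0]), frozenset(haps[1]))]
    else:
        if len(het) > MAX_UNPHASED_HET_SITES:
            raise ValueError(
                f"{len(het)} heterozygous sites exceed the unphased search cap "
                f"({MAX_UNPHASED_HET_SITES})"
            )
        partitions = []
        for mask in range(2 ** len(het)):
            h0 = set(hom)
            h1 = set(hom)
            for i, k in enumerate(het):
                (h0 if mask >> i & 1 else h1).add(k)
            partitions.append((frozenset(h0), frozenset(h1)))

    best: Optional[Tuple[Tuple[float, float, Tuple, Tuple], str, str, FrozenSet[VariantKey]]] = None
    for h0, h1 in partitions:
        a0 = match_haplotype(h0, gene_defs)
        a1 = match_haplotype(h1, gene_defs)
        n_known = (a0 != NOVEL_LABEL) + (a1 != NOVEL_LABEL)
        explained = (len(h0) if a0 != NOVEL_LABEL else 0) + (len(h1) if a1 != NOVEL_LABEL else 0)
        unmatched = (h0 if a0 == NOVEL_LABEL else frozenset()) | (h1 if a1 == NOVEL_LABEL else frozenset())
        pair = tuple(sorted((a0, a1), key=star_sort_key))
        rank = (-n_known, -explained, star_sort_key(pair[0]), star_sort_key(pair[1]))
        if best is None or rank < best[0]:
            best = (rank, pair[0], pair[1], frozenset(unmatched))

    assert best is not None  # at least one partition always exists
    _, allele1, allele2, unmatched = best
    phenotype = translate_phenotype(
        _allele_function(allele1, gene_defs),
        _allele_function(allele2, gene_defs),
        uncertain_policy=uncertain_policy,
    )
    if unmatched:
        logger.info("%s: %d variant(s) on novel haplotype(s): %s", gene, len(unmatched), sorted(unmatched))
    return DiplotypeCall(
        gene=gene,
        allele1=allele1,
        allele2=allele2,
        phenotype=phenotype,
        unmatched_variants=unmatched,
    )


def worst_phenotype(phenotypes: Iterable[Phenotype]) -> Phenotype:
    """Combine per-gene phenotypes into the highest-risk one (PM > IM > NM)."""
    phenos = list(phenotypes)
    if not phenos:
        raise ValueError("no phenotypes to combine")
    return max(phenos, key=lambda p: PHENOTYPE_RISK_ORDER[p])
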