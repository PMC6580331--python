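"""Domain types for annotated variant calls.

A variant here is one already-called, already-annotated alternate allele
observed in one sample within one pharmacogene: the pipeline consumes
annotated calls and never touches reads or raw genotyping.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Tuple

#: (chrom, pos, ref, alt) — the minimal identity of a biallelic variant.
VariantKey = Tuple[str, int, str, str]


class VariantClass(str, enum.Enum):
    SNV = "SNV"
    INSERTION = "insertion"
    DELETION = "deletion"


class Zygosity(str, enum.Enum):
    HET = "heterozygote"
    HOM = "homozygote"


def classify_alleles(ref: str, alt: str) -> VariantClass:
    """Infer the variant class from ref/alt allele lengths.

    Equal-length multi-base substitutions (MNVs) are treated as SNV-like:
    they require a deleteriousness score rather than the InDel substitute.
    """
    if len(alt) > len(ref):
        return VariantClass.INSERTION
    if len(alt) < len(ref):
        return VariantClass.DELETION
    return VariantClass.SNV


def normalize_variant(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Left-align and minimalize a ref/alt pair (VCF-style normalization).

    Trims the shared suffix, then the shared prefix (advancing ``pos``),
    keeping at least one base on each side. Needed so that differently
    padded representations of the same InDel compare equal during
    star-allele matching.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return (str(chrom), int(pos), ref, alt)


@dataclass(frozen=True)
class AnnotatedVariant:
    """One called alternate allele with its annotations.

    Parameters
    ----------
    gene : str
        Gene symbol the call is assigned to (e.g. ``"NUDT15"``).
    chrom, pos, ref, alt :
        VCF-style 1-based coordinates and alleles.
    variant_class : VariantClass
        SNV, insertion or deletion; must be consistent with ref/alt.
    zygosity : Zygosity
        Heterozygote or (alternate-)homozygote for this allele.
    sift : float, optional
        SIFT deleteriousness in [0, 1]; lower is more deleterious.
        SIFT does not score InDels, so it is typically absent for them.
    cadd : float, optional
        CADD score; carried as metadata, unused by default scoring.
    phase : int, optional
        For phased heterozygous calls, the haplotype index (0 or 1)
        carrying the alternate allele. None means unphased.
    """

    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: VariantClass
    zygosity: Zygosity
    sift: Optional[float] = None
    cadd: Optional[float] = None
    phase: Optional[int] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.sift is not None and not 0.0 <= self.sift <= 1.0:
            raise ValueError(f"SIFT score {self.sift} outside [0, 1]")
        expected = classify_alleles(self.ref, self.alt)
        if self.variant_class != expected:
            raise ValueError(
                f"variant_class {self.variant_class.value} inconsistent with "
                f"alleles {self.ref}>{self.alt} (expected {expected.value})"
            )
        if self.phase is not None and self.phase not in (0, 1):
            raise ValueError(f"phase must be 0 or 1, got {self.phase}")

    @classmethod
    def make(
        cls,
        gene: str,
        chrom: str,
        pos: int,
        ref: str,
        alt: str,
        zygosity: Zygosity,
        sift: Optional[float] = None,
        cadd: Optional[float] = None,
        phase: Optional[int] = None,
    ) -> "AnnotatedVariant":
        """Build a variant, inferring the class from the alleles."""
        return cls(
            gene=gene,
            chrom=str(chrom),
            pos=pos,
            ref=ref,
            alt=alt,
            variant_class=classify_alleles(ref, alt),
            zygosity=zygosity,
            sift=sift,
            cadd=cadd,
            phase=phase,
        )

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def normalized_key(self) -> VariantKey:
        return normalize_variant(self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return self.variant_class in (VariantClass.INSERTION, VariantClass.DELETION)
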