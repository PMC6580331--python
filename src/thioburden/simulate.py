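"""Synthetic pharmacogenomic cohort generator.

Generates cohorts with the statistical structure the downstream analysis
assumes: per gene, each patient draws two star alleles independently
from configured allele frequencies (Hardy-Weinberg pairing), the
alleles' defining variants are materialized as phased, SIFT-annotated
calls, the diplotype is translated to a metabolizer phenotype, and the
dose-intensity-percent (DIP) endpoint is drawn from a phenotype-specific
truncated normal. Actual dose is backed out of the DIP against a fixed
planned dose, so the dose table round-trips exactly.

Two deliberate discordance mechanisms give the burden score something
the star method cannot see, mirroring reported clinical behaviour of
this gene pair:

* ``mild_dip_alleles`` (default: NUDT15 *4) are alleles counted as
  no-function by the phenotype tables but whose carriers tolerate
  normal doses; their carriers draw DIP from the group obtained by
  treating the allele as normal function.
* with probability ``novel_variant_rate`` a patient receives a novel
  deleterious variant (a heterozygous in-frame deletion) that no star
  allele defines; the carrier's DIP group is downgraded to at least IM.

On top of the group model, DIP is rank-correlated with the combined
variant burden *within* each DIP group (``burden_dip_correlation``),
reflecting that tolerated dose falls gradually with deleterious load
rather than stepping only at the three phenotype levels. The
correlation is induced through a Gaussian copula on within-group
normal scores, so each group's configured truncated-normal marginal
(in particular its mean) is preserved.

The truth table records both the star-based phenotype and the
``dip_group`` the DIP sampler actually conditioned on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .gvb import combined_gvb, gene_gvb
from .star import (
    AlleleDefinition,
    AlleleFunction,
    Phenotype,
    load_allele_table,
    translate_phenotype,
    worst_phenotype,
)
from .variants import AnnotatedVariant, VariantKey, Zygosity

#: Table-derived allele counts over 488 chromosomes (244 diploid patients).
_ALLELE_COUNTS = {
    "NUDT15": {"*1": 438, "*2": 6, "*3": 35, "*4": 4, "*5": 4, "*6": 1},
    "TPMT": {"*1": 127, "*1S": 354, "*3C": 6, "*6": 1},
}

DEFAULT_ALLELE_FREQS: Dict[str, Dict[str, float]] = {
    gene: {a: c / 488.0 for a, c in counts.items()} for gene, counts in _ALLELE_COUNTS.items()
}

#: SIFT score per defining variant; None marks an InDel (no SIFT score).
#: Chosen so severe no-function alleles land at combined GVB <= 0.3 when
#: heterozygous, the mild NUDT15 *4 lands above it, and the decreased
#: TPMT *6 is invisible to the burden score (SIFT above the 0.7 cutoff).
DEFAULT_SIFT_MAP: Dict[VariantKey, Optional[float]] = {
    ("13", 48611918, "G", "GGAGTC"): None,   # NUDT15 *2/*6 in-frame insertion
    ("13", 48619855, "C", "T"): 0.0064,      # NUDT15 *2/*3 p.Arg139Cys
    ("13", 48619856, "G", "A"): 0.35,        # NUDT15 *4 p.Arg139His (mild)
    ("13", 48611934, "G", "A"): 0.0025,      # NUDT15 *5 p.Val18Ile (distinct from *3)
    ("6", 18139228, "A", "G"): 1.0,          # TPMT *1S synonymous tag
    ("6", 18130918, "T", "C"): 0.0064,       # TPMT *3C p.Tyr240Cys
    ("6", 18139243, "T", "A"): 0.8,          # TPMT *6 p.Tyr180Phe (non-qualifying)
}

#: Per-phenotype DIP model (mean, sd) in percent.
DEFAULT_DIP_MODEL: Dict[Phenotype, Tuple[float, float]] = {
    Phenotype.NM: (67.608, 28.2),
    Phenotype.IM: (56.452, 28.2),
    Phenotype.PM: (5.712, 5.0),
}

#: Novel deleterious variant injected at ``novel_variant_rate``: an
#: in-frame NUDT15 deletion on no defined allele.
DEFAULT_NOVEL_VARIANT: Tuple[str, VariantKey] = ("NUDT15", ("13", 48613000, "CATGTT", "C"))

_CONTIG_LENGTHS = {"13": 114364328, "6": 170805979}


@dataclass
class CohortSimParams:
    """Parameters of one simulated cohort.

    ``allele_freqs`` must sum to 1 per gene (to 1e-9). ``sift_map``
    assigns each defining variant its SIFT score (None = InDel).
    ``dip_model`` maps phenotype to (mean, sd) percent; draws are
    truncated to ``dip_bounds`` (DIP above 100 occurs when last-cycle
    doses exceed protocol). ``novel_variant_rate`` is the per-patient
    probability of carrying the novel deleterious variant.
    """

    n_patients: int = 244
    allele_freqs: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {g: dict(f) for g, f in DEFAULT_ALLELE_FREQS.items()}
    )
    sift_map: Dict[VariantKey, Optional[float]] = field(
        default_factory=lambda: dict(DEFAULT_SIFT_MAP)
    )
    dip_model: Dict[Phenotype, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DIP_MODEL)
    )
    dip_bounds: Tuple[float, float] = (0.0, 150.0)
    planned_dose: float = 50.0
    novel_variant_rate: float = 1.0 / 244.0
    mild_dip_alleles: FrozenSet[Tuple[str, str]] = frozenset({("NUDT15", "*4")})
    novel_variant: Tuple[str, VariantKey] = DEFAULT_NOVEL_VARIANT
    burden_dip_correlation: float = 0.3
    uncertain_policy: str = "normal"
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for gene, freqs in self.allele_freqs.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{gene} allele frequencies sum to {total}, not 1")
            if any(f < 0 for f in freqs.values()):
                raise ValueError(f"{gene} has a negative allele frequency")
        for pheno, (mean, sd) in self.dip_model.items():
            if sd <= 0:
                raise ValueError(f"DIP sd for {pheno} must be > 0")
        if not 0.0 <= self.novel_variant_rate <= 1.0:
            raise ValueError("novel_variant_rate must be in [0, 1]")
        if not 0.0 <= self.burden_dip_correlation < 1.0:
            raise ValueError("burden_dip_correlation must be in [0, 1)")
        if self.dip_bounds[0] >= self.dip_bounds[1]:
            raise ValueError("dip_bounds must be (low, high) with low < high")


@dataclass
class SimulatedCohort:
    """One simulated cohort: per-sample variants, dose table, truth table."""

    params: CohortSimParams
    variants: Dict[str, List[AnnotatedVariant]]
    dose: pd.DataFrame
    truth: pd.DataFrame

    @property
    def samples(self) -> List[str]:
        return list(self.truth["sample"])


def _defining_variants(defs: Sequence[AlleleDefinition], gene: str, name: str) -> FrozenSet[VariantKey]:
    for d in defs:
        if d.gene == gene and d.name == name:
            return d.defining_variants
    raise KeyError(f"allele {name} of {gene} not in the definition table")


def _allele_function(defs: Sequence[AlleleDefinition], gene: str, name: str) -> AlleleFunction:
    for d in defs:
        if d.gene == gene and d.name == name:
            return d.function
    raise KeyError(f"allele {name} of {gene} not in the definition table")


def _materialize(
    gene: str,
    haplotypes: Tuple[FrozenSet[VariantKey], FrozenSet[VariantKey]],
    sift_map: Mapping[VariantKey, Optional[float]],
) -> List[AnnotatedVariant]:
    """Turn two haplotype variant sets into phased annotated calls."""
    carriers: Dict[VariantKey, Set[int]] = {}
    for h, keys in enumerate(haplotypes):
        for k in keys:
            carriers.setdefault(k, set()).add(h)
    out = []
    for k in sorted(carriers):
        chrom, pos, ref, alt = k
        haps = carriers[k]
        zyg = Zygosity.HOM if len(haps) == 2 else Zygosity.HET
        phase = next(iter(haps)) if zyg is Zygosity.HET else None
        out.append(
            AnnotatedVariant.make(
                gene=gene,
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                zygosity=zyg,
                sift=sift_map.get(k),
                phase=phase,
            )
        )
    return out


def _calibrated_loc(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Location of a [lo, hi]-truncated normal whose mean equals the target.

    Truncation pulls the realized mean away from the location parameter
    (strongly for the PM group, whose location sits close to the lower
    bound); solving for the location keeps the configured group means
    exactly recoverable from simulated cohorts.
    """
    if not lo < target_mean < hi:
        raise ValueError(f"target mean {target_mean} outside bounds ({lo}, {hi})")
    from scipy.optimize import brentq

    def realized(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - target_mean

    return float(brentq(realized, target_mean - 20 * sd, target_mean + 20 * sd, xtol=1e-10))


def simulate_cohort(
    params: CohortSimParams,
    defs: Optional[Sequence[AlleleDefinition]] = None,
) -> SimulatedCohort:
    """Draw one cohort under Hardy-Weinberg allele pairing.

    Fully reproducible from ``params.seed``: every random draw comes
    from one :class:`numpy.random.Generator`.
    """
    params.validate()
    if defs is None:
        defs = load_allele_table()
    rng = np.random.default_rng(params.seed)
    genes = sorted(params.allele_freqs)

    variants: Dict[str, List[AnnotatedVariant]] = {}
    dose_rows = []
    truth_rows = []
    novel_gene, novel_key = params.novel_variant
    lo, hi = params.dip_bounds

    # pass 1: draw alleles, materialize variants, derive phenotype groups
    for i in range(params.n_patients):
        sample = f"S{i + 1:04d}"
        calls: List[AnnotatedVariant] = []
        pheno_per_gene: Dict[str, Phenotype] = {}
        dip_pheno_per_gene: Dict[str, Phenotype] = {}
        diplo_per_gene: Dict[str, str] = {}
        hap_sets: Dict[str, List[Set[VariantKey]]] = {}

        for gene in genes:
            freqs = params.allele_freqs[gene]
            names = sorted(freqs)
            probs = np.array([freqs[n] for n in names])
            probs = probs / probs.sum()
            a0, a1 = (names[j] for j in rng.choice(len(names), size=2, p=probs))
            h0 = set(_defining_variants(defs, gene, a0))
            h1 = set(_defining_variants(defs, gene, a1))
            hap_sets[gene] = [h0, h1]
            f0, f1 = _allele_function(defs, gene, a0), _allele_function(defs, gene, a1)
            pheno_per_gene[gene] = translate_phenotype(f0, f1, uncertain_policy=params.uncertain_policy)
            # DIP group treats mild alleles as normal function
            ef0 = AlleleFunction.NORMAL if (gene, a0) in params.mild_dip_alleles else f0
            ef1 = AlleleFunction.NORMAL if (gene, a1) in params.mild_dip_alleles else f1
            dip_pheno_per_gene[gene] = translate_phenotype(ef0, ef1, uncertain_policy=params.uncertain_policy)
            diplo_per_gene[gene] = "/".join(sorted((a0, a1)))

        novel_carrier = bool(rng.random() < params.novel_variant_rate)
        if novel_carrier:
            hap = int(rng.integers(0, 2))
            hap_sets[novel_gene][hap].add(novel_key)

        for gene in genes:
            h0, h1 = hap_sets[gene]
            calls.extend(_materialize(gene, (frozenset(h0), frozenset(h1)), params.sift_map))

        phenotype = worst_phenotype(pheno_per_gene.values())
        dip_group = worst_phenotype(dip_pheno_per_gene.values())
        if novel_carrier and dip_group is Phenotype.NM:
            dip_group = Phenotype.IM

        variants[sample] = calls
        per_gene_scores = {
            gene: gene_gvb([v for v in calls if v.gene == gene], gene=gene).gvb
            for gene in genes
        }
        truth_row = {"sample": sample}
        for gene in genes:
            truth_row[f"{gene}_diplotype"] = diplo_per_gene[gene]
            truth_row[f"{gene}_phenotype"] = pheno_per_gene[gene].value
        truth_row.update(
            {
                "phenotype": phenotype.value,
                "dip_group": dip_group.value,
                "novel_carrier": novel_carrier,
                "combined_gvb": combined_gvb(per_gene_scores).combined,
            }
        )
        truth_rows.append(truth_row)

    # pass 2: draw DIP with a within-group burden rank correlation.
    # Each patient's uniform comes from a Gaussian copula mixing a
    # within-group normal score of the combined GVB (higher burden ->
    # lower score -> lower DIP) with fresh noise; the configured
    # truncated-normal marginal is then applied via its quantile
    # function, so group means are untouched.
    rho = params.burden_dip_correlation
    groups = np.array([row["dip_group"] for row in truth_rows])
    burden = np.array([row["combined_gvb"] for row in truth_rows])
    z_safe = np.zeros(len(truth_rows))
    for grp in np.unique(groups):
        if grp == Phenotype.NM.value:
            # the NM group is burden-free by construction (mild alleles
            # behave like wild type there); no gradient applies
            continue
        mask = groups == grp
        ranks = stats.rankdata(burden[mask], method="average")
        z_safe[mask] = stats.norm.ppf(ranks / (mask.sum() + 1.0))
    z_noise = rng.standard_normal(len(truth_rows))
    u = stats.norm.cdf(rho * z_safe + math.sqrt(1.0 - rho**2) * z_noise)

    loc_cache = {
        pheno: _calibrated_loc(mean, sd, lo, hi)
        for pheno, (mean, sd) in params.dip_model.items()
    }
    for i, row in enumerate(truth_rows):
        pheno = Phenotype(row["dip_group"])
        _, sd = params.dip_model[pheno]
        loc = loc_cache[pheno]
        a, b = (lo - loc) / sd, (hi - loc) / sd
        dip = float(stats.truncnorm.ppf(u[i], a, b, loc=loc, scale=sd))
        row["dip"] = dip
        dose_rows.append(
            {
                "sample": row["sample"],
                "planned_dose": params.planned_dose,
                "actual_dose": dip / 100.0 * params.planned_dose,
            }
        )

    return SimulatedCohort(
        params=params,
        variants=variants,
        dose=pd.DataFrame(dose_rows),
        truth=pd.DataFrame(truth_rows),
    )


def write_cohort(cohort: SimulatedCohort, out_dir: str) -> Dict[str, str]:
    """Write the cohort as a multi-sample VCF plus dose and truth TSVs.

    The VCF carries SIFT and GENE INFO tags and phased per-sample GT
    fields, and round-trips losslessly through :func:`thioburden.io.read_vcf`.
    Returns the paths keyed ``vcf``, ``dose``, ``truth``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples = cohort.samples

    # collect the union of sites
    sites: Dict[VariantKey, Dict[str, object]] = {}
    for sample, calls in cohort.variants.items():
        for v in calls:
            site = sites.setdefault(v.key, {"gene": v.gene, "sift": v.sift, "calls": {}})
            site["calls"][sample] = v

    header = pysam.VariantHeader()
    for chrom in sorted({k[0] for k in sites} | set(_CONTIG_LENGTHS)):
        header.contigs.add(chrom, length=_CONTIG_LENGTHS.get(chrom))
    header.info.add("GENE", 1, "String", "Gene symbol of the variant")
    header.info.add("SIFT", "A", "Float", "SIFT deleteriousness score (absent for InDels)")
    header.formats.add("GT", 1, "String", "Genotype")
    for s in samples:
        header.add_sample(s)

    vcf_path = str(out / "cohort.vcf")
    with pysam.VariantFile(vcf_path, "w", header=header) as vf:
        for key in sorted(sites, key=lambda k: (k[0], k[1], k[2], k[3])):
            chrom, pos, ref, alt = key
            site = sites[key]
            rec = vf.new_record(contig=chrom, start=pos - 1, alleles=(ref, alt))
            rec.info["GENE"] = site["gene"]
            if site["sift"] is not None:
                rec.info["SIFT"] = (float(site["sift"]),)
            for s in samples:
                v = site["calls"].get(s)
                if v is None:
                    rec.samples[s]["GT"] = (0, 0)
                elif v.zygosity is Zygosity.HOM:
                    rec.samples[s]["GT"] = (1, 1)
                elif v.phase == 0:
                    rec.samples[s]["GT"] = (1, 0)
                else:
                    rec.samples[s]["GT"] = (0, 1)
                rec.samples[s].phased = True
            vf.write(rec)

    dose = cohort.dose.copy()
    dose_path = str(out / "dose.tsv")
    dose.to_csv(dose_path, sep="\t", index=False)
    truth_path = str(out / "truth.tsv")
    cohort.truth.to_csv(truth_path, sep="\t", index=False)
    return {"vcf": vcf_path, "dose": dose_path, "truth": truth_path}
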