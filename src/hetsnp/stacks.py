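"""Candidate SNP calling from read stacks.

In a single heterozygous diploid, a true SNP shows up as two bases
segregating within the stack of mapped reads at one site, each at an
expected frequency of 0.5.  Sequencing and mapping errors instead produce
a minor variant at low frequency.  The variant frequency VF (fraction of
reads differing from the reference base) and its folded form
FVF = min(VF, 1 - VF) separate the two regimes: FVF near 0.5 supports a
heterozygous site, FVF near 0 an error.  A t-test against the null
FVF = 0.5 (binomial sampling of reads from two haplotypes) decides the
boundary instead of a fixed FVF threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy import stats

from .io import BASES, PileupColumn, ReferenceSeq


@dataclass
class CandidateSNP:
    """A called variant site with the statistics the filter cascade consumes."""

    ref_id: str
    pos: int
    ref_base: str
    allele1: str  # major allele (count ties broken A<C<G<T)
    allele2: str  # minor allele
    vf: float
    fvf: float
    rmd: int
    mqs: float
    ref_base_quality: int | None = None
    ref_avg_quality: float | None = None
    annotation: str = "unknown"
    ref_error_inferred: bool = False
    t_stat: float | None = None
    filter_flags: list[str] = field(default_factory=list)
    pfalse: float | None = None
    infinium_type: str | None = None
    design_score: float | None = None
    gene_id: str | None = None
    contig_id: str | None = None

    @property
    def passed(self) -> bool:
        return not self.filter_flags


def compute_vf(column: PileupColumn) -> float:
    """Variant frequency: reads differing from the reference base / all reads."""
    if column.depth <= 0:
        raise ValueError(f"{column.ref_id}:{column.pos}: VF undefined at depth 0")
    return (column.depth - column.counts.get(column.ref_base, 0)) / column.depth


def fold_vf(vf: float) -> float:
    """Fold VF onto [0, 0.5]: 1 - VF when VF > 0.5, else VF."""
    if not 0.0 <= vf <= 1.0:
        raise ValueError(f"VF {vf} outside [0, 1]")
    return 1.0 - vf if vf > 0.5 else vf


def fvf_deviation_test(fvf: float, rmd: int, alpha: float = 0.05) -> tuple[float, bool]:
    """Test whether FVF deviates from the heterozygous expectation 0.5.

    Small stacks (RMD * 0.5 < 30) get a continuity correction of 0.5/RMD.
    The fold makes the alternative one-sided, so significance compares t
    against the upper-alpha Student-t quantile with RMD - 1 df.  A
    significant deviation marks the site as a likely error (discard).

    Returns ``(t, significant)``.
    """
    if rmd < 2:
        raise ValueError("FVF deviation test needs RMD >= 2 (df = RMD - 1)")
    if not 0.0 <= fvf <= 0.5:
        raise ValueError(f"FVF {fvf} outside [0, 0.5]")
    se = 0.5 * (1.0 / rmd) ** 0.5
    dev = abs(fvf - 0.5)
    if rmd * 0.5 < 30:
        t = (dev - 0.5 / rmd) / se
    else:
        t = dev / se
    crit = stats.t.ppf(1.0 - alpha, rmd - 1)
    return t, bool(t >= crit)


def call_site(column: PileupColumn, reference: ReferenceSeq | None = None) -> CandidateSNP | None:
    """Call a heterozygosity candidate from one pileup column.

    The two most frequent bases become the alleles when both are observed.
    When neither allele matches the reference base, the reference base
    itself is inferred to be a sequencing error (``ref_error_inferred``)
    and FVF is taken within the two-allele stack.  Sites with a single
    observed base are homozygous in this one-individual design and yield
    no SNP.  Third-ranked bases are treated as noise: they are ignored for
    allele naming but still count toward depth and VF.
    """
    if column.depth <= 0:
        return None
    observed = [(b, column.counts[b]) for b in BASES if column.counts[b] > 0]
    if len(observed) < 2:
        return None
    observed.sort(key=lambda bc: (-bc[1], bc[0]))
    (a1, c1), (a2, c2) = observed[0], observed[1]
    vf = compute_vf(column)
    if column.ref_base in (a1, a2):
        fvf = fold_vf(vf)
        ref_err = False
    else:
        fvf = c2 / (c1 + c2)
        ref_err = True
    snp = CandidateSNP(
        ref_id=column.ref_id,
        pos=column.pos,
        ref_base=column.ref_base,
        allele1=a1,
        allele2=a2,
        vf=vf,
        fvf=fvf,
        rmd=column.depth,
        mqs=column.mqs,
        ref_error_inferred=ref_err,
    )
    if reference is not None:
        _attach_reference(snp, reference)
    return snp


def _attach_reference(snp: CandidateSNP, ref: ReferenceSeq) -> None:
    if snp.pos > len(ref):
        raise ValueError(f"{snp.ref_id}:{snp.pos} beyond reference length {len(ref)}")
    snp.ref_base_quality = int(ref.base_quality[snp.pos - 1])
    snp.ref_avg_quality = ref.avg_quality
    snp.annotation = ref.annotation
    snp.contig_id = ref.contig_id


def annotate_candidates(
    snps: list[CandidateSNP],
    annotation_map: dict[str, str],
    references: dict[str, ReferenceSeq] | list[ReferenceSeq],
) -> list[CandidateSNP]:
    """Attach annotation and reference quality context to each candidate.

    References absent from the annotation map stay ``unknown``; a candidate
    whose reference sequence is missing entirely is an error.
    """
    if not isinstance(references, dict):
        references = {r.id: r for r in references}
    for ref in references.values():
        if ref.id in annotation_map:
            ref.annotation = annotation_map[ref.id]
    for snp in snps:
        if snp.ref_id not in references:
            raise KeyError(f"candidate {snp.ref_id}:{snp.pos}: reference not loaded")
        _attach_reference(snp, references[snp.ref_id])
    return snps
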