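"""The SNP filter cascade.

Candidates are screened on read mapping depth (minimum, and a maximum
derived from the extreme-value depth model), folded variant frequency
(fixed threshold or the FVF-vs-0.5 t-test), mapping quality, reference
base quality (stricter for non-genic references, whose Sanger consensus
is less reliable), homopolymer context, inter-SNP spacing, and distance
from the 3' (right) end of the reference read where Sanger quality
decays.  Every filter is evaluated for every candidate (no
short-circuiting) so the report can attribute each failure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .io import ReferenceSeq
from .stacks import CandidateSNP, fvf_deviation_test

FILTER_ORDER = (
    "min_rmd",
    "max_rmd",
    "fvf",
    "mqs",
    "ref_base_quality",
    "homopolymer",
    "spacing",
    "right_edge",
)


@dataclass
class FilterParams:
    """Thresholds of the filter cascade.

    Two presets mirror the published criteria: ``initial()`` (fixed
    FVF >= 0.2, MQS >= 25, no maximum depth) and ``adjusted()``
    (FVF t-test, MQS >= 30, maximum depth from the fitted depth model,
    defaulting to 25).
    """

    min_rmd: int = 5
    max_rmd: int | None = 25  # None = no constraint
    min_mqs: float = 30.0
    min_ref_snp_qual_genic: int = 40
    min_ref_snp_qual_nongenic: int = 45
    homopolymer_len: int = 3
    min_snp_spacing: int = 4  # required distance between contiguous SNPs (> 3 bp)
    right_edge_bp: int = 30
    assay_spacing: int = 60  # applied at assay design, not here
    fvf_mode: str = "ttest"  # "fixed_threshold" | "ttest"
    fvf_threshold: float = 0.2
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.fvf_mode not in ("fixed_threshold", "ttest"):
            raise ValueError(f"bad fvf_mode {self.fvf_mode!r}")

    @classmethod
    def initial(cls) -> "FilterParams":
        return cls(max_rmd=None, min_mqs=25.0, fvf_mode="fixed_threshold")

    @classmethod
    def adjusted(cls, max_rmd: int | None = 25) -> "FilterParams":
        return cls(max_rmd=max_rmd, min_mqs=30.0, fvf_mode="ttest")

    def with_max_rmd(self, cutoff: int) -> "FilterParams":
        return replace(self, max_rmd=cutoff)


@dataclass
class FilterReport:
    """Per-filter accounting: input, failed and passed counts."""

    counts: dict[str, dict[str, int]] = field(
        default_factory=lambda: {f: {"input": 0, "failed": 0, "passed": 0} for f in FILTER_ORDER}
    )
    n_candidates: int = 0
    n_passed: int = 0

    def record(self, name: str, failed: bool) -> None:
        row = self.counts[name]
        row["input"] += 1
        row["failed" if failed else "passed"] += 1

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(self.counts, orient="index")
        df.index.name = "filter"
        return df


def quality_filters(snp: CandidateSNP, params: FilterParams) -> list[str]:
    """Depth/MQS/reference-base-quality checks; returns the failed filter names."""
    failed = []
    if snp.rmd < params.min_rmd:
        failed.append("min_rmd")
    if params.max_rmd is not None and snp.rmd > params.max_rmd:
        failed.append("max_rmd")
    if snp.mqs < params.min_mqs:
        failed.append("mqs")
    if params.min_ref_snp_qual_genic is not None:
        # unknown annotation gets the stricter (non-genic) threshold
        thr = (
            params.min_ref_snp_qual_genic
            if snp.annotation == "genic"
            else params.min_ref_snp_qual_nongenic
        )
        q = snp.ref_base_quality
        if q is None or q < thr:
            failed.append("ref_base_quality")
    return failed


def fvf_filter(snp: CandidateSNP, params: FilterParams) -> bool:
    """True when the candidate's FVF is consistent with heterozygosity."""
    if params.fvf_mode == "fixed_threshold":
        return snp.fvf >= params.fvf_threshold
    t, significant = fvf_deviation_test(snp.fvf, snp.rmd, params.alpha)
    snp.t_stat = t
    return not significant


def _run_length_at(seq: str, idx: int) -> int:
    """Length of the maximal run of identical bases covering 0-based idx."""
    b = seq[idx]
    lo = idx
    while lo > 0 and seq[lo - 1] == b:
        lo -= 1
    hi = idx
    while hi + 1 < len(seq) and seq[hi + 1] == b:
        hi += 1
    return hi - lo + 1


def homopolymer_filter(snp: CandidateSNP, reference: ReferenceSeq, params: FilterParams) -> bool:
    """True (pass) unless the site sits in, or an allele creates, a homopolymer run."""
    seq = reference.sequence
    idx = snp.pos - 1
    if not 0 <= idx < len(seq):
        raise ValueError(f"{snp.ref_id}:{snp.pos} outside reference of length {len(seq)}")
    if _run_length_at(seq, idx) >= params.homopolymer_len:
        return False
    for allele in (snp.allele1, snp.allele2):
        sub = seq[:idx] + allele + seq[idx + 1 :]
        if _run_length_at(sub, idx) >= params.homopolymer_len:
            return False
    return True


def proximity_filter(snps: list[CandidateSNP], params: FilterParams) -> set[int]:
    """Indices (into ``snps``) failing the inter-SNP spacing rule.

    Both members of a pair closer than ``min_snp_spacing`` are removed:
    a near neighbour casts doubt on the local alignment of either site.
    Candidates must share one reference.
    """
    return _spacing_fails(snps, params.min_snp_spacing)


def _spacing_fails(snps: list[CandidateSNP], min_dist: int) -> set[int]:
    order = sorted(range(len(snps)), key=lambda i: snps[i].pos)
    failed: set[int] = set()
    for a, b in zip(order, order[1:]):
        if snps[b].pos - snps[a].pos < min_dist:
            failed.add(a)
            failed.add(b)
    return failed


def right_edge_filter(snp: CandidateSNP, reference: ReferenceSeq, params: FilterParams) -> bool:
    """True (pass) when the site lies > right_edge_bp from the 3' end."""
    return (len(reference) - snp.pos) >= params.right_edge_bp


def run_cascade(
    candidates: list[CandidateSNP],
    references: dict[str, ReferenceSeq] | list[ReferenceSeq],
    params: FilterParams | None = None,
) -> tuple[list[CandidateSNP], FilterReport]:
    """Apply the full cascade; returns (passing SNPs, per-filter report).

    Every candidate's ``filter_flags`` lists all failed filters, in
    cascade order.  The result is invariant to input order: candidates
    are sorted (ref_id, pos) first.
    """
    if params is None:
        params = FilterParams.adjusted()
    if not isinstance(references, dict):
        references = {r.id: r for r in references}
    candidates = sorted(candidates, key=lambda s: (s.ref_id, s.pos))
    report = FilterReport(n_candidates=len(candidates))

    per_ref: dict[str, list[CandidateSNP]] = {}
    for s in candidates:
        s.filter_flags = []
        per_ref.setdefault(s.ref_id, []).append(s)

    spacing_failed: dict[int, bool] = {}
    for ref_id, group in per_ref.items():
        fails = _spacing_fails(group, params.min_snp_spacing)
        for i, s in enumerate(group):
            spacing_failed[id(s)] = i in fails

    for s in candidates:
        ref = references.get(s.ref_id)
        if ref is None:
            raise KeyError(f"candidate {s.ref_id}:{s.pos}: reference not loaded")
        failed_quality = quality_filters(s, params)
        outcomes = {
            "min_rmd": "min_rmd" in failed_quality,
            "max_rmd": "max_rmd" in failed_quality,
            "fvf": not fvf_filter(s, params),
            "mqs": "mqs" in failed_quality,
            "ref_base_quality": "ref_base_quality" in failed_quality,
            "homopolymer": not homopolymer_filter(s, ref, params),
            "spacing": spacing_failed[id(s)],
            "right_edge": not right_edge_filter(s, ref, params),
        }
        for name in FILTER_ORDER:
            report.record(name, outcomes[name])
            if outcomes[name]:
                s.filter_flags.append(name)

    passed = [s for s in candidates if not s.filter_flags]
    report.n_passed = len(passed)
    return passed, report
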