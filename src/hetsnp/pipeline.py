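"""High-level discovery pipeline: stacks -> depth model -> filter cascade."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .depth import DepthModel, fit_evd
from .filters import FilterParams, FilterReport, run_cascade
from .io import PileupColumn, ReferenceSeq
from .stacks import CandidateSNP, annotate_candidates, call_site


@dataclass
class DiscoveryResult:
    candidates: list[CandidateSNP]
    passed: list[CandidateSNP]
    report: FilterReport
    depth_model: DepthModel | None


def discover(
    references: list[ReferenceSeq] | dict[str, ReferenceSeq],
    columns: Iterable[PileupColumn],
    annotation: dict[str, str] | None = None,
    params: FilterParams | None = None,
    fit_depth_cutoff: bool = True,
    cutoff_k: float = 0.5,
) -> DiscoveryResult:
    """Run the discovery pipeline over a pileup stream.

    When ``fit_depth_cutoff`` is set, a Gumbel model is fitted to the
    pooled per-site depths and its floor(X̄ + k*s) cutoff replaces
    ``params.max_rmd``; with it off (the initial-criteria preset) the
    preset's own maximum applies.
    """
    if not isinstance(references, dict):
        references = {r.id: r for r in references}
    params = params or FilterParams.adjusted()

    depths: list[int] = []
    candidates: list[CandidateSNP] = []
    for col in columns:
        depths.append(col.depth)
        snp = call_site(col)
        if snp is not None:
            candidates.append(snp)

    annotate_candidates(candidates, annotation or {}, references)

    model = None
    if fit_depth_cutoff:
        model = fit_evd(depths, k=cutoff_k)
        params = params.with_max_rmd(model.cutoff)

    passed, report = run_cascade(candidates, references, params)
    return DiscoveryResult(candidates=candidates, passed=passed, report=report, depth_model=model)
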