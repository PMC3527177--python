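"""Infinium assay typing and panel selection.

Biallelic SNPs fall into two Infinium bead classes: [A/T] and [C/G]
need two probes (type I, both alleles extend with the same channel),
the other four pairs need one probe (type II).  Type II SNPs are cheaper
per locus, so panels are built from them only.  Selection aims for even
genome coverage: one SNP per reference read, at least one per physical-map
contig, per-contig counts proportional to contig size, and picks spread
along each contig.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .stacks import CandidateSNP

_TYPE_I_PAIRS = ({"A", "T"}, {"C", "G"})


def classify_infinium(allele1: str, allele2: str) -> str:
    """Infinium assay type: "I" for A/T and C/G pairs, "II" otherwise."""
    pair = {allele1.upper(), allele2.upper()}
    if len(pair) != 2:
        raise ValueError(f"alleles must differ, got {allele1}/{allele2}")
    if not pair <= {"A", "C", "G", "T"}:
        raise ValueError(f"non-DNA alleles {allele1}/{allele2}")
    return "I" if pair in _TYPE_I_PAIRS else "II"


def assay_spacing_filter(snps: list[CandidateSNP], spacing: int = 60) -> set[int]:
    """Indices of SNPs with another detected variant within < spacing bp.

    A nearby second variant can disturb probe hybridisation, so both
    members of a close pair are dropped.  ``snps`` share one reference.
    """
    from .filters import _spacing_fails

    return _spacing_fails(snps, spacing)


@dataclass
class AssayPanel:
    """Result of panel selection: the chosen SNPs and per-contig allocation."""

    selected: list[CandidateSNP]
    allocation: dict[str, int] = field(default_factory=dict)
    budget: int = 0


def _largest_remainder(weights: dict[str, float], seats: int) -> dict[str, int]:
    total = sum(weights.values())
    if total <= 0:
        return {k: 0 for k in weights}
    quotas = {k: seats * w / total for k, w in weights.items()}
    alloc = {k: int(q) for k, q in quotas.items()}
    leftover = seats - sum(alloc.values())
    # hand remaining seats to the largest fractional remainders (ties by size)
    order = sorted(weights, key=lambda k: (quotas[k] - alloc[k], weights[k]), reverse=True)
    for k in order[:leftover]:
        alloc[k] += 1
    return alloc


def select_assay_snps(
    snps: list[CandidateSNP],
    contig_map: dict[str, str],
    contig_sizes: dict[str, float],
    budget: int,
    min_design_score: float = 0.7,
) -> AssayPanel:
    """Select a genotyping panel under the five design rules.

    Eligibility: Infinium type II, design score >= ``min_design_score``,
    at most one SNP per reference (best design score wins, ties by
    position), and at most one reference per gene when ``gene_id`` is
    set.  Allocation: seats apportioned to contigs proportionally to
    ``contig_sizes`` by largest remainder, then floored at one seat per
    contig with eligible supply while the budget allows; within a contig
    picks are spread by position percentile.
    """
    eligible = []
    for s in snps:
        itype = s.infinium_type or classify_infinium(s.allele1, s.allele2)
        s.infinium_type = itype
        if itype != "II":
            continue
        if s.design_score is None or s.design_score < min_design_score:
            continue
        eligible.append(s)

    # rule: one SNP per reference
    best_per_ref: dict[str, CandidateSNP] = {}
    for s in eligible:
        cur = best_per_ref.get(s.ref_id)
        if cur is None or (s.design_score, -s.pos) > (cur.design_score, -cur.pos):
            best_per_ref[s.ref_id] = s
    eligible = list(best_per_ref.values())

    # rule: one reference per duplicated gene (skipped when gene ids absent)
    by_gene: dict[str, CandidateSNP] = {}
    kept = []
    for s in eligible:
        if s.gene_id is None:
            kept.append(s)
        elif s.gene_id not in by_gene or (s.design_score, -s.pos) > (
            by_gene[s.gene_id].design_score,
            -by_gene[s.gene_id].pos,
        ):
            by_gene[s.gene_id] = s
    eligible = kept + list(by_gene.values())

    per_contig: dict[str, list[CandidateSNP]] = {}
    for s in eligible:
        contig = s.contig_id or contig_map.get(s.ref_id)
        if contig is None:
            continue  # unplaced references cannot serve even-coverage selection
        s.contig_id = contig
        per_contig.setdefault(contig, []).append(s)

    contigs = sorted(per_contig, key=lambda c: (-contig_sizes.get(c, 0.0), c))
    if budget < len(contigs):
        warnings.warn(
            f"budget {budget} below eligible contig count {len(contigs)}; "
            "smallest contigs dropped",
            stacklevel=2,
        )
        contigs = contigs[:budget]

    weights = {c: float(contig_sizes.get(c, 0.0)) for c in contigs}
    alloc = _largest_remainder(weights, budget)
    # floor: every contig with supply gets >= 1, funded by the largest allocations
    donors = sorted(contigs, key=lambda c: -alloc[c])
    for c in contigs:
        if alloc[c] == 0:
            for d in donors:
                if alloc[d] > 1:
                    alloc[d] -= 1
                    alloc[c] = 1
                    break
    # cap by supply, re-seat the surplus by contig size
    surplus = 0
    for c in contigs:
        cap = len(per_contig[c])
        if alloc[c] > cap:
            surplus += alloc[c] - cap
            alloc[c] = cap
    while surplus > 0:
        takers = [c for c in contigs if alloc[c] < len(per_contig[c])]
        if not takers:
            break
        extra = _largest_remainder({c: weights[c] or 1.0 for c in takers}, surplus)
        moved = 0
        for c in takers:
            room = len(per_contig[c]) - alloc[c]
            give = min(extra.get(c, 0), room)
            alloc[c] += give
            moved += give
        if moved == 0:
            break
        surplus -= moved

    selected: list[CandidateSNP] = []
    for c in contigs:
        group = sorted(per_contig[c], key=lambda s: (s.ref_id, s.pos))
        n_pick = alloc[c]
        if n_pick >= len(group):
            selected.extend(group)
            continue
        # spread picks by position percentile along the contig
        idx = sorted({round(i * (len(group) - 1) / max(n_pick - 1, 1)) for i in range(n_pick)})
        while len(idx) < n_pick:  # rounding collisions: fill from unused slots
            pool = [j for j in range(len(group)) if j not in idx]
            idx.append(pool[0])
        selected.extend(group[j] for j in sorted(idx))

    return AssayPanel(selected=selected, allocation={c: alloc[c] for c in contigs}, budget=budget)
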