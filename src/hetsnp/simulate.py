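"""Synthetic data with known truth for every pipeline stage.

The generator emulates the statistical structure of BAC-end-sequence
resequencing of a single heterozygous individual: Sanger-like references
with 3'-decaying base quality, a Gumbel-distributed read-depth profile
with a repeat class at inflated depth, heterozygous sites whose read
variants arrive at expected frequency 0.5, Phred-driven base errors that
skew VF low, paralog-divergence sites on repeat references (the dominant
false-positive source), and Mendelian F1 segregation from two parents
with genotyping error and missingness.

True heterozygous sites are planted only at assayable positions —
reference quality >= 45, outside homopolymer context, > 30 bp from the
3' end, >= 61 bp apart — so the truth table represents discoverable
SNPs rather than sites the cascade removes by construction (see
docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BASES, GenotypeMatrix, PedigreeTable, PileupColumn, ReferenceSeq

_BASE_ARR = np.array(list(BASES))


@dataclass
class SimConfig:
    """Study-condition parameters of the generator.

    Defaults follow the walnut BES study design where stated: reference
    length ~721 bp, one het site per ~1500 bp, depth location ~16 reads,
    MQS ~34 +/- 1.6 at true sites, 428 F1 progeny.
    """

    n_refs: int = 300
    ref_length_mean: float = 721.0
    ref_length_sd: float = 80.0
    genic_fraction: float = 0.6
    repeat_fraction: float = 0.1
    repeat_depth_multiplier: float = 3.0
    het_site_rate: float = 1.0 / 1500.0
    depth_mu: float = 16.0  # Gumbel location, reads
    depth_beta: float = 2.5  # Gumbel scale, reads
    depth_jitter: float = 0.1  # per-site +/-10% around the per-reference depth
    paralog_site_rate: float = 0.002  # diverged-copy sites per bp on repeat refs
    mqs_mean: float = 34.3
    mqs_sd: float = 1.6
    mqs_mean_error: float = 33.7  # MQS at non-het (error/paralog) sites
    mqs_sd_error: float = 2.0
    quality_peak: int = 55
    quality_floor: int = 20
    quality_decay_bp: int = 100  # Sanger quality decays over the final stretch
    n_progeny: int = 428
    genotyping_error: float = 0.005
    missing_rate: float = 0.01
    seed: int = 0
    # placement constraints for assayable truth sites
    het_min_quality: int = 45
    het_min_spacing: int = 61
    het_edge_margin: int = 31
    homopolymer_len: int = 3

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _quality_profile(length: int, cfg: SimConfig) -> np.ndarray:
    """Phred profile: flat at the peak, linear decay over the final stretch."""
    q = np.full(length, cfg.quality_peak, dtype=int)
    decay = min(cfg.quality_decay_bp, length)
    # distance d from the 3' end; quality falls linearly peak -> floor
    d = np.arange(decay - 1, -1, -1)
    q[length - decay :] = np.round(
        cfg.quality_floor + (cfg.quality_peak - cfg.quality_floor) * d / cfg.quality_decay_bp
    ).astype(int)
    return q


def _homopolymer_safe(seq: np.ndarray, idx: int, alt: str, run_len: int) -> bool:
    """Neither the reference context nor the alt allele forms a run >= run_len."""
    s = seq.copy()
    for base in (s[idx], alt):
        s[idx] = base
        lo = idx
        while lo > 0 and s[lo - 1] == base:
            lo -= 1
        hi = idx
        while hi + 1 < len(s) and s[hi + 1] == base:
            hi += 1
        if hi - lo + 1 >= run_len:
            return False
    return True


def simulate_references(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[ReferenceSeq], pd.DataFrame]:
    """Generate references plus the truth table of planted het sites.

    Returns ``(references, truth)`` where truth has columns
    ref_id, pos (1-based), ref_base, alt_base, and references carry
    annotation (genic/nongenic), a contig id, and an ``is_repeat`` flag
    stashed on the contig naming (repeat refs get contig id prefix "rep").
    """
    rng = config.rng() if rng is None else rng
    refs: list[ReferenceSeq] = []
    truth_rows = []
    n_repeat = int(round(config.repeat_fraction * config.n_refs))
    n_genic = int(round(config.genic_fraction * config.n_refs))
    for i in range(config.n_refs):
        length = max(200, int(round(rng.normal(config.ref_length_mean, config.ref_length_sd))))
        seq = rng.choice(_BASE_ARR, size=length)
        qual = _quality_profile(length, config)
        is_repeat = i < n_repeat
        rid = f"{'rep' if is_repeat else 'bes'}{i:05d}"
        annotation = "genic" if (i % config.n_refs) < n_genic else "nongenic"
        # plant het sites at assayable positions only
        n_het = rng.binomial(length, config.het_site_rate)
        if n_het > 0:
            eligible = np.flatnonzero(
                (qual >= config.het_min_quality)
                & (np.arange(length) < length - config.het_edge_margin)
            )
            rng.shuffle(eligible)
            chosen: list[int] = []
            chosen_alt: dict[int, str] = {}
            for idx in eligible:
                if len(chosen) == n_het:
                    break
                if any(abs(idx - c) < config.het_min_spacing for c in chosen):
                    continue
                alts = [b for b in BASES if b != seq[idx]]
                rng.shuffle(alts)
                alt = next(
                    (a for a in alts if _homopolymer_safe(seq, idx, a, config.homopolymer_len)),
                    None,
                )
                if alt is None:
                    continue
                chosen.append(idx)
                chosen_alt[idx] = alt
            for idx in sorted(chosen):
                truth_rows.append(
                    {
                        "ref_id": rid,
                        "pos": int(idx + 1),
                        "ref_base": str(seq[idx]),
                        "alt_base": chosen_alt[idx],
                    }
                )
        refs.append(
            ReferenceSeq(
                id=rid,
                sequence="".join(seq),
                base_quality=[int(q) for q in qual],
                annotation=annotation,
                contig_id=f"ctg{i % max(config.n_refs // 10, 1):04d}",
            )
        )
    truth = pd.DataFrame(truth_rows, columns=["ref_id", "pos", "ref_base", "alt_base"])
    return refs, truth


def is_repeat_ref(ref_id: str) -> bool:
    return ref_id.startswith("rep")


def simulate_pileup(
    references: list[ReferenceSeq],
    truth: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
):
    """Yield pileup columns over every reference base (depth-0 sites skipped).

    Depth is drawn per reference from Gumbel(mu, beta), multiplied by the
    repeat multiplier on repeat references, then jittered per site.  At
    het sites the variant count is Binomial(depth, 0.5); at paralog sites
    on repeat references Binomial(depth, 1/multiplier); elsewhere errors
    arrive at the local Phred error rate 10^(-Q/10).
    """
    rng = config.rng() if rng is None else rng
    het = {
        (r.ref_id, r.pos): r.alt_base for r in truth.itertuples(index=False)
    } if len(truth) else {}
    for ref in references:
        length = len(ref)
        repeat = is_repeat_ref(ref.id)
        base_depth = rng.gumbel(config.depth_mu, config.depth_beta)
        if repeat:
            base_depth *= config.repeat_depth_multiplier
        jitter = rng.uniform(1 - config.depth_jitter, 1 + config.depth_jitter, size=length)
        depths = np.maximum(np.round(base_depth * jitter), 0).astype(int)
        err_rate = 10.0 ** (-np.asarray(ref.base_quality) / 10.0)
        paralog = (
            set(np.flatnonzero(rng.random(length) < config.paralog_site_rate) + 1)
            if repeat
            else set()
        )
        seq = ref.sequence
        for pos in range(1, length + 1):
            depth = int(depths[pos - 1])
            if depth == 0:
                continue
            ref_base = seq[pos - 1]
            if ref_base == "N":
                continue
            counts = {b: 0 for b in BASES}
            alt = het.get((ref.id, pos))
            if alt is not None:
                v = rng.binomial(depth, 0.5)
                counts[ref_base] = depth - v
                counts[alt] += v
                mqs = max(rng.normal(config.mqs_mean, config.mqs_sd), 0.0)
            else:
                if pos in paralog:
                    v = rng.binomial(depth, 1.0 / config.repeat_depth_multiplier)
                    alt_b = rng.choice([b for b in BASES if b != ref_base])
                    counts[ref_base] = depth - v
                    counts[alt_b] += v
                else:
                    k = rng.binomial(depth, min(err_rate[pos - 1], 1.0))
                    counts[ref_base] = depth - k
                    if k:
                        others = [b for b in BASES if b != ref_base]
                        split = rng.multinomial(k, [1 / 3] * 3)
                        for b, c in zip(others, split):
                            counts[b] += int(c)
                mqs = max(rng.normal(config.mqs_mean_error, config.mqs_sd_error), 0.0)
            yield PileupColumn(ref.id, pos, ref_base, depth, counts, float(mqs))


_GAMETES = {"AA": "AA", "AB": "AB", "BB": "BB"}


def simulate_cross(
    parent1_genotypes,
    parent2_genotypes,
    n_progeny: int,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Mendelian F1 progeny from two parents over shared markers.

    Parent genotypes are mappings/Series marker -> {AA, AB, BB}.
    Genotyping error replaces a call with a random different genotype;
    missingness sets it to NA.
    """
    rng = config.rng() if rng is None else rng
    p1 = dict(parent1_genotypes)
    p2 = dict(parent2_genotypes)
    markers = [m for m in p1 if m in p2]
    samples = [f"F1_{i:04d}" for i in range(n_progeny)]
    grid = np.empty((n_progeny, len(markers)), dtype=object)
    for j, m in enumerate(markers):
        for gt in (p1[m], p2[m]):
            if gt not in _GAMETES:
                raise ValueError(f"marker {m}: bad parent genotype {gt!r}")
        g1 = rng.integers(0, 2, size=n_progeny) if p1[m] == "AB" else None
        g2 = rng.integers(0, 2, size=n_progeny) if p2[m] == "AB" else None
        a1 = g1 if g1 is not None else np.full(n_progeny, 0 if p1[m] == "AA" else 1)
        a2 = g2 if g2 is not None else np.full(n_progeny, 0 if p2[m] == "AA" else 1)
        dose = a1 + a2
        col = np.array(["AA", "AB", "BB"], dtype=object)[dose]
        err = rng.random(n_progeny) < config.genotyping_error
        for i in np.flatnonzero(err):
            col[i] = rng.choice([g for g in ("AA", "AB", "BB") if g != col[i]])
        col[rng.random(n_progeny) < config.missing_rate] = "NA"
        grid[:, j] = col
    return GenotypeMatrix(pd.DataFrame(grid, index=samples, columns=markers))


def simulate_pedigree(
    n_founders: int,
    n_generations: int,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> PedigreeTable:
    """Random-mating multi-generation pedigree; founders have no parents."""
    rng = config.rng() if rng is None else rng
    rows: list[tuple[str, str, str]] = []
    prev = [f"G0_{i:03d}" for i in range(n_founders)]
    for ind in prev:
        rows.append((ind, "UNKNOWN", "UNKNOWN"))
    for g in range(1, n_generations + 1):
        cur = []
        for i in range(n_founders):
            sire, dam = rng.choice(prev, size=2, replace=False)
            ind = f"G{g}_{i:03d}"
            rows.append((ind, str(sire), str(dam)))
            cur.append(ind)
        prev = cur
    return PedigreeTable(rows)


def genotypes_through_pedigree(
    pedigree: PedigreeTable,
    n_markers: int,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Drop biallelic genotypes through the pedigree by Mendelian inheritance.

    Founders draw alleles at frequency 0.5; descendants inherit one
    allele from each parent.  Supports the COP-vs-dissimilarity checks.
    """
    rng = config.rng() if rng is None else rng
    order = sorted(pedigree.individuals, key=pedigree.depth)
    markers = [f"m{j:04d}" for j in range(n_markers)]
    alleles: dict[str, np.ndarray] = {}
    for ind in order:
        sire, dam = pedigree.parents[ind]
        a = (
            rng.integers(0, 2, size=n_markers)
            if sire is None
            else alleles[sire][np.arange(n_markers), rng.integers(0, 2, size=n_markers)]
        )
        b = (
            rng.integers(0, 2, size=n_markers)
            if dam is None
            else alleles[dam][np.arange(n_markers), rng.integers(0, 2, size=n_markers)]
        )
        alleles[ind] = np.stack([a, b], axis=1)
    grid = {}
    for ind in order:
        dose = alleles[ind].sum(axis=1)
        grid[ind] = np.array(["AA", "AB", "BB"], dtype=object)[dose]
    df = pd.DataFrame.from_dict(grid, orient="index", columns=markers)
    return GenotypeMatrix(df)
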