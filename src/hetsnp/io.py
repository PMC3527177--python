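"""Readers and writers for every external format the pipeline touches.

All coordinates are 1-based inclusive (pileup/VCF convention).  Read stacks
are strand-collapsed: base counts refer to the reference forward strand.
Phred qualities are capped at 93; QUAL files are whitespace-separated
integers, one block per FASTA record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = ("A", "C", "G", "T")
GENOTYPE_TOKENS = ("AA", "AB", "BB", "NA")
MISSING = "NA"
UNKNOWN_PARENT = "UNKNOWN"
MAX_PHRED = 93
ANNOTATIONS = ("genic", "nongenic", "unknown")


class FormatError(ValueError):
    """An input file violates its format contract."""


# ---------------------------------------------------------------------------
# reference sequences


@dataclass
class ReferenceSeq:
    """One reference read (e.g. a Sanger BAC-end sequence) with per-base Phred."""

    id: str
    sequence: str
    base_quality: list[int]
    annotation: str = "unknown"
    contig_id: str | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if set(self.sequence) - set("ACGTN"):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise FormatError(f"reference {self.id}: non-DNA characters {bad}")
        if len(self.base_quality) != len(self.sequence):
            raise FormatError(
                f"reference {self.id}: {len(self.sequence)} bases but "
                f"{len(self.base_quality)} quality values"
            )
        if any(q < 0 or q > MAX_PHRED for q in self.base_quality):
            raise FormatError(f"reference {self.id}: Phred outside [0, {MAX_PHRED}]")
        if self.annotation not in ANNOTATIONS:
            raise FormatError(f"reference {self.id}: bad annotation {self.annotation!r}")

    @property
    def avg_quality(self) -> float:
        return float(np.mean(self.base_quality))

    def __len__(self) -> int:
        return len(self.sequence)


def read_references(fasta_path, qual_path) -> list[ReferenceSeq]:
    """Load references from paired FASTA + QUAL files.

    The two files must contain the same record ids; lengths are checked
    per record.
    """
    seqs = {r.id: str(r.seq) for r in SeqIO.parse(str(fasta_path), "fasta")}
    quals: dict[str, list[int]] = {}
    for rec in SeqIO.parse(str(qual_path), "qual"):
        quals[rec.id] = list(rec.letter_annotations["phred_quality"])
    if set(seqs) != set(quals):
        only_f = sorted(set(seqs) - set(quals))
        only_q = sorted(set(quals) - set(seqs))
        raise FormatError(
            f"FASTA/QUAL id mismatch: only in FASTA {only_f[:5]}, only in QUAL {only_q[:5]}"
        )
    return [ReferenceSeq(rid, seqs[rid], quals[rid]) for rid in seqs]


def write_references(refs: Iterable[ReferenceSeq], fasta_path, qual_path) -> None:
    records = []
    for r in refs:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(r.base_quality)
        records.append(rec)
    SeqIO.write(records, str(fasta_path), "fasta")
    SeqIO.write(records, str(qual_path), "qual")


# ---------------------------------------------------------------------------
# pileup columns


@dataclass
class PileupColumn:
    """Per-site summary of the stack of mapped reads against one reference base."""

    ref_id: str
    pos: int  # 1-based
    ref_base: str
    depth: int
    counts: dict[str, int]
    mqs: float

    def __post_init__(self) -> None:
        if self.ref_base not in BASES:
            raise FormatError(f"{self.ref_id}:{self.pos}: bad reference base {self.ref_base!r}")
        if self.pos < 1:
            raise FormatError(f"{self.ref_id}:{self.pos}: positions are 1-based")
        self.counts = {b: int(self.counts.get(b, 0)) for b in BASES}
        if any(c < 0 for c in self.counts.values()):
            raise FormatError(f"{self.ref_id}:{self.pos}: negative base count")
        if sum(self.counts.values()) != self.depth:
            raise FormatError(
                f"{self.ref_id}:{self.pos}: counts sum {sum(self.counts.values())} "
                f"!= depth {self.depth}"
            )
        if self.mqs < 0:
            raise FormatError(f"{self.ref_id}:{self.pos}: negative MQS")


def _parse_tsv_pileup(line: str, lineno: int) -> PileupColumn:
    parts = line.split("\t")
    if len(parts) != 6:
        parts = line.split()
    if len(parts) != 6:
        raise FormatError(f"pileup line {lineno}: expected 6 fields, got {len(parts)}")
    ref_id, pos, ref_base, depth, packed, mqs = parts
    try:
        cnt = [int(x) for x in packed.split(",")]
        if len(cnt) != 4:
            raise ValueError
    except ValueError:
        raise FormatError(f"pileup line {lineno}: bad packed counts {packed!r}") from None
    return PileupColumn(
        ref_id=ref_id,
        pos=int(pos),
        ref_base=ref_base.upper(),
        depth=int(depth),
        counts=dict(zip(BASES, cnt)),
        mqs=float(mqs),
    )


def _parse_mpileup_bases(bases: str, ref_base: str) -> dict[str, int]:
    """Decode a samtools mpileup read-base string into forward-strand counts."""
    counts = {b: 0 for b in BASES}
    i = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":  # read start: skip the mapping-quality char
            i += 2
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":  # indel: skip the length-prefixed insert
            i += 1
            num = ""
            while i < n and bases[i].isdigit():
                num += bases[i]
                i += 1
            i += int(num or 0)
            continue
        if c in ".,":
            counts[ref_base] += 1
        elif c.upper() in BASES:
            counts[c.upper()] += 1
        # '*', 'N', '<', '>' contribute no base call
        i += 1
    return counts


def _parse_mpileup(line: str, lineno: int) -> PileupColumn:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < 5:
        raise FormatError(f"mpileup line {lineno}: expected >= 5 fields")
    ref_id, pos, ref_base = parts[0], int(parts[1]), parts[2].upper()
    bases = parts[4]
    counts = _parse_mpileup_bases(bases, ref_base)
    # column 7 (samtools mpileup -s) holds per-read mapping qualities; the
    # site MQS is their root-mean-square.  Without it MQS defaults to 0.
    if len(parts) >= 7 and parts[6]:
        mq = np.array([ord(ch) - 33 for ch in parts[6]], dtype=float)
        mqs = float(np.sqrt(np.mean(mq**2)))
    else:
        mqs = 0.0
    # indels/skips make the printed depth disagree with counted bases;
    # depth is recomputed from the counts so the invariant holds
    return PileupColumn(ref_id, pos, ref_base, sum(counts.values()), counts, mqs)


def read_pileup(path, dialect: str = "tsv") -> Iterator[PileupColumn]:
    """Stream pileup columns from ``path``.

    dialect "tsv" is the canonical 7-field format
    ``ref_id pos ref_base depth A,C,G,T mqs``; "mpileup" is a best-effort
    parse of the samtools text pileup.
    """
    if dialect not in ("tsv", "mpileup"):
        raise ValueError(f"unknown pileup dialect {dialect!r}")
    parse = _parse_tsv_pileup if dialect == "tsv" else _parse_mpileup
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield parse(line, lineno)


def write_pileup(columns: Iterable[PileupColumn], path) -> None:
    with open(path, "w") as fh:
        for c in columns:
            packed = ",".join(str(c.counts[b]) for b in BASES)
            fh.write(f"{c.ref_id}\t{c.pos}\t{c.ref_base}\t{c.depth}\t{packed}\t{_fmt(c.mqs)}\n")


# ---------------------------------------------------------------------------
# annotation


def read_annotation(path) -> dict[str, str]:
    """Two-column TSV ``ref_id  genic|nongenic`` -> mapping."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"annotation line {lineno}: expected 2 columns")
            rid, label = parts
            if label not in ("genic", "nongenic"):
                raise FormatError(f"annotation line {lineno}: bad label {label!r}")
            if rid in out and out[rid] != label:
                raise FormatError(f"annotation: conflicting labels for {rid}")
            out[rid] = label
    return out


def write_annotation(annotation: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for rid, label in annotation.items():
            fh.write(f"{rid}\t{label}\n")


# ---------------------------------------------------------------------------
# genotype matrix


@dataclass
class GenotypeMatrix:
    """Samples x markers grid of diploid calls AA/AB/BB/NA."""

    calls: pd.DataFrame  # index = samples, columns = markers, values = tokens

    def __post_init__(self) -> None:
        bad = set(np.unique(self.calls.to_numpy().astype(str))) - set(GENOTYPE_TOKENS)
        if bad:
            raise FormatError(f"genotype matrix: bad tokens {sorted(bad)}")

    @property
    def samples(self) -> list[str]:
        return list(self.calls.index)

    @property
    def markers(self) -> list[str]:
        return list(self.calls.columns)

    def marker(self, marker_id: str) -> pd.Series:
        return self.calls[marker_id]

    def sample(self, sample_id: str) -> pd.Series:
        return self.calls.loc[sample_id]


def read_genotypes(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    return GenotypeMatrix(df)


def write_genotypes(gm: GenotypeMatrix, path) -> None:
    gm.calls.to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# pedigree


@dataclass
class PedigreeTable:
    """Rows of (individual, sire, dam); UNKNOWN marks a missing parent."""

    rows: list[tuple[str, str, str]]
    parents: dict[str, tuple[str | None, str | None]] = field(init=False)

    def __post_init__(self) -> None:
        self.parents = {}
        for ind, sire, dam in self.rows:
            s = None if sire == UNKNOWN_PARENT else sire
            d = None if dam == UNKNOWN_PARENT else dam
            if ind in self.parents:
                raise FormatError(f"pedigree: duplicate individual {ind}")
            self.parents[ind] = (s, d)
        # implicit founders: parents never declared as individuals
        for s, d in list(self.parents.values()):
            for p in (s, d):
                if p is not None and p not in self.parents:
                    self.parents[p] = (None, None)
        self._check_acyclic()
        self._depth: dict[str, int] = {}

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(x: str, stack: list[str]) -> None:
            if state.get(x) == 1:
                return
            if state.get(x) == 0:
                raise FormatError(f"pedigree: cycle through {x} ({'->'.join(stack)})")
            state[x] = 0
            for p in self.parents[x]:
                if p is not None:
                    visit(p, stack + [p])
            state[x] = 1

        for ind in self.parents:
            visit(ind, [ind])

    def depth(self, x: str) -> int:
        """Generation depth: founders 0, else 1 + max parental depth."""
        if x not in self.parents:
            raise KeyError(f"pedigree: unknown individual {x}")
        if x in self._depth:
            return self._depth[x]
        s, d = self.parents[x]
        val = 0 if s is None and d is None else 1 + max(
            self.depth(p) for p in (s, d) if p is not None
        )
        self._depth[x] = val
        return val

    @property
    def individuals(self) -> list[str]:
        return list(self.parents)


def read_pedigree(path) -> PedigreeTable:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(f"pedigree line {lineno}: expected 3 columns")
            rows.append(tuple(parts))
    return PedigreeTable(rows)


def write_pedigree(ped: PedigreeTable, path) -> None:
    with open(path, "w") as fh:
        for ind, sire, dam in ped.rows:
            fh.write(f"{ind}\t{sire}\t{dam}\n")


# ---------------------------------------------------------------------------
# VCF


_INFO_KEYS = ("VF", "FVF", "RMD", "MQS", "REFQ", "ANN", "ITYPE", "PFALSE")

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=hetsnp
##INFO=<ID=VF,Number=1,Type=Float,Description="Variant frequency">
##INFO=<ID=FVF,Number=1,Type=Float,Description="Folded variant frequency">
##INFO=<ID=RMD,Number=1,Type=Integer,Description="Read mapping depth">
##INFO=<ID=MQS,Number=1,Type=Float,Description="Site mapping quality score">
##INFO=<ID=REFQ,Number=1,Type=Integer,Description="Reference base Phred quality at the site">
##INFO=<ID=ANN,Number=1,Type=String,Description="Reference annotation (genic/nongenic/unknown)">
##INFO=<ID=ITYPE,Number=1,Type=String,Description="Infinium assay type (I or II)">
##INFO=<ID=PFALSE,Number=1,Type=Float,Description="Predicted probability of being a false positive">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def _fmt(x: float) -> str:
    """Compact float formatting (0.5 -> '0.5', 25.0 -> '25')."""
    return f"{float(x):g}"


def write_vcf(snps, path) -> None:
    """Write candidate SNPs as minimal VCF 4.2.

    FILTER carries the first failing filter name, or PASS.  ALT lists the
    allele(s) differing from the reference base.
    """
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for s in snps:
            alts = [a for a in (s.allele1, s.allele2) if a != s.ref_base]
            info = [f"VF={_fmt(s.vf)}", f"FVF={_fmt(s.fvf)}", f"RMD={s.rmd}", f"MQS={_fmt(s.mqs)}"]
            if s.ref_base_quality is not None:
                info.append(f"REFQ={int(s.ref_base_quality)}")
            info.append(f"ANN={s.annotation}")
            if s.infinium_type is not None:
                info.append(f"ITYPE={s.infinium_type}")
            if s.pfalse is not None:
                info.append(f"PFALSE={_fmt(s.pfalse)}")
            filt = s.filter_flags[0] if s.filter_flags else "PASS"
            qual = "." if s.ref_base_quality is None else str(int(s.ref_base_quality))
            fh.write(
                f"{s.ref_id}\t{s.pos}\t.\t{s.ref_base}\t{','.join(alts) or '.'}\t"
                f"{qual}\t{filt}\t{';'.join(info)}\n"
            )


def read_vcf(path):
    """Read back a VCF written by :func:`write_vcf` (round-trip support)."""
    from .stacks import CandidateSNP  # local import to avoid a cycle

    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, _id, ref, alt, qual, filt, info = line.rstrip("\n").split("\t")
            kv = dict(item.split("=", 1) for item in info.split(";"))
            alts = [] if alt == "." else alt.split(",")
            if len(alts) == 2:
                a1, a2 = alts
            elif len(alts) == 1:
                a1, a2 = ref, alts[0]
            else:
                a1 = a2 = ref
            snp = CandidateSNP(
                ref_id=chrom,
                pos=int(pos),
                ref_base=ref,
                allele1=a1,
                allele2=a2,
                vf=float(kv["VF"]),
                fvf=float(kv["FVF"]),
                rmd=int(kv["RMD"]),
                mqs=float(kv["MQS"]),
                ref_base_quality=int(kv["REFQ"]) if "REFQ" in kv else None,
                annotation=kv.get("ANN", "unknown"),
                infinium_type=kv.get("ITYPE"),
                pfalse=float(kv["PFALSE"]) if "PFALSE" in kv else None,
                ref_error_inferred=ref not in (a1, a2),
            )
            if filt != "PASS":
                snp.filter_flags.append(filt)
            out.append(snp)
    return out
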