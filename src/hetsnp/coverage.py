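"""Sequencing arithmetic helpers."""

from __future__ import annotations


def genome_coverage(n_reads: int, read_length_bp: float, genome_size_bp: float) -> float:
    """Genome equivalents of sequence: n_reads * read_length / genome size.

    E.g. 395,528,231 reads of 50 bp over a 606 Mbp genome ~ 32.6x.
    """
    if genome_size_bp <= 0:
        raise ValueError("genome size must be positive")
    return n_reads * read_length_bp / genome_size_bp
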