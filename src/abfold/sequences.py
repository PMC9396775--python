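"""Fibonacci benchmark sequences and FASTA I/O for AB strings.

The benchmark family is built from S0 = "A", S1 = "B" by concatenation,
S_{k+1} = S_{k-1} + S_k, giving AB strings whose lengths and letter counts
are Fibonacci numbers (13-mer: 5 A / 8 B, ..., 55-mer: 21 A / 34 B).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, List, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import ABSequence, ValidationError

__all__ = [
    "fibonacci_sequence",
    "benchmark_sequences",
    "read_ab_fasta",
    "write_ab_fasta",
    "BENCHMARK_LENGTHS",
]

#: Chain lengths of the four standard benchmark sequences.
BENCHMARK_LENGTHS = (13, 21, 34, 55)


def fibonacci_sequence(target_length: int) -> ABSequence:
    """Generate the unique Fibonacci AB string of a given length.

    Raises :class:`ValidationError` if ``target_length`` is not a
    Fibonacci number, listing the nearby valid lengths.
    """
    if target_length < 1:
        raise ValidationError("target length must be a positive integer")
    prev, cur = "A", "B"
    lengths = [1]
    while len(cur) < target_length:
        prev, cur = cur, prev + cur
        lengths.append(len(cur))
    if len(prev) == target_length:
        cur = prev
    if len(cur) != target_length:
        raise ValidationError(
            f"{target_length} is not a Fibonacci length; valid lengths "
            f"include {sorted(set(lengths))} ..."
        )
    return ABSequence(cur, name=f"fib{target_length}")


def benchmark_sequences() -> List[ABSequence]:
    """The four standard benchmark sequences (lengths 13, 21, 34, 55)."""
    return [fibonacci_sequence(n) for n in BENCHMARK_LENGTHS]


def read_ab_fasta(path: Union[str, Path]) -> List[ABSequence]:
    """Read AB sequences from a FASTA file.

    Lowercase a/b is accepted and uppercased; any other character is
    rejected with the record id and 0-based position.
    """
    sequences = []
    for record in SeqIO.parse(str(path), "fasta"):
        raw = str(record.seq)
        for pos, ch in enumerate(raw):
            if ch.upper() not in "AB":
                raise ValidationError(
                    f"record {record.id!r}: invalid character {ch!r} "
                    f"at position {pos}"
                )
        sequences.append(ABSequence(raw, name=record.id))
    return sequences


def write_ab_fasta(sequences: Iterable[ABSequence], path: Union[str, Path]) -> None:
    """Write AB sequences as plain FASTA (one record per sequence)."""
    records = [
        SeqRecord(Seq(s.residues), id=s.name or f"seq{i}", description="")
        for i, s in enumerate(sequences)
    ]
    SeqIO.write(records, str(path), "fasta")
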