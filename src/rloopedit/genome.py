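"""Genome sequences: in-memory dict of contigs plus FASTA round-trip."""

from __future__ import annotations

from pathlib import Path

from pyfaidx import Fasta

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def contig_lengths(genome: dict[str, str]) -> dict[str, int]:
    return {name: len(seq) for name, seq in genome.items()}


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    fa = Fasta(str(path))  # writes a .fai index next to the file
    return {name: str(fa[name][:]).upper() for name in fa.keys()}
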