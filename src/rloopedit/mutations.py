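"""Point mutations and minimal VCF v4.2 I/O.

Mutations live in a DataFrame with columns ``contig``, ``position``
(0-based in memory; converted to 1-based only at the VCF boundary),
``ref``, ``alt`` and ``sample``.  This is the single place in the package
where the 1-based/0-based conversion happens.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pysam

MUTATION_COLUMNS = ["contig", "position", "ref", "alt", "sample"]
_BASES = {"A", "C", "G", "T"}


def validate_mutations(df: pd.DataFrame, genome: dict[str, str] | None = None) -> None:
    if not set(MUTATION_COLUMNS) <= set(df.columns):
        raise ValueError(f"mutation table needs columns {MUTATION_COLUMNS}")
    if len(df) == 0:
        return
    if not df["ref"].isin(_BASES).all() or not df["alt"].isin(_BASES).all():
        raise ValueError("ref/alt must be single bases in ACGT")
    if (df["ref"] == df["alt"]).any():
        raise ValueError("ref must differ from alt")
    if genome is not None:
        for row in df.itertuples(index=True):
            actual = genome[row.contig][row.position]
            if actual != row.ref:
                raise ValueError(
                    f"mutation {row.Index}: ref {row.ref} does not match genome "
                    f"base {actual} at {row.contig}:{row.position}"
                )


def write_vcf(df: pd.DataFrame, path: str | Path, contig_lengths: dict[str, int]) -> None:
    """Write mutations as minimal VCF v4.2 (positions converted to 1-based)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample label">\n')
        for contig, length in contig_lengths.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        if len(df):
            ordered = df.sort_values(["contig", "position"], kind="stable")
            for row in ordered.itertuples(index=False):
                fh.write(
                    f"{row.contig}\t{row.position + 1}\t.\t{row.ref}\t{row.alt}"
                    f"\t.\t.\tSAMPLE={row.sample}\n"
                )


def read_vcf(path: str | Path) -> pd.DataFrame:
    """Read a VCF of SNVs back into the 0-based in-memory representation."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            sample = rec.info.get("SAMPLE", ".")
            for alt in rec.alts or ():
                rows.append((rec.contig, rec.pos - 1, rec.ref, alt, sample))
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS)
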