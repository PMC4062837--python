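"""FASTA reading/writing helpers shared by the CLI subcommands."""

from __future__ import annotations

from typing import Mapping

from pyfaidx import Fasta

__all__ = ["read_fasta", "write_fasta"]

FASTA_WIDTH = 60


def read_fasta(path: str) -> dict[str, str]:
    """Load all sequences into memory, uppercased."""
    with Fasta(path) as fa:
        return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(sequences: Mapping[str, str], path: str, comment: str = "") -> None:
    """Write sequences at fixed line width; ``comment`` lands in each header."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            suffix = f" {comment}" if comment else ""
            fh.write(f">{name}{suffix}\n")
            for i in range(0, len(seq), FASTA_WIDTH):
                fh.write(seq[i : i + FASTA_WIDTH] + "\n")
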