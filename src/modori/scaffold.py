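"""Scaffold sequences: FASTA I/O and a synthetic M13-length generator.

The design engine only needs a scaffold *sequence* to assign staple strings;
none of the staple counts or replacement statistics depend on what the
sequence actually is.  The default scaffold here is therefore a synthetic,
seeded 7,249-nt random sequence standing in for M13mp18 (same length,
balanced composition).  Real scaffolds can be supplied as FASTA.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: length of the M13mp18 single-stranded scaffold in nucleotides
M13_LENGTH = 7249

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def synthetic_scaffold(length: int = M13_LENGTH, seed: int = 2017) -> str:
    """Seeded synthetic scaffold sequence (stand-in for M13mp18).

    Deterministic for a given ``(length, seed)``.
    """
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_scaffold_fasta(path: str | Path) -> str:
    """First record of a FASTA file, uppercased."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()


def write_scaffold_fasta(path: str | Path, sequence: str,
                         name: str = "synthetic_scaffold") -> None:
    SeqIO.write([SeqRecord(Seq(sequence), id=name, description="")],
                str(path), "fasta")
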