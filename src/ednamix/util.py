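"""Small shared sequence/IO helpers used across the pipeline."""

from __future__ import annotations

import numpy as np

DNA = "ACGT"
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def is_transversion(a: str, b: str) -> bool:
    """True if {a, b} is a purine<->pyrimidine pair."""
    return (a in PURINES) != (b in PURINES)


def seq_to_array(seq: str) -> np.ndarray:
    """Byte view of a sequence for vectorised comparison."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(DNA), size=length))


def write_fasta(path, records) -> None:
    """records: iterable of (name, sequence)."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_fasta(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]


def write_fastq(path, records, quality_char: str = "I") -> None:
    """records: iterable of (name, sequence); constant base quality."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_fastq(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fastq")]
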