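"""Small sequence helpers shared across the pipeline.

All in-memory analysis uses the RNA alphabet {A, C, G, U}; DNA input (T) is
mapped to U at the boundary.  FASTA/FASTQ files on disk use the DNA alphabet,
as sequencers and genome releases do.
"""

from __future__ import annotations

import numpy as np

RNA_ALPHABET = "ACGU"

_RNA_COMP = str.maketrans("ACGU", "UGCA")
_TO_RNA = str.maketrans("Tt", "Uu")
_TO_DNA = str.maketrans("Uu", "Tt")

# integer codes for vectorised work: A=0 C=1 G=2 U=3
_CODE = np.full(128, -1, dtype=np.int8)
for _i, _c in enumerate(RNA_ALPHABET):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i
_CODE[ord("T")] = 3
_CODE[ord("t")] = 3


def to_rna(seq: str) -> str:
    """Uppercase and map T->U."""
    return seq.upper().translate(_TO_RNA)


def to_dna(seq: str) -> str:
    """Uppercase and map U->T (for writing FASTA/FASTQ)."""
    return seq.upper().translate(_TO_DNA)


def revcomp(seq: str) -> str:
    """Reverse complement in the RNA alphabet."""
    return to_rna(seq).translate(_RNA_COMP)[::-1]


def complement(seq: str) -> str:
    return to_rna(seq).translate(_RNA_COMP)


def encode(seq: str) -> np.ndarray:
    """Encode an RNA/DNA string as int8 codes A=0 C=1 G=2 U/T=3.

    Raises ValueError on any other character.
    """
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        bad = seq[int(np.argmax(arr < 0))]
        raise ValueError(f"non-RNA character {bad!r} in sequence")
    return arr


def is_rna(seq: str) -> bool:
    return all(c in RNA_ALPHABET for c in seq)


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(RNA_ALPHABET[i] for i in rng.integers(0, 4, size=length))


# Watson-Crick / wobble pair values used by the internal energy model,
# in units of -0.5 kcal/mol per pair-half: GC=3, AU=2, GU=1, 0 = no pair.
PAIR_VALUE = np.zeros((4, 4), dtype=np.int32)
for _a, _b, _v in [("G", "C", 3), ("A", "U", 2), ("G", "U", 1)]:
    PAIR_VALUE[RNA_ALPHABET.index(_a), RNA_ALPHABET.index(_b)] = _v
    PAIR_VALUE[RNA_ALPHABET.index(_b), RNA_ALPHABET.index(_a)] = _v


def pair_value(a: str, b: str) -> int:
    """3 for G:C, 2 for A:U, 1 for G:U wobble, 0 if the bases cannot pair."""
    return int(PAIR_VALUE[RNA_ALPHABET.index(a), RNA_ALPHABET.index(b)])


def read_fasta(text: str) -> dict[str, str]:
    """FASTA text -> {id: RNA sequence} (T mapped to U)."""
    from io import StringIO

    from Bio import SeqIO

    return {rec.id: to_rna(str(rec.seq)) for rec in SeqIO.parse(StringIO(text), "fasta")}
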