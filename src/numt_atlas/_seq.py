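"""Low-level sequence helpers shared across modules.

Sequences are handled as plain upper-case strings at module boundaries and
as uint8 arrays (A=0, G=1, C=2, T=3) internally, an encoding chosen so that
``code ^ 1`` is the transition partner and ``code ^ 2`` / ``code ^ 3`` the
two transversion partners.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "AGCT"
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_DECODE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)

_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string to uint8 codes; non-ACGT raises."""
    arr = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        bad = set(seq) - set("ACGTacgt")
        raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)}")
    return arr


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode()


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def wrap_fasta(name: str, seq: str, width: int = 60) -> str:
    lines = [f">{name}"]
    for i in range(0, len(seq), width):
        lines.append(seq[i : i + width])
    return "\n".join(lines) + "\n"


def write_fasta(path, records, width: int = 60) -> None:
    """Write (name, seq) pairs as wrapped FASTA."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(wrap_fasta(name, seq, width))


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an ordered {name: sequence} dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
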