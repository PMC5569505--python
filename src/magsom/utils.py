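"""Small shared helpers: seeded substreams, sequence utilities."""

from __future__ import annotations

import zlib

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: byte value -> 2-bit base code (A=0, C=1, G=2, T=3), 255 for anything else
BASE_CODES = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    BASE_CODES[_b] = _i
    BASE_CODES[_b + 32] = _i  # lower case

CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random substream derived from one top-level seed.

    Stages (genome/fragment/read/annotation/...) each draw from their own
    stream so regenerating one stage never perturbs another.
    """
    key = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """GC content as a fraction of ACGT bases (ambiguous symbols ignored)."""
    codes = encode_sequence(seq)
    valid = codes < 4
    n = int(valid.sum())
    if n == 0:
        return 0.0
    gc = int(((codes == 1) | (codes == 2)).sum())
    return gc / n


def encode_sequence(seq: str) -> np.ndarray:
    """Sequence string -> uint8 codes (A=0,C=1,G=2,T=3; 255 = non-ACGT)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return BASE_CODES[raw]


def decode_sequence(codes: np.ndarray) -> str:
    return CODE_TO_BASE[codes].tobytes().decode("ascii")
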