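"""Tetranucleotide-frequency (TNF) profiles of scaffolds.

The compositional signature used for binning: all overlapping 4-mers of a
sequence, counted with a reverse-complement fold so the signature is
independent of assembly strand. Folding the 256 tetramers with their
reverse complements leaves 136 canonical classes (16 palindromes plus 120
merged pairs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .utils import encode_sequence

N_CANONICAL = 136
N_RAW = 256


def _build_canonical_index() -> tuple[np.ndarray, list[str]]:
    bases = "ACGT"
    comp = {0: 3, 1: 2, 2: 1, 3: 0}

    def revcomp_code(code: int) -> int:
        digits = [(code >> (2 * i)) & 3 for i in range(4)]  # low digit = last base
        # digits[0] is the 4th base; reverse complement reverses order and complements
        rc = 0
        for d in digits:  # last base first -> already reversed
            rc = rc * 4 + comp[d]
        return rc

    canon = np.array([min(c, revcomp_code(c)) for c in range(256)])
    classes = sorted(set(int(c) for c in canon))
    index_of = {c: i for i, c in enumerate(classes)}
    idx = np.array([index_of[int(c)] for c in canon])

    def decode(code: int) -> str:
        return "".join(bases[(code >> (2 * (3 - i))) & 3] for i in range(4))

    return idx, [decode(c) for c in classes]


#: map raw 4-mer code -> canonical class index (0..135)
CANONICAL_INDEX, CANONICAL_KMERS = _build_canonical_index()


class EmptyProfileError(ValueError):
    """Raised when a sequence has no valid (all-ACGT) 4-mer window."""


@dataclass
class TNFVector:
    scaffold_id: str
    window_index: int
    values: np.ndarray  # length 136 (canonical) or 256 (raw), sums to 1
    n_windows: int  # span of the window in bases


def tetranucleotide_frequencies(sequence: str, canonical: bool = True) -> np.ndarray:
    """Normalized 4-mer frequencies of a sequence.

    Counts every overlapping 4-mer (positions 0..L-4); windows containing
    a non-ACGT symbol are skipped. Raises :class:`EmptyProfileError` if no
    valid window exists, rather than returning silent zeros.
    """
    if len(sequence) < 4:
        raise EmptyProfileError(f"sequence of length {len(sequence)} has no 4-mer window")
    codes = encode_sequence(sequence).astype(np.int32)
    valid = codes < 4
    ok = valid[:-3] & valid[1:-2] & valid[2:-1] & valid[3:]
    n_valid = int(ok.sum())
    if n_valid == 0:
        raise EmptyProfileError("no 4-mer window free of ambiguous bases")
    kmers = (codes[:-3] << 6) | (codes[1:-2] << 4) | (codes[2:-1] << 2) | codes[3:]
    counts = np.bincount(kmers[ok], minlength=N_RAW).astype(float)
    if canonical:
        counts = np.bincount(CANONICAL_INDEX, weights=counts, minlength=N_CANONICAL)
    return counts / n_valid


def window_profiles(
    scaffold_id: str,
    sequence: str,
    window_len: int = 10_000,
    min_scaffold_len: int = 5000,
    canonical: bool = True,
) -> list[TNFVector]:
    """Non-overlapping window profiles of one scaffold.

    Scaffolds no longer than ``window_len`` yield a single profile; longer
    scaffolds are split into ``window_len`` windows, with a final partial
    window shorter than ``window_len / 2`` merged into the previous one.
    Scaffolds below ``min_scaffold_len`` are outside the binning gate and
    rejected here.
    """
    n = len(sequence)
    if n < min_scaffold_len:
        raise ValueError(
            f"scaffold {scaffold_id} is {n} bp, below the {min_scaffold_len} bp binning gate"
        )
    if n <= window_len:
        bounds = [(0, n)]
    else:
        n_full, rem = divmod(n, window_len)
        bounds = [(i * window_len, (i + 1) * window_len) for i in range(n_full)]
        if rem >= window_len / 2:
            bounds.append((n_full * window_len, n))
        else:
            bounds[-1] = (bounds[-1][0], n)
    out = []
    for w, (a, b) in enumerate(bounds):
        vec = tetranucleotide_frequencies(sequence[a:b], canonical=canonical)
        out.append(TNFVector(scaffold_id, w, vec, b - a))
    return out


def profile_scaffolds(
    scaffolds: dict[str, str],
    window_len: int = 10_000,
    min_scaffold_len: int = 5000,
    canonical: bool = True,
) -> tuple[list[TNFVector], list[str]]:
    """Profile every scaffold passing the length gate.

    Returns (profiles, excluded scaffold ids). Scaffolds whose windows are
    all ambiguous are excluded and reported rather than failing the run.
    """
    profiles: list[TNFVector] = []
    excluded: list[str] = []
    for sid in sorted(scaffolds):
        seq = scaffolds[sid]
        if len(seq) < min_scaffold_len:
            excluded.append(sid)
            continue
        try:
            profiles.extend(window_profiles(sid, seq, window_len, min_scaffold_len, canonical))
        except EmptyProfileError:
            excluded.append(sid)
    return profiles, excluded
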