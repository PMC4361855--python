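"""Sequence-level genome statistics.

Linear *Streptomyces* chromosomes carry terminal inverted repeats (TIRs):
the chromosome start matches the reverse complement of the chromosome end.
This module detects the maximal TIR by ungapped position-wise comparison,
and computes GC content and windowed GC skew ((G-C)/(G+C)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple, Union

import numpy as np

from .dtypes import GenomeSequence, reverse_complement

#: consecutive-mismatch run that terminates the TIR scan early
_TIR_STOP_RUN = 100


@dataclass(frozen=True)
class TirResult:
    """Maximal terminal inverted repeat of a linear chromosome."""

    length: int
    mismatch_count: int
    gc_of_tir: float  # percent GC over the 5' copy; 0.0 when length == 0


def _seq(seq: Union[str, GenomeSequence]) -> str:
    return seq.sequence if isinstance(seq, GenomeSequence) else seq


def gc_content(seq: Union[str, GenomeSequence]) -> float:
    """Percent G+C over called bases (N excluded), one decimal.

    Raises on an empty or all-N sequence, where the quantity is undefined.
    """
    s = _seq(seq)
    g = s.count("G")
    c = s.count("C")
    called = g + c + s.count("A") + s.count("T")
    if called == 0:
        raise ValueError("GC content undefined: no called bases")
    return round(100.0 * (g + c) / called, 1)


def gc_skew(
    seq: Union[str, GenomeSequence],
    window_bp: int,
    step_bp: int | None = None,
) -> List[Tuple[int, float, bool]]:
    """Windowed GC skew (G-C)/(G+C).

    Returns one ``(window_start, skew, defined)`` triple per window
    (1-based start).  Windows with G+C = 0 emit skew 0.0 with
    ``defined=False``.
    """
    s = _seq(seq)
    if window_bp > len(s):
        raise ValueError("window longer than sequence")
    step = step_bp or window_bp
    out: List[Tuple[int, float, bool]] = []
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    is_g = (arr == ord("G")).astype(np.int64)
    is_c = (arr == ord("C")).astype(np.int64)
    cg = np.concatenate([[0], np.cumsum(is_g)])
    cc = np.concatenate([[0], np.cumsum(is_c)])
    for start in range(0, len(s) - window_bp + 1, step):
        g = int(cg[start + window_bp] - cg[start])
        c = int(cc[start + window_bp] - cc[start])
        if g + c == 0:
            out.append((start + 1, 0.0, False))
        else:
            out.append((start + 1, (g - c) / (g + c), True))
    return out


def detect_tir(
    seq: Union[str, GenomeSequence],
    min_len: int = 0,
    max_mismatch_rate: float = 0.01,
) -> TirResult:
    """Detect the maximal terminal inverted repeat of a linear genome.

    The prefix is compared position-by-position against the reverse
    complement of the suffix; the reported length is the largest L whose
    running mismatch fraction stays within ``max_mismatch_rate``.  The scan
    stops greedily after a run of consecutive mismatches (the repeat has
    clearly ended); length 0 is a valid result.
    """
    s = _seq(seq)
    rc = reverse_complement(s)
    limit = len(s) // 2
    best_len = 0
    best_mm = 0
    mismatches = 0
    run = 0
    for i in range(limit):
        if s[i] == rc[i]:
            run = 0
        else:
            mismatches += 1
            run += 1
            if run >= _TIR_STOP_RUN:
                break
        if mismatches <= max_mismatch_rate * (i + 1):
            best_len = i + 1
            best_mm = mismatches
    if best_len < min_len:
        return TirResult(length=0, mismatch_count=0, gc_of_tir=0.0)
    gc = gc_content(s[:best_len]) if best_len else 0.0
    return TirResult(length=best_len, mismatch_count=best_mm, gc_of_tir=gc)
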