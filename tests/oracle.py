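"""Independent brute-force oracle for the MATCH-style scoring scheme.

Pure-Python, written directly from the scoring formulas, deliberately sharing
no code with the package: frequencies with pseudocount, per-position
information weights, min-max normalised similarity, leftmost maximal 5-window
core, exhaustive enumeration of all offsets and orientations.
"""

import math

_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def oracle_prepare(counts, pseudocount):
    """(freqs, info, core_start) from a list-of-rows count matrix."""
    freqs = []
    for row in counts:
        total = sum(row) + 4.0 * pseudocount
        freqs.append([(c + pseudocount) / total for c in row])
    info = []
    for row in freqs:
        info.append(sum(f * math.log(4.0 * f) for f in row if f > 0.0))
    info = [max(v, 0.0) for v in info]
    sums = [sum(info[i : i + 5]) for i in range(len(info) - 4)]
    core_start = sums.index(max(sums))
    return freqs, info, core_start


def _similarity(freqs, info, window):
    cur = sum(i * f[_IDX[b]] for i, f, b in zip(info, freqs, window))
    lo = sum(i * min(f) for i, f in zip(info, freqs))
    hi = sum(i * max(f) for i, f in zip(info, freqs))
    if hi == lo:
        return 1.0
    return (cur - lo) / (hi - lo)


def oracle_score(counts, pseudocount, window):
    """(core_score, matrix_score) of one window, brute force."""
    freqs, info, core_start = oracle_prepare(counts, pseudocount)
    core = slice(core_start, core_start + 5)
    core_score = _similarity(freqs[core], info[core], window[core])
    matrix_score = _similarity(freqs, info, window)
    return core_score, matrix_score


def _revcomp(seq):
    return "".join(_COMP[b] for b in reversed(seq))


def oracle_scan(counts, pseudocount, seq, orientations=("forward", "reverse")):
    """Score every (offset, orientation) window of ``seq`` exhaustively.

    Returns {(offset, orientation): (core_score, matrix_score)}. The matrix is
    prepared once; every window is then scored by the same formulas as
    :func:`oracle_score`.
    """
    width = len(counts)
    freqs, info, core_start = oracle_prepare(counts, pseudocount)
    core = slice(core_start, core_start + 5)
    out = {}
    for offset in range(len(seq) - width + 1):
        window = seq[offset : offset + width]
        for orientation in orientations:
            scanned = window if orientation == "forward" else _revcomp(window)
            out[(offset, orientation)] = (
                _similarity(freqs[core], info[core], scanned[core]),
                _similarity(freqs, info, scanned),
            )
    return out
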