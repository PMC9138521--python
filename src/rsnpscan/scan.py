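"""MATCH-style PWM scanning with core and matrix similarity scores.

The scoring scheme follows the published MATCH method. Count matrices are
regularised with a pseudocount and converted to per-position base frequencies

    f(i, b) = (counts(i, b) + p) / (sum_b counts(i, b) + 4 p),

each position is weighted by its information content

    I(i) = sum_b f(i, b) * ln(4 f(i, b))   (0 for a uniform position, up to ln 4),

and a window w of the matrix width is scored by min-max normalising the
information-weighted frequency sum:

    matrix_score = (Current - Min) / (Max - Min),
    Current = sum_i I(i) f(i, w_i),
    Min/Max = sum_i I(i) min_b/max_b f(i, b).

The core similarity score is the same quantity restricted to the five
consecutive most-conserved positions (highest summed information; leftmost on
ties, unless the library annotates a core start). A window is reported as a
binding-site match only if it passes both the core and the matrix cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .types import NUCLEOTIDES, Pwm, TfbsMatch, revcomp

#: pseudocount added per base before frequency conversion
DEFAULT_PSEUDOCOUNT = 0.8
CORE_LENGTH = 5
ORIENTATIONS = ("forward", "reverse")

_BASE_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}


@dataclass(frozen=True)
class ScoredPwm:
    """A PWM prepared for scanning: regularised frequencies, information
    weights, core window, and precomputed min/max normalisation terms."""

    pwm: Pwm
    freqs: np.ndarray  # width x 4, rows sum to 1
    info: np.ndarray  # width, >= 0
    core_start: int

    @property
    def width(self) -> int:
        return self.pwm.width

    @property
    def core_slice(self) -> slice:
        return slice(self.core_start, self.core_start + CORE_LENGTH)


def prepare(pwm: Pwm, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> ScoredPwm:
    """Regularise a count matrix and locate its 5-position core.

    The core is the 5-window of consecutive positions with maximal summed
    information, leftmost on ties; an annotated ``pwm.core_start`` overrides
    the computation.
    """
    if pseudocount <= 0 and np.any(pwm.counts.sum(axis=1) == 0):
        raise ValueError(
            f"{pwm.pwm_id}: all-zero count row requires a positive pseudocount"
        )
    totals = pwm.counts.sum(axis=1, keepdims=True) + 4.0 * pseudocount
    freqs = (pwm.counts + pseudocount) / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(freqs > 0, freqs * np.log(4.0 * freqs), 0.0)
    info = terms.sum(axis=1)
    # numerical floor: a uniform row gives exactly 0, tiny negatives are noise
    info = np.maximum(info, 0.0)
    if pwm.core_start is not None:
        core_start = pwm.core_start
    else:
        window_sums = np.convolve(info, np.ones(CORE_LENGTH), mode="valid")
        core_start = int(np.argmax(window_sums))  # argmax is leftmost on ties
    return ScoredPwm(pwm=pwm, freqs=freqs, info=info, core_start=core_start)


def _similarity(freqs: np.ndarray, info: np.ndarray, idx: np.ndarray) -> float:
    current = float(np.sum(info * freqs[np.arange(len(idx)), idx]))
    lo = float(np.sum(info * freqs.min(axis=1)))
    hi = float(np.sum(info * freqs.max(axis=1)))
    if hi == lo:  # fully uninformative matrix: every window matches equally
        return 1.0
    return (current - lo) / (hi - lo)


def score_window(spwm: ScoredPwm, window: str) -> tuple[float, float]:
    """(core_score, matrix_score) of one width-length window, both in [0, 1]."""
    if len(window) != spwm.width:
        raise ValueError(
            f"{spwm.pwm.pwm_id}: window length {len(window)} != matrix width {spwm.width}"
        )
    idx = np.fromiter((_BASE_INDEX[b] for b in window), dtype=int, count=len(window))
    core = spwm.core_slice
    core_score = _similarity(spwm.freqs[core], spwm.info[core], idx[core])
    matrix_score = _similarity(spwm.freqs, spwm.info, idx)
    return core_score, matrix_score


def _format_site(spwm: ScoredPwm, window: str) -> str:
    """Matched site with core positions upper-case, flanks lower-case."""
    core = spwm.core_slice
    return window[: core.start].lower() + window[core] + window[core.stop :].lower()


def scan_sequence(
    spwm: ScoredPwm,
    seq: str,
    orientations: Sequence[str] = ORIENTATIONS,
) -> list[TfbsMatch]:
    """Score every window of ``seq`` in the requested orientations and return
    the matches passing both cutoffs.

    Reverse-orientation windows are reverse-complemented before scoring;
    their offsets are still reported in the coordinates of ``seq`` and their
    ``site_seq`` shows the sequence as aligned to the matrix.
    """
    unknown = set(orientations) - set(ORIENTATIONS)
    if unknown:
        raise ValueError(f"unknown orientations: {sorted(unknown)}")
    w = spwm.width
    matches: list[TfbsMatch] = []
    for offset in range(len(seq) - w + 1):
        window = seq[offset : offset + w]
        for orientation in orientations:
            scanned = window if orientation == "forward" else revcomp(window)
            core_score, matrix_score = score_window(spwm, scanned)
            if core_score >= spwm.pwm.core_cutoff and matrix_score >= spwm.pwm.matrix_cutoff:
                matches.append(
                    TfbsMatch(
                        pwm_id=spwm.pwm.pwm_id,
                        seq_offset=offset,
                        orientation=orientation,
                        core_score=core_score,
                        matrix_score=matrix_score,
                        site_seq=_format_site(spwm, scanned),
                    )
                )
    return matches


def scan_library(
    spwms: Iterable[ScoredPwm],
    seq: str,
    orientations: Sequence[str] = ORIENTATIONS,
) -> list[TfbsMatch]:
    """Scan one sequence against every prepared matrix in a library."""
    matches: list[TfbsMatch] = []
    for spwm in spwms:
        matches.extend(scan_sequence(spwm, seq, orientations))
    return matches
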