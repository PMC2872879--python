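"""Benchmark bookkeeping: success calls against a literature consensus."""

from __future__ import annotations

import math
from typing import Sequence, Tuple

from .postprocess import Pssm, harbison_similarity


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def success_rates(tp: int, fn: int, tn: int, fp: int) -> Tuple[int, int]:
    """(TP rate, FP rate) as integer percents, half rounded away from zero."""
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("zero denominator in rate computation")
    tp_rate = _round_half_away(100.0 * tp / (tp + fn))
    fp_rate = _round_half_away(100.0 * fp / (fp + tn))
    return tp_rate, fp_rate


def evaluate_success(
    predictions: Sequence[Pssm],
    literature: Pssm,
    cutoff: float = 0.75,
    top_n: int = 1,
    *,
    mode: str = "dna",
) -> bool:
    """True iff any of the first ``top_n`` predictions matches the known
    consensus at the similarity cutoff."""
    if not predictions:
        raise ValueError("no predictions to evaluate")
    for pssm in list(predictions)[:top_n]:
        if harbison_similarity(pssm, literature, mode=mode) >= cutoff:
            return True
    return False
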