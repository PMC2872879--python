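"""Per-region evidence of regulation.

Raw experimental measurements (ChIP-chip binding P-values, ChIP-seq peak
densities, expression fold-changes) are transformed into a common log-odds
style evidence score e_j per region.  The search objective is invariant to
positive affine rescaling of the evidence vector, so the log base affects
only the absolute numbers in reports, not motif rankings.

P-values are calibrated into approximate Bayes factors through the
closed-form upper bound B10(p) = 1/(-e * p * ln p) for p < 1/e (clamped to
1 otherwise), which avoids the "P-value fallacy" of reading 1/p as an odds
ratio: at p = 0.001 the bound gives odds of about 53, not 1000.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

EVIDENCE_TYPES = ("chip_pvalue", "chipseq_score", "log_fold_change", "raw")


@dataclass
class EvidenceSet:
    """Evidence vector aligned with a region set.

    ``values`` holds the transformed evidence e_1..e_d; ``raw`` retains the
    untransformed measurements when a transform was applied.
    """

    ids: list
    values: np.ndarray
    evidence_type: str = "raw"
    raw: Optional[np.ndarray] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.ids) != self.values.size:
            raise ValueError(
                f"{len(self.ids)} ids vs {self.values.size} evidence values"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("evidence values must all be finite")
        if self.evidence_type not in EVIDENCE_TYPES:
            raise ValueError(f"unknown evidence type {self.evidence_type!r}")

    def __len__(self) -> int:
        return self.values.size

    def value_map(self) -> dict:
        return dict(zip(self.ids, self.values.tolist()))

    def reordered(self, ids: Sequence[str]) -> "EvidenceSet":
        """Evidence restricted/reordered to the given region ids."""
        lookup = {rid: i for i, rid in enumerate(self.ids)}
        missing = [rid for rid in ids if rid not in lookup]
        if missing:
            raise KeyError(
                f"{len(missing)} region ids lack evidence (first: {missing[:5]})"
            )
        sel = [lookup[rid] for rid in ids]
        return EvidenceSet(
            ids=list(ids),
            values=self.values[sel],
            evidence_type=self.evidence_type,
            raw=None if self.raw is None else np.asarray(self.raw)[sel],
        )


def pvalue_to_evidence(p, *, floor: float = 1e-300, neglog: bool = False):
    """Log approximate Bayes factor for a binding P-value.

    Returns ln(B10(p)) with B10(p) = 1/(-e * p * ln p) for p < 1/e; for
    p >= 1/e the bound is clamped to 1 so the evidence is 0 (no support over
    the null).  Monotone non-increasing in p.  ``neglog`` switches to the
    naive e = -ln p for comparison runs.  Scalar in, scalar out.
    """
    scalar = np.isscalar(p)
    arr = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("P-values must lie in (0, 1]")
    if np.any(arr == 0):
        warnings.warn(f"P-value of 0 floored at {floor}", stacklevel=2)
        arr = np.maximum(arr, floor)
    if neglog:
        out = -np.log(arr)
    else:
        bound = -math.e * arr * np.log(arr)  # = 1 / B10(p), valid for p < 1/e
        with np.errstate(divide="ignore"):
            out = np.where(arr < 1.0 / math.e, -np.log(bound), 0.0)
    return float(out[0]) if scalar else out


def bayes_factor_bound(p: float) -> float:
    """The calibration bound -e * p * ln p itself (reciprocal of B10)."""
    if not 0 < p < 1.0 / math.e:
        raise ValueError("bound is defined for 0 < p < 1/e")
    return -math.e * p * math.log(p)


def pvalue_evidence_set(ids, pvalues, **kwargs) -> EvidenceSet:
    raw = np.asarray(pvalues, dtype=float)
    return EvidenceSet(
        ids=list(ids),
        values=np.asarray(pvalue_to_evidence(raw, **kwargs)),
        evidence_type="chip_pvalue",
        raw=raw,
    )


def chipseq_evidence(
    kde_max: Mapping[str, float], background_percentile: float = 85.0
) -> EvidenceSet:
    """Log-odds of per-region peak density against a background level.

    ``kde_max`` maps region id to the maximum kernel-density score observed
    anywhere in the region.  The background b is the given percentile
    (linear-interpolation method) of the strictly positive scores; zero
    scores are floored at smallest-positive x 1e-3 before the log ratio
    e_j = ln(score_j / b).
    """
    ids = list(kde_max.keys())
    scores = np.asarray([kde_max[i] for i in ids], dtype=float)
    if np.any(scores < 0):
        raise ValueError("kernel density scores must be >= 0")
    positive = scores[scores > 0]
    if positive.size == 0:
        raise ValueError("all kernel density scores are zero")
    b = float(np.percentile(positive, background_percentile))
    floor = float(positive.min()) * 1e-3
    values = np.log(np.maximum(scores, floor) / b)
    return EvidenceSet(ids=ids, values=values, evidence_type="chipseq_score", raw=scores)


def expression_evidence(x_before, x_after, *, downregulation_positive: bool = True):
    """Evidence from an expression fold-change, e = -log2(after/before).

    Down-regulation upon induction of the regulator (e.g. a transfected
    miRNA) yields positive evidence under the default sign convention;
    ``downregulation_positive=False`` flips it for activator studies.
    """
    before = np.asarray(x_before, dtype=float)
    after = np.asarray(x_after, dtype=float)
    if np.any(before <= 0) or np.any(after <= 0):
        bad = np.nonzero((np.atleast_1d(before) <= 0) | (np.atleast_1d(after) <= 0))[0]
        raise ValueError(f"non-positive expression value at index {bad[:5].tolist()}")
    e = -np.log2(after / before)
    if not downregulation_positive:
        e = -e
    return float(e) if np.isscalar(x_before) and np.isscalar(x_after) else e


def make_evidence(
    ids, raw_values, evidence_type: str, *, downregulation_positive: bool = True, **kwargs
) -> EvidenceSet:
    """Dispatch a raw two-column evidence table to the right transform.

    ``log_fold_change`` values are assumed to already be log2(after/before)
    ratios; the sign convention of :func:`expression_evidence` is applied.
    """
    raw = np.asarray(raw_values, dtype=float)
    if evidence_type == "chip_pvalue":
        return pvalue_evidence_set(ids, raw, **kwargs)
    if evidence_type == "chipseq_score":
        return chipseq_evidence(dict(zip(ids, raw)), **kwargs)
    if evidence_type == "log_fold_change":
        values = -raw if downregulation_positive else raw.copy()
        return EvidenceSet(ids=list(ids), values=values, evidence_type=evidence_type, raw=raw)
    if evidence_type == "raw":
        return EvidenceSet(ids=list(ids), values=raw, evidence_type="raw", raw=raw)
    raise ValueError(f"unknown evidence type {evidence_type!r}")
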