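"""DNA-fragmentation intactness model.

If all DNA were cut into pieces of exactly S bp, a target of length L bp
survives intact (is wholly contained in one piece) with probability

    I(S, L) = (S - L + 1) / S   if S >= L,   else 0.

This module exposes the closed form, the amplicon-length bias ratio it
implies (full-length vs partial target), its closed-form inverse for
estimating an effective fragment size from an observed intact fraction,
and a copy-number-aware predictor of amplicon relative abundances.

A target is "intact" iff no cut falls strictly inside it, which gives
S - L + 1 valid start positions per piece; circularity is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .abundance import AbundanceTable
from .errors import DataError

#: Default full-length and partial (V4-like) amplicon target lengths, bp.
FULL_LENGTH_TARGET = 1500
PARTIAL_TARGET = 300


@dataclass
class FragmentationParams:
    """Bundle of the model symbols for reporting.

    ``n`` is the implied number of pieces for a genome of ``total_length``;
    it is informational and not used in any computation.
    """

    S: float
    L: int
    I: float
    n: int | None = None

    @classmethod
    def from_size(cls, S: float, L: int, total_length: int | None = None) -> "FragmentationParams":
        n = int(round(total_length / S)) if total_length else None
        return cls(S=S, L=L, I=intact_fraction(S, L), n=n)


@dataclass
class SpeciesBiasSpec:
    """Per-species inputs for amplicon abundance prediction."""

    species: str
    S: float  # effective uniform fragment size, bp
    true_abundance: float
    copy_number: int = 1

    def __post_init__(self) -> None:
        if self.S <= 0:
            raise DataError(f"{self.species}: fragment size must be positive, got {self.S}")
        if self.true_abundance < 0:
            raise DataError(f"{self.species}: negative true abundance")
        if self.copy_number < 1:
            raise DataError(f"{self.species}: copy number must be a positive integer")


def intact_fraction(S: float, L: float) -> float:
    """Fraction of length-L targets left intact at uniform fragment size S."""
    if S < 1 or L < 1:
        raise DataError(f"S and L must be >= 1, got S={S}, L={L}")
    if S < L:
        return 0.0
    return (S - L + 1) / S


def amplicon_bias_ratio(
    S: float,
    L_full: float = FULL_LENGTH_TARGET,
    L_partial: float = PARTIAL_TARGET,
) -> float | None:
    """I(S, L_full) / I(S, L_partial): how much a full-length amplicon is
    disfavoured relative to a partial one at fragment size S.

    Monotone increasing in S, approaching 1 for S >> L_full.  Returns
    ``None`` (undefined) when even the partial target cannot survive
    (I(S, L_partial) = 0).
    """
    if L_full < L_partial:
        raise DataError(f"L_full {L_full} must be >= L_partial {L_partial}")
    denom = intact_fraction(S, L_partial)
    if denom == 0.0:
        return None
    return intact_fraction(S, L_full) / denom


def infer_effective_fragment_size(I_observed: float, L: float) -> float:
    """Closed-form inverse of :func:`intact_fraction`: S = (L - 1)/(1 - I).

    Valid for 0 < I < 1.  I = 0 only bounds S below L; I >= 1 implies an
    unfragmented (infinite-S) template.  Both raise.
    """
    if L < 1:
        raise DataError(f"L must be >= 1, got {L}")
    if I_observed >= 1:
        raise DataError(
            f"intact fraction {I_observed} >= 1 implies unfragmented DNA (S unbounded)"
        )
    if I_observed <= 0:
        raise DataError(
            f"intact fraction {I_observed} <= 0 only implies S < L = {L}; "
            "no point estimate exists"
        )
    return (L - 1) / (1 - I_observed)


def predict_amplicon_abundance(
    specs: Sequence[SpeciesBiasSpec],
    L: int = FULL_LENGTH_TARGET,
    use_copy_number: bool = False,
    sample_id: str = "predicted",
) -> AbundanceTable:
    """Predicted amplicon relative abundances under the intactness model.

    Each species is weighted by true abundance times its intact fraction at
    target length L, optionally times its 16S copy number (off by default:
    copy number is a bias direction, not a fitted correction), then
    renormalized.
    """
    total_truth = sum(s.true_abundance for s in specs)
    if abs(total_truth - 1.0) > 1e-9:
        raise DataError(f"true abundances must sum to 1, got {total_truth!r}")
    weights = {}
    for s in specs:
        w = s.true_abundance * intact_fraction(s.S, L)
        if use_copy_number:
            w *= s.copy_number
        weights[s.species] = w
    total = sum(weights.values())
    if total == 0:
        raise DataError(
            f"every species has intact fraction 0 at L={L}; no amplicons predicted"
        )
    return AbundanceTable(
        sample_id=sample_id,
        mode="amplicon",
        entries={sp: w / total for sp, w in weights.items()},
    )
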