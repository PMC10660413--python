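"""Diet-composition statistics from scat prey occurrences.

Three standard descriptors of a carnivore's scat-based diet profile:

* RFO (relative frequency of occurrence): for each prey species, the number
  of scats in which it occurs (i) over the total occurrence count across
  all species (j), as a percentage A = i/j*100.  Scats containing k prey
  species contribute k occurrences to j.
* Relative consumed biomass: RFO weighted by the digestibility correction
  Y = 1.980 + 0.035 X (X = mean body weight in kg, Y = kg of prey consumed
  per collectable faeces), normalised to percent: D = A*Y / sum(A*Y) * 100.
* AFO (absolute frequency of occurrence) by body-size class: the percentage
  of scats containing at least one prey of a given class (large >= 60 kg,
  medium 16-60 kg, small < 16 kg).  Classes are not mutually exclusive
  across a scat, so the AFO column may sum to more than 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .samples import PreyReference, SampleValidationError, StudyGroup

__all__ = [
    "SIZE_CLASSES",
    "ACKERMAN_INTERCEPT",
    "ACKERMAN_SLOPE",
    "GroupDietSummary",
    "classify_prey_size",
    "ackerman_correction",
    "compute_rfo",
    "compute_biomass",
    "compute_afo",
    "summarize_group",
    "round_half_up",
]

SIZE_CLASSES = ("large", "medium", "small")

# digestibility correction constants (kg per collectable faeces)
ACKERMAN_INTERCEPT = 1.980
ACKERMAN_SLOPE = 0.035

_LARGE_MIN_KG = 60.0
_MEDIUM_MIN_KG = 16.0


@dataclass
class GroupDietSummary:
    """Per-group occurrence counts and the derived RFO / biomass / AFO tables."""

    group_label: str
    n_samples: int
    occurrence_counts: dict[str, int] = field(default_factory=dict)
    total_occurrences: int = 0
    rfo_pct: dict[str, float] = field(default_factory=dict)
    ackerman_y: dict[str, float] = field(default_factory=dict)
    biomass_pct: dict[str, float] = field(default_factory=dict)
    class_counts: dict[str, int] = field(default_factory=dict)
    afo_pct: dict[str, float] = field(default_factory=dict)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as in hand-reported percentage tables."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def classify_prey_size(weight_kg: float) -> str:
    """Body-size class of a prey species from its mean body weight.

    large for >= 60 kg, medium for [16, 60) kg, small below 16 kg.
    """
    if not weight_kg > 0:
        raise SampleValidationError(f"prey weight {weight_kg} must be positive")
    if weight_kg >= _LARGE_MIN_KG:
        return "large"
    if weight_kg >= _MEDIUM_MIN_KG:
        return "medium"
    return "small"


def ackerman_correction(weight_kg: float) -> float:
    """Kg of prey consumed per collectable faeces: Y = 1.980 + 0.035 X."""
    if not weight_kg > 0:
        raise SampleValidationError(f"prey weight {weight_kg} must be positive")
    return ACKERMAN_INTERCEPT + ACKERMAN_SLOPE * weight_kg


def compute_rfo(group: StudyGroup, ref: PreyReference) -> GroupDietSummary:
    """Occurrence counts and relative frequency of occurrence for one group.

    Each species counts once per scat in which it occurs; the denominator j
    is the total occurrence count over all species (multi-prey scats
    contribute one count per species they contain).
    """
    counts: dict[str, int] = {}
    for s in group.samples:
        for sp in s.prey:
            ref.weight(sp)  # resolve against the reference; error if unknown
            counts[sp] = counts.get(sp, 0) + 1
    j = sum(counts.values())
    if j == 0:
        raise SampleValidationError(
            f"group {group.label}: no identifiable prey occurrences"
        )
    summary = GroupDietSummary(group.label, len(group.samples))
    summary.occurrence_counts = dict(sorted(counts.items()))
    summary.total_occurrences = j
    summary.rfo_pct = {sp: c / j * 100.0 for sp, c in summary.occurrence_counts.items()}
    return summary


def compute_biomass(summary: GroupDietSummary, ref: PreyReference) -> GroupDietSummary:
    """Relative consumed biomass D = A*Y / sum(A*Y) * 100 from RFO values A.

    Accepts either a pipeline summary (unrounded A) or one whose ``rfo_pct``
    was filled with printed, rounded RFO values for a reproduction run.
    """
    if not summary.rfo_pct:
        raise SampleValidationError(
            f"group {summary.group_label}: RFO must be computed before biomass"
        )
    y = {sp: ackerman_correction(ref.weight(sp)) for sp in summary.rfo_pct}
    ay = {sp: summary.rfo_pct[sp] * y[sp] for sp in summary.rfo_pct}
    total = sum(ay.values())
    summary.ackerman_y = y
    summary.biomass_pct = {sp: v / total * 100.0 for sp, v in ay.items()}
    return summary


def compute_afo(group: StudyGroup, ref: PreyReference) -> GroupDietSummary:
    """Absolute frequency of occurrence of each body-size class.

    A scat containing two species of the same class increments that class
    count once; afo_k = s_k * 100 / n with n the number of scats analysed.
    """
    if len(group.samples) == 0:
        raise SampleValidationError(f"group {group.label}: no samples")
    s_k = {cls: 0 for cls in SIZE_CLASSES}
    for s in group.samples:
        classes = {ref.size_class(sp) for sp in s.prey}
        for cls in classes:
            s_k[cls] += 1
    n = len(group.samples)
    summary = GroupDietSummary(group.label, n)
    summary.class_counts = s_k
    summary.afo_pct = {cls: c * 100.0 / n for cls, c in s_k.items()}
    return summary


def summarize_group(group: StudyGroup, ref: PreyReference) -> GroupDietSummary:
    """Full diet summary (counts, RFO, biomass, size-class AFO) for a group."""
    summary = compute_rfo(group, ref)
    compute_biomass(summary, ref)
    afo = compute_afo(group, ref)
    summary.class_counts = afo.class_counts
    summary.afo_pct = afo.afo_pct
    return summary
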