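"""Familial co-segregation of a candidate variant with disease.

A relative is *informative* when they are typed for the variant, not the
proband, and of known affection status -- except unaffected carriers still
younger than the penetrance age, who are uninformative rather than
discordant (ADPKD imaging penetrance is near-complete only by
mid-adulthood).  Any typed affected non-carrier, or typed unaffected
carrier past the penetrance age, is discordant and makes segregation
negative; with no discordance and enough informative relatives the result
is positive, otherwise inconclusive.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .models import (
    Affection,
    Carrier,
    Family,
    PedigreeIndividual,
    SegregationStatus,
)

__all__ = ["SegregationResult", "evaluate_segregation", "find_proband"]

DEFAULT_PENETRANCE_AGE = 40.0


@dataclass
class SegregationResult:
    variant_key: str
    family_id: str
    status: SegregationStatus
    informative_affected: int = 0
    informative_unaffected: int = 0
    discordant: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.status is SegregationStatus.NEGATIVE) != bool(self.discordant):
            raise ValueError("discordant list must be non-empty iff status is negative")


def find_proband(family: Family, variant_key: str) -> Optional[PedigreeIndividual]:
    """Default proband: first affected typed carrier in family order."""
    for m in family.members:
        if (
            m.affected is Affection.AFFECTED
            and m.carrier_status(variant_key) is Carrier.CARRIER
        ):
            return m
    return None


def evaluate_segregation(
    family: Family,
    variant_key: str,
    proband_id: Optional[str] = None,
    min_informative: int = 1,
    penetrance_age: float = DEFAULT_PENETRANCE_AGE,
) -> SegregationResult:
    """Evaluate co-segregation of ``variant_key`` with disease in a family.

    Raises ``KeyError`` when no family member is typed for the variant and
    ``ValueError`` when the proband is not a typed carrier.
    """
    if min_informative < 1:
        raise ValueError("min_informative must be >= 1")
    typed = [
        m for m in family.members if m.carrier_status(variant_key) is not Carrier.UNTYPED
    ]
    if not typed:
        raise KeyError(
            f"variant {variant_key} has no typed member in family {family.family_id}"
        )
    if proband_id is None:
        proband = find_proband(family, variant_key)
        if proband is None:
            raise ValueError(
                f"family {family.family_id} has no affected typed carrier proband "
                f"for {variant_key}"
            )
    else:
        proband = family.get(proband_id)
        if proband.carrier_status(variant_key) is not Carrier.CARRIER:
            raise ValueError(f"proband {proband_id} is not a typed carrier")

    informative_affected = 0
    informative_unaffected = 0
    discordant: list[str] = []
    for m in family.members:
        if m.individual_id == proband.individual_id:
            continue
        status = m.carrier_status(variant_key)
        if status is Carrier.UNTYPED or m.affected is Affection.UNKNOWN:
            continue
        if m.affected is Affection.UNAFFECTED and status is Carrier.CARRIER:
            # penetrance-age rule: young unaffected carriers are uninformative
            if m.age is None or m.age <= penetrance_age:
                continue
            discordant.append(m.individual_id)
            informative_unaffected += 1
            continue
        if m.affected is Affection.AFFECTED:
            informative_affected += 1
            if status is Carrier.NON_CARRIER:
                discordant.append(m.individual_id)
        else:
            informative_unaffected += 1

    if discordant:
        status_out = SegregationStatus.NEGATIVE
    elif informative_affected + informative_unaffected >= min_informative:
        status_out = SegregationStatus.POSITIVE
    else:
        status_out = SegregationStatus.INCONCLUSIVE
    return SegregationResult(
        variant_key=variant_key,
        family_id=family.family_id,
        status=status_out,
        informative_affected=informative_affected,
        informative_unaffected=informative_unaffected,
        discordant=discordant,
    )
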