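"""Familial co-segregation of a candidate variant with polycystic disease.

An affected carrier father and an unaffected non-carrier mother make a
trio fully concordant: segregation is positive, which upgrades a novel
likely-pathogenic missense variant to highly likely pathogenic.
"""
from pkdcohort import (
    Affection,
    Carrier,
    Family,
    Grade,
    InsilicoVerdict,
    PedigreeIndividual,
    SegregationStatus,
    VariantClass,
    assign_grade,
    evaluate_segregation,
)

KEY = "16:1042:C:T"


def person(iid, affected, carrier, age):
    p = PedigreeIndividual(family_id="F1", individual_id=iid,
                           affected=affected, age=age)
    p.carrier[KEY] = carrier
    return p


family = Family(family_id="F1", members=[
    person("proband", Affection.AFFECTED, Carrier.CARRIER, 34),
    person("father", Affection.AFFECTED, Carrier.CARRIER, 61),
    person("mother", Affection.UNAFFECTED, Carrier.NON_CARRIER, 58),
])

res = evaluate_segregation(family, KEY)
print(f"status: {res.status.value}")
print(f"informative affected/unaffected: {res.informative_affected}/"
      f"{res.informative_unaffected}, discordant: {res.discordant or 'none'}")

damaging = InsilicoVerdict(sift_hit=True, pp2_hit=True, gerp_hit=False)
before = assign_grade(VariantClass.MISSENSE, verdict=damaging)
after = assign_grade(VariantClass.MISSENSE, verdict=damaging, segregation=res.status)
print(f"grade before segregation: {before.value}; after: {after.value}")
assert before is Grade.LP and after is Grade.HLP and res.status is SegregationStatus.POSITIVE
print()
print("Both parents typed and concordant give the clearest segregation")
print("evidence; a single typed affected non-carrier would instead flip the")
print("variant to likely neutral.")
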