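"""Walk one ELISPOT sample through the decision table by hand.

Spot counts are per 4x10^5 CD8-depleted PBMC in four depletion conditions:
(CD8-dep, CD8+CD19-dep, CD8+CD25-dep, CD8+CD25+CD19-dep).  Positivity uses
count >= 10 spots and >= 2x background; Bdep/Breg/Treg flags use a >=20 %
relative change between paired wells.
"""

from camrspot import ElispotSample, PositivityRule, classify_sample
from camrspot.records import AntigenClass, TimePoint

sample = ElispotSample(
    patient_id="demo",
    time_point=TimePoint.T1,
    antigen_class=AntigenClass.DONOR,
    c_cd8dep=120,          # reactive: donor-specific reactivity (DSR)
    c_cd8cd19dep=35,       # falls ~71% without B cells -> B-dependent
    c_cd8cd25dep=150,      # rises 25% without CD25+ cells -> Treg activity
    c_cd8cd25cd19dep=30,   # B-dependence persists without CD25+ cells
    background=4,
    viable=True,
)
call = classify_sample(sample, PositivityRule(min_spots=10, background_multiplier=2.0))

print("positivity quadruple:", call.positivity)
print("depletion flags:     ", sorted(f.value for f in call.flags))
print("fine pattern:        ", call.fine_pattern.value)
print("coarse category:     ", call.coarse_category.value)
print("DSR / B-dependent:   ", call.dsr, "/", call.b_dependent)
print("\nA (+,+,+,+) quadruple is not one of the nine tabulated patterns, so the")
print("coarse category comes from the flag fallback: DSR with B-dependence and")
print("Treg regulation present classifies as a regulated B-dependent response.")
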