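"""Growth-cone/axon encounter classification.

Generates the 23-event in-vivo fixture and the 100-event homotypic
co-culture fixture, classifies every event with the geometric cascade
(fasciculation / crossing / tracking / stalling / retraction), and prints
the class fractions.  Fasciculation dominates in-tract encounters; homotypic
contacts split mostly between fasciculation and crossing.
"""

from axonquant import behavior_fractions, compare_groups
from axonquant.synthetic import make_encounter

for profile in ("fig2c", "fig2i_homo"):
    events, _ = make_encounter(profile, seed=0)
    df = behavior_fractions(events)
    sub = df[df.group == ("homotypic" if profile == "fig2i_homo" else "all")]
    print(f"{profile}: {len(events)} events")
    for row in sub.itertuples():
        if row.n:
            print(f"  {row.behavior:<14}: {row.n:3d}  ({row.percent:.2f} %)")
    print()

# a two-sided Fisher test on a fasciculation-vs-other contingency table
out = compare_groups([11, 12], [51, 49], test="fisher")
print(f"fasciculation in-vivo vs homotypic: Fisher's exact p = {out['p']:.3f}")
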