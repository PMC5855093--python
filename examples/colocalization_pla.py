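"""Colocalization metrics: Manders coefficients, puncta association, PLA.

Computes Manders split coefficients on a toy two-channel pair, the fraction
of channel-A puncta within 0.5 um of a channel-B granule on the 84/100
fixture, and central/peripheral PLA dot counts with the C/P ratio.
"""

import numpy as np
from shapely.geometry import Polygon

from axonquant import PunctumSet, manders, pla_counts, puncta_association
from axonquant.synthetic import make_puncta_fixture

rng = np.random.default_rng(0)
ch1 = rng.uniform(0, 100, (64, 64))
ch2 = 0.6 * ch1 + rng.uniform(0, 40, (64, 64))  # partially colocalized
M1, M2 = manders(ch1, ch2)
print(f"Manders M1 = {M1:.3f}, M2 = {M2:.3f}  (fraction of each channel's "
      "signal inside the other's mask)")

a, b, truth = make_puncta_fixture(n=100, associated=84, radius=0.5, seed=13)
frac = puncta_association(a, b, radius=0.5)
print(f"puncta association: {100 * frac:.0f} % of channel-A puncta within "
      f"{truth['radius']} um of a channel-B granule")

outline = Polygon([(0, 0), (12, 0), (12, 10), (0, 10)])
central = Polygon([(3, 2), (9, 2), (9, 8), (3, 8)])
dots = PunctumSet("pla", rng.uniform(0, [12, 10], (40, 2)))
res = pla_counts(dots, central, outline.difference(central))
print(f"PLA dots: {res.n_central} central, {res.n_peripheral} peripheral "
      f"(C/P ratio {res.cp_ratio:.2f}), {res.n_outside} outside")
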