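"""Filopodia detection and dynamics on a scripted growth-cone sequence.

Detects protrusions >= 2 um on a synthetic mask with programmed spike
lengths, then summarizes a 5-min recording (5-s sampling) of scripted
length trajectories as formation / retraction / stable events with
lifetimes and active-phase speeds.
"""

from axonquant import classify_dynamics, detect_filopodia
from axonquant.synthetic import make_gc_mask, make_gc_sequence

mask, truth = make_gc_mask([0.8, 1.5, 2.0, 2.5, 3.0], seed=1)
found = detect_filopodia(mask, truth["pixel_size"])
print(f"programmed spikes (um): {truth['spike_lengths_um']}")
print(f"detected filopodia    : {sorted(round(f['length_um'], 2) for f in found)}"
      "   (only protrusions >= 2 um count)")

_, traces, log = make_gc_sequence(n_filopodia=4, seed=5)
s = classify_dynamics(traces, recording=300.0, sampling=5.0)
print(f"\nscripted kinds: {log['kinds']}")
print(f"formation {s.n_formation}, retraction {s.n_retraction}, stable {s.n_stable}")
print(f"lifetimes (s): {s.lifetimes}")
print(f"elongation speeds (um/s): {[round(v, 3) for v in s.elongation_speeds]}")
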