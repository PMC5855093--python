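# Methods

This note documents the quantitative procedures implemented in axonquant,
the parameter choices behind them, what the synthetic fixtures emulate, and
the limits of what passing tests demonstrate.

## Missorting index

The tract image is a two-channel maximum projection; intensities are
sampled along a user-supplied reference line with bilinear interpolation at
0.5-pixel steps (positions reported in μm via the pixel size, which must be
supplied — the code never assumes 1 px = 1 μm). The protocol draws the line
perpendicular to the tract, 70 μm from the chiasm; the offset is metadata
here, since the computation depends only on the endpoints.

Brachium assignment supports two modes. *Faithful* mode takes a manual
split position and a `dm_side`, mirroring by-eye assignment on the image.
*Convenience* mode, for unattended runs, smooths the dorsal+ventral sum
with a 2-μm Gaussian, finds the two most prominent peaks, and splits at the
valley between them. Because the valley floor can be flat (both bands near
zero over many μm), the argmin is ill-conditioned; the split is therefore
the centroid of all positions within 2% of the valley minimum — a
deterministic tie-break that is stable under noise. Auto mode uses both
channels to locate the valley; this is a choice, flagged because the
protocol does not specify whether the ventral dye participates.

MI is the ratio of per-side *means* of the dorsal channel. It equals the
dorsal-dye mass fraction in the wrong brachium only when the two sides of
the split have equal length, so parameter-recovery checks use the faithful
split at the fixture's known band midpoint; the convenience mode recovers
the programmed fraction to better than 0.01 for moderate fractions and
degenerates (by construction) when one band vanishes, where a manual split
is required. Background subtraction is available but off by default: the
protocol describes background ROIs for cell-culture images, not tract
projections. MI is reported to 4 decimals in tables; comparisons use
unrounded values. No correction for dye-loading variability is applied —
the measure assumes mean intensity is proportional to labeled-axon amount.

## Granule transport

Tracks are 1-D arc-length positions (μm, anterograde-positive); projecting
2-D detections onto the axon midline is the caller's concern. The motion
rule uses the maximal excursion from the starting position, not endpoint
displacement, because the protocol's criterion is displacement "from the
origin"; the threshold (2 μm, strict inequality) classifies a track as
anterograde/retrograde, with the deterministic tie-break d+ = d− →
anterograde. Tracks shorter than the nominal 1-min window are classified on
the available samples (≥ 2 required) — a documented deviation, since the
handling of short-lived granules is not specified. Percentages are rounded
half-up to 2 decimals.

Domain counts arrive per 30-s bin aligned to contact (T = 0); empty bins
yield flagged, not imputed, fractions. Anterograde flux counts distinct
anterograde-classified granules whose position first crosses the
growth-cone boundary (position 0) per bin, restricted to tracks within the
terminal 50-μm segment; normalization divides by the per-axon mean, so a
defined series has mean exactly 1 and an all-zero series is flagged.

## Growth-cone morphometrics

Domain partition is manual-first; the automatic fallback erodes the
outline polygon inward (default 3 μm) to form the central domain, with the
peripheral domain as the set difference. This is a stand-in for manual
tracing, not a validated segmentation.

Filopodia detection subtracts the morphological opening of the binary mask
(disk radius 0.6 μm) and measures each attached residual component by the
geodesic distance from its attachment ring to its farthest pixel. The raw
pixel-metric geodesic is biased by rasterization, so the path is coarsened
to a polyline (every 5th pixel) and summed as chords, plus a one-pixel
endpoint correction; on programmed straight spikes this recovers lengths to
better than ±0.1 μm at 0.1 μm/pixel. Protrusions with length ≥ 2 μm
(inclusive) count as filopodia. Raising the threshold can only shrink the
count (monotonicity). Lengths within roughly one pixel of the threshold are
inherently ambiguous under rasterization; the random fixtures therefore
keep programmed lengths ≥ 0.2 μm away from 2 μm, matching the separation
margins used for tracks.

Dynamics: "completely retracted" is interpreted as dropping below 2 μm with
no recovery within the recording, consistent with the lifetime rule (time
spent ≥ 2 μm); a trace may count as both formation and retraction. Speeds
average per-5-s increments over the maximal monotone run ending at (for
elongation) or starting from (for retraction) the length maximum; plateaus
are excluded. A filopodium that fully retracts and re-extends is two traces
if tracked as such. ROI intensities subtract a congruent adjacent
background ROI and may be negative. Tip enrichment (distal 1 μm of the
skeleton, factor 1.5, per-filopodium call at ≥ 50% of present frames) is an
operational criterion exposed in the configuration; the underlying
observation was scored by eye, so these defaults are choices, recorded in
output metadata.

## Encounter classification

The published behavior definitions are qualitative; the implementation
makes them operational with explicit geometry, evaluated as a cascade after
the contact time: fasciculation (trajectory within `merge_tol` = 1 μm of the
contacted axon for ≥ `min_follow` = 10 μm of arc), crossing (side flip
relative to the axon, proceeding ≥ `cross_dist` = 5 μm beyond, heading
change < 30°), tracking (≥ 2 filopodial contacts, heading turned > 20°
toward the axon tangent, centroid kept > `merge_tol` away), retraction (net
advance along the pre-contact heading < −5 μm), stalling (|net advance| <
5 μm over the full 45-min window). Events matching no rule are reported
unclassified; events observed for less than 45 min without triggering rules
1–4 are censored ("indeterminate"), never dropped. All tolerances are
configuration fields. The classification is invariant under rigid motions
of the whole event. Summary tables pool stalling/retraction into one class
where the detail split is also retained.

## Synthetic fixtures

Each generator draws all randomness from one seeded `numpy` generator, so
identical configurations are bit-identical. Every fixture emits a truth
record sufficient to score the corresponding analysis without re-deriving
it.

- **Tract images**: two Gaussian bands (σ = 5 μm, centers 30/70 μm,
  0.5 μm/pixel) with the dorsal-dye mass split (1−f)/f between the sorted
  and missorted band and the ventral dye occupying the opposite brachium;
  optional additive Gaussian noise. Conservation of channel mass makes the
  recovered MI equal f at the midpoint split.
- **Tracks** (53 tracks, 61 samples at 1 Hz): 29 confined (reflected random
  walk, step σ = 0.2 μm, excursion hard-clipped at 1.5 μm), 13 retrograde
  and 11 anterograde (drift ∓/±0.05 μm/s, additive noise σ = 0.05 μm), so
  drift tracks reach 3 μm and every track stays ≥ 0.5 μm from the 2-μm
  decision boundary.
- **Domain time courses**: baseline peripheral occupancy 0.236;
  heterotypic contact ramps to a sustained 0.45 plateau within 3.5 min;
  homotypic contact rises transiently to 0.37 and returns to baseline by
  8 min. The contact-free fixture allocates the pooled peripheral count by
  largest remainder so the pooled fraction is exact (118/500).
- **Growth-cone sequences**: elliptical body (5 × 3.6 μm) with radial
  spikes whose per-frame lengths follow scripted stable / formation /
  retraction / transient trajectories at 5-s steps.
- **Encounters**: canonical parametric trajectories per class (30-s frames,
  0.6 μm/frame, 45-min observation) under random rigid transforms with
  0.05-μm positional jitter.
- **Puncta**: associated channel-A points placed within radius/2 of a
  channel-B point, the rest rejection-sampled beyond 2× radius, making the
  association fraction at the query radius exact.

The named fixture compositions (29/13/11 of 53; 11/7/5 of 23; 51/43/6 of
100; 382/118; 84/100) are the minimal integer reconstructions of published
summary percentages. They are reconstructions, not measured data, and are
labeled `synthetic` in their truth records; the 100-event homotypic
composition in particular reconstructs two printed ratios whose underlying
n is not printed, with n = 100 the smallest round composition reproducing
both.

What the fixtures do *not* emulate: realistic point-spread functions and
camera noise, tracking/linking errors, curved axon midlines, filopodia that
branch or cross, drift in imaging geometry. Passing tests therefore
demonstrate that the measurement rules are implemented exactly and are
robust at realistic noise margins — not that the upstream manual tracing or
tracking steps of a real experiment are reproduced.

## Problem sizes and numerical choices

Default problem sizes (53 tracks, 23/100 events, 500 granules, 200
round-trip events, 1,000 round-trip tracks, 50 random mask fixtures) mirror
the fixture definitions and keep the full test suite fast and deterministic.
Degenerate inputs raise (zero-denominator MI, empty bins, all-zero flux,
over-erosion) rather than returning silent defaults; boundary ties are
deterministic and documented (threshold excursions are static, d+ = d−
ties are anterograde, PLA dots on the shared boundary count as central).
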