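# Methods

`rnaid` analyzes single-channel nanopore recordings of RNA identifiers
(RNA IDs): RNA transcripts hybridized with complementary DNA oligos, a few
of which carry streptavidin labels that imprint sequence-specific downward
spikes on the translocation current. The package covers the whole chain
from raw current trace to population statistics, plus a synthetic trace
generator so every stage is testable without instrument data. Units are
fixed throughout: currents in pA, times in ms, charge in fC (1 pA·ms =
1 fC), lengths in kbp.

## Construct model

A design (`rnaid.design.IDDesign`) describes the transcript geometry in
transcript coordinates (kbp from the 5′ end):

- within-cycle label layout — here a repeats label `R` at 0.10 kbp
  (two streptavidins, ~2× the blockage of a bit) followed by two `1` bits at
  0.60 and 1.20 kbp, i.e. R-to-bit spacing 0.5 kbp and bit-to-bit spacing
  0.6 kbp;
- the OriC premature-termination point, 1.75 kbp into the linear construct
  and 1.6 kbp into each cycle of the circular construct;
- for the linear construct, the full-length (END) product at 3.19 kbp;
- for the circular construct, explicit cycle-start offsets
  `[0, 3.0, 6.3, 9.6, 12.9]` kbp. These are a list rather than a single
  period because the OriC-terminated product lengths they have to reproduce
  (1.6, 4.6, 7.9 kbp for n = 1..3) imply unequal increments (3.0, then
  3.3 kbp); the package honors the printed lengths instead of forcing
  periodicity.

Both fixtures ship as YAML under `rnaid/data/` and carry their termination
statistics (per-encounter OriC termination probability 0.47; a low
dissociation hazard for the circular construct) under a `sim` key.

## Termination model and synthetic traces

`draw_transcript` samples one transcript. Linear templates terminate at the
OriC point with probability `p_term_per_cycle`, else run off at the template
end. Circular templates are walked cycle by cycle: each OriC encounter
terminates with that probability; a survivor is exposed to an exponential
dissociation hazard (`dissociation_rate_per_kbp`) over the remainder of the
cycle, with the stopping point uniform over the traversed span, before
entering the next cycle. The walk is capped at the last modelled cycle,
whose OriC encounter is forced — without a cap the event would leave the
modelled geometry; the forced encounter slightly inflates the last cycle's
OriC class, which only matters if that cycle is analyzed. With no
dissociation the cycle counts are censored-geometric with continuation
q = 1 − p_term.

A uniform hazard spreads dissociation lengths over each cycle; real data
may instead show localized dissociation populations near the end of a
cycle. An optional `dissociation_mode="end_of_cycle"` places the stop at
the next cycle start to emulate such peaks; the default is the uniform
hazard.

`simulate_event` renders one translocation: a rectangular blockade of depth
`duplex_drop_pA` for the RNA–DNA backbone, rectangular label spikes
(`bit_extra_drop_pA`, ×`r_depth_ratio` = 2 for `R`) of spatial width
`spike_width_kbp`, per-event lognormal speed (mean `speed_kbp_per_ms`, CV
`speed_cv`), an optional linear intra-event speed drift bounded by
`intra_event_drift` (the label times are placed by integrating the ramp
exactly), random 5′-first/3′-first entry, and additive Gaussian noise.
Folded molecules render a prefix (uniform 10–50 % of the event) at twice
the backbone drop; only partial fold-backs are modelled since fully folded
events are rejected downstream anyway. Spike shape is rectangular — the
pulse shape is not otherwise constrained — and an optional first-order
low-pass (`lowpass_tau_ms`) emulates analog filtering (off by default).

Default study conditions (all overridable):

| parameter | default | rationale |
|---|---|---|
| baseline | 1000 pA | open-pore level; only drops relative to it matter |
| noise SD | 10 pA | comfortable SNR for 60 pA bit spikes after smoothing |
| duplex drop | 120 pA | beyond the −100 pA screening filter with margin |
| bit extra drop | 60 pA | clears the spike prominence threshold |
| R depth ratio | 2.0 | two streptavidins vs one |
| spike width | 0.1 kbp | ≫ sample interval at the default speed |
| speed | 4 kbp/ms | keeps the ECD of 3-cycle products (7.9 kbp) under the 400 fC filter ceiling while all durations stay ≥ 0.05 ms |
| speed CV | 10 % | per-event variability; cancelled by per-event calibration |
| intra-event drift | ±10 % | bounded linear ramp; sizing stays within ~5 % |
| sample interval | 0.005 ms | 200 kHz; label spikes stay ≥ 5 samples wide |
| fold probability | 0.10 | minority population, excluded from sizing |
| reverse probability | 0.5 | entry orientation is random |
| inter-event gap | 2 ms mean | exponential open-pore intervals |

The 0.005 ms default sampling keeps simulated datasets small; a 1 MHz
equivalent (0.001 ms) is available by configuration. Exact contaminant
counts (`round(fraction × n_events)`) make filter tests deterministic;
contaminants are short (< 0.05 ms) or shallow (< 100 pA) blockades.

What the generator does *not* emulate: pore-to-pore conductance
variability, electro-osmotic capture physics, 1/f noise, partial label
occupancy, and RNA secondary structure beyond the single fold-back class.
Passing recovery tests therefore demonstrates the analysis is correct under
the stated signal model, not that it is robust to every instrument artifact.

## Event extraction

The open-pore baseline and noise scale are estimated robustly in two
passes: an initial median with a one-sided (upper) MAD — blockades only
pull the current down, so deviations above the median are noise-only —
then median and MAD recomputed on samples within three initial scales of
the median. This stays within ~1 pA of truth with 20–30 % of samples inside
deep events; a plain two-sided MAD would inflate the noise estimate by tens
of percent at that occupancy.

Events are maximal runs below `baseline − max(5σ, 50 pA)` (the 50 pA floor
keeps the rule meaningful for noiseless synthetic data); runs separated by
less than 0.02 ms are merged so deep label spikes cannot split an event.
Boundaries are then extended outward to the nearest return to
`baseline − 2σ`. Extending to the literal baseline crossing would, in
noise, walk a geometric number of extra noise samples on each side and bias
durations (hence sized lengths) upward; the 2σ stop level reduces the
boundary to the true blockade edge for deep events and degrades gracefully
to the exact crossing when σ = 0.

Per event: duration, mean drop (mean of current − baseline), and event
charge deficit ECD = Σ(baseline − I)·Δt. Screening keeps events with
0 < ECD ≤ 400 fC, duration ≥ 0.05 ms and mean drop ≤ −100 pA; rejected
events are annotated with the first failing rule.

## Spike calling, classification, folds, orientation

Within an event the duplex plateau is the sample median. Spikes are runs of
the median-filtered (width-3) signal below the plateau by more than
`max(4σ, 0.3 × plateau drop)`, at least 3 samples long; excursions closer
than one spike width are merged; depth is plateau minus the smoothed
minimum, time is the excursion midpoint.

Depths are split by 1-D two-means; the reference depth is the median of the
shallower cluster and a spike deeper than 1.5× the reference is called `R`.
A lone spike has no reference and stays UNKNOWN (the event is excluded from
sizing rather than guessed); with two spikes the deeper is `R` only if the
ratio exceeds 1.5. The 1.5 threshold sits midway between the nominal depth
ratios of 1 (bit/bit) and 2 (R/bit); all constants are exposed in
`AnalysisConfig`. An event consisting only of `R` spikes would be
misclassified (the reference would be an `R`), but the supported designs
place two bits in every cycle, so the case cannot arise from a complete
spike set.

Folded events are flagged by either of two rules: a contiguous region of
≥ 10 % of the event, starting within 5 % of either end, deeper than 1.7×
the population's median duplex level; or an ECD-vs-duration residual more
than 3 SDs above the population regression. Either rule alone catches the
simulated fold class; the pair is kept because they fail independently
(level rule: shallow long folds; residual rule: short deep artifacts).
Flagged events are excluded from sizing. The analysis here is automated
end-to-end, replacing the manual per-event spike selection typical of
interactive nanopore tooling.

Orientation comes from the time-ordered kind pattern: `R,1,1` per cycle
reads 5′→3′ (forward), the mirrored pattern reads 3′→5′; anything else —
including any UNKNOWN — is ambiguous and excluded from sizing. Reverse
events are canonicalized (times mirrored, order reversed) so downstream
code always works in transcript coordinates. The cycle count n is the
number of `R` calls and is invariant under time reversal.

## Calibration, sizing, termination

Each event is its own ruler. Spikes are matched positionally to the design
fiducials (a count mismatch makes the event UNCLASSIFIED — no partial
guessing). Per cycle, the conversion factor is the known span between the
first and last label (1.1 kbp here) divided by the time between their
spikes; algebraically this equals the span-weighted mean of adjacent
pairwise factors. Multi-cycle events average per-cycle factors weighted by
span, which damps intra-event speed drift relative to trusting any single
cycle. Length = event duration × conversion. Per-event calibration makes
sizing exactly invariant to event-to-event speed variation and to any
common rescaling of time; a symmetric ±10 % linear drift leaves the
estimator unbiased (the drift sign is random) with a per-event error of a
few percent.

Termination classes:

- linear — the label-free tail after the last spike, in kbp, separates
  premature termination from run-off at τ_tail = 0.8 kbp. The construct
  geometry puts the PT tail at ~0.55 kbp (OriC point minus last bit) and
  the END tail at ~1.99 kbp, so the threshold sits in a wide gap;
- circular — the residual of the last started cycle,
  `length − cycle_start[n−1]`, is compared to the OriC offset (`ORIC_PT`)
  and to a full cycle (`DISSOCIATION`) within τ_oric = 0.5 kbp; residuals
  matching neither are UNCLASSIFIED.

Both tolerances are configurable in `AnalysisConfig`.

## Population statistics

Class means are arithmetic with sample SD (SE also reported). Termination
efficiency is PT/(PT+END). ECD-vs-duration is ordinary least squares with
Pearson r. Cycle-count decay is fitted by maximum likelihood under a
geometric continuation model: by default the law is renormalized over the
observed support 1..N (counts 100/50/25 give exactly q̂ = 0.5; the score
equation is solved by bracketing); with `last_censored=True` events at N
are treated as right-censored — the correct likelihood for generator output
capped at the last modelled cycle, where the closed form
q̂ = S/(S + T − c_N) applies (S = Σ(n−1)cₙ, T = Σcₙ). Histograms default to
0.1 kbp bins; plots normalize counts to unit area.

## Problem sizes and numerical choices

The packaged studies simulate 500 linear events (class-mean recovery),
1000 linear events (termination efficiency) and 600 circular events (modal
lengths per cycle count); each runs in a few seconds at the default
sampling rate. Modal lengths are reported as the center of the fullest
0.1 kbp bin, so a point mass at 1.6 kbp may report 1.55 or 1.65 depending
on which side of the bin edge it falls — well inside the quoted ±0.3 kbp.
Degenerate inputs are handled explicitly: empty traces yield empty event
tables with a warning; transcripts shorter than the first label yield an
empty layout with a warning; fewer than three events disable the
regression-based fold rule; a zero PT+END denominator raises.

## Known limitations

- Events whose ECD exceeds 400 fC are screened out by design; at the
  default speed this truncates products beyond ~4 cycles, biasing the
  observed cycle-count decay at the tail (the censored MLE corrects the
  cap, not the filter loss).
- Orientation and calibration require the complete per-cycle spike set;
  heavily overlapped or missing labels make events UNCLASSIFIED rather
  than recovered.
- The folded-event model and its detection rules are a proxy for visual
  fold rejection; only single prefix fold-backs are simulated.
- The dissociation mechanism is modelled phenomenologically (uniform or
  end-of-cycle); no claim is made about the physical cause of localized
  dissociation populations.
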