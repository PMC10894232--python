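# rnaid

Single-molecule RNA sizing and transcription-termination analysis from
nanopore current traces of DNA-labeled RNA (RNA identifiers).

## The problem

In vitro transcription — the workhorse behind mRNA vaccines and RNA
therapeutics — does not always produce the transcript you designed. A
polymerase running on a template with no terminator can stop prematurely at
cryptic termination sites (for example inside an origin-of-replication,
OriC), run off the template end, or, on a circular template transcribed in
a rolling circle, go around many times before dissociating. Gels show
bands; they do not say which molecule is which.

An RNA identifier (RNA ID) makes each transcript read its own length into a
nanopore: the RNA is hybridized with complementary DNA oligos, a few of
which carry streptavidin labels at known positions. As the RNA–DNA duplex
translocates the pore it blocks the ionic current, and each label adds a
downward spike — the tandem-repeats label `R` (two streptavidins, roughly
twice the blockage) marks the start of every transcription cycle, and `1`
bits (one streptavidin) serve as positional fiducials.

`rnaid` implements the complete analysis for such recordings, for people
who characterize transcription reactions or polymerase processivity at the
single-molecule level:

- **synthetic traces** — a generator that emulates the recordings (baseline
  noise, duplex blockades, label spikes, speed variation, folded molecules,
  contaminants, and the termination model) with full ground truth;
- **event extraction** — robust baseline estimation, event segmentation,
  and the screening filters 0 < ECD ≤ 400 fC, duration ≥ 0.05 ms, mean drop
  ≤ −100 pA (ECD, the event charge deficit, is the area of the event:
  Σ(baseline − I)·Δt, in fC);
- **spike analysis** — label-spike calling, R-vs-bit classification by
  depth, folded-event flagging, orientation from the label pattern, and
  rolling-circle cycle counting (one `R` per cycle);
- **sizing** — each event carries its own ruler: the known base-pair
  spacing between labels divided by the time between their spikes gives a
  per-event conversion factor c (kbp/ms), and
  `length = duration × c`. Termination is then classified as premature
  (`ORIC_PT`), run-off (`END`), or polymerase dissociation;
- **population statistics** — class means ± SD, termination efficiency
  PT/(PT+END), ECD-vs-time regression, and the geometric decay of
  cycle counts, whose maximum-likelihood fit estimates the per-cycle
  continuation probability q of the polymerase.

The packaged fixtures describe two constructs: a **linear** template
(premature termination at 1.75 kbp, full length 3.19 kbp, termination
probability 0.47) and a **circular** template (rolling circle, OriC
termination at 1.6 / 4.6 / 7.9 kbp for 1–3 cycles). See
`docs/methods.md` for the full model and every default.

## Worked example

```python
from rnaid import (load_fixture, SimParams, simulate_trace,
                   analyze_trace, termination_efficiency)

design, sim = load_fixture("linear")
params = SimParams(seed=42, p_fold=0.0).with_overrides(sim)
trace, truth = simulate_trace(design, params, 300)
result = analyze_trace(trace, design)

print(f"events kept: {int(result.events['kept'].sum())} / {len(result.events)}")
print(result.summary.class_stats.round(3))
print(f"termination efficiency: {termination_efficiency(result.sized):.3f}")
```

prints

```
events kept: 300 / 300
           n  mean_kbp  sd_kbp  se_kbp
END      152     3.190   0.114   0.009
ORIC_PT  145     1.748   0.029   0.002
termination efficiency: 0.488
```

All 300 simulated translocations pass the screening filters; the pipeline
sizes the two populations at 1.748 and 3.190 kbp — the premature-termination
and full-length products of the construct (truths 1.75 and 3.19 kbp) — and
estimates a 48.8 % termination efficiency against the generator's 47 %
(n = 297 classified, so the binomial SE is ~2.9 %).

The same pipeline is available as staged commands with inspectable TSV
hand-offs:

```bash
rnaid all --design circular --n-events 200 --seed 7 --out-dir run/
rnaid summarize --sized run/sized.tsv --events run/events.tsv --plots --out-dir run/
```

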