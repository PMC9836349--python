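# Methods

## Scope and model

`attenscan` operationalizes a genome-browser observation — attenuated genes
carry a 5′ Pol II peak, promoter-proximal pA sites, and an upstream Hrp1
peak, with little Nrd1/Nab3 when termination runs through the hybrid
(cleavage-factor/Sen1) pathway — as a deterministic scoring chain:

```
promoter_window → peak_height → r = peak/PolII_peak → R = r/r_ref → category
```

The chain is a composition of ratios, so absolute track units cancel twice:
`r` is invariant to rescaling the genome-wide signal of any one dataset
jointly with Pol II, and `R` is invariant to rescaling any single factor's
track (the reference gene rescales identically). Input tracks can therefore
be raw or normalized coverage; the package treats values as given.

## Coordinates and windows

All internal coordinates are 0-based half-open (bedGraph/BED native); GFF3 is
converted from 1-based closed on load. Occupancy tracks are unstranded
(protein occupancy, not stranded RNA); pA/TSS site tracks are stranded and
peak queries match the gene strand.

The promoter-proximal window extends `upstream_bp = 100` bases 5′ and
`downstream_bp = 300` bases 3′ of the TSS (falling back to the +1 ATG when no
TSS is annotated). On the minus strand the window is the coordinate mirror of
the plus-strand arithmetic. The extent is a free parameter: experimentally
characterized attenuator fragments span roughly −283 to +297 around the ATG
(see `fixture_attenuator_panel()`), and the default window covers that range
around a TSS sitting 30–80 bp upstream of the ATG. Windows are clipped at
position 0; queries outside covered runs return 0 (tracks are sparse by
nature).

"Peak height" is the **maximum** per-base value (or single-site count) in the
window, matching how a peak is read off a browser track; a summed
(area/total-reads) alternative is available via `peak_stat="sum"` because 3′
end-sequencing pA clusters are sometimes quantified by total reads. Zero
Pol II in a window is guarded by `epsilon = 1e-9` signal units with a logged
warning rather than an error, since sparse tracks can be empty over any
particular window.

## Categories and candidate rule

Reference ratios are binned low / intermediate / high at edges 0.67 and 1.5.
Boundaries belong to the lower bin (R = 0.67 → low, R = 1.5 → intermediate)
so that "high" is strictly R > 1.5 — the only strict inequality the
convention defines. Candidates must exceed the enrichment threshold for
**every** enrichment factor (Hrp1 AND pA) and sit at or below the depletion
threshold for **every** depletion factor (Nrd1 AND Nab3). The conjunctive
depletion reading is the stricter of the two readings of "Nrd1/Nab3" and
minimizes false positives; `deplete_mode="any"` relaxes it. Candidate
ordering (descending minimum enrichment-factor R, ties by gene id) is an
artifact convention so outputs are stable; the screen itself defines no rank.

The Pol II travel ratio divides the mean 5′-window signal by the mean over
the ORF body (ORF minus its overlap with the window). It is reported
separately rather than folded into the candidate rule because the published
pausing metrics it resembles are defined on other datasets.

## Synthetic genomes

The generator emits one linear chromosome with alternating-strand genes
(lengths 900–2,400 bp, gaps 300–800 bp, TSS 30–80 bp upstream of the ATG) in
three classes: hybrid attenuators (default 20%), NNS attenuators (10%, one of
which is always the reference gene `NRD1LIKE`), and non-attenuated genes.
Class fractions, planted folds, and geometry are all configurable; a single
RNG seed fixes every draw, and identical seeds give byte-identical output
files.

Pol II at attenuated genes is a rectangular plateau at
`polII_body_level × polII_5prime_fold` (defaults 10 × 4) over the
promoter-proximal window, dropping to the body level over the rest of the
ORF; non-attenuated genes are flat from TSS to ORF end. Factor tracks are
plateaus over the same window at height `R_planted × r_ref × PolII_peak`,
anchored by the reference profile `r_ref = {pA: 0.5, Hrp1: 0.5, Nrd1: 2.0,
Nab3: 2.0}` — moderate pA/Hrp1 and strong Nrd1/Nab3, the profile of an NNS
attenuator. Hybrid genes plant R = 3 for pA/Hrp1 and R = 0.3 for Nrd1/Nab3;
non-attenuated genes plant R = 0.3 throughout and additionally carry 3′-end
Hrp1/pA peaks, as at conventionally terminated genes. pA sites are a 3-site
cluster spanning 30 bp just 3′ of the ATG (counts decreasing 1.0/0.65/0.3 of
the planted maximum). Rectangular plateaus were chosen over Gaussian peaks
deliberately: every planted peak height, ratio, and travel ratio is then an
exact closed form, and noise-free runs must reproduce them to ≤1e-9 relative.

Noise model: multiplicative mean-1 lognormal jitter applied per 10-bp bin of
each plateau (`noise_model="lognormal"`, default cv 0.2), plus Poisson
resampling of site counts (clamped at ≥1). Binning matters: a window peak is
then the maximum over ~40 mildly noisy bins, which concentrates the peak
statistic the way real per-base coverage noise does; a single draw per
plateau would make planted classes far less separable than per-base noise
ever would. `noise_model="poisson"` jitters counts only; `"none"` is exact.

What the simulator does **not** emulate: nucleotide sequence, read-level
sampling, mappability artifacts, overlapping/nested genes, antisense
transcription, and any correlation between factors beyond their shared
Pol II denominator. Passing the screen on synthetic data therefore
demonstrates the scoring chain is implemented correctly and recovers planted
structure under realistic noise levels — not that the default window and
thresholds would reproduce a published candidate list from real tracks,
which also depends on per-gene browser judgments that are not recorded
anywhere.

## Reporter kinetics

`fit_kinetic_slope` selects, among all contiguous windows of at least
`min_points = 10` readings (of a typical 60 one-minute reads), the longest
whose least-squares R² reaches `r2_floor`, breaking ties by higher R² then
earlier start; if none qualifies it returns the best 10-point window flagged
low-confidence. Fits are O(1) per window via prefix sums; a zero-variance
(flat) window counts as perfectly linear with slope 0, so saturated plateaus
are "linear" in the degenerate sense but never beat a longer rising segment.
The floor defaults to 0.995: at the assay's typical noise (SD ~0.002 OD on
slopes of ~0.002–0.006 OD/min) a laxer floor admits windows spanning the
saturation kink and biases the slope downward by >10%, defeating the linear-
range requirement, while 0.995 keeps full noisy linear windows (R² ≈ 0.9996)
comfortably qualified. Both knobs are configurable.

Activity is `slope / (volume_ml × OD600)` with `volume_ml = 0.1` by default.
The bracketing of the underlying kit equation is ambiguous on paper; dividing
by the volume–density product follows the kit convention, and the alternative
reading (multiplying by OD600) differs only by a constant when densities are
matched across samples — as they are in practice — so folds and percents are
unaffected. Percent repression is clipped at 0 (a terminator reading above
its no-terminator control reports 0% repression, not a negative strength).

## Growth and statistics

Doubling time is `ln 2 / slope` of an ordinary least-squares fit of
ln(OD600) against time over the closed window 60–360 min ("exponential line
of best fit" in log space, equivalent for noise-free data and numerically
stable otherwise). Non-positive slopes return an infinite-doubling-time
sentinel rather than a negative time; percent-change comparisons refuse the
sentinel and ask for direct reporting.

Two-group comparisons use Welch's unequal-variance t-test (two-sided,
Welch–Satterthwaite degrees of freedom, via scipy); three or more groups use
Welch's ANOVA (via pingouin). When every group is exactly constant the
statistic is 0/0; the package defines p = 1 for identical means and p = 0
otherwise so downstream star labels stay defined. Stars follow the
conventional ladder (* ≤0.05 down to **** ≤0.0001). No multiple-testing
correction is applied; callers name their comparisons explicitly.

## Numerical and testing choices

- All randomness flows through `numpy.random.default_rng` seeded from a
  single integer per run; the CLI requires explicit seeds.
- Heatmap correctness is cross-checked against a deliberately naive oracle
  that expands tracks into per-base hash maps and rescans every window,
  bypassing the run-length representation entirely; agreement is required to
  1e-12 relative on every cell.
- Slope-window selection is cross-checked against exhaustive enumeration of
  all windows with `numpy.polyfit`.
- Test problem sizes (50-gene genomes, 20 replicates, 60-point kinetic
  series, thousands of null draws for test calibration) were chosen as the
  smallest sizes at which the Monte-Carlo checks are statistically
  meaningful.

## Known limitations

- The default window/thresholds are calibrated on the synthetic generator's
  planted structure, not on real occupancy data; applying the screen to real
  tracks requires choosing the reference gene and window deliberately.
- pA "peak height" defaults to the tallest single site; cluster-sum
  quantification changes r for clustered sites and is offered as an option,
  not reconciled automatically.
- bigWig/BAM ingestion is out of scope; convert to bedGraph/BED first.
- The screen uses fixed thresholds, not significance tests, for enrichment —
  deliberately, as a categorical browser-style readout.
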