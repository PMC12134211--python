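# Methods

This note records the models, parameter choices and numerical decisions
behind `poolscreen`, and what the synthetic-data tests do and do not
demonstrate about real microscopy data.

## Barcode and codebook design

Barcode candidates are i.i.d. uniform 30-mers. All composition
constraints — GC fraction in [0.40, 0.60], longest homopolymer ≤ 3, both
terminal bases in a configurable set (default {G, C}) — are applied at the
selection stage together with the dissimilarity rule, rather than during
generation; the two placements select slightly different sets and the
selection-stage placement keeps generation trivially uniform. The
dissimilarity rule is deliberately *all-against-all*: a candidate is
retained only if its Hamming distance to every other candidate in the
input dataset is ≥ 8 ("distance > 7" made explicit), so two near-identical
candidates eliminate each other. This makes the filter idempotent on its
own output, and it is verified against an O(n²k) brute-force oracle in the
tests. Padlock arms: the target is reverse-complemented and split in half;
by convention the first half of the reverse complement is the 5′ arm.

Codebooks assign each barcode a length-*N* word over *C* colours (default
N = 7, C = 4, capacity C^N = 16384) by seeded rejection sampling: a
uniform candidate word is accepted if its Hamming distance to every
accepted word is ≥ 3. Construction aborts with a diagnostic after 10⁶
rejections for a single slot (infeasible specs). Distance ≥ 3 guarantees
any single-symbol corruption has a unique nearest codeword, so decoding
accepts exact matches (0 corrections) and unique distance-1 matches
(1 correction) and leaves everything else — including words with missing
rounds — unassigned.

## Decoding error budget

With independent per-round symbol errors at rate *p* (wrong symbols
uniform over the other C−1 colours), a trap decodes correctly iff it has
≤ 1 wrong round, probability (1−p)^7 + 7p(1−p)^6 ≈ 0.973 at p = 0.038.
Misassignment requires ≥ 2 errors landing within distance 1 of another
codeword; Monte Carlo over random distance-3 codebooks gives ≈ 0.002 at
p = 0.038 (an analytic ceiling is the ≥ 2-error probability, ≈ 0.028).
The per-round error rate estimated from decoded traps —
Σ corrections / (N × decoded traps) — is biased downward because
multi-error traps are excluded: conditioning on ≤ 1 error gives
p(1−p)^6 / ((1−p)^7 + 7p(1−p)^6) = p/(1+6p). The exact expectation
(enumerating all 4^7 observable words) sits slightly above p/(1+6p)
because a few ≥ 2-error traps decode (wrongly) and contribute
corrections; at p = 0.038 the two differ by < 1% relative. Misassignment
probability is reported per trial (per trap); the normalisation
conditional on being decoded is also exposed and differs by < 3%.

## Synthetic genotyping signals

The generator emulates a chip of `n_traps` (default 4000) at occupancy
0.80; occupied traps are no-signal with probability 0.15, double-signal
(two clones) with 0.05, otherwise carry one barcode drawn from the
configured abundance vector. Defaults follow the trap-category
composition reported for real chips of this design. Per round, the true
colour is rendered with probability 1 − p_round_error (default 0.038),
else a uniformly chosen wrong colour.

Two fidelities feed the same decoder entry points:

* **table mode** (default, fast): per trap/round/channel total intensity
  and above-threshold pixel count. Background totals are
  Normal(bg_mean = 100, bg_sd = 10); a signal adds
  blob_intensity_scale (5000) × lognormal(0, 0.3). In this mode bg_mean
  and bg_sd are interpreted directly on the total-intensity scale.
* **image mode**: per-trap tiles (default 40 × 16 px) with Gaussian pixel
  background and an isotropic 2-D Gaussian blob (σ = 1.5 px, peak
  5000 × lognormal(0, 0.3)) at a per-trap position held fixed across
  rounds, as a rolling-circle product would be.

Double-signal traps render both clones' colours with the *same*
brightness multiplier in a round, so rounds where the two codewords
differ always fail the 2× dominance rule; with code distance ≥ 3 this
makes the double_signal classification deterministic and the generator's
category bookkeeping exact.

## Decoding chain

Background statistics come from a Gaussian fitted to the binned intensity
histogram by least squares (robust to the bright blob tail); blob masks
are pixels above mean + 5 σ; the consensus mask keeps pixels present in
≥ half of the rounds (≥ 4 of 7, since the integer count must reach 3.5).
A channel's round signal is void unless it passes the intensity
threshold, the area threshold (default 4 px; the rule exists in the
protocol but its value is not published, so it is configurable), and the
consensus mask. One surviving channel is called directly; among several,
a channel is called only if its total intensity is ≥ 2× every other
survivor, else the round is ambiguous. Trap classification precedence is
fixed: all rounds silent → no_signal; any ambiguous round →
double_signal; any silent round → unassigned; else the decoded/unassigned
outcome of error correction. The categories are mutually exclusive and
sum to the occupied-trap count (published per-category tallies for real
chips do not quite sum, so an exclusive precedence had to be chosen).

For table-mode thresholds, per-channel totals are gated at
median ± 10 MAD-σ before the histogram fit: unlike pixel histograms,
whose blob tail is thin, a quarter or more of the totals are signal and
would otherwise capsize the fit onto the signal mode.

A vectorised array implementation handles large tables; its semantics
are pinned to the scalar `call_round`/`classify_trap` reference by a
randomised agreement test.

## Synthetic chases and maturation fitting

Each lineage's summed fluorescence is a noisy plateau at *c* before the
swap (t < 0) and follows the strain's single- or double-exponential model
after it; Gaussian noise (default sd 2 a.u. against c ≈ 50–200) is added
at the lineage level and apportioned to cells by area share, so
descendant sums reconstruct the lineage value exactly and division
conserves both area and fluorescence. Cells grow exponentially
(doubling time 40 min, a steady-state mid-log choice for succinate
medium at 30 °C) and divide on doubling; after the swap the growth rate
decays exponentially with a 30-min time constant, emulating the gradual
growth arrest under chloramphenicol. Observations are emitted on the
5-min fluorescence grid; growth is integrated internally on the 1-min
phase-contrast grid. Bleed-through adds `bleed_fraction` of the
neighbouring traps' mean fluorescence density to a trap's surroundings
(traps on a line, nearest neighbours), which is what the 3-fold
density-ratio inclusion filter consumes; the filter treats zero
surroundings with nonzero cell signal as infinitely clean.

Model selection per FP and experiment: mean over lineages of
end-point/peak fluorescence (end point = mean of the last two samples,
for noise robustness; peak = sample maximum) < 0.85 selects the
double-exponential model. Fitting is `scipy.optimize.least_squares`
with initialisation c₀ = F(0) clamped positive, α₀ = max(F_end/F₀ − 1,
0.1), τₘ₀ = time of half rise, τ_b₀ = 2·t_acq, and bounds c > 0, α ≥ 0,
τₘ > 0; the double model is parameterised as τ_b = τₘ + δ, δ > 0, which
enforces τ_b > τₘ and resolves the label-swap degeneracy (bleaching is
slower than maturation in all cases of interest). Non-convergence
returns a flagged failure, not an exception. τₘ > t_acq (300 min) sets
the censored flag.

The replicate-level τₘ is the fit to the *lineage-averaged* curve of an
FP in one experiment (per-lineage fits are also produced, for the
scatter output and the outlier module). This matters for precision: the
Cramér–Rao bound for a *single* lineage at 2%-of-plateau noise and
61 samples over 300 min is a ~2.4% median τₘ error even in the most
favourable corner of the (α, τₘ) grid, so only the averaged-curve
estimator can deliver few-percent recovery, and the recovery tests
exercise that estimator. The two-exponential model is markedly
ill-conditioned when τₘ approaches the window (τₘ and τ_b are strongly
correlated); per-experiment scatter of order 10% there is expected and
occasionally the fit fails outright, which the failure flag surfaces.
Replicate summaries drop experiments with ≤ 4 decoded traps, average τₘ
over the rest, attach an SEM only when three replicates qualify, and
label means beyond the window ">300".

## Outlier detection

Per FP, the pooled (τₘ, pre-swap brightness) points are standardised to
unit variance per axis — the axes are minutes vs arbitrary units, so raw
distances are meaningless — and clustered with DBSCAN (defaults
eps = 0.5, min_pts = 5; none of eps, min_pts or the scaling are published
for the original analysis, so all are configurable). The largest cluster
is the major cluster; a trap counts only with > 2 lineages all agreeing
on membership; an FP is reported only when the major cluster spans > 5
traps; the deviating fraction is deviating/(deviating + major).
Standardising a dataset that contains *only* one tight cluster inflates
it to unit spread; exactly coincident points still form one cluster, but
cluster-free noise returns an explicit all-noise flag rather than a
fraction.

## Scope of the synthetic validation

The generators reproduce the statistical structure the analysis relies
on — per-round symbol errors independent across rounds and probes,
Gaussian backgrounds with bright blobs, exponential-model chases,
bleed-through between adjacent traps — but not optics (PSF, focus drift,
registration error), segmentation or tracking mistakes, barcode-sequence-
dependent detection efficiency, or correlated/channel-asymmetric errors.
Passing tests therefore demonstrate the correctness of the *analysis*
under its own model assumptions and its statistical calibration
(binomial error arithmetic, estimator bias, recovery at stated noise),
not the performance of the full experimental protocol. Problem sizes in
the tests (10⁵-trap decoding runs, 10⁶-trial Monte Carlo, 1200–4000-trap
pipeline runs, 3 replicates) were chosen to make binomial standard
errors small against the tested effects.
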