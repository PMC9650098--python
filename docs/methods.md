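# Methods

## The measurement problem

In an ex vivo phrenic nerve–diaphragm strip, force evoked by repetitive
nerve stimulation declines for two confounded reasons: the muscle fatigues,
and neuromuscular transmission fails at some junctions. The
superimposed-stimulation technique separates them: every 15 s, direct
muscle stimulation is superimposed on the nerve train, driving all fibers
regardless of transmission. Fibers silenced by transmission failure are also
spared fatigue, so the directly-evoked force tracks muscle fatigue alone and
the normalized difference

NMTF(t) = [(MF/MF_init) − (NF/NF_init)] / (MF/MF_init) × 100

is the transmission-specific loss. The formula yields positive magnitudes;
this package stores the negated value so that negative numbers denote
failure, matching the convention in which results are usually plotted. At
the first epoch the statistic is identically zero by construction.

## Force-trace generator

`force_sim` renders the stimulation protocol (40 Hz pulses, 330-ms trains
each second — a 33% duty cycle — for 120 s, superimposition at 165 ms into
every 15th train) as a fused tetanic envelope: a mono-exponential rise to
plateau and an exponential relaxation after the train. Individual 40-Hz
pulses are deliberately not resolved, because every analyzer consumes train
plateau forces only. Trains are placed at 0, 1, …, 120 s inclusive, so the
final (120-s) superimposed assessment exists; a 120-s run therefore contains
121 trains, 9 of them superimposed.

The failure model is phenomenological, with closed forms that double as
analyzer oracles:

- failure fraction f(t) = f0 + (f120 − f0)(t/T)^γ removed from the
  nerve-driven force (γ default 1.5: failure accelerates late, as time-course
  plots of this preparation show);
- muscle capacity m(t) = 1 − (1 − m120)(t/T)^s common to both pathways
  (s default 1);
- within-train droop d(t) ramping linearly 0 → d120, applied to nerve-evoked
  trains only, beginning mid-train and holding flat for the last 10 ms. The
  droop endpoint is normalized so the within-train min/max force ratio
  equals exactly 1 − d(t) despite the residual exponential rise, which makes
  the generator's droop truth directly comparable to the measured statistic.

In a superimposed train the nerve-only plateau occupies the first 165 ms and
direct stimulation recruits the failing fibers in the second half, so MF and
NF are read from one train: nerve-evoked plateau = F0·m(t)·(1 − f(t)),
superimposed total = F0·m(t). F0 is peak specific force × strip CSA, with
CSA = weight/(Lo × 1.056 g/cm³).

Key parameter defaults: sampling rate 1 kHz (transducer rate is
configurable; analyses use plateau peaks and are insensitive to it), tetanic
rise τ = 20 ms, relaxation τ = 35 ms, additive Gaussian force noise with SD
0.5% of the initial peak force. The rise constant was set at 20 ms rather
than slower values so that the nerve-evoked force completes its rise
(>99.97% of plateau) within the 165-ms pre-superimposition window; with
τ = 25 ms the unfinished rise alone biases recovered initial NMTF by ≈0.12
points, which would dominate the generator–analyzer agreement budget. A
fused 40-Hz diaphragm tetanus reaching plateau in ~100 ms is physiological.

Stimulus markers are emitted as gate channels (1 while the stimulus is on):
330 ms is not an integer multiple of the 25-ms pulse period, so a gate is
the only representation from which the 33% duty cycle can be recovered
exactly; pulse rate and widths are carried as protocol metadata.

Cohorts: per-animal multiplicative Gaussian jitter (CV 0.05) on f120, m120,
d120 and peak specific force, additive jitter (SD 0.03) on f0, per-animal
seeds spawned from a single base seed. A CV of 0.05 on f120 propagates to a
final-NMTF dispersion of ≈4 percentage points at the control calibration,
matching the reported group confidence intervals. Group calibrations pin the
closed-form statistics to the published group means (final NMTF −65.4 /
−86.4 / −84.9 / −83.4%; initial NMTF −12.6 / −20.5 / −17.2 / −15.0%;
end-of-run intratrain fatigue −1.9 / −20.1 / −22.1 / −21.5%; specific force
22.3 / 23.4 / 22.9 / 21.9 N/cm²), with muscle-evoked force declining to
0.700 of initial in all groups.

## Trace analysis

Trains are detected from the marker gates; without markers, a fallback
thresholds force at 5% of each train's own early plateau (the global
maximum would lag on late, fatigued trains). Peak extraction smooths with a
5-ms moving average and takes window maxima, trimming half a smoothing
window from window edges so relaxation never leaks into a plateau estimate.
MF is the peak in the superimposed window, NF the peak in the same train's
pre-superimposition window.

Intratrain fatigue = −100·(max − min-after-peak)/max on the nerve-evoked
portion, with the minimum confined between the peak and the train offset.
Because the statistic is assessed every 15 s but superimposition replaces
the second half of those trains, the droop is measured on the nerve-only
train immediately preceding each assessment train (the assessment train's
own nerve window at time zero, where droop is zero anyway). The 5-ms
smoothed trace locates the extrema, but the plateau and trough *levels* are
10-ms raw-trace means anchored at them: on late trains the nerve-evoked
force is ~0.2 of initial, and extreme values of even lightly smoothed noise
would otherwise masquerade as several points of droop (measured −8% against
a true −1.9% at default noise). The windowed-mean estimator removes that
selection bias at the cost of ≤0.4 points of smoothing bias.

Interpretational choices the source conventions leave open: "initial" NMTF
uses the first train (not an early-train average); the intratrain minimum is
taken after the within-train maximum, else the rise phase would dominate;
the final NMTF is the 120-s epoch value.

## NMJ stack generator

`nmj_sim` renders the post-synaptic endplate as a thickened, radially
wobbled elliptical ring — the en-face "pretzel" — at 0.176 μm/px (a 60×
field heuristic; all outputs are in μm, so results are pixel-size
independent to first order) in a 256×256 field (growing automatically for
large targets), 8 z-slices at 2 μm with the junction occupying the interior
slices. Geometry is solved by nested bisection: at each candidate curve
scale the stroke half-width is bisected on the sub-pixel distance transform
to hit the projected-area target (within 2%, usually 0.4%); with area held,
the bounding rectangle grows monotonically with scale, so a second bisection
drives the fill ratio (relative planar area) to within 1 point of target
(3 points accepted). Unreachable combinations — e.g. a 99% fill ratio for a
ring — raise an error reporting achieved vs requested.

The pre-synaptic terminal is a spatially coherent random subset of the
endplate (a smoothed Gaussian random field thresholded at the exact quantile
covering the apposition target) plus a fringe of the nearest outside pixels
amounting to 5% of terminal area, so apposition (normalized by *post* area)
differs from overlap/pre-area as in the real measurement. Ground truth
(masks, areas, apposition, fill ratio) is recorded before optics: the
intensity volumes are the masks distributed over z, blurred by a Gaussian
PSF (σ 0.3 μm), plus background (100) and Gaussian noise (SD 50 at signal
amplitude 900), quantized to uint16.

One note on calibration consistency: published per-class means for this
preparation (endplate ≈280 μm², apposition ≈60%, terminal ≈123 μm²) are not
jointly realizable — 60% of 280 μm² already exceeds 123 μm² of terminal
label — presumably because the three numbers come from different
thresholding conventions. The generator treats endplate area and apposition
as primary; terminal area follows from them plus the fringe. Cohort
defaults also center the fast-fiber class at 560 μm² rather than its ~500
μm² literature mean, because 500 μm² sits exactly on the I/IIa vs IIx/IIb
classification boundary and a generator centered there would intend a class
its own rule rejects half the time.

## NMJ morphometry

Projection is maximum-intensity over the slices whose in-mask mean exceeds
twice the background estimate (volume median), or an explicit slice range.
Thresholding is Otsu by default — the original acquisition software's
settings are unreported, so a parameter-free, reproducible method is
preferred and the applied threshold is logged per image — with a fixed-value
override. Cleanup removes objects below 2 μm²; the endplate channel
additionally keeps only its largest connected component (it is a single
structure by definition), while the terminal channel keeps all blobs, since
a terminal legitimately fragments over the endplate. Areas are pixel counts
× pixel area; the orthogonal area is the axis-aligned bounding rectangle;
boundary-exact values (=500 μm², =50 μm) fall into the excluded class, which
is flagged but retained in per-animal means.

## Statistics

Shapiro–Wilk for normality; a single-pass ±2 SD outlier rule (mean and
sample SD computed once on all points — the source is silent on iteration
and SD flavor, and single-pass with sample SD is the conservative reading);
one-way and additive two-way between-subjects ANOVA via OLS; the NMTF and
intratrain time courses as mixed ANOVA (between = group, within = time,
subject as the error stratum for time), since the published time-course
degrees of freedom imply repeated measures although the test is named
two-way; Tukey or Bonferroni post-hoc comparisons; α = 0.05. Sexes are
pooled for analysis (no sex differences in these outcomes), and both pooled
and stratified paths run identically apart from n.

Sample size: the smallest per-group n for which a two-sided two-sample
t-test at α = 0.05 reaches power 0.80 against Δ = 20% of a reference mean,
by exact noncentral-t iteration. For the reference design (mean 59.0, SD
8.5, d ≈ 1.39) this gives n = 10 per group; the historical choice of 8
corresponds to a one-sided reading of the same inputs. The end-to-end
runner flags configured cohorts below the computed requirement.

## What the generators do and do not emulate

The trace generator reproduces the protocol timing, the separability of
nerve- and muscle-evoked force, realistic group dispersion and
additive recording noise. It does not model quantal release, vesicle
depletion, EMG, per-pulse force ripple, length–tension artifacts, or
temperature effects; failure is phenomenological. The stack generator
reproduces plausible endplate geometry, partial pre/post overlap, PSF blur
and shot-like noise, but not optical sectioning physics, fluorophore
spectra, chromatic registration error, or tissue autofluorescence.
Passing round-trip tests therefore demonstrates that the analyzers recover
the quantities they define, at realistic noise, from data whose generative
assumptions are known — not that the analyzers are robust to every artifact
of real recordings and micrographs.

## Numerical and degenerate-input conventions

All simulations and renders are deterministic given their seed (per-member
seeds spawned via `numpy` SeedSequence). Zero initial forces, empty masks,
constant images under Otsu, all-zero stacks, truncated recordings (missing
the final epoch) and insufficient ANOVA replication raise `ValueError` with
the offending quantity named. Recorded forces are clipped at zero after
noise. Problem sizes used throughout the tests and the acceptance script —
8 preparations per trace condition, 20 stacks per morphometry condition,
121-s recordings at 1 kHz, 256² × 8 × 2 voxel stacks — were chosen as the
smallest cohorts at which Monte-Carlo means are stable to well inside the
stated tolerances.
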