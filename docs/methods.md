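# Methods

This note documents the model's assumptions, parameter choices and known
limitations, in the package's own terms.

## Neural representation

Ensembles of normalized LIF neurons (R = 1, threshold 1, reset 0; membrane
time constant τ_RC = 20 ms, refractory 2 ms) represent real-valued
vectors. Simulation uses a 1 ms step with exponential-Euler voltage
updates and sub-step spike-time interpolation, so simulated rates track
the closed-form rate equation to well under 5% even at near-refractory
rates. Encoders are random unit vectors; intercepts default to
Uniform(−1, 0.9) and maximum rates to Uniform(200, 400) Hz. Decoders are
solved by ridge regression on sampled evaluation points with the
regularizer λ = (0.1·max activity)² · n_points; connections may scale this
(`reg_scale`) when the represented set is a known low-dimensional manifold
and shrinkage would bias the feedback gain of recurrent buffers. Synapses
are first-order low-pass filters with unit DC gain (5 ms cortical default,
2/8 ms AMPA/GABA in the basal ganglia, 100 ms for integrators and working
memories). Part of the visual system uses adaptive LIF neurons (adaptation
time constant 0.1 s; increment 0.22, set so that a sustained mid-range
input roughly halves the rate within half a second).

## Semantic pointers

Vocabularies hold named random unit vectors (512-D at full fidelity, 64-D
at desk scale). Pairs are `ITEM1 ⊛ w1 + ITEM2 ⊛ w2` and are deliberately
not renormalized: vector length is the clarity of a representation.
Unbinding uses the index-reversed approximate inverse; since convolution
with a *fixed* role vector is linear, unbinding sits directly on neural
connections as a circulant transform. Cleanup memories exist in a
mathematical form and as a spiking associative layer (a block of
thresholded neurons per candidate whose solved decoders snap the input to
the best candidate); the no-match threshold is 0.25–0.3 similarity.
Control states use a mutually orthonormal pointer set: condition
cross-talk between action rules must be zero, and orthonormality is what a
learned control vocabulary would approximate at high dimension.

## Plasticity

* **PES** `Δd_i = κ r a_i`, error r = input − output, activities are 5
  ms-filtered rates. The module-level default κ = 1e-4 is appropriate for
  noiseless rate-mode use; inside spiking feedback loops the effective
  gain is κ·Σa², so the memory modules use κ = 2e-6 (declarative) and
  5e-6 (familiarity) at main populations of 800 neurons.
* **Voja±** ratio form `Δe_i = η a_i (x − e_i)/(a_i − σ)` for a_i > 0,
  clamped to 0.01 per step, encoders renormalized after every update.
  The ratio form is the default because the effect is strongest when
  activity is near the threshold; the product form
  `η a_i (x − e_i)(a_i − σ)` is available by configuration. The desk
  calibration is η = 0.03 and σ = 240 Hz: with maximum rates of 200–400
  Hz, σ sits above nearly every response of a freshly initialized neuron,
  so early learning is dominated by repulsion — far more neurons are
  repelled than attracted — and only strongly driven neurons specialize.
  This is what makes the response to an item *decrease* with exposure.
* **BCM** `Δω_ij = κ a_i a_j (a_j − θ_j)` on the declarative recurrence,
  with θ a 1 s low-pass of a² normalized by a 100 Hz reference rate, and a
  hard weight limit (2e-5 at desk scale, so the recurrent current stays a
  fraction of the feedforward drive).

## Memory system

Both memories: a sparse main population (high intercepts placed at the
(1−p) quantile of the encoder–input cosine distribution, p ∈ [0.02,
0.15] — "high" must be read relative to the 1/√D concentration of random
directions) and an output layer of 10 neurons per dimension (50 at full
fidelity), PES-trained to reproduce the presented item. Declarative
additionally has Voja± on its input and the BCM recurrence; familiarity
has neither. Familiarity is trained on single words, declarative on bound
pairs.

**Training schedule.** Fan-2 items are presented about twice as often as
fan-1 items — 11 versus 5 exposures, the mean human cued-recall response
counts — at half the duration (0.3 vs 0.6 s at desk scale; 0.5 vs 1.0 s at
full fidelity). The exposure *counts* matter: fan-2 items receive ~10%
more integrated exposure plus twice the interleaving churn, and since the
net effect of exposure under Voja± is repulsive, frequently seen items end
up driving less activity. With an exactly equal-time schedule the
mechanism has no dose difference to act on.

**What carries the fan effect at desk scale.** Across seeds, the summed
main-population response to fan-1 pairs exceeds fan-2 robustly (ratio
≈ 1.2–1.6), and pattern separation (pairwise active-set overlap) reliably
drops below its untrained baseline. The *output-norm* clarity measure,
however, is noisy at 800 neurons: converged PES decoders largely
compensate for activity differences, and per-pair variation (active sets
of 9–30 neurons) is larger than the fan gradient, so the clarity ordering
holds only on average over seeds and can invert for individual draws.
This is a scale limitation, not a property of the rule.

## Action selection

The basal ganglia follow the standard box-model equations (striatal D1/D2,
STN, GPe, GPi with the usual thresholds and weights), each internal
quantity approximated by 50 spiking neurons per action channel. Decoders
for these pathways are solved with non-negative least squares so that
merged weights inherit the anatomical sign (striatal and pallidal
projections inhibitory, STN excitatory). A dedicated rate-model
fixed-point iterator serves as the independent selection oracle. The
thalamus holds tonically biased relays inhibited at −4.5× the GPi output;
a "do-nothing" channel pinned at the 0.3 utility threshold wins whenever
no rule condition matches.

**Pulse gating.** Each long cognitive action has a brief transition rule
whose effects *switch* cortical gates; the gates then stay switched until
the next transition (sustained adjusted connectivity after a brief
thalamic pulse, 50 ms default). In the continuous comparison mode,
maintainer rules stay selected for the whole stage and hold the gates
through sustained thalamic output — reproducing the default-framework
behaviour and making the energy cost of continuous gating measurable.

## Evidence accumulation

Integrators are recurrent identity-trained populations (synapse 0.1 s);
input is scaled by the recurrent time constant so the represented value
integrates the signed drift. Drift parameters default to the mean
fitted values: familiarity +1.14 / −0.10, retrieval +0.0057, comparison
threshold 0.89 and negative drift −0.11. Their timescales are mutually
irreconcilable under any single per-second reading, so the package
introduces two structural constants per accumulator, chosen once from
stage-duration arithmetic and exposed in configuration: an evidence gain
(1 for familiarity; 1000 for retrieval, i.e. its drift value is read per
millisecond; 2.5 for comparison) and asymmetric bound magnitudes
(familiarity +0.25/−0.06; retrieval 0.6; comparison +0.89/−0.25). These
place the familiarity decision near 250 ms, retrieval completion near
300–500 ms, and make negative decisions (absence of evidence) slower than
positive ones, as the asymmetric rates require. Retrieval evidence is the
declarative output norm above a 0.4 clarity floor; familiarity evidence is
±1 from thresholding the familiarity index at 0.5.

## Assembly and trial flow

The visual parser (300 desk / 2,000 full-fidelity adaptive-LIF neurons
with random 9×9 Gabor encoders over the 90×14 word image) feeds a
visual representation whose decoders are solved on the actual word images
(the parser never sees arbitrary pixel vectors); a concept lookup maps the
representation to the nearest word prototype and emits its pointer — the
desk-scale stand-in for the full trained visual hierarchy. Words are
attended in turn (150 ms each with a 50 ms saccade gap; the gap prevents
the parser's activity tail from blending consecutive words). The two
latched concepts are bound into the pair pointer.

Working-memory buffers (visual buffer, prefrontal representation) hold
pair vectors. Three engineering choices keep them stable at desk scale,
all documented here because they are easy to get wrong: (1) identity
decoders are solved on the *pair manifold* (random role-bound pairs at
varied clarity) with light regularization, since generic 64-D identity
decoding from ~500 neurons shrinks the feedback gain far below one;
(2) loading is difference-gated — the drive is k·(target − current) — so a
buffer converges to its target instead of integrating it into saturation;
(3) inter-trial resets inhibit the populations *and* clear the recurrent
synaptic traces, whose 100 ms time constants would otherwise carry the
previous trial's content through the reset. The representation stage is
held in reset until the retrieval accumulator shows real clarity evidence,
then re-expresses the retrieved direction at working strength (scaling
capped at 2×, empty retrievals stay empty).

The comparison unbinds both buffers word-by-word through spiking cleanup
layers over the studied words. Both cleaned slots agreeing is match
evidence (+1); any slot disagreeing — including a word with no retrieved
counterpart, the recall-to-reject signal — is mismatch evidence (−1);
evidence is zero only when there is nothing to compare. The motor stage
pre-activates both candidate fingers at 30% of the press threshold during
the decision, then drives the selected finger (index = yes, middle = no,
routed by the block's response hand); the key press is the threshold
crossing plus a fixed 60 ms transduction latency.

Scalar quantities that would need neural product networks (the familiarity
index dot product, the pair-binding of two attended words, the
match-evidence combination) are computed in node callbacks that feed
dedicated spiking populations; at desk scale this substitutes for product
networks without changing the information flow.

## Problem sizes

Desk scale uses 64-D pointers, 800-neuron memory mains, 300 parser
neurons, 512-neuron buffers, and a reduced experiment: a mini study list
of 4 fan-1 pairs plus 8 fan-2 pairs (two word-sharing cycles — one cycle
admits no re-paired foil because every recombination is studied), with
balanced test sets of 20–30 trials in the 2:2:1 target/re-paired/new-foil
composition of the full 80-trial blocks. The full design (32 pairs, 14
blocks, 1,120 trials) is generated and validated structurally. One
simulated participant (training plus 25 trials) takes ≈7 minutes on one
CPU.

## What the synthetic conditions do and do not show

Stimuli are synthetic pronounceable strings; only length class matters.
Pointers are random directions, so semantic relatedness between words is
absent by construction. Passing tests show that the architecture
reproduces the qualitative behavioural and neural patterns — fast new-foil
rejections, slow re-paired-foil rejections, retrieval-limited fan effects,
pattern separation, pulse-gating energy savings, and the
activity-versus-hemodynamics dissociation — under controlled synthetic
conditions. They do not show quantitative fits to human recordings, which
require the full-scale model and human data and are out of scope.

## Known limitations

* The output-norm clarity fan effect is seed-dependent at desk scale (see
  above); the activity fan effect is the robust carrier.
* Error rates are higher than human performance, dominated by weak or
  wrong retrievals at 800-neuron capacity; re-paired foils can be
  falsely accepted when the memory echoes the probe itself.
* The visual hierarchy between Gabor parsing and word pointers is a
  documented lookup stage, not a trained multi-layer network.
* Response-hand routing reads the trial's hand label directly; a full
  implementation would hold it in a control-state pointer.
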