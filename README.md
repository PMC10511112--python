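# neurocog

A spiking-neuron brain model of **associative recognition** — judging
whether two words were studied together — built from biologically grounded
components: leaky integrate-and-fire (LIF) ensembles with solved connection
weights, high-dimensional semantic pointers, a dual memory system with
three plasticity rules, basal-ganglia/thalamus action selection with brief
pulse gating, drift-to-bound evidence accumulation, and forward models that
turn spikes into MEG- and BOLD-like predictions.

The package is aimed at computational cognitive neuroscientists who want a
runnable, testable implementation of a whole-task spiking architecture at
"desk" scale (64-dimensional pointers, populations of a few hundred to a
few thousand neurons on one CPU), with the full-fidelity configuration
(512-D pointers, 30k-neuron memory populations, 2,000 Gabor-tuned
adaptive-LIF visual neurons) preserved as a preset.

## The model

**Representation.** A population of LIF neurons represents a vector *x*
through tuning curves: neuron *i* receives current
`J_i = α_i (e_i · x) + J_i^bias` and fires with the LIF nonlinearity;
decoding weights `d` are solved by ridge regression so that the filtered
spike trains reconstruct *x* (or any function of it). The product
`ω_ij = d_i · e_j` yields full connection weight matrices; factored and
merged forms simulate identically.

**Words and pairs.** Words are random 512-D (desk: 64-D) unit vectors;
a pair is the role-bound sum `ITEM1 ⊛ word1 + ITEM2 ⊛ word2`, with ⊛
circular convolution. Vector length carries the *clarity* of a
representation.

**Memory.** A familiarity memory (perirhinal analogue) and a declarative
memory (hippocampal analogue) each consist of a sparse high-intercept main
population and an output layer trained with the error-driven PES rule
(`Δd_i = κ r a_i`). The declarative memory additionally applies the
**Voja± rule** to its input encoders,

    Δe_i = 0                       if a_i = 0
    Δe_i = η a_i (x − e_i)/(a_i − σ)   if a_i > 0

which attracts strongly responding neurons toward the input and repels
weakly responding ones (strongest near the threshold σ), producing very
strong pattern separation — and, because far more neurons are repelled
than attracted, stimuli seen more often during study (fan-2 pairs) end up
driving *less* activity. An all-to-all BCM recurrence
(`Δω_ij = κ a_i a_j (a_j − θ_j)`, weight-limited) binds active patterns.

**Task flow.** Each trial proceeds encode → familiarity → (retrieve →
compare) → respond, sequenced by a Gurney-style spiking basal ganglia
whose thalamic output fires *brief pulses* that switch cortical gating
(sustained adjusted connectivity), rather than holding gates open with
continuous input. Familiarity, retrieval and decision are
accumulate-to-bound processes with the model's standard drift-rate parameters
(positive familiarity drift 1.14, negative −0.10, retrieval drift 0.0057,
comparison threshold 0.89, negative comparison drift −0.11). New foils
short-circuit to a fast "no" at the familiarity stage; re-paired foils are
rejected by retrieving the actual studied pair and detecting the mismatch
word-by-word through cleanup memories.

**Forward models.** MEG-like signals are mixture-weighted sums of spikes
per region (middle temporal = 60% familiarity + 40% declarative; superior
temporal = 55% declarative + 45% familiarity); BOLD-like signals convolve
per-module neurotransmitter usage (|weight|-weighted presynaptic activity)
with the canonical double-gamma hemodynamic response. The two dissociate:
fan-1 pairs evoke the larger momentary response while fan-2 trials, which
last longer, can produce the larger hemodynamic integral.

## Worked example

```python
from neurocog.config import RunConfig
from neurocog.runner import simulate_participant

cfg = RunConfig()
cfg.n_trials = 30
res = simulate_participant(cfg, seed=1)
ok = res.trials[(res.trials.response != "none") & res.trials.correct]
print(ok.groupby("probe").rt_ms.mean().round(0))
```

At desk scale with seed 1 this prints (values from an actual run):

```
probe
new_foil          947.0
repaired_foil    2968.0
target           1434.0
```

New foils are rejected quickly from familiarity alone; targets require
retrieval plus a matching comparison; re-paired foils are slowest because
rejecting them needs the full recall-to-reject chain with a lower negative
accumulation rate — the qualitative response-time pattern of human
associative recognition. `res.trials` also records per-stage crossing
times (familiarity, retrieval, decision) for every trial, and
`res.model.activity_log` / `usage_log` feed the MEG and BOLD proxies in
`neurocog.forward`.

A command-line interface wraps the same pipeline:

```bash
neurocog run-participant --seed 1 --n-trials 30 --out participant_out
neurocog report participant_out/trials.csv
```

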