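# Methods

## Task and corpus

The decoding target is a closed eight-sentence corpus: three ordered slots
(subject, destination, verb), two romaji phrase options per slot, so a
sentence is a point in {0,1}³. Phrases carry token IDs 0–5 (`watashiwa` 0,
`kimito` 1, `gakko:e` 2, `shokubani` 3, `itta` 4, `mukau` 5); 6 and 7 are
the start/end markers, and a full target sequence is `[6, t1, t2, t3, 7]`.
Trial schedules are balanced-then-shuffled: every sentence appears exactly
`n_trials/8` times (10 times in the standard 80-trial session), permuted by
a seeded RNG. Scoring always excludes the markers, so the TER denominator is
3 tokens per sentence and the chance floor of a constant guess is 50%.

## Synthetic recordings

Real clinical ECoG for this task cannot be redistributed, so the generator
emulates the study conditions with planted ground truth. Per trial and task
(overt, covert, perception) it produces a 32-electrode recording at 1200 Hz:
a 0.6 s dummy lead-in plus a 3.5 s sentence interval, inside a padded
segment, with a trigger table naming both intervals.

* **Background** is 1/f (pink) noise, unit RMS per electrode, plus 50 Hz
  line noise and its 100 Hz harmonic with random phases (amplitude 0.5 and
  0.25 of background RMS). Pink rather than white noise so the notch and
  band-pass stages face a realistic spectrum.
* **Token codes.** The sentence interval is split into equal thirds — the
  pacing implied by constant-rate text highlighting — and each third carries
  its slot's token as an amplitude-modulated 70–150 Hz noise burst (Tukey
  envelope, α = 0.25) on that token's electrode subset. Overt sets are
  disjoint pairs of electrodes (token *t* → {2t, 2t+1}); a second disjoint
  bank (electrodes 12–23) serves as covert-only territory, and electrodes
  24–31 never carry codes. Burst amplitude is calibrated against a Welch
  estimate of the background's 70–150 Hz band power and re-normalized per
  burst after windowing, so the in-window SNR equals `snr_db` (default
  10 dB, a deliberately clean regime in which recovery failures indicate
  pipeline defects rather than noise).
* **Covert condition.** Following the motor hypothesis that inner speech is
  an attenuated, less focal copy of overt speech, covert bursts are scaled
  by `covert_gain` (default 0.7), placed on electrode sets sharing a
  fraction `overlap` (α, default 1.0) of their electrodes with the overt
  sets — the remainder drawn from the covert-only bank — and leak at gain
  0.3 onto adjacent electrodes (`covert_spread`). With α = 1, gain = 1,
  spread = 0 the overt and covert generative laws coincide exactly.
* **Audio.** Overt and perception trials carry a 16 kHz waveform: three
  equal-duration harmonic complexes with token-specific fundamentals
  (110–349 Hz) and token-dependent formant-like harmonic envelopes, so MFCC
  trajectories separate tokens (verified: minimum inter-sentence MFCC
  distance exceeds maximum intra-sentence distance across noise seeds).
  Covert trials have no audio; perception-trial raw signal is background
  plus weak token-independent bursts and is used only as the covert model's
  audio source.

Everything derives from one seeded generator: identical configs give
bitwise-identical datasets.

**What the generator does not emulate.** No biophysics, no electrode
geometry, no artifacts or non-stationarity, token codes aligned to exact
thirds, and spatial codes far cleaner than cortex provides. Passing
recovery tests therefore demonstrates that the pipeline extracts planted
spatio-temporal amplitude codes end to end — not that real covert speech is
decodable at any particular accuracy.

## Feature extraction

Order is fixed: **trim → resample/notch → band envelopes → z-score**.
Trimming before any filtering prevents transients of neighboring periods
from leaking into the segment; all segments are cut to the dataset-wide
maximum sentence duration so length cannot encode sentence identity.

Resampling to 400 Hz uses polyphase filtering (anti-alias low-pass included;
for 1200 Hz input the cutoff sits at the 200 Hz Nyquist of the target
rate). Two IIR notches (50, 100 Hz, Q = 30, applied forward–backward)
remove line noise. Eight FIR band-pass filters (Hamming windowed-sinc,
401 taps) cover 68–78, 74–84, 82–92, 91–102, 101–112, 112–124, 124–136 and
137–150 Hz; `firwin` places the −6 dB points on these printed edges. The
tap count is bounded by zero-phase filtering: `filtfilt` needs a pad of 3×
the filter length inside a 1400-sample segment, which caps the order at
~460; at 401 taps the transition width is ≈3 Hz and the bands' printed
1 Hz seam at 136–137 Hz dips to −12 dB (single pass). Per band the
analytic-signal amplitude (Hilbert envelope) is taken, the eight envelopes
averaged, decimated 2:1 to 200 Hz behind an anti-alias low-pass, and
z-scored **per electrode per segment** (mean 0, sd 1 to 1e−6). Per-segment
normalization needs no cross-trial state, so no statistics can cross a
cross-validation fold boundary. A constant channel raises an error naming
the electrode; manual channel rejection is expressed as an explicit
exclusion list.

## Audio features

MFCCs use a 20 ms window, 5 ms step, pre-emphasis 0.97, Hamming window,
26 mel filters, DCT-II (orthonormal), 13 coefficients including c0,
sinusoidal liftering (22). The 13-coefficient width is forced by the
encoder head's 13 units. For the encoder target the MFCC frames are
decimated by the conv stride (every 12th frame) and edge-padded or
truncated to exactly N rows, with padding flagged. The overt model pairs
overt ECoG with the same trial's overt audio; the covert model pairs covert
ECoG with the same trial's perception audio (same sentence content). An
explicit `audio_source` argument substitutes another session's recordings
as audio donor — never silently. Because the MFCC head is auxiliary and
dropped at decode time, strict audio/ECoG synchrony is not required; the
tests shift audio by 10% of the segment without consequence.

## Networks

Implemented on the package's own numpy reverse-mode autodiff engine
(`ecogseq.nn`): broadcast-aware arithmetic, matmul, softmax/log-softmax,
gather/scatter embedding, slicing, concat — every op checked against
central finite differences (float64); the engine default is float32.

* **Temporal convolution**: kernel (12, K), stride (12, 1), 100 filters,
  dropout 0.1. Since the kernel spans all K electrodes and the stride
  equals the kernel's time width, this is a dense map of non-overlapping
  12-frame blocks; the input is right-zero-padded to a multiple of 12, and
  N = ⌈L/12⌉.
* **Transformer**: encoder of 2 post-norm layers (10 heads, width 100,
  feed-forward inner width 4× the model width, dropout 0.5); decoder of
  1 layer (width 500, masked self-attention, then cross-attention taking
  the encoder output as keys and values, dropout 0.5); token embedding
  8×500; sinusoidal positional encodings after the conv stage and the
  embedding (without them the attention stack is order-blind — verified by
  a frame-permutation test). "Hidden units" is read as model width, the
  conventional 4× inner width being a package choice.
* **BLSTM baseline**: same conv front end and heads; bidirectional LSTM
  encoder (50 units per direction → width 100), unidirectional LSTM decoder
  (width 500) initialized from the projected final encoder state, without
  cross-attention — the recurrent-baseline lineage this variant represents
  predates attention decoders.
* **Heads**: feed-forward 1 (100 → 13) predicts MFCCs during training only;
  feed-forward 2 (500 → 8) gives token logits.

Greedy decoding starts from token 6, appends the argmax at each step (ties
break toward the lowest ID, numpy argmax semantics), stops at token 7 or
after 4 generated tokens, and strips the markers. Teacher forcing
(right-shifted targets) is used in training.

## Training and experiments

Loss = cross-entropy over decoder positions + λ·MSE between predicted and
reference MFCCs, λ = 0.1; Adam with default moments at learning rate 5e−4,
batch 16, fixed 800 epochs (no schedule, no early stopping); an `epochs`
override exists for scaled runs. Repeat seeds are `base + 1000·fold +
repeat`, varying both initialization and batch order — deterministic on
CPU. Folds stratify by sentence (80 trials / 5 folds → 2 of each sentence
per fold, 64/16 train/test); train/test leakage is a hard error. The
shuffle control permutes each training segment's time frames jointly across
electrodes with a per-segment seeded permutation, preserving per-electrode
marginals exactly; test segments stay intact.

## Evaluation and statistics

TER per decode from a unit-cost Levenshtein alignment with backtrace
(ties prefer match/substitution, then deletion, then insertion; S+D+I is
the unique minimum either way, verified against an independent brute-force
oracle and edlib). Aggregation averages over all (model × fold × segment)
results. Comparisons: one-sided Wilcoxon signed-rank (exact distribution
for n ≤ 25, zeros dropped), Holm–Bonferroni over a family of m = 6 by
default (placeholders fill the family when fewer comparisons are supplied,
which is conservative), Cohen's *d* pooled by default with a paired
(mean/sd of differences) option.

## Electrode contributions

The saliency map of a decode is |∂ Σ_m log p(token_m) / ∂ features|,
teacher-forced on the reference by default (the hypothesis is an option),
dropout off; its shape equals the feature matrix. Per map, the variance
along time per electrode is z-scored across electrodes (relative
contributions; scale-free per trial) and averaged over maps. Scores are
exported as CSV per electrode; anatomical projection is out of scope since
no electrode coordinates exist for synthetic data.

## Scaled study size and known behavior

The test suite and the acceptance script run the full design at a reduced
budget chosen as the package's desk-scale standard: 80 trials,
32 electrodes, 2 folds × 1 repeat, 100 epochs. At these conditions the
in-sample decoder reaches ~0–2% TER, the overt-trained decoder transfers to
covert test data within a few points of the covert-trained one (α = 1,
gain = 0.7), and saliency scores rank planted electrodes above background
(Spearman ρ ≈ 0.7–0.85).

One behavior deserves emphasis: the shuffle-trained control hovers at
43–50% TER, occasionally a few points **below** the 50% constant-guess
floor. Time-shuffling preserves each electrode's envelope distribution and
instantaneous cross-electrode co-activation; burst codes skew those
marginals on informative electrodes, so a shuffle-trained model retains a
small, genuine edge at high SNR. This is a property of amplitude-burst
codes under time-only shuffling, not a defect of the control's
implementation; with real recordings (weaker, less spatially clean codes)
the same control sits at chance.

## Limitations

No real-data validation is possible inside the package; hyperparameters are
fixed rather than searched; greedy decoding only (no beam search); the
BLSTM baseline's layer sizes mirror the Transformer widths rather than any
published recurrent configuration; float32 arithmetic bounds
reproducibility across BLAS implementations to ~1e−6 per op.
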