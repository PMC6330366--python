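# Methods

## Model and assumptions

f0track treats fundamental-frequency estimation as frequency-domain peak
picking. The signal is assumed *tonal*: at any instant one (possibly
modulated) sinusoidal component dominates the spectrum, and that component
is the fundamental. Under this assumption the f0 trajectory is read directly
off the spectrogram:

    f0(t_k) = argmax_{f in [f_min, f_max]} S(f, t_k)

where `S` is the squared DFT magnitude of consecutive windowed segments.
Silent or noise-only bins receive no estimate; they are identified by
thresholding the amplitude envelope, not the spectrum. Nothing is smoothed,
interpolated or tracked across bins: each column is estimated independently,
which keeps the estimator transparent and makes its failure modes local.

The assumption breaks when a harmonic is more intense than the fundamental;
the tracker then reports the harmonic. The frequency band is the only
mitigation offered (place `f_min` above noise and below the fundamental,
`f_max` below strong harmonics). Recovering f0 in the harmonic-dominant
regime is deliberately out of scope, and a regression test documents the
behavior (a 600 Hz fundamental below the band with a half-amplitude second
harmonic inside it yields 1200 Hz).

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| `window` | 1024 | samples | 23.2 ms at 44.1 kHz: below the 33 ms syllable bound (below), 43.07 Hz bins |
| `overlap` | 512 | samples | 50% overlap; columns stay largely independent (no Welch averaging) |
| `window_function` | hann | — | standard low-leakage taper; any scipy window name accepted |
| `f_min`, `f_max` | 800, 8000 | Hz | the canary singing range; `f_max` above Nyquist is clipped with a warning |
| `threshold` | relative 0.05 | fraction of peak envelope | robust across recording gains; absolute mode for calibrated pipelines |
| `smooth_ms` | 5 | ms | envelope moving-average width; short enough to keep 10 ms syllables |
| `channel_policy` | average | — | stereo is collapsed before analysis; left/right/index also available |
| `max_syllabic_rate` | 30 | Hz | fastest syllable rate to resolve; drives the window-duration warning |

**Time-resolution bound.** To separate syllables produced at rate `R` the
window duration must be strictly below `1/R`. Canaries sing at 3-30 Hz, so
the bound is 1/30 s = 33 ms; the shortest syllables (~10 ms) argue for even
shorter windows at the cost of frequency resolution. The bound is enforced
as a warning, never an error, because the right compromise depends on the
recording.

**Accuracy.** The estimate is the raw grid frequency of the peak bin, so the
contract is ±1 bin (`sample_rate / window`); for a steady tone the peak lands
on the nearest bin, i.e. typically within half a bin. Parabolic interpolation
would sharpen this but would change the estimator; it is intentionally
omitted.

## Envelope and gate

The envelope is the magnitude of the analytic signal (Hilbert transform),
smoothed by a centered moving average (`smooth_ms`, rounded to samples,
nearest-value edge handling). The envelope definition is a design choice of
this package — rectification-plus-lowpass variants exist, and the smoothing
width is configurable so other definitions can be approximated.

Each spectrogram bin takes the *maximum* envelope value over its window
extent `[k*hop, k*hop + window)`: a bin containing any part of a syllable
onset counts as sound. The gate is `level >= T` with `T = r * max(level)`
(relative mode) or an absolute amplitude; ties count as voiced so the
behavior is deterministic. An all-zero recording is all-silent under
relative mode with `r > 0`. Silent bins carry NaN, never 0 Hz, because 0 Hz
is a legal spectrogram frequency.

## Numerical choices

- Segments start at sample 0 and advance by `hop = window - overlap`;
  trailing samples that do not fill a window are discarded, giving exactly
  `floor((n - window)/hop) + 1` columns. Bin-center times are
  `(k*hop + window/2)/sample_rate`.
- Power is stored linearly (squared magnitude, one-sided, no doubling, no
  zero-padding). Per-bin argmax is invariant under any monotone rescaling,
  so the scale convention cannot change tracker output; dB appears only in
  plots. One column satisfies Parseval against the windowed segment's
  time-domain energy, which the tests verify.
- Argmax ties break toward the lowest frequency (numpy's first-maximum),
  biasing toward the fundamental.
- Integer PCM is normalized by the type's full-scale magnitude (32768 for
  16-bit), keeping absolute thresholds comparable across encodings. 16-bit
  writing scales by 32768 with clipping, so write-then-read errs by at most
  2^-15.
- The output table is tab-separated text with a `#` header, 6 significant
  digits, and the literal token `nan` for silent bins.

## Synthetic fixtures: what they do and do not show

The generator emulates canary-like song: pure tones and linear sweeps in the
800 Hz-8 kHz range, syllable trains with raised-cosine onset/offset ramps
(default 5 ms, preventing edge splatter from leaking across the gate),
optional integer-multiple harmonic partials, and seeded white Gaussian
background noise. With zero noise the gaps are exactly zero, enabling exact
silence-gating tests; ground-truth onsets and linear f0 trajectories are
returned alongside the waveform, derived from the actual rendered sample
indices.

It does **not** emulate amplitude modulation, reverberation, colored or
nonstationary noise, biomechanical (syrinx) source-filter structure, or
overlapping singers. Passing tests therefore demonstrate correctness of the
algorithm's mechanics and its stated contracts — not that a given field
recording is tonal enough, or its band setting tight enough, for the peak
frequency to be the fundamental.

Test and acceptance problem sizes: 0.3-2 s signals at 8-44.1 kHz, 20 random
tones per window length, 100 random 64x40 grids for the peak-picking oracle,
a 5-syllable train — sizes at which every check is exact or
bin-width-bounded and the whole suite runs in seconds.

## Known limitations

- Harmonic-dominant sounds are reported at the harmonic (see above).
- No octave-error correction, pitch smoothing or syllable segmentation.
- Frequency resolution is the bin width; fast sweeps blur across bins within
  a window, so the per-bin estimate is the window-average peak.
- The relative threshold is global (fraction of the recording's peak): a
  recording whose loudest event dwarfs the song will under-gate; use the
  absolute mode in that case.
- WAV only (PCM 8/16/24/32-bit, IEEE float); no resampling or compressed
  codecs.
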