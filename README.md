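# f0track

Fundamental-frequency (f0) tracking for tonal animal sounds, built around
canary (*Serinus canaria*) song analysis. For biologists and bioacousticians
who need a simple, transparent, tunable f0 trajectory from field or lab
recordings without signal-processing expertise: no model fitting, no hidden
state — just the spectral peak of each spectrogram column, gated by loudness.

## The method

For a mostly tonal sound the strongest spectral component of each short-time
spectrum *is* the fundamental, so the tracker computes

1. a short-time spectrogram `S(f, t_k)` from consecutive windowed segments
   (window `N` samples, hop `N − overlap`, Hann taper by default, squared
   DFT magnitude, no averaging between segments);
2. a band restriction `f ∈ [f_min, f_max]` — default 800 Hz–8 kHz, the
   canary singing range — which also suppresses out-of-band harmonics and
   low-frequency noise;
3. the per-column intensity maximum
   `f0(t_k) = argmax_{f ∈ [f_min, f_max]} S(f, t_k)`, ties broken toward the
   lowest frequency;
4. an amplitude-envelope gate: the analytic-signal magnitude, smoothed by a
   short moving average, is reduced to one level per time bin; bins whose
   level falls below a threshold `E` (default 5% of the recording's peak
   envelope) are marked silent and carry `NaN` instead of a frequency.

Accuracy is ±1 frequency bin (`sample_rate / window`); there is no peak
interpolation. The window duration must stay below the syllable period —
canaries sing at 3–30 Hz syllabic rate, so windows must be shorter than
1/30 s ≈ 33 ms (the default 1024 samples at 44.1 kHz is 23.2 ms); the
configuration validator warns when this compromise between time and
frequency resolution is violated. When a harmonic carries more in-band power
than the fundamental the tracker reports the harmonic — the band filter is
the intended mitigation, and recovering f0 in that regime is out of scope.

## Worked example

Generate a synthetic canary-like song — five 100 ms tonal syllables at 1, 2,
3, 4, 5 kHz separated by 150 ms silences — then track it:

```
f0track synth --preset train --train-f0 1000,2000,3000,4000,5000 \
              --out train.wav --truth truth.txt
f0track track --input train.wav --out-table f0.txt --plot f0.png
```

`f0.txt` holds one row per spectrogram time bin (tab-separated, seconds and
Hz). The opening silence is gated:

```
# time_s	f0_hz
0.01161	nan
0.02322	nan
```

and inside the first syllable the estimate sits at 990.527 Hz — the grid
frequency nearest 1000 Hz, 9.5 Hz from truth, well within the 43.07 Hz bin
width of a 1024-sample window at 44.1 kHz:

```
0.15093	990.527
0.16254	990.527
...
0.24381	990.527
0.25542	990.527
0.267029	nan
```

The manifest (`f0.txt.manifest.txt`) records the resolved parameters plus
`n_bins: 119` and `voiced_bins: 54`: the 54 voiced bins are exactly the bins
overlapping the five bursts. `f0.png` shows the four diagnostic panels
(waveform, spectrogram, f0 overlaid on the spectrogram, f0 vs. time).

The same pipeline from Python:

```python
import f0track as ft

signal = ft.read_wav("train.wav")
track = ft.track_f0(signal, ft.TrackerConfig(f_min=800, f_max=8000))
print(track.voiced_count, track.n_bins)   # -> 54 119
```

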