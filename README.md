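# nck

Analysis toolkit for discontinuous neonatal LFP recordings from paired
hippocampal (CA1) and prelimbic cortical sites: burst and sharp-wave
detection, spectral power, undirected and directed cross-region coupling,
spike-level statistics, and optogenetic pulse-train response analysis —
plus a synthetic two-region session generator with complete ground truth
so every stage can be validated without access to in-vivo data.

## What it does

- **core** — domain types (`Recording`, `SpikeTrainSet`, `BandDefinition`,
  `PulseProtocol`), zero-phase Butterworth filtering, anti-aliased
  downsampling, spike-band (500–5000 Hz) filtering.
- **synth** — deterministic synthetic sessions: 1/f background, tapered
  theta bursts placed as a renewal process (configurable occurrence,
  duration, envelope peak), sharp-wave transients reversing polarity
  across a designated pyramidal channel with superimposed ripples, delayed
  directional HP→PL coupling, and spike trains with von Mises phase
  locking, SPW modulation, and light-evoked responses.
- **detect** — oscillatory-event detection (sliding RMS of the 1–100 Hz
  signal against a threshold fitted from the Gaussian core of the RMS
  histogram; events <200 ms apart merged; only events >1 s kept) and
  sharp-wave detection (5-SD peaks of the ±100 µm channel-subtraction
  trace), plus automatic pyramidal-channel selection from the polarity
  reversal.
- **spectral** — Welch PSD on glued segments (1 s / 300 ms / 100 ms / 3 s
  presets), event-normalized relative power P(f)/P₀(f), Morlet
  spectrograms, band summaries, SPW-triggered pre/post power, and
  per-band stimulation power ratios P_stim/P_pre.
- **coupling** — imaginary coherence (squared form, unsquared variant
  available), wavelet denoising, least-squares VAR fitting with BIC order
  selection, generalized partial directed coherence with the exact
  column-normalization identity, and band-limited cross-correlograms.
- **spiking** — firing rates, SPW-triggered PSTHs, Hilbert-phase locking
  with the Rayleigh test, locked-unit fractions, and light-pulse
  stimulation efficacy (probability of ≥1 spike within 15 ms).
- **pipeline / cli** — end-to-end orchestration with JSON configs,
  reproducible manifests, CSV/Markdown reports, and the `nck` CLI.

## Test

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` implements the parameter-recovery and
calibration criteria (burst occurrence/duration/amplitude, SPW
rate/amplitude, firing rate, gPDC directionality and normalization,
imaginary-coherence nulls, Rayleigh type-I error, stimulation-efficacy
closed form) at their stated tolerances.

## CLI

```bash
nck simulate --config cfg.json --out session.h5 --truth truth.json
nck inspect session.h5
nck detect-bursts session.h5 --region HP --out events.csv
nck detect-spws session.h5 --pyr-channel 2 --out spws.csv
nck psd session.h5 --out psd.csv
nck coherence session.h5 --out imcoh.csv
nck gpdc session.h5 --out gpdc.json
nck xcorr session.h5
nck psth session.h5 --out psth.csv
nck phase-lock session.h5 --out locking.csv
nck stim-efficacy session.h5 --out efficacy.csv
nck run --config cfg.json --out outdir/ --seed 1
```

`cfg.json` holds a `"generator"` section (any `GeneratorConfig` field)
plus optional per-stage overrides (`detect`, `spw`, `spectral`,
`coupling`, `spiking`).

Sessions are HDF5 containers: `/regions/<name>/lfp` (float32
channels×samples with `fs`, `depths_um`, `t0` attributes),
`/regions/<name>/units/<id>/spike_times` (float64 seconds), and an
optional `/stimulation/pulse_onsets` group. Event tables are CSV with one
row per event (`region, channel, start_s, stop_s, amplitude_uv`).

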