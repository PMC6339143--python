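# oncoephys

Analysis toolkit for **extracellular electrophysiology of cancer-cell
populations** recorded on large-area (mm²) planar gold electrodes in a
multi-electrode array (MEA).  Non-neuronal tumour lines such as the
prostate-cancer model PC-3 produce picoampere-scale population currents
with two characteristic regimes:

* an **asynchronous, sporadic** regime — unipolar spikes of ~100 pA,
  mostly negative, widths mostly 30–200 ms, attributed to uncorrelated
  single-cell activity summed over the electrode;
* a **synchronous, quasi-periodic** regime — biphasic spikes of
  ±150 pA (widths 50–300 ms) recurring at ≈0.5 Hz, consistent with a
  slow extracellular wave (hundreds of µm/s) that raises the electrode
  potential on entry and lowers it on exit.

The package implements the full chain around these signals:

| stage | module | what it does |
|---|---|---|
| measurement model | `oncoephys.circuit` | v_o = −R_F·i_s and i_s = C_D·(dv_s/dt)·(1−e^{−t/τ}), τ = C_D·(R_c‖R_D), for the electrode–electrolyte interface |
| synthetic data | `oncoephys.simulate` | seeded generator for baseline / asynchronous / synchronous regimes and a three-phase channel-blocker protocol, with a ground-truth event log |
| spike detection | `oncoephys.detect` | ±threshold crossings (default ±50 pA), interpolated widths, refractory merging, greedy biphasic pairing |
| characterization | `oncoephys.characterize` | regime segmentation (rate + ISI regularity), amplitude/width/ISI histograms, wave-speed estimation from lobe separations |
| inhibition assay | `oncoephys.inhibition` | per-phase counts and robust fluctuation magnitudes; block / recovery calls |
| growth & viability | `oncoephys.viability` | electrode-count growth normalization, MTT percent viability, blocker dilution arithmetic |
| I/O & pipeline | `oncoephys.io`, `oncoephys.pipeline`, `oncoephys.cli` | CSV/HDF5 formats, strict config validation, end-to-end `run` with figures |

## Worked example

`examples/02_simulate_and_detect.py` simulates 10 min of each regime,
detects spikes and characterizes them:

```
simulated 1200 s at 1000 Hz, 303 ground-truth events
detected 576 threshold crossings
  asynchronous: [     0,    600) s, 28 spikes (0.047 /s)
   synchronous: [   600,   1200) s, 274 spikes (0.457 /s)
synchronous median |amplitude|: 150 pA (generator: ±150 pA)
synchronous rate: 0.46 spikes/s (one biphasic pair = one spike; ~0.5 Hz quasi-periodicity)
modal inter-spike-interval bin: 2-3 s
wave speed from 274 biphasic pairs: 3761 um/s (1 mm2 electrode crossed in 0.30 s)
```

Reading the numbers: the detector finds 576 threshold crossings, which
the pairer resolves into 274 biphasic spikes in the synchronous phase
and 28 sporadic spikes in the asynchronous phase — the ~10× count
disparity between regimes.  The synchronous spikes keep the generator's
±150 pA amplitude, recur at ≈0.5 Hz with the modal inter-spike interval
in the 2–3 s bin, and their 0.3-s lobe separation corresponds to a wave
crossing the 1.13-mm electrode diameter at the reported speed.

The other examples cover the circuit model (`01`), the blocker assay
with its block/recovery calls (`03`), and the growth/viability
arithmetic (`04`).  The same stages are scriptable from the shell:

```sh
oncoephys simulate --duration-s 1200 --seed 1 --out rec.h5
oncoephys detect --input rec.h5 --threshold-pa 50 --out events.csv
oncoephys characterize --events events.csv --span 0,1200 --out stats.json
oncoephys run --config config.yaml --out results/
```

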