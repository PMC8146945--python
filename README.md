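# snnmorph

Spiking-neural-network modelling of longitudinal EEG recorded around a
stepped morphing sound therapy, plus the stimulus-generation side of the
protocol and a synthetic-EEG generator for download-free testing.

The analysis chain mirrors the study design end to end:

1. **Synthetic data** (`snnmorph.synthetic`) — 66-channel recordings for
   the six-condition schedule (Pre, Sound 1–3, Post, 3-month Post) with
   *planted* lagged inter-channel couplings whose laterality moves
   left → bilateral → right across conditions. All conditions share one
   seeded noise background, so downstream differences are attributable
   purely to the planted structure.
2. **Spike encoding** (`snnmorph.encoding`) — Step Forward (SF) ternary
   encoding with a fixed threshold and moving baseline, per-channel
   threshold optimisation, and the decoding inverse used for validation.
3. **Reservoir** (`snnmorph.reservoir`) — neurons at 3D template
   coordinates (file-loaded grids or a synthetic ellipsoid lattice),
   nearest-neuron input mapping, distance-decaying small-world initial
   wiring, and discrete-time leaky integrate-and-fire dynamics (numba
   kernel).
4. **Plasticity** (`snnmorph.plasticity`) — nearest-spike STDP
   interleaved with the dynamics; one model per condition trained from an
   identical seeded initial state.
5. **Connectivity analysis** (`snnmorph.analysis`) — trained-model
   subtraction, increase/decrease classification, retention of the top
   5 % of relative changes, aggregation into ten scalp zones
   (left/right × frontal, frontocentral, temporal, centroparietal,
   occipitoparietal), a hemispheric dominance index, and a planted-layout
   recovery score.
6. **Sound morphing** (`snnmorph.morph`) — tinnitus-avatar synthesis
   (pure tone or band-limited noise on the octave-bandwidth ladder) and
   the acute (90 % → 10 %) and chronic (100 % → 0 % over four versions)
   intensity-ratio cross-fade schedules, rendered with a square-root
   amplitude law so the *power* ratio tracks the schedule.
7. **I/O & pipeline** (`snnmorph.pipeline`, `snnmorph.edf`,
   `snnmorph.checkpoint`, `snnmorph.cli`) — EDF/BDF/TSV recordings,
   anti-aliased decimation (8192 Hz → 256 Hz), YAML config, HDF5 model
   checkpoints, JSON reports, and a click CLI.

## CLI

```bash
snnmorph fixture --seed 1 --out fx/                  # synthetic study data
snnmorph encode --recording fx/Pre.tsv --threshold auto --out spikes.tsv
snnmorph reservoir --grid synthetic --seed 1 --out model.h5
snnmorph train --model model.h5 --recording fx/Sound1.tsv \
               --condition Sound1 --out trained.h5
snnmorph analyze --pre pre.h5 --post trained.h5 --out edges.tsv
snnmorph run --seed 1 --out results/                 # full pipeline
snnmorph morph render --pitch 4000 --bandwidth 0.5 --schedule acute \
                      --rate 16000 --out morph.wav
```

`snnmorph run` encodes each condition, trains per-condition models from
one shared seeded reservoir, subtracts every condition against Pre,
retains the top 5 % of relative changes, and writes `report.json`
(spike/firing counts, retained-edge counts, dominance and recovery score
per contrast) plus per-contrast edge tables and 10 × 10 region matrices.
Reports are byte-identical for a fixed seed.

## Notes

- A real recording can be substituted for the fixture: read it with
  `read_recording` (EDF/BDF/TSV), downsample to 256 Hz with
  `downsample`, tag conditions, and pass the list to `run_pipeline`.
- Default LIF/SWC/STDP parameters live in one config block
  (`PipelineConfig`) and are documented design choices, not fitted
  values.
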