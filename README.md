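# eegaffect

Session-level EEG affect detection: synthetic 62-channel EEG with
class-dependent band power, standard preprocessing (200 Hz, 0–75 Hz
zero-phase passband, 180 s segments), band-wise differential-entropy
features smoothed by a linear-dynamic-system pass, a 224×224 min–max
standardized feature image, a residual CNN 3-class emotion classifier
(negative / neutral / positive), a 1–100 pleasure score per measurement
session, and the detector-vs-questionnaire evaluation arithmetic.

The neural network is implemented in pure NumPy (im2col convolutions,
batch normalization, Adam with explicit backprop) so the whole pipeline is
bit-reproducible from seeds and runs offline on one CPU. Two presets exist:
`resnet50` (stage blocks [3, 4, 6, 3], 16 bottleneck blocks, 50 weighted
layers) and `small`, a narrow [1, 1, 1, 1] variant for desk-scale training.

## Package layout

| module | contents |
| --- | --- |
| `eegaffect.synthio` | seeded synthetic EEG generator (class profiles, datasets) |
| `eegaffect.preprocess` | resample / bandpass / segment |
| `eegaffect.features` | differential entropy, DE tensors, LDS smoothing, feature images |
| `eegaffect.model` | layers, residual network, training loop, split/selection |
| `eegaffect.detector` | session classification, pleasure score, improvement |
| `eegaffect.evaluate` | pairwise error, accuracy, group-contrast consistency |
| `eegaffect.io` | delimited/EDF/HDF5 readers & writers, manifests, SEED adapter, CLI glue |

## CLI

```bash
eegaffect synth --n-per-class 5 --duration 180 --rate 200 --seed 1 --outdir data/
eegaffect featurize --manifest data/manifest.csv --outdir feats/
eegaffect train --manifest data/manifest.csv --features-dir feats/ \
    --preset small --epochs 15 --seed 1 --out model.h5
eegaffect detect --input session.csv --model model.h5 --stimulus --out report.json
eegaffect evaluate --detector-scores det.csv --reference-scores ref.csv --out eval.json
```

Recordings are read/written as delimited text (channels as rows, header of
channel names), EDF, or an HDF5 array container (bit-exact round trips);
manifests and score tables are CSV.

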