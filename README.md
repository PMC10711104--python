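# stemleaf

Stem/leaf semantic segmentation and phenotyping toolkit for plant images:
a VGG16-encoder U-Net with a re-tuned ASPP bridge (dilation rates
1/2/7/15 validated against the gridding effect), criss-cross attention in
the decoder, a composite Dice + Boundary training loss, pixel-level
evaluation metrics (mPA, mIoU, precision, recall, F1), preprocessing
(cropping, median filtering), and downstream HSV/Otsu trait extraction
(crown area, stem/leaf proportions).

Everything runs on a pure numpy/scipy stack: the network core is a small
in-repo autograd backend (`stemleaf.nn`), so no deep-learning framework
is required. A seeded synthetic plant-scene generator (`stemleaf.synthdata`)
makes the whole pipeline exercisable end-to-end without any external data.

## CLI

```bash
# validate a dilation schedule (prints per-level M_i and the verdict)
stemleaf validate-rates --k 3 --rates 1,2,7,15

# generate a synthetic dataset (images/, masks/, train/val lists)
stemleaf synth --n 100 --size 128 --seed 7 --out data/

# crop + median-filter a directory of images
stemleaf preprocess --in data/images --out data/clean --crop 0,0,96,96 --median 3

# train / predict / evaluate
stemleaf train --config cfg.yaml --data data/ --out run/
stemleaf predict --ckpt run/model.npz --image data/images/scene_0000.png --out mask.png
stemleaf evaluate --ckpt run/model.npz --data data/ --out metrics.json

# phenotyping from a class mask (0=background, 1=stem, 2=leaf)
stemleaf phenotype --mask mask.png --scale 0.1 --out record.json
```

Training config is strict YAML (unknown keys error). Defaults: Adam,
learning rate 1e-3, batch size 4, 100 epochs, Dice+Boundary loss with
weight 1, 9:1 train/val split. Network options live under `network:`
(e.g. `width_scale`, `encoder_blocks`, `use_aspp`, `use_cca`,
`feature_norm` for from-scratch training stability). Every run writes a
JSON manifest (config echo, seed, input content hash, outputs).

## Layout

```
src/stemleaf/
  dilation.py    receptive-field arithmetic + gridding validation (rule & oracle)
  nn/            numpy autograd, layers, Adam
  segnet.py      network assembly (encoder/ASPP/decoder/CCA), training loop
  losses.py      Dice, signed-distance Boundary, composite
  metrics.py     confusion matrix and derived scores
  preprocess.py  crop, median filter (square/cross/line windows)
  phenotype.py   HSV ranges, Otsu, crown area, proportions, OLS fit
  synthdata.py   seeded scene/dataset generator (paletted PNG masks)
  config.py      strict run configuration
  runio.py       checkpoints and run manifests
  cli.py         `stemleaf` command group
```
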