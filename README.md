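# medcrypt

Privacy-preserving medical-image analysis needs two things at once: an
image cipher faithful enough that the decrypted scan is diagnostically
identical to the original, and a classification stack that turns the
restored images into a normal/abnormal decision. `medcrypt` implements
both ends for 8-bit grayscale images, exercised entirely on synthetic
brain phantoms so nothing external is required:

- **Cipher** — extended zigzag confusion (anti-diagonal scan from a
  chaotically chosen corner, defined for non-square matrices) followed by
  two-pass chained XOR diffusion, E_i = E_{i−1} ⊕ R_i ⊕ Q_i forward and
  its right-to-left mirror, with keystreams R1, R2 quantised from three
  logistic maps x ← r·x·(1−x) seeded by the secret key. The keystream is
  bound to a plaintext checksum so a one-pixel change re-keys the cipher
  and yields NPCR ≈ 99.6 %, UACI ≈ 33.5 % between ciphertext pairs. An
  optional block autoencoder (tansig/logsig, compression rate t = ui/ut)
  gives a lossy compressed mode; the default is bit-exact.
- **Cryptanalysis metrics** — histogram entropy F = −Σ p log₂ p,
  adjacent-pixel correlation r_xy over sampled neighbour pairs, NPCR and
  UACI (denominator 255).
- **Diagnosis stack** — improved PCA (component count chosen by the 85 %
  cumulative contribution-rate threshold), K-means intensity segmentation
  (Lloyd iterations, deterministic tie-breaks), and a fuzzy convolutional
  neural network: Gaussian fuzzification → fuzzified-kernel convolution →
  ReLU + max pooling → centre-of-gravity defuzzification → sigmoid
  classifier, trained by gradient descent on cross-entropy with
  hand-derived chain-rule gradients.
- **Phantom generator** — seeded MRI-like ellipse phantoms with optional
  bright tumour blobs, exact masks and labels.

See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
import numpy as np
import medcrypt as mc
from medcrypt.synthdata import PhantomConfig, generate_phantom

key = mc.random_key(seed=7)                      # the secret: a chaotic seed
img, label, mask = generate_phantom(PhantomConfig(size=(64, 64), seed=7),
                                    force_tumour=True)

cipher, meta = mc.encrypt(img, key)
restored = mc.decrypt(cipher, meta, key)
print(np.array_equal(restored, img))             # True — bit-exact round trip

report = mc.analyze(img, key, n_pairs=1500, seed=7)
print(f"{report.entropy_plain:.3f} {report.entropy_cipher:.3f}")
print(f"{report.npcr:.2f} {report.uaci:.2f}")
```

prints

```
True
6.233 7.956
99.54 34.28
```

The plain phantom carries 6.23 bits/pixel of histogram entropy; its
ciphertext reaches 7.96 bits (the 8-bit ideal for a 64×64 image is ~7.96
— entropy saturates toward 8 as the image grows), and encrypting a copy
that differs in a single pixel changes 99.54 % of ciphertext pixels with a
mean intensity change of 34.28 % of the gray range — i.e. the two
ciphertexts are statistically unrelated. Training the fuzzy CNN on 120
phantoms (75/25 split, 40 epochs, seeded) classifies the held-out
phantoms perfectly at the default 10-sigma lesion contrast:

```
held-out accuracy 1.00  sensitivity 1.00  specificity 1.00
```

The same flow is scriptable from the shell:

```sh
medcrypt keygen --seed 7 --out key.json
medcrypt simulate --n 50 --size 64 --seed 7 --out data/
medcrypt encrypt --key key.json --in data/phantom_0000.png --out cipher.png
medcrypt decrypt --key key.json --in cipher.png --out restored.png
medcrypt analyze --key key.json --in data/phantom_0000.png --report report.json
medcrypt pipeline --seed 7 --report run.json
```

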