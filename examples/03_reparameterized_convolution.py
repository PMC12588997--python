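"""Six-branch OREPA: train-time forward vs compressed single convolution.

The block sums six parallel linear branches during training; at inference it
folds analytically into one 3x3 convolution.  The fold is exact, and the
compressed form carries far fewer parameters.
"""

import numpy as np

from leafchem.segblocks import OREPABlock, orepa_compress, orepa_forward_train
from leafchem.segblocks.orepa import BRANCH_NAMES, fit_orepa, orepa_forward

rng = np.random.default_rng(0)
block = OREPABlock.init(c_in=8, c_out=8, rng=rng)
x = rng.normal(size=(8, 32, 32))

y_train = orepa_forward_train(x, block)
compressed = orepa_compress(block)
y_inference = orepa_forward(x, compressed)

print("branches:", ", ".join(BRANCH_NAMES))
print(f"max |train forward - compressed forward| = "
      f"{np.abs(y_train - y_inference).max():.2e}")      # float-epsilon scale
print(f"parameters: {block.n_parameters(compressed=False)} (train) -> "
      f"{compressed.n_parameters()} (compressed)")

# the block is trainable: fit it to a random target convolution
target = rng.normal(size=(8, 8, 3, 3))
from leafchem.segblocks.nn import conv2d
losses = fit_orepa(OREPABlock.init(8, 8, np.random.default_rng(1)),
                   [x], [conv2d(x, target)], lr=0.05, epochs=20)
print(f"training loss: {losses[0]:.3f} -> {losses[-1]:.3f}")
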