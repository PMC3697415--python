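"""Compare the three preprocessing variants on one pure spectrum.

SNV standardises each spectrum (mean 0, sd 1), removing multiplicative
scatter and offsets; orthogonal projection (OP) removes the component along
the pure-water spectrum, so the cosine between every OP spectrum and the
water reference is ~0.  The printed numbers verify both contracts.
"""

import numpy as np

from ocplsnir import (
    GeneratorConfig,
    PreprocessSpec,
    apply_preprocess,
    generate_study,
)

pure, _, reference, _ = generate_study(GeneratorConfig(seed=7))

raw = pure.matrix[0]
s = reference.absorbance
print(f"raw spectrum:  mean {raw.mean():.4f}  sd {raw.std(ddof=1):.4f}  "
      f"cos(x, water) {raw @ s / np.linalg.norm(raw) / np.linalg.norm(s):.4f}")

snv = apply_preprocess(pure, PreprocessSpec("snv")).matrix[0]
print(f"SNV spectrum:  mean {snv.mean():.1e}  sd {snv.std(ddof=1):.4f}  "
      "(standardised per spectrum)")

op = apply_preprocess(pure, PreprocessSpec("op", reference)).matrix[0]
cos = op @ s / np.linalg.norm(op) / np.linalg.norm(s)
print(f"OP spectrum:   mean {op.mean():.4f}  sd {op.std(ddof=1):.4f}  "
      f"cos(x, water) {cos:.1e}  (water direction removed)")
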