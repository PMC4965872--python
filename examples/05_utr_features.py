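"""Extract cis-element features from a 5'UTR sequence.

Plants known features into an AUG-free background, then recovers them with
the feature scanners and folds the cap window.
"""

import numpy as np

from isote import extract_features, plant_utr_features
from isote.simulate import random_background

rng = np.random.default_rng(3)
seq = plant_utr_features(
    random_background(rng, 220),
    ["top", "structure", "uorf", "uorf", "uaug_out", ("hexamer", "AATCCC")],
    rng,
)
fv = extract_features(seq)
print(f"UTR length: {fv.utr_length} nt")
print(f"uORFs: {fv.n_uorf}   in-frame uAUGs: {fv.n_uaug_in_frame}   "
      f"out-of-frame uAUGs: {fv.n_uaug_out_of_frame}")
print(f"5' TOP: {fv.has_top}")
print(f"cap-window MFE: {fv.fold.cap_mfe:.1f} kcal/mol  (stable: {fv.fold.cap_stable})")
print(f"hexamer occurrences counted: {int(fv.hexamers.sum())} "
      f"over {len(fv.hexamers)} AUG-free hexamers")
# The planted GC hairpin drives the cap-window MFE below -30 kcal/mol, the
# threshold for a translation-inhibiting cap-adjacent structure.
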