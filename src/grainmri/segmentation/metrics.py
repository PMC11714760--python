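"""Segmentation quality metrics."""

from __future__ import annotations

import numpy as np

from ..errors import ValidationError
from ..io import TISSUE_CLASSES


def dice_score(pred, truth, classes=TISSUE_CLASSES):
    """Per-class Sorensen-Dice overlap and its mean over tissue classes.

    D_c = 2 |pred_c & truth_c| / (|pred_c| + |truth_c|).  By default the
    mean runs over classes 1-4 (background ignored).  A class empty in both
    volumes scores 1.0 (correct absence); such classes are listed under the
    ``"empty"`` key of the returned dict.

    Accepts :class:`~grainmri.io.LabelVolume` objects or bare arrays.
    """
    p = pred.data if not isinstance(pred, np.ndarray) and hasattr(pred, "data") else np.asarray(pred)
    t = truth.data if not isinstance(truth, np.ndarray) and hasattr(truth, "data") else np.asarray(truth)
    if p.shape != t.shape:
        raise ValidationError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    scores, empty = {}, []
    for c in classes:
        pc, tc = p == c, t == c
        denom = int(pc.sum()) + int(tc.sum())
        if denom == 0:
            scores[c] = 1.0
            empty.append(c)
        else:
            scores[c] = 2.0 * int((pc & tc).sum()) / denom
    scores["mean"] = float(np.mean([scores[c] for c in classes]))
    scores["empty"] = empty
    return scores
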