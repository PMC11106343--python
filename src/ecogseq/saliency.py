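"""Gradient saliency maps and per-electrode contribution scores.

For a trained decoder and one feature segment, the saliency map is the
absolute gradient of the summed log-probability of the sentence's tokens
(teacher-forced on the reference by default, or on the decoded hypothesis)
with respect to every input feature value; it has the same time x electrode
shape as the input.  Per-electrode contributions take the variance of the map
along time, z-score it across electrodes within the trial (relative, not
absolute, contributions), and average the z-scores over all decodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus import START_TOKEN
from .models import Seq2SeqDecoder
from .nn import Tensor
from .preprocess import FeatureSequence


@dataclass
class ElectrodeContribution:
    scores: np.ndarray  # (n_electrodes,) mean z-scored variance
    n_maps: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "electrode_id": np.arange(self.scores.size),
            "mean_z": self.scores,
            "n_maps": self.n_maps,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def saliency_map(model: Seq2SeqDecoder, features: np.ndarray,
                 target: tuple[int, ...] | list[int]) -> np.ndarray:
    """|d sum_m log p(target_m) / d features|, same (L, K) shape as the input.

    ``target`` is the scored token sequence (no start/end markers needed; a
    full [6, ..., 7] sequence is accepted and stripped).  Dropout is off: the
    model is evaluated in inference mode.
    """
    from .corpus import END_TOKEN

    toks = [t for t in target]
    if toks and toks[0] == START_TOKEN:
        toks = toks[1:]
    if len(toks) > 1 and toks[-1] == END_TOKEN:
        toks = toks[:-1]
    if not toks:
        raise ValueError("empty target sequence")
    was_training = model.training
    model.training = False
    try:
        x = Tensor(features[None], requires_grad=True)
        tok_in = np.array([[START_TOKEN] + toks[:-1]])
        logits, _ = model.forward(x, tok_in)
        logp = logits.log_softmax(axis=-1)
        picked = logp[0, np.arange(len(toks)), np.array(toks)]
        picked.sum().backward()
    finally:
        model.training = was_training
    assert x.grad is not None
    return np.abs(x.grad[0])


def electrode_contribution(maps: list[np.ndarray]) -> ElectrodeContribution:
    """Average across maps of the within-trial z-score of per-electrode
    time-variance.  Scale-free per trial: rescaling one map does not change
    its z-scores."""
    if not maps:
        raise ValueError("need at least one saliency map")
    zs = []
    for m in maps:
        if m.shape[1] < 2:
            raise ValueError("z-score across electrodes needs >= 2 electrodes")
        var = m.var(axis=0)  # variance along time, per electrode
        sd = var.std()
        if sd == 0:
            raise ValueError("degenerate saliency map: identical variance on all electrodes")
        zs.append((var - var.mean()) / sd)
    scores = np.mean(zs, axis=0)
    return ElectrodeContribution(scores=scores, n_maps=len(maps))


def contributions_for_segments(model: Seq2SeqDecoder, features: list[FeatureSequence],
                               references: list[tuple[int, ...]] | None = None) -> ElectrodeContribution:
    """Contribution scores over a set of segments.

    With ``references`` given, gradients are teacher-forced on those token
    sequences; otherwise each segment's own greedy decode is differentiated.
    """
    maps = []
    for i, feat in enumerate(features):
        if references is not None:
            target = references[i]
        else:
            from .corpus import END_TOKEN

            target = tuple(model.decode_greedy(feat.data)[0]) or (END_TOKEN,)
        maps.append(saliency_map(model, feat.data, target))
    return electrode_contribution(maps)
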