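"""Pixelwise segmentation evaluation against gold-standard masks."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EvalResult", "evaluate", "dice"]


@dataclass
class EvalResult:
    """Confusion counts and derived rates over the evaluated pixels.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    accuracy = (TP+TN)/n_eval.  A zero denominator yields NaN for the
    affected rate rather than an exception.
    """

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n_eval(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def accuracy(self) -> float:
        d = self.n_eval
        return (self.tp + self.tn) / d if d else float("nan")


def evaluate(
    pred: np.ndarray, gold: np.ndarray, fov: np.ndarray | None = None
) -> EvalResult:
    """Confusion counts of a predicted mask against a gold standard.

    By default every pixel of the frame counts; pass ``fov`` (the camera
    aperture mask) to restrict evaluation to fov=1 pixels, the alternative
    convention used by some benchmarks.
    """
    pred = np.asarray(pred).astype(bool)
    gold = np.asarray(gold).astype(bool)
    if pred.shape != gold.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gold {gold.shape}")
    if fov is not None:
        fov = np.asarray(fov).astype(bool)
        if fov.shape != pred.shape:
            raise ValueError(f"fov shape {fov.shape} != {pred.shape}")
        pred, gold = pred[fov], gold[fov]
    tp = int(np.count_nonzero(pred & gold))
    tn = int(np.count_nonzero(~pred & ~gold))
    fp = int(np.count_nonzero(pred & ~gold))
    fn = int(np.count_nonzero(~pred & gold))
    return EvalResult(tp=tp, tn=tn, fp=fp, fn=fn)


def dice(pred: np.ndarray, gold: np.ndarray) -> float:
    """Dice overlap coefficient 2|A∩B|/(|A|+|B|); 1.0 when both empty."""
    r = evaluate(pred, gold)
    d = 2 * r.tp + r.fp + r.fn
    return 2 * r.tp / d if d else 1.0
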