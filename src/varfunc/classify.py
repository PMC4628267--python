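"""Soft classification of a variant into loss / switch / gain / conservation
of function.

Two logistic probabilities are formed from the variant's scores and a user
cutoff t: the loss probability L = 1/(1+exp(-(S0-t))) from the score S0
against the query's own subfamily, and the acquire probability
A = 1/(1+exp(-(t-Sx))) from the minimum score Sx over the other subfamilies.
Treating loss and acquisition as independent, the four outcome confidences
are the products L(1-A), LA, (1-L)A, (1-L)(1-A) for LoF, SoF, GoF, CoF; the
prediction is the maximum-confidence type, ties broken in the order LoF,
SoF, CoF, GoF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .hmm import VariantScoreSet

TYPES = ("LoF", "SoF", "GoF", "CoF")
TIE_ORDER = ("LoF", "SoF", "CoF", "GoF")

DEFAULT_CUTOFF = 2.7


class ClassificationError(ValueError):
    pass


def _sigmoid(x: float) -> float:
    # saturates instead of overflowing for extreme scores
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def loss_probability(target_score: float, cutoff: float) -> float:
    """Probability of losing the original subfamily's function:
    1 / (1 + e^-(S0 - t))."""
    _check_finite(target_score, cutoff)
    return _sigmoid(target_score - cutoff)


def gain_probability(min_other_score: float, cutoff: float) -> float:
    """Probability of acquiring another subfamily's function:
    1 / (1 + e^-(t - Sx))."""
    _check_finite(min_other_score, cutoff)
    return _sigmoid(cutoff - min_other_score)


def _check_finite(score: float, cutoff: float) -> None:
    if not (math.isfinite(score) and math.isfinite(cutoff)):
        raise ClassificationError("score and cutoff must be finite")


def confidence_scores(loss_prob: float, acquire_prob: float) -> dict[str, float]:
    """Combine L and A into the four outcome confidences (they sum to 1)."""
    if not (0 <= loss_prob <= 1 and 0 <= acquire_prob <= 1):
        raise ClassificationError("probabilities must lie in [0, 1]")
    L, A = loss_prob, acquire_prob
    return {
        "LoF": L * (1 - A),
        "SoF": L * A,
        "GoF": (1 - L) * A,
        "CoF": (1 - L) * (1 - A),
    }


def invert_logistic(p: float, cutoff: float, which: str) -> float:
    """Recover the underlying score from a printed probability:
    loss -> t + ln(p/(1-p)); gain -> t - ln(p/(1-p))."""
    if not 0 < p < 1:
        raise ClassificationError("probability must be strictly inside (0, 1)")
    logit = math.log(p / (1 - p))
    if which == "loss":
        return cutoff + logit
    if which == "gain":
        return cutoff - logit
    raise ClassificationError(f"which must be 'loss' or 'gain', got {which!r}")


@dataclass
class SoftClassification:
    variant: str
    target_score: float | None
    min_other_score: float | None
    argmin_cluster: int | None
    cutoff: float
    loss_prob: float | None
    acquire_prob: float | None
    confidences: dict[str, float] | None
    predicted: str                       # LoF / SoF / GoF / CoF / no_call
    low_confidence: bool = False

    @property
    def max_confidence(self) -> float | None:
        if self.confidences is None:
            return None
        return max(self.confidences.values())


def classify_from_probs(
    loss_prob: float, acquire_prob: float, cutoff: float,
    variant: str = "", target_score: float | None = None,
    min_other_score: float | None = None, argmin_cluster: int | None = None,
) -> SoftClassification:
    conf = confidence_scores(loss_prob, acquire_prob)
    best = max(conf.values())
    predicted = next(t for t in TIE_ORDER if conf[t] == best)
    return SoftClassification(
        variant=variant,
        target_score=target_score,
        min_other_score=min_other_score,
        argmin_cluster=argmin_cluster,
        cutoff=cutoff,
        loss_prob=loss_prob,
        acquire_prob=acquire_prob,
        confidences=conf,
        predicted=predicted,
        low_confidence=best <= 0.5,
    )


def classify(
    scores: VariantScoreSet, cutoff: float = DEFAULT_CUTOFF, variant: str = ""
) -> SoftClassification:
    """Classify a scored variant at cutoff t.

    A no-call score set passes through as ``predicted="no_call"`` with the
    probabilities unset.  When no eligible non-target cluster exists the
    acquire probability is fixed at 0 (the variant can only lose or conserve
    the original function).  Predictions whose maximum confidence does not
    exceed 0.5 carry a ``low_confidence`` flag.
    """
    if scores.no_call:
        return SoftClassification(
            variant=variant, target_score=scores.target_score,
            min_other_score=scores.min_other_score,
            argmin_cluster=scores.argmin_cluster, cutoff=cutoff,
            loss_prob=None, acquire_prob=None, confidences=None,
            predicted="no_call",
        )
    L = loss_probability(scores.target_score, cutoff)
    A = (
        gain_probability(scores.min_other_score, cutoff)
        if scores.min_other_score is not None else 0.0
    )
    return classify_from_probs(
        L, A, cutoff, variant=variant,
        target_score=scores.target_score,
        min_other_score=scores.min_other_score,
        argmin_cluster=scores.argmin_cluster,
    )


RESULT_COLUMNS = [
    "variant", "S0", "Sx", "argmin_cluster", "L", "A",
    "conf_LoF", "conf_SoF", "conf_GoF", "conf_CoF", "predicted", "no_call",
]


def result_row(c: SoftClassification) -> dict:
    """One output-table row; confidences reported to 3 decimals."""
    def f3(v):
        return "" if v is None else f"{v:.3f}"

    def f4(v):
        return "" if v is None else f"{v:.4f}"

    no_call = c.predicted == "no_call"
    conf = c.confidences or {}
    return {
        "variant": c.variant,
        "S0": f4(c.target_score),
        "Sx": f4(c.min_other_score),
        "argmin_cluster": "" if c.argmin_cluster is None else c.argmin_cluster,
        "L": f3(c.loss_prob),
        "A": f3(c.acquire_prob),
        "conf_LoF": f3(conf.get("LoF")),
        "conf_SoF": f3(conf.get("SoF")),
        "conf_GoF": f3(conf.get("GoF")),
        "conf_CoF": f3(conf.get("CoF")),
        "predicted": c.predicted,
        "no_call": no_call,
    }
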