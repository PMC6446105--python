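"""Link-level evaluation.

Counts follow the T/F/C convention: *T* solvable anaphoric expressions in
the gold standard, *F* expressions the system resolved, *C* of them resolved
correctly.  Metrics are recall R = C/T, precision P = C/F and their harmonic
mean F1 = 2RP/(R+P), with the zero conventions R=0 when T=0, P=0 when F=0
and F1=0 when R+P=0.

A predicted link is *correct* when its referent span and its mention span
set exactly equal some gold link's spans; subtypes are ignored unless strict
mode is requested.  No partial-credit scheme (MUC, B-cubed, CEAF) is used —
mentions are plain spans here and exact equality is the natural criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .model import CoreferenceLink, ValidationError


@dataclass(frozen=True)
class EvalCounts:
    T: int  # total solvable expressions
    F: int  # expressions resolved by the system
    C: int  # correctly resolved

    def __post_init__(self) -> None:
        if self.T < 0 or self.F < 0 or self.C < 0:
            raise ValidationError("counts must be non-negative")
        if self.C > min(self.T, self.F):
            raise ValidationError("C cannot exceed min(T, F)")


def _round3(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Metrics:
    R: float
    P: float
    F1: float

    def rounded(self) -> "Metrics":
        """Half-up to three decimals, as reported; raw values retained here."""
        return Metrics(_round3(self.R), _round3(self.P), _round3(self.F1))


def compute_metrics(counts: EvalCounts) -> Metrics:
    r = counts.C / counts.T if counts.T else 0.0
    p = counts.C / counts.F if counts.F else 0.0
    f1 = 2 * r * p / (r + p) if (r + p) > 0 else 0.0
    return Metrics(r, p, f1)


def _link_key(link: CoreferenceLink, strict: bool):
    key = (link.referent_span, link.mention_spans())
    return key + (link.subtype,) if strict else key


def score_links(
    gold: list[CoreferenceLink],
    predicted: list[CoreferenceLink],
    total_solvable: int,
    strict: bool = False,
) -> EvalCounts:
    """Count predicted links against gold by exact span equality.

    Duplicate predicted links (same referent and mention spans) collapse to
    one before counting.  ``total_solvable`` (T) is supplied by the gold
    standard, not derived here.
    """
    pred_keys = {_link_key(l, strict) for l in predicted}
    gold_keys = {_link_key(l, strict) for l in gold}
    correct = len(pred_keys & gold_keys)
    return EvalCounts(T=total_solvable, F=len(pred_keys), C=correct)
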