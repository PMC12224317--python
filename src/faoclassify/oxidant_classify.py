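"""Oxidant-preference classification of FAO enzymes.

Given the measured bimolecular rate constants of an enzyme's oxidative
half-reaction — k_ox^O2 and, when a genome-associated cytochrome c exists,
k_ox1^CytC and k_ox2^CytC — the classifier issues one of four verdicts:

* ``dehydrogenase``: CytC is strongly preferred (k_ox1^CytC / k_ox^O2 at or
  above the preference threshold, default 100; the characterized
  dehydrogenases show ratios of ~290 up to >10^4).
* ``dual``: the O2 rate is already in the flavoprotein-oxidase range yet
  CytC still reacts at least as fast (ratio between 1 and the threshold).
* ``oxidase``: no CytC constants are available and the O2 rate is in the
  canonical oxidase range (>= 1e4 M^-1 s^-1; bona fide oxidases span
  ~1e4-1e6).
* ``indeterminate``: everything else, e.g. a near-free-flavin O2 rate
  (free FAD reacts at ~250 M^-1 s^-1) paired with only a modest CytC rate,
  or a TAT-exported enzyme with no adjacent CytC and a slow O2 rate that may
  use an unknown periplasmic oxidant.

The numeric thresholds are configuration, not measured quantities: the
verdicts in the source tables are verbal, so the defaults encode that
reasoning explicitly and every call carries a rationale string naming the
rule that fired.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "RateConstantSet",
    "PreferenceCall",
    "ClassifierThresholds",
    "preference_ratio",
    "classify",
]

CATEGORIES = ("dehydrogenase", "oxidase", "dual", "indeterminate")


@dataclass(frozen=True)
class RateConstantSet:
    """Per-enzyme bimolecular rate constants and genomic flags."""

    enzyme: str
    k_ox_o2: float
    k_ox1_cytc: float | None = None
    k_ox2_cytc: float | None = None
    has_signal_peptide: bool = False
    has_adjacent_cytc: bool = False

    def __post_init__(self) -> None:
        if not (self.k_ox_o2 > 0):
            raise ValueError("k_ox_o2 must be > 0")
        if self.k_ox2_cytc is not None:
            if self.k_ox1_cytc is None:
                raise ValueError("k_ox2_cytc requires k_ox1_cytc")
            if not (self.k_ox1_cytc > self.k_ox2_cytc):
                raise ValueError("k_ox1_cytc must exceed k_ox2_cytc")
        if self.k_ox1_cytc is not None and not (self.k_ox1_cytc > 0):
            raise ValueError("k_ox1_cytc must be > 0")


@dataclass(frozen=True)
class ClassifierThresholds:
    """Decision thresholds, exposed so the judgment is auditable.

    r_dehydro : minimum CytC/O2 rate ratio for a dehydrogenase call.
    k_oxidase_floor : minimum k_ox^O2 (M^-1 s^-1) for the dual call; set at
        10^3.5, the lower edge of where oxidase-like O2 reactivity begins.
    k_oxidase_fast : minimum k_ox^O2 for an oxidase call in the absence of
        CytC data (the bottom of the bona fide oxidase range).
    """

    r_dehydro: float = 100.0
    k_oxidase_floor: float = 10 ** 3.5
    k_oxidase_fast: float = 1e4


@dataclass(frozen=True)
class PreferenceCall:
    category: str
    ratio: float | None
    rationale: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def preference_ratio(k_cytc: float, k_o2: float) -> float:
    """CytC preference ratio k_ox1^CytC / k_ox^O2."""
    if not (k_cytc > 0 and k_o2 > 0):
        raise ValueError("both rate constants must be > 0")
    return k_cytc / k_o2


def classify(rc: RateConstantSet,
             thresholds: ClassifierThresholds | None = None) -> PreferenceCall:
    """Issue an oxidant-preference verdict for one enzyme.

    Always returns a call; ambiguous patterns are labelled indeterminate
    rather than forced into a category.
    """
    th = thresholds or ClassifierThresholds()
    if rc.k_ox1_cytc is not None:
        ratio = preference_ratio(rc.k_ox1_cytc, rc.k_ox_o2)
        if ratio >= th.r_dehydro:
            return PreferenceCall(
                "dehydrogenase", ratio,
                f"k_ox1_CytC/k_ox_O2 = {ratio:.3g} >= {th.r_dehydro:g}: "
                "CytC strongly preferred",
            )
        if rc.k_ox_o2 >= th.k_oxidase_floor and ratio >= 1.0:
            return PreferenceCall(
                "dual", ratio,
                f"oxidase-range k_ox_O2 = {rc.k_ox_o2:.3g} >= "
                f"{th.k_oxidase_floor:.3g} with CytC ratio {ratio:.3g} in "
                f"[1, {th.r_dehydro:g}): both activities plausible",
            )
        return PreferenceCall(
            "indeterminate", ratio,
            f"slow O2 rate ({rc.k_ox_o2:.3g}) and modest CytC preference "
            f"({ratio:.3g}): no rule fired",
        )
    if rc.k_ox_o2 >= th.k_oxidase_fast:
        return PreferenceCall(
            "oxidase", None,
            f"no CytC constants and k_ox_O2 = {rc.k_ox_o2:.3g} >= "
            f"{th.k_oxidase_fast:.3g}: canonical oxidase range",
        )
    return PreferenceCall(
        "indeterminate", None,
        f"no CytC constants and k_ox_O2 = {rc.k_ox_o2:.3g} below the "
        "oxidase range: oxidant unresolved",
    )
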