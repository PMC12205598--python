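"""Compensation / dependency calls and screen-level summaries.

A protein responds to the loss of its paralog along two axes.  On the
abundance axis, an increase is compensation and a decrease is dependency.
On the relocalization axis, moving to the paralog's wild-type compartment is
compensation, while moving to a compartment that is neither its own nor its
paralog's is dependency.  Relocalization destinations are an explicit input
(visual inspection on real screens, generator truth on synthetic ones): the
redistribution score itself is not directional.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

COMPENSATION = "compensation"
DEPENDENCY = "dependency"
NONE = "none"


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class RelocalizationAnnotation:
    protein: str
    relocalized: bool
    destination: str | None
    own_wt_compartment: str
    paralog_wt_compartment: str

    def __post_init__(self) -> None:
        if self.relocalized and self.destination is None:
            raise AnnotationError(f"{self.protein}: relocalized without a destination")
        if not self.relocalized and self.destination is not None:
            raise AnnotationError(f"{self.protein}: destination given without relocalization")


@dataclass(frozen=True)
class ParalogCall:
    protein: str
    reloc_call: str  # compensation | dependency | none
    abundance_call: str


def call_direction(annotation: RelocalizationAnnotation, abundance_class: str) -> ParalogCall:
    """Combine a relocalization annotation and an abundance class into calls."""
    if abundance_class == "increase":
        abundance_call = COMPENSATION
    elif abundance_class == "decrease":
        abundance_call = DEPENDENCY
    elif abundance_class == "ns":
        abundance_call = NONE
    else:
        raise ValueError(f"unknown abundance class {abundance_class!r}")

    if not annotation.relocalized:
        reloc_call = NONE
    elif annotation.destination == annotation.own_wt_compartment:
        raise AnnotationError(
            f"{annotation.protein}: destination equals its own wild-type compartment"
        )
    elif annotation.destination == annotation.paralog_wt_compartment:
        reloc_call = COMPENSATION
    else:
        reloc_call = DEPENDENCY
    return ParalogCall(protein=annotation.protein, reloc_call=reloc_call, abundance_call=abundance_call)


def pair_summary(
    flags: dict[str, bool], pair_map: dict[str, tuple[str, str]]
) -> dict[str, int]:
    """Count pairs by responsiveness: both members flagged (reciprocal),
    exactly one (single), or neither (none)."""
    for protein in flags:
        if protein not in pair_map:
            raise KeyError(f"protein {protein!r} is not mapped to a pair")
    pairs = {tuple(sorted(p)) for p in pair_map.values()}
    counts = {"reciprocal": 0, "single": 0, "none": 0}
    for a, b in sorted(pairs):
        n = int(bool(flags.get(a, False))) + int(bool(flags.get(b, False)))
        counts["reciprocal" if n == 2 else "single" if n == 1 else "none"] += 1
    return counts


def _round_half_up_percent(num: int, den: int) -> int:
    return int(math.floor(100.0 * num / den + 0.5))


def screen_summary(
    flags: dict[str, bool],
    abundance_classes: dict[str, str],
    relocalized: dict[str, bool],
    roster: list[str],
) -> dict:
    """Screen-level counts and integer percentages.

    Percentages of relocalization / abundance change / both are computed on
    the redistributed (flagged) subset, rounded half-up to whole percent.
    When nothing is flagged the conditional fractions are reported missing.
    """
    if len(roster) == 0:
        raise ValueError("empty roster")
    flagged = [p for p in roster if flags.get(p, False)]
    n, nf = len(roster), len(flagged)
    out: dict = {
        "n_proteins": n,
        "n_redistributed": nf,
        "pct_redistributed": _round_half_up_percent(nf, n),
    }
    if nf == 0:
        out.update(
            n_relocalized=0, n_abundance_changed=0, n_both=0,
            pct_relocalized=None, pct_abundance_changed=None, pct_both=None,
        )
        return out
    reloc = [p for p in flagged if relocalized.get(p, False)]
    abund = [p for p in flagged if abundance_classes.get(p, "ns") != "ns"]
    both = [p for p in flagged if p in set(reloc) and p in set(abund)]
    out.update(
        n_relocalized=len(reloc),
        n_abundance_changed=len(abund),
        n_both=len(both),
        pct_relocalized=_round_half_up_percent(len(reloc), nf),
        pct_abundance_changed=_round_half_up_percent(len(abund), nf),
        pct_both=_round_half_up_percent(len(both), nf),
    )
    return out


def roster_filter(
    pairs: list[tuple[str, str]], flagged_pairs: list[tuple[str, str]]
) -> dict:
    """Remove quality-failed pairs from the roster, pairwise.

    Both members of a flagged pair leave together; flagging a pair outside
    the roster is an error.  Returns the remaining pairs with counts.
    """
    roster = [tuple(p) for p in pairs]
    roster_set = {tuple(sorted(p)) for p in roster}
    flagged_set = set()
    for p in flagged_pairs:
        key = tuple(sorted(tuple(p)))
        if key not in roster_set:
            raise KeyError(f"flagged pair {p!r} is not in the roster")
        flagged_set.add(key)
    remaining = [p for p in roster if tuple(sorted(p)) not in flagged_set]
    return {
        "pairs": remaining,
        "n_pairs": len(remaining),
        "n_proteins": 2 * len(remaining),
        "n_removed_pairs": len(flagged_set),
        "n_removed_proteins": 2 * len(flagged_set),
    }
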