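"""Inter-annotator reliability for independently segmented, time-aligned tiers.

When two annotators segment the same recording from scratch, their spans do
not line up one-to-one, so agreement has two parts: a temporal matching step
(which of A's spans correspond to which of B's?) and a tag-agreement step on
the matched pairs.  Following the modified Cohen's kappa scheme for gesture
annotation, two spans are comparable only if their temporal overlap reaches a
minimum fraction (default 61% — the conservative choice from the method's
source); kappa is then chance-corrected agreement over the tag vocabulary,
reported both excluding unmatched spans and including them as an explicit
"unmatched" pseudo-category.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from nodphon.pose_io import AnnotationSpan

DEFAULT_MIN_OVERLAP = 0.61
UNMATCHED = "<unmatched>"


@dataclass
class MatchResult:
    """One-to-one temporal matching between two tiers."""

    pairs: list[tuple[AnnotationSpan, AnnotationSpan, float]]
    unmatched_a: list[AnnotationSpan]
    unmatched_b: list[AnnotationSpan]
    min_overlap: float
    denominator: str = "union"


@dataclass
class IARResult:
    """Agreement summary for one tier pair.

    ``raw_agreement`` and ``kappa`` are computed on matched pairs only (the
    "excluding unmatched" variant); ``kappa_including_unmatched`` adds every
    unmatched span as a disagreement with an unmatched pseudo-category.
    """

    raw_agreement: float
    kappa: float
    kappa_including_unmatched: float
    average_overlap: float
    n_a: int
    n_b: int
    n_matched: int
    kappa_undefined: bool = False
    match: MatchResult | None = field(default=None, repr=False)


def overlap_fraction(a: AnnotationSpan, b: AnnotationSpan, denominator: str = "union") -> float:
    """Temporal overlap of two spans as a fraction of the chosen denominator.

    ``union`` (the default) is symmetric in the two spans and conservative;
    ``shorter`` and ``longer`` are offered for comparison with tools that use
    them.
    """
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    if denominator == "union":
        denom = max(a.end, b.end) - min(a.start, b.start)
    elif denominator == "shorter":
        denom = min(a.duration_ms, b.duration_ms)
    elif denominator == "longer":
        denom = max(a.duration_ms, b.duration_ms)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return inter / denom


def match_spans(
    tier_a: list[AnnotationSpan],
    tier_b: list[AnnotationSpan],
    min_overlap: float = DEFAULT_MIN_OVERLAP,
    denominator: str = "union",
    optimal: bool = False,
) -> MatchResult:
    """One-to-one matching of spans with at least ``min_overlap`` overlap.

    Default strategy is greedy in decreasing overlap (ties broken by the
    earlier A-span start), which is reproducible and near-optimal on sparse
    tiers; ``optimal=True`` instead maximizes total overlap with an
    assignment solver.
    """
    candidates = []
    for i, a in enumerate(tier_a):
        for j, b in enumerate(tier_b):
            f = overlap_fraction(a, b, denominator)
            if f >= min_overlap:
                candidates.append((f, i, j))

    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[AnnotationSpan, AnnotationSpan, float]] = []
    if optimal and candidates:
        cost = np.zeros((len(tier_a), len(tier_b)))
        for f, i, j in candidates:
            cost[i, j] = -f
        rows, cols = linear_sum_assignment(cost)
        for i, j in zip(rows, cols):
            if cost[i, j] < 0:
                pairs.append((tier_a[i], tier_b[j], -cost[i, j]))
                used_a.add(i)
                used_b.add(j)
    else:
        for f, i, j in sorted(candidates, key=lambda c: (-c[0], tier_a[c[1]].start, c[1], c[2])):
            if i in used_a or j in used_b:
                continue
            pairs.append((tier_a[i], tier_b[j], f))
            used_a.add(i)
            used_b.add(j)
        pairs.sort(key=lambda p: p[0].start)

    return MatchResult(
        pairs=pairs,
        unmatched_a=[s for i, s in enumerate(tier_a) if i not in used_a],
        unmatched_b=[s for j, s in enumerate(tier_b) if j not in used_b],
        min_overlap=min_overlap,
        denominator=denominator,
    )


def _kappa_from_pairs(pairs: list[tuple[str, str]]) -> float:
    """Cohen's kappa from (tag_a, tag_b) pairs via marginal chance agreement."""
    n = len(pairs)
    cats = sorted({t for p in pairs for t in p})
    idx = {c: k for k, c in enumerate(cats)}
    table = np.zeros((len(cats), len(cats)))
    for a, b in pairs:
        table[idx[a], idx[b]] += 1
    p_o = np.trace(table) / n
    p_e = float(np.sum(table.sum(axis=1) * table.sum(axis=0)) / n**2)
    if p_e >= 1.0:
        # single shared category: observed agreement is complete or chance is total
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1 - p_e)


def modified_kappa(match: MatchResult) -> IARResult:
    """Agreement statistics over a temporal match (tags read from the spans).

    Raw agreement is the share of matched pairs with identical tags.  The
    headline kappa uses matched pairs only; the including-unmatched variant
    adds one pair per unmatched span against the pseudo-category, which
    penalizes segmentation disagreement as well as tag disagreement.
    """
    tag_pairs = [(a.value, b.value) for a, b, _ in match.pairs]
    n_a = len(match.pairs) + len(match.unmatched_a)
    n_b = len(match.pairs) + len(match.unmatched_b)

    if not tag_pairs:
        return IARResult(
            raw_agreement=float("nan"), kappa=float("nan"),
            kappa_including_unmatched=float("nan"), average_overlap=float("nan"),
            n_a=n_a, n_b=n_b, n_matched=0, kappa_undefined=True, match=match,
        )

    raw = sum(a == b for a, b in tag_pairs) / len(tag_pairs)
    kappa = _kappa_from_pairs(tag_pairs)
    inclusive = (
        tag_pairs
        + [(s.value, UNMATCHED) for s in match.unmatched_a]
        + [(UNMATCHED, s.value) for s in match.unmatched_b]
    )
    kappa_incl = _kappa_from_pairs(inclusive)
    avg_overlap = float(np.mean([f for _, _, f in match.pairs]))
    return IARResult(
        raw_agreement=raw, kappa=kappa, kappa_including_unmatched=kappa_incl,
        average_overlap=avg_overlap, n_a=n_a, n_b=n_b, n_matched=len(tag_pairs),
        match=match,
    )


def compute_iar(
    tier_a: list[AnnotationSpan],
    tier_b: list[AnnotationSpan],
    min_overlap: float = DEFAULT_MIN_OVERLAP,
    denominator: str = "union",
    optimal: bool = False,
) -> IARResult:
    """Convenience wrapper: match two tiers, then compute agreement."""
    return modified_kappa(match_spans(tier_a, tier_b, min_overlap, denominator, optimal))
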