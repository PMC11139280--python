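"""Tag-scheme validation, turn-taking classification, co-occurrence, summaries.

The study's unit of analysis is the annotated head nod.  Nod form uses a
five-way vocabulary (sn/ln = single small/large nod, hnn/lnn = many small/
large nods, mn = mixed); function is feedback, affirmation or other; and
turn-taking behavior distinguishes passive recipiency (PR: the nodder lets
the other continue) from turn initialization (TI: the nodder takes the floor
within 300 ms of the nod's offset).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from nodphon.pose_io import AnnotationSpan

FORM_TAGS = frozenset({"sn", "ln", "hnn", "lnn", "mn"})
FUNCTION_TAGS = frozenset({"feedback", "affirmation", "other"})
TURN_TAGS = frozenset({"PR", "TI", "unset"})

#: two nods separated by less than this are one continuous-nodding annotation
MIN_SEPARATION_MS = 300.0
#: a turn transition within this window after nod offset counts as taking the floor
TURN_TRANSITION_MS = 300.0

#: corpus glossing convention: gesture glosses are $-prefixed (e.g. $GEST-NM)
GESTURE_GLOSS_PATTERN = r"^\$"
#: mouth gestures carry the single [MG] tag; everything else is a mouthing
MOUTH_GESTURE_PATTERN = r"^\[MG\]"


@dataclass(frozen=True)
class NodEvent:
    """One annotated nod with its form/function/turn tags."""

    span: AnnotationSpan
    form: str
    function: str
    turn: str = "unset"
    signer: str = ""

    def __post_init__(self) -> None:
        if self.form not in FORM_TAGS:
            raise ValueError(f"unknown form tag {self.form!r}")
        if self.function not in FUNCTION_TAGS:
            raise ValueError(f"unknown function tag {self.function!r}")
        if self.turn not in TURN_TAGS:
            raise ValueError(f"unknown turn tag {self.turn!r}")
        if self.function == "other" and self.turn != "unset":
            raise ValueError("turn is only coded for feedback/affirmation nods")

    @property
    def duration_s(self) -> float:
        return self.span.duration_ms / 1000.0


@dataclass(frozen=True)
class CooccurrenceRecord:
    """Temporal co-occurrence of one nod with manual and mouth activity."""

    nod: NodEvent
    manual_status: str  # lexical | gesture | none
    mouth_status: str   # mouthing | mouth_gesture | none

    def __post_init__(self) -> None:
        if self.manual_status not in {"lexical", "gesture", "none"}:
            raise ValueError(f"bad manual_status {self.manual_status!r}")
        if self.mouth_status not in {"mouthing", "mouth_gesture", "none"}:
            raise ValueError(f"bad mouth_status {self.mouth_status!r}")


@dataclass(frozen=True)
class Violation:
    kind: str
    message: str
    span: AnnotationSpan | None = None


def validate_nod_tier(
    spans: list[AnnotationSpan],
    min_separation_ms: float = MIN_SEPARATION_MS,
    long_single_nod_s: float = 4.0,
) -> list[Violation]:
    """Check a form tier against the segmentation rules; returns findings.

    Adjacent nods closer than ``min_separation_ms`` should have been one
    continuous-nodding annotation; unknown form tags and non-positive
    durations are flagged.  Single nods (sn/ln) far longer than plausible are
    flagged as suspicious (a held up-position is a head back tilt, not a nod
    — a judgment a validator can only hint at).
    """
    out: list[Violation] = []
    for span in spans:
        if span.value not in FORM_TAGS:
            out.append(Violation("unknown-tag", f"unknown form tag {span.value!r}", span))
        if span.duration_ms <= 0:
            out.append(Violation("non-positive-duration", f"span {span} has no duration", span))
        if span.value in {"sn", "ln"} and span.duration_ms > long_single_nod_s * 1000:
            out.append(
                Violation("long-single-nod", f"single nod of {span.duration_ms / 1000:.2f} s", span)
            )
    for a, b in zip(spans, spans[1:]):
        gap = b.start - a.end
        if 0 <= gap < min_separation_ms:
            out.append(
                Violation(
                    "gap-below-threshold",
                    f"gap of {gap:.0f} ms between ({a.start}, {a.end}) and ({b.start}, {b.end}) "
                    f"is below {min_separation_ms:.0f} ms; should be continuous nodding",
                    b,
                )
            )
    return out


def classify_turn(
    nod: NodEvent,
    own_gloss_tier: list[AnnotationSpan],
    transition_ms: float = TURN_TRANSITION_MS,
    min_turn_duration_ms: float = 1000.0,
    require_turn_constituting: bool = True,
) -> str:
    """Classify a nod as turn initialization (TI) or passive recipiency (PR).

    TI requires the nodder's own gloss stream to take the floor right after
    the nod: a gloss span starting within ``transition_ms`` of the nod offset
    (on either side, so a sign overlapping the nod's tail counts).  Because a
    lone feedback token (a single YES) is not a turn, the candidate gloss must
    additionally either be followed by at least one further gloss span or
    itself last at least ``min_turn_duration_ms``; set
    ``require_turn_constituting=False`` for the bare 300 ms rule.
    """
    if own_gloss_tier is None:
        raise ValueError("gloss tier required for turn classification")
    end = nod.span.end
    for i, gloss in enumerate(own_gloss_tier):
        if gloss.start < end - transition_ms:
            continue
        if gloss.start > end + transition_ms:
            break
        if not require_turn_constituting:
            return "TI"
        has_follower = i + 1 < len(own_gloss_tier)
        if has_follower or gloss.duration_ms >= min_turn_duration_ms:
            return "TI"
    return "PR"


def _status(
    nod_span: AnnotationSpan,
    spans: list[AnnotationSpan],
    pattern: str,
    hit_name: str,
    miss_name: str,
) -> str:
    """First matching status by precedence: non-pattern beats pattern beats none."""
    rx = re.compile(pattern)
    hit = False
    for s in spans:
        if s.intersects(nod_span):
            if rx.search(s.value or ""):
                hit = True
            else:
                return miss_name
    return hit_name if hit else "none"


def link_manual_items(
    nods: list[NodEvent],
    gloss_spans: list[AnnotationSpan],
    mouth_spans: list[AnnotationSpan],
    gesture_pattern: str = GESTURE_GLOSS_PATTERN,
    mouth_gesture_pattern: str = MOUTH_GESTURE_PATTERN,
) -> list[CooccurrenceRecord]:
    """Link each nod to co-occurring manual and mouth activity.

    Any strictly positive temporal intersection counts as co-occurrence; no
    minimum-overlap fraction is imposed.  When both a lexical gloss and a
    gesture gloss intersect a nod, lexical takes precedence (the
    precedence is fixed; the records keep every nod so the alternative can be
    recomputed from the tiers).  Gesture glosses are recognized by the
    corpus's label convention (configurable regex), mouth gestures by the
    [MG] tag; other mouth annotations are mouthings.
    """
    out = []
    for nod in nods:
        manual = _status(nod.span, gloss_spans, gesture_pattern, "gesture", "lexical")
        mouth = _status(nod.span, mouth_spans, mouth_gesture_pattern, "mouth_gesture", "mouthing")
        out.append(CooccurrenceRecord(nod=nod, manual_status=manual, mouth_status=mouth))
    return out


def summarize_durations(nods: list[NodEvent]) -> pd.DataFrame:
    """Mean/median duration (s) and count per form tag, plus an overall row."""
    cols = ["form", "mean_duration_s", "median_duration_s", "n"]
    if not nods:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame({"form": [n.form for n in nods], "d": [n.duration_s for n in nods]})
    rows = []
    for form in [f for f in ("sn", "ln", "hnn", "lnn", "mn") if f in set(df["form"])]:
        d = df.loc[df["form"] == form, "d"]
        rows.append((form, d.mean(), d.median(), len(d)))
    rows.append(("overall", df["d"].mean(), df["d"].median(), len(df)))
    return pd.DataFrame(rows, columns=cols)


def _dist(series: pd.Series, decimals: int) -> pd.DataFrame:
    counts = series.value_counts().sort_index()
    pct = 100 * counts / counts.sum()
    return pd.DataFrame(
        {"count": counts, "percent": pct.round(decimals) if decimals else pct.round().astype(int)}
    )


def summarize_distribution(nods: list[NodEvent]) -> dict[str, pd.DataFrame]:
    """Counts and percentages by form, function, form x function, function x turn.

    Form and function percentages are rounded to integers; the turn split
    within each function is given to one decimal.  Underlying counts are
    always present so no precision is lost to rounding.
    """
    df = pd.DataFrame(
        {
            "form": [n.form for n in nods],
            "function": [n.function for n in nods],
            "turn": [n.turn for n in nods],
        }
    )
    out: dict[str, pd.DataFrame] = {}
    if df.empty:
        empty = pd.DataFrame(columns=["count", "percent"])
        return {k: empty.copy() for k in ("by_form", "by_function", "form_by_function", "turn_by_function")}
    out["by_form"] = _dist(df["form"], 0)
    out["by_function"] = _dist(df["function"], 0)

    ff = df.groupby(["function", "form"]).size().rename("count").reset_index()
    ff["percent"] = (100 * ff["count"] / ff["count"].sum()).round(1)
    out["form_by_function"] = ff

    coded = df[df["turn"] != "unset"]
    if coded.empty:
        out["turn_by_function"] = pd.DataFrame(columns=["function", "turn", "count", "percent_within_function"])
    else:
        ft = coded.groupby(["function", "turn"]).size().rename("count").reset_index()
        totals = ft.groupby("function")["count"].transform("sum")
        ft["percent_within_function"] = (100 * ft["count"] / totals).round(1)
        out["turn_by_function"] = ft
    return out


def events_from_document(
    form_spans: list[AnnotationSpan],
    function_spans: list[AnnotationSpan],
    turn_spans: list[AnnotationSpan] | None = None,
    signer: str = "",
    tolerance_ms: float = 1.0,
) -> list[NodEvent]:
    """Zip parallel form/function(/turn) tiers into :class:`NodEvent` objects.

    Tiers are parallel in the study's scheme: one function (and, for
    feedback/affirmation, one turn) annotation per form annotation, aligned
    to the same interval within ``tolerance_ms``.
    """

    def lookup(spans: list[AnnotationSpan] | None, span: AnnotationSpan) -> str | None:
        if not spans:
            return None
        for s in spans:
            if abs(s.start - span.start) <= tolerance_ms and abs(s.end - span.end) <= tolerance_ms:
                return s.value
        return None

    events = []
    for span in form_spans:
        function = lookup(function_spans, span)
        if function is None:
            raise ValueError(f"no function annotation aligned with form span {span}")
        turn = lookup(turn_spans, span)
        events.append(
            NodEvent(
                span=span,
                form=span.value,
                function=function,
                turn=turn if (turn and function != "other") else "unset",
                signer=signer,
            )
        )
    return events


def with_turn(nod: NodEvent, turn: str) -> NodEvent:
    """Return a copy of the nod with its turn tag set."""
    return replace(nod, turn=turn)
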