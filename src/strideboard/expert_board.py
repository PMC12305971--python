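"""Aggregation of expert-panel recommendations into board subscores and the total SMS.

The Stroke Mobility Score (SMS) is the sum of six ordinal subscores (trunk
posture, leg movement, arm movement, gait speed, gait fluency, stability),
each rated 0 (no pathological findings) to 3 (significant findings) by five
clinicians from different disciplines.  The board value for a subscore is the
mode of the five recommendations; when two values tie for the highest count
(the only possible ambiguity with five raters over four levels is a 2-2-1
count pattern) the singleton value acts as tiebreaker: it is returned itself
if it lies between the tied values ("compromise"), otherwise it pulls the
decision to the nearer tied value ("weight").
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

SUBSCORES = ("trunk", "leg", "arm", "speed", "fluency", "stability")

SCORE_MIN = 0
SCORE_MAX = 3
N_RATERS = 5


@dataclass(frozen=True)
class RaterPanel:
    """Five integer recommendations in {0..3} for one subscore of one patient."""

    subscore: str
    recommendations: tuple[int, int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.recommendations) != N_RATERS:
            raise ValueError(
                f"panel needs exactly {N_RATERS} recommendations, "
                f"got {len(self.recommendations)}"
            )
        for r in self.recommendations:
            if not (isinstance(r, (int,)) and SCORE_MIN <= r <= SCORE_MAX):
                raise ValueError(f"recommendation {r!r} outside {{0..3}}")


@dataclass(frozen=True)
class BoardAssessment:
    """Board subscores (one per functional criterion) and their sum, the SMS."""

    subscores: dict[str, int]

    @property
    def sms(self) -> int:
        return sum(self.subscores.values())


def board_subscore(recommendations) -> int:
    """Aggregate five recommendations into the expert-board subscore.

    Unique mode wins outright.  In a 2-2-1 tie the count-1 value ``t``
    decides: if ``t`` lies strictly between the tied pair it is the board
    value (compromise); otherwise the tied value closer to ``t`` wins
    (weight).  With five raters a pigeonhole argument guarantees one of the
    two cases.

    Parameters
    ----------
    recommendations : iterable of int
        Exactly five values, each in {0, 1, 2, 3}.
    """
    recs = list(recommendations)
    if len(recs) != N_RATERS:
        raise ValueError(f"expected {N_RATERS} recommendations, got {len(recs)}")
    for r in recs:
        if r not in (0, 1, 2, 3):
            raise ValueError(f"recommendation {r!r} outside {{0..3}}")

    counts = Counter(recs)
    top = counts.most_common()
    if len(top) == 1 or top[0][1] > top[1][1]:
        return top[0][0]

    # 2-2-1 tie: two values with count 2, one singleton tiebreaker.
    tied = sorted(v for v, c in counts.items() if c == 2)
    (tiebreaker,) = [v for v, c in counts.items() if c == 1]
    lo, hi = tied
    if lo < tiebreaker < hi:
        return tiebreaker  # compromise
    # weight: tiebreaker sits outside the tied interval; the tied values are
    # distinct integers, so one of them is strictly nearer.
    return lo if abs(lo - tiebreaker) < abs(hi - tiebreaker) else hi


def board_assessment(panels: dict[str, RaterPanel] | list[RaterPanel]) -> BoardAssessment:
    """Compute all six board subscores and the SMS from one panel per subscore."""
    if isinstance(panels, list):
        panels = {p.subscore: p for p in panels}
    missing = [s for s in SUBSCORES if s not in panels]
    if missing:
        raise ValueError(f"missing rater panels for subscores: {missing}")
    subs = {s: board_subscore(panels[s].recommendations) for s in SUBSCORES}
    return BoardAssessment(subscores=subs)
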