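"""State-sequence construction for longitudinal intervention-use panels.

Each individual reports, once per calendar year, whether they used therapy
(T), counseling (C) and/or medication (M) in that year.  The joint value of
the three binary indicators defines one of eight *states*; an optional ninth
state codes a missing wave.  This module turns raw per-year records into
eligible, left-aligned state sequences:

1. intermittent missing waves are filled from the nearest observed
   neighbours (per indicator, with a configurable tie rule),
2. individuals with fewer than five *consecutive* observed waves are
   excluded,
3. each eligible individual's longest run of observed waves (at most seven)
   is re-indexed to start at time point T1, regardless of calendar year —
   the analysis prioritises the order of states over their timing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "MISSING_STATE",
    "STATE_LABELS",
    "WaveObservation",
    "IndividualRecord",
    "StateSequence",
    "SequencePanel",
    "FillRule",
    "EligibilityResult",
    "UnfillableMissingError",
    "PanelConstructionError",
    "encode_state",
    "decode_state",
    "fill_intermittent",
    "eligible",
    "build_panel",
    "drop_waves",
]

#: State alphabet: joint use of therapy / counseling / medication in a year.
STATE_LABELS = {
    1: "No",
    2: "T",
    3: "C",
    4: "M",
    5: "T&C",
    6: "T&M",
    7: "C&M",
    8: "T&C&M",
    9: "Missing",
}

MISSING_STATE = 9

_TRIPLE_TO_STATE = {
    (0, 0, 0): 1,
    (1, 0, 0): 2,
    (0, 1, 0): 3,
    (0, 0, 1): 4,
    (1, 1, 0): 5,
    (1, 0, 1): 6,
    (0, 1, 1): 7,
    (1, 1, 1): 8,
}
_STATE_TO_TRIPLE = {v: k for k, v in _TRIPLE_TO_STATE.items()}

INDICATORS = ("therapy", "counseling", "medication")


class UnfillableMissingError(ValueError):
    """A wave with a missing indicator cannot be encoded in the 8-state alphabet."""


class PanelConstructionError(ValueError):
    """A record violates a panel invariant (length bounds / length spread)."""


@dataclass(frozen=True)
class WaveObservation:
    """One year's report: each indicator is 0, 1 or None (missing)."""

    therapy: Optional[int] = None
    counseling: Optional[int] = None
    medication: Optional[int] = None

    @property
    def observed(self) -> bool:
        """True iff all three indicators are non-missing (strict observedness)."""
        return (
            self.therapy is not None
            and self.counseling is not None
            and self.medication is not None
        )

    @property
    def empty(self) -> bool:
        return self.therapy is None and self.counseling is None and self.medication is None

    def values(self) -> tuple[Optional[int], Optional[int], Optional[int]]:
        return (self.therapy, self.counseling, self.medication)


MISSING_WAVE = WaveObservation(None, None, None)


@dataclass(frozen=True)
class IndividualRecord:
    """One individual's yearly observations plus demographic covariates.

    ``waves`` covers consecutive calendar years starting at ``first_year``;
    missing years within the span are explicit :data:`MISSING_WAVE` entries.
    """

    id: str
    first_year: int
    waves: tuple[WaveObservation, ...]
    demographics: Mapping[str, object] = field(default_factory=dict)

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.waves) - 1

    def year_of(self, index: int) -> int:
        return self.first_year + index

    def wave_in_year(self, year: int) -> WaveObservation:
        if not (self.first_year <= year <= self.last_year):
            return MISSING_WAVE
        return self.waves[year - self.first_year]


@dataclass(frozen=True)
class StateSequence:
    """Left-aligned sequence of state codes for one individual.

    ``start_year`` records the calendar year of T1 as metadata so that
    sensitivity analyses can still address chronological years.
    """

    id: str
    states: tuple[int, ...]
    start_year: Optional[int] = None

    @property
    def length(self) -> int:
        return len(self.states)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.states)


@dataclass
class SequencePanel:
    """A cohort of state sequences sharing one alphabet.

    ``alphabet`` is ``"state8"`` (missing waves excluded by construction) or
    ``"state9"`` (unfillable missing waves coded as state 9).
    """

    sequences: list[StateSequence]
    alphabet: str = "state8"
    demographics: dict[str, Mapping[str, object]] = field(default_factory=dict)
    records: Optional[list[IndividualRecord]] = None
    dropped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    @property
    def lengths(self) -> list[int]:
        return [s.length for s in self.sequences]

    @property
    def max_length(self) -> int:
        return max(self.lengths) if self.sequences else 0


def encode_state(
    therapy: Optional[int],
    counseling: Optional[int],
    medication: Optional[int],
    *,
    alphabet: str = "state8",
) -> int:
    """Map an indicator triple to its state code (1..8, or 9 when missing).

    With the default 8-state alphabet a missing indicator is an error; the
    9-state alphabet codes any wave with a missing indicator as state 9.
    """
    triple = (therapy, counseling, medication)
    if any(v is None for v in triple):
        if alphabet == "state9":
            return MISSING_STATE
        raise UnfillableMissingError(
            f"missing indicator in {triple!r}; not encodable in the 8-state alphabet"
        )
    if any(v not in (0, 1) for v in triple):
        raise ValueError(f"indicators must be 0/1, got {triple!r}")
    return _TRIPLE_TO_STATE[triple]  # type: ignore[index]


def decode_state(code: int) -> tuple[Optional[int], Optional[int], Optional[int]]:
    """Inverse of :func:`encode_state`; state 9 decodes to (None, None, None)."""
    if code == MISSING_STATE:
        return (None, None, None)
    try:
        return _STATE_TO_TRIPLE[code]
    except KeyError:
        raise ValueError(f"unknown state code {code!r}") from None


@dataclass(frozen=True)
class FillRule:
    """How to fill an intermittent missing indicator value.

    When the nearest observed values before and after a gap agree, the gap
    takes that value.  On disagreement, ``tie`` decides:

    - ``"carry_forward"`` (default): use the earlier value,
    - ``"carry_backward"``: use the later value,
    - ``"leave"``: leave the indicator missing.
    """

    tie: str = "carry_forward"

    def __post_init__(self) -> None:
        if self.tie not in ("carry_forward", "carry_backward", "leave"):
            raise ValueError(f"unknown tie rule {self.tie!r}")


def _nearest(values: Sequence[Optional[int]], i: int, direction: int) -> Optional[int]:
    j = i + direction
    while 0 <= j < len(values):
        if values[j] is not None:
            return values[j]
        j += direction
    return None


def fill_intermittent(record: IndividualRecord, rule: FillRule = FillRule()) -> IndividualRecord:
    """Fill intermittent missing indicators from surrounding years.

    Only waves with at least one fully observed wave both before and after
    are candidates; leading and trailing gaps are never filled.  Filling acts
    per indicator on the *original* values, so the operation is idempotent
    and never alters observed entries.
    """
    obs = [w.observed for w in record.waves]
    n = len(record.waves)
    per_ind = {k: [getattr(w, k) for w in record.waves] for k in INDICATORS}

    new_waves = list(record.waves)
    changed = False
    for i in range(n):
        if obs[i]:
            continue
        if not (any(obs[:i]) and any(obs[i + 1 :])):
            continue  # leading/trailing gap: not fillable
        filled = {}
        for k in INDICATORS:
            vals = per_ind[k]
            if vals[i] is not None:
                filled[k] = vals[i]
                continue
            before = _nearest(vals, i, -1)
            after = _nearest(vals, i, +1)
            if before is None or after is None:
                filled[k] = None
            elif before == after:
                filled[k] = before
            elif rule.tie == "carry_forward":
                filled[k] = before
            elif rule.tie == "carry_backward":
                filled[k] = after
            else:
                filled[k] = None
        wave = WaveObservation(**filled)
        if wave != new_waves[i]:
            new_waves[i] = wave
            changed = True
    if not changed:
        return record
    return replace(record, waves=tuple(new_waves))


@dataclass(frozen=True)
class EligibilityResult:
    eligible: bool
    reason: str  # "ok" | "too_few_consecutive"
    longest_run: int
    run_start: int  # index of the earliest maximal run


def _longest_observed_run(record: IndividualRecord) -> tuple[int, int]:
    """(length, start index) of the longest run of observed waves; ties -> earliest."""
    best_len, best_start = 0, 0
    cur_len, cur_start = 0, 0
    for i, w in enumerate(record.waves):
        if w.observed:
            if cur_len == 0:
                cur_start = i
            cur_len += 1
            if cur_len > best_len:
                best_len, best_start = cur_len, cur_start
        else:
            cur_len = 0
    return best_len, best_start


def eligible(record: IndividualRecord, min_run: int = 5) -> EligibilityResult:
    """An individual is eligible iff they have >= ``min_run`` consecutive observed waves."""
    run_len, run_start = _longest_observed_run(record)
    if run_len >= min_run:
        return EligibilityResult(True, "ok", run_len, run_start)
    return EligibilityResult(False, "too_few_consecutive", run_len, run_start)


def build_panel(
    records: Iterable[IndividualRecord],
    alphabet: str = "state8",
    *,
    min_run: int = 5,
    max_length: int = 7,
) -> SequencePanel:
    """Build a left-aligned sequence panel from (already filled) records.

    8-state alphabet: each eligible individual's sequence is their longest
    run of consecutive observed waves (earliest on ties), clipped to
    ``max_length`` waves.  9-state alphabet: all waves between the first and
    last observed wave are kept, unobserved ones coded as state 9.

    Ineligible records are dropped and listed in ``panel.dropped``.
    """
    if alphabet not in ("state8", "state9"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    sequences: list[StateSequence] = []
    demographics: dict[str, Mapping[str, object]] = {}
    kept_records: list[IndividualRecord] = []
    dropped: list[tuple[str, str]] = []
    for rec in records:
        res = eligible(rec, min_run=min_run)
        if not res.eligible:
            dropped.append((rec.id, res.reason))
            continue
        if alphabet == "state8":
            start = res.run_start
            length = min(res.longest_run, max_length)
            window = rec.waves[start : start + length]
        else:
            obs_idx = [i for i, w in enumerate(rec.waves) if w.observed]
            start = obs_idx[0]
            length = min(obs_idx[-1] - start + 1, max_length)
            window = rec.waves[start : start + length]
        states = tuple(
            encode_state(w.therapy, w.counseling, w.medication, alphabet=alphabet)
            for w in window
        )
        sequences.append(StateSequence(rec.id, states, start_year=rec.year_of(start)))
        demographics[rec.id] = dict(rec.demographics)
        kept_records.append(rec)

    lengths = [s.length for s in sequences]
    if lengths:
        for s in sequences:
            if not (min_run <= s.length <= max_length):
                raise PanelConstructionError(
                    f"sequence {s.id!r} has length {s.length}, outside [{min_run}, {max_length}]"
                )
        if max(lengths) - min(lengths) > max_length - min_run:
            raise PanelConstructionError(
                f"length spread {max(lengths) - min(lengths)} exceeds {max_length - min_run}"
            )
    return SequencePanel(
        sequences,
        alphabet=alphabet,
        demographics=demographics,
        records=kept_records,
        dropped=dropped,
    )


def drop_waves(panel: SequencePanel, calendar_years: set[int], **panel_kwargs) -> SequencePanel:
    """Rebuild the panel with the named calendar years removed.

    The underlying records are masked at those years *before* eligibility and
    alignment are re-applied, so individuals can drop out of the rebuilt
    panel (reported in ``panel.dropped``).  Used for the pandemic-years
    sensitivity analysis.
    """
    if panel.records is None:
        raise ValueError("panel does not retain its source records")
    if not calendar_years:
        return build_panel(panel.records, alphabet=panel.alphabet, **panel_kwargs)
    masked: list[IndividualRecord] = []
    for rec in panel.records:
        waves = tuple(
            MISSING_WAVE if rec.year_of(i) in calendar_years else w
            for i, w in enumerate(rec.waves)
        )
        masked.append(replace(rec, waves=waves))
    return build_panel(masked, alphabet=panel.alphabet, **panel_kwargs)
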