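"""Rule-based multi-class consensus over one-vs-one pairwise classifiers.

With C disease classes there are C(C,2) pairwise networks (15 for the
six-way pancreatic label set).  The consensus predictor combines their
binary votes without training anything new:

Stage 1 (unanimity): walk a priority list of classes; if every pairwise
model involving class c votes c, return c.  The default priority puts the
empirically strongest classes first (PDAC, then CP).

Stage 2 (tournament fallback): if no class is unanimous, count pairwise
wins across all votes and return the class with the most; ties break by
priority order.

The decision is a pure function of the binary vote table, which is always
returned for audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

from .io import PointPattern

#: Default class priority: strongest pairwise performers first.
DEFAULT_PRIORITY: tuple[str, ...] = (
    "PDAC",
    "CP",
    "IPMN",
    "IPMN-associated PDAC",
    "PanIN",
    "MCN",
)


class ConsensusConfigError(ValueError):
    """Raised when the pairwise model collection is incomplete or inconsistent."""


@dataclass
class ConsensusModel:
    """All pairwise models plus the priority order.

    ``models`` maps each unordered class pair (a frozenset of two symbols)
    to an object exposing ``predict(pattern) -> winning class symbol`` —
    normally a trained :class:`~cgatnet.model.PairwiseModel`, but any
    stand-in with that method works (useful for audit and testing).
    """

    models: Mapping[frozenset, object]
    priority: tuple[str, ...] = DEFAULT_PRIORITY

    def __post_init__(self) -> None:
        self.priority = tuple(self.priority)
        classes = set(self.priority)
        if len(self.priority) != len(classes):
            raise ConsensusConfigError("priority list has duplicates")
        expected = {frozenset(p) for p in combinations(sorted(classes), 2)}
        have = {frozenset(k) for k in self.models}
        missing = expected - have
        if missing:
            raise ConsensusConfigError(
                f"missing pairwise model(s): {sorted(tuple(sorted(m)) for m in missing)}"
            )

    @property
    def classes(self) -> tuple[str, ...]:
        return self.priority


def consensus_predict(
    model: ConsensusModel, pattern: PointPattern
) -> tuple[str, dict[tuple[str, str], str]]:
    """Predict one sample's class; returns (label, per-pair vote table).

    The vote table keys are sorted class pairs, values the winning class.
    """
    votes: dict[tuple[str, str], str] = {}
    for pair_key, pw in model.models.items():
        pair = tuple(sorted(pair_key))
        winner = pw.predict(pattern)
        if winner not in pair:
            raise ConsensusConfigError(
                f"model for {pair} voted {winner!r}, not a member of the pair"
            )
        votes[pair] = winner

    # Stage 1: unanimous one-vs-each in priority order.
    for c in model.priority:
        involved = [v for pair, v in votes.items() if c in pair]
        if involved and all(v == c for v in involved):
            return c, votes

    # Stage 2: round-robin tournament, priority tie-break.
    wins = {c: 0 for c in model.priority}
    for winner in votes.values():
        wins[winner] += 1
    best = max(wins.values())
    for c in model.priority:
        if wins[c] == best:
            return c, votes
    raise AssertionError("unreachable: priority covers all classes")


def predict_cohort(
    model: ConsensusModel, cohort: Sequence[PointPattern]
):
    """Consensus predictions for many samples as a tidy DataFrame."""
    import pandas as pd

    rows = []
    for pat in cohort:
        label, votes = consensus_predict(model, pat)
        row = {"sample_id": pat.sample_id, "predicted_class": label}
        if pat.disease_class is not None:
            row["true_class"] = pat.disease_class
        for pair, winner in sorted(votes.items()):
            row[f"vote[{pair[0]}|{pair[1]}]"] = winner
        rows.append(row)
    return pd.DataFrame(rows)
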