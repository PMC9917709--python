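"""Threshold screening, cross-model consensus and endpoint evaluation.

Accounting over the per-model synthesizability scores: which derivatives
clear the 0.5 threshold under each model, which clear it under all
models simultaneously (the consensus set), how much the screen shrinks
the unlabeled search space, and how the surviving derivatives compare
with their parent musks on docking/toxicity endpoints.

The threshold comparison is inclusive (score >= tau counts as
synthesizable): the published score tables list several molecules at
exactly 0.50 among the synthesizable ones, so the inclusive rule is the
one that reproduces the published sets; reports also carry the strict
count to surface the difference. Percentages are rounded half-up to two
decimals, matching the published formatting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

from .io_tables import ENDPOINT_DIRECTIONS, EndpointTable, ScoreTable

__all__ = [
    "ScreeningReport",
    "EndpointTable",
    "threshold_classify",
    "consensus_sets",
    "reduction_percent",
    "pairwise_relative_deviation",
    "change_rate",
    "evaluate_derivative",
    "build_screening_report",
    "round_half_up",
]

DEFAULT_TAU = 0.5


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (26109.375 -> 26109.38, not banker's)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def threshold_classify(scores: ScoreTable, tau: float = DEFAULT_TAU,
                       inclusive: bool = True) -> set[str]:
    """Ids whose synthesizability clears tau (>= by default, > if strict)."""
    if inclusive:
        return {i for i, s in scores.scores.items() if s >= tau}
    return {i for i, s in scores.scores.items() if s > tau}


def consensus_sets(sets: Sequence[set[str]]) -> set[str]:
    """Exact intersection of the per-model synthesizable sets."""
    if not sets:
        raise ValueError("need at least one set")
    out = set(sets[0])
    for s in sets[1:]:
        out &= set(s)
    return out


def reduction_percent(n_unlabeled: int, n_kept: int) -> float:
    """Search-space shrinkage 100 * (n_unlabeled - n_kept) / n_unlabeled."""
    if n_unlabeled <= 0:
        raise ValueError("no unlabeled molecules")
    if not 0 <= n_kept <= n_unlabeled:
        raise ValueError("n_kept must be between 0 and n_unlabeled")
    return round_half_up(100.0 * (n_unlabeled - n_kept) / n_unlabeled)


def pairwise_relative_deviation(a: float, b: float, denom: str = "first") -> float:
    """Percent deviation 100 * |a - b| / denominator between two model scores."""
    denominators = {"first": a, "second": b, "mean": (a + b) / 2.0}
    if denom not in denominators:
        raise ValueError(f"denom must be one of {sorted(denominators)}")
    d = denominators[denom]
    if d == 0:
        raise ValueError("zero denominator score")
    return round_half_up(100.0 * abs(a - b) / d)


def change_rate(parent_value: float, derivative_value: float,
                ndigits: int | None = 2) -> float:
    """Signed percent change of a derivative endpoint relative to its parent."""
    if parent_value == 0:
        raise ValueError("zero parent value")
    rate = 100.0 * (derivative_value - parent_value) / parent_value
    return rate if ndigits is None else round_half_up(rate, ndigits)


def evaluate_derivative(endpoints: EndpointTable, molecule_id: str) -> dict[str, dict]:
    """Per-endpoint verdicts for one derivative against its parent.

    The sign of the change rate is combined with the endpoint direction
    (docking to hormone receptors and skin keratin: lower is better;
    olfactory binding and fish LC50: higher is better). Missing endpoint
    rows yield the verdict "unknown".
    """
    parent = endpoints.parent_of(molecule_id)
    verdicts: dict[str, dict] = {}
    for endpoint, direction in ENDPOINT_DIRECTIONS.items():
        try:
            pv = endpoints.value(parent, endpoint)
            dv = endpoints.value(molecule_id, endpoint)
        except KeyError:
            verdicts[endpoint] = {"verdict": "unknown", "change_rate": None,
                                  "direction": direction}
            continue
        rate = change_rate(pv, dv)
        if rate == 0.0:
            verdict = "unchanged"
        elif (rate < 0) == (direction == "lower_better"):
            verdict = "improved"
        else:
            verdict = "worsened"
        verdicts[endpoint] = {"verdict": verdict, "change_rate": rate,
                              "direction": direction}
    return verdicts


@dataclass
class ScreeningReport:
    """Cross-model screening summary over one set of score tables."""

    per_model_sets: dict[str, set[str]]
    per_model_strict_sets: dict[str, set[str]]
    consensus: set[str]
    rankings: dict[str, list[str]]
    reduction_percent: float
    deviations: dict[str, float]
    tau: float
    n_unlabeled: int

    def to_dict(self) -> dict:
        return {
            "tau": self.tau,
            "n_unlabeled": self.n_unlabeled,
            "per_model_sets": {m: sorted(s) for m, s in self.per_model_sets.items()},
            "per_model_counts": {m: len(s) for m, s in self.per_model_sets.items()},
            "per_model_strict_counts": {m: len(s)
                                        for m, s in self.per_model_strict_sets.items()},
            "consensus": sorted(self.consensus),
            "consensus_size": len(self.consensus),
            "rankings": self.rankings,
            "reduction_percent": self.reduction_percent,
            "deviations": self.deviations,
        }


def build_screening_report(score_tables: Iterable[ScoreTable], tau: float = DEFAULT_TAU,
                           top_k: int = 10) -> ScreeningReport:
    """Threshold each model, intersect, rank and account for the reduction.

    ``deviations`` compares the first two models' scores (first model's
    score as denominator) for every molecule synthesizable under both —
    the cross-model agreement check. Ties in the rankings are broken by
    id order, so a top-k cut through a tie is deterministic here even
    though it is ambiguous in principle.
    """
    tables = list(score_tables)
    if not tables:
        raise ValueError("need at least one score table")
    per_model = {t.model_name: threshold_classify(t, tau) for t in tables}
    strict = {t.model_name: threshold_classify(t, tau, inclusive=False) for t in tables}
    consensus = consensus_sets(list(per_model.values()))
    rankings = {
        t.model_name: sorted(t.scores, key=lambda i: (-t.scores[i], i))[:top_k]
        for t in tables
    }
    n_unl = len(tables[0].scores)
    kept = per_model[tables[0].model_name]
    reduction = reduction_percent(n_unl, len(kept))
    deviations: dict[str, float] = {}
    if len(tables) >= 2:
        a, b = tables[0], tables[1]
        for mol in sorted(per_model[a.model_name] & per_model[b.model_name]):
            deviations[mol] = pairwise_relative_deviation(
                a.scores[mol], b.scores[mol], denom="first")
    return ScreeningReport(per_model_sets=per_model, per_model_strict_sets=strict,
                           consensus=consensus, rankings=rankings,
                           reduction_percent=reduction, deviations=deviations,
                           tau=tau, n_unlabeled=n_unl)
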