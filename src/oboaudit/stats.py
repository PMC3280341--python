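"""Agreement, prevalence and population-estimate statistics for ratings.

Verdicts answer the rating question "is the ontological dependence of
the source class on the target class justified?" with *yes* (the
existential restriction is fine) or *no* (it is false/suspicious).

A record rated by two experts contributes the mean of its verdicts to
the false count, so per-record effective false weights lie in
{0, 0.5, 1} — this is what makes fractional totals such as 83.5 false
restrictions out of 1650 possible.  Agreement on double-rated records
is chance-corrected with Cohen's kappa; population totals are estimated
by stratified expansion (sum over strata of population size times the
stratum's sampled false rate) with a stratified bootstrap CI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "RatingSet",
    "AgreementResult",
    "PrevalenceResult",
    "PopulationEstimate",
    "HeatmapCell",
    "cohen_kappa",
    "marginal_prevalence",
    "stratum_error_rates",
    "estimate_population",
    "heatmap_table",
]

log = logging.getLogger(__name__)

VERDICTS = ("yes", "no")


@dataclass
class RatingSet:
    """Verdicts by rater on records; at most two ratings per record."""

    ratings: list[tuple[str, str, str]] = field(default_factory=list)
    # each tuple: (record_id, rater_id, verdict)

    def __post_init__(self) -> None:
        counts: dict[str, int] = {}
        for record_id, _rater, verdict in self.ratings:
            if verdict not in VERDICTS:
                raise ValueError(f"verdict must be one of {VERDICTS}, got {verdict!r}")
            counts[record_id] = counts.get(record_id, 0) + 1
            if counts[record_id] > 2:
                raise ValueError(f"record {record_id} has more than 2 ratings")

    def by_record(self) -> dict[str, list[tuple[str, str]]]:
        out: dict[str, list[tuple[str, str]]] = {}
        for record_id, rater, verdict in self.ratings:
            out.setdefault(record_id, []).append((rater, verdict))
        return out

    def false_weights(self) -> dict[str, float]:
        """Per-record effective false weight: mean over its raters of
        1[verdict == 'no'], in {0, 0.5, 1}."""
        return {
            rid: float(np.mean([v == "no" for _, v in pairs]))
            for rid, pairs in self.by_record().items()
        }

    def double_rated_pairs(self) -> list[tuple[str, str]]:
        """(verdict_a, verdict_b) per double-rated record, the two slots
        ordered by rater id for determinism."""
        pairs = []
        for _rid, rated in sorted(self.by_record().items()):
            if len(rated) == 2:
                (ra, va), (rb, vb) = sorted(rated)
                pairs.append((va, vb))
        return pairs


@dataclass(frozen=True)
class AgreementResult:
    kappa: float
    ci95: tuple[float, float]
    p_observed: float
    p_expected: float
    n_pairs: int


@dataclass(frozen=True)
class PrevalenceResult:
    effective_false: float
    n_total: int

    @property
    def proportion(self) -> float:
        return self.effective_false / self.n_total

    @property
    def proportion_2dp(self) -> float:
        return round(self.proportion, 2)

    def percent(self, ndigits: int = 0) -> float:
        """Percentage at the requested precision (reports use whole
        percents, sub-percent rates one decimal)."""
        return round(100.0 * self.proportion, ndigits)


@dataclass(frozen=True)
class PopulationEstimate:
    point: float
    ci95: tuple[float, float]
    per_stratum: dict = field(default_factory=dict)


@dataclass(frozen=True)
class HeatmapCell:
    ontology: str
    relation: str
    n_sampled: int
    error_rate: float
    size_bin: str


def _kappa_from_table(table: np.ndarray) -> tuple[float, float, float]:
    """(kappa, p_o, p_e) from a 2x2 verdict contingency table."""
    n = table.sum()
    if n == 0:
        raise ValueError("empty contingency table")
    p_o = float(np.trace(table) / n)
    rows = table.sum(axis=1) / n
    cols = table.sum(axis=0) / n
    p_e = float(rows @ cols)
    if p_e >= 1.0:
        return 1.0, p_o, p_e
    return (p_o - p_e) / (1.0 - p_e), p_o, p_e


def _pairs_to_table(pairs: Sequence[tuple[str, str]]) -> np.ndarray:
    table = np.zeros((2, 2), dtype=float)
    for va, vb in pairs:
        table[VERDICTS.index(va), VERDICTS.index(vb)] += 1
    return table


def cohen_kappa(
    ratings: RatingSet,
    ci_method: str = "bootstrap",
    n_boot: int = 2000,
    seed: int = 0,
) -> AgreementResult:
    """Cohen's kappa over the double-rated records, pooled across rater
    identities into a single 2x2 table.

    kappa = (p_o - p_e) / (1 - p_e).  The default CI is a seeded
    percentile bootstrap over records (2.5/97.5); ``ci_method="asymptotic"``
    uses the large-sample standard error
    sqrt(p_o (1 - p_o) / (n (1 - p_e)^2)).

    When both raters are constant and identical, p_e = 1 and kappa is
    defined as 1 with a degenerate CI (logged): agreement is perfect and
    chance correction is undefined.
    """
    pairs = ratings.double_rated_pairs()
    if not pairs:
        raise ValueError("no double-rated records; kappa is undefined")
    table = _pairs_to_table(pairs)
    kappa, p_o, p_e = _kappa_from_table(table)
    n = len(pairs)
    if p_e >= 1.0:
        log.warning("degenerate kappa: both raters constant and identical")
        return AgreementResult(1.0, (1.0, 1.0), p_o, p_e, n)

    if ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        codes = np.array([[VERDICTS.index(a), VERDICTS.index(b)] for a, b in pairs])
        stats = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            boot = np.zeros((2, 2))
            np.add.at(boot, (codes[idx, 0], codes[idx, 1]), 1.0)
            stats[b] = _kappa_from_table(boot)[0]
        low, high = np.percentile(stats, [2.5, 97.5])
        ci = (float(low), float(high))
    elif ci_method == "asymptotic":
        se = np.sqrt(p_o * (1.0 - p_o) / (n * (1.0 - p_e) ** 2))
        ci = (float(kappa - 1.96 * se), float(kappa + 1.96 * se))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return AgreementResult(float(kappa), ci, p_o, p_e, n)


def marginal_prevalence(ratings: RatingSet) -> PrevalenceResult:
    """Effective false count and proportion over all rated records.

    effective_false = sum of per-record false weights; proportion =
    effective_false / number of distinct rated records.
    """
    weights = ratings.false_weights()
    if not weights:
        raise ValueError("empty rating set")
    return PrevalenceResult(
        effective_false=float(sum(weights.values())), n_total=len(weights)
    )


def stratum_error_rates(
    ratings: RatingSet,
    record_strata: Mapping[str, tuple[str, str]],
) -> tuple[dict[tuple[str, str], float], dict[str, float]]:
    """Per-stratum and per-ontology false rates from sampled ratings.

    Stratum rate = effective false weight / sampled count.  The
    ontology-level rate aggregates that ontology's strata weighted by
    sampled counts (i.e. total false weight over total sampled).
    Strata with zero sampled records are excluded with a log note.
    """
    weights = ratings.false_weights()
    false_by_stratum: dict[tuple[str, str], float] = {}
    n_by_stratum: dict[tuple[str, str], int] = {}
    for rid, w in weights.items():
        if rid not in record_strata:
            raise KeyError(f"record {rid} has no stratum key")
        key = record_strata[rid]
        false_by_stratum[key] = false_by_stratum.get(key, 0.0) + w
        n_by_stratum[key] = n_by_stratum.get(key, 0) + 1
    for key in set(record_strata.values()) - set(n_by_stratum):
        log.info("stratum %s has zero sampled records; excluded", key)

    rates = {key: false_by_stratum[key] / n_by_stratum[key] for key in n_by_stratum}
    onto_false: dict[str, float] = {}
    onto_n: dict[str, int] = {}
    for (onto, _rel), key in ((k, k) for k in n_by_stratum):
        onto_false[onto] = onto_false.get(onto, 0.0) + false_by_stratum[key]
        onto_n[onto] = onto_n.get(onto, 0) + n_by_stratum[key]
    onto_rates = {o: onto_false[o] / onto_n[o] for o in onto_n}
    return rates, onto_rates


def estimate_population(
    weights_by_stratum: Mapping[tuple[str, str], Sequence[float]],
    population_sizes: Mapping[tuple[str, str], int],
    n_boot: int = 2000,
    seed: int = 0,
) -> PopulationEstimate:
    """Stratified expansion estimate of the total false-restriction count.

    point = sum over strata of N_h * mean(w_h) where w_h are the
    sampled per-record false weights of stratum h.  The 95% CI is a
    stratified percentile bootstrap: verdict weights are resampled with
    replacement within each stratum, the expansion recomputed B times.
    """
    per_stratum: dict = {}
    keys = sorted(weights_by_stratum)
    for key in keys:
        if key not in population_sizes:
            raise ValueError(f"missing population size for stratum {key}")
        w = np.asarray(weights_by_stratum[key], dtype=float)
        if len(w) == 0:
            raise ValueError(f"stratum {key} has no sampled weights")
        if population_sizes[key] < len(w):
            raise ValueError(f"stratum {key}: population smaller than sample")
        per_stratum[key] = {
            "n_sampled": int(len(w)),
            "population": int(population_sizes[key]),
            "rate": float(w.mean()),
            "estimated_false": float(population_sizes[key] * w.mean()),
        }
    point = float(sum(s["estimated_false"] for s in per_stratum.values()))

    rng = np.random.default_rng(seed)
    totals = np.zeros(n_boot)
    for key in keys:
        w = np.asarray(weights_by_stratum[key], dtype=float)
        n_h = len(w)
        idx = rng.integers(0, n_h, size=(n_boot, n_h))
        totals += population_sizes[key] * w[idx].mean(axis=1)
    low, high = np.percentile(totals, [2.5, 97.5])
    return PopulationEstimate(
        point=point, ci95=(float(low), float(high)), per_stratum=per_stratum
    )


def _size_bin(n: int) -> str:
    if n < 20:
        return "<20"
    if n <= 39:
        return "20-39"
    return "40+"


def heatmap_table(
    rates: Mapping[tuple[str, str], float],
    sampled_counts: Mapping[tuple[str, str], int],
) -> list[HeatmapCell]:
    """The relation-by-ontology error-rate table behind the heat map,
    with sample size binned as in the figure legend (<20 / 20-39 / 40+),
    sorted by ontology then relation."""
    cells = []
    for (onto, rel) in sorted(rates):
        n = sampled_counts[(onto, rel)]
        cells.append(
            HeatmapCell(
                ontology=onto,
                relation=rel,
                n_sampled=n,
                error_rate=float(rates[(onto, rel)]),
                size_bin=_size_bin(n),
            )
        )
    return cells
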