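"""Triplet topology census and the minority-topology asymmetry test.

Under incomplete lineage sorting alone the two gene-tree topologies
discordant with the species tree are equally frequent; an excess of one of
them is the classic signal of introgression.  The census tallies the three
rooted-triplet classes (optionally only among genes passing a bootstrap
support threshold) and the asymmetry test is an exact two-sided binomial
test of the two minority counts against a 50:50 null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

from .records import Topology, TopologyCensus, TripletRecord


def classify(records: Iterable[TripletRecord]) -> list[TripletRecord]:
    """Ensure each record carries a topology call.

    Records produced by triplet extraction are already classified; records
    built from raw distances plus midpoint metadata get the topology implied
    by the midpoint-selected outgroup (the sister pair excludes it).
    """
    out = []
    for rec in records:
        if rec.topology is Topology.UNRESOLVED and rec.midpoint_outgroup is not None:
            rec.topology = {
                "A": Topology.BC,
                "B": Topology.AC,
                "C": Topology.AB,
            }[rec.midpoint_outgroup]
        out.append(rec)
    return out


def census(
    records: Iterable[TripletRecord], threshold: float | None = None
) -> TopologyCensus:
    """Count topologies among records passing the support filter.

    With a numeric threshold, records with unknown support are excluded
    (conservative); with ``threshold=None`` every classified record counts.
    UNRESOLVED records are excluded and reported in ``n_rejected``.
    """
    n = {Topology.AB: 0, Topology.BC: 0, Topology.AC: 0}
    n_input = 0
    n_rejected = 0
    for rec in records:
        n_input += 1
        if rec.topology is Topology.UNRESOLVED:
            n_rejected += 1
            continue
        if threshold is not None:
            if rec.support is None or rec.support < threshold:
                n_rejected += 1
                continue
        n[rec.topology] += 1
    return TopologyCensus(
        n_ab=n[Topology.AB],
        n_bc=n[Topology.BC],
        n_ac=n[Topology.AC],
        threshold=threshold,
        n_input=n_input,
        n_rejected=n_rejected,
    )


@dataclass
class BinomialTestResult:
    """Two-sided exact binomial test of the two minority-topology counts."""

    k1: int
    k2: int
    p_value: float
    null_prob: float = 0.5
    majority: Topology | None = None
    minority_pair: tuple[Topology, Topology] | None = None


def binomial_two_sided(k1: int, k2: int) -> float:
    """Exact two-sided binomial p for k1 of n=k1+k2 at p0=0.5.

    Uses the minimum-likelihood rule (sum P(X=k) over all k whose point
    probability does not exceed the observed one); at p0=0.5 this equals
    doubling the smaller tail, capped at 1.
    """
    n = k1 + k2
    if n == 0:
        raise ValueError("binomial test needs at least one observation")
    return stats.binomtest(k1, n, 0.5, alternative="two-sided").pvalue


def minority_asymmetry_test(cens: TopologyCensus) -> BinomialTestResult:
    """Test whether the two minority topologies deviate from 50:50.

    The majority topology is identified from the same (filtered) census; a
    tie for the majority is an error.  ``k1``/``k2`` are the two remaining
    counts in fixed AB < BC < AC reporting order.
    """
    counts = dict(zip((Topology.AB, Topology.BC, Topology.AC), cens.counts))
    top = max(counts.values())
    majors = [t for t, v in counts.items() if v == top]
    if len(majors) != 1:
        raise ValueError(f"tie for majority topology: counts {cens.counts}")
    majority = majors[0]
    minors = [t for t in (Topology.AB, Topology.BC, Topology.AC) if t is not majority]
    k1, k2 = counts[minors[0]], counts[minors[1]]
    p = binomial_two_sided(k1, k2)
    return BinomialTestResult(
        k1=k1, k2=k2, p_value=p, majority=majority, minority_pair=tuple(minors)
    )


def census_table(cens: TopologyCensus) -> list[dict]:
    """Census as rows (topology, count, proportion) for TSV output."""
    props = cens.proportions()
    return [
        {"topology": t.value, "count": c, "proportion": p}
        for t, c, p in zip((Topology.AB, Topology.BC, Topology.AC), cens.counts, props)
    ]
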