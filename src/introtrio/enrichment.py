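"""Exact 2x3 topology-enrichment tests for gene categories.

Asks whether a gene set (for example the nuclear-encoded subunits of an
OXPHOS complex) deviates from the genome-wide mix of the three triplet
topologies.  The test is the Fisher-Freeman-Halton exact test for a 2x3
contingency table — the category's (AB, BC, AC) counts against the
genome-wide census — with Holm adjustment across categories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .census import census as _census
from .records import Topology, TopologyCensus, TripletRecord


@dataclass(frozen=True)
class ContingencyTable2x3:
    """Category counts (row1) vs background counts (row2), columns fixed
    to topology order (AB, BC, AC)."""

    row1: tuple[int, int, int]
    row2: tuple[int, int, int]

    def __post_init__(self) -> None:
        for row in (self.row1, self.row2):
            if len(row) != 3 or any(x < 0 or x != int(x) for x in row):
                raise ValueError(f"rows must be three non-negative integers: {row}")
            if sum(row) == 0:
                raise ValueError("each row needs at least one nonzero entry")


_REL_TOL = 1e-12  # tables this close (relative log-prob) to observed count as ties


def fisher_exact_2x3(table: ContingencyTable2x3) -> float:
    """Two-sided Fisher-Freeman-Halton p for a 2x3 table.

    Enumerates every table with the observed margins; each has multivariate
    hypergeometric point probability

        P(a1,a2,a3) = r1! r2! c1! c2! c3! / (N! a1! a2! a3! b1! b2! b3!)

    and the p-value sums those with probability <= that of the observed
    table (with a small relative tolerance so floating-point ties are
    included deterministically).  Computed in log space; empty columns
    contribute a single term, so degenerate tables reduce gracefully to
    2x2 or to p=1.
    """
    row1, row2 = table.row1, table.row2
    r1, r2 = sum(row1), sum(row2)
    cols = tuple(a + b for a, b in zip(row1, row2))
    n_tot = r1 + r2
    lf = math.lgamma  # lgamma(x+1) = log(x!)
    const = (
        lf(r1 + 1) + lf(r2 + 1) + sum(lf(c + 1) for c in cols) - lf(n_tot + 1)
    )

    def logp(a1: int, a2: int, a3: int) -> float:
        return const - (
            lf(a1 + 1) + lf(a2 + 1) + lf(a3 + 1)
            + lf(cols[0] - a1 + 1) + lf(cols[1] - a2 + 1) + lf(cols[2] - a3 + 1)
        )

    lp_obs = logp(*row1)
    cutoff = lp_obs + _REL_TOL * abs(lp_obs) + 1e-300
    tail = 0.0
    mass = 0.0  # total over all tables; normalizing out float residue
    for a1 in range(max(0, cols[0] - r2), min(r1, cols[0]) + 1):
        rem = r1 - a1
        lo2 = max(0, rem - cols[2])
        hi2 = min(rem, cols[1])
        for a2 in range(lo2, hi2 + 1):
            a3 = rem - a2
            lp = logp(a1, a2, a3)
            p = math.exp(lp)
            mass += p
            if lp <= cutoff:
                tail += p
    return min(tail / mass, 1.0)


def fisher_point_probabilities(table: ContingencyTable2x3) -> np.ndarray:
    """Point probabilities of every table sharing the observed margins
    (diagnostic; they must sum to 1)."""
    row1, row2 = table.row1, table.row2
    r1, r2 = sum(row1), sum(row2)
    cols = tuple(a + b for a, b in zip(row1, row2))
    probs = []
    lf = math.lgamma
    const = lf(r1 + 1) + lf(r2 + 1) + sum(lf(c + 1) for c in cols) - lf(r1 + r2 + 1)
    for a1 in range(max(0, cols[0] - r2), min(r1, cols[0]) + 1):
        rem = r1 - a1
        for a2 in range(max(0, rem - cols[2]), min(rem, cols[1]) + 1):
            a3 = rem - a2
            lp = const - (
                lf(a1 + 1) + lf(a2 + 1) + lf(a3 + 1)
                + lf(cols[0] - a1 + 1) + lf(cols[1] - a2 + 1) + lf(cols[2] - a3 + 1)
            )
            probs.append(math.exp(lp))
    return np.array(probs)


def holm_adjust(pvals: Sequence[float]) -> list[float]:
    """Holm step-down adjustment, returned in input order.

    Sort ascending; adjusted_(k) = max_{j<=k} (m-j+1) * p_(j), capped at 1.
    """
    m = len(pvals)
    if m == 0:
        return []
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * pvals[i])
        adjusted[i] = min(1.0, running)
    return adjusted


@dataclass
class EnrichmentRow:
    category: str
    counts: tuple[int, int, int]  # (AB, BC, AC)
    n_genes: int
    raw_p: float | None
    holm_p: float | None
    direction: str


def _direction(counts: tuple[int, int, int], background: tuple[int, int, int]) -> str:
    cat_t, bg_t = sum(counts), sum(background)
    if cat_t == 0 or bg_t == 0:
        return ""
    diffs = {
        t.value: counts[i] / cat_t - background[i] / bg_t
        for i, t in enumerate((Topology.AB, Topology.BC, Topology.AC))
    }
    top = max(diffs, key=lambda k: diffs[k])
    bottom = min(diffs, key=lambda k: diffs[k])
    return f"{top} over-represented, {bottom} under-represented"


def topology_enrichment(
    assignments: Mapping[str, str],
    records: Sequence[TripletRecord],
    background: TopologyCensus,
    threshold: float | None = None,
) -> list[EnrichmentRow]:
    """Per-category exact 2x3 tests against the genome-wide census.

    ``assignments`` maps gene_id -> category.  Category counts are taken
    from ``records`` under the same support-threshold rule as the census;
    the background row is the supplied genome-wide census (which, as in the
    source analyses, includes the category genes themselves).  Raw p-values
    are Holm-adjusted across all testable categories.  A category with no
    resolvable genes yields a row with p = None.
    """
    by_cat: dict[str, list[TripletRecord]] = {}
    rec_by_id = {r.gene_id: r for r in records}
    for gene_id, cat in assignments.items():
        rec = rec_by_id.get(gene_id)
        if rec is not None:
            by_cat.setdefault(cat, []).append(rec)
    for cat in set(assignments.values()) - set(by_cat):
        by_cat[cat] = []

    rows: list[EnrichmentRow] = []
    testable: list[int] = []
    for cat in sorted(by_cat):
        cat_census = _census(by_cat[cat], threshold=threshold)
        counts = cat_census.counts
        if sum(counts) == 0:
            rows.append(
                EnrichmentRow(cat, counts, len(by_cat[cat]), None, None, "")
            )
            continue
        table = ContingencyTable2x3(row1=counts, row2=background.counts)
        raw = fisher_exact_2x3(table)
        rows.append(
            EnrichmentRow(
                cat, counts, len(by_cat[cat]), raw, None,
                _direction(counts, background.counts),
            )
        )
        testable.append(len(rows) - 1)
    adj = holm_adjust([rows[i].raw_p for i in testable])
    for i, a in zip(testable, adj):
        rows[i].holm_p = a
    return rows


def read_category_table(path) -> dict[str, str]:
    """Read a gene->category TSV (columns gene_id, category; header allowed)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected gene_id<TAB>category")
            if ln == 1 and parts[0].lower() in {"gene_id", "gene"}:
                continue
            out[parts[0]] = parts[1]
    return out
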