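"""Branch-length discrimination of the species topology from the
introgression topology, and the ghost-lineage test.

Recent introgression between two taxa leaves their gene trees with less
time to accumulate substitutions than either the species-tree or the
ILS-discordant gene trees.  Three per-gene metrics capture this: the
patristic distance from the triplet's (midpoint-selected) outgroup taxon
to the ingroup, the total triplet tree length, and the pendant branch of
the midpoint-selected outgroup.  The topology class that is significantly
LOWER than both others on all three metrics is declared the introgression
class; the species tree is the majority topology among the remaining two
(the expected pattern is species = ILS >> introgression).

The ghost-lineage test asks whether the discordance excess could instead
come from gene flow out of an unsampled lineage: genuine B-C introgression
shortens d(B,C) in BC-topology trees relative to AB-topology trees,
whereas a ghost donor does not.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from statistics import median
from typing import Sequence

import numpy as np
from scipy import stats

from .enrichment import holm_adjust
from .records import TOPOLOGY_ORDER, Topology, TripletRecord

_EXACT_LIMIT = 20  # pooled size at or below which the exact MWU is used


@dataclass
class MWUResult:
    U: float
    p_value: float
    n1: int
    n2: int
    method: str  # "exact" | "normal-approx-tie-corrected"


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> MWUResult:
    """Two-sided Mann-Whitney U test.

    U counts pairs with x > y plus half the tied pairs.  For pooled sizes
    up to 20 the p-value is exact — via scipy's exact distribution when
    there are no ties, otherwise by direct enumeration of all C(n1+n2, n1)
    labelings (which handles ties correctly).  Larger samples use the
    normal approximation with tie and continuity corrections.
    """
    x = list(x)
    y = list(y)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = x + y
    has_ties = len(set(pooled)) < len(pooled)
    if n1 + n2 <= _EXACT_LIMIT:
        if not has_ties:
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            return MWUResult(float(res.statistic), float(res.pvalue), n1, n2, "exact")
        return _exact_mwu_with_ties(x, y)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return MWUResult(
        float(res.statistic), float(res.pvalue), n1, n2,
        "normal-approx-tie-corrected",
    )


def _exact_mwu_with_ties(x: list[float], y: list[float]) -> MWUResult:
    n1, n2 = len(x), len(y)
    pooled = x + y
    ranks = stats.rankdata(pooled)  # midranks
    r1 = float(ranks[:n1].sum())
    u_obs = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    dev_obs = abs(u_obs - mu) - 1e-9
    count = 0
    total = 0
    offset = n1 * (n1 + 1) / 2.0
    for combo in itertools.combinations(range(n1 + n2), n1):
        u = sum(ranks[i] for i in combo) - offset
        if abs(u - mu) >= dev_obs:
            count += 1
        total += 1
    return MWUResult(u_obs, count / total, n1, n2, "exact")


def outgroup_ingroup_distance(
    record: TripletRecord, metric: str = "mean-tip"
) -> float:
    """Outgroup-to-ingroup distance for a classified triplet.

    The "outgroup" here is the ingroup taxon excluded from the sister
    pair.  ``mean-tip`` (default) averages its two tip-to-tip distances to
    the pair members; ``to-mrca`` uses its pendant to the triplet hub
    (distance to the ingroup-pair MRCA), which differs from the default
    only by the pair's pendant edges.
    """
    z = record.topology.excluded_taxon
    xy = sorted(set("ABC") - {z})
    if metric == "mean-tip":
        return 0.5 * (
            record.distance(frozenset((z, xy[0])))
            + record.distance(frozenset((z, xy[1])))
        )
    if metric == "to-mrca":
        return record.pendants[z]
    raise ValueError(f"unknown outgroup metric {metric!r}")


def outgroup_branch_length(record: TripletRecord) -> float | None:
    """Pendant edge of the midpoint-selected outgroup tip (None when the
    midpoint rooting was unresolvable)."""
    return record.outgroup_branch


METRICS = ("outgroup_ingroup_distance", "total_tree_length", "outgroup_branch_length")


def _metric_value(rec: TripletRecord, metric: str, outgroup_metric: str) -> float | None:
    if metric == "outgroup_ingroup_distance":
        return outgroup_ingroup_distance(rec, metric=outgroup_metric)
    if metric == "total_tree_length":
        return rec.total_length
    if metric == "outgroup_branch_length":
        return rec.outgroup_branch
    raise ValueError(metric)


@dataclass
class DiscriminationReport:
    class_sizes: dict[str, int]
    medians: dict[str, dict[str, float]]  # metric -> topology -> median
    raw_p: dict[str, dict[str, float]]  # metric -> "XY-vs-ZW" -> p
    holm_p: dict[str, dict[str, float]]
    verdict: str  # "supports-AB-species-tree" | "supports-BC-species-tree" | "inconclusive"
    introgression_class: str | None = None
    message: str = ""
    n_skipped: int = 0


def discriminate(
    records: Sequence[TripletRecord],
    alpha: float = 0.05,
    outgroup_metric: str = "mean-tip",
) -> DiscriminationReport:
    """Run the three-metric discrimination across topology classes.

    Pairwise Mann-Whitney tests are Holm-adjusted within each metric (the
    family is the 3 pairwise comparisons for that metric); all medians and
    p-values are reported.  The verdict is a contest between the two most
    common classes — the two species-tree contenders: the runner-up class
    is declared the introgression class only when it sits significantly
    below the majority class on all three metrics (Holm-adjusted p <
    ``alpha``) with a lower median on each.  The ILS (least common) class
    is reported for context but deliberately kept out of the verdict: it
    absorbs introgressed genes whose lineages failed to sort, and under
    pure ILS the concordant class is itself the shortest on these metrics,
    so conjunctions against the ILS class are either uninformative or
    break the null.
    """
    groups: dict[Topology, list[TripletRecord]] = {t: [] for t in TOPOLOGY_ORDER}
    n_skipped = 0
    for rec in records:
        if rec.topology is Topology.UNRESOLVED or not rec.has_distances:
            n_skipped += 1
            continue
        groups[rec.topology].append(rec)
    sizes = {t.value: len(v) for t, v in groups.items()}
    empty = [t for t, v in groups.items() if not v]
    if empty:
        return DiscriminationReport(
            class_sizes=sizes, medians={}, raw_p={}, holm_p={},
            verdict="inconclusive",
            message=f"empty topology class(es): {[t.value for t in empty]}",
            n_skipped=n_skipped,
        )

    values: dict[str, dict[Topology, list[float]]] = {}
    for metric in METRICS:
        values[metric] = {}
        for topo, recs in groups.items():
            vals = [
                v for r in recs
                if (v := _metric_value(r, metric, outgroup_metric)) is not None
                and not math.isnan(v)
            ]
            values[metric][topo] = vals

    medians = {
        m: {t.value: (median(v) if v else math.nan) for t, v in values[m].items()}
        for m in METRICS
    }
    pairs = list(itertools.combinations(TOPOLOGY_ORDER, 2))
    raw_p: dict[str, dict[str, float]] = {}
    holm_p: dict[str, dict[str, float]] = {}
    for metric in METRICS:
        raws = []
        keys = []
        for t1, t2 in pairs:
            res = mann_whitney(values[metric][t1], values[metric][t2])
            keys.append(f"{t1.value}-vs-{t2.value}")
            raws.append(res.p_value)
        adj = holm_adjust(raws)
        raw_p[metric] = dict(zip(keys, raws))
        holm_p[metric] = dict(zip(keys, adj))

    def pair_key(t1: Topology, t2: Topology) -> str:
        for a, b in pairs:
            if {a, b} == {t1, t2}:
                return f"{a.value}-vs-{b.value}"
        raise KeyError

    ranked = sorted(TOPOLOGY_ORDER, key=lambda t: sizes[t.value], reverse=True)
    majority, runner = ranked[0], ranked[1]
    if sizes[majority.value] == sizes[runner.value]:
        return DiscriminationReport(
            class_sizes=sizes, medians=medians, raw_p=raw_p, holm_p=holm_p,
            verdict="inconclusive",
            message=f"tie for majority topology: {sizes}",
            n_skipped=n_skipped,
        )
    runner_lower = all(
        medians[m][runner.value] < medians[m][majority.value]
        and holm_p[m][pair_key(runner, majority)] < alpha
        for m in METRICS
    )
    if not runner_lower:
        return DiscriminationReport(
            class_sizes=sizes, medians=medians, raw_p=raw_p, holm_p=holm_p,
            verdict="inconclusive",
            message=(
                f"runner-up class {runner.value} is not consistently shorter "
                f"than the majority class {majority.value} on all metrics"
            ),
            n_skipped=n_skipped,
        )
    if majority is Topology.AB:
        verdict = "supports-AB-species-tree"
    elif majority is Topology.BC:
        verdict = "supports-BC-species-tree"
    else:
        verdict = "inconclusive"
    return DiscriminationReport(
        class_sizes=sizes, medians=medians, raw_p=raw_p, holm_p=holm_p,
        verdict=verdict, introgression_class=runner.value, n_skipped=n_skipped,
    )


@dataclass
class GhostTestResult:
    mwu: MWUResult
    median_d_bc_in_bc_trees: float
    median_d_bc_in_ab_trees: float
    direction: str  # "BC-trees-shorter" | "BC-trees-longer" | "equal"
    one_sided_p: float


def ghost_lineage_test(records: Sequence[TripletRecord]) -> GhostTestResult:
    """Compare d(B,C) between BC-topology and AB-topology gene trees.

    True B-C introgression predicts markedly smaller d(B,C) in BC trees;
    a ghost-lineage donor predicts similar distributions.  Reports the
    two-sided Mann-Whitney result, group medians, the observed direction,
    and the one-sided p for the shorter-in-BC-trees alternative.
    """
    bc = [r.d_bc for r in records if r.topology is Topology.BC and r.has_distances]
    ab = [r.d_bc for r in records if r.topology is Topology.AB and r.has_distances]
    if not bc or not ab:
        raise ValueError("both BC-topology and AB-topology records are required")
    res = mann_whitney(bc, ab)
    med_bc, med_ab = median(bc), median(ab)
    if med_bc < med_ab:
        direction = "BC-trees-shorter"
    elif med_bc > med_ab:
        direction = "BC-trees-longer"
    else:
        direction = "equal"
    one_sided = stats.mannwhitneyu(
        bc, ab, alternative="less",
        method="asymptotic" if len(bc) + len(ab) > _EXACT_LIMIT else "auto",
    ).pvalue
    return GhostTestResult(
        mwu=res,
        median_d_bc_in_bc_trees=med_bc,
        median_d_bc_in_ab_trees=med_ab,
        direction=direction,
        one_sided_p=float(one_sided),
    )
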