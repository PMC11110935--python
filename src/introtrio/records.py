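"""Shared record types passed between pipeline stages."""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field


class Topology(enum.Enum):
    """Rooted triplet topology: which pair of the three ingroup taxa is sister.

    With the conventional assignment A = P. antipodarum (Pa), B =
    P. kaitunuparaoa (Pk), C = P. estuarinus (Pe), the three classes are
    AB = "Pa-Pk" (the mitochondrial / species topology), BC = "Pe-Pk"
    (the introgression topology) and AC = "Pa-Pe" (the ILS topology).
    """

    AB = "AB"
    BC = "BC"
    AC = "AC"
    UNRESOLVED = "UNRESOLVED"

    @property
    def sister_pair(self) -> frozenset[str]:
        if self is Topology.UNRESOLVED:
            raise ValueError("unresolved topology has no sister pair")
        return frozenset(self.value)

    @property
    def excluded_taxon(self) -> str:
        """The ingroup taxon outside the sister pair ('A', 'B' or 'C')."""
        if self is Topology.UNRESOLVED:
            raise ValueError("unresolved topology has no excluded taxon")
        (only,) = set("ABC") - set(self.value)
        return only


#: Fixed reporting order for the three resolved classes.
TOPOLOGY_ORDER = (Topology.AB, Topology.BC, Topology.AC)


@dataclass
class TripletRecord:
    """One gene's 3-taxon topology call with branch-length summaries.

    Distances are patristic (sum of branch lengths, substitutions/site)
    between the single A, B and C tips; ``nan`` when the source tree lacks
    branch lengths.  ``support`` is a bootstrap percentage in [0, 100] or
    None when unknown.  ``outgroup_branch`` is the pendant edge of the
    midpoint-selected outgroup tip on the unrooted 3-taxon tree, and
    ``midpoint_outgroup`` names that taxon ('A'/'B'/'C').
    """

    gene_id: str
    topology: Topology = Topology.UNRESOLVED
    support: float | None = None
    d_ab: float = math.nan
    d_ac: float = math.nan
    d_bc: float = math.nan
    total_length: float = math.nan
    outgroup_branch: float | None = None
    midpoint_outgroup: str | None = None
    provenance: str = "context-rooted"

    def distance(self, pair: frozenset[str] | str) -> float:
        key = "".join(sorted(pair))
        return {"AB": self.d_ab, "AC": self.d_ac, "BC": self.d_bc}[key]

    @property
    def pendants(self) -> dict[str, float]:
        """Pendant edge lengths of the unrooted 3-taxon star.

        A pruned triplet (degree-2 nodes suppressed) is a star, so the three
        pendants follow from the pairwise distances:
        p_a = (d_ab + d_ac - d_bc)/2 etc.
        """
        return {
            "A": 0.5 * (self.d_ab + self.d_ac - self.d_bc),
            "B": 0.5 * (self.d_ab + self.d_bc - self.d_ac),
            "C": 0.5 * (self.d_ac + self.d_bc - self.d_ab),
        }

    @property
    def has_distances(self) -> bool:
        return not (
            math.isnan(self.d_ab) or math.isnan(self.d_ac) or math.isnan(self.d_bc)
        )


@dataclass
class TripletRejection:
    """A gene excluded from the triplet set, with the reason why."""

    gene_id: str
    reason: str  # "copy-number" | "no-context" | "ambiguous" | "no-branch-lengths"
    detail: str = ""


@dataclass
class TopologyCensus:
    """Counts of the three resolved triplet topologies at a support threshold."""

    n_ab: int
    n_bc: int
    n_ac: int
    threshold: float | None = None
    n_input: int = 0
    n_rejected: int = 0

    @property
    def counts(self) -> tuple[int, int, int]:
        return (self.n_ab, self.n_bc, self.n_ac)

    @property
    def total(self) -> int:
        return self.n_ab + self.n_bc + self.n_ac

    def count(self, topo: Topology) -> int:
        return dict(zip(TOPOLOGY_ORDER, self.counts))[topo]

    def proportions(self) -> tuple[float, float, float]:
        t = self.total
        if t == 0:
            return (math.nan, math.nan, math.nan)
        return (self.n_ab / t, self.n_bc / t, self.n_ac / t)
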