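"""Coalescent simulation of gene genealogies for ((A,B),C) plus outgroup,
with an optional B-C introgression pulse and an optional ghost-lineage
mimic, plus JC69 sequence simulation and bootstrap supports.

The model is the multispecies coalescent in coalescent units (time scaled
by 2N generations): within a population, each lineage pair coalesces at
rate 1.  The species history is A and B merging at ``tau_ab``, the ingroup
root at ``tau_abc`` and the outgroup joining at ``tau_out``.  With
probability ``gamma`` a gene is introgressed, and the coalescent history
of an introgressed gene depends on the (forward-time) direction of flow.
Donor B, recipient C ("B->C"): the sampled C lineage traces back into B's
population at the pulse time ``tau_m``, rides with B's lineage until the
A-B split and then enters the A+B ancestral population — so the pair's
head start is ``T2b = tau_ab - tau_m``, after which the pair can coalesce
deep branches with A's lineage well before ``tau_abc``.  Donor C,
recipient B ("C->B"): the sampled B lineage traces back into C's
population, which persists until the ingroup root, giving the pair a head
start of ``T2 = tau_abc - tau_m`` but no early access to A's lineage.
The early deep coalescence available on the B->C route is what shortens
outgroup-to-ingroup distances, total tree length and the
midpoint-outgroup branch in introgression trees — the three signals the
discrimination stage tests; the C->B route shortens only d(B,C).  The
``pulse_via_ab_ancestor`` parameter sets the fraction of introgressed
genes taking the B->C route.  Either way the BC topology plays the
concordant role for introgressed genes.  With probability
``ghost_gamma`` a gene instead received gene flow from an unsampled
lineage into A: its A lineage is sequestered until ``tau_ghost_join``,
which inflates BC-topology counts WITHOUT shortening d(B,C) — the
signature the ghost-lineage test discriminates against.

Branch lengths are durations times ``rate`` (substitutions/site per
coalescent unit) times an independent lognormal multiplier per branch
(median 1, log-sd ``rate_noise_sigma``), so trees are clock-like only when
the noise is off.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .records import TOPOLOGY_ORDER, Topology, TopologyCensus, TripletRecord
from .trees import GeneAlignment, TaxonScheme, _midpoint_metadata

#: Default tip labels mirroring the motivating snail system:
#: A = P. antipodarum (Pa), B = P. kaitunuparaoa (Pk),
#: C = P. estuarinus (Pe), outgroup = O. hupensis (Oh).
DEFAULT_SCHEME = TaxonScheme(taxon_a="Pa", taxon_b="Pk", taxon_c="Pe", outgroup="Oh")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimParams:
    """Simulation parameters (times in coalescent units of 2N generations).

    Defaults set T1 = tau_abc - tau_ab = 0.5, T2 = tau_abc - tau_m = 1.0
    and gamma = 0.25, yielding a clear majority/asymmetry census pattern
    of the kind the analysis pipeline is built to detect, with the pulse
    placed at a third of the A-B split age — introgression recent relative
    to the speciations, as inferred for the motivating snail system — and
    most introgressed genes routed through the A+B ancestral pool, the
    pathway that produces the branch-length discrimination signals.
    """

    tau_ab: float = 0.75
    tau_abc: float = 1.25
    tau_out: float = 2.5
    gamma: float = 0.25
    tau_m: float = 0.25
    pulse_via_ab_ancestor: float = 0.8
    ghost_gamma: float = 0.0
    tau_ghost_join: float = 2.0
    rate: float = 0.01
    rate_noise_sigma: float = 0.2
    n_genes: int = 1000
    aln_length: int = 1000
    support_bootstraps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.tau_m < self.tau_ab < self.tau_abc < self.tau_out):
            raise ValueError(
                "need 0 < tau_m < tau_ab < tau_abc < tau_out, got "
                f"{self.tau_m}, {self.tau_ab}, {self.tau_abc}, {self.tau_out}"
            )
        if not (0.0 <= self.gamma <= 1.0 and 0.0 <= self.ghost_gamma <= 1.0):
            raise ValueError("gamma and ghost_gamma must lie in [0, 1]")
        if not (0.0 <= self.pulse_via_ab_ancestor <= 1.0):
            raise ValueError("pulse_via_ab_ancestor must lie in [0, 1]")
        if self.gamma + self.ghost_gamma > 1.0:
            raise ValueError("gamma + ghost_gamma must not exceed 1")
        if self.ghost_gamma > 0 and not (
            self.tau_abc < self.tau_ghost_join <= self.tau_out
        ):
            raise ValueError("need tau_abc < tau_ghost_join <= tau_out")
        if self.rate <= 0 or self.rate_noise_sigma < 0:
            raise ValueError("rate must be positive, rate_noise_sigma non-negative")

    @property
    def T1(self) -> float:
        """Internal-branch duration available to sort A-B coalescence."""
        return self.tau_abc - self.tau_ab

    @property
    def T2(self) -> float:
        """Head start of the introgressed pair in the B->C direction."""
        return self.tau_abc - self.tau_m

    @property
    def T2b(self) -> float:
        """Head start of the introgressed pair in the C->B direction."""
        return self.tau_ab - self.tau_m


class SimNode:
    __slots__ = ("name", "height", "children", "length")

    def __init__(self, name=None, height=0.0, children=None):
        self.name = name
        self.height = height
        self.children = children or []
        self.length = 0.0  # substitution-unit edge length, set after noise

    def leaves(self):
        if not self.children:
            return [self]
        out = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out


@dataclass
class SimGene:
    """One simulated gene: genealogy, truth flags and (optionally) data."""

    gene_id: str
    root: SimNode
    true_topology: Topology  # first coalescence among the ingroup lineages
    observed_pair: Topology  # quartet split read with the outgroup, i.e.
    # what a census of the emitted tree sees (rarely differs from the truth
    # when the outgroup lineage intrudes among uncoalesced ingroup lineages)
    introgressed: bool
    ghost: bool
    direction: str  # "B->C" | "C->B" | "" (bookkeeping label; symmetric model)
    resistant: bool = False
    coal_times: dict = field(default_factory=dict)  # frozenset pair -> time
    tip_dist: dict = field(default_factory=dict)  # frozenset pair -> subst. dist
    alignment: GeneAlignment | None = None
    support: float | None = None
    support_tie: bool = False


def _coalesce(pool: list[SimNode], t0: float, t1: float, rng) -> tuple[list[SimNode], float]:
    t = t0
    while len(pool) > 1:
        k = len(pool)
        t += rng.exponential(2.0 / (k * (k - 1)))
        if t > t1:
            return pool, t1
        j = int(rng.integers(0, k))
        i = int(rng.integers(0, k - 1))
        if i >= j:
            i += 1
        i, j = min(i, j), max(i, j)
        right = pool.pop(j)
        left = pool.pop(i)
        pool.append(SimNode(height=t, children=[left, right]))
    return pool, t


def simulate_genealogy(params: SimParams, rng, gene_id: str = "g", *,
                       force_no_introgression: bool = False) -> SimGene:
    """Draw one gene genealogy (tree only; no sequences).

    ``force_no_introgression`` marks the gene "resistant": it follows the
    plain species history regardless of gamma (used to embed categories
    that resist gene flow inside an otherwise introgressed genome).
    """
    u = rng.random()
    if force_no_introgression:
        introgressed = ghost = False
    else:
        introgressed = u < params.gamma
        ghost = (not introgressed) and u < params.gamma + params.ghost_gamma
    direction = ""
    if introgressed:
        via_ab = rng.random() < params.pulse_via_ab_ancestor
        direction = "B->C" if via_ab else "C->B"

    a, b, c, o = (SimNode(name=n) for n in ("A", "B", "C", "O"))
    if introgressed and direction == "B->C":
        # recipient C's sampled lineage traces back into B's population,
        # then the A+B ancestor where it can meet A's lineage early
        pool_b, _ = _coalesce([b, c], params.tau_m, params.tau_ab, rng)
        pool_ab, _ = _coalesce(pool_b + [a], params.tau_ab, params.tau_abc, rng)
        pool_c = []
    elif introgressed:
        # recipient B's sampled lineage traces back into C's population,
        # which persists until the ingroup root
        pool_c, _ = _coalesce([c, b], params.tau_m, params.tau_abc, rng)
        pool_ab = [a]
    else:
        pool_c = [c]
        if ghost:
            pool_ab = [b]  # A sequestered in the ghost population
        else:
            pool_ab, _ = _coalesce([a, b], params.tau_ab, params.tau_abc, rng)
    if ghost:
        pool, _ = _coalesce(pool_ab + pool_c, params.tau_abc, params.tau_ghost_join, rng)
        pool, _ = _coalesce(pool + [a], params.tau_ghost_join, params.tau_out, rng)
    else:
        pool, _ = _coalesce(pool_ab + pool_c, params.tau_abc, params.tau_out, rng)
    pool, _ = _coalesce(pool + [o], params.tau_out, math.inf, rng)
    root = pool[0]

    # pairwise coalescence times from the merge tree
    times: dict[frozenset, float] = {}

    def collect(node: SimNode) -> set[str]:
        if not node.children:
            return {node.name}
        sets = [collect(ch) for ch in node.children]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                for x in sets[i]:
                    for y in sets[j]:
                        times[frozenset((x, y))] = node.height
        out = set()
        for s in sets:
            out |= s
        return out

    collect(root)
    ingroup_pairs = {
        Topology.AB: frozenset(("A", "B")),
        Topology.BC: frozenset(("B", "C")),
        Topology.AC: frozenset(("A", "C")),
    }
    true_topo = min(ingroup_pairs, key=lambda t: times[ingroup_pairs[t]])
    # quartet split read against the outgroup (four-point on ultrametric times)
    split_score = {}
    for t, pair in ingroup_pairs.items():
        (z,) = set("ABC") - pair
        split_score[t] = times[pair] + times[frozenset((z, "O"))]
    observed = min(split_score, key=lambda t: split_score[t])

    # realized branch lengths: duration x rate x lognormal multiplier
    def set_lengths(node: SimNode) -> None:
        for ch in node.children:
            dur = node.height - ch.height
            mult = (
                rng.lognormal(0.0, params.rate_noise_sigma)
                if params.rate_noise_sigma > 0
                else 1.0
            )
            ch.length = dur * params.rate * mult
            set_lengths(ch)

    set_lengths(root)

    dist: dict[frozenset, float] = {}

    def collect_dist(node: SimNode) -> dict[str, float]:
        if not node.children:
            return {node.name: 0.0}
        maps = [
            {k: v + ch.length for k, v in collect_dist(ch).items()}
            for ch in node.children
        ]
        for i in range(len(maps)):
            for j in range(i + 1, len(maps)):
                for x, dx in maps[i].items():
                    for y, dy in maps[j].items():
                        dist[frozenset((x, y))] = dx + dy
        merged = {}
        for mp in maps:
            merged.update(mp)
        return merged

    collect_dist(root)

    return SimGene(
        gene_id=gene_id,
        root=root,
        true_topology=true_topo,
        observed_pair=observed,
        introgressed=introgressed,
        ghost=ghost,
        direction=direction,
        coal_times=times,
        tip_dist=dist,
    )


def _msc_probs(T: float, concordant: Topology) -> np.ndarray:
    """Topology probabilities when one pair has a head start of T.

    The pair coalesces within its shared interval with probability
    1 - e^(-T); failing that, three lineages enter the common ancestral
    population and the first coalescence is any pair with probability 1/3.
    """
    e = math.exp(-T)
    out = np.full(3, e / 3.0)
    out[TOPOLOGY_ORDER.index(concordant)] = 1.0 - 2.0 * e / 3.0
    return out


def expected_topology_probs(params: SimParams) -> tuple[float, float, float]:
    """Closed-form (p_AB, p_BC, p_AC) mixture twin of the simulator.

    Each gene class is an MSC race with a class-specific head start: the
    species history gives the A-B pair T1 = tau_abc - tau_ab; the two
    introgression directions give the B-C pair T2 = tau_abc - tau_m or
    T2b = tau_ab - tau_m (after which three lineages share a population
    and the first coalescence is uniform, so the same functional form is
    exact); the ghost mimic gives B-C the interval during which A's
    lineage is sequestered.
    """
    base = 1.0 - params.gamma - params.ghost_gamma
    f = params.pulse_via_ab_ancestor
    p = base * _msc_probs(params.T1, Topology.AB)
    p = p + (1.0 - f) * params.gamma * _msc_probs(params.T2, Topology.BC)
    p = p + f * params.gamma * _msc_probs(params.T2b, Topology.BC)
    if params.ghost_gamma > 0:
        t_ghost = params.tau_ghost_join - params.tau_abc
        p = p + params.ghost_gamma * _msc_probs(t_ghost, Topology.BC)
    return tuple(p)


def simulate_topologies(params: SimParams, n: int, rng) -> np.ndarray:
    """Vectorized topology-only simulation (indices into AB, BC, AC order).

    Uses the same generative steps as :func:`simulate_genealogy` — draw the
    per-gene class and direction, race the head-start pair against its
    interval, fall back to a uniform pair among three lineages — without
    building trees.
    """
    u = rng.random(n)
    intro = u < params.gamma
    ghost = (~intro) & (u < params.gamma + params.ghost_gamma)
    via_ab = rng.random(n) < params.pulse_via_ab_ancestor
    T = np.where(
        intro, np.where(via_ab, params.T2b, params.T2),
        np.where(ghost, params.tau_ghost_join - params.tau_abc, params.T1),
    )
    concord_idx = np.where(intro | ghost, TOPOLOGY_ORDER.index(Topology.BC),
                           TOPOLOGY_ORDER.index(Topology.AB))
    sorted_ = rng.random(n) < (1.0 - np.exp(-T))
    uniform_pick = rng.integers(0, 3, size=n)
    return np.where(sorted_, concord_idx, uniform_pick)


def census_from_topology_indices(idx: np.ndarray, threshold=None) -> TopologyCensus:
    n_ab = int((idx == 0).sum())
    n_bc = int((idx == 1).sum())
    n_ac = int((idx == 2).sum())
    return TopologyCensus(
        n_ab=n_ab, n_bc=n_bc, n_ac=n_ac, threshold=threshold,
        n_input=len(idx), n_rejected=0,
    )


def simulate_alignment(gene: SimGene, params: SimParams, rng,
                       scheme: TaxonScheme = DEFAULT_SCHEME) -> GeneAlignment:
    """Evolve a JC69 alignment along the gene's realized branch lengths.

    The root sequence is uniform over {A,C,G,T}; each branch substitutes
    each site independently with probability (3/4)(1 - e^(-4L/3)) to a
    uniformly chosen different base; columns are independent.
    """
    L = params.aln_length
    if L <= 0:
        raise ValueError("aln_length must be positive")
    seqs: dict[str, np.ndarray] = {}

    def evolve(node: SimNode, seq: np.ndarray) -> None:
        if not node.children:
            seqs[node.name] = seq
            return
        for ch in node.children:
            p_sub = 0.75 * (1.0 - math.exp(-4.0 * ch.length / 3.0))
            mask = rng.random(L) < p_sub
            child_seq = seq.copy()
            if mask.any():
                shift = rng.integers(1, 4, size=int(mask.sum()))
                child_seq[mask] = (child_seq[mask] + shift) % 4
            evolve(ch, child_seq)

    evolve(gene.root, rng.integers(0, 4, size=L))
    labels = {"A": scheme.taxon_a, "B": scheme.taxon_b,
              "C": scheme.taxon_c, "O": scheme.outgroup}
    return GeneAlignment(
        gene_id=gene.gene_id,
        sequences={
            labels[role]: "".join(chr(b) for b in _BASES[arr])
            for role, arr in seqs.items()
        },
    )


_PAIRS = (Topology.AB, Topology.BC, Topology.AC)


def attach_supports(gene: SimGene, params: SimParams, rng,
                    scheme: TaxonScheme = DEFAULT_SCHEME) -> float | None:
    """Bootstrap support (percent) for the gene's ingroup pairing.

    Columns are resampled ``support_bootstraps`` times; each replicate's
    minimum-evolution pairing is the ingroup pair with the smallest
    JC-corrected distance (ties broken in fixed AB, BC, AC order and
    flagged on the gene).  The support is the percentage of replicates
    whose pairing matches the pairing of the emitted tree.  Returns None
    when ``support_bootstraps`` is 0.
    """
    B = params.support_bootstraps
    if B == 0:
        return None
    if gene.alignment is None:
        raise ValueError(f"{gene.gene_id}: simulate the alignment first")
    labels = {"A": scheme.taxon_a, "B": scheme.taxon_b, "C": scheme.taxon_c}
    rows = {
        role: np.frombuffer(gene.alignment.sequences[lab].encode(), dtype=np.uint8)
        for role, lab in labels.items()
    }
    L = gene.alignment.length
    diffs = {}
    for topo in _PAIRS:
        x, y = sorted(topo.sister_pair)
        diffs[topo] = (rows[x] != rows[y]).astype(np.float64)
    idx = rng.integers(0, L, size=(B, L))
    dists = np.empty((3, B))
    for k, topo in enumerate(_PAIRS):
        p = diffs[topo][idx].mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(p < 0.75, -0.75 * np.log(1.0 - 4.0 * p / 3.0), np.inf)
        dists[k] = d
    best = dists.min(axis=0)
    winner = dists.argmin(axis=0)  # argmin takes the first => fixed-order tie-break
    ties = (dists == best).sum(axis=0) > 1
    gene.support_tie = bool(ties.any())
    target = _PAIRS.index(gene.observed_pair)
    support = 100.0 * float((winner == target).mean())
    gene.support = support
    return support


def simulate_dataset(
    params: SimParams,
    n_resistant: int = 0,
    with_alignments: bool = False,
    with_supports: bool = False,
    scheme: TaxonScheme = DEFAULT_SCHEME,
    seed: int | None = None,
) -> list[SimGene]:
    """Simulate ``params.n_genes`` genes; the first ``n_resistant`` are
    forced to follow the species history (introgression-resistant)."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    width = max(4, len(str(params.n_genes)))
    genes = []
    for i in range(params.n_genes):
        gene = simulate_genealogy(
            params, rng, gene_id=f"g{i:0{width}d}",
            force_no_introgression=i < n_resistant,
        )
        gene.resistant = i < n_resistant
        if with_alignments or with_supports:
            gene.alignment = simulate_alignment(gene, params, rng, scheme)
        if with_supports:
            attach_supports(gene, params, rng, scheme)
        genes.append(gene)
    return genes


def to_newick(gene: SimGene, scheme: TaxonScheme = DEFAULT_SCHEME) -> str:
    """Emit the gene tree as newick with branch lengths and, when known,
    the support as the label of the ingroup-pair junction node."""
    labels = {"A": scheme.taxon_a, "B": scheme.taxon_b,
              "C": scheme.taxon_c, "O": scheme.outgroup}
    sup = None if gene.support is None else f"{gene.support:g}"
    # the ingroup junction (lowest pairwise ingroup MRCA) is the node whose
    # label triplet extraction reads as the pair support
    hub_height = min(
        gene.coal_times[frozenset(p)] for p in (("A", "B"), ("A", "C"), ("B", "C"))
    )

    def render(node: SimNode) -> str:
        if not node.children:
            return f"{labels[node.name]}:{node.length:.10g}"
        inner = ",".join(render(ch) for ch in node.children)
        lab = ""
        if sup is not None and node.height == hub_height:
            lab = sup
        return f"({inner}){lab}:{node.length:.10g}"

    body = ",".join(render(ch) for ch in gene.root.children)
    return f"({body});"


def triplet_record_from_sim(gene: SimGene) -> TripletRecord:
    """Fast-path conversion of a simulated gene to a TripletRecord,
    bypassing newick round-tripping (distances come straight from the
    realized genealogy; topology is the context-read quartet split)."""
    d_ab = gene.tip_dist[frozenset(("A", "B"))]
    d_ac = gene.tip_dist[frozenset(("A", "C"))]
    d_bc = gene.tip_dist[frozenset(("B", "C"))]
    rec = TripletRecord(
        gene_id=gene.gene_id,
        topology=gene.observed_pair,
        support=gene.support,
        d_ab=d_ab,
        d_ac=d_ac,
        d_bc=d_bc,
        total_length=0.5 * (d_ab + d_ac + d_bc),
        provenance="context-rooted",
    )
    meta = _midpoint_metadata(d_ab, d_ac, d_bc)
    if meta is not None:
        rec.midpoint_outgroup, rec.outgroup_branch = meta
    return rec


def estimate_gamma(
    cens: TopologyCensus,
    T2: float,
    T2b: float | None = None,
    via_ab_frac: float = 0.5,
) -> tuple[float, float, float]:
    """Maximum-likelihood (gamma, T1) from a topology census, T2 known.

    Two free census frequencies cannot pin down more than two parameters,
    so the introgressed-class head start(s) must be supplied: ``T2`` alone
    for a pulse routed entirely through the recipient-C population, plus
    ``T2b`` (with mixing weight ``via_ab_frac`` on the T2b route) when
    some introgressed genes travel via the A+B ancestral pool, matching
    the generator.  The trinomial log-likelihood under the closed-form
    mixture is maximized on a coarse (gamma, T1) grid and refined with
    L-BFGS-B; a profile fit along the gamma = 0 boundary is compared so
    symmetric censuses land exactly on gamma_hat = 0.
    Returns (gamma_hat, T1_hat, loglik).
    """
    counts = np.array([cens.n_ab, cens.n_bc, cens.n_ac], dtype=float)
    if counts.sum() == 0:
        raise ValueError("census has no counts")

    def head_start_probs(T: float) -> np.ndarray:
        e = math.exp(-T)
        return np.array([e / 3.0, 1.0 - 2.0 * e / 3.0, e / 3.0])

    intro_p = head_start_probs(T2)
    if T2b is not None:
        intro_p = (1.0 - via_ab_frac) * intro_p + via_ab_frac * head_start_probs(T2b)

    def probs(gamma: float, T1: float) -> np.ndarray:
        e1 = math.exp(-T1)
        base = np.array([1.0 - 2.0 * e1 / 3.0, e1 / 3.0, e1 / 3.0])
        return (1.0 - gamma) * base + gamma * intro_p

    def negll(theta) -> float:
        gamma, T1 = theta
        p = np.clip(probs(gamma, T1), 1e-300, 1.0)
        return -float(counts @ np.log(p))

    gammas = np.linspace(0.0, 1.0, 51)
    t1s = np.geomspace(0.01, 8.0, 60)
    best = None
    for g in gammas:
        for t in t1s:
            v = negll((g, t))
            if best is None or v < best[0]:
                best = (v, g, t)
    res = optimize.minimize(
        negll, x0=[best[1], best[2]], method="L-BFGS-B",
        bounds=[(0.0, 1.0), (1e-8, 20.0)],
    )
    g_hat, t1_hat = res.x
    ll = -res.fun
    # profile along the gamma = 0 boundary
    res0 = optimize.minimize_scalar(
        lambda t: negll((0.0, t)), bounds=(1e-8, 20.0), method="bounded"
    )
    if -res0.fun >= ll - 1e-9:
        return 0.0, float(res0.x), float(-res0.fun)
    return float(g_hat), float(t1_hat), float(ll)


# ---------------------------------------------------------------------------
# dataset writers

def write_dataset(
    genes: Sequence[SimGene],
    outdir: str | Path,
    params: SimParams,
    scheme: TaxonScheme = DEFAULT_SCHEME,
    write_alignments: bool = True,
) -> None:
    """Write trees.tsv, truth.tsv, params.json and (optionally) per-gene
    FASTA alignments under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "trees.tsv", "w") as fh:
        for g in genes:
            fh.write(f"{g.gene_id}\t{to_newick(g, scheme)}\n")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("gene_id\ttrue_topology\tobserved_pair\tintrogressed\tghost\tresistant\tsupport\n")
        for g in genes:
            sup = "" if g.support is None else f"{g.support:g}"
            fh.write(
                f"{g.gene_id}\t{g.true_topology.value}\t{g.observed_pair.value}\t"
                f"{int(g.introgressed)}\t{int(g.ghost)}\t{int(g.resistant)}\t{sup}\n"
            )
    with open(outdir / "params.json", "w") as fh:
        json.dump(asdict(params), fh, indent=2)
    if write_alignments and any(g.alignment is not None for g in genes):
        aln_dir = outdir / "alignments"
        aln_dir.mkdir(exist_ok=True)
        for g in genes:
            if g.alignment is None:
                continue
            with open(aln_dir / f"{g.gene_id}.fasta", "w") as fh:
                for lab, seq in g.alignment.sequences.items():
                    fh.write(f">{lab}\n{seq}\n")
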