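"""Patterson's D (ABBA-BABA) and the distance-based D3, with gene-level
bootstrap confidence intervals.

Both statistics test for an excess of one of the two discordant histories.
D uses biallelic site patterns in four-taxon alignments ordered
(P1, P2, P3, O) = (A, B, C, outgroup), with the outgroup allele taken as
ancestral: ABBA sites pair the derived allele in P2 and P3, BABA sites in
P1 and P3.  D3 needs no outgroup: it contrasts the two cross-pair
patristic distances of the rooted triplet, d(B,C) vs d(A,C).

Aggregation is ratio-of-sums across genes (sum the counts or distances,
then form the ratio) — stabler than averaging per-gene ratios for short
genes.  Uncertainty comes from resampling whole genes with replacement,
which respects within-gene linkage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .records import TripletRecord
from .trees import GeneAlignment, TaxonScheme

_VALID = b"ACGT"


@dataclass
class SitePatternCounts:
    """Per-gene ABBA/BABA tallies."""

    gene_id: str
    n_abba: int
    n_baba: int
    n_sites_used: int

    def __post_init__(self) -> None:
        if min(self.n_abba, self.n_baba, self.n_sites_used) < 0:
            raise ValueError("site-pattern counts must be non-negative")
        if self.n_abba + self.n_baba > self.n_sites_used:
            raise ValueError("ABBA+BABA cannot exceed sites used")


def count_site_patterns(
    aln: GeneAlignment, scheme: TaxonScheme
) -> SitePatternCounts:
    """Count ABBA/BABA columns in a four-taxon alignment.

    A column contributes only if it is biallelic across the four rows,
    contains no gap or ambiguity code, and the outgroup carries one of the
    two alleles (it always does when the column is biallelic and clean).
    """
    rows = [
        np.frombuffer(
            aln.row_for_role(scheme, role).upper().encode(), dtype=np.uint8
        )
        for role in ("A", "B", "C", "O")
    ]
    p1, p2, p3, out = rows
    valid = np.ones(aln.length, dtype=bool)
    for r in rows:
        valid &= np.isin(r, np.frombuffer(_VALID, dtype=np.uint8))
    # biallelic: exactly two distinct states among the four rows
    stacked = np.stack(rows)
    n_states = np.zeros(aln.length, dtype=np.int8)
    for base in _VALID:
        n_states += (stacked == base).any(axis=0)
    biallelic = valid & (n_states == 2)
    abba = biallelic & (p1 == out) & (p2 == p3) & (p2 != out)
    baba = biallelic & (p2 == out) & (p1 == p3) & (p1 != out)
    return SitePatternCounts(
        gene_id=aln.gene_id,
        n_abba=int(abba.sum()),
        n_baba=int(baba.sum()),
        n_sites_used=int(valid.sum()),
    )


@dataclass
class DStatResult:
    D: float
    ci_low: float
    ci_high: float
    Z: float
    p_value: float
    n_genes: int
    B: int
    seed: int


@dataclass
class D3Result:
    D3: float
    orientation: str
    implicated_pair: str  # "BC-closer" | "AC-closer" | "none"
    ci_low: float
    ci_high: float
    Z: float
    p_value: float
    n_genes: int
    B: int
    seed: int


D3_ORIENTATION = (
    "(sum d_BC - sum d_AC) / (sum d_BC + sum d_AC) over genes; species tree "
    "((A,B),C); negative values mean B and C are the closer pair"
)


def _ratio_of_sums_bootstrap(
    num: np.ndarray, den: np.ndarray, B: int, seed: int
) -> tuple[float, float, float, float, float]:
    """Point estimate and gene-level bootstrap of sum(num)/sum(den).

    Returns (estimate, ci_low, ci_high, Z, p).  Percentile CI at 95%;
    Z = estimate / sd(bootstrap estimates); p from the normal tail.
    """
    tot_den = den.sum()
    if tot_den == 0:
        raise ValueError("no informative sites/distances (denominator is zero)")
    est = float(num.sum() / tot_den)
    n = len(num)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    reps_num = num[idx].sum(axis=1)
    reps_den = den[idx].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        reps = np.where(reps_den > 0, reps_num / reps_den, np.nan)
    reps = reps[np.isfinite(reps)]
    if len(reps) < B:
        warnings.warn(
            f"{B - len(reps)} bootstrap replicates dropped (zero denominator)"
        )
    ci_low, ci_high = np.percentile(reps, [2.5, 97.5])
    sd = float(reps.std(ddof=1)) if len(reps) > 1 else 0.0
    if sd == 0.0:
        warnings.warn("bootstrap sd is zero; Z reported as infinite")
        z = math.inf if est != 0 else 0.0
    else:
        z = est / sd
    p = 2.0 * stats.norm.sf(abs(z)) if math.isfinite(z) else 0.0
    return est, float(ci_low), float(ci_high), float(z), float(p)


def patterson_d(
    counts: Sequence[SitePatternCounts], B: int = 1000, seed: int = 0
) -> DStatResult:
    """Four-taxon D = (sum ABBA - sum BABA) / (sum ABBA + sum BABA).

    Positive D (with taxa ordered A, B, C, outgroup) marks an excess of
    derived-allele sharing between B and C.  CIs/Z/p come from resampling
    genes with replacement ``B`` times.
    """
    if not counts:
        raise ValueError("no genes supplied")
    abba = np.array([c.n_abba for c in counts], dtype=float)
    baba = np.array([c.n_baba for c in counts], dtype=float)
    d, lo, hi, z, p = _ratio_of_sums_bootstrap(abba - baba, abba + baba, B, seed)
    return DStatResult(
        D=d, ci_low=lo, ci_high=hi, Z=z, p_value=p,
        n_genes=len(counts), B=B, seed=seed,
    )


def d3(
    records: Sequence[TripletRecord], B: int = 1000, seed: int = 0
) -> D3Result:
    """Three-taxon D3 from per-gene patristic distances.

    D3 = (sum d_BC - sum d_AC) / (sum d_BC + sum d_AC); under the species
    tree ((A,B),C) both cross distances share the same expectation, so the
    sign implicates the closer-than-expected pair (negative: B-C).
    """
    usable = [r for r in records if r.has_distances]
    if not usable:
        raise ValueError("no records with distances")
    dbc = np.array([r.d_bc for r in usable], dtype=float)
    dac = np.array([r.d_ac for r in usable], dtype=float)
    est, lo, hi, z, p = _ratio_of_sums_bootstrap(dbc - dac, dbc + dac, B, seed)
    if est < 0:
        pair = "BC-closer"
    elif est > 0:
        pair = "AC-closer"
    else:
        pair = "none"
    return D3Result(
        D3=est, orientation=D3_ORIENTATION, implicated_pair=pair,
        ci_low=lo, ci_high=hi, Z=z, p_value=p,
        n_genes=len(usable), B=B, seed=seed,
    )
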