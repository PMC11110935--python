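# Methods

## The inference problem

Three closely related species A, B, C (species tree ((A,B),C)) plus an
outgroup O. Each single-copy gene ("1:1:1 triplet") carries one of three
rooted topologies: AB, BC or AC. Incomplete lineage sorting (ILS) makes
gene trees discordant with the species tree, but symmetrically: the two
discordant classes have equal expected frequency (1/3)·e^(−T1) each,
where T1 is the internal branch in coalescent units (time / 2N). Gene
flow after speciation breaks the symmetry — the topology uniting the
exchanging pair is inflated — and additionally shortens branch lengths in
the affected trees, because introgressed lineages coalesce after the
(more recent) gene-flow event. The package implements the census,
site-pattern, branch-length and enrichment tests that exploit these two
signatures, and a simulator that generates data under the null and
alternative so that every test can be validated end to end.

## Triplet extraction and classification

Gene trees may contain many tips. A gene is used only when exactly one
tip maps (by label prefix) to each of A, B and C. The topology is read by
*context rooting*: every non-focal tip o defines an induced quartet
{a, b, c, o}, whose split is found structurally from the attachment point
of o on the {a, b, c} spanning subtree (attachment on the z-side groups o
with z and votes for the pair excluding z; attachment at the hub
abstains, which handles polytomies). The majority vote decides; ties are
rejected as ambiguous. The pair support is the parsed label of the
spanning-subtree hub — this node is the focal-pair MRCA under rooting at
*any* concordant context tip, so no per-tip choice arises. A gene whose
hub sits at zero patristic distance from the deciding context attachment
is classified UNRESOLVED (its internal edge has zero length). Genes with
no context tips fall back to midpoint rooting of the bare 3-taxon tree:
the pruned triplet is a star with pendants p_a = (d_AB + d_AC − d_BC)/2
(cyclically), the midpoint of the longest tip-to-tip path lands on the
pendant of the tip with the largest pendant edge, that tip is the
"midpoint-selected outgroup", and ties break to the alphabetically first
taxon for reproducibility. Internal newick labels are read as bootstrap
supports on the 0–100 scale; values in (0, 1] are treated as proportions
and rescaled with a warning. Branch lengths are required for all
distance-based stages (a missing length is an error, never a silent 0);
length-free trees still count in the topology-only census.

## Statistics

**Minority asymmetry.** With the majority topology set aside, the two
minority counts (k1, k2) are tested against Binomial(k1+k2, 1/2),
two-sided by the minimum-likelihood rule (sum of all outcome
probabilities not exceeding the observed one — at p0 = 1/2 this equals
doubling the smaller tail, capped at 1). Records with unknown support
are excluded whenever a numeric support threshold is in force.

**Patterson's D.** Sites are used only if biallelic across the four rows
with no gaps/ambiguity; the outgroup allele is ancestral. ABBA: P1
ancestral, P2 and P3 derived; BABA: P2 ancestral, P1 and P3 derived.
Aggregation is ratio-of-sums across genes (stabler than averaging
per-gene ratios when genes are short). Uncertainty: resample genes with
replacement B times (default 1,000), percentile 95% CI, Z = D/sd of the
bootstrap distribution, p = 2Φ(−|Z|). The statistic and Z are reported
signed, with the implicated pair stated explicitly, since sign
conventions differ across the literature.

**D3.** Same aggregation and bootstrap applied to per-gene patristic
distances: D3 = (Σd_BC − Σd_AC)/(Σd_BC + Σd_AC), orientation fixed to
the species tree ((A,B),C), so negative D3 implicates B–C proximity.
Tree distances are the default source; alignment p-distances would be a
trivial substitution but tree lengths are what the rest of the pipeline
consumes.

**Branch-length discrimination.** Three per-record metrics: (i) mean
patristic distance from the excluded ("outgroup") taxon to the two pair
members (a distance-to-pair-MRCA variant is available), (ii) total
triplet length (half the sum of the three pairwise distances), (iii) the
midpoint-selected outgroup's pendant edge. Pairwise Mann–Whitney U tests
run within each metric and are Holm-adjusted per metric (family = the 3
pairwise comparisons). The *verdict* is a contest between the two most
common classes, which are the two species-tree contenders: the runner-up
is declared the introgression class only if it is significantly below
the majority class on all three metrics with lower medians. Two facts
dictated this design rather than a conjunction against all classes:
under pure ILS the concordant class is itself the shortest on all these
metrics (discordant resolutions require deeper coalescence), so a
"lower than everything" rule misfires on null data once n is large; and
the least-common (ILS) class absorbs introgressed genes whose lineages
failed to sort, which makes introgression-vs-ILS pendant comparisons
uninformative. All nine pairwise tests and the per-class medians are
still reported for inspection.

**Ghost-lineage test.** d(B,C) compared between BC-topology and
AB-topology records (Mann–Whitney; medians and the one-sided p for the
shorter-in-BC direction reported). Genuine B–C introgression collapses
this distance; gene flow from an unsampled lineage into A inflates BC
counts while leaving d(B,C) at ILS-like depths, so the reduction is far
weaker. The simulator's ghost mimic shows a residual reduction (its BC
class still contains ordinary ILS genes, which coalesce somewhat
earlier), so the package's validation compares effect sizes between the
genuine and ghost scenarios rather than asserting a flat null.

**Mann–Whitney U.** U = #{x>y} + ½#{x=y}. Pooled sizes ≤ 20 use an exact
two-sided p — scipy's exact distribution when there are no ties,
otherwise direct enumeration of all C(n1+n2, n1) labelings with midranks
(scipy's exact method refuses ties). Larger samples use the normal
approximation with tie and continuity corrections.

**Fisher–Freeman–Halton 2×3.** All tables with the observed margins are
enumerated; point probabilities are multivariate hypergeometric,
computed in log space; p sums the probabilities ≤ the observed one, with
a relative tolerance of 1e−12 so floating-point ties are included
deterministically, and is normalized by the enumerated total mass to
absorb rounding residue (degenerate margins then reduce exactly to 2×2
or p = 1). The per-category tests use the genome-wide census *including*
the category genes as the background row, matching how the reference
analysis tabulated its counts; Holm adjustment runs across the tested
categories. The reference table's printed p-values are reproduced by the
raw exact test; the Holm column is computed and reported separately.

**Holm.** adjusted_(k) = max_{j≤k} (m−j+1)·p_(j), capped at 1, returned
in input order.

## The simulator

Standard multispecies coalescent, one sampled lineage per species,
coalescence rate 1 per lineage pair within a population, times in units
of 2N generations. Populations: A, B, C and O until their splits at
`tau_ab` (A+B), `tau_abc` (ingroup root) and `tau_out`; unresolved
lineages move to the parent population. With probability `gamma` a gene
is introgressed; the forward-time direction determines the backward
genealogy. Donor B → recipient C: the sampled C lineage enters B's
population at the pulse time `tau_m` and the A+B ancestral population at
`tau_ab`, so the pair's head start is T2b = tau_ab − tau_m and the deep
coalescence with A's lineage can happen well before the ingroup root —
this is the route that shortens outgroup distances, total lengths and
midpoint-outgroup pendants (the discrimination signals). Donor C →
recipient B: the sampled B lineage sits in C's population until
`tau_abc` (head start T2 = tau_abc − tau_m), shortening only d(B,C).
`pulse_via_ab_ancestor` (default 0.8) is the fraction of introgressed
genes on the first route; the default reflects the scenario the
branch-length predictions presuppose — introgressed material reaching
the outgroup-side ancestral pool — while keeping a minority on the other
route. A 50:50 mix makes the pendant metric cancel exactly at class
level (the two routes shift it in opposite directions); the parameter
exposes that trade-off. With probability `ghost_gamma` a gene instead
received flow from an unsampled lineage into A: its A lineage is
sequestered until `tau_ghost_join`.

The closed-form twin is exact for the first-ingroup-coalescence topology
definition: each class is an MSC race, concordant with probability
1 − (2/3)e^(−T) for head start T (T1, T2, T2b, or the ghost window), the
rest split uniformly — uniformity survives outgroup intrusion because a
merge with O's lineage does not bias which ingroup pair coalesces first.
The emitted-tree topology is instead the quartet split read against the
outgroup; the two differ for the rare genes (≈0.3% at the defaults)
where O's lineage interleaves among unsorted ingroup lineages, which is
a realistic feature, not an error.

Branch lengths are durations × `rate` (substitutions/site per coalescent
unit, default 0.01) × an independent lognormal multiplier per branch
(median 1, log-sd `rate_noise_sigma` = 0.2) emulating among-branch rate
variation; trees are exactly ultrametric when the noise is off.
Alignments evolve by JC69 along the realized branch lengths from a
uniform root sequence, columns independent. Supports are
column-resampling bootstraps: each replicate's minimum-evolution pairing
(smallest JC-corrected distance among the three ingroup pairs, ties
broken in fixed AB/BC/AC order and flagged) is compared with the
emitted tree's pairing; support = percent matching.

Default times: tau_m = 0.25, tau_ab = 0.75, tau_abc = 1.25,
tau_out = 2.5, i.e. T1 = 0.5, T2 = 1.0, and the pulse at one third of
the A–B split age — introgression recent relative to the speciations,
as inferred for the motivating system. With gamma = 0.25 the expected
census is ≈ 49/31/20% (AB/BC/AC): a clear majority, a clear BC-over-AC
excess, the qualitative pattern the pipeline is designed to detect.
The γ estimator maximizes the trinomial likelihood of the census counts
over (γ, T1) on a coarse grid refined by L-BFGS-B, with the
introgressed-class head starts supplied (they are not identifiable from
two free frequencies); a profile fit along γ = 0 is compared so exactly
symmetric censuses return γ̂ = 0.

What the simulator does **not** model: recombination within genes,
demographic size changes, continuous migration (a single pulse only),
among-site rate variation, alignment error, or gene-tree estimation
error beyond the bootstrap-support machinery. Passing tests therefore
show that the statistics behave correctly under a clean coalescent
signal of realistic magnitude — not that they are robust to alignment
or inference artifacts in real data.

## Validation sizes and numerical choices

The test suite validates: printed-count statistics exactly (4 decimal
places); the binomial test against a pmf-enumeration oracle for all
n ≤ 500; the 2×3 exact test against a rational-arithmetic brute-force
oracle for all row-1 totals ≤ 12 over a panel of backgrounds; the
Mann–Whitney test against a labeling-enumeration oracle for all sizes
≤ 8 (with ties); simulator topology frequencies against the closed form
within 3 binomial SE at n = 10^5 over a 3×3 (γ, T1) grid; null
calibration with 500 censuses of 1,000 genes (asymmetry-test rejection
rate in [0.03, 0.07]) and 100–200 replicate genomes for mean D and D3;
power and recovery on a γ = 0.3 genome of 10,000 genes (binomial, D3,
discrimination verdict, ghost test, γ̂ within ±0.05); and end-to-end
enrichment detection of a 250-gene introgression-resistant category in a
5,000-gene genome (the reference analysis's category had 121 of 8,077
genes; 250 of 5,000 keeps single-dataset detection power near 1 at the
same effect size). Problem sizes were chosen so the whole suite
completes in a few minutes on one CPU.

Seeds are explicit everywhere randomness enters (simulation, bootstrap,
category sampling). Bootstrap replicates that draw a zero denominator
are dropped with a warning; a zero bootstrap sd reports Z = ∞ with a
warning rather than NaN. All topology outputs use the fixed (AB, BC,
AC) order; all tie-breaks (midpoint outgroup, ME pairing, Fisher
tail inclusion) are deterministic and documented above.

## Known limitations

* The discrimination verdict deliberately compares only the two most
  common classes; a scenario where the introgression class outnumbers
  the species-tree class returns "inconclusive" rather than guessing.
* The γ estimator conditions on known head-start durations; absolute
  times and γ are not jointly identifiable from a single census.
* The ghost mimic is a single sequestered-lineage model; richer ghost
  demographies (multiple pulses, ghost-to-B/C flow) are out of scope.
* Patterson's D assumes the outgroup carries the ancestral allele at
  biallelic sites; deep outgroups near saturation weaken this premise
  in real data (the simulator's outgroup is shallow enough not to).
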