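# Methods

## Synthetic chromatin model

The generator plants the structure the analysis is designed to detect,
so every stage has a recovery test with known truth.

**Dyad lattice.** Around each TF site a nucleosome-free region (NFR) of
the preset width is centered; the first dyads sit at
`site ± (nfr/2 + 73)` and subsequent dyads follow at steps of the
nucleosome repeat length NRL = 147 + linker.  Arrays from neighboring
NFRs grow toward each other and stop at the midpoint; dyads closer than
147 bp at the seam are dropped.  Positional jitter is i.i.d. Gaussian
around the ideal lattice (default sd 5 bp), i.e. non-cumulative:
remodelers position nucleosomes against the TF-site anchor rather than
against the previous nucleosome, so phase errors do not accumulate.
Unphased presets (RSC-like, unremodeled) keep the NRL but draw a
uniform phase per inter-NFR region.  Presets encode the in vitro ruler
signatures: INO80 41/126, ISW2 29/68, Chd1 22/92 (linker bp / NFR bp).

**Ligation pairs.** Nucleosome pairs (i, j) are sampled with
probability ∝ `s^(-alpha) · Π beta(w)`, where `s` is the dyad distance
(shorter arc on circular contigs), alpha defaults to 1 (typical of
nucleosome-scale contact decay), and each NFR of width `w` strictly
between the dyads multiplies the weight by `beta(w) = exp(-w/w0)` with
w0 = 150 bp — about one DNA persistence length, so that naked DNA
stretches insulate in proportion to their length.  No quantitative
width–attenuation law is established experimentally; `beta` is a
modeling choice and only its monotonicity is relied upon.  Junctions
are emitted at `dyad ∓ 80` with read directions drawn from the
orientation mix (default uniform, independent of distance), so the
downstream 80 bp dyad shift inverts the offset exactly.  An optional
fraction of sub-147 bp "undigested" pairs exercises the short-distance
filter.

**Cut sites.** A fraction `f_cut` of molecules treats each restriction
site as severed: the contig decomposes into linear segments, pairs are
sampled within segments only, and distance is the linear path.  With a
single cut on a circle the molecule stays one (opened) segment — loci
flanking the cut remain connected the long way round, which models the
observed residual cross-cut contacts in incompletely digested samples.
The mixture is implemented exactly: the sampling distribution is
`(1-f_cut)·P_uncut + f_cut·P_cut`, each term normalized separately.

**MNase fragments.** Midpoints scatter Normal(0, 5 bp) around a
uniformly chosen dyad; lengths are Normal(160, 25) truncated to
[100, 260] bp so the 125–205 bp filter cuts on both flanks.

What the generator does **not** emulate: sequence (no FASTA/FASTQ, no
MNase sequence bias), octamer thermodynamics, inter-contig ligation,
distance-dependent orientation mixes, and real polymer physics (the
contact law is a bounded power law with multiplicative attenuation, not
a polymer simulation).  Passing recovery tests therefore demonstrate
that the estimators are unbiased and well conditioned under the assumed
statistical structure — not that real libraries satisfy that structure.

## Pair processing

Directions are recorded relative to the ligation junction
(`+` = read extends downstream, `-` = upstream).  After canonical side
ordering, (down, up) → inward, (up, down) → outward, (down, down) →
tandem entry, (up, up) → tandem exit.  Which equal-direction class is
"entry" vs "exit" is a convention; it is fixed here and documented
rather than inferred.  The dyad shift moves each side 80 bp into the
nucleosome its read enters (downstream +80, upstream −80).  Filtering
removes interchromosomal pairs and pairs strictly closer than 147 bp
(147 itself is kept).  A `#shifted:` header records shift status so the
classify→shift→filter pipeline is idempotent on its own output.

## Matrices and derived summaries

Counts are raw throughout — no balancing; `log10(1+x)` is applied only
for correlation (and display).  Nucleosome binning assigns each pair
end to the nearest dyad (ties to the leftmost; ends beyond 100 bp from
any dyad discard the pair, counted).  Pile-ups average square snippets
around anchors, skipping anchors whose window leaves the contig.
Decay curves use 20 log-spaced bins per decade from 147 bp; the slope
is fit on `log10(freq/bin width)` over 400–8,000 bp.  On a regular
lattice the discrete distance spectrum distorts per-bin densities, so
the decay-exponent validation uses irregular (unphased, 40 bp jitter)
chromatin on a 200 kb contig where the availability correction is
negligible over the fit range.  Replicate correlation is Pearson on
`log10(1+count)` over all cells within 5 kb separation.

## Insulation and boundaries

Diamond score for bin *i*, window *w* bins: mean count over cells
(a, b) with `i−w ≤ a < i < b ≤ i+w`; NaN where the diamond does not
fit; normalized as log2 ratio to the contig-wide mean (configurable to
raw means).  A contact boundary that falls between two bins produces a
two-bin tied minimum; the leftmost bin is reported.  Prominence is
topographic prominence of the inverted profile (scipy convention:
climb from the minimum to the lower of the two enclosing key saddles,
contig ends acting as saddles).  Li's threshold is computed on the
prominences on a linear scale by fixed-point iteration
`t' = (μ_low − μ_high)/(ln μ_low − ln μ_high)` from the sample mean,
tolerance 1e-6.  Li assumes a roughly bimodal input; on conditions with
weak insulation (narrow NFRs) the prominence distribution is close to
unimodal and the threshold then splits it near the mean, inflating the
strong-boundary count — visible in the ISW2 condition of
`analysis/04_insulation_boundaries.py` and flagged as a known
limitation of prominence thresholding rather than worked around.

## Nucleosome profiles

Dyad coverage: keep 125–205 bp fragments, place a 50 bp unit footprint
on `[mid−25, mid+25)`, smooth with a centered 20 bp rolling mean
(edges truncated).  Composites divide each anchor window by its own
mean before averaging ("normalized per window"); windows are
strand-flipped for minus-strand anchors.  Peak calling accepts local
maxima greedily by height with 120 bp minimum separation, excluding
±50 bp around the anchor so the TF footprint itself is never called as
a nucleosome.  Metrics per side: linkers = first three peak gaps − 147;
border-to-TF = first-peak offset − 73; NFR width = the **sum** of the
two border distances (per-side means first, then summed).  Negative
values are reported with a warning, never clamped.

Estimator precision is set by the number of anchor sites: with jitter
sd 5 bp, each border estimate has standard error ≈ 5/√n_sites, so the
validation experiments composite over 25 planted sites (the in vivo
analyses use 119–128 TF sites and ~1,200 +1-nucleosome sites).  The
flatness check for unphased chromatin composites over 4,000 random
anchors for the same reason: the realized dyad landscape is a fixed
set of bumps and only many anchor phases average it away.

## 3D reconstruction

Bead geometry: 23 wrapped DNA beads per nucleosome on a left-handed
superhelix (1.65 turns = 594°, radius 4.18 nm, pitch 2.39 nm/turn),
4 histone beads of 3 nm radius along the superhelical axis (their
in-core arrangement is not otherwise constrained), linker DNA at one
bead per 5.88 bp with bond rest length 5.88 × 0.34 = 2.0 nm
(0.34 nm/bp is standard B-DNA rise, an external constant).  Wrapped
beads are tethered to their nearest histone bead to keep cores compact;
the helical geometry is exact at initialization and free to deform
afterwards.

Energy (kT units): bonds `k_b (|d|−d0)²` with k_b = 100; bend term
`k_a θ²` on linker joints with k_a = Lp/(2·l_bond) = 12.5 from the
50 nm DNA persistence length; soft repulsion `k_rep (2r−d)²` between
histone beads only (k_rep = 5; DNA–DNA overlap is not penalized — the
model is descriptive, not a force field); restraints
`w·k_r·(|d|−11 nm)²` active beyond 11 nm, with `w = ln(1+count)` per
nonzero off-diagonal cell of the nucleosome-binned matrix and
k_r = 2.  Inward-tagged restraints act between entry/exit wrapped
beads, all others between histone-core beads.  Minimization is
Metropolis single-bead annealing (Gaussian moves, geometric cooling,
default 8 → 0.02 over 2,500 sweeps, 1.5 nm moves), compiled with numba
and bit-reproducible per seed.  The stiffnesses and schedule were set
so that the annealer converges on the two-domain reference toy
(bond residuals < 5%, domains separate); they are implementation
parameters, not physical claims.  Model contact maps count nucleosome
pairs whose histone-center distance is ≤ 15 nm.

## Numerical conventions and degenerate inputs

Coordinates are 0-based, intervals half-open.  All randomness flows
from explicit seeds through `numpy.random.default_rng` (the annealing
kernel uses numba's seeded RNG); regenerating with the same
configuration is bit-identical.  Equidistant assignment ties go to the
leftmost dyad; plateau minima/maxima report their leftmost position.
Zero-pair orientation classes give NaN decay curves with a warning;
all-NaN insulation profiles give an empty boundary list with a warning;
Li's threshold raises on fewer than two distinct values; the
NFR-vs-insulation correlation raises on zero variance.

## Validation scales

The standard experiments use 10^6 fragments or pairs per condition,
30 kb contigs with 5 planted NFRs for boundary calling, a 106 kb contig
with 25 TF sites for metric recovery, a 17 kb circular plasmid for
linearization, and a 50-nucleosome two-domain toy for reconstruction —
sizes at which every estimator's sampling error is several times
smaller than its acceptance tolerance, while the full validation suite
runs in minutes on one CPU.
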