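# Methods

## Coordinate model and segment deduction

Coordinates are 1-based and inclusive (UniProt convention). A record is a
protein sequence with an optional cleavable signal peptide (always starting
at residue 1), an ordered list of non-overlapping TMD spans, and the membrane
side of the N terminus. For n TMDs, the n+1 extramembrane segments are
deduced arithmetically: the N tail runs from residue 1 (or signal_end+1) to
TMD1_start−1, internal loops between consecutive TMDs, and the C tail from
TMDn_end+1 to the protein end. Abutting TMDs give zero-length loops, encoded
with end = start−1 and length clamped at 0. Segment sides alternate from the
N terminus; a cleavable signal forces the mature N terminus outside
(exoplasmic). The tiling (signal + tails + loops + TMDs partitions
[1, length]) and alternation are asserted as properties for every parsed or
generated record.

Nonstandard residues: X is tolerated in sequences but makes a TMD
unscoreable; B/Z/U/J/O are rejected at parse with a row-level reason, as is a
record claiming both a signal peptide and a cytosolic N terminus. When a
table carries explicit loop columns they are cross-checked against the
recomputed segments and mismatches reported; the recomputed coordinates are
used.

## Biological hydrophobicity scale

ΔG_app of a segment of length L is the sum of per-residue positional
contributions, a hydrophobic-moment term, and a length correction:

    ΔG_app = Σ_i ΔG_aa(pos_i)
           + c_mom · |Σ_i ΔG_i e^(j·100°·i)|
           + c0 + c1·L + c2·L²

with pos_i = 9·(2i/(L−1) − 1) mapping the segment onto [−9, 9]. Each residue
type carries a Gaussian profile a0·exp(−a1·pos²); Trp and Tyr add a symmetric
two-Gaussian term peaking near the membrane interfaces (|pos| ≈ 6.5–6.9),
reflecting their interfacial preference. The moment term (c_mom = 0.27045 at
the α-helical periodicity of 100°/turn) penalizes segregating the polar
contributions onto one helix face; the quadratic length correction
(9.29274167549645 − 0.64513139783394·L + 0.00822196628688·L²) penalizes
short helices. The full coefficient set ships as package data
(`src/memtopo/data/biological_hydrophobicity_scale.tsv`) and its provenance
string is logged by the CLI with every run. Negative values favor insertion.

Because the profiles are even in pos and the moment is a magnitude, ΔG_app
is exactly invariant under sequence reversal — a property test. Supported
lengths are 9–40 aa; recorded TMDs longer than 40 aa are scored by a
minimal-ΔG window scan (default window policy 19–23 aa) within the TMD span.
`dg_scan` enumerates all (start, length) windows and breaks ties toward the
smallest start, then the smallest length; it is verified against brute-force
enumeration. One numerical subtlety worth stating: Ile's central contribution
(−0.4597) is below Leu's (−0.4283), so substituting Leu for Ile can raise
ΔG_app slightly; the hydrophobic-substitution property holds in the
positional form (replacing a residue whose positional contribution exceeds
Leu's at that position never raises ΔG_app, because c_mom < 1).

## Topology classification

Single-pass: a cleavable signal gives Type I (SP-I, necessarily N_exo); a
signal anchor (SA) gives Type II (N_cyt with C tail >50 aa), Type III
(N_exo), or Type IV / tail-anchored (N_cyt with C tail ≤50 aa). The TA
threshold follows the stricter C-tail ≤50 aa definition. Multipass proteins
split into MP-SS (cleavable signal), MP-Nexo and MP-Ncyt. Note that by
alternation the C tail of an N_cyt single-pass protein is exoplasmic, so a
Type II protein with a >100 aa C tail is an N_cyt-long SA.

TMD pairs — two TMDs separated by a ≤50 aa exoplasmic loop — are found by a
greedy left-to-right walk that never reuses a TMD. Because segment sides
alternate, an exoplasmic loop is always followed by a cytosolic one, so the
greedy rule cannot orphan a TMD between two short exoplasmic loops, and it
reproduces the canonical patterns (a 7-TMD N_exo receptor = one unpaired TMD
followed by pairs (2,3)(4,5)(6,7); an even N_cyt protein = (1,2)(3,4)…).
Pair context is first_pair for (1,2); otherwise the preceding cytosolic loop
assigns internal_after_short_cyt (≤50), after_long_cyt (>100), or a distinct
after_intermediate_cyt (51–100) kept out of the short/long contrast strata.

SA classes for cotranslational first TMDs (signal-bearing and TA proteins
excluded): N_exo; N_cyt-long (downstream translocated domain >100 aa);
N_cyt-pair (member of a TMD pair); the 51–100 aa remainder is SA_other —
such domains can plausibly use either translocation route and are reported
separately rather than forced into a class.

Insertion reactions per TMD: R1 (TMD after a cleavable signal; Sec61 lateral
gate), R2 (N_cyt-long SA; Sec61), R3 (N_exo SA; insertase), R4
(tail-anchored; posttranslational insertase), R6a/R6b (first/second of a TMD
pair; insertase), R5a/R5b (the TMDs flanking a >100 aa exoplasmic loop;
Sec61). First-TMD rules are applied first, then pairs, then long-exoplasmic
flanks; in particular the TMD downstream of an N_cyt-long SA's translocated
loop is labelled R5b while the SA keeps R2. Everything else is residual with
a sub-reason (intermediate loop, unpaired terminal/internal TMD). Per-TMD
context tags (SS-following, N_cyt-long-following, pair first/second × pair
context, long-exo first/second, final C-terminal) define the census strata.

## Charge statistics

Charges are K/R (+1) and D/E (−1); His is not counted. Each TMD is split
into five zones — exoplasmic interface (outer 20%), hydrophobic core
(15/30/15%), cytosolic interface (inner 20%) — with boundaries at cumulative
fractions 0.20/0.35/0.65/0.80 of length rounded half-up, which guarantees
tiling for every length ≥5. Zone order follows the TMD's orientation (the
side of its preceding segment). Charge depth maps place each charged residue
at fractional depth (i − 0.5)/L from the exoplasmic end, using residue
centers so no residue sits on a zone boundary.

Flanking net charges are counted over 5/10/15-residue windows in the
adjacent loop or tail only — windows never read through a neighboring TMD or
into a cleaved signal peptide. A flank shorter than the window is scaled by
W/L ("proportional" counts: the only reading that keeps the statistic an
expected count over W residues); scaled values are flagged, and a switch
disables scaling so any summary's sensitivity to this choice can be
reported. The combined charge adds the TMD's own interfacial-zone net charge
(unscaled) to the 10-aa flank. For a TMD pair as a unit, the inside bias
sums both members' combined cytosolic charges; the outside bias is the net
charge of the entire exoplasmic loop plus both exoplasmic interfacial zones,
untruncated and unscaled.

## Sequon census

N-glycosylation sequons are N-X-[S/T]; the strict default excludes Pro at X.
A sequon is usable iff its Asn lies in an exoplasmic segment at least 12
residues (configurable; the report records the value) from every TMD
boundary.

## Synthetic proteome generator

The generator's defaults are the census conditions: topology-class
probabilities from the curated class counts (single-pass share 2,248/4,863);
TMD counts per multipass class from parity-biased distributions (odd-favoring
for MP-Nexo with 7 dominant, even-favoring for MP-Ncyt), giving ≈7 TMDs per
multipass protein; TMD lengths from a discretized normal (mean 23.6, sd 3.0,
support 15–35); tails from lognormals whose (median, mean) pairs match the
census length table — e.g. single-pass exoplasmic tails lognormal(median
277, mean 408); inter-TMD loops from explicit short/intermediate/long
mixtures (exoplasmic 85/6.7/8.3% for the first loop, 93/5.1/1.9% downstream,
cytosolic 89/6.6/4.4%), with short exoplasmic loops lognormal(median 10,
σ 0.8) so pair loops average ≈13.8 aa. Structural constraints are enforced
exactly (a Type II C tail is resampled to >50 aa, a TA tail clipped to
1–50), so every record satisfies exactly one class definition and the truth
bookkeeping (class, segment sides, loop classes, greedy pair list, TMD
roles) is recovered deterministically by the pipeline.

TMD composition is a two-table mixture (a hydrophobic-core table dominated
by Leu/Ile/Val/Ala/Phe and a polar table including charged residues). The
mixing weight for each hydrophobicity stratum (single-pass classes, SA
classes, pair members, long-exoplasmic flanks, remainder) is calibrated by
bisection so the Monte-Carlo mean ΔG_app under the bundled scale matches the
stratum target (e.g. −1.89 for signal-following single-pass TMDs, +0.47 for
N_cyt-pair SAs, +1.12 for pair members); calibration runs at config build
with a fixed internal substream and is part of the build, not hand-entered.

Flank charges are placed by explicit per-residue Bernoulli draws inside
15-aa membrane-adjacent zones of each loop/tail, with rates set so the
expected net charge over a 10-aa window equals the stratum target (+2.04
single-pass / +0.93 multipass inside; −0.17 / −0.12 outside) over a small
background of the opposite charge; everything else is charge-free filler, so
drawn counts are the only charges outside TMDs. Because the rate is uniform
within the zone, proportional W/L scaling of short flanks is unbiased, and
the generator targets are recovered by `positive_inside_summary` within
Monte-Carlo error. A single seed feeds three named substreams (structure,
composition, charges), making generation byte-reproducible and insulating
each component's draws from changes in the others.

What the generator does not emulate: real protein families and homology,
domain content of soluble regions (filler composition is uniform), charge
density beyond the 15-aa flank zones, window-dependent saturation of the
positive-inside bias (real charge density concentrates nearer the TMD), and
any correlation between hydrophobicity and loop length. Passing recovery
tests therefore demonstrates the pipeline's correctness and the stated
statistical structure, not fidelity to any particular real proteome.

## Problem sizes and tolerances

Property-tier acceptance runs use 10,000 generated records for
tiling/alternation, 200 random sequences (≤200 aa) for scan-vs-enumeration,
1,000 sequences for reversal invariance, all lengths 5–40 for zone tiling,
and a 5,000-protein simulation for recovery, chosen to keep the whole suite
under a minute of simulation time while leaving binomial/CLT standard errors
well inside the tolerances: class-mix ±2% (SE ≈ 0.7% at n = 5,000), TMD
length mean ±0.2 aa (SE ≈ 0.02), single-pass inside-flank bias ±0.15
(SE ≈ 0.04), per-stratum ΔG means ±0.4 (calibration bias plus SE ≈ 0.1).
Medians of even samples are the mean of the central pair; report floats are
rounded to 4 decimals with fixed key order, so identical inputs give
byte-identical reports.

## Known limitations

- The ΔG reproduction anchor (SEC61A1 TMD6, −0.117 kcal/mol) and the curated
  census totals require third-party inputs (the curated table, the P61619
  sequence) that are not distributed with the package; the corresponding
  acceptance tests state where to place them and fail until provided.
- Concordance of the bundled coefficient set with any particular ΔG server
  version beyond the package's internal oracles is assessed, not asserted.
- Structural burial of charges (whether they face a helix bundle interior)
  and snorkeling geometry are out of scope; charge statistics are purely
  sequence/topology-based.
- The six-reaction labelling follows topology alone; it does not predict
  which insertase (EMC vs GET vs GEL) handles a given TMD.
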