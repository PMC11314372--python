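# Methods

`pcskit` re-implements, as a tested pipeline, a comparative sequence
analysis of phytochelatin synthase (PCS) proteins across cyanobacteria and
eukaryotic microalgae: catalytic-triad annotation, isoform classification,
physicochemical profiling, distance-based phylogeny, ungapped motif
discovery and group statistics. This note records the models, the
parameters that matter, and the design decisions taken where the design
was genuinely open.

## The biology being modelled

PCS enzymes (EC 2.3.2.15, papain-like peptidase superfamily) carry a
conserved N-terminal catalytic domain with a Cys/His/Asp triad
(Cys56/His162/Asp180 in Arabidopsis AtPCS1). Comparative analysis of
cyanobacterial and algal PCS sequences separates them into two groups by
the residue four positions upstream of the catalytic Cys: Asn (the "N"
isoform, group 1, short half-PCS-like proteins) versus Glu or Asp (the
"E"/"D" isoforms, group 2, plant-like proteins with a Cys-rich C-terminal
extension). A Ser/Thr seven residues upstream of the catalytic Cys is a
casein-kinase-2 phosphorylation candidate only when the −4 residue is
acidic (the [ST]-X2-[DE] context), which makes group membership a proxy
for phospho-regulatability. The His–Asp spacing of the triad is invariant
at 17 intervening residues; the Cys–His spacing varies (94–155 in the
sequences profiled).

## Synthetic data generator

Because the original dataset is a set of NCBI accessions, every stage is
tested against synthetic PCS-like scaffolds with planted ground truth:

    [N-term] [T|filler] [x x] [N|E|D] [Q|P] [x] [Y|F] [C]
    [Cys–His segment, optional CC and C-X3-C] [H] [17 spacer] [D] [tail]

* Free positions are drawn uniformly over the 17 residues excluding C, H
  and D, so the planted triad is the only position triple satisfying the
  spacing constraints. The uniform background is a stand-in — no
  composition statistics for real PCS backgrounds are modelled.
* The four residues upstream of each planted conserved Cys (CC/CXXXC) are
  kept out of {N, E, D} so no spurious triad candidate can outscore the
  true one in the fallback scanner; remaining ties resolve to the smaller
  Cys position, which is always the true one.
* Cys–His spacing defaults to a uniform draw from the observed 94–155
  range; His–Asp spacing is fixed at 17; the C-terminal tail has a
  configurable Cys fraction (default 0.15) to emulate the metal-sensing
  tail of plant-like isoforms.
* `evolve_pair` and `mutate_sequence` simulate sites independently under
  the JTT substitution model (ancestor from equilibrium frequencies,
  descendant from exp(Qt)); no indels are simulated, so "alignment" of
  simulated families is the identity. `two_group_dataset` freezes the
  triad and its 7-mer context during mutation so the ground truth
  survives; that conservation is imposed, not emergent.
* One integer seed drives a splittable generator (`numpy.random.
  SeedSequence.spawn`) per record, so datasets are reproducible from a
  single seed.

What passing tests on this generator do *not* show: robustness to indels
inside the classification window, to non-uniform residue composition, or
to triads whose spacing falls outside the configured scan bounds. Real
sequences with those features exercise the reference-alignment route
instead.

## Triad detection

Primary route: global pairwise alignment (BLOSUM62, affine gaps; a gap of
length L costs 11 + L) of the query to each annotated reference, mapping
the reference triad through the alignment, and accepting only if the
mapped residues are exactly C/H/D with His–Asp spacing 17. The packaged
default reference is a *synthetic* AtPCS1-like scaffold with the AtPCS1
triad coordinates (56/162/180); real annotated references can be supplied.
Fallback route: enumeration of all (C, H, D) triples with spacing 17 and
Cys–His spacing inside [90, 160] (bracketing the observed 94–155), scored
by context plausibility (+2 for N/E/D at −4, +1 for S/T/N at −7, +1 for
Y/F at −1), ties to the smallest Cys position.

"Distance" between catalytic residues throughout means the count of
residues strictly between them (AtPCS1 56/162/180 → C–H 105, H–D 17),
computed on the raw sequence, not on alignment columns.

In tests, the alignment route is exercised with references *related to
the query* (the unmutated scaffold as reference for a 5%-mutated copy).
Aligning unrelated random scaffolds to a fixed reference is uninformative
because the synthetic inter-segment residues are i.i.d.; real PCS
N-terminal domains are conserved, synthetic ones are not.

## Classification

Fixed sequence offsets from the catalytic Cys (−4 isoform residue, −7
phospho residue), not alignment columns. N → group 1; E/D → group 2;
anything else is retained as `unclassified` rather than guessed. Ser is
accepted at −7. Conserved-Cys counting caps at 4 (the CC + CXXXC
bookkeeping) and excludes the catalytic Cys. Sequence-logo support is an
information-content matrix (IC_j = log2 20 − H_j, bits); no graphics.

## Physicochemical profile

All formulas implemented here; constants from published tables (average
residue masses and the Guruprasad dipeptide instability weights via
Biopython's data modules; the Bjellqvist pKa set frozen locally). The pI
is the unique root of the monotone Henderson–Hasselbalch net-charge
function, found by bisection to 1e-4 pH; because the terminal pKa values
depend on the terminal residues, pI is *not* invariant under permutations
that change the termini (composition statistics otherwise are). X
contributes to length but zero to mass/charge/instability sums, with a
logged warning. Stability flag: instability index < 40.

## Phylogeny

Pairwise maximum-likelihood distances under JTT: t maximising
Σ log(π_a P_ab(t)) per ungapped column pair, bounded scalar optimisation
to 1e-6, capped at 10 substitutions/site for saturated pairs. P(t) comes
from a cached spectral decomposition of the reversible rate matrix
(exchangeabilities and frequencies as distributed in the published JTT
model files), scaled to one expected substitution per unit t. Trees:
classical neighbor joining (Studier–Keppler criterion), deterministic
label-order tie-breaks, negative branch lengths clamped to zero. NJ on
JTT ML distances is the deliberate desk-scale substitute for a full ML
heuristic topology search; it is exact on additive matrices and
sufficient for the two-group split that constitutes the analysis claim.
Bootstrap: site resampling, NJ per replicate, supports as the percentage
of replicates containing each internal bipartition of the reference tree.
Multiple-alignment construction is reference-anchored stacking of
pairwise alignments (insertions relative to the reference dropped), with
a user-supplied aligned FASTA overriding; gap/X columns are deleted
pairwise, not listwise, because the C-terminal domain is highly variable.

## Motif discovery

ZOOPS (zero-or-one occurrence per sequence) EM over width × 20
letter-probability matrices, 0-order background estimated from the input,
pseudocount 0.01 per cell, occurrence prior fitted per motif. Seeds are
subsequence windows chosen by a match-coverage heuristic over a sampled
pool (the cheap stand-in for trying every subsequence); widths are
searched on a step-2 grid with ±1 refinement; motifs are selected by a
BIC-penalised log-likelihood ratio (substituting the E-value statistic
this package does not implement), then their sites are masked and
discovery repeats, up to `nmotifs` (default 15, widths 6–50, mirroring
the original analysis settings).

Because the M-step uses pseudocounts, the monotone EM objective is the
data LLR plus the Dirichlet log-prior; it is asserted non-decreasing at
every iteration.

Two numerical choices deserve emphasis:

* **Reporting floor.** ZOOPS EM run on pure uniform noise still converges
  to spurious alignments of about 1.5–1.7 bits/column at typical sizes
  (tens of sequences, ~100 residues). The reporting floor of 2.0
  bits/column was set from that null calibration; it is a parameter, not
  a law, and should be lowered for genuinely degenerate motifs. The floor
  is evaluated on the raw EM matrix, before purification (below), which
  would otherwise concentrate even a noise alignment into a sharp matrix.
* **Site purification.** On datasets of homologous clades, ZOOPS EM can
  converge to a *blended* matrix whose columns mix two unrelated site
  families (one per clade), because absorbing every sequence's best
  window raises the total likelihood. After convergence, sites sharing
  fewer than half their letters with the top-scoring site are dropped and
  the matrix is refit from the dominant family. Motifs genuinely shared
  by all sequences are unaffected.

Scanning uses total log-odds against the background with a default
threshold of 0.75 × the maximum achievable score; the presence table
marks a sequence/motif cell when at least one non-overlapping occurrence
clears the threshold.

## Statistics

Two-sided pooled-variance Student's t (Welch by flag), preceded by
Shapiro–Wilk per group and Levene across groups at α = 0.05; violations
are flagged, never acted on, and no multiple-testing correction is
applied — both choices mirror the analysis being reproduced. The
statistical routines are scipy's; the module contract (report fields,
assumption flags) is this package's.

## Problem sizes

The test suite and the acceptance script run at desk scale: 200 random
scaffolds for triad/classification recovery, 50 mutated copies for the
alignment route, 10^4 sites for distance calibration, 20–50 random 5–12
taxon trees for NJ exactness, a 30-sequence planted-motif experiment,
a 10-sequence two-group dataset with 100 bootstrap replicates, and
1000–2000 null datasets for t-test calibration. The original dataset-level
tree (hundreds of sequences, thousands of alignment columns) is out of
scope: without the original accession set and the ML heuristic search it
is not reproducible, and the two-group property experiments above stand
in for it.

## Known limitations

* The generator's uniform background and frozen classification context
  make recovery rates upper bounds on real-data performance.
* Reference-anchored stacking is not a true multiple alignment; for
  datasets with long insertions a user-supplied MSA is preferable.
* The penalised-LLR motif score is not calibrated as a p-value; motif
  *numbering* is dataset-dependent and not comparable across runs.
* pI, molecular weight and instability reproduce the ProtParam
  conventions; other pKa sets or monoisotopic masses are out of scope.
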