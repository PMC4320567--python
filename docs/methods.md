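# Methods

This note documents the models, rules, and numerical choices behind each
stage, the defaults and why they were chosen, what the synthetic data does
and does not emulate, and the known limitations.

## ORF calling

An open reading frame is a *maximal stop-free region of one reading frame*,
bounded by in-frame stop codons or by the sequence ends — deliberately with
no start-codon requirement, since the downstream domain filter (not coding
statistics) decides what is a gene.  All six frames are scanned; the length
test is strict (`nt_length > 150`).  Coordinates are reported 0-based
half-open on the forward strand for both strands; intervals at sequence ends
include any partial trailing codon (which cannot contain a stop), and
translation drops it.  Codons containing N translate to X and are never
treated as stops.  The genetic code defaults to the bacterial/archaeal
table 11 (the study organisms are Bacteria and Archaea) and is configurable.
Replicons are treated as linear; ORFs spanning the origin of a circular
chromosome are not modelled.  Such an ORF would be split into two
sub-threshold pieces only if both fragments were short — a marginal loss
given the 150 bp threshold.

## Domain annotation

HMMER3 `--domtblout` rows are parsed positionally (22 whitespace-delimited
fields plus a verbatim description).  The E-value filter applies to the
**full-sequence** E-value with an inclusive boundary (≤ 10⁻⁵): the original
workflow description does not distinguish full-sequence from per-domain
conditional E-values, and the full-sequence value is hmmscan's headline
statistic.
The diagnostic catalog is the set of distinct pfams among hits to the curated
reference alkane hydroxylases minus a shipped exclusion list of seven
families with regulatory or electron-carrier-binding roles, leaving nine
diagnostic families.  The curated reference set itself is shipped as a fixture
list (the original curation was a manual protein-name search, which is not
reproducible computation).  Multiple hits of the same pfam on one ORF
collapse to one candidate — genes are counted, not domains — while one ORF
hitting two diagnostic pfams yields two candidates under their respective
families.

## Family assembly and trimming

Alignment itself is delegated to an external aligner (the config records a
three-iteration Clustal Omega template); tests and fixtures use pre-aligned
input.  Reference families larger than 5,000 sequences are uniformly
subsampled to 5,000, reproducibly under a seed.  The trim window runs from
the *latest* first-residue column to the *earliest* end column over the
reference ("uniprot") rows; trimming to it and re-trimming is a fixed point.
The original "minimum length guideline" after trimming is not numerically
specified anywhere we could follow, so it is implemented scale-free: a row
is dropped when its non-gap residue count inside the window falls below a
configurable fraction (default 0.66) of the window width.  Reference rows
are never dropped, since the window is defined by them.

## Kimura distances, NMDS, clusters

Observed difference fractions *p* are computed with pairwise gap deletion
(columns gapped in either row are excluded for that pair only).  The Kimura
correction d = −ln(1 − p − 0.2 p²) diverges at p ≈ 0.8541; such pairs are
capped at a configurable d_max = 10.0 with a warning rather than erroring,
keeping matrices complete for embedding.  Saturated pairs are exactly what
distinct clusters on an NMDS plot look like, so capping does not distort the
downstream cluster reading.

NMDS minimizes Kruskal stress-1 by SMACOF majorization with isotonic
(monotone) regression of configuration distances on dissimilarity ranks,
best of 4 random starts by default, reproducible under a seed.  The
dimension rule is 3 below 3,000 sequences, 4 from 3,000 to 6,000 inclusive,
5 above — boundaries read inclusive into the middle band.  Reported stress
is recomputed from the final coordinates.

The outlier rule formalizes "far from the majority of points in the 2-D
plot": a point is culled when its Euclidean distance from the coordinate-wise
median of dimensions 1–2 exceeds 6 × the median absolute deviation of those
distances; re-embedding after culling is an orchestration step.  Cluster
selection uses user-supplied axis-aligned boxes on dimensions 1–2 with
closed-interval containment (the original selection was graphical);
selections lacking a reference member are flagged not-candidate.

Embedding validation regresses **ln(2-D Euclidean embedding distance)** on
the other pair metric: identity predictor for patristic tree distance
("log-linear") and log predictor for reciprocal bit score ("log-log").  The
description of the original fits does not say which axis carries the log in
the log-linear form; logging the response was chosen because embedding
distances are the common variable of both fits, and both forms are
selectable.  Pairs with non-positive values entering a log are excluded and
counted; at most 10,000 randomly selected pairs are fit.  Patristic
distances come from summed branch lengths via the tree's path metric;
reciprocal search rows are averaged per unordered pair.

## Protein parameters

All windowed profiles are uniform arithmetic means over a 9-residue window
centered on each position (centers w//2+1 … L−w//2, 1-based).  Flexibility
uses the Vihinen normalized scale with the uniform mean; the center-weighted
scheme of some implementations is noted but the uniform mean is the
documented procedure here (a weighting hook is the natural extension point).
Whole-protein flexibility is the mean of the windowed profile; GRAVY,
aromaticity, and aliphatic index are computed from full composition.
Unknown residues (X) carry no scale value: they are excluded from window
means (reduced denominator) and from composition denominators.

The aliphatic index follows Ikai: AI = X(Ala) + 2.9·X(Val) +
3.9·(X(Ile)+X(Leu)) in mole percent.  The isoelectric point solves net
charge = 0 under a Henderson–Hasselbalch model (N-terminus, C-terminus, and
D/E/C/Y/H/K/R side chains) by bisection on pH ∈ [0, 14] to |charge| < 10⁻⁴;
the pKa table defaults to the Bjellqvist values with the EMBOSS set
selectable, since no table is canonical for this analysis.

## Group comparisons

PSIPRED `.ss2` files are read vertically; the per-residue label is the
maximum-probability state with tie precedence C > H > E (coil as the
unstructured default).  Each windowed value is assigned to the region of its
*center* residue.  "Wilcox test" is implemented as the two-sided
Mann–Whitney U on independent value pools: exact permutation distribution
when both samples have ≤ 8 observations and no ties, otherwise the
tie-corrected normal approximation with continuity correction.
Holm-Bonferroni is the step-down max–min formula, applied by convention to
all parameters × regions within one pfam (the correction family is
configurable, as the original one is not defined).  A contrast is
*significant* when the corrected p < α (default 0.05) and *trending* when
the raw p < α but the corrected one is not.  Taxon-pair contrasts compare
every psychrophile candidate against every mesophile candidate within a
pair (cross-product, summed over pairs), counting strict "psychrophile
higher" outcomes; ties count as not-higher.  Applied to the published
per-strain count table this rule reproduces 11 possible comparisons for the
AlmA-family pairs and 4 for the AlkB-family pair; for the p450 family it
gives 10 where the published total reads 9 — the published tables do not
reconcile on that cell under any pairing rule we could construct, so the
pooled rule stands and the discrepancy is documented here.  The published
psychrophile candidate inventory likewise appears once as 26 and once as 27;
the per-strain table sums to 27, and aggregation targets the
table-consistent value.

## Flexibility deviation sites

Profiles are projected onto the family alignment by non-gap rank: the value
at residue i lands in the column holding the row's i-th non-gap character.
Per column, group means and **sample** (n−1) standard deviations are
computed over present values (population SD selectable); columns where
either group has fewer than 2 values are skipped — the analogue of
alignment gaps preventing the calculation.  A column is flagged when
|Δmean| strictly exceeds σ₍psy₎ + σ₍meso₎, with direction from the sign of
Δ.  Summaries report directional flag counts and Δ sums over all and over
flagged columns.  Flagged columns can be mapped to a representative
protein's residue numbering for downstream structural inspection; columns
gapped in the representative are dropped and counted.  3-D modelling and
rendering are out of scope; the per-residue flag export replaces them.

## Synthetic data

The generators emulate the *structure* of the study inputs, not their
biology: ancestors are drawn from a uniform residue background (empirical
frequencies pluggable), descendants substitute independently per site, and
reference rows are low-divergence copies of the ancestor so trim windows
stay defined.  Flexibility windows are planted by mixing substitutions from
the top/bottom quintiles of the Vihinen scale (donor pools of 4 residues
each, means ≈ 0.165 apart) with the background at a mixing probability
offset/0.165 — so requested offsets above 0.165 are rejected as
unattainable, and realized offsets match targets within Monte-Carlo error
(≈ 5% relative at offset 0.03 over 20 replicates).  Genomes are built by
uniform synonymous reverse translation (table 11) with each CDS flanked by
in-frame stops and separated by stop-motif-salted spacers, making every
planted CDS a maximal stop-free region.  Random additive trees accumulate
their patristic matrices during construction, so additivity holds by
construction.  Tool-output writers emit syntactically valid domtblout
(E-values straddling 10⁻⁵), ss2 with certainty-one probabilities, and
reciprocal bit-score tables as a monotone transform of planted distances.

What passing tests on this material does **not** show: robustness to real
alignment error, phylogenetic correlation between sequences (descendants are
star-shaped around the ancestor), realistic codon usage or amino-acid
frequencies, PSIPRED prediction error, or hmmscan score behaviour — those
belong to the external tools this pipeline consumes.

## Problem sizes and numerical choices

Default analysis sizes in tests and the acceptance script are chosen to
exercise every code path at desk scale: families of 10 sequences per group
and 120–150 residues, 20 replicate families for recovery rates, trees up to
32 tips, NMDS on tens of points with 4–8 restarts.  The statistic
implementations themselves are vectorized and scale to the thousands of
sequences the dimension rule anticipates.  Degenerate inputs fail loudly:
empty sequences, sub-codon translation input, all-gap distance pairs,
disjoint reference spans, missing branch lengths, and out-of-range p-values
all raise typed errors; saturated Kimura pairs and dropped non-reference row
sets warn instead, because the enclosing computation remains well defined.

## Known limitations

- Circular replicons are treated as linear (origin-spanning ORFs split).
- The NMDS embedding, like the original, is stochastic in its
  initialization; all randomness flows from explicit seeds and the manifest
  records them, but different seeds can reach different local minima on
  hard matrices.
- Cluster boxes are configuration, faithfully mirroring a graphical
  selection step; the density-mode convenience fitter is not a substitute
  for inspection.
- The published R² values for the embedding validation depend on a 2014
  PFAM snapshot and full-size families; the validation machinery is
  implemented and tested on synthetic monotone/null fixtures instead.
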