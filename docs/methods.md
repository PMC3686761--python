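# Methods

## The scan

`psgscan` tests, gene by gene, whether a designated (foreground) lineage has
experienced episodic positive selection at a subset of codon sites. The unit
of analysis is an ortholog group: single-copy 1:1 orthologs of one gene
across a variable set of species. Each group is tested independently with
its own species tree (pruned from one master topology), because each group
has its own species composition. Two foreground hypotheses (e.g. the dolphin
and the cow terminal branches) can be run over the same groups, sharing all
per-gene preprocessing; the genes significant for one foreground and not the
other form that lineage's exclusive positively-selected-gene (PSG) set.

## Group selection ("non-exact search")

A group is retained when (i) it contains every *required* species, and
(ii) after restricting members to an *allowed taxon* (e.g. mammals) it still
has at least `min_species` members. Members outside the allowed taxon are
dropped from retained groups and logged. The filter is idempotent, and
tightening either constraint can only shrink the kept set — both properties
are enforced by tests.

## Codon alignment assembly

Aligned proteins are an input (the package does not align); the codon
alignment is their exact back-translation: each residue is replaced by its
source codon, each gap by `---`. One terminal stop codon is stripped before
the 3x-length check; internal stops and codon/residue conflicts are hard
errors. Sequences are uppercased and U is mapped to T. IUPAC ambiguity codes
are *retained* and treated as missing data in the likelihood (the partial
likelihood is 1 over all compatible sense codons) rather than deleting the
column; degapping any output row reproduces the input CDS byte for byte.

## The codon model

The substitution process is the Goldman–Yang Markov process on the 61 sense
codons of the standard genetic code. For codons i, j differing at exactly
one position,

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous],

zero for multi-position changes, diagonal fixed by rows summing to zero.
Equilibrium frequencies pi default to F3x4 — products of position-specific
nucleotide frequencies counted over non-gap, unambiguous cells, normalized
over sense codons; codons containing a never-observed base get frequency 0
and are excluded from the state space (uniform and F1x4-style inputs can be
supplied instead). The process is time-reversible, so likelihoods are
invariant to root placement; trees are handled as rooted structures but the
rooting carries no signal.

Branch-site model A adds four latent site classes with proportions
(p0, p1, p2a, p2b), where p2a = (1-p0-p1) p0/(p0+p1) and analogously p2b:

| class | background omega | foreground omega |
|-------|------------------|------------------|
| 0     | omega0 (<= 1)    | omega0           |
| 1     | 1                | 1                |
| 2a    | omega0           | omega2 (>= 1)    |
| 2b    | 1                | omega2           |

The null model fixes omega2 = 1; the alternative estimates it in [1, inf).

**Rate scaling.** One scale factor per parameter vector divides the
generator so that the *background mixture's* expected substitution rate is
1; branch lengths are therefore expected substitutions per codon and remain
comparable between the null and alternative fits. The same scale is applied
to the foreground branch.

## Likelihood and optimization

Site likelihoods are computed by Felsenstein pruning over compressed site
patterns with per-node rescaling. Because the four classes differ only on
the single foreground branch, the tree is pruned once for the two
background regimes (omega0 and 1) and only the nodes on the path from the
foreground branch to the root are recomputed for classes 2a/2b — an exact
factorization, verified against brute-force summation over internal-node
state assignments on 3- and 4-taxon trees (|delta log-likelihood| < 1e-8
over 100 randomized instances).

Transition matrices use the symmetric eigendecomposition available for
reversible generators (D^1/2 Q D^-1/2), one decomposition per omega value
per likelihood evaluation, shared across branches.

Fitting maximizes over (kappa, omega0, p0, p1[, omega2]) with L-BFGS-B on
transformed coordinates: log kappa, logit omega0, a softmax chart for
(p0, p1), and log(omega2 - 1) bounded below so the boundary omega2 -> 1 is
numerically reachable. Following the multi-start protocol, three starting
omega values (0.5, 1, 2) seed each fit — the start value caps omega0 below
1 and floors omega2 above 1 — and the run with the best log-likelihood is
kept, ties broken by start order. The alternative fit additionally starts
from the null solution, which guarantees the nesting inequality up to
optimizer noise. Convergence tolerance is ~1e-8 on the log-likelihood.

**Branch lengths** are estimated once per gene under the one-ratio (M0)
model — single omega, all branch lengths and kappa free — and held fixed in
both branch-site fits. This mirrors common practice and keeps the per-gene
optimization low-dimensional. In simulation studies where the generating
tree's lengths are known, fits may be run directly on those lengths; the
full M0-then-branch-site path is exercised by the pipeline tests and the
planted-truth scan.

## The LRT

The test statistic is max(0, 2(lnL_alt - lnL_null)), referred to
chi-squared with one degree of freedom; a gene is a PSG when p < 0.05.
Because omega2 = 1 lies on the boundary of the alternative's parameter
space, the chi2(1) reference is conservative; the boundary-respecting 50:50
{0, chi2(1)} mixture is available via `null_distribution="mixture"` but the
default decision rule is plain chi2(1). No cross-gene multiple-testing
correction is applied to the headline counts; the per-gene p-values in the
output table support any correction downstream.

## Enrichment

PSG lists are characterized two ways. Slim mapping counts, per high-level
GO term, the genes with at least one annotation equal to it or below it via
is_a edges (part_of traversal is optional). Overrepresentation is a
one-sided binomial test of the PSG set against the reference of all
analyzed genes: with q = |PSG|/|reference|, a category with n annotated
reference genes and k annotated PSGs gets p = P(Bin(n, q) >= k); expected
count is n*q. Unannotated genes stay in both denominators (whole-list
fractions). Bonferroni multiplies by the number of categories with >= 1
annotated reference gene (recorded in the output header), capped at 1;
significance is p_corrected < 0.05.

## Synthetic data

The generators provide every input with known ground truth:

- **Codon alignments** are evolved exactly under the branch-site process:
  per site a class is drawn from (p0, p1, p2a, p2b), the root codon from
  pi, and each branch's child codon directly from the class- and
  branch-appropriate P(t) (no event-by-event simulation). The manifest
  records seed, parameters, tree and per-site class labels; replaying the
  seed reproduces the alignment byte for byte.
- **Group collections** draw each group's species as the required set plus
  a random subset of the pool, with per-group ancestral CDS of sense codons
  and per-species random codon substitutions (rate 0.05), so proteins are
  translations of their CDS and rows align without gaps.
- **Annotation tables** annotate each gene to each category independently
  at a baseline rate and raise a gene's PSG probability by the planted fold
  when it carries a planted category.

What the generators do *not* emulate: indels and alignment error,
sequencing error, among-gene tree-topology error, codon usage bias beyond
F3x4, and correlated annotations. Passing tests therefore demonstrate
correctness and statistical calibration of the method under its own model,
not robustness to real-data misspecification.

## Study conditions and problem sizes

Simulation studies in the tests and the acceptance script use desk-scale
conditions chosen once: 8–10 taxa, 150–500 codons, foreground terminal
branch 0.3 expected substitutions per codon (a realistic, detectable
mammalian terminal-branch length; much shorter branches carry too few
events for any method), background omega0 0.1–0.15, kappa 2, p2a+p2b ≈ 0.1,
and omega2 = 5–8 for selection regimes. Null calibration uses 36–60
replicates at 200 codons; power uses 10–12 replicates at 500 codons; the
planted-truth scan runs 10 groups of 500 codons through the full pipeline
(M0 branch lengths, three-start fits). These stand in for the genome-scale
setting of thousands of groups over ~30 mammals.

## Numerical choices and degenerate inputs

- Pattern compression before pruning; per-node rescaling in likelihood.
- P(t) entries are clipped at 0 after eigen-reconstruction (spurious ~1e-17
  negatives).
- Zero-frequency codons (F3x4 artifacts) shrink the state space; observing
  such a codon at a leaf is an error.
- Optimizer failures on a start are recorded per start; a gene errors only
  when every start fails. Pipeline-level failures mark the gene's row
  (`failed:...`/`skipped:...`) and never abort the scan.
- Groups with fewer than 3 species, or missing a foreground species, are
  skipped and flagged.
- Ties in the multi-start protocol resolve to the earliest start; group
  iteration order is input order; all generators are pure functions of
  (arguments, seed).

## Known limitations

- Branch lengths fixed at M0 estimates (not re-estimated under the
  branch-site models); joint estimation would be slower and is not exposed.
- No Bayes-empirical-Bayes identification of the selected sites; inference
  is gene-level only.
- Standard genetic code only.
- The binomial enrichment test, like its database implementations, treats
  genes as exchangeable; gene-length or annotation-bias corrections are out
  of scope.
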