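# Methods

This note records the models, conventions and numerical choices behind
`thermofold`, and what the synthetic fixtures do and do not establish
about behavior on real structures.

## Atomic model

PDB text is parsed (via gemmi) into a minimal chain → residue → atom
hierarchy. Only the first model of multi-model (NMR) files is kept.
Alternate locations are resolved per atom name to the highest-occupancy
conformer, ties going to altloc `A`. HETATM records are dropped except
selenomethionine, which is mapped to Met with SE renamed SD — it is
chemically a methionine for every feature computed here. Residues other
than the twenty standard amino acids are retained for geometry but carry
the code `X` and are excluded from composition, accessibility statistics
and interaction chemistry.

**Protein length** is the number of standard residues with at least one
resolved atom in the analyzed chain(s). Structure-derived features exist
only for resolved residues, so resolved count — not SEQRES length — is
the normalizer for per-residue rates and composition frequencies. For
multi-chain entries the analyzed chain is the one named in the manifest,
defaulting to the first protein chain.

## Interaction detection

All criteria are purely geometric on heavy atoms; cutoffs are inclusive
(≤) except the aromatic window, which is a closed interval. Defaults:

| category | criterion | cutoff |
|---|---|---|
| ionic (salt bridge) | Lys NZ, Arg NE/NH1/NH2, His ND1/NE2 vs Asp OD1/OD2, Glu OE1/OE2 | 6.0 Å |
| aromatic–aromatic | ring-centroid distance (Phe/Tyr/Trp; Trp six-ring) | 4.5–7.0 Å |
| aromatic–sulfur | Cys SG / Met SD to ring centroid | 5.3 Å |
| cation–π | Lys NZ / Arg CZ to ring centroid | 6.0 Å |
| disulfide | Cys SG–SG | 2.5 Å |
| hydrophobic | side-chain C–C between {A,V,L,I,M,F,W,P,Y} residues | 5.0 Å |
| hydrogen bond | donor/acceptor N/O heavy-atom distance | 3.5 Å |

Choices worth stating:

- **His is counted as cationic** for salt bridges (protonation state is
  unknowable from coordinates) but is excluded from the π-ring set, which
  is Phe/Tyr/Trp only.
- **Ionic and hydrophobic interactions are counted once per residue
  pair** at the minimal atom distance; hydrogen bonds are counted per
  donor–acceptor atom pair (deduplicated as unordered pairs), since one
  residue pair can form several chemically distinct bonds.
- **Salt bridges are not double-counted as hydrogen bonds.** An N/O pair
  that satisfies the ionic criterion is classified ionic only. A
  distance-only H-bond definition would otherwise relabel every
  short salt bridge as an SC–SC bond; classifying the charged–charged
  contact as ionic keeps the categories disjoint.
- **Sequence separation** ≥ 2 (author residue numbering; unlimited
  across chains) is required for side-chain categories and MC–MC bonds,
  excluding trivially covalent i, i+1 contacts. Disulfides are exempt:
  an i, i+1 disulfide is real chemistry.
- The hydrogen-bond criterion is distance-only on donor/acceptor heavy
  atoms because crystallographic structures usually lack hydrogens; no
  angle term is applied. The hydrogen-bond, disulfide and hydrophobic
  cutoffs (3.5 / 2.5 / 5.0 Å) are package defaults exposed in
  `InteractionConfig`; the ionic, aromatic, aromatic–sulfur and cation–π
  cutoffs follow the values standard in the comparative-thermostability
  literature.
- An independently written salt-bridge counter may differ by a few
  contacts near the cutoff from other tools' published counts; boundary
  behavior here is documented (inclusive) and tested.

## Residue environment

**SASA.** Shrake–Rupley with probe radius 1.4 Å, van der Waals radii
C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, Se 1.90 Å (configurable; unknown
elements fall back to 1.70 Å with a warning). The sphere quadrature uses
a deterministic Fibonacci point set — no RNG anywhere in the geometry
stack — with 960 points per atom by default (isolated-sphere error well
under 1 %; per-residue values converge to < 0.5 Å² per doubling from
1920 points). The study pipeline uses 480 points for throughput; the
difference is ~1 Å² per residue, far below the 9 %/36 % class widths.

**Relative accessibility** is `A_i = SASA_i / maxASA(type_i)` with the
Tien et al. (2013) theoretical maximum scale as default (Miller 1987 is
packaged as an alternative; the scale is pluggable because published
analyses differ in this choice). Values above 1 occur in extended
conformations and are not clipped. Classes: buried `A_i < 0.09`,
intermediate `0.09 ≤ A_i ≤ 0.36`, exposed `A_i > 0.36`.

**Secondary structure.** Kabsch–Sander hydrogen-bond assignment: the
amide hydrogen is placed 1 Å from N along the preceding carbonyl O→C
direction, the bond energy is
`E = 0.084 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol, and a
bond exists when `E < −0.5`. Helices come from consecutive n-turns
(4 → H, 3 → G, 5 → I), strands from bridge patterns (ladder → E,
isolated → B), with turns (T) and bends (S, Cα virtual angle > 70°)
otherwise, priority H > E > B > G > I > T > S. The full DSSP
ladder/sheet bookkeeping is deliberately not reproduced — only what the
three-class reduction needs. The blank (coil) state reduces to loop, as
do T and S. Chains shorter than four residues are left unassigned.
Classic fixed-column DSSP output files can be ingested verbatim, in
which case relative accessibility is recomputed from the ACC column with
the same max-ASA scale.

## Group statistics

Per-protein samples enter an unpaired two-tailed t-test per feature.
Welch's unequal-variance form is the default (the common default of
modern statistical software); the pooled-variance form is a flag. No
multiple-testing correction is applied by default, matching the raw
p < 0.05 convention of comparative-thermostability studies; a
Benjamini–Hochberg option exists. Zero-variance degeneracies: equal
means → p = 1; unequal means → p = 0 with a warning. Features absent
from every structure get p = 1 and a flag rather than NaN.

Aggregation is per-protein by default. A family-averaged mode (profiles
averaged within enzyme family before testing) is provided because both
conventions appear in the literature; with the small per-family counts
of realistic datasets it leaves very few degrees of freedom, which is
why it is not the default.

Environment-preference screens test, for each focus amino acid and each
class, the per-protein fraction of that amino acid's residues in the
class; proteins lacking the amino acid are omitted from that row's
sample and the per-row n is reported.

## Pair superposition and tallies

The Kabsch fit is the closed-form SVD solution with the determinant
correction forcing a proper rotation. Equivalences are seeded either
from a supplied aligned FASTA or from a global BLOSUM62 alignment
(gap open 10, extend 0.5), then refined: superpose on current pairs,
re-pair mutually nearest Cα within 3.5 Å (ties broken by sequence
order), repeat to convergence or 20 iterations, accepting a refinement
only if it does not worsen the RMSD. Identity uses aligned (non-gap)
pairs as denominator; the gap count is the number of residues of either
structure left unpaired. Fewer than 30 surviving pairs is an alignment
failure, not a result. This aligner is a deliberate substitute for
combinatorial-extension structural alignment: on closely related pairs
(identity ≳ 30 %, RMSD ≲ 1.5 Å) the seeded-plus-refined procedure finds
essentially the same equivalence set; alignment Z-scores are out of
scope.

Substitution tallies map the partner amino acid at each aligned
focus-position to one of eight exhaustive, disjoint classes: polar
{S,T,N,Q}, aromatic {F,W,Y,H}, hydrophobic {A,V,L,I,M}, acidic {D,E},
basic {K,R}, proline, cysteine, glycine. Proline, glycine and cysteine
stay separate because of their special structural roles (helix breaking,
flexibility, disulfide formation). His sits with the aromatics — each
amino acid gets exactly one slot, and the mapping is overridable. The
invariant `Σ counts + conserved + unaligned = occurrences` is enforced
when the caller supplies the source occurrence total.

## Phylogeny

Distances are maximum-likelihood branch lengths under the JTT empirical
model: the packaged published exchangeabilities and equilibrium
frequencies (`data/jtt.dat`) are assembled into a reversible rate matrix
scaled to one expected substitution per site, eigendecomposed through
the symmetrized form `diag(√π) Q diag(1/√π)` for numerical stability,
and `−Σ n_ab log(π_a P_ab(t))` is minimized by bounded scalar search on
t ∈ [10⁻⁶, 10] with tolerance 10⁻⁸. Gap-containing columns are skipped
(pairwise deletion); no rate heterogeneity is modelled. Symmetrizing
the pair-count matrix makes the estimate exactly direction-independent.
An optimum at the upper bound is capped with a warning — at such
distances the alignment carries no usable signal anyway.

Neighbor joining is the canonical Saitou–Nei algorithm. Negative branch
lengths are clamped to zero with the deficit moved to the sibling
branch, preserving every leaf-to-leaf path length. Trees serialize to
newick (scikit-bio `TreeNode` is the container). The "closest
thermophile–mesophile pair" is defined by patristic distance on the NJ
tree — not by the raw distance matrix — because pair selection is a
tree-reading step; ties break lexicographically.

## Study pipeline

Strata are nested groupings of one manifest: the whole enzyme group, two
catalytic mechanisms (retaining = (α/β)₈ + β-jelly roll; inverting =
(α/α)₆), and the three folds. A stratum missing two structures in
either group is skipped with an explicit warning; tiny-but-valid strata
(n = 2 per group) still run, with n reported per stratum. Because the
inverting mechanism contains exactly the (α/α)₆ fold, those two strata
are the same protein sets and the pipeline must produce identical tables
for them — this is asserted, not assumed. Reports are plain delimited
text plus a JSON summary with full provenance (config, version, seed).

## Synthetic data: what it emulates, and what it does not

The generators produce: residues with idealized covalent geometry and a
single canonical rotamer, placed on a coarse grid so the only contacts
are planted ones; planted interactions tuned to their target defining
distance within 0.05 Å and verified against the package's own detectors
before the fixture is returned (generation fails loudly otherwise);
ideal helices and numerically registered antiparallel glycine strand
pairs; multinomial composition cohorts (default 17 vs 13 proteins of
400 residues, matching the packaged dataset's shape) with additive
effect shifts and Gaussian jitter (σ = 0.005); and homologous structure
sets sharing a backbone with per-member substitutions, rigid moves and
isotropic coordinate noise (σ = 0.2 Å for pair fixtures).

These fixtures establish correctness of the geometry, the statistics
and the plumbing: that detectors implement their stated criteria
exactly, that the estimators match independent oracles, that planted
effects are recovered at the expected rates. They do not establish
anything about crystallographic reality — no alternate conformers, no
missing atoms beyond what tests construct, no realistic packing density
(real proteins have orders of magnitude more hydrophobic contacts and
hydrogen bonds per residue), and no evolutionary correlation structure
in the cohorts. Conclusions about real thermophile/mesophile datasets
therefore rest on the real structures, which the pipeline consumes
through exactly the code paths the fixtures exercise.

## Problem sizes used in checks

The packaged checks run: 13 planted-interaction specs; 100 random
10-point clouds for superposition; 100 random small samples for the
t-test oracle; 1000 null-cohort replicates (type-I error) and 200
planted-effect replicates (power) at n = 8 + 8; a 100-column alignment
pair against a step-10⁻⁴ likelihood grid; and a 12-structure,
three-fold synthetic study for the stratum-equivalence property.
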