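# thermofold

Fold-stratified structural comparison of thermophilic and mesophilic
endoglucanases (EC 3.2.1.4), for structural bioinformaticians studying
what makes a cellulose-degrading enzyme keep working at high temperature.

Endoglucanases adopt three unrelated folds — the (α/β)₈ TIM barrel, the
β-jelly roll and the (α/α)₆ toroid — and the sequence features that
correlate with thermostability differ between folds. This package
implements the full comparative pipeline needed to ask that question of a
set of PDB structures:

- **Interaction detection.** Nine geometric categories per structure:
  salt bridges (cationic side-chain N to anionic side-chain O ≤ 6 Å),
  aromatic–aromatic pairs (ring-centroid distance in [4.5, 7] Å),
  aromatic–sulfur (≤ 5.3 Å), cation–π (≤ 6 Å), disulfides (S–S ≤ 2.5 Å),
  hydrophobic contacts, and hydrogen bonds split into main-chain/side-chain
  membership classes (MC–MC, MC–SC, SC–SC). Counts are normalized per
  residue: `n_c / L` for category *c* and protein length *L*.
- **Residue environment.** Solvent-accessible surface area by a
  deterministic Shrake–Rupley quadrature; relative accessibility
  `A_i = SASA_i / maxASA(aa_i)` classified buried (< 9 %), intermediate
  (9–36 %) or exposed (> 36 %); Kabsch–Sander secondary structure reduced
  to three classes (H/G/I → helix, E/B → sheet, rest → loop). Precomputed
  DSSP output files can be ingested instead.
- **Composition statistics.** Length-normalized amino-acid frequencies,
  per-residue interaction rates and per-amino-acid environment-class
  fractions compared between groups with an unpaired two-tailed Welch
  t-test at α = 0.05; the enriched group is the one with the larger mean.
- **Pair superposition.** Sequence-alignment-seeded Kabsch superposition
  with iterative nearest-Cα re-pairing (3.5 Å), reporting RMSD, identity
  and aligned/gap counts; substitutions at structurally equivalent
  positions of a focus amino acid tallied into eight chemical classes
  (polar, aromatic, hydrophobic, acidic, basic, and proline / cysteine /
  glycine kept separate).
- **Phylogeny.** Pairwise maximum-likelihood distances under the
  Jones–Taylor–Thornton model (`t̂ = argmax_t Σ_sites log π(a) P(a→b; t)`),
  Saitou–Nei neighbor joining, and selection of the closest
  thermophile–mesophile leaf pair by patristic distance.
- **Synthetic data.** Generators for PDB files with planted interactions
  at exact distances, ideal helix/sheet geometry, composition cohorts with
  planted effect sizes, and homologous structure pairs — every stage of
  the pipeline is testable without downloading anything.

The packaged manifest (`thermofold/data/endoglucanase_manifest.tsv`)
lists the 30 endoglucanase PDB entries of the study dataset — 17
thermophiles and 13 mesophiles across the three folds — with
thermophile/mesophile labels assigned by source-organism optimum growth
temperature (above/below 40 °C).

## Worked example

Screen a simulated cohort (8 thermophiles vs 8 mesophiles, planted +0.03
Arg frequency shift) and compare a structure pair:

```python
from thermofold import significance_screen, align_pair, parse_structure, tally_substitutions
from thermofold.synthetic import CohortSpec, make_cohort, make_paired_structures

thermo, meso, truth = make_cohort(CohortSpec(n_thermo=8, n_meso=8,
                                             effects={"R": 0.03}, seed=5))
table = significance_screen(thermo, meso)
print(table[table.significant][["feature", "mean_thermo", "mean_meso",
                                "p_value", "enriched_in"]])
#  feature  mean_thermo  mean_meso   p_value  enriched_in
#        R     0.078461   0.040242  0.000361  thermophile

pdb_a, pdb_b, _ = make_paired_structures(base_sequence="ARAG" * 15,
                                         noise_sd=0.1, seed=9,
                                         class_substitutions={"R": ["S", "T", "N", "Q"]})
pa = align_pair(parse_structure(pdb_a, "a"), parse_structure(pdb_b, "b"))
print(round(pa.rmsd, 2), pa.identity_pct)   # 0.18 93.33...
print(tally_substitutions(pa, "R").counts["polar"])  # 4
```

The screen recovers the planted arginine enrichment (p = 3.6 × 10⁻⁴,
enriched in thermophiles) and nothing else beyond α-level noise; the
aligner recovers the rigid transform to 0.18 Å RMSD and the tally finds
exactly the four planted polar replacements.

The `examples/` directory holds one short script per capability;
`thermofold --help` exposes the same stages as CLI subcommands
(`interactions`, `environment`, `align-pair`, `tally`, `tree`, `compare`,
`run-all`, `simulate`).

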