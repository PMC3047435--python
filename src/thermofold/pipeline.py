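"""Study orchestration: manifest -> per-structure features -> stratified
significance screens -> pair superposition and substitution tallies ->
trees -> report tables.

Strata are three nested groupings of the same manifest: the whole enzyme
group, the two catalytic mechanisms (retaining = (a/b)8 + beta-jelly
folds, inverting = (a/a)6), and the three folds individually.  Whenever
the manifest's fold-to-mechanism map holds, the inverting-mechanism
stratum is by construction identical to the (a/a)6 stratum.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .compstats import (
    _FreqBag,
    environment_preference_screen,
    environment_profile,
    composition_profile,
    significance_grid,
    significance_screen,
)
from .environment import compute_environment, environment_table, DEFAULT_MAX_ASA_SCALE
from .interactions import InteractionConfig, interactions_table, summarize_interactions
from .phylo import (
    closest_cross_pair,
    distance_matrix_from_msa,
    neighbor_joining,
    read_fasta_alignment,
    serialize_newick,
)
from .structalign import align_pair, pair_table, tally_substitutions
from .structure_io import first_protein_chain, load_manifest, parse_structure

logger = logging.getLogger(__name__)

FOLD_TO_MECHANISM = {"(a/b)8": "retaining", "beta-jelly": "retaining",
                     "(a/a)6": "inverting"}
STRATIFICATIONS = ("enzyme_group", "mechanism", "fold")


@dataclass
class StudyConfig:
    manifest_path: str | None = None
    structures_dir: str = "."
    stratifications: tuple[str, ...] = STRATIFICATIONS
    alpha: float = 0.05
    interaction_config: InteractionConfig = field(default_factory=InteractionConfig)
    max_asa_scale: str = DEFAULT_MAX_ASA_SCALE
    t_test_variant: str = "welch"
    aggregation: str = "per_protein"
    msa_paths: dict[str, str] = field(default_factory=dict)  # fold -> aligned FASTA
    environment_points: int = 480
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not self.stratifications:
            raise ValueError("at least one stratification required")
        unknown = set(self.stratifications) - set(STRATIFICATIONS)
        if unknown:
            raise ValueError(f"unknown stratifications: {sorted(unknown)}")


@dataclass
class StudyReport:
    composition_tables: dict[str, pd.DataFrame]
    interaction_tables: dict[str, pd.DataFrame]
    environment_tables: dict[str, pd.DataFrame]
    composition_grid: pd.DataFrame
    interaction_grid: pd.DataFrame
    pair_summaries: pd.DataFrame
    tallies: pd.DataFrame
    trees: dict[str, str]
    cross_pairs: dict[str, tuple[str, str]]
    stratum_sizes: dict[str, tuple[int, int]]
    provenance: dict

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)

        def safe(name: str) -> str:
            return "".join(c if c.isalnum() or c in "-_." else "_" for c in name)

        for name, table in self.composition_tables.items():
            table.to_csv(out / f"composition_{safe(name)}.tsv", sep="\t", index=False)
        for name, table in self.interaction_tables.items():
            table.to_csv(out / f"interactions_{safe(name)}.tsv", sep="\t", index=False)
        for name, table in self.environment_tables.items():
            table.to_csv(out / f"environment_{safe(name)}.tsv", sep="\t", index=False)
        self.composition_grid.to_csv(out / "composition_grid.tsv", sep="\t")
        self.interaction_grid.to_csv(out / "interaction_grid.tsv", sep="\t")
        if len(self.pair_summaries):
            self.pair_summaries.to_csv(out / "pair_alignments.tsv", sep="\t", index=False)
        if len(self.tallies):
            self.tallies.to_csv(out / "substitution_tallies.tsv", sep="\t", index=False)
        for fold, nwk in self.trees.items():
            (out / f"tree_{safe(fold)}.nwk").write_text(nwk + "\n")
        (out / "summary.json").write_text(json.dumps({
            "stratum_sizes": {k: list(v) for k, v in self.stratum_sizes.items()},
            "cross_pairs": {k: list(v) for k, v in self.cross_pairs.items()},
            "provenance": self.provenance,
        }, indent=2))


def _strata(manifest: pd.DataFrame, which: tuple[str, ...]) -> dict[str, pd.DataFrame]:
    out: dict[str, pd.DataFrame] = {}
    if "enzyme_group" in which:
        out["enzyme_group"] = manifest
    if "mechanism" in which:
        mech = manifest["fold"].map(FOLD_TO_MECHANISM)
        for m in sorted(mech.dropna().unique()):
            out[f"mechanism:{m}"] = manifest[mech == m]
    if "fold" in which:
        for f in sorted(manifest["fold"].unique()):
            out[f"fold:{f}"] = manifest[manifest["fold"] == f]
    return out


def run_study(cfg: StudyConfig) -> StudyReport:
    """Run the full comparative analysis for a manifest of structures."""
    manifest = load_manifest(cfg.manifest_path)
    features: dict[str, dict] = {}
    for _, row in manifest.iterrows():
        pdb_id = row["pdb_id"]
        path = Path(cfg.structures_dir) / f"{pdb_id}.pdb"
        if not path.exists():
            raise FileNotFoundError(f"structure file missing for manifest entry: {path}")
        struct = parse_structure(path.read_text(), structure_id=pdb_id)
        chain = row.get("chain", "") or first_protein_chain(struct)
        if chain not in struct.chains:
            raise KeyError(f"{pdb_id}: manifest names chain {chain!r} not in structure")
        sub = parse_structure(path.read_text(), structure_id=pdb_id, chain_filter=[chain])
        seq = "".join(r.aa for r in sub.chains[chain])
        envs = compute_environment(sub, n_points=cfg.environment_points,
                                   max_asa_scale=cfg.max_asa_scale)
        family = row.get("family", "")
        features[pdb_id] = {
            "label": row["label"], "fold": row["fold"], "chain": chain,
            "structure": sub,
            "composition": composition_profile(seq, structure_id=pdb_id, family=family),
            "interactions": summarize_interactions(sub, cfg.interaction_config),
            "environment": environment_profile(envs, structure_id=pdb_id, family=family),
        }
        logger.info("featurized %s: %d residues", pdb_id, sub.length)

    comp_tables: dict[str, pd.DataFrame] = {}
    inter_tables: dict[str, pd.DataFrame] = {}
    env_tables: dict[str, pd.DataFrame] = {}
    sizes: dict[str, tuple[int, int]] = {}
    for name, stratum in _strata(manifest, cfg.stratifications).items():
        ids_t = [i for i in stratum["pdb_id"] if features[i]["label"] == "thermophile"]
        ids_m = [i for i in stratum["pdb_id"] if features[i]["label"] == "mesophile"]
        sizes[name] = (len(ids_t), len(ids_m))
        if len(ids_t) < 2 or len(ids_m) < 2:
            logger.warning("stratum %s skipped: %d thermophiles, %d mesophiles "
                           "(need 2+ each)", name, len(ids_t), len(ids_m))
            continue
        comp_t = [features[i]["composition"] for i in ids_t]
        comp_m = [features[i]["composition"] for i in ids_m]
        comp_tables[name] = significance_screen(
            comp_t, comp_m, alpha=cfg.alpha, variant=cfg.t_test_variant,
            aggregate=cfg.aggregation)
        int_t = [_FreqBag(i, dict(features[i]["interactions"].normalized_counts),
                          features[i]["composition"].family) for i in ids_t]
        int_m = [_FreqBag(i, dict(features[i]["interactions"].normalized_counts),
                          features[i]["composition"].family) for i in ids_m]
        inter_tables[name] = significance_screen(
            int_t, int_m, alpha=cfg.alpha, variant=cfg.t_test_variant,
            aggregate=cfg.aggregation)
        sig_aas = sorted(comp_tables[name].loc[comp_tables[name]["significant"],
                                               "feature"])
        env_tables[name] = environment_preference_screen(
            [features[i]["environment"] for i in ids_t],
            [features[i]["environment"] for i in ids_m],
            focus_aas=sig_aas, alpha=cfg.alpha, variant=cfg.t_test_variant)

    trees: dict[str, str] = {}
    cross_pairs: dict[str, tuple[str, str]] = {}
    pair_rows: list[pd.DataFrame] = []
    tally_rows: list[dict] = []
    labels = dict(zip(manifest["pdb_id"], manifest["label"]))
    for fold, msa_path in cfg.msa_paths.items():
        msa = read_fasta_alignment(Path(msa_path).read_text())
        dm = distance_matrix_from_msa(msa)
        tree = neighbor_joining(dm)
        trees[fold] = serialize_newick(tree)
        t_id, m_id = closest_cross_pair(tree, labels)
        cross_pairs[fold] = (t_id, m_id)
        if t_id in features and m_id in features:
            pa = align_pair(features[t_id]["structure"], features[m_id]["structure"],
                            chain_a=features[t_id]["chain"],
                            chain_b=features[m_id]["chain"])
            pair_rows.append(pair_table(pa).assign(fold=fold))
            fold_key = f"fold:{fold}"
            sig = comp_tables.get(fold_key)
            focus = sorted(sig.loc[sig["significant"], "feature"]) if sig is not None else []
            for aa in focus:
                direction = "thermo->meso"
                occurrences = sum(1 for r in features[t_id]["structure"]
                                  .chains[features[t_id]["chain"]] if r.aa == aa)
                tally = tally_substitutions(pa, aa, direction,
                                            source_occurrences=occurrences)
                row = {"fold": fold, "focus_aa": aa, "direction": direction,
                       "conserved": tally.conserved, "unaligned": tally.unaligned}
                row.update(tally.counts)
                tally_rows.append(row)

    report = StudyReport(
        composition_tables=comp_tables,
        interaction_tables=inter_tables,
        environment_tables=env_tables,
        composition_grid=significance_grid(comp_tables) if comp_tables else pd.DataFrame(),
        interaction_grid=significance_grid(inter_tables) if inter_tables else pd.DataFrame(),
        pair_summaries=pd.concat(pair_rows, ignore_index=True) if pair_rows else pd.DataFrame(),
        tallies=pd.DataFrame(tally_rows),
        trees=trees,
        cross_pairs=cross_pairs,
        stratum_sizes=sizes,
        provenance={
            "package_version": __version__,
            "alpha": cfg.alpha,
            "t_test_variant": cfg.t_test_variant,
            "aggregation": cfg.aggregation,
            "max_asa_scale": cfg.max_asa_scale,
            "environment_points": cfg.environment_points,
            "seed": cfg.seed,
            "n_structures": len(features),
        },
    )
    return report
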