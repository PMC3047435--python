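"""Length-normalized composition statistics and group significance screens.

Per-protein amino-acid frequencies (counts over protein length), per-residue
normalized interaction counts and per-amino-acid environment-class fractions
are compared between thermophile and mesophile groups with an unpaired
two-tailed t-test.  Welch's unequal-variance form is the default; the
pooled-variance form is available by flag.  A feature is called significant
at p below alpha (default 0.05, no multiple-testing correction; an optional
Benjamini-Hochberg adjustment can be switched on), and the enriched group
is the one with the larger mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .environment import ACC_CLASSES, SS3_CLASSES, ResidueEnvironment
from .structure_io import STANDARD_AAS

logger = logging.getLogger(__name__)

ALPHA_DEFAULT = 0.05


@dataclass
class CompositionProfile:
    structure_id: str
    freq: dict[str, float]
    length: int
    family: str = ""

    def __post_init__(self) -> None:
        total = sum(self.freq.values())
        if self.freq and abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {total}, expected 1")
        if any(v < 0 for v in self.freq.values()):
            raise ValueError("negative frequency")


@dataclass
class EnvironmentProfile:
    """Per-amino-acid class fractions within one protein.

    ``ss3`` maps (aa, class) to the fraction of that amino acid's residues
    assigned to the class; likewise ``acc`` for accessibility classes.
    Amino acids absent from the protein have no entries.
    """
    structure_id: str
    ss3: dict[tuple[str, str], float] = field(default_factory=dict)
    acc: dict[tuple[str, str], float] = field(default_factory=dict)
    family: str = ""


def composition_profile(seq: str, structure_id: str = "", family: str = "") -> CompositionProfile:
    """Amino-acid frequencies of a sequence, normalized by its length."""
    clean = [c for c in seq if c in STANDARD_AAS]
    if not clean:
        raise ValueError("empty sequence after removing nonstandard residues")
    n = len(clean)
    freq = {aa: clean.count(aa) / n for aa in STANDARD_AAS}
    return CompositionProfile(structure_id=structure_id, freq=freq, length=n, family=family)


def environment_profile(envs: list[ResidueEnvironment], structure_id: str = "",
                        family: str = "") -> EnvironmentProfile:
    """Class-occupancy fractions per amino acid from a residue environment list."""
    ss_counts: dict[str, dict[str, int]] = {}
    acc_counts: dict[str, dict[str, int]] = {}
    for e in envs:
        aa = e.residue[2]
        if aa == "X":
            continue
        ss_counts.setdefault(aa, {c: 0 for c in SS3_CLASSES})[e.ss3] += 1
        if e.acc_class is not None:
            acc_counts.setdefault(aa, {c: 0 for c in ACC_CLASSES})[e.acc_class] += 1
    prof = EnvironmentProfile(structure_id=structure_id, family=family)
    for aa, counts in ss_counts.items():
        total = sum(counts.values())
        for cls, c in counts.items():
            prof.ss3[(aa, cls)] = c / total
    for aa, counts in acc_counts.items():
        total = sum(counts.values())
        for cls, c in counts.items():
            prof.acc[(aa, cls)] = c / total
    return prof


def t_test_unpaired(a, b, variant: str = "welch") -> tuple[float, float, float]:
    """Two-sample two-tailed t-test; returns (t, df, p).

    Degenerate zero-variance inputs: equal means give p = 1, unequal means
    give p = 0 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        logger.warning("zero-variance groups with unequal means; p set to 0")
        return float("inf"), float(len(a) + len(b) - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    if variant == "pooled":
        df = float(len(a) + len(b) - 2)
    else:
        na, nb = len(a), len(b)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def _screen_rows(features, thermo_values, meso_values, alpha, variant):
    rows = []
    for feat in features:
        tv = np.asarray(thermo_values[feat], dtype=float)
        mv = np.asarray(meso_values[feat], dtype=float)
        flagged = ""
        if len(tv) < 2 or len(mv) < 2:
            t, df, p = float("nan"), float("nan"), 1.0
            flagged = "insufficient_sample"
        elif not (np.any(tv) or np.any(mv)):
            t, df, p = 0.0, float(len(tv) + len(mv) - 2), 1.0
            flagged = "absent_in_all"
        else:
            t, df, p = t_test_unpaired(tv, mv, variant=variant)
        mean_t = float(tv.mean()) if len(tv) else float("nan")
        mean_m = float(mv.mean()) if len(mv) else float("nan")
        significant = p < alpha
        if not significant:
            enriched = "none"
        else:
            enriched = "thermophile" if mean_t > mean_m else "mesophile"
        rows.append({
            "feature": feat, "mean_thermo": mean_t, "mean_meso": mean_m,
            "t": t, "df": df, "p_value": p, "significant": significant,
            "enriched_in": enriched, "n_thermo": len(tv), "n_meso": len(mv),
            "flag": flagged,
        })
    return pd.DataFrame(rows)


def _maybe_family_average(profiles, getter, aggregate: str):
    """Return {structure-or-family id: value-mapping} samples."""
    if aggregate == "per_protein":
        return [getter(p) for p in profiles]
    if aggregate != "family_averaged":
        raise ValueError(f"unknown aggregation mode {aggregate!r}")
    by_family: dict[str, list] = {}
    for p in profiles:
        by_family.setdefault(p.family or p.structure_id, []).append(getter(p))
    averaged = []
    for fam, maps in by_family.items():
        keys = set().union(*[set(m) for m in maps])
        averaged.append({k: float(np.mean([m.get(k, 0.0) for m in maps])) for k in keys})
    return averaged


def significance_screen(
    thermo: list,
    meso: list,
    alpha: float = ALPHA_DEFAULT,
    variant: str = "welch",
    aggregate: str = "per_protein",
    features: list[str] | None = None,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Feature-wise group comparison table.

    Accepts :class:`CompositionProfile` lists (features = amino acids) or
    any objects with a ``freq``-like mapping exposed via ``.freq``; for
    interaction screens, pass plain objects with ``freq`` holding the
    per-residue normalized category counts.
    """
    if len(thermo) < 2 or len(meso) < 2:
        raise ValueError("need at least two profiles per group")
    tmaps = _maybe_family_average(thermo, lambda p: p.freq, aggregate)
    mmaps = _maybe_family_average(meso, lambda p: p.freq, aggregate)
    if features is None:
        features = sorted(set().union(*[set(m) for m in tmaps + mmaps]))
    tvals = {f: [m.get(f, 0.0) for m in tmaps] for f in features}
    mvals = {f: [m.get(f, 0.0) for m in mmaps] for f in features}
    table = _screen_rows(features, tvals, mvals, alpha, variant)
    if bh_correction:
        from statsmodels.stats.multitest import multipletests

        reject, p_adj, _, _ = multipletests(table["p_value"], alpha=alpha, method="fdr_bh")
        table["p_adjusted"] = p_adj
        table["significant"] = reject
        table.loc[~table["significant"], "enriched_in"] = "none"
    return table


@dataclass
class _FreqBag:
    """Adapter giving arbitrary feature mappings the profile interface."""
    structure_id: str
    freq: dict
    family: str = ""


def interaction_screen(thermo_counts: list[dict], meso_counts: list[dict],
                       ids_thermo=None, ids_meso=None, **kwargs) -> pd.DataFrame:
    """Significance screen over per-residue normalized interaction counts."""
    ids_thermo = ids_thermo or [str(k) for k in range(len(thermo_counts))]
    ids_meso = ids_meso or [str(k) for k in range(len(meso_counts))]
    t = [_FreqBag(i, dict(c)) for i, c in zip(ids_thermo, thermo_counts)]
    m = [_FreqBag(i, dict(c)) for i, c in zip(ids_meso, meso_counts)]
    return significance_screen(t, m, **kwargs)


def environment_preference_screen(
    thermo_env: list[EnvironmentProfile],
    meso_env: list[EnvironmentProfile],
    focus_aas: list[str],
    alpha: float = ALPHA_DEFAULT,
    variant: str = "welch",
) -> pd.DataFrame:
    """Class-preference comparison for selected amino acids.

    One row per (amino acid, secondary-structure class) and per (amino
    acid, accessibility class).  A protein lacking the amino acid is
    omitted from that row's sample.
    """
    rows = []
    for aa in focus_aas:
        for kind, classes in (("ss3", SS3_CLASSES), ("acc", ACC_CLASSES)):
            for cls in classes:
                tv = [getattr(p, kind)[(aa, cls)] for p in thermo_env
                      if (aa, cls) in getattr(p, kind)]
                mv = [getattr(p, kind)[(aa, cls)] for p in meso_env
                      if (aa, cls) in getattr(p, kind)]
                dropped = (len(thermo_env) - len(tv)) + (len(meso_env) - len(mv))
                if dropped:
                    logger.info("aa %s absent from %d proteins for %s/%s", aa, dropped, kind, cls)
                feat = f"{aa}:{kind}:{cls}"
                df = _screen_rows([feat], {feat: tv}, {feat: mv}, alpha, variant)
                df["aa"], df["kind"], df["class"] = aa, kind, cls
                rows.append(df)
    if not rows:
        return pd.DataFrame(columns=["feature", "aa", "kind", "class", "mean_thermo",
                                     "mean_meso", "t", "df", "p_value", "significant",
                                     "enriched_in", "n_thermo", "n_meso", "flag"])
    return pd.concat(rows, ignore_index=True)


def significance_grid(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Feature-by-stratification grid of enriched groups (blank when not
    significant), mirroring a compact significance figure."""
    features = sorted(set().union(*[set(t["feature"]) for t in tables.values()]))
    grid = pd.DataFrame(index=features, columns=list(tables), data="")
    for name, t in tables.items():
        for _, row in t.iterrows():
            if row["significant"]:
                grid.loc[row["feature"], name] = row["enriched_in"]
    grid.index.name = "feature"
    return grid
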