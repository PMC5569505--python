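"""Functional profiling: evidence filtering, multi-database consensus,
pathway presence calls, and domain-level gene-family statistics.

A metabolic process is called present in a MAG only when (a) every key
enzyme of the pathway is confirmed by at least two independent annotation
sources, and (b) strictly more than half of the pathway's component
enzymes are detected at all (single-source detections count toward the
component fraction but cannot confirm a key enzyme). Gene-family counts
are compared between archaeal and bacterial MAGs with a two-sided
Mann-Whitney U test, Bonferroni-corrected across families.
"""

from __future__ import annotations

import configparser
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# annotation filtering and consensus
# ---------------------------------------------------------------------------


def filter_records(
    records: pd.DataFrame,
    evalue_max: float = 1e-20,
    bitscore_min: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Keep records passing their score gate.

    E-value records pass at ``score <= evalue_max`` (inclusive);
    bit-score records pass at ``score >= bitscore_min[enzyme_id]``
    (per-family custom thresholds). Records with an unknown score type are
    dropped with a warning.
    """
    bitscore_min = bitscore_min or {}
    keep = np.zeros(len(records), dtype=bool)
    unknown = 0
    for i, (_, row) in enumerate(records.iterrows()):
        st = row["score_type"]
        if st == "evalue":
            keep[i] = row["score"] <= evalue_max
        elif st == "bitscore":
            thr = bitscore_min.get(row["enzyme_id"])
            keep[i] = thr is not None and row["score"] >= thr
            if thr is None:
                unknown += 1
        else:
            unknown += 1
    if unknown:
        warnings.warn(f"dropped {unknown} records with unknown score type or missing threshold")
    return records[keep].reset_index(drop=True)


def consensus_enzymes(
    records: pd.DataFrame, min_databases: int = 2
) -> dict[str, tuple[set[str], set[str]]]:
    """Split each MAG's enzymes into multi-database-confirmed vs unconfirmed.

    Returns mag_id -> (confirmed, unconfirmed); an enzyme is confirmed
    when reported by at least ``min_databases`` distinct sources.
    """
    out: dict[str, tuple[set[str], set[str]]] = {}
    if len(records) == 0:
        return out
    grouped = records.groupby(["mag_id", "enzyme_id"])["database"].nunique()
    for (mag, enz), ndb in grouped.items():
        confirmed, unconfirmed = out.setdefault(str(mag), (set(), set()))
        (confirmed if ndb >= min_databases else unconfirmed).add(str(enz))
    return out


# ---------------------------------------------------------------------------
# pathway definitions and calls
# ---------------------------------------------------------------------------


@dataclass
class PathwayDefinition:
    pathway_id: str
    name: str
    components: set[str]
    key_enzymes: set[str]
    min_component_fraction: float = 0.5  # strict: detected/total must EXCEED this

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError(f"pathway {self.pathway_id} has no components")
        if not self.key_enzymes <= self.components:
            raise ValueError(f"pathway {self.pathway_id}: key enzymes must be components")


@dataclass
class PathwayCall:
    pathway_id: str
    mag_id: str
    present: bool
    detected_components: set[str]
    component_fraction: float
    keys_confirmed: bool
    missing_keys: set[str] = field(default_factory=set)


def call_pathway(
    mag_id: str,
    confirmed: set[str],
    unconfirmed: set[str],
    definition: PathwayDefinition,
) -> PathwayCall:
    """Presence call for one pathway in one MAG.

    Present iff every key enzyme is in the confirmed set AND strictly more
    than ``min_component_fraction`` of components are detected (counting
    confirmed and unconfirmed detections alike).
    """
    detected = (confirmed | unconfirmed) & definition.components
    frac = len(detected) / len(definition.components)
    missing_keys = definition.key_enzymes - confirmed
    present = not missing_keys and frac > definition.min_component_fraction
    return PathwayCall(
        pathway_id=definition.pathway_id,
        mag_id=mag_id,
        present=present,
        detected_components=detected,
        component_fraction=frac,
        keys_confirmed=not missing_keys,
        missing_keys=missing_keys,
    )


def call_pathways(
    records: pd.DataFrame,
    catalog: dict[str, PathwayDefinition],
    min_databases: int = 2,
    evalue_max: float = 1e-20,
    prefiltered: bool = False,
) -> pd.DataFrame:
    """Pathway presence matrix for every MAG in an annotation table."""
    if not prefiltered:
        records = filter_records(records, evalue_max)
    consensus = consensus_enzymes(records, min_databases)
    rows = []
    for mag in sorted(consensus):
        confirmed, unconfirmed = consensus[mag]
        for pid in sorted(catalog):
            call = call_pathway(mag, confirmed, unconfirmed, catalog[pid])
            rows.append(
                {
                    "mag_id": mag,
                    "pathway_id": pid,
                    "present": call.present,
                    "component_fraction": call.component_fraction,
                    "keys_confirmed": call.keys_confirmed,
                }
            )
    return pd.DataFrame(
        rows, columns=["mag_id", "pathway_id", "present", "component_fraction", "keys_confirmed"]
    )


def parse_pathways(text: str) -> dict[str, PathwayDefinition]:
    """Parse the pathway-definition format (INI sections, one per pathway):

    .. code-block:: ini

        [reverse_methanogenesis]
        name = Reverse methanogenesis
        components = mcrA, mcrB, mcrG, mtrA
        keys = mcrA
    """
    cp = configparser.ConfigParser()
    cp.read_string(text)
    out = {}
    for sec in cp.sections():
        comps = {c.strip() for c in cp[sec]["components"].split(",") if c.strip()}
        keys = {c.strip() for c in cp[sec].get("keys", "").split(",") if c.strip()}
        out[sec] = PathwayDefinition(
            pathway_id=sec,
            name=cp[sec].get("name", sec),
            components=comps,
            key_enzymes=keys,
            min_component_fraction=float(cp[sec].get("min_component_fraction", "0.5")),
        )
    return out


def format_pathways(catalog: dict[str, PathwayDefinition]) -> str:
    lines = []
    for pid in sorted(catalog):
        d = catalog[pid]
        lines += [
            f"[{pid}]",
            f"name = {d.name}",
            f"components = {', '.join(sorted(d.components))}",
            f"keys = {', '.join(sorted(d.key_enzymes))}",
            f"min_component_fraction = {d.min_component_fraction}",
            "",
        ]
    return "\n".join(lines)


def starter_pathways() -> dict[str, PathwayDefinition]:
    """Editable starter catalog of exemplar anaerobic processes.

    Key enzymes follow field convention: mcrA for (reverse)
    methanogenesis, dsrAB for dissimilatory sulfate reduction, napA for
    periplasmic nitrate reduction, bssA/assA for fumarate-addition
    hydrocarbon activation; beta-oxidation is called on its four core
    steps without a single diagnostic key.
    """
    defs = [
        PathwayDefinition(
            "reverse_methanogenesis",
            "Reverse methanogenesis / methanogenesis",
            {"mcrA", "mcrB", "mcrG", "mtrA", "mer", "mtd", "ftr", "fwdA"},
            {"mcrA"},
        ),
        PathwayDefinition(
            "sulfate_reduction",
            "Dissimilatory sulfate reduction",
            {"dsrA", "dsrB", "aprA", "aprB", "sat"},
            {"dsrA", "dsrB"},
        ),
        PathwayDefinition(
            "beta_oxidation",
            "Fatty-acid beta-oxidation",
            {
                "acyl-CoA_dehydrogenase",
                "enoyl-CoA_hydratase",
                "3-hydroxyacyl-CoA_dehydrogenase",
                "acetyl-CoA_C-acyltransferase",
            },
            set(),
        ),
        PathwayDefinition(
            "denitrification",
            "Denitrification (nitrate reduction)",
            {"napA", "napB", "nirS", "norB", "nosZ"},
            {"napA"},
        ),
        PathwayDefinition(
            "fumarate_addition",
            "Fumarate-addition hydrocarbon activation",
            {"bssA", "assA", "bssB", "bbsA", "bbsB"},
            {"bssA", "assA"},
        ),
    ]
    return {d.pathway_id: d for d in defs}


# ---------------------------------------------------------------------------
# gene-family statistics
# ---------------------------------------------------------------------------


def family_abundance(
    matrix: pd.DataFrame,
    groups: dict[str, str],
) -> pd.DataFrame:
    """Mean gene count per MAG per group (domain or phylum) per family.

    ``matrix`` is MAG x family counts; ``groups`` maps MAG -> label. The
    normalization divides each group's total count by its number of MAGs.
    """
    labels = pd.Series({m: groups[m] for m in matrix.index})
    sizes = labels.value_counts()
    if (sizes == 0).any() or len(sizes) == 0:
        raise ValueError("every group must contain at least one MAG")
    rows = []
    for fam in matrix.columns:
        row = {"family": fam}
        for g in sorted(sizes.index):
            row[f"mean_{g}"] = matrix.loc[labels == g, fam].sum() / sizes[g]
        rows.append(row)
    return pd.DataFrame(rows)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of group x: pairwise wins over y, ties counting one half."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney(x, y, exact_max_n: int = 8) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact branch (min group size <= ``exact_max_n``): the null is built by
    enumerating all assignments of the pooled observations to the two
    groups, so ties are handled exactly; the two-sided p-value is the
    probability of a U at least as far from its null mean n1*n2/2 as
    observed. Larger groups use the normal approximation with tie
    correction and continuity correction. Constant pooled data gives
    p = 1 by convention. Returns (U of the first group, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both groups must be non-empty")
    u = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return u, 1.0
    n1, n2 = len(x), len(y)
    if min(n1, n2) <= exact_max_n and comb(n1 + n2, n1) <= 200_000:
        mid = n1 * n2 / 2.0
        dev = abs(u - mid)
        hits = 0
        total = comb(n1 + n2, n1)
        idx = np.arange(n1 + n2)
        for picked in combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(picked)] = True
            u_perm = _u_statistic(pooled[mask], pooled[~mask])
            if abs(u_perm - mid) >= dev - 1e-12:
                hits += 1
        return u, hits / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u, float(res.pvalue)


def bonferroni(p_values: list[float], n_tests: int | None = None) -> list[float]:
    """Bonferroni adjustment: p * number of tests, capped at 1."""
    m = n_tests if n_tests is not None else len(p_values)
    return [min(1.0, p * m) for p in p_values]


def domain_comparison_test(
    matrix: pd.DataFrame,
    domains: dict[str, str],
    families: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-family archaea-vs-bacteria comparison, Bonferroni-corrected.

    ``matrix`` is MAG x family counts; ``domains`` maps each MAG to
    'archaea' or 'bacteria'. Significance means adjusted p < alpha.
    """
    labels = pd.Series({m: domains[m] for m in matrix.index})
    arch = matrix.loc[labels == "archaea"]
    bact = matrix.loc[labels == "bacteria"]
    if len(arch) < 2 or len(bact) < 2:
        raise ValueError("need at least 2 MAGs per domain")
    families = list(families) if families is not None else list(matrix.columns)
    rows = []
    for fam in families:
        u, p = mann_whitney(arch[fam].to_numpy(), bact[fam].to_numpy())
        rows.append(
            {
                "family": fam,
                "mean_archaea": arch[fam].sum() / len(arch),
                "mean_bacteria": bact[fam].sum() / len(bact),
                "U": u,
                "p_raw": p,
            }
        )
    df = pd.DataFrame(rows)
    df["p_adj"] = bonferroni(list(df["p_raw"]))
    df["significant"] = df["p_adj"] < alpha
    return df
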