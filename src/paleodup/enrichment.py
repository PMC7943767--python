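"""OGC group classification and cluster-level binomial functional enrichment.

Clusters are classified by their species composition: a group-A-specific
cluster contains proteins from at least two distinct A-group species and
none from group B (and symmetrically); a shared cluster contains at least
one species from each group; clusters with fewer than two distinct species
are unclassified.

Enrichment of a functional term in a foreground cluster set is measured
against a background cluster set with a one-sided binomial test: with
``p_bg = k_bg / n_bg`` the background rate of clusters carrying the term,
the p-value is the exact upper tail ``P(X >= k_fg)`` for
``X ~ Binomial(n_fg, p_bg)``.  P-values are adjusted across terms with
Benjamini–Hochberg.  Each cluster's term set is the union of its member
genes' terms — a term appearing on several members counts once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .genome_io import AnnotationTable, OGCTable

logger = logging.getLogger(__name__)

__all__ = [
    "GroupLabel",
    "classify_ogcs",
    "ogc_terms",
    "binomial_tail",
    "binomial_enrich",
    "expanded_set_enrich",
]


def binomial_tail(k: int, n: int, p: float) -> float:
    """Exact one-sided tail P(X >= k) for X ~ Binomial(n, p)."""
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    if k == 0:
        return 1.0
    return float(min(max(binom.sf(k - 1, n, p), 0.0), 1.0))


class GroupLabel(str, Enum):
    SPECIFIC_TO_A = "specific_to_A"
    SPECIFIC_TO_B = "specific_to_B"
    SHARED = "shared"
    UNCLASSIFIED = "unclassified"


def classify_ogcs(
    table: OGCTable, group_a_species: set[str], group_b_species: set[str]
) -> dict[str, GroupLabel]:
    """Classify every cluster by which species groups it contains."""
    group_a_species, group_b_species = set(group_a_species), set(group_b_species)
    if group_a_species & group_b_species:
        raise ValueError("species groups overlap")
    labels: dict[str, GroupLabel] = {}
    for cid in table.clusters:
        present = table.species_present(cid)
        unknown = present - group_a_species - group_b_species
        if unknown:
            raise ValueError(f"cluster {cid}: species without group label: {sorted(unknown)}")
        n_a = len(present & group_a_species)
        n_b = len(present & group_b_species)
        if len(present) < 2:
            labels[cid] = GroupLabel.UNCLASSIFIED
        elif n_a >= 2 and n_b == 0:
            labels[cid] = GroupLabel.SPECIFIC_TO_A
        elif n_b >= 2 and n_a == 0:
            labels[cid] = GroupLabel.SPECIFIC_TO_B
        elif n_a >= 1 and n_b >= 1:
            labels[cid] = GroupLabel.SHARED
        else:
            labels[cid] = GroupLabel.UNCLASSIFIED
    return labels


def ogc_terms(member_gene_ids: list[str], annotations: AnnotationTable) -> set[str]:
    """Deduplicated union of member genes' term sets."""
    terms: set[str] = set()
    for gid in member_gene_ids:
        terms |= annotations.terms_for(gid)
    return terms


def _cluster_term_map(
    cluster_ids: list[str], table: OGCTable, annotations: AnnotationTable
) -> dict[str, set[str]]:
    return {cid: ogc_terms(table.members(cid), annotations) for cid in cluster_ids}


def binomial_enrich(
    foreground: list[str],
    background: list[str],
    table: OGCTable,
    annotations: AnnotationTable,
    alpha: float = 0.01,
    min_fg_count: int = 3,
    annotated_only: bool = True,
) -> pd.DataFrame:
    """Cluster-level binomial enrichment of terms in foreground vs background.

    ``n_fg``/``n_bg`` count clusters carrying at least one term in the
    namespace when ``annotated_only`` (default; unannotatable clusters would
    otherwise dilute the background rate).  ``p_bg`` gets add-one smoothing
    when ``k_bg = 0``.  Terms present in fewer than ``min_fg_count``
    foreground clusters are skipped.  Columns: term, k_fg, n_fg, k_bg, n_bg,
    p_bg, p_value, p_adj, significant; sorted by p_value.
    """
    if not background:
        raise ValueError("empty background")
    if set(foreground) & set(background):
        raise ValueError("foreground and background cluster sets must be disjoint")
    fg_terms = _cluster_term_map(list(foreground), table, annotations)
    bg_terms = _cluster_term_map(list(background), table, annotations)
    if annotated_only:
        fg_terms = {c: t for c, t in fg_terms.items() if t}
        bg_terms = {c: t for c, t in bg_terms.items() if t}
    n_fg, n_bg = len(fg_terms), len(bg_terms)
    if n_bg == 0:
        raise ValueError("no annotated background clusters")

    k_fg: dict[str, int] = {}
    for terms in fg_terms.values():
        for t in terms:
            k_fg[t] = k_fg.get(t, 0) + 1
    k_bg: dict[str, int] = {}
    for terms in bg_terms.values():
        for t in terms:
            k_bg[t] = k_bg.get(t, 0) + 1

    tested = sorted(t for t, k in k_fg.items() if k >= min_fg_count)
    n_skipped = sum(1 for k in k_fg.values() if k < min_fg_count)
    if n_skipped:
        logger.info("skipped %d terms in < %d foreground clusters", n_skipped, min_fg_count)
    rows = []
    for t in tested:
        kb = k_bg.get(t, 0)
        p_bg = kb / n_bg if kb > 0 else 1.0 / (n_bg + 1.0)
        p_value = binomial_tail(k_fg[t], n_fg, p_bg)
        rows.append(
            {
                "term": t,
                "k_fg": k_fg[t],
                "n_fg": n_fg,
                "k_bg": kb,
                "n_bg": n_bg,
                "p_bg": p_bg,
                "p_value": p_value,
            }
        )
    columns = ["term", "k_fg", "n_fg", "k_bg", "n_bg", "p_bg", "p_value", "p_adj", "significant"]
    if not rows:
        return pd.DataFrame(columns=columns)
    df = pd.DataFrame(rows)
    _, p_adj, _, _ = multipletests(df["p_value"].to_numpy(), method="fdr_bh")
    df["p_adj"] = p_adj
    df["significant"] = df["p_adj"] < alpha
    return df.sort_values(["p_value", "term"], kind="mergesort").reset_index(drop=True)[columns]


def expanded_set_enrich(
    expanded_ids: list[str],
    table: OGCTable,
    clade_map: dict[str, str],
    annotations: AnnotationTable,
    alpha: float = 0.01,
    min_fg_count: int = 3,
) -> pd.DataFrame:
    """Enrichment of an externally supplied expanded-cluster set.

    Foreground is the supplied expanded set (e.g. clusters a birth–death
    analysis found significantly expanded in one lineage); background is the
    conserved clusters containing at least one species from every clade in
    ``clade_map``, minus the expanded set (forced disjoint).
    """
    missing = [c for c in expanded_ids if c not in table.clusters]
    if missing:
        raise KeyError(f"expanded cluster ids not in table: {missing}")
    clades = set(clade_map.values())
    expanded = set(expanded_ids)
    background = []
    for cid in table.clusters:
        if cid in expanded:
            continue
        present_clades = {clade_map[sp] for sp in table.species_present(cid) if sp in clade_map}
        if present_clades >= clades:
            background.append(cid)
    return binomial_enrich(
        sorted(expanded), sorted(background), table, annotations,
        alpha=alpha, min_fg_count=min_fg_count,
    )
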