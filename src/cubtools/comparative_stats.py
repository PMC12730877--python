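"""Cross-genome statistics.

Group comparisons are nonparametric throughout (Kruskal-Wallis across groups,
pairwise two-sided Wilcoxon rank-sum with Bonferroni adjustment over the group
pairs); Shapiro-Wilk and Bartlett pre-tests are provided for reporting only.
Trait correlations are computed both on raw tip values (Spearman) and on
Felsenstein's phylogenetically independent contrasts (Pearson through the
origin), so phylogenetic pseudo-replication can be assessed side by side.
Genome profiles are clustered agglomeratively with Euclidean distance and
complete linkage; annotation-term enrichment uses the one-sided hypergeometric
upper tail with Bonferroni correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

logger = logging.getLogger(__name__)

#: per-group size above which the rank-sum test switches to the tie-corrected
#: normal approximation (exact distribution below)
WILCOXON_EXACT_MAX_N = 25


@dataclass
class GroupComparison:
    trait: str
    kw_statistic: float
    kw_p: float
    pairwise: pd.DataFrame  # group1, group2, n1, n2, statistic, p_raw, p_adj
    n_comparisons: int
    excluded_groups: tuple[str, ...] = ()


def _bonferroni(p: float, m: int) -> float:
    return min(1.0, p * m)


def group_compare(
    values: Mapping[str, float],
    groups: Mapping[str, str],
    trait: str = "trait",
) -> GroupComparison:
    """Kruskal-Wallis plus pairwise Wilcoxon rank-sum (Bonferroni) on one trait.

    ``values`` and ``groups`` map genome_id to trait value / group label.
    Groups with fewer than 2 members are excluded with a warning.
    """
    by_group: dict[str, list[float]] = {}
    for gid, value in values.items():
        if gid in groups and not (isinstance(value, float) and math.isnan(value)):
            by_group.setdefault(groups[gid], []).append(float(value))
    excluded = tuple(sorted(g for g, v in by_group.items() if len(v) < 2))
    for g in excluded:
        logger.warning("group %r has < 2 members and is excluded from %s", g, trait)
    usable = {g: np.asarray(v) for g, v in by_group.items() if len(v) >= 2}
    if len(usable) < 2:
        raise ValueError(f"need >= 2 groups with >= 2 members for {trait}")

    labels = sorted(usable)
    kw_stat, kw_p = stats.kruskal(*(usable[g] for g in labels))

    pairs = list(combinations(labels, 2))
    m = len(pairs)
    rows = []
    for g1, g2 in pairs:
        a, b = usable[g1], usable[g2]
        pooled = np.concatenate([a, b])
        has_ties = np.unique(pooled).size < pooled.size
        method = (
            "exact"
            if max(a.size, b.size) <= WILCOXON_EXACT_MAX_N and not has_ties
            else "asymptotic"
        )
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        rows.append(
            {
                "trait": trait,
                "group1": g1,
                "group2": g2,
                "n1": a.size,
                "n2": b.size,
                "statistic": float(res.statistic),
                "p_raw": float(res.pvalue),
                "p_adj": _bonferroni(float(res.pvalue), m),
            }
        )
    return GroupComparison(
        trait=trait,
        kw_statistic=float(kw_stat),
        kw_p=float(kw_p),
        pairwise=pd.DataFrame(rows),
        n_comparisons=m,
        excluded_groups=excluded,
    )


def pretest_normality(
    values: Mapping[str, float], groups: Mapping[str, str], trait: str = "trait"
) -> pd.DataFrame:
    """Shapiro-Wilk per group and Bartlett across groups (reporting only)."""
    by_group: dict[str, list[float]] = {}
    for gid, v in values.items():
        if gid in groups:
            by_group.setdefault(groups[gid], []).append(float(v))
    rows = []
    samples = []
    for g in sorted(by_group):
        v = np.asarray(by_group[g])
        if v.size >= 3:
            w, p = stats.shapiro(v)
            rows.append({"trait": trait, "test": "shapiro", "group": g, "statistic": w, "p": p})
        if v.size >= 2:
            samples.append(v)
    if len(samples) >= 2:
        b, p = stats.bartlett(*samples)
        rows.append({"trait": trait, "test": "bartlett", "group": "all", "statistic": b, "p": p})
    return pd.DataFrame(rows, columns=["trait", "test", "group", "statistic", "p"])


def spearman_corr(
    x: Mapping[str, float], y: Mapping[str, float]
) -> tuple[float, float]:
    """Spearman rho and two-sided p over genomes shared by both traits."""
    shared = sorted(set(x) & set(y))
    if len(shared) < 4:
        raise ValueError(f"need >= 4 shared genomes, got {len(shared)}")
    res = stats.spearmanr([x[g] for g in shared], [y[g] for g in shared])
    return float(res.statistic), float(res.pvalue)


def _as_tree(tree: "dendropy.Tree | str") -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree.clone(depth=1)
    return dendropy.Tree.get(data=tree, schema="newick", preserve_underscores=True)


def pic_contrasts(
    tree: "dendropy.Tree | str", trait: Mapping[str, float]
) -> np.ndarray:
    """Felsenstein's standardized independent contrasts for one trait.

    ``tree`` is a dendropy tree or newick string whose tip labels are genome
    ids; polytomies are resolved into zero-length bifurcations first.  Returns
    ``n_tips - 1`` contrasts in a deterministic post-order; contrast signs
    depend on child order and are only identified up to sign.
    """
    t = _as_tree(tree)
    t.resolve_polytomies(update_bipartitions=False)
    tips = [leaf.taxon.label for leaf in t.leaf_node_iter()]
    missing = [label for label in tips if label not in trait]
    if missing:
        raise ValueError(f"tips without trait values: {missing[:5]}")
    if len(set(tips)) != len(tips):
        raise ValueError("duplicate tip labels")

    contrasts: list[float] = []
    # node -> (working value, extended branch length)
    state: dict[dendropy.Node, tuple[float, float]] = {}
    for node in t.postorder_node_iter():
        bl = node.edge.length if node.edge.length is not None else 0.0
        if node.is_leaf():
            state[node] = (float(trait[node.taxon.label]), float(bl))
            continue
        children = node.child_nodes()
        if len(children) != 2:  # pragma: no cover - resolve_polytomies guarantees 2
            raise ValueError("tree not fully bifurcating after polytomy resolution")
        (v1, b1), (v2, b2) = state[children[0]], state[children[1]]
        if b1 + b2 == 0.0:
            raise ValueError(
                f"zero-length sibling branch pair at node {node.bipartition if node.taxon is None else node.taxon.label}; "
                "contrast undefined"
            )
        contrasts.append((v1 - v2) / math.sqrt(b1 + b2))
        if b1 == 0.0:
            value = v1
        elif b2 == 0.0:
            value = v2
        else:
            value = (v1 / b1 + v2 / b2) / (1.0 / b1 + 1.0 / b2)
        state[node] = (value, float(bl) + b1 * b2 / (b1 + b2))
    return np.asarray(contrasts)


def correlate_contrasts(
    cx: Sequence[float], cy: Sequence[float]
) -> tuple[float, float]:
    """Through-the-origin Pearson correlation of paired contrasts.

    Contrast signs are arbitrary, so the regression/correlation must be forced
    through the origin; both contrast vectors must come from the same tree
    traversal.  Returns (rho, two-sided p) with n - 1 degrees of freedom.
    """
    x = np.asarray(cx, dtype=float)
    y = np.asarray(cy, dtype=float)
    if x.shape != y.shape:
        raise ValueError("contrast vectors differ in length")
    if x.size < 2:
        raise ValueError("need >= 2 contrasts")
    denom = math.sqrt(float(x @ x) * float(y @ y))
    if denom == 0.0:
        return 0.0, 1.0
    rho = float(x @ y) / denom
    df = x.size - 1
    rho_clipped = max(min(rho, 1.0 - 1e-15), -1.0 + 1e-15)
    t = rho_clipped * math.sqrt(df / (1.0 - rho_clipped**2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return rho, float(p)


def cluster_genomes(
    profiles: "pd.DataFrame | Mapping[str, Sequence[float]]",
    method: str = "complete",
) -> tuple[np.ndarray, list[str]]:
    """Euclidean hierarchical clustering of genome profile vectors.

    ``profiles`` is a genomes-by-features frame (or mapping of equal-length
    vectors) with no missing values; use :func:`impute_rscu` first for RSCU
    matrices with zero-count families.  Returns the scipy linkage matrix and
    the dendrogram leaf order (genome ids).
    """
    if not isinstance(profiles, pd.DataFrame):
        lengths = {len(v) for v in profiles.values()}
        if len(lengths) > 1:
            raise ValueError("profile vectors have unequal lengths")
        profiles = pd.DataFrame({k: list(v) for k, v in profiles.items()}).T
    if profiles.shape[0] < 2:
        raise ValueError("need >= 2 genomes to cluster")
    if profiles.isna().to_numpy().any():
        raise ValueError("profiles contain missing values; impute before clustering")
    z = hierarchy.linkage(profiles.to_numpy(dtype=float), method=method, metric="euclidean")
    order = [profiles.index[i] for i in hierarchy.leaves_list(z)]
    return z, order


def impute_rscu(rscu_matrix: pd.DataFrame, fill: float = 1.0) -> pd.DataFrame:
    """Replace undefined RSCU entries (zero-count families) with the neutral value 1."""
    return rscu_matrix.fillna(fill)


def term_enrichment(
    study_genes: set[str],
    population_genes: set[str],
    annotations: Mapping[str, set[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of annotation terms in a study set.

    Terms with at least one study occurrence are tested; the Bonferroni family
    is the number of tested terms.  Rows are sorted by adjusted p-value.
    """
    if not study_genes:
        raise ValueError("study set is empty")
    if not study_genes <= population_genes:
        raise ValueError("study genes must be a subset of the population")
    n_pop = len(population_genes)
    n_study = len(study_genes)
    term_pop: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene in population_genes:
        for term in annotations.get(gene, ()):
            term_pop[term] = term_pop.get(term, 0) + 1
            if gene in study_genes:
                term_study[term] = term_study.get(term, 0) + 1
    tested = sorted(term_study)
    m = len(tested)
    rows = []
    for term in tested:
        k_study = term_study[term]
        k_pop = term_pop[term]
        p_raw = float(stats.hypergeom.sf(k_study - 1, n_pop, k_pop, n_study))
        rows.append(
            {
                "term": term,
                "k_study": k_study,
                "n_study": n_study,
                "k_pop": k_pop,
                "n_pop": n_pop,
                "p_raw": p_raw,
                "p_bonferroni": _bonferroni(p_raw, m),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["term", "k_study", "n_study", "k_pop", "n_pop", "p_raw", "p_bonferroni"],
    )
    return out.sort_values(["p_bonferroni", "term"], kind="stable").reset_index(drop=True)
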