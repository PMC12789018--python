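"""Per-site alpha-diversity descriptors of wild-bee assemblages.

For every site (after excluding managed honey bees, normalizing abundance by
sampling effort and averaging over years and sampling methods) the module
computes: abundance per sample unit, observed and rarefied species richness,
functional diversity (total branch length of the UPGMA dendrogram of the
Gower functional dissimilarities), phylogenetic diversity (total branch
length on the Grafen taxonomy tree), abundance-weighted functional and
phylogenetic mean pairwise distance (MPD), functional evenness (Villeger
FEve along the minimum spanning tree of the assemblage in functional space)
and functional specialization (abundance-weighted mean distance to the
centroid of the dataset-wide species pool, normalized by the pool maximum).

Metrics are left undefined (NaN) where their domain requires it: MPD needs
two species, FEve three; branch-length diversity of an empty site is absent.
Sites averaging ten or fewer bees are flagged for exclusion downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .trait_phylo import (
    FunctionalSpace,
    Tree,
    balance_trait_contributions,
    gower_dissimilarity,
    grafen_lengths,
    minimum_spanning_tree,
    pcoa_embed,
    taxonomy_tree,
    upgma_dendrogram,
)

__all__ = [
    "exclude_taxa",
    "normalize_abundance",
    "rarefied_richness",
    "tree_branch_diversity",
    "weighted_mpd",
    "functional_evenness",
    "functional_specialization",
    "DatasetContext",
    "build_dataset_context",
    "compute_site_metrics",
    "aggregate_site_metrics",
]

INCLUSION_THRESHOLD = 10.0  # mean bees per site required for inclusion (strict >)


def exclude_taxa(matrix: pd.DataFrame, taxa) -> pd.DataFrame:
    """Drop species columns (e.g. Apis mellifera) before any metric; no-op if absent."""
    present = [t for t in taxa if t in matrix.columns]
    return matrix.drop(columns=present)


def normalize_abundance(totals, effort):
    """Individuals per sample unit: row total / effort. Zero effort is an error."""
    effort = np.asarray(effort, dtype=float)
    if (effort <= 0).any():
        raise ValueError("sampling effort must be positive")
    return np.asarray(totals, dtype=float) / effort


def rarefied_richness(counts, m: int) -> float:
    """Expected species count in a random draw of *m* individuals.

    Interpolation (m <= N) uses the exact hypergeometric formula
    ``S_obs - sum_i C(N - N_i, m) / C(N, m)``; extrapolation (m > N) uses the
    Chao1 estimator of undetected richness with the bias-corrected variant
    when no doubletons are present.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    counts = np.asarray([c for c in counts if c > 0], dtype=float)
    N = counts.sum()
    if N < 1:
        raise ValueError("need at least one individual")
    S = len(counts)
    if m <= N:
        # log-scale binomial ratios; terms with N - N_i < m vanish
        keep = (N - counts) >= m
        if not keep.any():
            return float(S)
        Ni = counts[keep]
        logterm = (
            gammaln(N - Ni + 1)
            - gammaln(N - Ni - m + 1)
            - (gammaln(N + 1) - gammaln(N - m + 1))
        )
        return float(S - np.exp(logterm).sum())
    f1 = float((counts == 1).sum())
    f2 = float((counts == 2).sum())
    if f1 == 0:
        return float(S)
    if f2 > 0:
        f0 = (N - 1) / N * f1**2 / (2 * f2)
    else:
        f0 = (N - 1) / N * f1 * (f1 - 1) / (2 * (f2 + 1))
    if f0 == 0:
        return float(S)
    return float(S + f0 * (1 - (1 - f1 / (N * f0 + f1)) ** (m - N)))


def tree_branch_diversity(tree: Tree, species) -> float:
    """Total branch length of the minimal root-inclusive subtree over *species*."""
    species = [s for s in species]
    if not species:
        return float("nan")
    return tree.subtree_length(species, include_root=True)


def weighted_mpd(d: pd.DataFrame, weights: pd.Series) -> float:
    """Abundance-weighted mean pairwise distance over species with positive weight."""
    w = weights[weights > 0]
    if len(w) < 2:
        return float("nan")
    p = (w / w.sum()).to_numpy()
    D = d.loc[w.index, w.index].to_numpy()
    P = np.outer(p, p)
    np.fill_diagonal(P, 0.0)
    return float((P * D).sum() / P.sum())


def functional_evenness(space: FunctionalSpace, weights: pd.Series) -> float:
    """Villeger FEve: regularity of abundance along the assemblage MST.

    Requires at least three species with positive abundance; per MST edge
    joining species i and j, EW = dist(i, j) / (p_i + p_j), partial evennesses
    are compared with the 1/(S-1) reference and rescaled to [0, 1].
    """
    w = weights[weights > 0]
    S = len(w)
    if S < 3:
        return float("nan")
    p = w / w.sum()
    edges = minimum_spanning_tree(space.coordinates.loc[w.index])
    ew = np.array([length / (p[a] + p[b]) for a, b, length in edges])
    if ew.sum() == 0:
        return float("nan")
    pew = ew / ew.sum()
    ref = 1.0 / (S - 1)
    return float((np.minimum(pew, ref).sum() - ref) / (1 - ref))


def functional_specialization(space: FunctionalSpace, weights: pd.Series) -> float:
    """FSpe: weighted mean distance to the pool centroid / pool maximum.

    The pool is every species embedded in *space* (the dataset species pool);
    a degenerate pool in which all species coincide yields NaN.
    """
    pool = space.coordinates.to_numpy()
    centroid = pool.mean(axis=0)
    dist_pool = np.sqrt(((pool - centroid) ** 2).sum(axis=1))
    dmax = dist_pool.max()
    if dmax == 0:
        return float("nan")
    w = weights[weights > 0]
    if w.empty:
        return float("nan")
    p = (w / w.sum()).to_numpy()
    x = space.coordinates.loc[w.index].to_numpy()
    di = np.sqrt(((x - centroid) ** 2).sum(axis=1))
    return float((p * di).sum() / dmax)


# ---------------------------------------------------------------------------
# Dataset-level supports and the per-site descriptor table


class DatasetContext:
    """Functional space, dendrogram and phylogeny shared by one dataset."""

    def __init__(self, space, fdendro, ftree_distances, phylo, trait_weights):
        self.space: FunctionalSpace = space
        self.fdendro: Tree = fdendro
        self.functional_distances: pd.DataFrame = ftree_distances
        self.phylo: Tree = phylo
        self.trait_weights: pd.Series = trait_weights
        self.phylo_distances: pd.DataFrame = phylo.cophenetic()


def build_dataset_context(
    traits: pd.DataFrame,
    species,
    n_axes: int = 4,
    balance: bool = True,
    exclude_trait_cols=(),
) -> DatasetContext:
    """Build the per-dataset functional space and trees over *species*.

    The functional space pool is the full species list of the dataset; traits
    named in *exclude_trait_cols* are dropped (the sensitivity analysis that
    removes body size and lecty, or method-biased traits).
    """
    from .trait_phylo import TRAIT_COLUMNS

    sub = traits[traits["species_id"].isin(species)].set_index("species_id", drop=False)
    sub = sub.loc[[s for s in species if s in sub.index]]
    cols = [c for c in TRAIT_COLUMNS if c not in exclude_trait_cols and c in sub.columns]
    weights = balance_trait_contributions(sub, trait_cols=cols) if balance else None
    d = gower_dissimilarity(sub, weights=weights, trait_cols=cols)
    space = pcoa_embed(d, n_axes=min(n_axes, len(sub) - 1))
    fdendro = upgma_dendrogram(d)
    phylo = grafen_lengths(taxonomy_tree(sub[["species_id", "genus", "family"]]))
    return DatasetContext(space, fdendro, space.distances(), phylo, weights)


def compute_site_metrics(
    matrix: pd.DataFrame,
    effort: pd.Series,
    ctx: DatasetContext,
    rarefaction_m: int | None = None,
    occurrence: bool = False,
) -> pd.DataFrame:
    """Descriptor vector for every site (row) of a site x species matrix.

    *rarefaction_m* defaults to the smallest positive site total of the
    matrix, so rarefied richness interpolates for every site.  With
    ``occurrence`` the composition metrics (MPD, FEve, FSpe) weight every
    present species equally instead of by abundance.
    """
    totals = matrix.sum(axis=1)
    if rarefaction_m is None:
        pos = totals[totals > 0]
        rarefaction_m = int(max(1, pos.min())) if len(pos) else 1
    rows = []
    for site, counts in matrix.iterrows():
        w = counts[counts > 0]
        if occurrence:
            w = (w > 0).astype(float)
        present = list(w.index)
        rec = {
            "site_id": site,
            "abundance": float(counts.sum()) / float(effort[site]),
            "richness": int((counts > 0).sum()),
        }
        rec["rarefied_richness"] = (
            rarefied_richness(w.to_numpy(), rarefaction_m) if len(w) else np.nan
        )
        rec["fd"] = tree_branch_diversity(ctx.fdendro, present) if present else np.nan
        rec["pd"] = tree_branch_diversity(ctx.phylo, present) if present else np.nan
        rec["fmpd"] = weighted_mpd(ctx.functional_distances, w)
        rec["pmpd"] = weighted_mpd(ctx.phylo_distances, w)
        rec["feve"] = functional_evenness(ctx.space, w)
        rec["fspe"] = functional_specialization(ctx.space, w)
        rows.append(rec)
    return pd.DataFrame(rows)


def aggregate_site_metrics(
    panels: pd.DataFrame,
    inclusion_threshold: float = INCLUSION_THRESHOLD,
) -> pd.DataFrame:
    """Average per-panel metrics over years, then methods, and flag inclusion.

    *panels* holds one row per (site_id, year, method) with metric columns
    plus raw_total (bees counted in that panel).  Sites whose mean bee count
    per panel is not strictly above the threshold are flagged ``excluded``.
    """
    metric_cols = [
        c for c in panels.columns if c not in ("site_id", "year", "method", "raw_total")
    ]
    by_method = (
        panels.groupby(["site_id", "method"], sort=True)[metric_cols].mean().reset_index()
    )
    out = by_method.groupby("site_id", sort=True)[metric_cols].mean().reset_index()
    mean_bees = panels.groupby("site_id")["raw_total"].mean()
    out["mean_bees"] = out["site_id"].map(mean_bees)
    out["excluded"] = ~(out["mean_bees"] > inclusion_threshold)
    return out
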