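"""Functional spaces and taxonomy-based phylogenies for bee assemblages.

Per dataset, a Gower multi-trait dissimilarity matrix is built over the
species pool (six traits: continuous body size, categorical lecty, sociality,
nest location and nesting strategy, binary kleptoparasitism), optionally with
per-trait weights balanced so every trait contributes equally, and embedded by
principal coordinates analysis (PCoA).  Taxonomic trees (root -> family ->
genus -> species) carry Grafen branch lengths: node heights proportional to
(number of descendant tips - 1), normalized to a root height of 1, so the tree
is ultrametric.  A UPGMA dendrogram of the functional dissimilarities and a
minimum spanning tree in the functional space support the dendrogram-based
diversity and evenness metrics.

Missing trait values are handled by pairwise deletion with weight
renormalization; no imputation is performed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "TRAIT_COLUMNS",
    "CONTINUOUS_TRAITS",
    "Tree",
    "FunctionalSpace",
    "gower_dissimilarity",
    "balance_trait_contributions",
    "pcoa_embed",
    "taxonomy_tree",
    "grafen_lengths",
    "upgma_dendrogram",
    "minimum_spanning_tree",
]

TRAIT_COLUMNS = (
    "body_size_mm",
    "lecty",
    "sociality",
    "nest_location",
    "nesting_strategy",
    "kleptoparasitism",
)
CONTINUOUS_TRAITS = ("body_size_mm",)


# ---------------------------------------------------------------------------
# Gower dissimilarity and trait-contribution balancing


def _per_trait_dissimilarity(traits: pd.DataFrame, trait_cols) -> tuple[np.ndarray, np.ndarray]:
    """Stacked (T, S, S) per-trait dissimilarities and availability masks."""
    S = len(traits)
    T = len(trait_cols)
    d = np.zeros((T, S, S))
    avail = np.zeros((T, S, S), dtype=bool)
    for t, col in enumerate(trait_cols):
        x = traits[col]
        present = x.notna().to_numpy()
        avail[t] = np.outer(present, present)
        if col in CONTINUOUS_TRAITS:
            v = x.to_numpy(dtype=float)
            rng = np.nanmax(v) - np.nanmin(v)
            if not np.isfinite(rng) or rng == 0:
                diff = np.zeros((S, S))
            else:
                diff = np.abs(v[:, None] - v[None, :]) / rng
            d[t] = np.nan_to_num(diff)
        else:
            codes = pd.factorize(x)[0]  # missing -> -1, masked by avail
            d[t] = (codes[:, None] != codes[None, :]).astype(float)
    return d, avail


def gower_dissimilarity(
    traits: pd.DataFrame,
    weights: dict[str, float] | pd.Series | None = None,
    trait_cols=TRAIT_COLUMNS,
) -> pd.DataFrame:
    """Weighted Gower dissimilarity over the traits available to each pair.

    Continuous traits contribute |x_i - x_j| / range (range over the table's
    species); categorical and binary traits contribute a 0/1 mismatch.  Per
    pair, weights are renormalized over the traits observed in both species.
    A species pair sharing no observed trait raises an error naming the pair.
    """
    if len(traits) < 2:
        raise ValueError("need at least 2 species")
    trait_cols = [c for c in trait_cols if c in traits.columns]
    d, avail = _per_trait_dissimilarity(traits, trait_cols)
    if weights is None:
        w = np.ones(len(trait_cols))
    else:
        w = np.asarray([float(weights[c]) for c in trait_cols])
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
    wa = w[:, None, None] * avail
    denom = wa.sum(axis=0)
    ids = traits["species_id"].tolist() if "species_id" in traits.columns else list(traits.index)
    if (denom == 0).any():
        i, j = np.argwhere(denom == 0)[0]
        raise ValueError(f"species pair ({ids[i]}, {ids[j]}) shares no observed trait")
    D = (wa * d).sum(axis=0) / denom
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2  # exact symmetry
    return pd.DataFrame(D, index=ids, columns=ids)


def _trait_contribution_spread(traits, trait_cols, w):
    """Spread of corr(per-trait dissimilarity, weighted total) across traits."""
    d, avail = _per_trait_dissimilarity(traits, trait_cols)
    iu = np.triu_indices(d.shape[1], k=1)
    wa = w[:, None, None] * avail
    denom = wa.sum(axis=0)
    denom[denom == 0] = np.nan
    total = ((wa * d).sum(axis=0) / denom)[iu]
    cors = []
    for t in range(len(trait_cols)):
        part = np.where(avail[t], d[t], np.nan)[iu]
        ok = np.isfinite(part) & np.isfinite(total)
        if ok.sum() > 2 and np.nanstd(part[ok]) > 0 and np.nanstd(total[ok]) > 0:
            cors.append(np.corrcoef(part[ok], total[ok])[0, 1])
        else:
            cors.append(np.nan)
    cors = np.asarray(cors)
    return float(np.nanmax(cors) - np.nanmin(cors)), cors


def balance_trait_contributions(traits: pd.DataFrame, trait_cols=TRAIT_COLUMNS) -> pd.Series:
    """Weights equalizing each trait's correlation with the total dissimilarity.

    Traits whose dissimilarity is constant over the table (zero variance) are
    excluded with a warning and get weight 0.  The remaining weights are found
    by constrained minimization of the spread of the trait-total correlations;
    if the optimizer fails, equal weights are returned with a warning.
    """
    if len(traits) < 3:
        raise ValueError("need at least 3 species to balance trait contributions")
    trait_cols = [c for c in trait_cols if c in traits.columns]
    d, avail = _per_trait_dissimilarity(traits, trait_cols)
    iu = np.triu_indices(len(traits), k=1)
    active = []
    for t, col in enumerate(trait_cols):
        vals = np.where(avail[t], d[t], np.nan)[iu]
        if np.isfinite(vals).sum() >= 3 and np.nanstd(vals) > 0:
            active.append(col)
        else:
            warnings.warn(f"trait {col!r} is constant or unobserved; excluded from balancing")
    weights = pd.Series(0.0, index=list(trait_cols))
    if len(active) == 1:
        weights[active[0]] = 1.0
        return weights
    if not active:
        raise ValueError("no trait shows variation; cannot build a functional space")

    k = len(active)

    def objective(w):
        w = np.abs(w)
        s = w.sum()
        if s == 0:
            return 1e6
        spread, _ = _trait_contribution_spread(traits, active, w / s)
        return spread

    try:
        res = optimize.minimize(
            objective,
            x0=np.full(k, 1.0 / k),
            method="SLSQP",
            bounds=[(1e-4, 1.0)] * k,
            constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
            options={"maxiter": 200, "ftol": 1e-10},
        )
        w = np.abs(res.x)
        w = w / w.sum()
        if not res.success and objective(w) > objective(np.full(k, 1.0 / k)):
            raise RuntimeError(res.message)
    except Exception as exc:  # pragma: no cover - optimizer pathologies
        warnings.warn(f"trait balancing failed ({exc}); using equal weights")
        w = np.full(k, 1.0 / k)
    for col, wi in zip(active, w):
        weights[col] = wi
    return weights


# ---------------------------------------------------------------------------
# Principal coordinates analysis


@dataclass
class FunctionalSpace:
    """Species coordinates on the retained PCoA axes."""

    coordinates: pd.DataFrame  # species x axes
    eigenvalues: np.ndarray  # all positive eigenvalues, nonincreasing
    quality: float  # mean |input dissimilarity - embedded distance|

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]

    def distances(self, species=None) -> pd.DataFrame:
        coords = self.coordinates if species is None else self.coordinates.loc[species]
        x = coords.to_numpy()
        diff = x[:, None, :] - x[None, :, :]
        D = np.sqrt((diff**2).sum(axis=-1))
        return pd.DataFrame(D, index=coords.index, columns=coords.index)


def pcoa_embed(d: pd.DataFrame, n_axes: int = 4, sqrt_transform: bool = True) -> FunctionalSpace:
    """Classical scaling of a dissimilarity matrix.

    With ``sqrt_transform`` (the default, appropriate for Gower input which
    need not be Euclidean) the square roots of the dissimilarities are
    embedded; without it the dissimilarities are taken as distances directly,
    in which case Euclidean input is reproduced exactly.  ``min(n_axes,
    #positive eigenvalues)`` axes are retained and the quality is the mean
    absolute deviation between the (transformed) input and the embedded
    Euclidean distances.
    """
    D = np.asarray(d, dtype=float)
    if sqrt_transform:
        D = np.sqrt(D)
    n = D.shape[0]
    D2 = D**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-10, 1e-8 * abs(evals[0])) if n else 0.0
    pos = evals > tol
    if pos.sum() < 1:
        raise ValueError("no positive eigenvalue; dissimilarity is degenerate")
    keep = min(n_axes, int(pos.sum()))
    coords = evecs[:, :keep] * np.sqrt(evals[:keep])
    ids = list(d.index) if isinstance(d, pd.DataFrame) else list(range(n))
    space = FunctionalSpace(
        coordinates=pd.DataFrame(coords, index=ids, columns=[f"axis{i+1}" for i in range(keep)]),
        eigenvalues=evals[pos],
        quality=0.0,
    )
    emb = space.distances().to_numpy()
    iu = np.triu_indices(n, k=1)
    space.quality = float(np.mean(np.abs(D[iu] - emb[iu])))
    return space


# ---------------------------------------------------------------------------
# Trees: a minimal rooted-tree container shared by the taxonomy phylogeny
# (Grafen branch lengths) and the functional UPGMA dendrogram.


@dataclass
class Tree:
    """Rooted tree with node heights; branch length = parent height - height."""

    parent: dict = field(default_factory=dict)  # node -> parent (root absent)
    children: dict = field(default_factory=dict)  # node -> list of children
    height: dict = field(default_factory=dict)  # node -> height above the tips
    root: object = None

    @property
    def tips(self) -> list:
        return [n for n in self.height if not self.children.get(n)]

    def branch_length(self, node) -> float:
        if node == self.root:
            return 0.0
        return self.height[self.parent[node]] - self.height[node]

    def total_length(self) -> float:
        return sum(self.branch_length(n) for n in self.height if n != self.root)

    def root_path(self, node) -> list:
        path = [node]
        while path[-1] != self.root:
            path.append(self.parent[path[-1]])
        return path

    def subtree_length(self, tips, include_root: bool = True) -> float:
        """Total branch length of the minimal subtree joining *tips* (+ root)."""
        tips = list(tips)
        if not tips:
            raise ValueError("empty tip set")
        paths = [self.root_path(t) for t in tips]
        nodes: set = set().union(*map(set, paths))
        total = sum(self.branch_length(n) for n in nodes if n != self.root)
        if not include_root:  # drop the spine above the MRCA of the set
            common = set(paths[0]).intersection(*map(set, paths[1:])) if len(paths) > 1 else {tips[0]}
            mrca = min(common, key=lambda n: self.height[n])
            total -= sum(self.branch_length(n) for n in self.root_path(mrca) if n != self.root)
        return total

    def mrca_height(self, a, b) -> float:
        pa = set(self.root_path(a))
        for n in self.root_path(b):
            if n in pa:
                return self.height[n]
        raise ValueError("disconnected tree")

    def cophenetic(self, tips=None) -> pd.DataFrame:
        """Pairwise tip-to-tip path distances (2 x MRCA height on ultrametric trees)."""
        tips = list(tips) if tips is not None else self.tips
        n = len(tips)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                hij = self.mrca_height(tips[i], tips[j])
                D[i, j] = D[j, i] = (hij - self.height[tips[i]]) + (hij - self.height[tips[j]])
        return pd.DataFrame(D, index=tips, columns=tips)

    def to_newick(self) -> str:
        def render(node):
            kids = self.children.get(node, [])
            label = str(node).replace(" ", "_")
            if not kids:
                return f"{label}:{self.branch_length(node):.10g}"
            inner = ",".join(render(c) for c in kids)
            bl = self.branch_length(node)
            return f"({inner}){label}:{bl:.10g}" if node != self.root else f"({inner}){label}"

        return render(self.root) + ";"


def taxonomy_tree(taxonomy: pd.DataFrame) -> Tree:
    """Rooted tree root -> family -> genus -> species from taxonomy labels.

    *taxonomy* needs columns species_id, genus, family.  Monotypic genera and
    families are kept as distinct internal nodes (they collapse to zero-length
    edges once Grafen heights are assigned, which is equivalent to collapsing
    the node); missing labels or duplicate species raise.
    """
    for col in ("species_id", "genus", "family"):
        if taxonomy[col].isna().any():
            bad = taxonomy.loc[taxonomy[col].isna(), "species_id"].tolist()
            raise ValueError(f"missing {col} for species: {bad}")
    if taxonomy["species_id"].duplicated().any():
        dup = taxonomy.loc[taxonomy["species_id"].duplicated(), "species_id"].tolist()
        raise ValueError(f"duplicate species ids: {dup}")
    tree = Tree(root="root")
    tree.children["root"] = []
    tree.height["root"] = 1.0
    for fam, fam_rows in taxonomy.groupby("family", sort=True):
        fnode = f"family:{fam}"
        tree.parent[fnode] = "root"
        tree.children["root"].append(fnode)
        tree.children[fnode] = []
        tree.height[fnode] = 0.0
        for gen, gen_rows in fam_rows.groupby("genus", sort=True):
            gnode = f"genus:{gen}"
            tree.parent[gnode] = fnode
            tree.children[fnode].append(gnode)
            tree.children[gnode] = []
            tree.height[gnode] = 0.0
            for sp in sorted(gen_rows["species_id"]):
                tree.parent[sp] = gnode
                tree.children[gnode].append(sp)
                tree.children[sp] = []
                tree.height[sp] = 0.0
    return tree


def _n_tips_below(tree: Tree, node, cache) -> int:
    if node in cache:
        return cache[node]
    kids = tree.children.get(node, [])
    n = 1 if not kids else sum(_n_tips_below(tree, k, cache) for k in kids)
    cache[node] = n
    return n


def grafen_lengths(tree: Tree, rho: float = 1.0) -> Tree:
    """Assign Grafen heights: ((#descendant tips - 1)/(#tips - 1))**rho.

    Tips sit at height 0 and the root at height 1, so the tree is ultrametric
    with all tip-to-root paths of length 1.
    """
    cache: dict = {}
    total = _n_tips_below(tree, tree.root, cache)
    if total < 2:
        raise ValueError("Grafen lengths need at least 2 tips")
    for node in tree.height:
        n = cache.get(node) or _n_tips_below(tree, node, cache)
        tree.height[node] = ((n - 1) / (total - 1)) ** rho if n > 1 else 0.0
    tree.height[tree.root] = 1.0
    return tree


def upgma_dendrogram(d: pd.DataFrame) -> Tree:
    """Average-linkage (UPGMA) dendrogram with merge heights = distance / 2.

    Ties in the minimal average distance are broken by the lexicographic pair
    of the smallest member ids of the candidate clusters, making the tree
    deterministic for any input.
    """
    ids = list(d.index)
    if len(ids) < 2:
        raise ValueError("need at least 2 species")
    D = {frozenset((a, b)): float(d.loc[a, b]) for a, b in itertools.combinations(ids, 2)}
    clusters = {i: (ids[i],) for i in range(len(ids))}  # cluster key -> member tips
    key_of = {i: i for i in range(len(ids))}
    dist = {}
    for (i, a), (j, b) in itertools.combinations(enumerate(ids), 2):
        dist[(i, j)] = D[frozenset((a, b))]

    tree = Tree()
    for sp in ids:
        tree.children[sp] = []
        tree.height[sp] = 0.0
    sizes = {i: 1 for i in range(len(ids))}
    node_of = {i: ids[i] for i in range(len(ids))}
    next_internal = 0
    active = set(range(len(ids)))
    last = None
    while len(active) > 1:
        best = None
        for i, j in itertools.combinations(sorted(active), 2):
            dij = dist[(min(i, j), max(i, j))]
            tiebreak = tuple(sorted((min(clusters[i]), min(clusters[j]))))
            if best is None or (dij, tiebreak) < (best[0], best[1]):
                best = (dij, tiebreak, i, j)
        dij, _, i, j = best
        name = f"node{next_internal}"
        next_internal += 1
        for k in (i, j):
            child = node_of[k]
            tree.parent[child] = name
        tree.children[name] = [node_of[i], node_of[j]]
        tree.height[name] = dij / 2.0
        new = max(active) + 1
        clusters[new] = clusters[i] + clusters[j]
        sizes[new] = sizes[i] + sizes[j]
        node_of[new] = name
        for k in active - {i, j}:
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dist[(min(new, k), max(new, k))] = (sizes[i] * dik + sizes[j] * djk) / sizes[new]
        active -= {i, j}
        active.add(new)
        last = name
    tree.root = last
    return tree


def minimum_spanning_tree(coords: pd.DataFrame) -> list[tuple]:
    """Euclidean MST over species coordinates (Prim, deterministic tie-break).

    Returns ``[(id_a, id_b, length), ...]`` with n-1 edges; among equal-length
    candidate edges the one with the lexicographically smallest
    (min id, max id) pair is chosen.
    """
    ids = list(coords.index)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 points")
    x = coords.to_numpy(dtype=float)
    diff = x[:, None, :] - x[None, :, :]
    D = np.sqrt((diff**2).sum(axis=-1))
    in_tree = [0]
    out = set(range(1, n))
    edges = []
    while out:
        best = None
        for i in in_tree:
            for j in out:
                a, b = sorted((ids[i], ids[j]))
                cand = (D[i, j], a, b, i, j)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        length, _, _, i, j = best
        edges.append((ids[i], ids[j], float(length)))
        in_tree.append(j)
        out.discard(j)
    return edges
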