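"""Rarity-weighted co-ancestry matrix, clustering, and sibling detection.

This is a documented simplified analogue of chromosome-painting co-ancestry:
for each SNP the pairwise similarity is the fraction of allele copies two
samples share, and SNPs are weighted by the rarity of their minor allele
(w_j = -log p_j), so rare shared alleles — the signature of recent shared
ancestry such as sibship or hybridization — dominate the matrix.  Average-
linkage hierarchical clustering over 1 - C provides the dendrogram used for
hybrid placement, and sibling groups are pairs whose co-ancestry exceeds the
within-group mean by a configurable number of standard deviations, merged by
transitive closure and corroborated by shared collection site and shared
mtDNA haplotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .genotypes import GenotypeMatrix

logger = logging.getLogger("vetkey")


@dataclass
class CoancestryMatrix:
    C: np.ndarray                      # samples x samples similarity in [0, 1]
    sample_ids: list[str]
    linkage: np.ndarray | None = None  # scipy linkage over 1 - C
    group_means: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if C.shape[0] != C.shape[1] or C.shape[0] != len(self.sample_ids):
            raise ValueError("C must be square and match sample_ids")
        finite = np.isfinite(C)
        if not np.allclose(np.where(finite, C, 0.0), np.where(finite.T, C.T, 0.0), atol=1e-10):
            raise ValueError("C must be symmetric")
        self.C = C

    def index_of(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def pair(self, a: str, b: str) -> float:
        return float(self.C[self.index_of(a), self.index_of(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.C, index=self.sample_ids, columns=self.sample_ids)

    def cophenetic(self) -> np.ndarray:
        if self.linkage is None:
            raise ValueError("no dendrogram computed")
        return squareform(hierarchy.cophenet(self.linkage))

    def to_newick(self) -> str:
        if self.linkage is None:
            raise ValueError("no dendrogram computed")
        tree = hierarchy.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return f"{self.sample_ids[node.id]}:{node.dist:.6f}"
            left, right = rec(node.get_left()), rec(node.get_right())
            return f"({left},{right}):{node.dist:.6f}"

        return f"({rec(tree.get_left())},{rec(tree.get_right())});"


@dataclass
class SiblingGroup:
    members: list[str]
    mean_coancestry: float
    shared_site: bool
    shared_haplotype: bool | None  # None when no haplotype table supplied
    confirmed: bool
    representative: str


@dataclass
class SiblingGroups:
    groups: list[SiblingGroup] = field(default_factory=list)

    def confirmed(self) -> list[SiblingGroup]:
        return [g for g in self.groups if g.confirmed]

    def all_members(self, confirmed_only: bool = False) -> set[str]:
        groups = self.confirmed() if confirmed_only else self.groups
        return {m for g in groups for m in g.members}


# ---------------------------------------------------------------------------
# Matrix construction
# ---------------------------------------------------------------------------

def coancestry_matrix(
    gm: GenotypeMatrix,
    groups: pd.Series | None = None,
    maf_floor: float = 1e-3,
) -> CoancestryMatrix:
    """Rarity-weighted allele-sharing matrix with average-linkage dendrogram.

    At SNP j with minor-allele frequency p_j the pairwise sharing between
    samples a, b is s_j(a,b) = 1 - |g_a - g_b| / 2 (fraction of allele copies
    shared, complete pairs only) and C(a,b) = sum_j w_j s_j / sum_j w_j with
    w_j = -log max(p_j, maf_floor).  Pairs with no jointly observed SNP get a
    NaN cell (flagged missing).
    """
    G = gm.values
    obs = (~np.isnan(G)).astype(float)
    p = gm.minor_allele_frequency()
    w = -np.log(np.clip(p, maf_floor, None))
    w = np.where(np.isnan(w) | (w <= 0), 0.0, w)

    # |g_a - g_b| via one-hot planes: sum_{x,y} |x-y| X_x W X_y^T
    planes = [np.where(obs.astype(bool) & (G == x), 1.0, 0.0) for x in (0.0, 1.0, 2.0)]
    diff = np.zeros((G.shape[0], G.shape[0]))
    for x in range(3):
        for y in range(3):
            c = abs(x - y)
            if c:
                diff += c * (planes[x] * w) @ planes[y].T
    denom = (obs * w) @ obs.T
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(denom > 0, 1.0 - diff / (2.0 * denom), np.nan)
    n_undefined = int(np.isnan(C).sum())
    if n_undefined:
        logger.warning("%d coancestry cells undefined (no jointly observed SNPs)", n_undefined)

    D = 1.0 - np.where(np.isnan(C), np.nanmin(C), C)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    link = hierarchy.linkage(squareform(D, checks=False), method="average")

    cm = CoancestryMatrix(C=C, sample_ids=list(gm.sample_ids), linkage=link)
    if groups is not None:
        cm.group_means = group_mean_coancestry(cm, groups)
    return cm


def group_mean_coancestry(cm: CoancestryMatrix, groups: pd.Series) -> pd.DataFrame:
    """Group x group average of C (off-diagonal pairs within a group)."""
    names = sorted(groups.dropna().unique())
    idx = {g: [i for i, s in enumerate(cm.sample_ids) if groups.get(s) == g] for g in names}
    out = pd.DataFrame(index=names, columns=names, dtype=float)
    for a in names:
        for b in names:
            block = cm.C[np.ix_(idx[a], idx[b])]
            if a == b:
                mask = ~np.eye(len(idx[a]), dtype=bool)
                vals = block[mask]
            else:
                vals = block.ravel()
            out.loc[a, b] = float(np.nanmean(vals)) if vals.size else np.nan
    return out


# ---------------------------------------------------------------------------
# Sibling detection
# ---------------------------------------------------------------------------

def detect_siblings(
    cm: CoancestryMatrix,
    meta: pd.DataFrame,
    haplotypes: pd.DataFrame | None = None,
    t_sd: float = 3.0,
) -> SiblingGroups:
    """Flag putative sibling groups from elevated pairwise co-ancestry.

    Candidate pairs are same-population pairs whose C exceeds that
    population's within-group mean by ``t_sd`` standard deviations; pairs are
    merged into groups by transitive closure.  A group is confirmed when all
    members share a collection site AND (when a haplotype table is supplied)
    one mtDNA haplotype; otherwise it is retained unconfirmed.  The
    representative is the lexicographically first member.

    ``meta`` needs columns sample_id, population, site; ``haplotypes`` (from
    haplotype collapsing) needs sample_id, haplotype.
    """
    required = {"sample_id", "population", "site"}
    if not required <= set(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    meta = meta.set_index("sample_id")
    missing_meta = [s for s in cm.sample_ids if s not in meta.index]
    if missing_meta:
        raise ValueError(f"metadata missing for samples: {missing_meta[:5]}")
    hap = None
    if haplotypes is not None:
        hap = haplotypes.set_index("sample_id")["haplotype"]

    n = len(cm.sample_ids)
    pops = meta.loc[cm.sample_ids, "population"].to_numpy()
    pairs: list[tuple[int, int]] = []
    for pop in pd.unique(pops):
        members = np.flatnonzero(pops == pop)
        if members.size < 2:
            continue
        block = cm.C[np.ix_(members, members)]
        tri = block[np.triu_indices(members.size, k=1)]
        tri = tri[~np.isnan(tri)]
        if tri.size < 2:
            continue
        cutoff = tri.mean() + t_sd * tri.std(ddof=1)
        for ai in range(members.size):
            for bi in range(ai + 1, members.size):
                c = block[ai, bi]
                if np.isfinite(c) and c > cutoff:
                    pairs.append((int(members[ai]), int(members[bi])))

    # transitive closure via union-find
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    clusters: dict[int, list[int]] = {}
    for a, b in pairs:
        clusters.setdefault(find(a), [])
    for i in range(n):
        r = find(i)
        if r in clusters:
            clusters[r].append(i)

    groups: list[SiblingGroup] = []
    for members_idx in clusters.values():
        if len(members_idx) < 2:
            continue
        ids = sorted(cm.sample_ids[i] for i in members_idx)
        block = cm.C[np.ix_(members_idx, members_idx)]
        tri = block[np.triu_indices(len(members_idx), k=1)]
        shared_site = meta.loc[ids, "site"].nunique() == 1
        if hap is None:
            shared_hap: bool | None = None
        elif all(s in hap.index for s in ids):
            shared_hap = hap.loc[ids].nunique() == 1
        else:
            shared_hap = None
        confirmed = shared_site and (shared_hap is not False)
        groups.append(SiblingGroup(
            members=ids,
            mean_coancestry=float(np.nanmean(tri)),
            shared_site=bool(shared_site),
            shared_haplotype=shared_hap,
            confirmed=bool(confirmed),
            representative=ids[0],
        ))
    groups.sort(key=lambda g: g.representative)
    return SiblingGroups(groups=groups)


def drop_to_representatives(gm: GenotypeMatrix, siblings: SiblingGroups,
                            confirmed_only: bool = False) -> GenotypeMatrix:
    """Remove all but one representative per sibling group."""
    groups = siblings.confirmed() if confirmed_only else siblings.groups
    drop = {m for g in groups for m in g.members if m != g.representative}
    keep = [s for s in gm.sample_ids if s not in drop]
    return gm.take_samples(keep)
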