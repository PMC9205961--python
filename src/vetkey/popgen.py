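"""Diversity and differentiation statistics, haplotype collapsing, haplogroups.

Nucleotide diversity follows the standard per-site definitions: for aligned
sequences it is the mean pairwise Hamming distance per comparable site
(pairwise deletion of gaps/Ns); for diploid SNP panels it is the unbiased
per-site expected heterozygosity 2p(1-p) * n/(n-1) averaged over the assayed
sites of a partition.  Between-group differentiation uses the Hudson-form
estimator PhiST = 1 - (mean within-group diversity) / (between-group
diversity), computed as a composite over all sites of the partition.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

logger = logging.getLogger("vetkey")

_VALID = frozenset("ACGT")


# ---------------------------------------------------------------------------
# Nucleotide diversity
# ---------------------------------------------------------------------------

def _seq_array(sequences: list[str]) -> np.ndarray:
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned to equal length")
    return np.array([list(s.upper()) for s in sequences])


def nucleotide_diversity_sequences(sequences: list[str]) -> float:
    """Mean pairwise Hamming differences per site (pairwise deletion)."""
    if len(sequences) < 2:
        raise ValueError("nucleotide diversity needs >= 2 sequences")
    arr = _seq_array(sequences)
    valid = np.isin(arr, list(_VALID))
    total = 0.0
    n_pairs = 0
    for i, j in itertools.combinations(range(arr.shape[0]), 2):
        ok = valid[i] & valid[j]
        sites = int(ok.sum())
        if sites == 0:
            continue
        total += float((arr[i, ok] != arr[j, ok]).sum()) / sites
        n_pairs += 1
    if n_pairs == 0:
        raise ValueError("no comparable site pairs")
    return total / n_pairs


def nucleotide_diversity_genotypes(gm: GenotypeMatrix, total_sites: int | None = None) -> float:
    """Per-site unbiased heterozygosity averaged over assayed sites.

    ``total_sites`` lets callers express pi per base pair of the surveyed
    loci rather than per variable site; default is the SNP count.
    """
    if gm.n_samples < 2:
        raise ValueError("nucleotide diversity needs >= 2 samples")
    obs = ~np.isnan(gm.values)
    n_alleles = 2.0 * obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(gm.values, axis=0) / n_alleles
        h = 2.0 * p * (1.0 - p) * n_alleles / (n_alleles - 1.0)
    h = h[n_alleles >= 2]
    denom = total_sites if total_sites is not None else h.size
    if denom == 0:
        return 0.0
    return float(np.nansum(h) / denom)


@dataclass
class DiversityTable:
    rows: pd.DataFrame = field(default_factory=pd.DataFrame)


def diversity_table(
    gm: GenotypeMatrix,
    groups: pd.Series,
    mtdna: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per group x partition nucleotide diversity (autosomal, Z, mtDNA)."""
    rows = []
    for partition in ("autosomal", "Z"):
        sub = gm.subset_partition(partition)
        if sub.n_snps == 0:
            continue
        for grp in sorted(groups.dropna().unique()):
            ids = [s for s in sub.sample_ids if groups.get(s) == grp]
            if len(ids) < 2:
                continue
            pi = nucleotide_diversity_genotypes(sub.take_samples(ids))
            rows.append({"group": grp, "partition": partition, "pi": pi,
                         "n": len(ids), "sites": sub.n_snps})
    if mtdna:
        for grp in sorted(groups.dropna().unique()):
            seqs = [mtdna[s] for s in mtdna if groups.get(s) == grp]
            if len(seqs) < 2:
                continue
            pi = nucleotide_diversity_sequences(seqs)
            rows.append({"group": grp, "partition": "mtDNA", "pi": pi,
                         "n": len(seqs), "sites": len(next(iter(mtdna.values())))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PhiST (Hudson-form, composite over sites)
# ---------------------------------------------------------------------------

def _within_between_sums(ga: np.ndarray, gb: np.ndarray) -> tuple[float, float]:
    """Composite within and between pairwise-difference sums for two dosage groups."""
    def within(g: np.ndarray) -> float:
        obs = ~np.isnan(g)
        n = 2.0 * obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.nansum(g, axis=0) / n
            h = 2.0 * p * (1.0 - p) * n / (n - 1.0)
        return float(np.nansum(h[n >= 2]))

    def freqs(g: np.ndarray) -> np.ndarray:
        obs = ~np.isnan(g)
        n = 2.0 * obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, np.nansum(g, axis=0) / n, np.nan)

    pa, pb = freqs(ga), freqs(gb)
    ok = ~np.isnan(pa) & ~np.isnan(pb)
    between = float(np.sum(pa[ok] * (1 - pb[ok]) + pb[ok] * (1 - pa[ok])))
    mean_within = 0.5 * (within(ga) + within(gb))
    return mean_within, between


def phi_st_genotypes(gm: GenotypeMatrix, groups: pd.Series) -> pd.DataFrame:
    """Pairwise Hudson-form PhiST between groups on a dosage partition.

    Negative raw estimates are clamped to 0 (raw value logged and reported in
    the ``raw`` column); a zero between-group diversity with positive within
    diversity is flagged undefined.
    """
    names = sorted(groups.dropna().unique())
    if len(names) < 2:
        raise ValueError("PhiST needs >= 2 groups")
    members = {g: [s for s in gm.sample_ids if groups.get(s) == g] for g in names}
    for g, ids in members.items():
        if len(ids) < 2:
            raise ValueError(f"group {g} has < 2 members")
    idx = {s: i for i, s in enumerate(gm.sample_ids)}
    rows = []
    for a, b in itertools.combinations(names, 2):
        ga = gm.values[[idx[s] for s in members[a]], :]
        gb = gm.values[[idx[s] for s in members[b]], :]
        w, btw = _within_between_sums(ga, gb)
        if btw == 0.0:
            if w > 0.0:
                logger.warning("PhiST %s vs %s undefined: zero between-group diversity", a, b)
                rows.append({"group_a": a, "group_b": b, "phi_st": np.nan,
                             "raw": np.nan, "undefined": True})
                continue
            raw = 0.0
        else:
            raw = 1.0 - w / btw
        clamped = max(raw, 0.0)
        if raw < 0:
            logger.info("PhiST %s vs %s raw estimate %.4g clamped to 0", a, b, raw)
        rows.append({"group_a": a, "group_b": b, "phi_st": clamped,
                     "raw": raw, "undefined": False})
    return pd.DataFrame(rows)


def phi_st_sequences(sequences: dict[str, str], groups: pd.Series) -> pd.DataFrame:
    """Pairwise Hudson-form PhiST from aligned sequences."""
    names = sorted(groups.dropna().unique())
    members = {g: [s for s in sequences if groups.get(s) == g] for g in names}
    for g, ids in members.items():
        if len(ids) < 2:
            raise ValueError(f"group {g} has < 2 members")

    def mean_pairwise(ids_a: list[str], ids_b: list[str] | None = None) -> float:
        arrs = {s: np.array(list(sequences[s].upper())) for s in set(ids_a) | set(ids_b or [])}
        pairs = (itertools.combinations(ids_a, 2) if ids_b is None
                 else itertools.product(ids_a, ids_b))
        total, n = 0.0, 0
        for i, j in pairs:
            ai, aj = arrs[i], arrs[j]
            ok = np.isin(ai, list(_VALID)) & np.isin(aj, list(_VALID))
            if not ok.any():
                continue
            total += float((ai[ok] != aj[ok]).sum()) / ok.sum()
            n += 1
        return total / n if n else 0.0

    rows = []
    for a, b in itertools.combinations(names, 2):
        w = 0.5 * (mean_pairwise(members[a]) + mean_pairwise(members[b]))
        btw = mean_pairwise(members[a], members[b])
        if btw == 0.0:
            if w > 0.0:
                rows.append({"group_a": a, "group_b": b, "phi_st": np.nan,
                             "raw": np.nan, "undefined": True})
                continue
            raw = 0.0
        else:
            raw = 1.0 - w / btw
        rows.append({"group_a": a, "group_b": b, "phi_st": max(raw, 0.0),
                     "raw": raw, "undefined": False})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Haplotypes
# ---------------------------------------------------------------------------

def collapse_haplotypes(sequences: dict[str, str],
                        groups: pd.Series | None = None) -> pd.DataFrame:
    """Exact-sequence haplotype collapsing after uppercasing.

    Identical sequences share one haplotype id; any sequence containing an
    ambiguity character is its own haplotype unless byte-identical to
    another.  Returns per-sample rows (sample_id, haplotype, group) — unique
    counts per group via :func:`haplotype_counts`.
    """
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) > 1:
        raise ValueError("sequences must be aligned to equal length")
    hap_ids: dict[str, str] = {}
    rows = []
    for sample in sorted(sequences):
        seq = sequences[sample].upper()
        if seq not in hap_ids:
            hap_ids[seq] = f"H{len(hap_ids) + 1:03d}"
        rows.append({"sample_id": sample, "haplotype": hap_ids[seq],
                     "group": groups.get(sample) if groups is not None else None})
    return pd.DataFrame(rows)


def haplotype_counts(table: pd.DataFrame) -> pd.Series:
    """Unique haplotype count per group (0 for groups absent from the table)."""
    return table.groupby("group")["haplotype"].nunique()


def assign_haplogroup(haplotype: str, references: dict[str, list[str]]) -> str:
    """Nearest-reference haplogroup by Hamming distance; ties -> unassigned."""
    if not references or not any(references.values()):
        raise ValueError("empty reference set")
    seq = np.array(list(haplotype.upper()))
    best: dict[str, int] = {}
    for group, refs in references.items():
        for ref in refs:
            r = np.array(list(ref.upper()))
            if r.size != seq.size:
                raise ValueError("reference and haplotype lengths differ")
            ok = np.isin(seq, list(_VALID)) & np.isin(r, list(_VALID))
            d = int((seq[ok] != r[ok]).sum())
            if group not in best or d < best[group]:
                best[group] = d
    ranked = sorted(best.items(), key=lambda kv: kv[1])
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return "unassigned"
    return ranked[0][0]


def assign_haplogroups(sequences: dict[str, str],
                       references: dict[str, list[str]]) -> pd.Series:
    return pd.Series({s: assign_haplogroup(seq, references)
                      for s, seq in sequences.items()}, name="haplogroup")
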