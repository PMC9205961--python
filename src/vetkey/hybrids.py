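"""Hybrid decision rules from assignment and co-ancestry matrices.

Two rules are applied and cross-tabulated.  The assignment rule calls a
sample hybrid when its summed ancestry to BOTH sides (the focal taxon and
the union of the other types) strictly exceeds a threshold (default 10%).
The co-ancestry rule calls a sample hybrid when its mean co-ancestry to each
parental reference group exceeds the between-group background mean AND its
dendrogram attachment lies outside both parental clades.  Assignment-based
calling is known to over-call under isolation-by-distance and retained
shared ancestry; the concordance report quantifies the disagreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coancestry import CoancestryMatrix
from .structure import AssignmentMatrix, combine_clusters

PURE_A = "pure-A"
PURE_B = "pure-B"
HYBRID_CALL = "hybrid"


@dataclass
class HybridCallReport:
    per_sample: pd.DataFrame
    summary: dict


def call_hybrids_assignment(
    am: AssignmentMatrix,
    group_map: dict[str, list[str]],
    threshold: float = 0.10,
) -> pd.DataFrame:
    """Threshold rule on combined ancestry fractions.

    ``group_map`` must define exactly two disjoint sides covering all
    clusters, e.g. {"mexican_duck": [...], "mallard": [...]}; a sample is
    hybrid iff its combined assignment to both sides is strictly greater than
    ``threshold``.  When bootstrap SEs are present, 95% confidence intervals
    are attached and samples whose second-side CI overlaps 0 are flagged
    low-confidence.
    """
    if len(group_map) != 2:
        raise ValueError("group_map must define exactly two sides")
    sides = list(group_map)
    members = [set(m) for m in group_map.values()]
    if members[0] & members[1]:
        raise ValueError("the two sides must be disjoint")
    combined = combine_clusters(am, group_map)
    qa, qb = combined.Q[:, 0], combined.Q[:, 1]
    call = np.where((qa > threshold) & (qb > threshold), HYBRID_CALL,
                    np.where(qa >= qb, PURE_A, PURE_B))
    df = pd.DataFrame({
        "sample_id": combined.sample_ids,
        f"q_{sides[0]}": qa,
        f"q_{sides[1]}": qb,
        "assignment_call": call,
    }).set_index("sample_id")
    if combined.SE is not None:
        se_a, se_b = combined.SE[:, 0], combined.SE[:, 1]
        df[f"se_{sides[0]}"] = se_a
        df[f"se_{sides[1]}"] = se_b
        df[f"ci_lo_{sides[1]}"] = qb - 1.96 * se_b
        df[f"ci_hi_{sides[1]}"] = qb + 1.96 * se_b
        df["low_confidence"] = df[f"ci_lo_{sides[1]}"] <= 0.0
    return df


def call_hybrids_coancestry(
    cm: CoancestryMatrix,
    reference_groups: dict[str, list[str]],
    populations: pd.Series | None = None,
    subgroups: dict[str, list[str]] | None = None,
    domestic_group: str | None = None,
    wild_group: str | None = None,
    whisker: float = 1.0,
) -> pd.DataFrame:
    """Co-ancestry + dendrogram-placement rule.

    ``reference_groups`` maps the two parental taxa to their purebred
    reference sample ids (>= 2 each).  A sample is hybrid iff (a) its mean
    co-ancestry to EACH parental group exceeds the between-group background
    mean (the grand mean of cross-group co-ancestry), and (b) its dendrogram
    attachment lies outside every parental clade: its merge height with each
    reference population clade exceeds that clade's internal maximum merge
    height.  ``populations`` (sample_id -> population) refines the clade test
    to the reference populations; without it each side is one clade.  When
    ``subgroups`` names a domestic and a wild reference subset, a
    feral-parent flag is set for hybrids whose co-ancestry to the domestic
    subset exceeds that to wild mallards.
    """
    if len(reference_groups) != 2:
        raise ValueError("need exactly two parental reference groups")
    for name, ids in reference_groups.items():
        if len(ids) < 2:
            raise ValueError(f"reference group {name} has < 2 members")
    names = list(reference_groups)
    idx = {s: i for i, s in enumerate(cm.sample_ids)}
    ref_idx = {g: np.array([idx[s] for s in ids]) for g, ids in reference_groups.items()}

    background = float(np.nanmean(cm.C[np.ix_(ref_idx[names[0]], ref_idx[names[1]])]))
    coph = cm.cophenetic()

    # clades = reference populations (or whole sides if no population labels)
    clades: list[np.ndarray] = []
    if populations is not None:
        for g in names:
            ids = reference_groups[g]
            pops = pd.Series([populations.get(s) for s in ids], index=ids)
            for _, members in pops.groupby(pops):
                ii = np.array([idx[s] for s in members.index])
                if ii.size >= 2:
                    clades.append(ii)
    else:
        clades = [ref_idx[g] for g in names]

    def core_height(c: np.ndarray) -> tuple[np.ndarray, float]:
        # trim straggler members (Tukey upper whisker on per-member merge
        # heights) so one outlying reference sample cannot widen the clade
        stats = np.array([np.median(coph[m, c[c != m]]) for m in c])
        q1, q3 = np.percentile(stats, [25, 75])
        keep = c[stats <= q3 + whisker * (q3 - q1)]
        if keep.size < 2:
            keep = c
        return keep, float(coph[np.ix_(keep, keep)].max())

    cores = [core_height(c) for c in clades]

    rows = []
    for s in cm.sample_ids:
        i = idx[s]
        mean_to = {}
        for g in names:
            others = ref_idx[g][ref_idx[g] != i]
            mean_to[g] = float(np.nanmean(cm.C[i, others]))
        elevated = all(mean_to[g] > background for g in names)
        outside = True
        for keep, h in cores:
            others = keep[keep != i]
            if others.size and float(np.median(coph[i, others])) <= h:
                outside = False
                break
        call = HYBRID_CALL if (elevated and outside) else (
            PURE_A if mean_to[names[0]] >= mean_to[names[1]] else PURE_B
        )
        feral = False
        if (call == HYBRID_CALL and subgroups is not None
                and domestic_group is not None and wild_group is not None):
            feral = _feral_flag(cm, i, subgroups, domestic_group, wild_group, idx)
        rows.append({"sample_id": s,
                     f"coancestry_{names[0]}": mean_to[names[0]],
                     f"coancestry_{names[1]}": mean_to[names[1]],
                     "background": background,
                     "outside_both_clades": bool(outside),
                     "coancestry_call": call,
                     "feral_parent_suspected": bool(feral)})
    return pd.DataFrame(rows).set_index("sample_id")


def _feral_flag(cm: CoancestryMatrix, i: int, subgroups: dict[str, list[str]],
                domestic: str, wild: str, idx: dict[str, int]) -> bool:
    dom_ids = [idx[s] for s in subgroups.get(domestic, []) if s in idx and idx[s] != i]
    wild_ids = [idx[s] for s in subgroups.get(wild, []) if s in idx and idx[s] != i]
    if not dom_ids or not wild_ids:
        return False
    return float(np.nanmean(cm.C[i, dom_ids])) > float(np.nanmean(cm.C[i, wild_ids]))


def concordance(calls_a: pd.Series, calls_b: pd.Series,
                regions: pd.Series | None = None) -> HybridCallReport:
    """Cross-tabulate two call vectors and list rule-specific hybrid calls."""
    if set(calls_a.index) != set(calls_b.index):
        raise ValueError("call vectors cover different sample sets")
    ids = calls_a.index
    calls_b = calls_b.reindex(ids)
    agree = calls_a == calls_b
    df = pd.DataFrame({"assignment_call": calls_a, "coancestry_call": calls_b,
                       "agree": agree})
    only_a = sorted(ids[(calls_a == HYBRID_CALL) & (calls_b != HYBRID_CALL)])
    only_b = sorted(ids[(calls_b == HYBRID_CALL) & (calls_a != HYBRID_CALL)])
    summary = {
        "n": int(len(ids)),
        "hybrids_assignment": int((calls_a == HYBRID_CALL).sum()),
        "hybrids_coancestry": int((calls_b == HYBRID_CALL).sum()),
        "hybrids_both": int(((calls_a == HYBRID_CALL) & (calls_b == HYBRID_CALL)).sum()),
        "only_assignment": only_a,
        "only_coancestry": only_b,
        "crosstab": (pd.crosstab(calls_a, calls_b) if len(ids) else pd.DataFrame()),
    }
    if regions is not None and len(ids):
        hyb = calls_a == HYBRID_CALL
        summary["per_region_assignment"] = (
            regions.reindex(ids)[hyb].value_counts().to_dict()
        )
    return HybridCallReport(per_sample=df, summary=summary)
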