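"""Ordinal plumage-trait schema, plumage scores, and cohort keys.

Each plumage trait is coded on an ordinal scale where 0 is the Mexican-duck
(null) state and the maximum is the mallard (alternative) state, with
intermediate levels on traits that vary continuously (e.g. percent green in
the head).  A specimen's plumage score (PS) is the sum of its ordinal scores
over the traits applicable to its sex-age cohort.  Keys map PS intervals to
classes per cohort; the Mexican-duck interval is [0, 4] in every cohort,
while the hybrid and mallard intervals are calibrated from a genetically
vetted reference panel.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

logger = logging.getLogger("vetkey")

COHORTS = ("MI", "MA", "FI", "FA")

MEXICAN_DUCK = "mexican_duck"
HYBRID = "hybrid"
MALLARD = "mallard"
HYBRID_MALLARD = "hybrid_mallard"

#: fixed upper PS bound of the Mexican-duck class, common to all cohorts
MEXICAN_DUCK_PS_MAX = 4


# ---------------------------------------------------------------------------
# Schema
# ---------------------------------------------------------------------------

@dataclass
class TraitDef:
    name: str
    kind: str  # plumage | structural | mass
    levels: list[tuple[int, str]] = field(default_factory=list)  # (ordinal, state)
    cohorts: frozenset[str] = frozenset(COHORTS)
    diagnostic_cohorts: frozenset[str] = frozenset()

    @property
    def max_ordinal(self) -> int:
        return max(o for o, _ in self.levels) if self.levels else 0


@dataclass
class TraitSchema:
    traits: list[TraitDef]

    def __post_init__(self) -> None:
        names = [t.name for t in self.traits]
        if len(set(names)) != len(names):
            raise ValueError("duplicate trait names in schema")
        for t in self.traits:
            if t.kind == "plumage":
                ordinals = sorted(o for o, _ in t.levels)
                if len(ordinals) < 2:
                    raise ValueError(f"plumage trait {t.name} needs >= 2 levels")
                if ordinals != list(range(len(ordinals))):
                    raise ValueError(
                        f"plumage trait {t.name}: ordinals must be consecutive from 0"
                    )
            if not t.cohorts <= set(COHORTS):
                raise ValueError(f"trait {t.name}: unknown cohorts {t.cohorts - set(COHORTS)}")

    def __getitem__(self, name: str) -> TraitDef:
        for t in self.traits:
            if t.name == name:
                return t
        raise KeyError(name)

    def plumage_traits(self, cohort: str | None = None) -> list[TraitDef]:
        out = [t for t in self.traits if t.kind == "plumage"]
        if cohort is not None:
            if cohort not in COHORTS:
                raise ValueError(f"unknown cohort {cohort!r}")
            out = [t for t in out if cohort in t.cohorts]
        return out

    def structural_traits(self) -> list[TraitDef]:
        return [t for t in self.traits if t.kind in ("structural", "mass")]

    def max_ps(self, cohort: str) -> int:
        return sum(t.max_ordinal for t in self.plumage_traits(cohort))


def load_trait_schema(path: str | None = None) -> TraitSchema:
    """Load a trait schema CSV; default is the packaged transcription."""
    if path is None:
        ref = importlib.resources.files("vetkey").joinpath("data/trait_schema.csv")
        df = pd.read_csv(str(ref))
    else:
        df = pd.read_csv(path)
    traits: list[TraitDef] = []
    for name, grp in df.groupby("trait", sort=False):
        kind = grp["kind"].iloc[0]
        cohorts = frozenset(str(grp["cohorts"].iloc[0]).split("|"))
        diag_raw = grp["diagnostic_cohorts"].iloc[0]
        diagnostic = (
            frozenset(str(diag_raw).split("|")) if pd.notna(diag_raw) and str(diag_raw) else frozenset()
        )
        levels = []
        if kind == "plumage":
            levels = [(int(r.ordinal), str(r.state)) for r in grp.itertuples()]
        traits.append(
            TraitDef(name=name, kind=kind, levels=levels, cohorts=cohorts,
                     diagnostic_cohorts=diagnostic)
        )
    return TraitSchema(traits=traits)


# ---------------------------------------------------------------------------
# Records and plumage scores
# ---------------------------------------------------------------------------

@dataclass
class PlumageScore:
    sample_id: str
    cohort: str
    ps: int
    traits_used: list[str]
    n_missing: int


def validate_record(record: pd.Series, schema: TraitSchema) -> None:
    cohort = record["cohort"]
    if cohort not in COHORTS:
        raise ValueError(f"sample {record.get('sample_id')}: unknown cohort {cohort!r}")
    for t in schema.plumage_traits():
        if t.name in record.index and pd.notna(record[t.name]):
            v = int(record[t.name])
            if not 0 <= v <= t.max_ordinal:
                raise ValueError(
                    f"sample {record.get('sample_id')}: trait {t.name} state {v} "
                    f"outside range 0..{t.max_ordinal}"
                )


def score_plumage(
    record: pd.Series,
    schema: TraitSchema,
    cohort_filtered: bool = False,
) -> PlumageScore:
    """Sum ordinal scores over the traits applicable to the record's cohort.

    Missing traits contribute 0 and are counted in ``n_missing`` (a bias
    toward the Mexican-duck class, made auditable by the count).  With
    ``cohort_filtered`` the sum is restricted to the cohort's diagnostic
    trait subset.
    """
    validate_record(record, schema)
    cohort = record["cohort"]
    traits = schema.plumage_traits(cohort)
    if cohort_filtered:
        traits = [t for t in traits if cohort in t.diagnostic_cohorts]
    total, used, n_missing = 0, [], 0
    for t in traits:
        v = record.get(t.name)
        if v is None or pd.isna(v):
            n_missing += 1
        else:
            total += int(v)
        used.append(t.name)
    return PlumageScore(
        sample_id=str(record["sample_id"]), cohort=cohort, ps=total,
        traits_used=used, n_missing=n_missing,
    )


def score_panel(records: pd.DataFrame, schema: TraitSchema,
                cohort_filtered: bool = False) -> pd.DataFrame:
    """Score every record; returns sample_id, cohort, ps, n_missing."""
    rows = []
    for _, rec in records.iterrows():
        s = score_plumage(rec, schema, cohort_filtered)
        rows.append({"sample_id": s.sample_id, "cohort": s.cohort,
                     "ps": s.ps, "n_missing": s.n_missing})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ordination and structural-trait tests
# ---------------------------------------------------------------------------

def plumage_pca(records: pd.DataFrame, schema: TraitSchema,
                n_components: int = 2) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Centered PCA over ordinal plumage columns; missing -> per-trait mean.

    Returns (scores, explained_variance_fraction, trait_names_used).
    All-missing traits are dropped with a warning.
    """
    if len(records) < 2:
        raise ValueError("plumage PCA needs at least 2 records")
    names = [t.name for t in schema.plumage_traits() if t.name in records.columns]
    X = records[names].to_numpy(dtype=float)
    keep = []
    for j, name in enumerate(names):
        col = X[:, j]
        if np.isnan(col).all():
            logger.warning("plumage trait %s all-missing; dropped from PCA", name)
            continue
        col[np.isnan(col)] = np.nanmean(col)
        keep.append(j)
    X = X[:, keep]
    used = [names[j] for j in keep]
    n_components = min(n_components, X.shape[0] - 1 if X.shape[0] > 1 else 1, X.shape[1])
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    evr = np.nan_to_num(pca.explained_variance_ratio_)
    return scores, evr, used


def structural_tests(
    records: pd.DataFrame,
    labels: pd.Series,
    schema: TraitSchema,
    alpha: float = 0.001,
) -> pd.DataFrame:
    """One-way ANOVA per structural/mass trait per cohort + pairwise t-tests.

    Returns rows: cohort, trait, F, p, significant, plus per-pair Welch
    comparisons at the same alpha.  Groups with fewer than 2 observations are
    excluded from the comparison (logged).
    """
    rows = []
    labels = labels.reindex(records.index)
    for cohort, sub in records.groupby("cohort"):
        lab = labels.loc[sub.index]
        for t in schema.structural_traits():
            if t.name not in sub.columns:
                continue
            groups, names = [], []
            for cls, vals in sub[t.name].groupby(lab):
                v = vals.dropna().to_numpy(dtype=float)
                if v.size < 2:
                    logger.info("cohort %s trait %s: group %s has <2 obs, excluded",
                                cohort, t.name, cls)
                    continue
                groups.append(v)
                names.append(cls)
            if len(groups) < 2:
                continue
            if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
                rows.append({"cohort": cohort, "trait": t.name, "comparison": "anova",
                             "F": np.nan, "p": np.nan, "significant": False,
                             "note": "constant trait"})
                continue
            F, p = stats.f_oneway(*groups)
            rows.append({"cohort": cohort, "trait": t.name, "comparison": "anova",
                         "F": float(F), "p": float(p), "significant": bool(p < alpha),
                         "note": ""})
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    tt, pp = stats.ttest_ind(groups[a], groups[b], equal_var=False)
                    rows.append({"cohort": cohort, "trait": t.name,
                                 "comparison": f"{names[a]} vs {names[b]}",
                                 "F": float(tt ** 2), "p": float(pp),
                                 "significant": bool(pp < alpha), "note": ""})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Diagnostic trait selection (LDA + forward leave-one-out search)
# ---------------------------------------------------------------------------

class _RidgeLda:
    """Gaussian LDA with a ridge-regularized pooled within-class covariance.

    The ridge keeps the discriminant defined when a trait perfectly separates
    the classes (zero within-class variance), where shrinkage estimators
    collapse to prior-only prediction.
    """

    def __init__(self, eps_scale: float = 1e-4):
        self.eps_scale = eps_scale

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_RidgeLda":
        self.classes_ = np.unique(y)
        n, p = X.shape
        W = np.zeros((p, p))
        self.means_, self.priors_ = {}, {}
        for c in self.classes_:
            Xc = X[y == c]
            self.means_[c] = Xc.mean(axis=0)
            self.priors_[c] = len(Xc) / n
            d = Xc - self.means_[c]
            W += d.T @ d
        W /= max(n - len(self.classes_), 1)
        eps = self.eps_scale * max(np.trace(np.cov(X.T, ddof=0).reshape(p, p)) / p, 1e-12)
        self.eps_ = eps
        self.W_inv_ = np.linalg.inv(W + eps * np.eye(p))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = []
        for c in self.classes_:
            mu = self.means_[c]
            a = self.W_inv_ @ mu
            scores.append(X @ a - 0.5 * mu @ a + np.log(self.priors_[c]))
        return self.classes_[np.argmax(np.column_stack(scores), axis=1)]


def _loo_accuracy(X: np.ndarray, y: np.ndarray) -> float:
    n = X.shape[0]
    correct = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            continue
        clf = _RidgeLda().fit(X[mask], y[mask])
        correct += int(clf.predict(X[i : i + 1])[0] == y[i])
    return correct / n


def select_diagnostic_traits(
    records: pd.DataFrame,
    labels: pd.Series,
    cohort: str,
    schema: TraitSchema,
) -> tuple[list[str], np.ndarray]:
    """Choose the plumage-trait subset that best separates genetic classes.

    A linear discriminant is fit on the cohort's ordinal traits; traits are
    ranked by absolute standardized loading and added greedily while
    leave-one-out accuracy improves (ties resolved toward fewer traits, then
    schema order).  Returns (selected trait names, discriminant axis over the
    full cohort trait set).
    """
    sub = records[records["cohort"] == cohort]
    y = labels.reindex(sub.index).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError(f"cohort {cohort}: need >= 2 genetic classes in reference records")
    names = [t.name for t in schema.plumage_traits(cohort) if t.name in sub.columns]
    X = sub[names].to_numpy(dtype=float)
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.isnan(col).any():
            col[np.isnan(col)] = np.nanmean(col) if not np.isnan(col).all() else 0.0

    # standardized loadings from a ridge LDA on all traits
    clf = _RidgeLda().fit(X, y)
    if clf.eps_ > 1e-3:
        logger.info("LDA within-class covariance regularized with epsilon %.3g", clf.eps_)
    axes = [clf.W_inv_ @ (clf.means_[a] - clf.means_[b])
            for ai, a in enumerate(clf.classes_) for b in clf.classes_[ai + 1:]]
    coefs = np.abs(np.vstack(axes)).max(axis=0)
    sd = X.std(axis=0)
    loading = coefs * np.where(sd > 0, sd, 0.0)
    # candidate preference under accuracy ties: higher loading, then schema order
    rank = {j: r for r, j in enumerate(
        sorted(range(len(names)), key=lambda j: (-loading[j], j)))}

    current: list[int] = []
    best_acc = -1.0
    remaining = list(range(len(names)))
    while remaining:
        trials = [(_loo_accuracy(X[:, current + [j]], y), j) for j in remaining]
        acc, j = max(trials, key=lambda t: (t[0], -rank[t[1]]))
        if acc <= best_acc + 1e-12:
            break  # no strict improvement: ties resolve toward fewer traits
        current.append(j)
        remaining.remove(j)
        best_acc = acc
        if best_acc >= 1.0:
            break
    selected = [names[j] for j in sorted(current)]  # schema order
    axis = axes[0] if len(axes) == 1 else np.vstack(axes)[
        np.abs(np.vstack(axes)).sum(axis=1).argmax()]
    return selected, axis


# ---------------------------------------------------------------------------
# Cohort keys
# ---------------------------------------------------------------------------

@dataclass
class CohortKey:
    cohort: str
    diagnostic_traits: list[str]
    intervals: dict[str, tuple[int, int]]  # class -> inclusive (lo, hi)
    calibration: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if MEXICAN_DUCK in self.intervals and self.intervals[MEXICAN_DUCK][1] != MEXICAN_DUCK_PS_MAX:
            raise ValueError("Mexican-duck interval upper bound must be 4")
        bounds = sorted(self.intervals.values())
        covered = []
        for lo, hi in bounds:
            covered.extend(range(lo, hi + 1))
        if covered != list(range(min(covered), max(covered) + 1)) or len(set(covered)) != len(covered):
            raise ValueError("key intervals must partition the PS range")

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort,
            "diagnostic_traits": self.diagnostic_traits,
            "intervals": {k: list(v) for k, v in self.intervals.items()},
            "calibration": {k: list(v) for k, v in self.calibration.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortKey":
        return cls(
            cohort=d["cohort"],
            diagnostic_traits=list(d["diagnostic_traits"]),
            intervals={k: (int(v[0]), int(v[1])) for k, v in d["intervals"].items()},
            calibration={k: (int(v[0]), int(v[1])) for k, v in d.get("calibration", {}).items()},
        )


def build_key(
    scores: pd.DataFrame,
    labels: pd.Series,
    cohort: str,
    schema: TraitSchema,
    diagnostic_traits: list[str] | None = None,
) -> CohortKey:
    """Calibrate one cohort's PS class intervals from a vetted reference panel.

    ``scores`` is the output of :func:`score_panel`; ``labels`` maps its index
    to genetic classes (mexican_duck | hybrid | mallard).  The Mexican-duck
    interval is fixed at [0, 4]; the hybrid interval extends to the observed
    hybrid maximum and the mallard interval covers the rest.  When observed
    hybrid and mallard ranges overlap the two are merged into a combined
    hybrid/mallard class.
    """
    sub = scores[scores["cohort"] == cohort]
    lab = labels.reindex(sub.index)
    max_ps = schema.max_ps(cohort)
    calibration: dict[str, tuple[int, int]] = {}
    for cls in (MEXICAN_DUCK, HYBRID, MALLARD):
        vals = sub.loc[lab == cls, "ps"]
        if len(vals):
            calibration[cls] = (int(vals.min()), int(vals.max()))
        else:
            logger.warning("cohort %s: reference class %s absent; key built without it",
                           cohort, cls)

    intervals: dict[str, tuple[int, int]] = {MEXICAN_DUCK: (0, MEXICAN_DUCK_PS_MAX)}
    have_h, have_m = HYBRID in calibration, MALLARD in calibration
    if have_h and have_m:
        h_lo, h_hi = calibration[HYBRID]
        m_lo, m_hi = calibration[MALLARD]
        if m_lo <= h_hi or h_hi <= MEXICAN_DUCK_PS_MAX or h_hi >= max_ps:
            # observed ranges overlap (or leave no room) -> merged class
            intervals[HYBRID_MALLARD] = (MEXICAN_DUCK_PS_MAX + 1, max_ps)
        else:
            intervals[HYBRID] = (MEXICAN_DUCK_PS_MAX + 1, h_hi)
            intervals[MALLARD] = (h_hi + 1, max_ps)
    elif have_h or have_m:
        cls = HYBRID if have_h else MALLARD
        intervals[cls] = (MEXICAN_DUCK_PS_MAX + 1, max_ps)
    else:
        intervals[HYBRID_MALLARD] = (MEXICAN_DUCK_PS_MAX + 1, max_ps)

    return CohortKey(cohort=cohort, intervals=intervals, calibration=calibration,
                     diagnostic_traits=diagnostic_traits or
                     [t.name for t in schema.plumage_traits(cohort)])


def classify(score: PlumageScore, key: CohortKey) -> str:
    """Map a plumage score to its key class (boundaries belong to the lower class)."""
    if score.cohort != key.cohort:
        raise ValueError(f"score cohort {score.cohort} does not match key cohort {key.cohort}")
    for cls, (lo, hi) in sorted(key.intervals.items(), key=lambda kv: kv[1][0]):
        if lo <= score.ps <= hi:
            return cls
    # PS above the calibrated range can only mean the top class
    top = max(key.intervals.items(), key=lambda kv: kv[1][1])
    return top[0]


def classify_panel(scores: pd.DataFrame, keys: dict[str, CohortKey]) -> pd.Series:
    out = {}
    for _, row in scores.iterrows():
        key = keys[row["cohort"]]
        s = PlumageScore(sample_id=row["sample_id"], cohort=row["cohort"],
                         ps=int(row["ps"]), traits_used=[], n_missing=0)
        out[row["sample_id"]] = classify(s, key)
    return pd.Series(out, name="predicted_class")


def evaluate_key(predictions: pd.Series, labels: pd.Series,
                 cohorts: pd.Series | None = None) -> dict:
    """Per-cohort/per-class accuracy and a confusion matrix.

    ``predictions`` and ``labels`` are indexed by sample id.  A merged
    hybrid/mallard prediction counts as correct for either parent class.
    """
    ids = predictions.index.intersection(labels.index)
    if len(ids) == 0:
        raise ValueError("no overlapping sample ids between predictions and labels")
    pred, lab = predictions.loc[ids], labels.loc[ids]
    correct = (pred == lab) | ((pred == HYBRID_MALLARD) & lab.isin([HYBRID, MALLARD]))
    result = {
        "accuracy": float(correct.mean()),
        "confusion": pd.crosstab(lab, pred, rownames=["true"], colnames=["predicted"]),
        "n": int(len(ids)),
    }
    if cohorts is not None:
        coh = cohorts.reindex(ids)
        result["per_cohort"] = {
            c: float(correct[coh == c].mean()) for c in sorted(coh.dropna().unique())
        }
    per_class = {c: float(correct[lab == c].mean()) for c in sorted(lab.unique())}
    result["per_class"] = per_class
    return result


def reassess_specimens(
    historical: pd.DataFrame,
    keys: dict[str, CohortKey],
    schema: TraitSchema,
    original_label_col: str = "original_label",
) -> pd.DataFrame:
    """Re-classify historical specimens with the calibrated keys.

    Input rows need trait columns, ``cohort`` and the original label.  Rows
    whose cohort has no key are skipped with a log message.  Returns
    per-specimen original vs key class plus the PS used.
    """
    rows = []
    for _, rec in historical.iterrows():
        cohort = rec.get("cohort")
        if cohort not in keys:
            logger.info("specimen %s skipped: no key for cohort %r",
                        rec.get("sample_id"), cohort)
            continue
        s = score_plumage(rec, schema)
        rows.append({
            "sample_id": s.sample_id,
            "cohort": cohort,
            "ps": s.ps,
            "original_label": rec[original_label_col],
            "key_class": classify(s, keys[cohort]),
        })
    return pd.DataFrame(rows,
                        columns=["sample_id", "cohort", "ps", "original_label", "key_class"])


def save_keys(keys: dict[str, CohortKey], path: str) -> None:
    with open(path, "w") as fh:
        json.dump({c: k.to_dict() for c, k in keys.items()}, fh, indent=2)


def load_keys(path: str) -> dict[str, CohortKey]:
    with open(path) as fh:
        raw = json.load(fh)
    return {c: CohortKey.from_dict(d) for c, d in raw.items()}
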