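"""Synthetic panels with the statistical structure of a two-species duck study.

Genotypes follow a Balding-Nichols drift model: each SNP has an ancestral
allele frequency drawn from Uniform(0.05, 0.95), and each population draws
its own frequency from a Beta distribution centered on the (possibly
admixed) base frequency with drift parameter F.  Diploid genotypes are two
binomial allele draws; F1 hybrids take one allele per SNP from each parental
frequency vector, first-generation backcrosses mix gametes 75/25, and
sibling groups are Mendelian offspring of two sampled parents.  Mitochondrial
control-region haplotypes fall into two divergent haplogroups (Old World A /
New World B) and are maternally inherited.  Trait records follow per-cohort
categorical distributions over the ordinal plumage states, including the
naturally occurring mallard-like variant expression of immature male
Mexican ducks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import AUTOSOMAL, Z_CHROM, GenotypeMatrix
from .morphology import (
    COHORTS,
    HYBRID,
    MALLARD,
    MEXICAN_DUCK,
    MEXICAN_DUCK_PS_MAX,
    TraitSchema,
    load_trait_schema,
)

OW_A = "OW-A"
NW_B = "NW-B"

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PopSpec:
    """One source population.

    ``F`` is the Balding-Nichols drift parameter in (0, 1); F -> 0 means no
    drift from the base frequency.  ``mix`` optionally makes the base
    frequency a weighted mixture of previously defined populations'
    frequencies (emulating shared ancestry / isolation-by-distance) instead
    of the panel-wide ancestral frequency.
    """

    name: str
    n_samples: int
    F: float
    mix: dict[str, float] | None = None
    n_sites: int = 5
    haplogroup_probs: dict[str, float] | None = None
    trait_class: str | None = None  # mexican_duck | mallard; inferred from name if None


@dataclass
class HybridSpec:
    parent_a: str
    parent_b: str
    generation: str  # F1 | BC1 (backcross toward parent_a)
    n: int
    maternal_parent: str


@dataclass
class SiblingSpec:
    population: str
    n_groups: int
    group_size: int


@dataclass
class MtdnaConfig:
    haplogroup_core_distance: int = 15
    within_group_mutation_rate: float = 1.5
    length: int = 625


@dataclass
class TraitModel:
    """Per-cohort categorical trait distributions, parameterized.

    ``variant_expression_prob`` is the probability that a genetically pure
    immature male Mexican duck expresses at least one mallard-like variant
    trait in formative plumage; ``ps_le4_fraction`` is the fraction of ALL
    pure immature males that stays at PS <= 4 (the complement is drawn from
    within the expressers and overflows into the hybrid PS range).
    """

    variant_expression_prob: float = 0.25
    ps_le4_fraction: float = 0.97
    null_noise_prob: float = 0.10
    mallard_max_prob: float = 0.97
    hybrid_overlap: int = 0
    panel_sizes: dict[tuple[str, str], int] = field(default_factory=lambda: {
        (MEXICAN_DUCK, "MI"): 200, (MEXICAN_DUCK, "MA"): 80,
        (MEXICAN_DUCK, "FI"): 80, (MEXICAN_DUCK, "FA"): 80,
        (MALLARD, "MI"): 60, (MALLARD, "MA"): 60,
        (MALLARD, "FI"): 60, (MALLARD, "FA"): 60,
        (HYBRID, "MI"): 30, (HYBRID, "MA"): 30,
        (HYBRID, "FI"): 30, (HYBRID, "FA"): 30,
    })


@dataclass
class SimulationConfig:
    seed: int
    n_snps: int = 1500
    pop_specs: list[PopSpec] = field(default_factory=list)
    hybrid_specs: list[HybridSpec] = field(default_factory=list)
    sibling_specs: list[SiblingSpec] = field(default_factory=list)
    mtdna: MtdnaConfig = field(default_factory=MtdnaConfig)
    trait_model: TraitModel = field(default_factory=TraitModel)
    missing_rate: float = 0.02
    z_fraction: float = 0.055
    ancestral_low: float = 0.05
    ancestral_high: float = 0.95

    def __post_init__(self) -> None:
        names = [p.name for p in self.pop_specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate population names")
        seen: set[str] = set()
        for p in self.pop_specs:
            if not (0.0 <= p.F < 1.0):
                raise ValueError(f"population {p.name}: F must be in [0, 1)")
            if p.n_samples < 1:
                raise ValueError(f"population {p.name}: n_samples >= 1 required")
            if p.mix:
                unknown = set(p.mix) - seen
                if unknown:
                    raise ValueError(
                        f"population {p.name}: mix references undefined populations {unknown}"
                    )
                if abs(sum(p.mix.values()) - 1.0) > 1e-9:
                    raise ValueError(f"population {p.name}: mix weights must sum to 1")
            seen.add(p.name)
        for h in self.hybrid_specs:
            for parent in (h.parent_a, h.parent_b, h.maternal_parent):
                if parent not in seen:
                    raise ValueError(f"hybrid spec references unknown population {parent!r}")
            if h.generation not in ("F1", "BC1"):
                raise ValueError(f"unknown hybrid generation {h.generation!r}")
            if h.maternal_parent not in (h.parent_a, h.parent_b):
                raise ValueError("maternal_parent must be one of the two parents")
        for s in self.sibling_specs:
            if s.population not in seen:
                raise ValueError(f"sibling spec references unknown population {s.population!r}")
            if s.group_size < 2:
                raise ValueError("sibling groups need size >= 2")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.mtdna.haplogroup_core_distance < 1:
            raise ValueError("haplogroup core distance must be >= 1")
        for prob in (self.trait_model.variant_expression_prob,
                     self.trait_model.ps_le4_fraction,
                     self.trait_model.null_noise_prob,
                     self.trait_model.mallard_max_prob):
            if not (0.0 <= prob <= 1.0):
                raise ValueError("trait-model probabilities must lie in [0, 1]")


def default_config(seed: int = 0) -> SimulationConfig:
    """Desk-scale emulation of the study's cohorts.

    Six genetic clusters: three Mexican duck populations (a northern
    population sharing ancestry with wild mallards, an interior population,
    and a recently founded western-coast population), wild mallards, and two
    domestic lineages (game-farm and Khaki Campbell) with stronger drift.
    A few F1/BC1 hybrids and sibling groups mirror the study's findings.
    """
    pops = [
        PopSpec("wild_mallard", 40, 0.05,
                haplogroup_probs={OW_A: 0.31, NW_B: 0.69}, trait_class=MALLARD),
        PopSpec("medu_interior", 30, 0.05,
                haplogroup_probs={OW_A: 0.01, NW_B: 0.99}, trait_class=MEXICAN_DUCK),
        PopSpec("medu_north", 40, 0.02, mix={"medu_interior": 0.85, "wild_mallard": 0.15},
                haplogroup_probs={OW_A: 0.01, NW_B: 0.99}, trait_class=MEXICAN_DUCK),
        PopSpec("medu_westcoast", 20, 0.05, mix={"medu_north": 1.0},
                haplogroup_probs={OW_A: 0.01, NW_B: 0.99}, trait_class=MEXICAN_DUCK),
        PopSpec("game_farm", 20, 0.15,
                haplogroup_probs={OW_A: 1.0}, trait_class=MALLARD),
        PopSpec("khaki_campbell", 10, 0.18,
                haplogroup_probs={OW_A: 1.0}, trait_class=MALLARD),
    ]
    hybrids = [
        HybridSpec("medu_north", "wild_mallard", "F1", 4, maternal_parent="wild_mallard"),
        HybridSpec("medu_north", "khaki_campbell", "F1", 2, maternal_parent="khaki_campbell"),
        HybridSpec("medu_north", "wild_mallard", "BC1", 2, maternal_parent="medu_north"),
    ]
    siblings = [
        SiblingSpec("medu_north", n_groups=2, group_size=3),
        SiblingSpec("medu_interior", n_groups=1, group_size=2),
    ]
    return SimulationConfig(seed=seed, n_snps=6000, pop_specs=pops,
                            hybrid_specs=hybrids, sibling_specs=siblings)


# ---------------------------------------------------------------------------
# Sample roster (shared by all three generators)
# ---------------------------------------------------------------------------

def _trait_class(pop: PopSpec) -> str:
    if pop.trait_class is not None:
        return pop.trait_class
    name = pop.name.lower()
    if any(k in name for k in ("mall", "game", "khaki", "feral")):
        return MALLARD
    return MEXICAN_DUCK


def _default_haplogroup_probs(pop: PopSpec) -> dict[str, float]:
    if pop.haplogroup_probs is not None:
        return pop.haplogroup_probs
    name = pop.name.lower()
    if any(k in name for k in ("game", "khaki", "feral", "domestic")):
        return {OW_A: 1.0}
    if "mall" in name:
        return {OW_A: 0.31, NW_B: 0.69}
    return {OW_A: 0.01, NW_B: 0.99}


def build_roster(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic sample roster with truth labels and metadata.

    One row per simulated sample: sample_id, true_class, population (label of
    the genetic background; hybrids carry 'parentA x parentB'), sibling_group
    (or None), maternal_population, site, sex, age, cohort.
    """
    rng = np.random.default_rng([config.seed, 101])
    rows: list[dict] = []

    def cohort_draw() -> tuple[str, str, str]:
        cohort = str(rng.choice(COHORTS))
        return cohort, cohort[0], ("immature" if cohort[1] == "I" else "adult")

    for pop in config.pop_specs:
        for i in range(pop.n_samples):
            cohort, sex, age = cohort_draw()
            rows.append({
                "sample_id": f"{pop.name}_{i:03d}",
                "true_class": pop.name,
                "population": pop.name,
                "sibling_group": None,
                "maternal_population": pop.name,
                "site": f"{pop.name}_s{rng.integers(pop.n_sites)}",
                "sex": sex, "age": age, "cohort": cohort,
            })
    for h_idx, h in enumerate(config.hybrid_specs):
        pop_a = next(p for p in config.pop_specs if p.name == h.parent_a)
        for i in range(h.n):
            cohort, sex, age = cohort_draw()
            rows.append({
                "sample_id": f"{h.generation}_{h.parent_a}x{h.parent_b}_{h_idx}_{i:02d}",
                "true_class": h.generation,
                "population": f"{h.parent_a} x {h.parent_b}",
                "sibling_group": None,
                "maternal_population": h.maternal_parent,
                "site": f"{h.parent_a}_s{rng.integers(pop_a.n_sites)}",
                "sex": sex, "age": age, "cohort": cohort,
            })
    group_counter = 0
    for s in config.sibling_specs:
        pop = next(p for p in config.pop_specs if p.name == s.population)
        for g in range(s.n_groups):
            group_id = f"sib{group_counter:02d}"
            group_counter += 1
            site = f"{s.population}_s{rng.integers(pop.n_sites)}"
            for k in range(s.group_size):
                cohort, sex, age = cohort_draw()
                rows.append({
                    "sample_id": f"{s.population}_{group_id}_{k}",
                    "true_class": s.population,
                    "population": s.population,
                    "sibling_group": group_id,
                    "maternal_population": s.population,
                    "site": site,  # siblings share a collection event
                    "sex": sex, "age": age, "cohort": cohort,
                })
    roster = pd.DataFrame(rows)
    if roster["sample_id"].duplicated().any():
        raise AssertionError("duplicate sample ids in roster")
    return roster


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _population_frequencies(config: SimulationConfig, rng: np.random.Generator
                            ) -> dict[str, np.ndarray]:
    """Per-population allele-frequency vectors under Balding-Nichols drift."""
    p_anc = rng.uniform(config.ancestral_low, config.ancestral_high, config.n_snps)
    freqs: dict[str, np.ndarray] = {}
    for pop in config.pop_specs:
        if pop.mix:
            base = np.zeros(config.n_snps)
            for src, w in pop.mix.items():
                base += w * freqs[src]
        else:
            base = p_anc
        if pop.F <= 0.0:
            freqs[pop.name] = base.copy()
        else:
            shape = (1.0 - pop.F) / pop.F
            a = np.clip(base * shape, 1e-6, None)
            b = np.clip((1.0 - base) * shape, 1e-6, None)
            freqs[pop.name] = np.clip(rng.beta(a, b), 1e-4, 1.0 - 1e-4)
    return freqs


def simulate_genotypes(config: SimulationConfig
                       ) -> tuple[GenotypeMatrix, pd.DataFrame, dict[str, np.ndarray]]:
    """Simulate the SNP panel.

    Returns the genotype matrix, the truth roster, and the realized
    per-population allele-frequency vectors (useful as an oracle for
    differentiation statistics).
    """
    roster = build_roster(config)
    rng = np.random.default_rng([config.seed, 202])
    freqs = _population_frequencies(config, rng)
    n, J = len(roster), config.n_snps
    values = np.empty((n, J))

    # parents for sibling groups are drawn once per group
    sib_parents: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for group_id, grp in roster[roster["sibling_group"].notna()].groupby("sibling_group"):
        p = freqs[grp["population"].iloc[0]]
        sib_parents[group_id] = (rng.binomial(2, p), rng.binomial(2, p))

    hybrid_lookup = {}
    for h_idx, h in enumerate(config.hybrid_specs):
        hybrid_lookup[(h.generation, h.parent_a, h.parent_b, h_idx)] = h

    for i, row in enumerate(roster.itertuples()):
        if row.sibling_group is not None:
            mg, fg = sib_parents[row.sibling_group]
            values[i] = rng.binomial(1, mg / 2.0) + rng.binomial(1, fg / 2.0)
        elif row.true_class == "F1":
            a, b = row.population.split(" x ")
            values[i] = rng.binomial(1, freqs[a]) + rng.binomial(1, freqs[b])
        elif row.true_class == "BC1":
            a, b = row.population.split(" x ")
            # gamete from the recurrent parent + gamete from an F1 (50/50 origin)
            from_a = rng.binomial(1, freqs[a])
            origin_b = rng.random(J) < 0.5
            f1_gamete = np.where(origin_b, rng.binomial(1, freqs[b]),
                                 rng.binomial(1, freqs[a]))
            values[i] = from_a + f1_gamete
        else:
            values[i] = rng.binomial(2, freqs[row.population])

    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values[mask] = np.nan

    n_z = int(round(config.z_fraction * J))
    chrom = np.array([AUTOSOMAL] * J, dtype=object)
    if n_z:
        chrom[rng.choice(J, size=n_z, replace=False)] = Z_CHROM
    meta = pd.DataFrame({
        "locus": [f"L{j // 4:05d}" for j in range(J)],
        "position": [j % 4 for j in range(J)],
        "chrom_class": chrom,
    })
    gm = GenotypeMatrix(values=values, sample_ids=list(roster["sample_id"]), snp_meta=meta)
    return gm, roster, freqs


# ---------------------------------------------------------------------------
# mtDNA
# ---------------------------------------------------------------------------

def _mutate(seq: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    for pos in positions:
        choices = _BASES[_BASES != out[pos]]
        out[pos] = rng.choice(choices)
    return out


def simulate_mtdna(config: SimulationConfig, roster: pd.DataFrame | None = None
                   ) -> tuple[dict[str, str], pd.DataFrame]:
    """Aligned control-region haplotypes with maternal inheritance.

    Two core sequences separated by the configured number of substitutions
    define the OW-A and NW-B haplogroups.  Each maternal lineage (one per
    independent sample, one per sibling group) adds Poisson-distributed
    private mutations to its haplogroup core.  Hybrids inherit the maternal
    parent's haplotype process; siblings share one haplotype.

    Returns (sample_id -> sequence, roster with a ``haplogroup`` column).
    """
    if roster is None:
        roster = build_roster(config)
    rng = np.random.default_rng([config.seed, 303])
    L = config.mtdna.length
    core_a = rng.choice(_BASES, size=L)
    diff_pos = rng.choice(L, size=config.mtdna.haplogroup_core_distance, replace=False)
    core_b = _mutate(core_a, diff_pos, rng)
    cores = {OW_A: core_a, NW_B: core_b}
    hap_probs = {p.name: _default_haplogroup_probs(p) for p in config.pop_specs}

    def lineage_haplotype(maternal_pop: str) -> tuple[str, str]:
        probs = hap_probs[maternal_pop]
        groups = sorted(probs)
        hg = str(rng.choice(groups, p=[probs[g] for g in groups]))
        n_mut = rng.poisson(config.mtdna.within_group_mutation_rate)
        seq = cores[hg]
        if n_mut:
            seq = _mutate(seq, rng.choice(L, size=min(n_mut, L), replace=False), rng)
        return hg, "".join(seq)

    sequences: dict[str, str] = {}
    haplogroups: dict[str, str] = {}
    sib_hap: dict[str, tuple[str, str]] = {}
    for row in roster.itertuples():
        if row.sibling_group is not None:
            if row.sibling_group not in sib_hap:
                sib_hap[row.sibling_group] = lineage_haplotype(row.maternal_population)
            hg, seq = sib_hap[row.sibling_group]
        else:
            hg, seq = lineage_haplotype(row.maternal_population)
        sequences[row.sample_id] = seq
        haplogroups[row.sample_id] = hg
    roster = roster.copy()
    roster["haplogroup"] = roster["sample_id"].map(haplogroups)
    return sequences, roster


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

#: mallard-like traits transiently expressed by immature male Mexican ducks
#: (level cap per trait; percent green capped at the <=25% level, tail curl
#: at partial)
_VARIANT_TRAITS = {
    "percent_green_in_head": 1,
    "back_pattern_color": 1,
    "rump": 2,
    "flank_feather_pattern": 1,
    "undertail_covert_pattern": 2,
    "central_tail_feather_curl": 1,
}

_STRUCTURAL_MODEL = {
    # trait -> (base, sd, per-class adult offsets)
    "bill_length": (55.0, 2.0, {}),
    "bill_width": (22.0, 1.0, {}),
    "central_tail_feather_length": (90.0, 4.0, {}),
    "culmen_nares": (38.0, 1.5, {}),
    "tarsus_length": (44.0, 1.0, {MALLARD: 2.5, HYBRID: 1.2}),
    "wing_arc": (272.0, 4.0, {MALLARD: 9.0, HYBRID: 4.5}),
    "mass": (950.0, 55.0, {MALLARD: 210.0, HYBRID: 105.0}),
}


def _variant_bundle(rng: np.random.Generator, schema: TraitSchema, cohort: str,
                    target: int) -> dict[str, int]:
    applicable = [(t, cap) for t, cap in _VARIANT_TRAITS.items()
                  if cohort in schema[t].cohorts]
    order = rng.permutation(len(applicable))
    values: dict[str, int] = {}
    remaining = target
    for idx in order:
        if remaining <= 0:
            break
        name, cap = applicable[idx]
        level = int(min(cap, remaining)) if cap == 1 else int(rng.integers(1, min(cap, remaining) + 1))
        values[name] = level
        remaining -= level
    return values


def _draw_traits(rng: np.random.Generator, cls: str, cohort: str,
                 schema: TraitSchema, tm: TraitModel) -> dict[str, int]:
    traits = schema.plumage_traits(cohort)
    values = {t.name: 0 for t in traits}
    if cls == MEXICAN_DUCK:
        expressed = False
        if cohort == "MI":
            u = rng.random()
            overflow = 1.0 - tm.ps_le4_fraction
            if u < overflow:
                target = int(rng.integers(MEXICAN_DUCK_PS_MAX + 1, MEXICAN_DUCK_PS_MAX + 4))
                values.update(_variant_bundle(rng, schema, cohort, target))
                expressed = True
            elif u < tm.variant_expression_prob:
                target = int(rng.integers(2, MEXICAN_DUCK_PS_MAX + 1))
                values.update(_variant_bundle(rng, schema, cohort, target))
                expressed = True
        if not expressed and tm.null_noise_prob > 0 and rng.random() < tm.null_noise_prob:
            # background scoring noise; for immature males it must not touch the
            # variant traits, whose expression is governed by variant_expression_prob
            pool = traits
            if cohort == "MI":
                pool = [t for t in traits if t.name not in _VARIANT_TRAITS]
            pick = pool[rng.integers(len(pool))]
            values[pick.name] = 1
    elif cls == MALLARD:
        for t in traits:
            top = t.max_ordinal
            values[t.name] = top if rng.random() < tm.mallard_max_prob else max(top - 1, 0)
    elif cls == HYBRID:
        max_ps = schema.max_ps(cohort)
        lo = MEXICAN_DUCK_PS_MAX + 1 - tm.hybrid_overlap
        hi = max_ps - 3 + tm.hybrid_overlap
        for _ in range(200):
            for t in traits:
                if t.max_ordinal == 2:
                    values[t.name] = 1  # forced intermediate on 3-level traits
                elif t.max_ordinal > 2:
                    values[t.name] = int(rng.integers(1, t.max_ordinal))
                else:
                    values[t.name] = t.max_ordinal if rng.random() < 0.5 else 0
            if lo <= sum(values.values()) <= hi:
                break
        else:
            # deterministic fallback: forced intermediates plus binaries up to lo
            values = {t.name: (1 if t.max_ordinal >= 2 else 0) for t in traits}
            for t in traits:
                if sum(values.values()) >= lo:
                    break
                if t.max_ordinal == 1:
                    values[t.name] = 1
    else:
        raise ValueError(f"trait model covers no class {cls!r}")
    return values


def _structural_draw(rng: np.random.Generator, cls: str, cohort: str) -> dict[str, float]:
    sex_scale = 0.90 if cohort.startswith("F") else 1.0
    age_scale = 0.94 if cohort.endswith("I") else 1.0
    out = {}
    for name, (base, sd, offsets) in _STRUCTURAL_MODEL.items():
        mean = base
        if cohort.endswith("A"):  # class differences emerge in adults
            mean = base + offsets.get(cls, 0.0)
        scale = sex_scale * age_scale if name == "mass" else 1.0
        out[name] = float(rng.normal(mean * scale, sd))
    return out


def _roster_trait_class(true_class: str, config: SimulationConfig) -> str:
    if true_class in ("F1", "BC1"):
        return HYBRID
    pop = next(p for p in config.pop_specs if p.name == true_class)
    return _trait_class(pop)


def simulate_traits(config: SimulationConfig, roster: pd.DataFrame,
                    schema: TraitSchema | None = None) -> pd.DataFrame:
    """Trait records for the genetic roster (one record per sample)."""
    schema = schema or load_trait_schema()
    rng = np.random.default_rng([config.seed, 404])
    rows = []
    for row in roster.itertuples():
        cls = _roster_trait_class(row.true_class, config)
        if row.cohort not in COHORTS:
            raise ValueError(f"cohort {row.cohort!r} absent from schema cohorts")
        rec = {"sample_id": row.sample_id, "cohort": row.cohort,
               "sex": row.sex, "age": row.age, "true_trait_class": cls}
        rec.update(_draw_traits(rng, cls, row.cohort, schema, config.trait_model))
        rec.update(_structural_draw(rng, cls, row.cohort))
        rows.append(rec)
    return pd.DataFrame(rows)


def simulate_trait_panel(config: SimulationConfig,
                         schema: TraitSchema | None = None) -> pd.DataFrame:
    """Stand-alone calibration panel drawn from the trait model's panel sizes.

    Emulates the study's larger morphology panel (reference mallards from
    allopatric range plus vetted Mexican ducks and hybrids), labeled with
    ground truth for key calibration and evaluation.
    """
    schema = schema or load_trait_schema()
    rng = np.random.default_rng([config.seed, 505])
    rows = []
    counter = 0
    for (cls, cohort), n in sorted(config.trait_model.panel_sizes.items()):
        if cohort not in COHORTS:
            raise ValueError(f"cohort {cohort!r} absent from schema cohorts")
        for _ in range(n):
            rec = {"sample_id": f"ref_{cls}_{cohort}_{counter:04d}",
                   "cohort": cohort, "sex": cohort[0],
                   "age": "immature" if cohort[1] == "I" else "adult",
                   "true_trait_class": cls}
            rec.update(_draw_traits(rng, cls, cohort, schema, config.trait_model))
            rec.update(_structural_draw(rng, cls, cohort))
            rows.append(rec)
            counter += 1
    return pd.DataFrame(rows)
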