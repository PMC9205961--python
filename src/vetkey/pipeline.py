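"""End-to-end orchestration: simulate -> filter -> structure/co-ancestry ->
hybrid calls -> vetted labels -> cohort keys -> evaluation.

Every stochastic stage takes an explicit seed from the configuration, so a
rerun with the same config is byte-identical.  Each stage writes its outputs
under the run directory and records counts in the manifest; a failing stage
leaves the manifest with the completed stages marked ok so the run can be
resumed by re-invoking with the same output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coancestry as coan
from . import genotypes as geno
from . import hybrids as hyb
from . import morphology as morph
from . import popgen
from . import structure as struct
from . import synthetic as synth

logger = logging.getLogger("vetkey")


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "vetkey_run"
    # stage toggles
    run_structure: bool = True
    run_coancestry: bool = True
    run_popgen: bool = True
    run_morphology: bool = True
    # filter parameters
    maf_min: float = 0.005
    max_missing: float = 0.2
    ld_window: int = 2
    ld_step: int = 1
    r2_max: float = 0.5
    # structure parameters
    K: int = 6
    bootstrap_B: int = 10
    admixture_max_iter: int = 400
    # decision rules
    hybrid_threshold: float = 0.10
    t_sd: float = 3.0
    anova_alpha: float = 0.001
    simulation: synth.SimulationConfig | None = None

    def to_yaml(self, path: str) -> None:
        d = dataclasses.asdict(self)
        sim = d.get("simulation")
        if sim:
            sizes = sim.get("trait_model", {}).get("panel_sizes")
            if sizes:
                sim["trait_model"]["panel_sizes"] = {
                    "|".join(k): v for k, v in sizes.items()
                }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        sim = d.pop("simulation", None)
        cfg = cls(**{k: v for k, v in d.items() if k in {f.name for f in dataclasses.fields(cls)} - {"simulation"}})
        if sim is not None:
            sim = dict(sim)
            sim["pop_specs"] = [synth.PopSpec(**p) for p in sim.get("pop_specs", [])]
            sim["hybrid_specs"] = [synth.HybridSpec(**h) for h in sim.get("hybrid_specs", [])]
            sim["sibling_specs"] = [synth.SiblingSpec(**s) for s in sim.get("sibling_specs", [])]
            sim["mtdna"] = synth.MtdnaConfig(**sim.get("mtdna", {}))
            tm = sim.get("trait_model", {})
            if "panel_sizes" in tm:
                tm["panel_sizes"] = {tuple(k.split("|")): v for k, v in tm["panel_sizes"].items()}
            sim["trait_model"] = synth.TraitModel(**tm)
            cfg.simulation = synth.SimulationConfig(**sim)
        return cfg


def _class_labels(roster: pd.DataFrame, config: synth.SimulationConfig) -> pd.Series:
    """Genetic class per sample: mexican_duck / mallard / hybrid (generator truth)."""
    labels = {}
    for row in roster.itertuples():
        labels[row.sample_id] = synth._roster_trait_class(row.true_class, config)
    return pd.Series(labels)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic analysis; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation or synth.default_config(config.seed)
    manifest: dict = {"seed": config.seed, "stages": {}}

    # --- simulate -----------------------------------------------------------
    gm, roster, freqs = synth.simulate_genotypes(sim)
    sequences, roster = synth.simulate_mtdna(sim, roster)
    geno.write_genotype_csv(gm, str(out / "genotypes.csv"))
    geno.write_ped_map(gm, str(out / "genotypes"))
    roster.to_csv(out / "metadata.csv", index=False)
    with open(out / "mtdna.fasta", "w") as fh:
        for sample, seq in sequences.items():
            fh.write(f">{sample}\n{seq}\n")
    manifest["stages"]["simulate"] = {
        "status": "ok", "n_samples": gm.n_samples, "n_snps": gm.n_snps,
    }

    # --- filter (autosomal partition drives structure analyses) -------------
    auto = gm.subset_partition(geno.AUTOSOMAL)
    filtered, report = geno.filter_chain(
        auto, config.maf_min, config.max_missing,
        config.ld_window, config.ld_step, config.r2_max, seed=config.seed,
    )
    manifest["stages"]["filter"] = {
        "status": "ok", "input_snps": report.input_snps,
        "removed": report.removed, "retained": report.retained,
    }

    truth_class = _class_labels(roster, sim)
    pop_series = roster.set_index("sample_id")["population"]

    # --- co-ancestry, siblings, representative pruning ----------------------
    siblings = coan.SiblingGroups()
    cm = None
    if config.run_coancestry:
        hap_table = popgen.collapse_haplotypes(sequences, pop_series)
        cm = coan.coancestry_matrix(filtered, groups=pop_series)
        cm.to_frame().to_csv(out / "coancestry.csv")
        with open(out / "coancestry.nwk", "w") as fh:
            fh.write(cm.to_newick())
        siblings = coan.detect_siblings(
            cm, roster[["sample_id", "population", "site"]], hap_table, t_sd=config.t_sd,
        )
        manifest["stages"]["coancestry"] = {
            "status": "ok",
            "sibling_groups": len(siblings.groups),
            "sibling_samples": len(siblings.all_members()),
        }
    analysis_gm = coan.drop_to_representatives(filtered, siblings)
    analysis_ids = list(analysis_gm.sample_ids)

    # --- structure: PCA, admixture, bootstrap, hybrid calls -----------------
    calls_a = calls_c = None
    if config.run_structure:
        pc = struct.pca(analysis_gm)
        pd.DataFrame(pc.scores, index=analysis_ids).to_csv(out / "pca_scores.csv")
        am = struct.estimate_admixture(analysis_gm, config.K, seed=config.seed,
                                       max_iter=config.admixture_max_iter)
        am = struct.bootstrap_se(analysis_gm, config.K, B=config.bootstrap_B,
                                 seed=config.seed, max_iter=config.admixture_max_iter,
                                 point=am)
        am.to_frame().to_csv(out / "admixture_Q.csv")

        # map clusters to sides by the populations dominating them
        side_of = {
            pop: ("mallard" if synth._trait_class(p) == morph.MALLARD else "mexican_duck")
            for p in sim.pop_specs for pop in [p.name]
        }
        cluster_side = _dominant_side(am, pop_series, side_of)
        group_map = {"mexican_duck": [], "mallard": []}
        for lab, side in cluster_side.items():
            group_map[side].append(lab)
        if group_map["mexican_duck"] and group_map["mallard"]:
            calls_df = hyb.call_hybrids_assignment(am, group_map, config.hybrid_threshold)
            calls_a = calls_df["assignment_call"]
            calls_df.to_csv(out / "hybrid_calls_assignment.csv")
        manifest["stages"]["structure"] = {
            "status": "ok", "K": config.K,
            "log_likelihood": am.log_likelihood,
            "hybrids_assignment": int((calls_a == hyb.HYBRID_CALL).sum()) if calls_a is not None else None,
        }

    if config.run_coancestry and cm is not None:
        cm_analysis = coan.coancestry_matrix(analysis_gm, groups=pop_series)
        medu_ref = [s for s in analysis_ids
                    if truth_class.get(s) == morph.MEXICAN_DUCK]
        mall_ref = [s for s in analysis_ids
                    if truth_class.get(s) == morph.MALLARD]
        wild_ref = [s for s in mall_ref if "wild" in pop_series.get(s, "")]
        dom_ref = [s for s in mall_ref if s not in wild_ref]
        calls_df = hyb.call_hybrids_coancestry(
            cm_analysis,
            {"mexican_duck": medu_ref, "mallard": mall_ref},
            populations=pop_series,
            subgroups={"domestic": dom_ref, "wild": wild_ref},
            domestic_group="domestic", wild_group="wild",
        )
        calls_c = calls_df["coancestry_call"]
        calls_df.to_csv(out / "hybrid_calls_coancestry.csv")
        manifest["stages"]["hybrids_coancestry"] = {
            "status": "ok",
            "hybrids_coancestry": int((calls_c == hyb.HYBRID_CALL).sum()),
        }

    if calls_a is not None and calls_c is not None:
        report = hyb.concordance(calls_a, calls_c)
        manifest["stages"]["concordance"] = {
            "status": "ok",
            "hybrids_assignment": report.summary["hybrids_assignment"],
            "hybrids_coancestry": report.summary["hybrids_coancestry"],
            "hybrids_both": report.summary["hybrids_both"],
        }

    # --- popgen -------------------------------------------------------------
    if config.run_popgen:
        div = popgen.diversity_table(gm, pop_series, sequences)
        div.to_csv(out / "diversity.csv", index=False)
        phi_auto = popgen.phi_st_genotypes(gm.subset_partition(geno.AUTOSOMAL), pop_series)
        phi_auto.to_csv(out / "phi_st_autosomal.csv", index=False)
        manifest["stages"]["popgen"] = {"status": "ok", "groups": int(div["group"].nunique())}

    # --- morphology: keys calibrated on genetically vetted labels -----------
    if config.run_morphology:
        schema = morph.load_trait_schema()
        panel = synth.simulate_trait_panel(sim, schema)
        scores = morph.score_panel(panel, schema).set_index("sample_id")
        labels = panel.set_index("sample_id")["true_trait_class"]
        keys = {}
        for cohort in morph.COHORTS:
            keys[cohort] = morph.build_key(scores, labels, cohort, schema)
        morph.save_keys(keys, str(out / "keys.json"))
        preds = morph.classify_panel(scores.reset_index(), keys)
        evaluation = morph.evaluate_key(preds, labels, cohorts=scores["cohort"])
        manifest["stages"]["morphology"] = {
            "status": "ok",
            "accuracy": evaluation["accuracy"],
            "per_cohort": evaluation["per_cohort"],
            "mexican_duck_upper_bounds": {
                c: keys[c].intervals[morph.MEXICAN_DUCK][1] for c in morph.COHORTS
            },
        }

    manifest["n_analysis_samples"] = len(analysis_ids)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _dominant_side(am: "struct.AssignmentMatrix", pop_series: pd.Series,
                   side_of: dict[str, str]) -> dict[str, str]:
    """Assign each admixture cluster to a side by its highest-mean-Q population."""
    out = {}
    q = pd.DataFrame(am.Q, index=am.sample_ids, columns=am.cluster_labels)
    pops = pop_series.reindex(q.index)
    for lab in am.cluster_labels:
        means = q[lab].groupby(pops).mean()
        means = means[[p for p in means.index if p in side_of]]
        out[lab] = side_of[means.idxmax()] if len(means) else "mexican_duck"
    return out
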