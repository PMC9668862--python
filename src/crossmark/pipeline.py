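"""End-to-end orchestration: simulate or load cohorts, then run every
analysis stage in order with one global seed and a hashed output manifest.

Stage order mirrors the analysis workflow: community-ecology overview →
confounder variance decomposition → per-cohort differential + consensus
voting → signature tuning/fitting → study-to-study transfer + LODO →
disease-specificity screen → functional (KO) screens.  Reruns with the same
config and seed reproduce byte-identical outputs (the manifest records
content hashes so this is checkable).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ecology, confounders as conf_mod, differential as diff_mod
from . import signatures as sig_mod, functional as func_mod
from .profiles import CohortProfile, read_abundance_table, read_metadata_table, pool_profiles, write_profile
from .simulate import default_config, generate_cohorts, generate_ko_table


@dataclass
class PipelineConfig:
    out_dir: str = "crossmark_run"
    seed: int = 0
    # inputs: either simulate, or per-cohort table paths
    simulate_preset: str | None = "default"
    cohort_tables: dict = field(default_factory=dict)  # cohort_id -> abundance path
    metadata_table: str | None = None
    # thresholds
    alpha_taxa: float = 0.05
    alpha_ko: float = 0.01
    vote_hc: int = 3
    vote_ca: int = 2
    fc_hi: float = 5.0
    fc_lo: float = 0.2
    alpha_pathway: float = 0.1
    # rf
    rf_params: dict = field(default_factory=lambda: {"mtry": 1, "ntree": 400})
    tune: bool = False
    mtry_grid: list = field(default_factory=lambda: [1, 2, 3])
    ntree_grid: list = field(default_factory=lambda: [200, 400, 600])
    n_permutations: int = 999
    run_functional: bool = True
    run_specificity: bool = True

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = PipelineConfig(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not 0 < self.alpha_taxa <= 1 or not 0 < self.alpha_ko <= 1:
            raise ValueError("alpha thresholds must be in (0, 1]")
        if self.vote_hc < 2 or self.vote_ca < 2:
            raise ValueError("vote thresholds must be >= 2")
        for cid, path in self.cohort_tables.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"cohort {cid}: {path} not found")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_cohorts(config: PipelineConfig):
    if config.cohort_tables:
        md = read_metadata_table(config.metadata_table) if config.metadata_table else None
        profiles = []
        for cid, path in config.cohort_tables.items():
            p = read_abundance_table(path, cohort_id=cid)
            if md is not None:
                sub = md[md.get("cohort", cid) == cid] if "cohort" in md.columns else md
                p = CohortProfile(cid, p.abundance, sub.reindex(p.sample_ids))
            profiles.append(p)
        return profiles, None, None
    sim = default_config(seed=config.seed)
    profiles, truth = generate_cohorts(sim)
    return profiles, truth, sim


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run manifest (also written to
    ``out_dir/manifest.json``).  Any stage failure aborts with the stage name
    attached; files already written stay on disk."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}
    stage = "load"
    try:
        profiles, truth, sim = _load_cohorts(config)
        stage_files: list[Path] = []
        for p in profiles:
            ab = out / f"{p.cohort_id}_abundance.tsv"
            mdp = out / f"{p.cohort_id}_metadata.tsv"
            write_profile(p, ab, mdp)
            stage_files += [ab, mdp]
        manifest["stages"]["load"] = [f.name for f in stage_files]

        stage = "ecology"
        pooled = pool_profiles(profiles)
        alpha_rows = []
        for p in profiles:
            for sid, row in p.abundance.iterrows():
                alpha_rows.append({
                    "cohort": p.cohort_id, "sample_id": sid,
                    "group": p.metadata.loc[sid, "group"] if p.metadata is not None else "",
                    "shannon": ecology.shannon(row.to_numpy()),
                    "richness": ecology.richness(row.to_numpy()),
                })
        alpha_df = pd.DataFrame(alpha_rows)
        alpha_path = out / "alpha_diversity.tsv"
        alpha_df.to_csv(alpha_path, sep="\t", index=False)
        dm = ecology.bray_curtis(pooled)
        study = pooled.metadata["cohort"].to_numpy()
        perm = ecology.permanova(dm, study, n_perm=config.n_permutations, seed=config.seed)
        disp = ecology.betadisper(dm, study, n_perm=config.n_permutations, seed=config.seed)
        pcoa_res = ecology.pcoa(dm, k=2)
        eco_path = out / "ecology_overview.json"
        eco_path.write_text(json.dumps({
            "permanova_by_study": {"pseudo_F": perm.statistic, "p": perm.p_value},
            "betadisper_by_study": {"F": disp.statistic, "p": disp.p_value},
            "pcoa_proportion_explained": pcoa_res.proportion_explained[:2].tolist(),
        }, indent=1))
        manifest["stages"]["ecology"] = [alpha_path.name, eco_path.name]

        stage = "confounders"
        records = conf_mod.confounder_report(pooled)
        conf_path = out / "confounder_variance.tsv"
        conf_mod.report_to_frame(records).to_csv(conf_path, sep="\t", index=False)
        manifest["stages"]["confounders"] = [conf_path.name]

        stage = "differential"
        all_records = {"CRC_vs_HC": [], "CRC_vs_CA": []}
        for contrast in all_records:
            for p in profiles:
                try:
                    all_records[contrast] += diff_mod.cohort_differential(
                        p, contrast=contrast, alpha=config.alpha_taxa
                    )
                except ValueError:
                    warnings.warn(f"{p.cohort_id}: skipping {contrast} (missing group)")
        consensus = {
            "CRC_vs_HC": diff_mod.consensus_markers(all_records["CRC_vs_HC"], config.vote_hc),
            "CRC_vs_CA": diff_mod.consensus_markers(all_records["CRC_vs_CA"], config.vote_ca),
        }
        diff_files = []
        for contrast, recs in all_records.items():
            pth = out / f"differential_{contrast}.tsv"
            diff_mod.records_to_frame(recs).to_csv(pth, sep="\t", index=False)
            diff_files.append(pth)
        cons_path = out / "consensus_markers.tsv"
        diff_mod.markers_to_frame(
            consensus["CRC_vs_HC"] + consensus["CRC_vs_CA"]
        ).to_csv(cons_path, sep="\t", index=False)
        diff_files.append(cons_path)
        for contrast, markers in consensus.items():
            if not markers:
                warnings.warn(f"no consensus markers for {contrast} at current thresholds")
        manifest["stages"]["differential"] = [f.name for f in diff_files]

        stage = "signature"
        genera_hc = [m.taxon for m in consensus["CRC_vs_HC"]]
        sig_files = []
        results: dict = {}
        if genera_hc:
            train = profiles[0]
            rf_params = dict(config.rf_params)
            oob_grid: dict = {}
            if config.tune:
                rf_params, oob_grid = sig_mod.tune_rf(
                    train, genera_hc, "CRC_vs_HC",
                    config.mtry_grid, config.ntree_grid, seed=config.seed,
                )
            model = sig_mod.fit_signature(
                train, genera_hc, rf_params, "CRC_vs_HC",
                seed=config.seed, name="signature-HC", oob_grid=oob_grid,
            )
            rep = sig_mod.evaluate(model, train, "CRC_vs_HC")
            results["signature_hc"] = {
                "genera": genera_hc, "rf_params": rf_params,
                "train_cohort": train.cohort_id, "train_auc": rep.auc,
            }
            model_path = out / "signature_hc.pkl"
            model.save(model_path)

            stage = "transfer"
            tm = sig_mod.transfer_validation(
                profiles, genera_hc, "CRC_vs_HC", rf_params, seed=config.seed
            )
            lodo = sig_mod.lodo_validation(
                profiles, genera_hc, "CRC_vs_HC", rf_params, seed=config.seed
            )
            tm_path = out / "transfer_auc.tsv"
            tm.auc.to_csv(tm_path, sep="\t", index_label="train_cohort")
            lodo_path = out / "lodo_auc.tsv"
            lodo.to_csv(lodo_path, sep="\t", index_label="held_out_cohort")
            sig_files += [tm_path, lodo_path]
            results["transfer_mean_auc"] = float(
                tm.auc.where(~np.eye(len(tm.cohort_ids), dtype=bool)).stack().mean()
            )
            results["lodo_mean_auc"] = float(lodo.mean())

            if config.run_specificity:
                stage = "specificity"
                disease = _null_disease_profiles(config.seed)
                spec = sig_mod.specificity_screen(model, disease)
                spec_path = out / "specificity_auc.tsv"
                spec.to_csv(spec_path, sep="\t", index_label="disease_set")
                sig_files.append(spec_path)
                results["specificity_auc"] = spec.to_dict()
        else:
            warnings.warn("signature stage skipped: no consensus genera")
        sig_path = out / "signature_results.json"
        sig_path.write_text(json.dumps(results, indent=1))
        sig_files.append(sig_path)
        manifest["stages"]["signature"] = [f.name for f in sig_files]

        stage = "functional"
        func_files = []
        if config.run_functional and sim is not None:
            ko_tables = generate_ko_table(profiles, truth, sim)
            ko_records = []
            for p in profiles:
                fp = func_mod.FunctionalProfile(p.cohort_id, ko_tables[p.cohort_id], p.metadata)
                ko_records += func_mod.ko_differential(fp, "CRC_vs_HC", config.alpha_ko)
            ko_cons = func_mod.ko_consensus(ko_records, min_cohorts=config.vote_hc)
            ko_path = out / "ko_consensus.tsv"
            diff_mod.markers_to_frame(ko_cons).to_csv(ko_path, sep="\t", index=False)
            func_files.append(ko_path)
            if genera_hc and ko_cons:
                pooled_ko = pd.concat(
                    [ko_tables[p.cohort_id] for p in profiles]
                ).set_axis(pooled.abundance.index)
                edges = func_mod.marker_ko_network(
                    pooled.abundance[genera_hc],
                    pooled_ko[[m.taxon for m in ko_cons]],
                    alpha=0.05,
                    center_by=pooled.metadata["cohort"],
                )
                net_path = out / "marker_ko_network.tsv"
                func_mod.write_network(edges, tsv_path=net_path)
                func_files.append(net_path)
        manifest["stages"]["functional"] = [f.name for f in func_files]

        stage = "manifest"
        for f in sorted(out.iterdir()):
            if f.name != "manifest.json" and f.is_file():
                manifest["files"][f.name] = _sha256(f)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _null_disease_profiles(seed: int):
    """Synthetic other-disease cohorts with no CRC-marker shift: used by the
    specificity screen as a negative panel (expected AUC near 0.5)."""
    sim = default_config(
        seed=seed + 1000,
        markers=[], ko_links=[],
        n_cohorts=2,
        samples_per_group={"HC": 30, "CRC": 30},
    )
    profiles, _ = generate_cohorts(sim)
    out = []
    for i, p in enumerate(profiles):
        md = p.metadata.copy()
        md["group"] = md["group"].map({"HC": "control", "CRC": "disease"})
        out.append(CohortProfile(f"disease{i + 1}", p.abundance, md))
    return out
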