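"""End-to-end orchestration of the comparative EMT analysis.

``run_pipeline`` ties the stages together: module detection and eigengenes
for both time courses, EMT-module flagging against the seed list, cross-
dataset signature extraction, TF regulator inference with hub scoring,
cohort PEP staging, and survival stratification.  Every stage writes its
TSV/JSON artifacts into the run directory and a manifest records the
configuration hash and applied thresholds, so identical configurations
produce byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import coexpression as cx
from . import io as eio
from . import regnet as rn
from . import signature as sg
from . import staging as st
from . import survival as sv
from .containers import TimeSeriesMatrix, ValidationError

__all__ = ["PipelineConfig", "run_pipeline"]

STAGES = ("modules", "signature", "regnet", "pep", "survive")


@dataclass
class PipelineConfig:
    """Input paths, thresholds and mode switches for a full run."""

    timeseries_a: str = ""
    timeseries_b: str = ""
    seed_genes: str = ""
    regnet: str = ""
    cohort: str = ""
    survival: str = ""

    min_module_size: int = 30
    scale_free_target: float = 0.8
    soft_power: int | None = 6         # None -> pick by scale-free fit
    network_mode: str = "signed"
    r_emt: float = 0.9
    absolute_kme: bool = False
    top_k: int = 50
    p_tf: float = 0.05
    r_tf: float = 0.7
    min_cluster: int = 10
    reference_cluster: str = "h0-8"
    log_cohort: bool = True
    seed: int = 0
    skip: tuple = ()

    def validate(self) -> None:
        if not 0 < self.p_tf <= 1:
            raise ValidationError("p_tf must be in (0, 1]")
        for name in ("r_emt", "r_tf", "scale_free_target"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.min_module_size < 1 or self.top_k < 1:
            raise ValidationError("min_module_size and top_k must be >= 1")
        if self.network_mode not in ("signed", "unsigned"):
            raise ValidationError("network_mode must be 'signed' or 'unsigned'")
        unknown = set(self.skip) - set(STAGES)
        if unknown:
            raise ValidationError(f"unknown skip stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        if isinstance(cfg.skip, list):
            cfg.skip = tuple(cfg.skip)
        return cfg

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _detect(X: TimeSeriesMatrix, config: PipelineConfig):
    X = X.drop_zero_variance()
    corr = cx.correlation_matrix(X)
    if config.soft_power is None:
        report = cx.pick_soft_power(corr, target_fit=config.scale_free_target,
                                    mode=config.network_mode)
        beta = report.chosen_power
    else:
        report, beta = None, config.soft_power
    adj = cx.adjacency(corr, beta, mode=config.network_mode)
    tom = cx.tom_similarity(adj)
    part = cx.detect_modules(tom, min_size=config.min_module_size, expr=X)
    eig = cx.module_eigengenes(X, part)
    return X, part, eig, beta, report


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the configured stages; returns a manifest dict (also written
    to ``manifest.json`` in ``outdir``)."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.content_hash(),
        "stages_run": [],
        "artifacts": {},
        "thresholds": {
            "min_module_size": config.min_module_size,
            "scale_free_target": config.scale_free_target,
            "r_emt": config.r_emt,
            "top_k": config.top_k,
            "p_tf": config.p_tf,
            "r_tf": config.r_tf,
            "min_cluster": config.min_cluster,
        },
    }

    def save(df: pd.DataFrame, name: str, **kw):
        path = outdir / name
        df.to_csv(path, sep="\t", float_format="%.10g", **kw)
        manifest["artifacts"][name] = name
        return path

    def run_stage(name, fn):
        if name in config.skip:
            return None
        try:
            result = fn()
        except Exception as exc:
            manifest["failed_stage"] = name
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest["stages_run"].append(name)
        return result

    state: dict = {}

    def stage_modules():
        Xa = eio.read_timeseries_tsv(config.timeseries_a)
        Xb = eio.read_timeseries_tsv(config.timeseries_b)
        for tag, X in (("a", Xa), ("b", Xb)):
            X, part, eig, beta, report = _detect(X, config)
            state[f"X_{tag}"], state[f"part_{tag}"], state[f"eig_{tag}"] = X, part, eig
            save(part.assignment.to_frame(), f"modules_{tag}.tsv",
                 index_label="gene")
            prof = eig.profiles.copy()
            prof.columns = [f"{c:g}" for c in prof.columns]
            save(prof, f"eigengenes_{tag}.tsv", index_label="module")
            if report is not None:
                save(report.table, f"soft_power_{tag}.tsv", index=False)
            manifest.setdefault("soft_power", {})[tag] = beta

    def stage_signature():
        seeds = eio.read_gene_list(config.seed_genes)
        cands = {}
        for tag in ("a", "b"):
            X, eig = state[f"X_{tag}"], state[f"eig_{tag}"]
            seed_here = [g for g in seeds if g in X.gene_ids]
            mem = sg.module_membership(X, eig)
            flags = sg.flag_emt_modules(
                X.restrict(seed_here), eig,
                r_threshold=config.r_emt, absolute=config.absolute_kme,
            )
            cand = sg.top_membership_genes(mem, flags, k=config.top_k,
                                           absolute=config.absolute_kme)
            cands[tag] = cand
            save(flags, f"emt_flags_{tag}.tsv", index_label="module")
        signature = sg.intersect_signature(cands["a"], cands["b"])
        state["signature"] = signature
        save(signature.table, "signature.tsv", index=False)

    def stage_regnet():
        net = eio.read_regnet_tsv(config.regnet)
        regulators = rn.module_regulators(
            state["part_a"], state["eig_a"], net, state["X_a"],
            p_threshold=config.p_tf, r_threshold=config.r_tf,
        )
        save(regulators, "regulators.tsv", index=False)
        G = rn.tf_subnetwork(regulators, net)
        if G.number_of_nodes():
            hubs = rn.hub_scores(G)
            save(hubs.to_frame(), "hub_scores.tsv", index_label="node")
        state["regulators"] = regulators

    def stage_pep():
        cohort = eio.read_cohort_tsv(config.cohort)
        sig_genes = (state["signature"].genes if "signature" in state
                     else [g for g in cohort.gene_ids])
        profiles = st.stage_profiles(
            state["X_a"], [g for g in sig_genes if g in state["X_a"].gene_ids]
        )
        pep = st.assign_pep(cohort, profiles, log_transform=config.log_cohort)
        pep["pep_cluster"] = st.pool_pep_bins(pep["pep_hours"])
        state["pep"], state["cohort"] = pep, cohort
        save(pep, "pep.tsv", index_label="sample")

    def stage_survive():
        surv = eio.read_survival_tsv(config.survival)
        data = sv.make_survival_data(surv, state["pep"]["pep_cluster"])
        data = sv.filter_major_clusters(data, min_n=config.min_cluster,
                                        reference=config.reference_cluster)
        lr = sv.logrank_test(data)
        result = {"logrank": {"statistic": lr.statistic, "df": lr.df,
                              "p": lr.pvalue}}
        if config.reference_cluster in set(data["group"]):
            cox = sv.cox_hazard_ratios(data, reference=config.reference_cluster)
            result["cox"] = {
                "reference": cox.reference,
                "converged": cox.converged,
                "groups": cox.table.to_dict(orient="records"),
            }
        for g in sorted(set(data["group"])):
            save(sv.km_estimator(data, g), f"km_{g}.tsv", index=False)
        (outdir / "survival_tests.json").write_text(
            json.dumps(result, indent=2)
        )
        manifest["artifacts"]["survival_tests.json"] = "survival_tests.json"

    run_stage("modules", stage_modules)
    if "modules" not in config.skip:
        run_stage("signature", stage_signature)
        if config.regnet and "regnet" not in config.skip:
            run_stage("regnet", stage_regnet)
    if config.cohort and "pep" not in config.skip:
        run_stage("pep", stage_pep)
        if config.survival and "survive" not in config.skip:
            run_stage("survive", stage_survive)

    numeric = hashlib.sha256()
    for name in sorted(manifest["artifacts"]):
        numeric.update((outdir / name).read_bytes())
    manifest["output_hash"] = numeric.hexdigest()[:16]
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
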