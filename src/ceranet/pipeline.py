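"""End-to-end orchestration: simulate -> DE -> targets -> network -> topology
-> modules -> survival -> enrichment, with a run manifest.

Every stage can also be invoked standalone (see :mod:`ceranet.cli`); the
orchestrated run simply chains the same file-level contracts and records
per-stage row counts so the filtering funnel (candidates -> CLIP-retained ->
DE -> correlated -> shared-miRNA) is auditable. Identical config + seed give
identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import diffexpr, enrich, modules, network, survival, targets
from .matrix import ExpressionMatrix
from .simulate import SimConfig, read_dataset, simulate_cohort, write_dataset

log = logging.getLogger(__name__)

STAGES = ("simulate", "de", "targets", "network", "topology",
          "modules", "survival", "enrich")


@dataclass
class PipelineConfig:
    """Thresholds (defaults = the published values) plus paths and toggles."""

    out_dir: str = "ceranet_run"
    data_dir: str | None = None  # existing dataset; None => simulate stage
    pairs_path: str | None = None  # external pair table when 'targets' is disabled
    prefilter: float = 0.10
    zero_route: float = 0.30
    fc_up: float = 2.0
    fc_down: float = 0.5
    de_fdr: float = 0.01
    r_cut: float = 0.4
    corr_p: float = 0.01
    module_threshold: float = 0.6
    module_min_size: int = 3
    survival_alpha: float = 0.05
    seed: int = 0
    stages: tuple = STAGES
    sim: dict = field(default_factory=dict)  # SimConfig overrides

    def __post_init__(self):
        for name, lo, hi in (
            ("prefilter", 0, 1), ("zero_route", 0, 1), ("de_fdr", 0, 1),
            ("r_cut", 0, 1), ("corr_p", 0, 1), ("survival_alpha", 0, 1),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name} must be in [{lo}, {hi}], got {v}")
        if not 0 < self.module_threshold <= 1:
            raise ValueError("module_threshold must be in (0, 1]")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_all(config: PipelineConfig) -> dict:
    """Run the enabled stages in order and return the manifest."""
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "outputs": {},
                      "config": dataclasses.asdict(cfg)}
    (out / "resolved_config.json").write_text(
        json.dumps(dataclasses.asdict(cfg), indent=1, sort_keys=True, default=str)
    )
    state: dict = {}

    def done(stage, **counts):
        manifest["stages"][stage] = {"status": "complete", **counts}
        log.info("stage %s complete: %s", stage, counts)

    def save(name, df: pd.DataFrame):
        p = out / name
        df.to_csv(p, sep="\t", index=False)
        manifest["outputs"][name] = {"rows": int(len(df))}

    try:
        for stage in STAGES:
            if stage not in cfg.stages:
                manifest["stages"][stage] = {"status": "skipped"}
                continue
            _run_stage(stage, cfg, out, state, done, save)
    except Exception as exc:  # annotate and mark partial outputs
        stage = getattr(exc, "stage", "unknown")
        manifest["stages"].setdefault(stage, {})["status"] = "FAILED"
        manifest["stages"][stage]["error"] = str(exc)
        (out / "FAILED").write_text(f"{stage}: {exc}\n")
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True, default=str))
        raise
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return manifest


def _run_stage(stage, cfg, out, state, done, save):
    try:
        if stage == "simulate":
            if cfg.data_dir is not None:
                state["cohort"] = read_dataset(cfg.data_dir)
                done(stage, loaded_from=str(cfg.data_dir))
            else:
                sim_cfg = SimConfig(**{"seed": cfg.seed, **cfg.sim})
                state["cohort"] = simulate_cohort(sim_cfg)
                m = write_dataset(state["cohort"], out / "dataset")
                done(stage, files=len(m["files"]))
            state["expr"] = state["cohort"].combined

        elif stage == "de":
            de = diffexpr.call_differential_expression(
                state["expr"], prefilter=cfg.prefilter, zero_route=cfg.zero_route,
                fc_up=cfg.fc_up, fc_down=cfg.fc_down, alpha=cfg.de_fdr,
            )
            state["de"] = de
            save("de_calls.tsv", de)
            done(stage, tested=len(de),
                 called=int((de["status"] != "not_de").sum()))

        elif stage == "targets":
            cohort = state["cohort"]
            retained = targets.filter_by_clip(cohort.candidates, cohort.clip_sites)
            pairs = targets.collapse_to_pairs(retained)
            state["pairs"] = pairs
            save("retained_candidates.tsv", retained)
            save("pairs.tsv", pairs)
            done(stage, candidates=len(cohort.candidates),
                 clip_retained=len(retained), pairs=len(pairs))

        elif stage == "network":
            if "pairs" not in state:
                if cfg.pairs_path is None:
                    raise ValueError(
                        "network stage needs pairs: enable the 'targets' "
                        "stage or set pairs_path"
                    )
                state["pairs"] = pd.read_csv(cfg.pairs_path, sep="\t")
            net = network.build_network(
                state["de"], state["pairs"], state["expr"],
                r_cut=cfg.r_cut, p_cut=cfg.corr_p,
            )
            state["net"] = net
            save("network_edges.tsv", net.edges)
            save("network_nodes.tsv", net.nodes)
            done(stage, nodes=net.graph.number_of_nodes(),
                 edges=net.graph.number_of_edges())

        elif stage == "topology":
            topo = network.topology_summary(state["net"])
            state["topology"] = topo
            p = out / "topology.json"
            p.write_text(json.dumps(topo, indent=1, sort_keys=True, default=str))
            done(stage, nodes=topo["n_nodes"], edges=topo["n_edges"])

        elif stage == "modules":
            mods = modules.clique_extension_clusters(
                state["net"], threshold=cfg.module_threshold,
                min_size=cfg.module_min_size,
            )
            state["modules"] = mods
            save("modules.tsv", pd.DataFrame(
                [
                    {
                        "module_id": f"M{i + 1}",
                        "size": len(m),
                        "n_mirna": m.class_counts["miRNA"],
                        "n_lncrna": m.class_counts["lncRNA"],
                        "n_mrna": m.class_counts["mRNA"],
                        "members": ",".join(sorted(m.nodes)),
                    }
                    for i, m in enumerate(mods)
                ]
            ))
            done(stage, modules=len(mods))

        elif stage == "survival":
            cohort = state["cohort"]
            units = {
                f"M{i + 1}": sorted(m.nodes)
                for i, m in enumerate(state.get("modules", []))
            }
            # the planted module rides along so a simulated run always
            # exercises the module-level screen
            if cohort.ledger.prognostic_module:
                units["planted_module"] = cohort.ledger.prognostic_module
            results = survival.survival_screen(
                units, state["expr"], cohort.clinical,
                alpha=cfg.survival_alpha, seed=cfg.seed,
            )
            tab = survival.results_table(results)
            state["survival"] = tab
            save("survival.tsv", tab)
            for r in results:
                if r.significant and r.labels is not None:
                    hi = r.labels == 1
                    clin = cohort.clinical.set_index("sample_id").loc[r.labels.index]
                    km = pd.concat([
                        survival.km_curve(
                            clin["time_days"][mask], clin["event"][mask]
                        ).assign(group=g)
                        for g, mask in (("high", hi), ("low", ~hi))
                    ])
                    save(f"km_{r.unit_id}.tsv", km)
            done(stage, units=len(units),
                 significant=int(tab["significant"].sum()))

        elif stage == "enrich":
            cohort = state["cohort"]
            nodes = state["net"].nodes
            kept = diffexpr.prefilter_by_normal_zeros(
                state["expr"], cfg.prefilter)
            universe_genes = [
                m for m in kept.molecules
                if kept.molecule_class[m] == "mRNA"
            ]
            universe = len(universe_genes)
            de_status = dict(zip(state["de"]["molecule_id"], state["de"]["status"]))
            report = enrich.overlap_report(nodes, cohort.gene_sets, de_status)
            pvals = []
            n_net = int((nodes["class"] == "mRNA").sum())
            for _, row in report.iterrows():
                members = set(cohort.gene_sets[row["set_name"]])
                set_in_universe = len(members & set(universe_genes))
                hits = len(members & set(
                    nodes["id"][nodes["class"] == "mRNA"]))
                pvals.append(enrich.hypergeometric_enrichment(
                    min(hits, set_in_universe), n_net, set_in_universe, universe)
                    if universe else 1.0)
            report["set_in_universe"] = [
                len(set(cohort.gene_sets[n]) & set(universe_genes))
                for n in report["set_name"]
            ]
            report["universe"] = universe
            report["network_genes"] = n_net
            report["p_value"] = pvals
            save("enrichment.tsv", report)
            done(stage, sets=len(report), universe=universe)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc
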