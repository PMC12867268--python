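"""End-to-end orchestration: simulate → TWAS per tissue → overlaps → DEG →
CGSEA → network analysis → ORA, from one config, with deterministic outputs.

Every stage writes a TSV under the output directory and the run finishes with
a manifest (config echo, seeds, row counts, skip logs) plus — when ground
truth is available — a recovery report comparing calls against the planted
signal. Rerunning an identical config reproduces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as ctio
from .cgsea import CgseaConfig, CgseaResult, build_gene_scores, run_cgsea
from .deg import DegResult, diff_expr, filter_degs
from .enrich import ora
from .network import build_graph, hub_table, mcode, top_modules
from .simulate import SimBundle, SimConfig, simulate_all
from .twas import (
    TwasResult,
    cluster_features,
    expression_correlation,
    pooled_fdr,
    run_twas,
)

__all__ = [
    "PipelineConfig",
    "OverlapReport",
    "cross_tissue_overlap",
    "overlap_ratio",
    "run_all",
]


@dataclass
class PipelineConfig:
    """All thresholds and simulation settings for one pipeline run.

    ``twas_fdr`` is the headline significance threshold (FDR < 0.05);
    ``twas_p`` defines the broader overlap universe (nominal P < 0.05), the
    two thresholds the source analysis keeps distinct.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    out_dir: str = "chemtwas_run"
    twas_fdr: float = 0.05
    twas_p: float = 0.05
    deg_adj_p: float = 0.05
    deg_lfc: float = 0.5
    cgsea: CgseaConfig = field(default_factory=CgseaConfig)
    string_cutoff: float = 0.4
    epc_iters: int = 1000
    mcode_top_n: int = 5

    def __post_init__(self) -> None:
        for name in ("twas_fdr", "twas_p", "deg_adj_p"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ctio.ValidationError(f"{name} must be in (0, 1], got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        if "set_size_range" in sim_raw:
            sim_raw["set_size_range"] = tuple(sim_raw["set_size_range"])
        if "ppi_planted_modules" in sim_raw:
            sim_raw["ppi_planted_modules"] = [
                tuple(m) for m in sim_raw["ppi_planted_modules"]
            ]
        cgsea_raw = raw.pop("cgsea", {})
        return cls(
            sim=SimConfig(**sim_raw), cgsea=CgseaConfig(**cgsea_raw), **raw
        )


@dataclass
class OverlapReport:
    per_tissue_sets: dict[str, set[str]]
    cross_tissue: set[str]
    twas_deg_overlap: dict[str, set[str]]
    ratio_lines: list[dict]


def cross_tissue_overlap(per_tissue_sets: Mapping[str, set[str]]) -> set[str]:
    """Exact intersection of per-tissue significant gene sets (>= 2 tissues)."""
    sets = list(per_tissue_sets.values())
    if len(sets) < 2:
        raise ctio.ValidationError("cross-tissue overlap needs >= 2 tissue sets")
    out = set(sets[0])
    for s in sets[1:]:
        out &= s
    return out


def overlap_ratio(numerator: int, denominator: int) -> float:
    """100 × numerator/denominator, round-half-even to 2 decimals."""
    if denominator <= 0:
        raise ctio.ValidationError("overlap_ratio denominator must be > 0")
    if not (0 <= numerator <= denominator):
        raise ctio.ValidationError("numerator outside [0, denominator]")
    return round(100.0 * numerator / denominator, 2)


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------


def _gene_corr_fn(panel: ctio.WeightPanel, gwas, ld_by_locus, tissue: str):
    """Predicted-expression correlation between two genes of one tissue.

    Genes with no shared LD locus are uncorrelated (disjoint SNP frames).
    """
    cache: dict[str, tuple[str, dict[str, float]]] = {}
    snp_to_locus: dict[str, str] = {}
    for locus, ld in ld_by_locus.items():
        for sid in ld.snp_ids:
            snp_to_locus[sid] = locus

    def gene_frame(gene: str) -> tuple[str, dict[str, float]]:
        if gene not in cache:
            entries = panel.gene_entries(gene, tissue)
            h = ctio.harmonize(entries, gwas, ld_by_locus[snp_to_locus[entries[0].snp_id]])
            cache[gene] = (snp_to_locus[h.snp_ids[0]], dict(zip(h.snp_ids, h.w)))
        return cache[gene]

    def corr(a: str, b: str) -> float:
        loc_a, wa = gene_frame(a)
        loc_b, wb = gene_frame(b)
        if loc_a != loc_b:
            return 0.0
        ld = ld_by_locus[loc_a]
        ids = [s for s in ld.snp_ids if s in wa or s in wb]
        sub = ld.submatrix(ids).corr
        va = np.array([wa.get(s, 0.0) for s in ids])
        vb = np.array([wb.get(s, 0.0) for s in ids])
        return expression_correlation(va, vb, sub)

    return corr


def _twas_frame(results: Sequence[TwasResult], cluster_map: Mapping[str, tuple[str, str]]) -> pd.DataFrame:
    rows = []
    for r in results:
        cid, rel = cluster_map.get((r.tissue, r.gene_id), ("NA", "NA"))
        rows.append(
            {
                "gene_id": r.gene_id,
                "tissue": r.tissue,
                "z": repr(r.z),
                "p": repr(r.p),
                "q_tissue": repr(r.q),
                "q_pooled": repr(r.q_pooled) if r.q_pooled is not None else "NA",
                "n_snps_used": r.n_snps_used,
                "n_snps_dropped": r.n_snps_dropped,
                "segment_id": r.segment_id,
                "cluster_id": cid,
                "cluster_relation": rel,
            }
        )
    return pd.DataFrame(rows)


def run_all(config: PipelineConfig) -> dict:
    """Run every stage in order; returns the report bundle as a dict.

    Writes per-stage TSVs, truth.json, a recovery report and manifest.json
    under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "seed": config.sim.seed}

    # stage 1: simulate
    bundle = simulate_all(config.sim)
    _write_inputs(bundle, out)
    manifest["stages"]["simulate"] = {
        "n_snps": len(bundle.gwas),
        "n_genes": config.sim.n_genes,
        "n_tissues": config.sim.n_tissues,
        "n_chemicals": len(bundle.chem_sets),
        "n_edges": len(bundle.edges),
    }

    # stage 2: TWAS per tissue
    all_results: list[TwasResult] = []
    skip_log: dict[str, list[str]] = {}
    cluster_map: dict[tuple[str, str], tuple[str, str]] = {}
    for tissue in config.sim.tissue_ids():
        results, skipped = run_twas(bundle.panel, bundle.gwas, bundle.ld, tissue)
        corr_fn = _gene_corr_fn(bundle.panel, bundle.gwas, bundle.ld, tissue)
        clusters = cluster_features(results, corr_fn, p_include=config.twas_p)
        for ci, cl in enumerate(clusters):
            for g in cl.member_genes:
                cluster_map[(tissue, g)] = (f"{tissue}_cl{ci:03d}", cl.relation)
        all_results.extend(results)
        if skipped:
            skip_log[tissue] = skipped
    pooled_fdr(all_results)
    twas_df = _twas_frame(all_results, cluster_map)
    twas_df.to_csv(out / "twas.tsv", sep="\t", index=False)
    manifest["stages"]["twas"] = {"n_rows": len(twas_df), "skipped": skip_log}

    # stage 3: DEG
    deg_results = diff_expr(bundle.expr, config.deg_adj_p, config.deg_lfc)
    up, down = filter_degs(deg_results, config.deg_adj_p, config.deg_lfc)
    deg_df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in deg_results],
            "log2fc": [repr(r.log2fc) for r in deg_results],
            "p": [repr(r.p) for r in deg_results],
            "adj_p": [repr(r.adj_p) for r in deg_results],
            "is_deg": [str(r.is_deg) for r in deg_results],
            "direction": [r.direction for r in deg_results],
        }
    )
    deg_df.to_csv(out / "deg.tsv", sep="\t", index=False)
    manifest["stages"]["deg"] = {"n_rows": len(deg_df), "n_up": len(up), "n_down": len(down)}

    # stage 4: overlaps
    per_tissue = {
        t: {r.gene_id for r in all_results if r.tissue == t and r.p < config.twas_p}
        for t in config.sim.tissue_ids()
    }
    cross = cross_tissue_overlap(per_tissue) if len(per_tissue) >= 2 else set(
        next(iter(per_tissue.values()))
    )
    deg_set = {r.gene_id for r in deg_results if r.is_deg}
    twas_deg = {t: s & deg_set for t, s in per_tissue.items()}
    ratio_lines = []
    for t in sorted(per_tissue):
        n_common = len(twas_deg[t])
        for label, denom in (("twas", len(per_tissue[t])), ("deg", len(deg_set))):
            if denom > 0:
                ratio_lines.append(
                    {
                        "tissue": t,
                        "denominator_set": label,
                        "numerator": n_common,
                        "denominator": denom,
                        "percent": overlap_ratio(n_common, denom),
                    }
                )
    overlap = OverlapReport(per_tissue, cross, twas_deg, ratio_lines)
    pd.DataFrame(ratio_lines).to_csv(out / "overlap_ratios.tsv", sep="\t", index=False)
    (out / "overlap_genes.tsv").write_text(
        "set\tgenes\n"
        + "".join(
            f"{t}\t{';'.join(sorted(s))}\n" for t, s in sorted(per_tissue.items())
        )
        + f"cross_tissue\t{';'.join(sorted(cross))}\n"
        + "".join(
            f"{t}_twas_and_deg\t{';'.join(sorted(s))}\n"
            for t, s in sorted(twas_deg.items())
        )
    )
    manifest["stages"]["overlap"] = {
        "cross_tissue_n": len(cross),
        "n_ratio_lines": len(ratio_lines),
    }

    # stage 5: CGSEA
    scores = build_gene_scores(all_results)
    cg_results = run_cgsea(scores, bundle.chem_sets, config.cgsea)
    cg_df = pd.DataFrame(
        {
            "chemical_id": [r.chemical_id for r in cg_results],
            "chemical_name": [r.chemical_name for r in cg_results],
            "set_size_used": [r.set_size_used for r in cg_results],
            "es": [repr(r.es) for r in cg_results],
            "nes": [repr(r.nes) if r.nes is not None else "NA" for r in cg_results],
            "p_perm": [repr(r.p_perm) for r in cg_results],
            "q": [repr(r.q) for r in cg_results],
            "significant": [str(r.significant) for r in cg_results],
            "leading_edge": [";".join(r.leading_edge) for r in cg_results],
        }
    )
    cg_df.to_csv(out / "cgsea.tsv", sep="\t", index=False)
    manifest["stages"]["cgsea"] = {
        "n_rows": len(cg_df),
        "n_significant": int(sum(r.significant for r in cg_results)),
        "universe_size": len(scores.scores),
    }

    # stage 6: network
    graph = build_graph(bundle.edges, config.string_cutoff)
    hubs = hub_table(graph, epc_iters=config.epc_iters, seed=config.sim.seed)
    modules = mcode(graph)
    top = top_modules(modules, config.mcode_top_n)
    pd.DataFrame(hubs).to_csv(out / "hubs.tsv", sep="\t", index=False, float_format="%.17g")
    pd.DataFrame(
        {
            "rank": [m.rank for m in top],
            "score": [repr(m.score) for m in top],
            "seed_node": [m.seed_node for m in top],
            "members": [";".join(sorted(m.members)) for m in top],
        }
    ).to_csv(out / "mcode_modules.tsv", sep="\t", index=False)
    manifest["stages"]["network"] = {
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "n_modules": len(modules),
    }

    # stage 7: ORA of headline TWAS genes against the chemical sets
    sig_genes = {
        r.gene_id for r in all_results if r.q_pooled is not None and r.q_pooled < config.twas_fdr
    }
    ora_rows: list[dict] = []
    if sig_genes:
        ora_results, _ = ora(sig_genes, bundle.chem_sets.sets, set(scores.scores))
        ora_rows = [dataclasses.asdict(r) for r in ora_results]
        ora_df = pd.DataFrame(ora_rows)
        for col in ("p", "adj_p", "fold_enrichment"):
            ora_df[col] = ora_df[col].map(repr)
        ora_df.to_csv(out / "ora.tsv", sep="\t", index=False)
    manifest["stages"]["ora"] = {"n_rows": len(ora_rows), "query_size": len(sig_genes)}

    # recovery report against planted truth
    recovery = _recovery_report(bundle, all_results, deg_results, cg_results, top, config)
    (out / "recovery.json").write_text(json.dumps(recovery, indent=2, sort_keys=True) + "\n")
    manifest["recovery"] = recovery

    manifest["config"] = _config_echo(config)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {
        "bundle": bundle,
        "twas": all_results,
        "deg": deg_results,
        "overlap": overlap,
        "cgsea": cg_results,
        "hubs": hubs,
        "modules": top,
        "manifest": manifest,
    }


def _precision_recall(called: set[str], truth: set[str]) -> dict:
    tp = len(called & truth)
    precision = tp / len(called) if called else float("nan")
    recall = tp / len(truth) if truth else float("nan")
    return {"n_called": len(called), "n_true": len(truth), "tp": tp,
            "precision": precision, "recall": recall}


def _jaccard(a: set[str], b: set[str]) -> float:
    return len(a & b) / len(a | b) if (a or b) else 0.0


def _recovery_report(bundle: SimBundle, twas_results, deg_results, cg_results,
                     top_mods, config: PipelineConfig) -> dict:
    truth = bundle.truth
    called_genes = {
        r.gene_id for r in twas_results
        if r.q_pooled is not None and r.q_pooled < config.twas_fdr
    }
    called_chems = {r.chemical_id for r in cg_results if r.significant}
    called_degs = {r.gene_id for r in deg_results if r.is_deg}
    module_jaccards = []
    for planted in truth.planted_module_memberships:
        best = max((_jaccard(set(m.members), planted) for m in top_mods), default=0.0)
        module_jaccards.append(best)
    return {
        "causal_genes": _precision_recall(called_genes, set(truth.causal_genes)),
        "active_chemicals": _precision_recall(called_chems, set(truth.active_chemicals)),
        "planted_degs": _precision_recall(called_degs, set(truth.planted_deg_genes)),
        "module_jaccards": module_jaccards,
    }


def _config_echo(config: PipelineConfig) -> dict:
    def clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        return obj

    echo = clean(config)
    echo.pop("out_dir", None)  # location is environmental, not part of the run
    return echo


def _write_inputs(bundle: SimBundle, out: Path) -> None:
    inputs = out / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    ctio.write_gwas(bundle.gwas, inputs / "gwas.tsv")
    ctio.write_weights(bundle.panel, inputs / "weights.tsv")
    ctio.write_ld_dir(bundle.ld, inputs / "ld")
    ctio.write_chemical_sets(bundle.chem_sets, inputs / "chemical_sets.tsv")
    ctio.write_expression(bundle.expr, inputs / "expression.tsv", inputs / "groups.tsv")
    ctio.write_edges(bundle.edges, inputs / "edges.tsv")
    truth = bundle.truth
    (inputs / "truth.json").write_text(
        json.dumps(
            {
                "causal_genes": truth.causal_genes,
                "active_chemicals": truth.active_chemicals,
                "planted_deg_genes": truth.planted_deg_genes,
                "planted_module_memberships": [
                    sorted(m) for m in truth.planted_module_memberships
                ],
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
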