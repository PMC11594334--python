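"""End-to-end orchestration of one oxidative-stress-model analysis.

One run covers one model (one 3-vs-3 count design): junction-read filter ->
differential expression of circRNAs and mRNAs -> one-sided Pearson
co-expression -> circRNA-miRNA seed scanning and miRNA-mRNA table filtering
-> shared-miRNA axis assembly -> hub ranking and subnetwork extraction ->
sponge/disease Fisher table -> optional over-representation analysis.
Every intermediate table is written to the output directory, and the run
report embeds the full configuration, so each number in the report can be
recomputed from the written files. Two runs with the same config produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import cerna_network as net
from . import coexpression as coex
from . import diff_expr as de
from . import enrichment as enr
from . import expression_io as eio
from . import target_prediction as tp

log = logging.getLogger("cernaforge")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths, thresholds, and options for one model run.

    Threshold defaults are the standard screen: junction filter (>=2 reads in
    >= half the samples), circRNA DE at p < 0.05 & FC > 2, mRNA DE at
    FDR < 0.05 & FC > 1.5, co-expression at r > 0.90 & adjusted p < 0.05,
    miRNA expression at >=1 count in >= half the samples, interaction sites
    at 7mer-A1 or better, degree-ranked top-10 hubs.
    """

    circ_counts: str
    mrna_counts: str
    mirna_counts: str
    circ_fasta: str
    mirna_fasta: str
    target_table: str
    disease_mirnas: str
    groups: dict[str, str] = field(default_factory=dict)
    model_label: str = "model"
    min_junction_reads: int = 2
    min_sample_fraction: float = 0.5
    de_method: str = "nb_exact"
    circ_max_p: float | None = 0.05
    circ_max_fdr: float | None = None
    circ_min_fc: float = 2.0
    mrna_max_p: float | None = None
    mrna_max_fdr: float | None = 0.05
    mrna_min_fc: float = 1.5
    r_min: float = 0.90
    max_adj_p: float = 0.05
    mirna_min_count: int = 1
    mirna_min_sample_fraction: float = 0.5
    min_site_type: str = "7mer-A1"
    overhang: int = 7
    hub_method: str = "degree"
    n_hubs: int = 10
    annotation_gmt: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def circ_thresholds(self) -> de.DEThresholds:
        return de.DEThresholds(self.circ_max_p, self.circ_max_fdr, self.circ_min_fc)

    def mrna_thresholds(self) -> de.DEThresholds:
        return de.DEThresholds(self.mrna_max_p, self.mrna_max_fdr, self.mrna_min_fc)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass
class RunResult:
    config: RunConfig
    circ_filtered: eio.CountMatrix
    de_circ_results: list[de.DEResult]
    de_mrna_results: list[de.DEResult]
    de_circ: set[str]
    de_mrna: set[str]
    pairs: list[coex.CoexprPair]
    sites: list[tp.MreSite]
    interactions: tp.InteractionSet
    expressed_mirnas: set[str]
    network: net.CeRNANetwork
    hubs: net.HubRanking | None
    subnetwork: net.CeRNANetwork
    fisher_table: enr.ContingencyTable2x2
    fisher_p: float
    ora: list[enr.EnrichmentResult] | None
    report: dict[str, Any]


def _stage(name: str):
    """Log a stage with wall-time; re-raise failures tagged with the stage."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                log.info("stage %s: done in %.2fs", name, dt)
                return False
            if isinstance(exc, PipelineError):
                return False
            raise PipelineError(name, str(exc)) from exc

    return _Ctx()


def run(config: RunConfig, outdir: str | Path) -> RunResult:
    """Execute the full screen for one model and write all intermediates."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"model": config.model_label, "config": config.to_dict()}

    with _stage("load"):
        circ = eio.read_count_matrix(config.circ_counts, config.groups)
        mrna = eio.read_count_matrix(config.mrna_counts, config.groups)
        mirna = eio.read_count_matrix(config.mirna_counts, config.groups)
        circ_seqs = eio.read_fasta(config.circ_fasta)
        mirna_seqs = eio.read_fasta(config.mirna_fasta)
        target_table = eio.read_target_table(config.target_table)
        disease = eio.read_annotation_list(config.disease_mirnas, "disease_associated")
        for cid in circ.feature_ids:
            eio.parse_circ_id(cid)  # validate identifiers early

    with _stage("junction_filter"):
        circ_f = eio.filter_by_junction_reads(
            circ, config.min_junction_reads, config.min_sample_fraction
        )
        eio.write_count_matrix(circ_f, outdir / "circ_counts.filtered.tsv")
        report["n_circ_input"] = len(circ.feature_ids)
        report["n_circ_retained"] = len(circ_f.feature_ids)

    with _stage("diff_expr"):
        de_circ_res = de.de_test(circ_f, method=config.de_method)
        de_mrna_res = de.de_test(mrna, method=config.de_method)
        de.results_to_frame(de_circ_res).to_csv(outdir / "de_circ.tsv", sep="\t")
        de.results_to_frame(de_mrna_res).to_csv(outdir / "de_mrna.tsv", sep="\t")
        de_circ_set = de.apply_thresholds(de_circ_res, config.circ_thresholds())
        de_mrna_set = de.apply_thresholds(de_mrna_res, config.mrna_thresholds())
        report["n_de_circ"] = len(de_circ_set)
        report["n_de_mrna"] = len(de_mrna_set)

    with _stage("coexpression"):
        eff_c = de.effective_library_sizes(circ_f)
        eff_m = de.effective_library_sizes(mrna)
        circ_expr = de.cpm(circ_f, log2=True, effective_sizes=eff_c).loc[sorted(de_circ_set)]
        mrna_expr = de.cpm(mrna, log2=True, effective_sizes=eff_m).loc[sorted(de_mrna_set)]
        if de_circ_set and de_mrna_set:
            pairs = coex.coexpressed_pairs(
                circ_expr, mrna_expr, r_min=config.r_min, max_adj_p=config.max_adj_p
            )
        else:
            pairs = []
        coex.pairs_to_frame(pairs).to_csv(outdir / "coexpressed_pairs.tsv", sep="\t", index=False)
        report["n_coexpressed_pairs"] = len(pairs)

    with _stage("interactions"):
        expressed = tp.expressed_mirnas(
            mirna, config.mirna_min_count, config.mirna_min_sample_fraction
        )
        de_circ_seqs = {c: circ_seqs[c] for c in sorted(de_circ_set) if c in circ_seqs}
        expr_mirna_seqs = {m: mirna_seqs[m] for m in sorted(expressed) if m in mirna_seqs}
        sites = tp.scan_all(de_circ_seqs, expr_mirna_seqs, overhang=config.overhang)
        circ_mir = tp.circ_mir_interactions(sites, config.min_site_type)
        mir_mrna = tp.mir_mrna_interactions(target_table, de_mrna_set)
        inter = tp.InteractionSet(frozenset(circ_mir), frozenset(mir_mrna))
        pd.DataFrame(tp.sites_to_rows(sites),
                     columns=["circ_id", "mirna_id", "site_type", "start", "spans_bsj"],
                     ).to_csv(outdir / "mre_sites.tsv", sep="\t", index=False)
        pd.DataFrame(sorted(circ_mir), columns=["circ_id", "mirna_id"]).to_csv(
            outdir / "circ_mir_interactions.tsv", sep="\t", index=False)
        pd.DataFrame(sorted(mir_mrna), columns=["mirna_id", "gene_id"]).to_csv(
            outdir / "mir_mrna_interactions.tsv", sep="\t", index=False)
        report["n_expressed_mirnas"] = len(expressed)
        report["n_circ_mir_candidates"] = len(circ_mir)
        report["n_mir_mrna_candidates"] = len(mir_mrna)

    with _stage("network"):
        network = net.build_axes(pairs, inter, expressed)
        stats = net.network_stats(network)
        net.write_axes(network, outdir / "axes.tsv")
        net.export_network(network, "sif", outdir / "network.sif")
        net.export_network(network, "graphml", outdir / "network.graphml")
        net.export_network(network, "edge_tsv", outdir / "network_edges.tsv")
        report["network"] = stats._asdict()
        report["empty_network"] = stats.n_axes == 0

    with _stage("hubs"):
        if network.circ_nodes:
            hubs = net.rank_hubs(network, method=config.hub_method, k=config.n_hubs)
            sub = net.extract_subnetwork(network, set(hubs.ranked_nodes))
            pd.DataFrame(
                [(c, hubs.scores[c]) for c in hubs.ranked_nodes],
                columns=["circ_id", "score"],
            ).to_csv(outdir / "hubs.tsv", sep="\t", index=False)
        else:
            hubs = None
            sub = net.CeRNANetwork(frozenset())
            (outdir / "hubs.tsv").write_text("circ_id\tscore\n")
        net.write_axes(sub, outdir / "subnetwork_axes.tsv")
        net.export_network(sub, "sif", outdir / "subnetwork.sif")
        substats = net.network_stats(sub)
        report["subnetwork"] = substats._asdict()
        report["subnetwork_mirnas"] = len(sub.mirna_nodes)
        report["subnetwork_mrnas"] = len(sub.gene_nodes)

    with _stage("fisher"):
        universe = set(expressed)
        sponged = {mi for _, mi in network.sponge_edges} & universe
        associated = set(disease.ids) & universe
        if universe:
            table = enr.build_sponge_table(sponged, associated, universe)
            fisher_p = enr.fisher_exact_greater(table)
        else:
            table = enr.ContingencyTable2x2(0, 0, 0, 1)
            fisher_p = 1.0
        report["fisher"] = {
            "a": table.a, "b": table.b, "c": table.c, "d": table.d, "p_greater": fisher_p,
        }
        (outdir / "fisher.json").write_text(json.dumps(report["fisher"], indent=2))

    with _stage("ora"):
        ora = None
        if config.annotation_gmt:
            ann = enr.read_gmt(config.annotation_gmt)
            query = sub.gene_nodes & set().union(*ann.values()) if ann else set()
            if query:
                ora = enr.hypergeom_ora(query, ann)
                enr.enrichment_to_frame(ora).to_csv(outdir / "ora.tsv", sep="\t", index=False)
                report["n_ora_significant"] = sum(r.fdr < 0.05 for r in ora)

    with _stage("report"):
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        (outdir / "report.md").write_text(_markdown_report(report))

    return RunResult(
        config=config,
        circ_filtered=circ_f,
        de_circ_results=de_circ_res,
        de_mrna_results=de_mrna_res,
        de_circ=de_circ_set,
        de_mrna=de_mrna_set,
        pairs=pairs,
        sites=sites,
        interactions=inter,
        expressed_mirnas=expressed,
        network=network,
        hubs=hubs,
        subnetwork=sub,
        fisher_table=table,
        fisher_p=fisher_p,
        ora=ora,
        report=report,
    )


def _markdown_report(report: Mapping[str, Any]) -> str:
    nw = report.get("network", {})
    fish = report.get("fisher", {})
    lines = [
        f"# ceRNA screen report: {report.get('model', 'model')}",
        "",
        f"- circRNAs: {report.get('n_circ_input', 0)} input, "
        f"{report.get('n_circ_retained', 0)} past the junction-read filter",
        f"- differentially expressed: {report.get('n_de_circ', 0)} circRNAs, "
        f"{report.get('n_de_mrna', 0)} mRNAs",
        f"- co-expressed circRNA-mRNA pairs: {report.get('n_coexpressed_pairs', 0)}",
        f"- expressed miRNAs: {report.get('n_expressed_mirnas', 0)}",
        f"- network: {nw.get('n_axes', 0)} axes, {nw.get('n_nodes', 0)} nodes, "
        f"{nw.get('n_circ_mir_edges', 0)} sponge edges, "
        f"{nw.get('n_mir_mrna_edges', 0)} target edges",
        f"- sponge/disease Fisher (greater): a={fish.get('a')}, b={fish.get('b')}, "
        f"c={fish.get('c')}, d={fish.get('d')}, p={fish.get('p_greater'):.3g}"
        if fish else "- sponge/disease Fisher: not computed",
    ]
    if report.get("empty_network"):
        lines.append("- NOTE: the network is empty (no axis satisfied all gates)")
    return "".join(f"{ln}\n" for ln in lines)


def compare(dir_a: str | Path, dir_b: str | Path) -> dict[str, Any]:
    """Intersect the DE circRNA calls of two completed runs (e.g. two models)."""
    shared: dict[str, Any] = {}
    sets = []
    for d in (dir_a, dir_b):
        rep = json.loads((Path(d) / "report.json").read_text())
        df = pd.read_csv(Path(d) / "de_circ.tsv", sep="\t", index_col=0)
        cfg = rep["config"]
        thr = de.DEThresholds(cfg["circ_max_p"], cfg["circ_max_fdr"], cfg["circ_min_fc"])
        res = [
            de.DEResult(i, r.log2_fc, r.p_value, r.fdr, r.mean_cpm, r.direction)
            for i, r in df.iterrows()
        ]
        sets.append(de.apply_thresholds(res, thr))
        shared.setdefault("models", []).append(rep.get("model"))
    shared["n_de_a"], shared["n_de_b"] = len(sets[0]), len(sets[1])
    shared["shared_de_circ"] = sorted(sets[0] & sets[1])
    shared["n_shared"] = len(shared["shared_de_circ"])
    return shared
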