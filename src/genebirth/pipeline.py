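"""End-to-end orchestration and summary reporting.

``run_all`` executes the stages in order — dating, origin classification,
selection tests, expression profiling, co-expression network — from a single
config pointing at the input files, writes each stage's table, and emits a
structured ``report.json`` plus a human-readable ``report.md``.  All summary
arithmetic (birth rates, proportions) uses half-up rounding at the precision
of each printed figure so reported percentages are recomputable from their
own numerators and denominators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from genebirth import dating, expression, network, origin, selection
from genebirth._util import round_half_up
from genebirth.io_formats import (
    RepeatTrack,
    SpeciesTree,
    ValidationError,
    read_expression,
    read_fasta,
    read_gff3,
    read_homology_tsv,
    read_sample_map,
    read_synteny_tsv,
)


def birth_rate(n_genes: int, interval_my: float, decimals: int = 2) -> float:
    """New genes per million years over a branch interval (half-up rounded)."""
    if interval_my <= 0:
        raise ValidationError(f"non-positive interval {interval_my}")
    return round_half_up(n_genes / interval_my, decimals)


def proportion(numerator: int, denominator: int, decimals: int = 2) -> float:
    """Percentage 100*n/d with half-up rounding to ``decimals``."""
    if denominator <= 0:
        raise ValidationError("denominator must be positive")
    return round_half_up(100.0 * numerator / denominator, decimals)


def overlap_check(new_gene_ids: Sequence[str], venom_gene_ids: Sequence[str]
                  ) -> tuple[list[str], int, int]:
    """Intersection of the new-gene and venom-gene id sets, with cardinalities."""
    a, b = set(new_gene_ids), set(venom_gene_ids)
    return sorted(a & b), len(a), len(b)


@dataclass
class PipelineConfig:
    """Input paths and stage parameters for a full run."""

    gff: str
    cds: str
    protein: str
    synteny: str
    repeats: str
    protein_hits: str
    paralog_hits: str
    dna_hits: str
    tree: str
    reference: str
    expression: str
    sample_map: str
    venom_genes: str | None = None
    outgroup_nt: str | None = None
    outgroup_species: str | None = None   # default: deepest-split species
    out_dir: str = "pipeline_out"
    dating_config: dating.DatingConfig = field(default_factory=dating.DatingConfig)
    selection_config: selection.SelectionConfig = field(default_factory=selection.SelectionConfig)
    network_config: network.NetworkConfig = field(default_factory=network.NetworkConfig)
    tpm_min: float = 1.0
    tau_min: float = 0.85

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sub = {}
        for key, klass in (("dating_config", dating.DatingConfig),
                           ("selection_config", selection.SelectionConfig),
                           ("network_config", network.NetworkConfig)):
            if key in raw:
                sub[key] = klass(**raw.pop(key))
        return cls(**raw, **sub)


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and return the summary report (also written to disk).

    A stage failure raises with the stage name attached; per-gene problems
    inside dating never abort the run (they surface as exclusion reasons).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def stage(name):
        log.append(name)
        return name

    try:
        stage("load")
        genes = read_gff3(config.gff)
        models = {g.gene_id: g for g in genes}
        cds = read_fasta(config.cds)
        synteny = read_synteny_tsv(config.synteny)
        repeats = RepeatTrack.from_bed(config.repeats)
        tree = SpeciesTree.from_newick(config.tree, config.reference)
        prot_hits = read_homology_tsv(config.protein_hits)
        para_hits = read_homology_tsv(config.paralog_hits)
        dna_hits = read_homology_tsv(
            config.dna_hits, query_lengths={g: len(s) for g, s in cds.items()})
        sample_map = read_sample_map(config.sample_map)
        expr = read_expression(config.expression, sample_map)
        venom_ids = []
        if config.venom_genes:
            venom_ids = [ln.strip() for ln in Path(config.venom_genes).read_text().splitlines()
                         if ln.strip()]
        outgroup_nt = {}
        if config.outgroup_nt:
            for name, seq in read_fasta(config.outgroup_nt).items():
                gid, sp = name.split("|", 1)
                outgroup_nt[gid] = (sp, seq)
        outgroup_species = config.outgroup_species or sorted(tree.groups[0])[0]

        stage("dating")
        if not genes:
            raise ValidationError("empty gene set")
        aged = dating.date_genome(genes, synteny, repeats, prot_hits, tree,
                                  config.dating_config)
        dating.write_aged_tsv(aged, out / "aged_genes.tsv")
        new_ids = [a.gene_id for a in aged if a.is_new]
        branch_by_gene = {a.gene_id: a.branch for a in aged
                          if a.excluded_reason == dating.REASON_NONE}

        stage("classification")
        calls = origin.classify_new_genes(
            new_ids, models, branch_by_gene, para_hits, prot_hits, dna_hits,
            outgroup_species, outgroup_nt=outgroup_nt, orf_nt=cds)
        origin.write_calls_tsv(calls, out / "origin_calls.tsv")

        stage("selection")
        pairs = [(c.gene_id, c.parent_id) for c in calls if c.parent_id]
        kaks_results = []
        for child, parent in pairs:
            kaks_results.append(selection.analyze_pair(
                cds[child], cds[parent], id_a=child, id_b=parent,
                config=config.selection_config))
        kaks_results = selection.filter_pairs(kaks_results, config.selection_config)
        if kaks_results:
            selection.results_to_frame(kaks_results).to_csv(
                out / "kaks.tsv", sep="\t", float_format="%.6g")

        stage("expression")
        tau_results = expression.profile_genes(expr, config.tpm_min, config.tau_min)
        expression.tau_results_to_frame(tau_results).to_csv(
            out / "tau.tsv", sep="\t", float_format="%.6g")
        age_stats = expression.age_group_compare(
            expr, aged, config.tpm_min, config.dating_config.new_gene_branch_threshold)
        expressed_new = [r.gene_id for r in tau_results
                         if r.gene_id in set(new_ids) and r.expressed]
        bias_bd = (expression.bias_breakdown(tau_results, expressed_new, expr.tissues)
                   if expressed_new else None)

        stage("network")
        net = network.run_network(expr, config.network_config, tpm_min=config.tpm_min)
        net.labels.to_csv(out / "modules.tsv", sep="\t")
        net.module_trait_r.to_csv(out / "module_trait_r.tsv", sep="\t", float_format="%.6g")

        stage("report")
        report = build_report(aged, calls, kaks_results, tau_results, age_stats,
                              bias_bd, net, tree, models, new_ids, venom_ids,
                              config.dating_config.new_gene_branch_threshold)
        report["stages"] = log
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=_jsonify)
            fh.write("\n")
        (out / "report.md").write_text(render_report_md(report))
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {log[-1]!r}: {exc}") from exc


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    raise TypeError(f"not JSON serialisable: {type(x)}")


def build_report(aged, calls, kaks_results, tau_results, age_stats, bias_bd,
                 net, tree: SpeciesTree, models, new_ids, venom_ids,
                 new_branch_threshold: int) -> dict:
    n_total = len(aged)
    per_branch = {}
    for a in aged:
        if a.branch is not None and a.excluded_reason == dating.REASON_NONE:
            per_branch[a.branch] = per_branch.get(a.branch, 0) + 1
    excl = {}
    for a in aged:
        if a.excluded_reason != dating.REASON_NONE:
            excl[a.excluded_reason] = excl.get(a.excluded_reason, 0) + 1

    mech_counts = {}
    for c in calls:
        mech_counts[c.mechanism] = mech_counts.get(c.mechanism, 0) + 1
    n_new = len(new_ids)

    rates = {}
    root_age = tree.split_ages[0]
    rates["all_new_per_my"] = birth_rate(n_new, root_age) if n_new else 0.0
    for b in range(new_branch_threshold, tree.n_branches):
        n_b = per_branch.get(b, 0)
        rates[f"branch_{b}_per_my"] = birth_rate(n_b, tree.branch_interval_my(b))

    single_exon_new = [g for g in new_ids if models[g].n_exons == 1]
    single_from_rna_or_denovo = [
        c.gene_id for c in calls
        if c.gene_id in set(single_exon_new)
        and c.mechanism in (origin.MECH_RETRO, origin.MECH_DENOVO)]

    selection_summary = None
    if kaks_results:
        try:
            n_neg, n_tested, pct = selection.summarize_selection(kaks_results)
            selection_summary = {"n_negative": n_neg, "n_tested": n_tested,
                                 "percent_negative": pct}
        except ValidationError:
            selection_summary = {"n_negative": 0, "n_tested": 0, "percent_negative": None}

    expressed_new = [r.gene_id for r in tau_results
                     if r.gene_id in set(new_ids) and r.expressed]
    tau_summary = {
        "n_new_expressed": len(expressed_new),
        "bias_breakdown": (None if bias_bd is None
                           else {t: {"count": int(row["count"]), "percent": row["percent"]}
                                 for t, row in bias_bd.iterrows()}),
    }

    new_in_modules = {g: int(net.labels[g]) for g in new_ids if g in net.labels.index}
    intersection, n_new_ids, n_venom = overlap_check(new_ids, venom_ids)

    p_key = lambda pair: f"{pair[0]} vs {pair[1]}"
    return {
        "n_genes": n_total,
        "per_branch_counts": {str(k): v for k, v in sorted(per_branch.items())},
        "excluded_counts": excl,
        "n_new_genes": n_new,
        "new_gene_percent_of_genome": proportion(n_new, n_total) if n_total else None,
        "mechanism_counts": mech_counts,
        "mechanism_percent": {m: proportion(c, n_new) for m, c in mech_counts.items()}
        if n_new else {},
        "birth_rates": rates,
        "single_exon": {
            "n_new_single_exon": len(single_exon_new),
            "percent_rna_or_denovo_among_single_exon": (
                proportion(len(single_from_rna_or_denovo), len(single_exon_new))
                if single_exon_new else None),
        },
        "selection": selection_summary,
        "expression": tau_summary,
        "age_group_p_abundance": {p_key(k): v for k, v in age_stats.p_abundance.items()},
        "age_group_p_breadth": {p_key(k): v for k, v in age_stats.p_breadth.items()},
        "network": {
            "n_modules": len(net.module_sizes),
            "module_sizes": {str(k): v for k, v in sorted(net.module_sizes.items())},
            "new_gene_modules": new_in_modules,
            "hubs": {str(k): v for k, v in net.hubs.items()},
        },
        "venom_overlap": {
            "intersection": intersection,
            "n_new_genes": n_new_ids,
            "n_venom_genes": n_venom,
        },
    }


def render_report_md(report: dict) -> str:
    lines = ["# New-gene pipeline report", ""]
    lines.append(f"Annotated genes: {report['n_genes']}")
    lines.append(f"New genes: {report['n_new_genes']} "
                 f"({report['new_gene_percent_of_genome']}% of the gene set)")
    lines.append("")
    lines.append("## Branch counts")
    for b, n in report["per_branch_counts"].items():
        lines.append(f"- branch {b}: {n}")
    lines.append("")
    lines.append("## Origin mechanisms")
    for m, n in sorted(report["mechanism_counts"].items()):
        pct = report["mechanism_percent"].get(m)
        lines.append(f"- {m}: {n} ({pct}%)")
    lines.append("")
    lines.append("## Birth rates (genes/MY)")
    for k, v in sorted(report["birth_rates"].items()):
        lines.append(f"- {k}: {v}")
    if report.get("selection"):
        s = report["selection"]
        lines.append("")
        lines.append("## Selection")
        lines.append(f"- {s['n_negative']} / {s['n_tested']} pairs under negative "
                     f"selection ({s['percent_negative']}%)")
    lines.append("")
    lines.append("## Network")
    net = report["network"]
    lines.append(f"- modules: {net['n_modules']} (sizes {net['module_sizes']})")
    lines.append(f"- hubs: {net['hubs']}")
    ov = report["venom_overlap"]
    lines.append("")
    lines.append(f"## Venom overlap: {len(ov['intersection'])} of "
                 f"{ov['n_new_genes']} new genes also in the {ov['n_venom_genes']}-gene venom list")
    return "\n".join(lines) + "\n"
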