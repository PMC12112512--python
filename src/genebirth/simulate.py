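"""Synthetic-data generator with planted ground truth for every pipeline stage.

The generator emulates the study design the pipeline targets: a seven-species
pteromalid ladder tree (root ~89.83 MY, reference-clade split at 8 MY,
youngest split at 1.49 MY), a reference genome of background genes shared
across the clade, planted gene births on the young branches with known
mechanism (DNA duplication / retroposition / de novo), codon sequence pairs
evolved under a known omega, and a TPM expression matrix over seven tissues
(two replicates each) with planted co-expression modules, tissue-biased
genes and an age-dependent abundance trend.

Everything derives from a single integer seed; writers use fixed float
formatting so regeneration is byte-identical.  TPM columns are not
renormalised to sum to 1e6 — every downstream analysis uses only thresholds,
ratios and correlations, which are insensitive to the column sum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from genebirth import selection as sel
from genebirth.io_formats import (
    DEFAULT_REFERENCE,
    DEFAULT_TREE_NEWICK,
    ExpressionMatrix,
    GeneModel,
    HomologyHit,
    RepeatTrack,
    SpeciesTree,
    ValidationError,
    write_fasta,
    write_gff3,
    write_homology_tsv,
    write_json,
    write_synteny_tsv,
)

DEFAULT_TISSUES = (
    "testis", "ovary", "venom_gland",
    "salivary_gland_3.5d", "salivary_gland_5.5d", "gut_3.5d", "gut_5.5d",
)


@dataclass
class ModuleSpec:
    """One planted co-expression module: size and an optional driving tissue."""

    size: int
    tissue: str | None = None  # None: a latent factor unrelated to any tissue


@dataclass
class SimulationConfig:
    seed: int = 42
    tree_newick: str = DEFAULT_TREE_NEWICK
    reference: str = DEFAULT_REFERENCE

    # gene-set design
    n_background: int = 300
    background_branch_weights: tuple[float, ...] = (0.55, 0.15, 0.15, 0.15)  # branches 0-3
    births_per_branch: Mapping[int, int] = field(
        default_factory=lambda: {4: 10, 5: 10, 6: 10})
    mechanism_cycle: tuple[str, ...] = ("dna_duplication", "retroposition", "de_novo")
    n_decoy_repeat: int = 5
    n_decoy_patchy: int = 5
    n_decoy_homology: int = 3
    n_venom_genes: int = 40
    presence_flip_rate: float = 0.0   # per-gene probability of one flipped species flag

    # codon evolution of duplicate pairs
    pair_omega: float = 0.2
    pair_t: float = 0.3
    pair_kappa: float = 2.0

    # expression design (log2 scale)
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    replicates: int = 2
    modules: tuple[ModuleSpec, ...] = (
        ModuleSpec(120, "ovary"), ModuleSpec(80, "venom_gland"), ModuleSpec(50, None))
    factor_loading: float = 2.0   # with noise_sigma 1.0 -> within-module r ~ 0.8
    noise_sigma: float = 1.0
    bias_effect: float = 6.0      # log2 boost in the designated tissue
    age_baselines: tuple[float, float, float] = (5.0, 3.5, 1.5)  # branch 0-1 / 2-3 / 4-6
    age_trend: bool = True

    def __post_init__(self):
        if self.pair_omega <= 0 or self.noise_sigma <= 0:
            raise ValidationError("omega and noise sigma must be positive")
        if any(n < 0 for n in self.births_per_branch.values()):
            raise ValidationError("birth counts must be >= 0")


@dataclass
class GroundTruth:
    branch: dict[str, int] = field(default_factory=dict)
    mechanism: dict[str, str] = field(default_factory=dict)
    parent: dict[str, str] = field(default_factory=dict)
    omega: dict[str, float] = field(default_factory=dict)
    decoy_reason: dict[str, str] = field(default_factory=dict)
    denovo_events: dict[str, dict] = field(default_factory=dict)
    module: dict[str, int] = field(default_factory=dict)
    biased_tissue: dict[str, str] = field(default_factory=dict)
    venom_genes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "branch": self.branch, "mechanism": self.mechanism,
            "parent": self.parent, "omega": self.omega,
            "decoy_reason": self.decoy_reason, "denovo_events": self.denovo_events,
            "module": self.module, "biased_tissue": self.biased_tissue,
            "venom_genes": self.venom_genes,
        }


@dataclass
class GeneSetFixture:
    tree: SpeciesTree
    genes: list[GeneModel]
    cds: dict[str, str]
    protein: dict[str, str]
    synteny: pd.DataFrame
    repeats: RepeatTrack
    paralog_hits: list[HomologyHit]
    protein_hits: list[HomologyHit]
    dna_hits: list[HomologyHit]
    outgroup_nt: dict[str, tuple[str, str]]   # de novo gene -> (species, sequence)
    truth: GroundTruth


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def _random_cds(rng: np.random.Generator, n_codons: int, pi: np.ndarray) -> str:
    """Random sense-codon CDS starting with ATG (no internal stops)."""
    idx = rng.choice(sel.N_SENSE, size=n_codons, p=pi)
    codons = [sel.SENSE_CODONS[i] for i in idx]
    codons[0] = "ATG"
    return "".join(codons)


def _translate(cds: str) -> str:
    return "".join(sel.CODON_AA[cds[k:k + 3]] for k in range(0, len(cds), 3))


def evolve_cds(cds: str, omega: float, t: float, kappa: float,
               rng: np.random.Generator, pi: np.ndarray | None = None) -> str:
    """Evolve a CDS along time t under the pairwise codon model's rate matrix."""
    if pi is None:
        pi = sel.uniform_codon_frequencies()
    Q = sel.build_rate_matrix(kappa, omega, pi)
    P = linalg.expm(Q * t)
    out = []
    for k in range(0, len(cds), 3):
        i = sel.CODON_INDEX[cds[k:k + 3]]
        j = rng.choice(sel.N_SENSE, p=P[i] / P[i].sum())
        out.append(sel.SENSE_CODONS[j])
    return "".join(out)


def simulate_codon_pair(omega: float, t: float, kappa: float, n_codons: int,
                        seed: int | np.random.Generator) -> tuple[str, str]:
    """An ancestor/descendant CDS pair evolved at the given omega and t.

    The ancestor is drawn from the model's stationary codon frequencies
    (uniform nucleotide composition, stops excluded); the descendant evolves
    under the same rate matrix used by the ML estimator.  t = 0 returns an
    identical pair.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pi = sel.uniform_codon_frequencies()
    idx = rng.choice(sel.N_SENSE, size=n_codons, p=pi)
    anc = "".join(sel.SENSE_CODONS[i] for i in idx)
    if t == 0:
        return anc, anc
    return anc, evolve_cds(anc, omega, t, kappa, rng, pi)


# ---------------------------------------------------------------------------
# gene-set fixture
# ---------------------------------------------------------------------------

def _make_exons(rng: np.random.Generator, start: int, total_len: int, n_exons: int
                ) -> list[tuple[int, int]]:
    """Partition ``total_len`` exonic bases into n_exons exons with introns."""
    if n_exons == 1:
        return [(start, start + total_len - 1)]
    cuts = np.sort(rng.choice(np.arange(1, total_len), size=n_exons - 1, replace=False))
    sizes = np.diff(np.concatenate([[0], cuts, [total_len]]))
    exons = []
    pos = start
    for sz in sizes:
        exons.append((pos, pos + int(sz) - 1))
        pos += int(sz) + int(rng.integers(80, 300))  # intron
    return exons


def simulate_gene_set(config: SimulationConfig | None = None,
                      rng: np.random.Generator | None = None) -> GeneSetFixture:
    """Generate the full dating/classification input set with ground truth."""
    config = config or SimulationConfig()
    rng = rng or np.random.default_rng(config.seed)
    tree = SpeciesTree.from_newick(config.tree_newick, config.reference)
    species = sorted(tree.non_reference_leaves)
    n_groups = len(tree.groups)
    truth = GroundTruth()

    genes: list[GeneModel] = []
    cds: dict[str, str] = {}
    presence_rows: dict[str, dict[str, int]] = {}
    repeat_ivs: dict[str, list[tuple[int, int]]] = {}
    paralog_hits: list[HomologyHit] = []
    protein_hits: list[HomologyHit] = []
    dna_hits: list[HomologyHit] = []
    outgroup_nt: dict[str, tuple[str, str]] = {}

    cursor = {"chr1": 1000}
    pi = sel.uniform_codon_frequencies()

    def place_gene(gid: str, n_codons: int, n_exons: int, seq: str | None = None,
                   chrom: str = "chr1") -> GeneModel:
        s = seq if seq is not None else _random_cds(rng, n_codons, pi)
        total = len(s)
        start = cursor[chrom]
        exons = _make_exons(rng, start, total, n_exons)
        g = GeneModel(gene_id=gid, chrom=chrom, start=exons[0][0], end=exons[-1][1],
                      strand="+" if rng.random() < 0.5 else "-",
                      exons=exons, cds_length=total)
        cursor[chrom] = exons[-1][1] + int(rng.integers(500, 2000))
        genes.append(g)
        cds[gid] = s
        return g

    def presence_for_branch(branch: int) -> dict[str, int]:
        row = {}
        for gi, grp in enumerate(tree.groups):
            for sp in grp:
                row[sp] = 1 if gi >= branch else 0
        return row

    # --- background genes on branches 0-3 -----------------------------------
    weights = np.array(config.background_branch_weights, dtype=float)
    weights = weights / weights.sum()
    bg_branches = rng.choice(len(weights), size=config.n_background, p=weights)
    background_ids = []
    for k, b in enumerate(bg_branches):
        gid = f"BG{k:04d}"
        n_codons = int(rng.integers(150, 400))
        n_exons = int(rng.integers(2, 8))
        place_gene(gid, n_codons, n_exons)
        presence_rows[gid] = presence_for_branch(int(b))
        truth.branch[gid] = int(b)
        background_ids.append(gid)

    old_multi_exon = [g for g in genes if g.n_exons >= 2 and truth.branch[g.gene_id] <= 3]

    # --- planted new-gene births --------------------------------------------
    mech_i = 0
    planted = []
    for branch, count in sorted(config.births_per_branch.items()):
        for k in range(count):
            mech = config.mechanism_cycle[mech_i % len(config.mechanism_cycle)]
            mech_i += 1
            gid = f"NG{branch}{k:03d}"
            if mech in ("dna_duplication", "retroposition"):
                parent = old_multi_exon[int(rng.integers(len(old_multi_exon)))]
                child_seq = evolve_cds(cds[parent.gene_id], config.pair_omega,
                                       config.pair_t, config.pair_kappa, rng, pi)
                n_exons = 1 if mech == "retroposition" else int(rng.integers(2, 5))
                place_gene(gid, 0, n_exons, seq=child_seq)
                truth.parent[gid] = parent.gene_id
                truth.omega[gid] = config.pair_omega
                paralog_hits.append(HomologyHit(
                    query_id=gid, target_id=parent.gene_id, species=config.reference,
                    percent_identity=85.0, evalue=1e-80,
                    alignment_length=len(child_seq) // 3, bitscore=300.0))
                # a weaker decoy paralog hit keeps parent picking honest
                decoy = background_ids[int(rng.integers(len(background_ids)))]
                if decoy != parent.gene_id:
                    paralog_hits.append(HomologyHit(
                        query_id=gid, target_id=decoy, species=config.reference,
                        percent_identity=30.0, evalue=1e-8,
                        alignment_length=60, bitscore=55.0))
            else:  # de novo
                n_codons = int(rng.integers(60, 160))
                g = place_gene(gid, n_codons, 1)
                # outgroup non-coding ortholog: ORF with the inverse enabling
                # events applied (one premature stop + one 1-nt frameshift)
                orf = cds[gid]
                seq = list(orf)
                stop_codon = int(rng.integers(2, len(orf) // 3 - 2))
                seq[3 * stop_codon:3 * stop_codon + 3] = list("TAA")
                del_pos = int(rng.integers(3, len(seq) - 6))
                del seq[del_pos]
                sp = sorted(tree.groups[-2])[0]  # a close non-sister species
                outgroup_nt[gid] = (sp, "".join(seq))
                truth.denovo_events[gid] = {"premature_stops": 1, "frameshifts": 1}
                # one DNA ortholog per close species, good coverage
                for grp in tree.groups[-2:]:
                    for s in sorted(grp):
                        span = int(rng.uniform(0.5, 0.95) * len(cds[gid]))
                        dna_hits.append(HomologyHit(
                            query_id=gid, target_id=f"{s}_locus_{gid}", species=s,
                            percent_identity=90.0, evalue=1e-30,
                            alignment_length=span, bitscore=100.0,
                            query_coverage=span / len(cds[gid])))
            presence_rows[gid] = presence_for_branch(branch)
            truth.branch[gid] = branch
            truth.mechanism[gid] = mech
            planted.append(gid)

    # --- decoys --------------------------------------------------------------
    for k in range(config.n_decoy_repeat):
        gid = f"DR{k:03d}"
        g = place_gene(gid, int(rng.integers(100, 200)), 1)
        presence_rows[gid] = presence_for_branch(5)
        truth.decoy_reason[gid] = "repeat_overlap"
        span = g.end - g.start + 1
        cov = int(0.8 * span)
        repeat_ivs.setdefault(g.chrom, []).append((g.start - 1, g.start - 1 + cov))
    for k in range(config.n_decoy_patchy):
        gid = f"DP{k:03d}"
        place_gene(gid, int(rng.integers(100, 200)), 2)
        row = {sp: 0 for sp in species}
        for sp in tree.groups[0]:
            row[sp] = 1  # present only in the deepest outgroup: patchy
        presence_rows[gid] = row
        truth.decoy_reason[gid] = "patchy"
    for k in range(config.n_decoy_homology):
        gid = f"DH{k:03d}"
        place_gene(gid, int(rng.integers(100, 200)), 2)
        presence_rows[gid] = presence_for_branch(5)
        truth.decoy_reason[gid] = "homology_conflict"
        old_sp = sorted(tree.groups[0])[0]
        protein_hits.append(HomologyHit(
            query_id=gid, target_id=f"{old_sp}_prot_{k}", species=old_sp,
            percent_identity=45.0, evalue=1e-30, alignment_length=120, bitscore=150.0))

    # --- presence-flip noise --------------------------------------------------
    if config.presence_flip_rate > 0:
        for gid in planted:
            if rng.random() < config.presence_flip_rate:
                sp = species[int(rng.integers(len(species)))]
                presence_rows[gid][sp] = 1 - presence_rows[gid][sp]

    truth.venom_genes = sorted(
        rng.choice(background_ids, size=min(config.n_venom_genes, len(background_ids)),
                   replace=False).tolist())

    synteny = pd.DataFrame.from_dict(presence_rows, orient="index")[species]
    synteny = synteny.loc[[g.gene_id for g in genes]]
    protein = {gid: _translate(s) for gid, s in cds.items()}
    return GeneSetFixture(
        tree=tree, genes=genes, cds=cds, protein=protein, synteny=synteny,
        repeats=RepeatTrack(repeat_ivs), paralog_hits=paralog_hits,
        protein_hits=protein_hits, dna_hits=dna_hits,
        outgroup_nt=outgroup_nt, truth=truth)


# ---------------------------------------------------------------------------
# expression fixture
# ---------------------------------------------------------------------------

def simulate_expression(config: SimulationConfig | None = None,
                        gene_ids: Sequence[str] | None = None,
                        branch_by_gene: Mapping[str, int] | None = None,
                        truth: GroundTruth | None = None,
                        rng: np.random.Generator | None = None) -> ExpressionMatrix:
    """Generate a TPM matrix with planted modules, tissue bias and age trend.

    When ``gene_ids``/``branch_by_gene`` come from a gene-set fixture the
    age-dependent abundance trend uses the true branches; new genes
    designated tissue-biased get a ``bias_effect`` log2 boost in their
    tissue.  Module membership and biased tissues are recorded on ``truth``.
    """
    config = config or SimulationConfig()
    rng = rng or np.random.default_rng(config.seed + 1)
    truth = truth if truth is not None else GroundTruth()
    if gene_ids is None:
        gene_ids = [f"G{k:04d}" for k in range(sum(m.size for m in config.modules) + 100)]
        branch_by_gene = {}
    branch_by_gene = branch_by_gene or {}

    samples = [f"{t}_r{r + 1}" for t in config.tissues for r in range(config.replicates)]
    sample_tissue = {s: s.rsplit("_r", 1)[0] for s in samples}
    n_s = len(samples)
    tissue_of_sample = np.array([sample_tissue[s] for s in samples])

    # module factors over samples
    factors = []
    for m in config.modules:
        if m.tissue is not None:
            ind = (tissue_of_sample == m.tissue).astype(float)
            f = 1.5 * ind + rng.normal(0.0, 0.3, size=n_s)
        else:
            f = rng.normal(0.0, 1.0, size=n_s)
        factors.append((f - f.mean()) / f.std())

    # deterministic module assignment: first genes fill modules in order
    gene_module = {}
    idx = 0
    for mi, m in enumerate(config.modules, start=1):
        for _ in range(m.size):
            if idx >= len(gene_ids):
                break
            gene_module[gene_ids[idx]] = mi
            idx += 1

    # designated tissue-biased genes: the planted new genes, round-robin
    # over tissues, so every tissue has some specifically expressed new gene
    new_ids = [g for g in gene_ids if branch_by_gene.get(g, 0) >= 4
               and truth.decoy_reason.get(g) is None]
    bias_of = {}
    for k, gid in enumerate(new_ids):
        bias_of[gid] = config.tissues[k % len(config.tissues)]

    base_by_group = dict(zip(("old", "mid", "new"), config.age_baselines))

    rows = np.empty((len(gene_ids), n_s))
    for gi, gid in enumerate(gene_ids):
        b = branch_by_gene.get(gid, 0)
        grp = "old" if b <= 1 else ("mid" if b <= 3 else "new")
        base = base_by_group[grp] if config.age_trend else base_by_group["mid"]
        base = base + rng.normal(0.0, 0.8)
        x = np.full(n_s, base)
        mi = gene_module.get(gid)
        if mi is not None:
            x = x + config.factor_loading * factors[mi - 1]
            truth.module[gid] = mi
        if gid in bias_of:
            # tissue-specific, low-abundance profile: a modest peak in the
            # designated tissue and near-zero expression elsewhere, so new
            # genes stay below older genes in maximum expression
            t = bias_of[gid]
            ind = (tissue_of_sample == t).astype(float)
            x = base + 1.0 + config.bias_effect * (ind - 1.0)
            x = x + rng.normal(0.0, config.noise_sigma, size=n_s)
            truth.biased_tissue[gid] = t
            rows[gi] = np.maximum(2.0 ** x - 1.0, 0.0)
            continue
        x = x + rng.normal(0.0, config.noise_sigma, size=n_s)
        rows[gi] = np.maximum(2.0 ** x - 1.0, 0.0)  # back to TPM scale

    df = pd.DataFrame(np.round(rows, 4), index=list(gene_ids), columns=samples)
    return ExpressionMatrix(df, sample_tissue, list(config.tissues))


# ---------------------------------------------------------------------------
# fixture writer
# ---------------------------------------------------------------------------

def write_fixture(config: SimulationConfig, out_dir) -> dict[str, Path]:
    """Write the complete fixture tree (all pipeline inputs + ground truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    fx = simulate_gene_set(config, rng)
    expr = simulate_expression(
        config, gene_ids=[g.gene_id for g in fx.genes],
        branch_by_gene=fx.truth.branch, truth=fx.truth, rng=rng)

    paths = {
        "gff": out / "genes.gff3",
        "cds": out / "cds.fa",
        "protein": out / "protein.fa",
        "synteny": out / "synteny.tsv",
        "repeats": out / "repeats.bed",
        "paralog_hits": out / "paralog_hits.tsv",
        "protein_hits": out / "protein_hits.tsv",
        "dna_hits": out / "dna_hits.tsv",
        "outgroup_nt": out / "outgroup_nt.fa",
        "tree": out / "tree.nwk",
        "expression": out / "expression.tsv",
        "sample_map": out / "sample_map.tsv",
        "venom_genes": out / "venom_genes.txt",
        "ground_truth": out / "ground_truth.json",
    }
    write_gff3(fx.genes, paths["gff"])
    write_fasta(fx.cds, paths["cds"])
    write_fasta(fx.protein, paths["protein"])
    write_synteny_tsv(fx.synteny, paths["synteny"])
    fx.repeats.to_bed(paths["repeats"])
    write_homology_tsv(fx.paralog_hits, paths["paralog_hits"])
    write_homology_tsv(fx.protein_hits, paths["protein_hits"])
    write_homology_tsv(fx.dna_hits, paths["dna_hits"])
    write_fasta({f"{gid}|{sp}": s for gid, (sp, s) in fx.outgroup_nt.items()},
                paths["outgroup_nt"])
    paths["tree"].write_text(config.tree_newick + "\n")
    expr.to_tsv(paths["expression"])
    with open(paths["sample_map"], "w") as fh:
        for s in expr.samples:
            fh.write(f"{s}\t{expr.sample_tissue[s]}\n")
    paths["venom_genes"].write_text("\n".join(fx.truth.venom_genes) + "\n")
    write_json(fx.truth.to_dict(), paths["ground_truth"])
    return paths
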