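"""Synteny-based gene-age dating.

Each reference gene is assigned an integer branch age along the
root-to-reference path of the species tree from the presence/absence of a
syntenic ortholocus in every other species: the deepest split whose species
group still contains the gene fixes the branch.  Three quality filters are
applied before a gene may be called new:

* repeat filter — genes whose exonic regions are more than 70% covered by
  repetitive elements are excluded (likely annotation artefacts);
* patchy filter — presence in a distant lineage combined with complete
  absence of an intermediate split's species group is inconsistent with a
  single origin and the gene is excluded from dating;
* homology validation — a candidate new gene with a qualifying protein
  homolog (identity > 20%, E-value < 1e-5) in a species older than its
  assigned branch cannot be new and is excluded.

Genes on a branch at or above ``new_gene_branch_threshold`` (default 4, the
split that separates the reference clade from its closest dated outgroups)
that survive all filters are flagged as new genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from genebirth.io_formats import (
    GeneModel,
    HomologyHit,
    RepeatTrack,
    SpeciesTree,
    ValidationError,
    exonic_overlap_fraction,
)

PATCHY = "patchy"

REASON_NONE = "none"
REASON_REPEAT = "repeat_overlap"
REASON_PATCHY = "patchy"
REASON_HOMOLOGY = "homology_conflict"


@dataclass
class DatingConfig:
    new_gene_branch_threshold: int = 4
    repeat_overlap_threshold: float = 0.70
    homology_identity_min: float = 20.0
    homology_evalue_max: float = 1e-5


@dataclass
class AgedGene:
    """A dated reference gene: branch index, new-gene flag, exclusion reason."""

    gene_id: str
    branch: int | None
    is_new: bool
    excluded_reason: str = REASON_NONE

    def __post_init__(self):
        if self.is_new and self.excluded_reason != REASON_NONE:
            raise ValidationError(f"{self.gene_id}: excluded gene cannot be new")


def assign_branch(presence: Mapping[str, bool], tree: SpeciesTree) -> int | str:
    """Assign a branch age from a per-species presence vector.

    ``presence`` maps every non-reference leaf to a boolean (syntenic locus
    found).  Returns the branch index, or the string ``"patchy"`` when a
    species at a deeper split is present while the species group of some
    shallower (more recent) split is entirely absent — a distribution that no
    single origin explains.
    """
    missing = tree.non_reference_leaves - set(presence)
    if missing:
        raise ValidationError(f"species missing from presence vector: {sorted(missing)}")
    group_present = [any(presence[sp] for sp in grp) for grp in tree.groups]
    try:
        deepest = group_present.index(True)
    except ValueError:
        return tree.n_branches - 1  # absent everywhere: reference-specific
    if not all(group_present[deepest:]):
        return PATCHY
    return deepest


def apply_repeat_filter(genes: Iterable[GeneModel], repeats: RepeatTrack,
                        threshold: float = 0.70) -> set[str]:
    """Gene ids whose exonic repeat-overlap fraction strictly exceeds the threshold."""
    excluded = set()
    for g in genes:
        if exonic_overlap_fraction(g, repeats) > threshold:
            excluded.add(g.gene_id)
    return excluded


def validate_new_gene_homology(gene_id: str, branch: int,
                               hits: Sequence[HomologyHit], tree: SpeciesTree,
                               identity_min: float = 20.0,
                               evalue_max: float = 1e-5) -> str:
    """Check a candidate new gene against cross-species protein hits.

    Returns ``"conflict"`` when a qualifying hit (identity strictly above
    ``identity_min`` and E-value strictly below ``evalue_max``) exists in a
    species that diverged before the gene's assigned branch; ``"pass"``
    otherwise.
    """
    older = tree.species_older_than_branch(branch)
    for h in hits:
        if h.query_id != gene_id:
            continue
        if h.species in older and h.percent_identity > identity_min and h.evalue < evalue_max:
            return "conflict"
    return "pass"


def presence_from_table(synteny: pd.DataFrame, tree: SpeciesTree) -> dict[str, dict[str, bool]]:
    """Convert a synteny table (flags or coverage fractions) to presence vectors."""
    expected = tree.non_reference_leaves
    cols = set(synteny.columns)
    if cols != expected:
        raise ValidationError(
            f"synteny table species {sorted(cols)} != tree non-reference leaves {sorted(expected)}")
    return {
        gene_id: {sp: bool(row[sp] > 0) for sp in synteny.columns}
        for gene_id, row in synteny.iterrows()
    }


def date_genome(genes: Sequence[GeneModel], synteny: pd.DataFrame,
                repeats: RepeatTrack, hits: Sequence[HomologyHit],
                tree: SpeciesTree, config: DatingConfig | None = None) -> list[AgedGene]:
    """Date every gene and flag new genes, applying all filters.

    Output order follows input order.  A gene is never dropped: failures are
    reported through ``excluded_reason`` (checked in the order repeat overlap,
    patchy distribution, homology conflict).  Genes missing from the synteny
    table are treated as an input error.
    """
    config = config or DatingConfig()
    presence = presence_from_table(synteny, tree)
    repeat_excluded = apply_repeat_filter(genes, repeats, config.repeat_overlap_threshold)

    out: list[AgedGene] = []
    for g in genes:
        if g.gene_id not in presence:
            raise ValidationError(f"gene {g.gene_id} missing from synteny table")
        if g.gene_id in repeat_excluded:
            out.append(AgedGene(g.gene_id, None, False, REASON_REPEAT))
            continue
        branch = assign_branch(presence[g.gene_id], tree)
        if branch == PATCHY:
            out.append(AgedGene(g.gene_id, None, False, REASON_PATCHY))
            continue
        is_new = branch >= config.new_gene_branch_threshold
        if is_new:
            verdict = validate_new_gene_homology(
                g.gene_id, branch, hits, tree,
                config.homology_identity_min, config.homology_evalue_max)
            if verdict == "conflict":
                out.append(AgedGene(g.gene_id, branch, False, REASON_HOMOLOGY))
                continue
        out.append(AgedGene(g.gene_id, branch, is_new))
    return out


def aged_genes_to_frame(aged: Sequence[AgedGene]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"gene_id": a.gene_id,
          "branch": -1 if a.branch is None else a.branch,
          "is_new": a.is_new,
          "excluded_reason": a.excluded_reason} for a in aged]
    ).set_index("gene_id")


def write_aged_tsv(aged: Sequence[AgedGene], path) -> None:
    aged_genes_to_frame(aged).to_csv(path, sep="\t")


def read_aged_tsv(path) -> list[AgedGene]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return [
        AgedGene(gene_id=str(gid),
                 branch=None if row["branch"] < 0 else int(row["branch"]),
                 is_new=bool(row["is_new"]),
                 excluded_reason=str(row["excluded_reason"]))
        for gid, row in df.iterrows()
    ]
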