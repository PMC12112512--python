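"""Origin-mechanism classification for new genes.

New genes are partitioned into three mechanisms:

* **DNA-mediated duplication** — the default for any new gene with an older
  paralogous parent;
* **retroposition (RNA-mediated duplication)** — an intronless (single-exon)
  child derived from a parent with at least one intron (>= 2 exons), the
  hallmark of reverse-transcribed mRNA reinsertion;
* **de novo birth** — no parental paralog, with sequential homology criteria
  met, and enabling mutations (frameshift indels, premature-stop removal)
  traceable against the closest outgroup non-coding ortholog.

A new gene matching none of these is reported with an explicit
``unclassified`` status rather than silently dropped.  Note that a retrocopy
of an ancestrally intronless parent is indistinguishable from a DNA
duplication by exon structure and is labelled dna_duplication.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from Bio.Align import PairwiseAligner

from genebirth.io_formats import GeneModel, HomologyHit, ValidationError

MECH_DNA = "dna_duplication"
MECH_RETRO = "retroposition"
MECH_DENOVO = "de_novo"
MECH_UNCLASSIFIED = "unclassified"

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class MutationEvent:
    """One enabling-mutation event relative to the outgroup ortholog.

    ``kind`` is one of frameshift_insertion, frameshift_deletion,
    substitution, premature_stop.  ``position`` is a 1-based coordinate on
    the ORF (codon index for premature_stop).  ``length`` applies to indels;
    ``base_from``/``base_to`` to substitutions (outgroup -> ORF, without any
    claim about ancestral direction).
    """

    kind: str
    position: int
    length: int = 0
    base_from: str = ""
    base_to: str = ""


@dataclass
class DeNovoEvidence:
    outgroup_species: str
    events: list[MutationEvent] = field(default_factory=list)

    @property
    def n_frameshifts(self) -> int:
        return sum(1 for e in self.events if e.kind.startswith("frameshift"))

    @property
    def n_premature_stops(self) -> int:
        return sum(1 for e in self.events if e.kind == "premature_stop")

    @property
    def n_substitutions(self) -> int:
        return sum(1 for e in self.events if e.kind == "substitution")


@dataclass
class OriginCall:
    gene_id: str
    mechanism: str
    parent_id: str | None = None
    evidence: str = ""
    denovo: DeNovoEvidence | None = None

    def __post_init__(self):
        if self.mechanism in (MECH_DNA, MECH_RETRO) and self.parent_id is None:
            raise ValidationError(f"{self.gene_id}: duplication call without parent")
        if self.mechanism == MECH_DENOVO and self.parent_id is not None:
            raise ValidationError(f"{self.gene_id}: de novo call with parent")


def find_parent(child_id: str, paralog_hits: Sequence[HomologyHit],
                branch_by_gene: Mapping[str, int | None],
                max_parent_branch: int = 3) -> str | None:
    """Pick the closest old paralog of a new gene from within-genome hits.

    Candidate parents are restricted to dated genes on branches
    ``0..max_parent_branch`` (old duplicates).  The best hit wins: lowest
    E-value, then highest bitscore, then lexicographically smallest target
    id.  Self-hits are ignored.
    """
    candidates = []
    for h in paralog_hits:
        if h.query_id != child_id or h.target_id == child_id:
            continue
        b = branch_by_gene.get(h.target_id)
        if b is None or b > max_parent_branch:
            continue
        candidates.append(h)
    if not candidates:
        return None
    best = min(candidates, key=lambda h: (h.evalue, -h.bitscore, h.target_id))
    return best.target_id


def classify_mechanism(child: GeneModel, parent: GeneModel | None,
                       denovo: DeNovoEvidence | None = None,
                       denovo_ok: bool = False) -> OriginCall:
    """Apply the mechanism rules to a single new gene.

    Intronless child (1 exon) of an intron-bearing parent (>= 2 exons) is a
    retrocopy; any other child with a parent is a DNA duplication; a gene
    with no parent is de novo only when the sequential homology criteria
    passed (``denovo_ok``).
    """
    if parent is not None:
        if child.n_exons == 1 and parent.n_exons >= 2:
            mech = MECH_RETRO
            why = f"intronless child of {parent.n_exons}-exon parent {parent.gene_id}"
        else:
            mech = MECH_DNA
            why = (f"{child.n_exons}-exon child of {parent.n_exons}-exon "
                   f"parent {parent.gene_id}")
        return OriginCall(child.gene_id, mech, parent_id=parent.gene_id, evidence=why)
    if denovo_ok:
        return OriginCall(child.gene_id, MECH_DENOVO, evidence="de novo criteria passed",
                          denovo=denovo)
    return OriginCall(child.gene_id, MECH_UNCLASSIFIED,
                      evidence="no parental paralog and de novo criteria not met")


def check_de_novo_criteria(orf_id: str, protein_hits: Sequence[HomologyHit],
                           dna_hits: Sequence[HomologyHit], outgroup_species: str,
                           min_dna_coverage: float = 0.20) -> tuple[bool, str | None]:
    """Sequential criteria for a de novo candidate ORF.

    1. no protein homolog in the designated outgroup species and at most one
       protein homolog in each other species;
    2. at most one homologous DNA sequence per species, with at least one
       ortholog covering strictly more than ``min_dna_coverage`` of the ORF.

    Returns ``(passed, reason)`` where ``reason`` names the failed criterion.
    """
    prot_per_species: dict[str, int] = {}
    for h in protein_hits:
        if h.query_id == orf_id:
            prot_per_species[h.species] = prot_per_species.get(h.species, 0) + 1
    if prot_per_species.get(outgroup_species, 0) > 0:
        return False, "criterion 1: protein homolog in outgroup"
    if any(n > 1 for n in prot_per_species.values()):
        return False, "criterion 1: more than one protein homolog in a species"

    dna_per_species: dict[str, int] = {}
    best_cov = 0.0
    any_dna = False
    for h in dna_hits:
        if h.query_id != orf_id:
            continue
        any_dna = True
        dna_per_species[h.species] = dna_per_species.get(h.species, 0) + 1
        if h.query_coverage is not None:
            best_cov = max(best_cov, h.query_coverage)
    if any(n > 1 for n in dna_per_species.values()):
        return False, "criterion 2: more than one homologous DNA sequence in a species"
    if not any_dna or best_cov <= min_dna_coverage:
        return False, "criterion 2: no DNA ortholog with coverage > 20%"
    return True, None


def _make_aligner(match: float = 1.0, mismatch: float = -1.0,
                  gap_open: float = -2.0, gap_extend: float = -0.5) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def reconstruct_enabling_mutations(orf_nt: str, outgroup_nt: str,
                                   outgroup_species: str = "outgroup",
                                   aligner: PairwiseAligner | None = None) -> DeNovoEvidence:
    """Trace the mutations separating an ORF from its outgroup non-coding ortholog.

    The two sequences are globally aligned (match +1, mismatch -1, gap open
    -2, gap extend -0.5 by default).  Indels whose length is not a multiple
    of 3 become frameshift events (a gap in the outgroup row is a deletion
    relative to the ORF; a gap in the ORF row an insertion).  The aligned
    outgroup sequence is then read in the ORF's frame: an in-frame stop codon
    before the ORF's final codon is reported as a premature stop.  Aligned
    mismatches become substitution events.
    """
    orf_nt = orf_nt.upper().replace("U", "T")
    outgroup_nt = outgroup_nt.upper().replace("U", "T")
    if not orf_nt or not outgroup_nt:
        raise ValidationError("empty sequence")
    aligner = aligner or _make_aligner()
    aln = aligner.align(orf_nt, outgroup_nt)[0]
    row_orf, row_out = str(aln[0]), str(aln[1])

    events: list[MutationEvent] = []
    orf_pos = 0  # 0-based ORF coordinate consumed so far
    i = 0
    ncols = len(row_orf)
    # codon-aligned outgroup bases at in-frame ORF positions (None where gapped)
    frame_bases: list[str | None] = [None] * len(orf_nt)
    while i < ncols:
        a, b = row_orf[i], row_out[i]
        if a != "-" and b != "-":
            frame_bases[orf_pos] = b
            if a != b:
                events.append(MutationEvent("substitution", orf_pos + 1,
                                            base_from=b, base_to=a))
            orf_pos += 1
            i += 1
        elif b == "-":  # gap in outgroup: deletion relative to the ORF
            j = i
            while j < ncols and row_out[j] == "-":
                j += 1
            length = j - i
            if length % 3 != 0:
                events.append(MutationEvent("frameshift_deletion", orf_pos + 1, length=length))
            orf_pos += length
            i = j
        else:  # gap in ORF: insertion in the outgroup
            j = i
            while j < ncols and row_orf[j] == "-":
                j += 1
            length = j - i
            if length % 3 != 0:
                events.append(MutationEvent("frameshift_insertion", orf_pos + 1, length=length))
            i = j

    n_codons = len(orf_nt) // 3
    for c in range(n_codons - 1):  # terminal codon excluded
        triplet = frame_bases[3 * c:3 * c + 3]
        if None in triplet:
            continue
        if "".join(triplet) in STOP_CODONS:  # type: ignore[arg-type]
            events.append(MutationEvent("premature_stop", c + 1))

    events.sort(key=lambda e: (e.position, e.kind))
    return DeNovoEvidence(outgroup_species=outgroup_species, events=events)


def classify_new_genes(new_gene_ids: Sequence[str],
                       models: Mapping[str, GeneModel],
                       branch_by_gene: Mapping[str, int | None],
                       paralog_hits: Sequence[HomologyHit],
                       protein_hits: Sequence[HomologyHit],
                       dna_hits: Sequence[HomologyHit],
                       outgroup_species: str,
                       outgroup_nt: Mapping[str, tuple[str, str]] | None = None,
                       orf_nt: Mapping[str, str] | None = None,
                       max_parent_branch: int = 3) -> list[OriginCall]:
    """Classify every new gene; the calls partition the input id list.

    ``outgroup_nt`` optionally maps a de novo candidate to
    ``(species, sequence)`` of its closest outgroup non-coding ortholog, and
    ``orf_nt`` to its own CDS, enabling mutation reconstruction.
    """
    calls = []
    for gid in new_gene_ids:
        if gid not in models:
            raise ValidationError(f"new gene {gid} missing from gene models")
        parent_id = find_parent(gid, paralog_hits, branch_by_gene, max_parent_branch)
        parent = models.get(parent_id) if parent_id else None
        if parent_id is not None and parent is None:
            raise ValidationError(f"parent {parent_id} of {gid} missing from gene models")
        denovo_ok = False
        denovo = None
        if parent is None:
            denovo_ok, _reason = check_de_novo_criteria(
                gid, protein_hits, dna_hits, outgroup_species)
            if denovo_ok and outgroup_nt and orf_nt and gid in outgroup_nt and gid in orf_nt:
                sp, seq = outgroup_nt[gid]
                denovo = reconstruct_enabling_mutations(orf_nt[gid], seq, sp)
        calls.append(classify_mechanism(models[gid], parent, denovo, denovo_ok))
    return calls


def calls_to_frame(calls: Sequence[OriginCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append({
            "gene_id": c.gene_id,
            "mechanism": c.mechanism,
            "parent_id": c.parent_id or "",
            "n_frameshifts": c.denovo.n_frameshifts if c.denovo else 0,
            "n_premature_stops": c.denovo.n_premature_stops if c.denovo else 0,
        })
    return pd.DataFrame(rows).set_index("gene_id")


def write_calls_tsv(calls: Sequence[OriginCall], path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t")
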