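"""Readers, writers and core containers for the pipeline's external formats.

One coordinate convention is used internally everywhere: 1-based inclusive
intervals (the GFF3 convention).  BED input, which is 0-based half-open, is
converted at the boundary by :func:`bed_to_internal` / :func:`internal_to_bed`.
Strand is carried on gene models but all overlap and length computations are
strand-agnostic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class ParseError(ValueError):
    """Raised when an input file is malformed; carries the offending line."""

    def __init__(self, message: str, path=None, line_number: int | None = None):
        self.path = path
        self.line_number = line_number
        loc = ""
        if path is not None:
            loc += f" in {path}"
        if line_number is not None:
            loc += f" at line {line_number}"
        super().__init__(message + loc)


class ValidationError(ValueError):
    """Raised when parsed records violate a container invariant."""


# ---------------------------------------------------------------------------
# coordinate conversion
# ---------------------------------------------------------------------------

def bed_to_internal(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based inclusive."""
    if end <= start:
        raise ValidationError(f"empty or inverted BED interval [{start},{end})")
    return start + 1, end


def internal_to_bed(start: int, end: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open."""
    if end < start:
        raise ValidationError(f"inverted interval {start}..{end}")
    return start - 1, end


# ---------------------------------------------------------------------------
# gene models (GFF3)
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A protein-coding gene with its representative transcript structure.

    Coordinates are 1-based inclusive.  ``exons`` is the exon list of the
    representative transcript (the one with the longest CDS), sorted in
    genomic order and non-overlapping.  ``cds_length`` is the summed CDS
    length of that transcript in nucleotides.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]
    cds_length: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise ValidationError(f"{self.gene_id}: gene without exons")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValidationError(f"{self.gene_id}: inverted exon {s}..{e}")
            if prev_end is not None and s <= prev_end:
                raise ValidationError(f"{self.gene_id}: overlapping exons")
            prev_end = e

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exonic_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def intronless(self) -> bool:
        return len(self.exons) == 1


_GFF_COLS = 9


def read_gff3(path) -> list[GeneModel]:
    """Parse a GFF3 file into one :class:`GeneModel` per gene.

    Only ``gene``/``mRNA``/``exon``/``CDS`` features are interpreted.  When a
    gene has several mRNAs the transcript with the longest total CDS is taken
    as representative; ties are broken by lexicographically smallest
    transcript id.
    """
    genes: dict[str, dict] = {}
    transcripts: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != _GFF_COLS:
                raise ParseError(
                    f"expected {_GFF_COLS} tab-separated columns, got {len(parts)}",
                    path, lineno,
                )
            chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attrs_s = parts
            if ftype not in ("gene", "mRNA", "exon", "CDS"):
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError("non-integer coordinates", path, lineno) from None
            attrs = _parse_attributes(attrs_s, path, lineno)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise ParseError("gene feature without ID attribute", path, lineno)
                genes[gid] = {"chrom": chrom, "start": start, "end": end,
                              "strand": strand, "transcripts": []}
            elif ftype == "mRNA":
                tid, parent = attrs.get("ID"), attrs.get("Parent")
                if tid is None or parent is None:
                    raise ParseError("mRNA without ID or Parent", path, lineno)
                transcripts[tid] = {"gene": parent, "exons": [], "cds": 0}
                if parent in genes:
                    genes[parent]["transcripts"].append(tid)
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None or parent not in transcripts:
                    raise ParseError("exon with unknown Parent", path, lineno)
                transcripts[parent]["exons"].append((start, end))
            elif ftype == "CDS":
                parent = attrs.get("Parent")
                if parent is None or parent not in transcripts:
                    raise ParseError("CDS with unknown Parent", path, lineno)
                transcripts[parent]["cds"] += end - start + 1

    out = []
    for gid, g in genes.items():
        tids = g["transcripts"]
        if not tids:
            raise ValidationError(f"gene {gid} has no transcripts/exons")
        # representative = longest CDS, ties by smallest transcript id
        rep = min(tids, key=lambda t: (-transcripts[t]["cds"], t))
        exons = transcripts[rep]["exons"]
        if not exons:
            raise ValidationError(f"gene {gid} representative transcript has no exons")
        out.append(GeneModel(
            gene_id=gid, chrom=g["chrom"], start=g["start"], end=g["end"],
            strand=g["strand"], exons=exons, cds_length=transcripts[rep]["cds"],
        ))
    return out


def _parse_attributes(s: str, path, lineno) -> dict[str, str]:
    attrs = {}
    for item in s.split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise ParseError(f"malformed attribute {item!r}", path, lineno)
        k, v = item.split("=", 1)
        attrs[k] = v
    return attrs


def write_gff3(genes: Iterable[GeneModel], path) -> None:
    """Write gene models as minimal gene/mRNA/exon/CDS GFF3 (round-trips)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\tgenebirth\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n")
            tid = f"{g.gene_id}.t1"
            fh.write(f"{g.chrom}\tgenebirth\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={tid};Parent={g.gene_id}\n")
            remaining = g.cds_length
            for s, e in g.exons:
                fh.write(f"{g.chrom}\tgenebirth\texon\t{s}\t{e}\t.\t{g.strand}\t.\tParent={tid}\n")
            # CDS laid out over exons from the left until cds_length is used up
            for s, e in g.exons:
                if remaining <= 0:
                    break
                span = min(remaining, e - s + 1)
                fh.write(f"{g.chrom}\tgenebirth\tCDS\t{s}\t{s + span - 1}\t.\t{g.strand}\t0\tParent={tid}\n")
                remaining -= span


# ---------------------------------------------------------------------------
# repeats (BED)
# ---------------------------------------------------------------------------

class RepeatTrack:
    """Repeat intervals per chromosome, stored 0-based half-open and merged."""

    def __init__(self, intervals: Mapping[str, Sequence[tuple[int, int]]] | None = None):
        self._by_chrom: dict[str, list[tuple[int, int]]] = {}
        if intervals:
            for chrom, ivs in intervals.items():
                self._by_chrom[chrom] = merge_intervals(ivs)

    @classmethod
    def from_bed(cls, path) -> "RepeatTrack":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ParseError("BED line with fewer than 3 columns", path, lineno)
                try:
                    start, end = int(parts[1]), int(parts[2])
                except ValueError:
                    raise ParseError("non-integer BED coordinates", path, lineno) from None
                if end <= start:
                    raise ParseError(f"empty BED interval [{start},{end})", path, lineno)
                by_chrom.setdefault(parts[0], []).append((start, end))
        return cls(by_chrom)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._by_chrom):
                for s, e in self._by_chrom[chrom]:
                    fh.write(f"{chrom}\t{s}\t{e}\n")

    def intervals(self, chrom: str) -> list[tuple[int, int]]:
        return list(self._by_chrom.get(chrom, []))

    @property
    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def __eq__(self, other):
        return isinstance(other, RepeatTrack) and self._by_chrom == other._by_chrom


def merge_intervals(ivs: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge possibly-overlapping half-open intervals into a disjoint sorted set."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def exonic_overlap_fraction(gene: GeneModel, repeats: RepeatTrack) -> float:
    """Fraction of a gene's exonic bases covered by repeat intervals.

    Exons are unioned first; the repeat track is already merged, so covered
    bases are counted once regardless of how repeat intervals are split.
    """
    exon_bed = merge_intervals([internal_to_bed(s, e) for s, e in gene.exons])
    total = sum(e - s for s, e in exon_bed)
    if total == 0:
        raise ValidationError(f"{gene.gene_id}: zero exonic length")
    covered = 0
    reps = repeats.intervals(gene.chrom)
    for xs, xe in exon_bed:
        for rs, re_ in reps:
            lo, hi = max(xs, rs), min(xe, re_)
            if hi > lo:
                covered += hi - lo
    return covered / total


# ---------------------------------------------------------------------------
# homology hits (12-column outfmt-6 + species)
# ---------------------------------------------------------------------------

@dataclass
class HomologyHit:
    """One tabular homology hit (BLAST outfmt-6 style) with a species tag."""

    query_id: str
    target_id: str
    species: str
    percent_identity: float
    evalue: float
    alignment_length: int
    bitscore: float = 0.0
    query_coverage: float | None = None  # fraction of the query aligned

    def __post_init__(self):
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValidationError(f"percent_identity {self.percent_identity} outside [0,100]")
        if self.evalue < 0:
            raise ValidationError(f"negative evalue {self.evalue}")
        if self.query_coverage is not None and not (0.0 <= self.query_coverage <= 1.0):
            raise ValidationError(f"query_coverage {self.query_coverage} outside [0,1]")


_OUTFMT6_COLS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
                 "qstart", "qend", "sstart", "send", "evalue", "bitscore", "species"]


def read_homology_tsv(path, query_lengths: Mapping[str, int] | None = None) -> list[HomologyHit]:
    """Read a 13-column hits table (outfmt-6 plus a trailing species column).

    ``query_lengths`` (nt or aa, matching the search) enables query-coverage
    fractions computed as (qend - qstart + 1) / query length.
    """
    hits = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(_OUTFMT6_COLS):
                raise ParseError(
                    f"expected {len(_OUTFMT6_COLS)} columns, got {len(parts)}", path, lineno)
            rec = dict(zip(_OUTFMT6_COLS, parts))
            cov = None
            if query_lengths is not None and rec["qseqid"] in query_lengths:
                span = int(rec["qend"]) - int(rec["qstart"]) + 1
                cov = min(1.0, span / query_lengths[rec["qseqid"]])
            try:
                hits.append(HomologyHit(
                    query_id=rec["qseqid"], target_id=rec["sseqid"], species=rec["species"],
                    percent_identity=float(rec["pident"]), evalue=float(rec["evalue"]),
                    alignment_length=int(rec["length"]), bitscore=float(rec["bitscore"]),
                    query_coverage=cov,
                ))
            except ValueError as exc:
                raise ParseError(str(exc), path, lineno) from None
    return hits


def write_homology_tsv(hits: Iterable[HomologyHit], path,
                       query_lengths: Mapping[str, int] | None = None) -> None:
    """Write hits in the 13-column layout read by :func:`read_homology_tsv`.

    qstart/qend are reconstructed from alignment length (qstart=1) so that the
    coverage fraction survives a round trip when ``query_lengths`` is given.
    """
    with open(path, "w") as fh:
        for h in hits:
            qend = h.alignment_length
            fh.write("\t".join(str(x) for x in (
                h.query_id, h.target_id, f"{h.percent_identity:.2f}", h.alignment_length,
                0, 0, 1, qend, 1, qend, f"{h.evalue:.3g}", f"{h.bitscore:.1f}", h.species,
            )) + "\n")


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

class SpeciesTree:
    """A dated species tree with branch labels along the root-to-reference path.

    Gene ages are expressed as an integer branch index ``0..S-1``: the splits
    on the path from the root to the reference leaf are ordered by decreasing
    age; a gene born before the deepest split has branch 0, a gene private to
    the reference lineage (younger than the last split) has the maximum
    branch.  ``groups[i]`` is the set of non-reference leaves whose lineage
    diverges from the reference path at split ``i`` (0 = deepest); a gene on
    branch ``b`` is expected in every group with index >= b and no group with
    index < b.
    """

    def __init__(self, tree: dendropy.Tree, reference: str):
        self.tree = tree
        self.reference = reference
        leaf_names = {lf.taxon.label for lf in tree.leaf_node_iter()}
        if reference not in leaf_names:
            raise ValidationError(f"reference leaf {reference!r} not in tree")
        self.leaves = sorted(leaf_names)

        tree.calc_node_ages(ultrametricity_precision=1e-2)
        ref_leaf = next(lf for lf in tree.leaf_node_iter() if lf.taxon.label == reference)
        path = []  # internal nodes root -> reference
        node = ref_leaf.parent_node
        while node is not None:
            path.append(node)
            node = node.parent_node
        path.reverse()

        self.split_ages: list[float] = [float(n.age) for n in path]
        if any(a2 >= a1 for a1, a2 in zip(self.split_ages, self.split_ages[1:])):
            raise ValidationError("node ages along root-to-reference path not strictly decreasing")

        # species diverging at each split, ordered deepest -> shallowest
        self.groups: list[frozenset[str]] = []
        on_path = set(path)
        for node in path:
            members = set()
            for child in node.child_nodes():
                if child in on_path or child is ref_leaf:
                    continue
                members.update(lf.taxon.label for lf in child.leaf_iter())
            self.groups.append(frozenset(members))
        if any(not g for g in self.groups):
            raise ValidationError("a split on the reference path contributes no species")

    @classmethod
    def from_newick(cls, source: str, reference: str) -> "SpeciesTree":
        """Build from a newick string or file path (branch lengths in MY)."""
        p = Path(source)
        if p.exists():
            tree = dendropy.Tree.get(path=str(p), schema="newick",
                                     preserve_underscores=True)
        else:
            tree = dendropy.Tree.get(data=source, schema="newick",
                                     preserve_underscores=True)
        return cls(tree, reference)

    @property
    def n_branches(self) -> int:
        """Number of branch-age classes (number of splits + 1)."""
        return len(self.groups) + 1

    @property
    def non_reference_leaves(self) -> frozenset[str]:
        return frozenset().union(*self.groups)

    def branch_interval_my(self, branch: int) -> float:
        """Length in MY of the age interval covered by a branch index.

        Branch 0 is open-ended at the root; its interval is taken from the
        root age down to the next split.  The youngest branch runs from the
        last split to the present.
        """
        ages = self.split_ages + [0.0]
        if not (0 <= branch < self.n_branches):
            raise ValidationError(f"branch {branch} out of range")
        if branch == 0:
            return ages[0] - ages[1] if len(ages) > 1 else ages[0]
        return ages[branch - 1] - ages[branch]

    def species_older_than_branch(self, branch: int) -> frozenset[str]:
        """Leaves that diverged before a gene of the given branch was born."""
        older: set[str] = set()
        for i, grp in enumerate(self.groups):
            if i < branch:
                older.update(grp)
        return frozenset(older)


# the seven-species pteromalid ladder used throughout the synthetic fixtures;
# root and the two dated splits follow the study system (89.83, 8 and 1.49 MY)
DEFAULT_TREE_NEWICK = (
    "((((((P_puparum:1.49,P_venustus:1.49):2.51,P_qinghaiensis:4.0):4.0,"
    "N_vitripennis:8.0):32.0,A_calandrae:40.0):35.0,P_vindemmiae:75.0):14.83,"
    "T_elegans:89.83);"
)
DEFAULT_REFERENCE = "P_puparum"


def default_species_tree() -> SpeciesTree:
    return SpeciesTree.from_newick(DEFAULT_TREE_NEWICK, DEFAULT_REFERENCE)


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

class ExpressionMatrix:
    """A genes x samples TPM matrix with a sample-to-tissue map.

    ``tissues`` fixes the tissue order used for tie-breaking and output
    column order.  All values must be >= 0 and every sample must map to
    exactly one tissue.
    """

    def __init__(self, values: pd.DataFrame, sample_tissue: Mapping[str, str],
                 tissues: Sequence[str] | None = None):
        if values.index.duplicated().any():
            dup = values.index[values.index.duplicated()][0]
            raise ValidationError(f"duplicated gene id {dup!r}")
        if (values.values < 0).any():
            raise ValidationError("negative TPM value in expression matrix")
        missing = [s for s in values.columns if s not in sample_tissue]
        if missing:
            raise ValidationError(f"samples missing from tissue map: {missing}")
        self.values = values.astype(float)
        self.sample_tissue = dict(sample_tissue)
        if tissues is None:
            seen: list[str] = []
            for s in values.columns:
                t = sample_tissue[s]
                if t not in seen:
                    seen.append(t)
            tissues = seen
        if len(tissues) < 2:
            raise ValidationError("need at least 2 tissues")
        self.tissues = list(tissues)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def tissue_medians(self) -> pd.DataFrame:
        """Collapse replicate samples of each tissue by the median TPM."""
        cols = {}
        for t in self.tissues:
            samp = [s for s in self.values.columns if self.sample_tissue[s] == t]
            cols[t] = self.values[samp].median(axis=1)
        return pd.DataFrame(cols)[self.tissues]

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")

    def __eq__(self, other):
        return (isinstance(other, ExpressionMatrix)
                and self.values.equals(other.values)
                and self.sample_tissue == other.sample_tissue
                and self.tissues == other.tissues)


def read_expression(path, sample_map: Mapping[str, str],
                    tissues: Sequence[str] | None = None) -> ExpressionMatrix:
    """Read a TSV TPM matrix (first column gene ids, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df, sample_map, tissues)


def read_sample_map(path) -> dict[str, str]:
    """Read a two-column sample-to-tissue TSV (with or without header)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if list(df.iloc[0]) == ["sample", "tissue"]:
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


# ---------------------------------------------------------------------------
# sequences, synteny tables, misc
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_synteny_tsv(path) -> pd.DataFrame:
    """Read a synteny-presence table: gene_id + one column per species.

    Values are presence flags (0/1) or alignment-coverage fractions; any
    value > 0 counts as presence downstream.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValidationError("duplicated gene id in synteny table")
    if (df.values < 0).any():
        raise ValidationError("negative value in synteny table")
    return df


def write_synteny_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
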