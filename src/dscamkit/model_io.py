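"""Domain types and readers/writers for the gene-model formats the pipeline touches.

Chelicerate Dscam genes come in five structural flavours: the canonical
long form (LDscam, 10 Ig + 6 FNIII), a shortened intermediate (mDscam),
and three short forms (sDscamα/β/γ).  sDscamα and sDscamβ carry a tandem
array of 5' variable cassettes, each preceded by its own promoter and
encoding one (α) or two (β) N-terminal Ig domains; the cassette array is
followed by a constant region shared by all isoforms of the gene.

This module defines the in-memory representation of such gene models and
the on-disk dialect used to exchange them:

* coordinates are **0-based half-open** internally and **1-based
  inclusive** in GFF3, the standard convention for each side;
* cassette membership is carried on exon features via the GFF3 attributes
  ``region=constant|variable``, ``cassette_index`` (1-based position in
  the array), ``ig_count`` (Ig domains the cassette encodes) and
  ``exon_role=ig`` (the exon used for cassette-level quantification);
* per-gene domain calls (LEADER/IG/FN3/TM/CYTO tokens with amino-acid
  coordinates) are an input TSV, not computed here.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import gffutils
import pandas as pd
from Bio.Seq import Seq
from pyfaidx import Fasta

logger = logging.getLogger("dscamkit")

DOMAIN_TOKENS = ("LEADER", "IG", "FN3", "TM", "CYTO")

#: genomic span, 0-based half-open
Span = tuple[int, int]


class DscamClass(str, Enum):
    """The five structural Dscam types plus a fallback."""

    LDSCAM = "LDscam"
    MDSCAM = "mDscam"
    SDSCAM_ALPHA = "sDscamAlpha"
    SDSCAM_BETA = "sDscamBeta"
    SDSCAM_GAMMA = "sDscamGamma"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class DomainArchitecture:
    """Ordered protein-domain tokens with amino-acid coordinates."""

    gene_id: str
    domains: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        prev_end = -1
        singles = {"TM": 0, "CYTO": 0, "LEADER": 0}
        for token, start, end in self.domains:
            if token not in DOMAIN_TOKENS:
                raise ValueError(
                    f"{self.gene_id}: unknown domain token {token!r}"
                )
            if start < prev_end:
                raise ValueError(
                    f"{self.gene_id}: domains must be sorted and non-overlapping"
                )
            if end <= start:
                raise ValueError(f"{self.gene_id}: empty domain interval")
            prev_end = end
            if token in singles:
                singles[token] += 1
        for token, n in singles.items():
            if n > 1:
                raise ValueError(f"{self.gene_id}: more than one {token} domain")

    def count(self, token: str) -> int:
        return sum(1 for t, _, _ in self.domains if t == token)

    @property
    def tokens(self) -> tuple[str, ...]:
        return tuple(t for t, _, _ in self.domains)


@dataclass(frozen=True)
class CassetteRepeat:
    """One unit of the tandem 5' variable array.

    ``interval`` spans the whole repeat unit (exons plus internal
    introns); ``variable_exon`` is the Ig-encoding exon used for
    cassette-level expression quantification; ``exons`` lists every exon
    of the cassette in genomic order.
    """

    index: int  # 1-based position in the array, genomic order
    interval: Span
    exons: tuple[Span, ...]
    variable_exon: Span
    encoded_ig_count: int
    intron_count: int

    def __post_init__(self) -> None:
        if self.encoded_ig_count not in (1, 2):
            raise ValueError(
                f"cassette {self.index}: encoded_ig_count must be 1 or 2, "
                f"got {self.encoded_ig_count}"
            )
        if self.intron_count < 0:
            raise ValueError("intron_count must be >= 0")

    @property
    def unit_size(self) -> int:
        """Genomic span of the repeat unit in nt, introns included."""
        return self.interval[1] - self.interval[0]


@dataclass
class GeneModel:
    """A Dscam gene model: constant exons, optional cassette array, architecture."""

    gene_id: str
    species: str
    seqid: str
    strand: str
    constant_exons: list[Span]
    cassette_array: list[CassetteRepeat] = field(default_factory=list)
    internal_clusters: list[int] = field(default_factory=list)
    architecture: Optional[DomainArchitecture] = None
    dscam_class: DscamClass = DscamClass.UNCLASSIFIED

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if not self.constant_exons:
            raise ValueError(f"{self.gene_id}: constant_exons must be non-empty")
        if any(c < 1 for c in self.internal_clusters):
            raise ValueError(f"{self.gene_id}: internal cluster sizes must be >= 1")
        ivs = [c.interval for c in self.cassette_array]
        for (a0, a1), (b0, b1) in zip(ivs, ivs[1:]):
            if b0 < a1:
                raise ValueError(
                    f"{self.gene_id}: cassette repeats overlap or are out of order"
                )

    @property
    def span(self) -> Span:
        spans = list(self.constant_exons) + [c.interval for c in self.cassette_array]
        return min(s[0] for s in spans), max(s[1] for s in spans)


@dataclass(frozen=True)
class SpeciesRecord:
    species: str
    genome_size_mb: float
    gene_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.genome_size_mb <= 0:
            raise ValueError(f"{self.species}: genome_size must be > 0")


# ---------------------------------------------------------------------------
# coordinate conventions
# ---------------------------------------------------------------------------

def gff_to_internal(start: int, end: int) -> Span:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def internal_to_gff(span: Span) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return span[0] + 1, span[1]


def extract_span(fasta: Fasta, seqid: str, span: Span, strand: str) -> str:
    """Genomic slice for a span; minus strand returns the reverse complement."""
    if seqid not in fasta:
        raise KeyError(f"sequence {seqid!r} not in FASTA")
    seq = str(fasta[seqid][span[0]:span[1]])
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def spliced_sequence(fasta: Fasta, seqid: str, exons: Sequence[Span], strand: str) -> str:
    """Concatenated exon sequence in transcription order.

    Exons are given in genomic order; on the minus strand the transcript
    runs right-to-left, so exon order is reversed and each is
    reverse-complemented.
    """
    if strand == "-":
        return "".join(extract_span(fasta, seqid, e, "-") for e in reversed(exons))
    return "".join(extract_span(fasta, seqid, e, "+") for e in exons)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_domains(domains_path: str | os.PathLike) -> dict[str, DomainArchitecture]:
    """Read the per-gene domain-call TSV (gene_id, token, start, end in aa)."""
    df = pd.read_csv(domains_path, sep="\t", comment="#")
    required = {"gene_id", "token", "start", "end"}
    if not required.issubset(df.columns):
        raise ValueError(f"domain table must have columns {sorted(required)}")
    archs: dict[str, DomainArchitecture] = {}
    for gene_id, sub in df.groupby("gene_id", sort=False):
        sub = sub.sort_values("start")
        domains = tuple(
            (str(r.token), int(r.start), int(r.end)) for r in sub.itertuples()
        )
        archs[str(gene_id)] = DomainArchitecture(str(gene_id), domains)
    return archs


def _attr(feature, key: str, default=None):
    vals = feature.attributes.get(key)
    return vals[0] if vals else default


def read_gene_models(
    gff_path: str | os.PathLike,
    fasta_path: str | os.PathLike,
    domains_path: str | os.PathLike,
) -> list[GeneModel]:
    """Load gene models from GFF3 + genome FASTA + domain-call TSV.

    Every gene must have a domain architecture; a gene whose seqid is
    missing from the FASTA, whose cassettes overlap, or whose domain
    table uses an unknown token is a fatal error naming the gene.
    """
    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    fasta = Fasta(str(fasta_path))
    archs = read_domains(domains_path)

    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by="start"):
        gene_id = g.id
        if g.seqid not in fasta:
            raise KeyError(f"gene {gene_id}: sequence {g.seqid!r} not in FASTA")
        if gene_id not in archs:
            raise ValueError(f"gene {gene_id}: no domain architecture in table")
        constant: list[Span] = []
        cassette_exons: dict[int, list[tuple[Span, str, int]]] = {}
        for exon in db.children(g, featuretype="exon", order_by="start"):
            span = gff_to_internal(exon.start, exon.end)
            region = _attr(exon, "region", "constant")
            if region == "constant":
                constant.append(span)
            elif region == "variable":
                idx = int(_attr(exon, "cassette_index", "0"))
                if idx < 1:
                    raise ValueError(
                        f"gene {gene_id}: variable exon without cassette_index"
                    )
                role = _attr(exon, "exon_role", "")
                ig = int(_attr(exon, "ig_count", "1"))
                cassette_exons.setdefault(idx, []).append((span, role, ig))
            else:
                raise ValueError(f"gene {gene_id}: unknown region {region!r}")
        cassettes = []
        for idx in sorted(cassette_exons):
            entries = sorted(cassette_exons[idx])
            exons = tuple(e[0] for e in entries)
            ig_counts = {e[2] for e in entries}
            if len(ig_counts) != 1:
                raise ValueError(f"gene {gene_id}: cassette {idx} has mixed ig_count")
            var = [e[0] for e in entries if e[1] == "ig"]
            variable_exon = var[0] if var else entries[0][0]
            cassettes.append(
                CassetteRepeat(
                    index=idx,
                    interval=(exons[0][0], exons[-1][1]),
                    exons=exons,
                    variable_exon=variable_exon,
                    encoded_ig_count=ig_counts.pop(),
                    intron_count=len(exons) - 1,
                )
            )
        # cassette index follows genomic (linear) order, the order heatmaps use
        cassettes.sort(key=lambda c: c.interval[0])
        cassettes = [
            CassetteRepeat(
                index=i + 1,
                interval=c.interval,
                exons=c.exons,
                variable_exon=c.variable_exon,
                encoded_ig_count=c.encoded_ig_count,
                intron_count=c.intron_count,
            )
            for i, c in enumerate(cassettes)
        ]
        clusters_attr = _attr(g, "internal_clusters", "")
        clusters = [int(x) for x in clusters_attr.split(",") if x] if clusters_attr else []
        genes.append(
            GeneModel(
                gene_id=gene_id,
                species=_attr(g, "species", "unknown"),
                seqid=g.seqid,
                strand=g.strand,
                constant_exons=constant,
                cassette_array=cassettes,
                internal_clusters=clusters,
                architecture=archs[gene_id],
            )
        )
    return genes


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_gene_models(genes: Iterable[GeneModel], path: str | os.PathLike) -> None:
    """Emit gene models as GFF3 (1-based inclusive) in the dialect read back by
    :func:`read_gene_models`."""
    lines = ["##gff-version 3"]
    for g in genes:
        s, e = internal_to_gff(g.span)
        attrs = [f"ID={g.gene_id}", f"species={g.species}"]
        if g.internal_clusters:
            attrs.append("internal_clusters=" + ",".join(map(str, g.internal_clusters)))
        lines.append(
            "\t".join(
                [g.seqid, "dscamkit", "gene", str(s), str(e), ".", g.strand, ".",
                 ";".join(attrs)]
            )
        )
        for i, span in enumerate(g.constant_exons, 1):
            s, e = internal_to_gff(span)
            lines.append(
                "\t".join(
                    [g.seqid, "dscamkit", "exon", str(s), str(e), ".", g.strand, ".",
                     f"ID={g.gene_id}.const{i};Parent={g.gene_id};region=constant"]
                )
            )
        for c in g.cassette_array:
            for j, span in enumerate(c.exons, 1):
                s, e = internal_to_gff(span)
                attrs = [
                    f"ID={g.gene_id}.c{c.index}.e{j}",
                    f"Parent={g.gene_id}",
                    "region=variable",
                    f"cassette_index={c.index}",
                    f"ig_count={c.encoded_ig_count}",
                ]
                if span == c.variable_exon:
                    attrs.append("exon_role=ig")
                lines.append(
                    "\t".join(
                        [g.seqid, "dscamkit", "exon", str(s), str(e), ".",
                         g.strand, ".", ";".join(attrs)]
                    )
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_domains(archs: Iterable[DomainArchitecture], path: str | os.PathLike) -> None:
    rows = [
        {"gene_id": a.gene_id, "token": t, "start": s, "end": e}
        for a in archs
        for t, s, e in a.domains
    ]
    pd.DataFrame(rows, columns=["gene_id", "token", "start", "end"]).to_csv(
        path, sep="\t", index=False
    )


def write_table(
    df: pd.DataFrame,
    path: str | os.PathLike,
    meta: Optional[dict] = None,
    index: bool = False,
) -> None:
    """Write a TSV with optional ``# key=value`` header comment lines."""
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path: str | os.PathLike, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_newick(tree, path: str | os.PathLike) -> None:
    """Write a scikit-bio TreeNode as Newick with branch lengths."""
    tree.write(str(path), format="newick")
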