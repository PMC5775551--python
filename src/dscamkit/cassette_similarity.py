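"""Pairwise identity of translated 5' cassettes, duplication-block detection,
and heatmap export.

The similarity stage translates each cassette's spliced coding sequence and
computes all-vs-all global percent identities.  Recent tandem duplication
leaves a signature of contiguous runs of near-identical cassettes
("duplication blocks"); identity heatmaps ordered by genomic position make
those blocks visible as high-identity sub-squares along the diagonal.

Alignment model
---------------
Global alignment (Needleman–Wunsch with affine gaps, Gotoh recursion):
BLOSUM62 by default, gap open −10 for the first position of a gap and
−0.5 for each extension.  Percent identity is

    100 × identical columns / alignment columns (gaps included).

Optimal alignments are generally not unique, and different co-optimal
alignments can have different identity counts.  To make the statistic
well defined, symmetric, and independent of traceback order, the aligner
optimises lexicographically: maximise score, then maximise identical
columns, then minimise alignment length.  Because all three objectives
are additive along an alignment path, a single dynamic programme computes
the optimum exactly; an exhaustive enumeration oracle over short
sequences reproduces it column for column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from numba import njit

from .model_io import GeneModel, spliced_sequence, write_table

logger = logging.getLogger("dscamkit")

_NEG = -1.0e18


def _load_matrix(name: str) -> tuple[str, np.ndarray]:
    m = substitution_matrices.load(name)
    alphabet = str(m.alphabet)
    return alphabet, np.asarray(m, dtype=np.float64)


@dataclass(frozen=True)
class AlignmentScoring:
    """Scoring scheme for global cassette alignment.

    ``gap_open`` is charged for the first residue of a gap and
    ``gap_extend`` for each subsequent one.  ``matrix_name`` may be any
    Biopython substitution matrix; ``nucleotide=True`` switches to simple
    match/mismatch scoring for alignments on the DNA rather than the
    translated cassettes.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = -10.0
    gap_extend: float = -0.5
    nucleotide: bool = False
    match: float = 2.0
    mismatch: float = -3.0

    def encode(self) -> tuple[dict[str, int], np.ndarray]:
        if self.nucleotide:
            alphabet = "ACGTN"
            sub = np.full((5, 5), self.mismatch)
            np.fill_diagonal(sub, self.match)
            sub[4, :] = sub[:, 4] = self.mismatch
        else:
            alphabet, sub = _load_matrix(self.matrix_name)
        return {c: i for i, c in enumerate(alphabet)}, sub


DEFAULT_SCORING = AlignmentScoring()


@njit(cache=True)
def _gotoh(a, b, sub, gap_open, gap_extend):  # pragma: no cover - jitted
    """Affine-gap global alignment maximising (score, identities, -columns).

    Returns (score, identical columns, total columns) of the optimum.
    States: 0 = match/mismatch, 1 = gap in b (consumes a), 2 = gap in a.
    """
    n, m = len(a), len(b)
    S = np.full((3, n + 1, m + 1), _NEG)
    I = np.zeros((3, n + 1, m + 1))
    C = np.zeros((3, n + 1, m + 1))
    S[0, 0, 0] = 0.0
    for i in range(1, n + 1):
        S[1, i, 0] = gap_open + (i - 1) * gap_extend
        C[1, i, 0] = i
    for j in range(1, m + 1):
        S[2, 0, j] = gap_open + (j - 1) * gap_extend
        C[2, 0, j] = j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # state 0: a[i-1] aligned to b[j-1]
            bs, bi, bc = _NEG, 0.0, 0.0
            for st in range(3):
                s = S[st, i - 1, j - 1]
                if s > _NEG / 2 and (
                    s > bs
                    or (s == bs and (I[st, i - 1, j - 1] > bi
                        or (I[st, i - 1, j - 1] == bi and C[st, i - 1, j - 1] < bc)))
                ):
                    bs, bi, bc = s, I[st, i - 1, j - 1], C[st, i - 1, j - 1]
            if bs > _NEG / 2:
                S[0, i, j] = bs + sub[a[i - 1], b[j - 1]]
                I[0, i, j] = bi + (1.0 if a[i - 1] == b[j - 1] else 0.0)
                C[0, i, j] = bc + 1.0
            # state 1: gap in b (consume a[i-1]); extend only from state 1
            bs, bi, bc = _NEG, 0.0, 0.0
            for st in range(3):
                s = S[st, i - 1, j]
                if s <= _NEG / 2:
                    continue
                s = s + (gap_extend if st == 1 else gap_open)
                if s > bs or (
                    s == bs and (I[st, i - 1, j] > bi
                    or (I[st, i - 1, j] == bi and C[st, i - 1, j] < bc))
                ):
                    bs, bi, bc = s, I[st, i - 1, j], C[st, i - 1, j]
            if bs > _NEG / 2:
                S[1, i, j] = bs
                I[1, i, j] = bi
                C[1, i, j] = bc + 1.0
            # state 2: gap in a (consume b[j-1])
            bs, bi, bc = _NEG, 0.0, 0.0
            for st in range(3):
                s = S[st, i, j - 1]
                if s <= _NEG / 2:
                    continue
                s = s + (gap_extend if st == 2 else gap_open)
                if s > bs or (
                    s == bs and (I[st, i, j - 1] > bi
                    or (I[st, i, j - 1] == bi and C[st, i, j - 1] < bc))
                ):
                    bs, bi, bc = s, I[st, i, j - 1], C[st, i, j - 1]
            if bs > _NEG / 2:
                S[2, i, j] = bs
                I[2, i, j] = bi
                C[2, i, j] = bc + 1.0
    bs, bi, bc = _NEG, 0.0, 0.0
    for st in range(3):
        s = S[st, n, m]
        if s > bs or (
            s == bs and (I[st, n, m] > bi
            or (I[st, n, m] == bi and C[st, n, m] < bc))
        ):
            bs, bi, bc = s, I[st, n, m], C[st, n, m]
    return bs, bi, bc


def percent_identity(
    a: str, b: str, scoring: AlignmentScoring = DEFAULT_SCORING
) -> float:
    """Global-alignment percent identity in [0, 100].

    Symmetric, 100 iff the sequences are equal (under match-favouring
    scoring), and deterministic regardless of co-optimal alignments.
    """
    if not a or not b:
        raise ValueError("percent_identity requires non-empty sequences")
    index, sub = scoring.encode()
    try:
        ea = np.array([index[c] for c in a.upper()], dtype=np.int64)
        eb = np.array([index[c] for c in b.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"residue {exc} not in alignment alphabet") from exc
    _, ident, cols = _gotoh(ea, eb, sub, scoring.gap_open, scoring.gap_extend)
    return 100.0 * ident / cols


# ---------------------------------------------------------------------------
# cassette translation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CassetteSeq:
    """A translated cassette, labelled ``<gene>.c<index>``."""

    label: str
    gene_id: str
    species: str
    index: int
    aa: str
    nt: str


def translate_cassettes(
    genes: Iterable[GeneModel], fasta, keep_untranslatable: bool = False
) -> tuple[list[CassetteSeq], list[str]]:
    """Translate each cassette's spliced coding sequence.

    The reading frame is chosen as the first of the three forward frames
    whose translation has no internal stop codon; a cassette with stops
    in every frame is excluded and its label returned in the second
    element (a warning is logged, processing continues).  With
    ``keep_untranslatable=True`` such cassettes are retained with an
    empty amino-acid field — usable for nucleotide-level analyses, where
    premature stops are irrelevant — while still being reported.
    """
    out: list[CassetteSeq] = []
    excluded: list[str] = []
    for g in genes:
        for c in g.cassette_array:
            label = f"{g.gene_id}.c{c.index}"
            nt = spliced_sequence(fasta, g.seqid, c.exons, g.strand)
            aa = None
            for frame in range(3):
                trimmed = nt[frame:]
                trimmed = trimmed[: len(trimmed) - len(trimmed) % 3]
                if not trimmed:
                    continue
                prot = str(Seq(trimmed).translate())
                core = prot[:-1] if prot.endswith("*") else prot
                if "*" not in core and core:
                    aa = core
                    break
            if aa is None:
                logger.warning("cassette %s untranslatable (internal stops); excluded", label)
                excluded.append(label)
                if not keep_untranslatable:
                    continue
                aa = ""
            out.append(CassetteSeq(label, g.gene_id, g.species, c.index, aa, nt))
    return out, excluded


# ---------------------------------------------------------------------------
# identity matrices and duplication blocks
# ---------------------------------------------------------------------------

def identity_matrix(
    cassettes: Sequence[CassetteSeq],
    scoring: AlignmentScoring = DEFAULT_SCORING,
    nucleotide: bool = False,
) -> pd.DataFrame:
    """All-vs-all percent-identity matrix.

    Labels keep the input order, which by construction is the linear
    genomic order of the cassettes within each gene, genes grouped.
    Symmetric with a 100 diagonal.
    """
    if len(cassettes) < 2:
        raise ValueError("identity_matrix needs at least 2 cassettes")
    if nucleotide and not scoring.nucleotide:
        scoring = AlignmentScoring(
            gap_open=scoring.gap_open, gap_extend=scoring.gap_extend, nucleotide=True
        )
    labels = [c.label for c in cassettes]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate cassette labels")
    seqs = [c.nt if nucleotide else c.aa for c in cassettes]
    n = len(seqs)
    values = np.full((n, n), 100.0)
    for i, j in combinations(range(n), 2):
        pid = percent_identity(seqs[i], seqs[j], scoring)
        values[i, j] = values[j, i] = pid
    return pd.DataFrame(values, index=labels, columns=labels)


def select_cassettes(
    cassettes: Sequence[CassetteSeq],
    scope: str = "within-species",
    gene_id: Optional[str] = None,
    species: Optional[str] = None,
) -> list[CassetteSeq]:
    """Subset cassettes for a matrix scope: within-gene, within-species, cross-species."""
    if scope == "within-gene":
        if gene_id is None:
            raise ValueError("within-gene scope needs gene_id")
        sel = [c for c in cassettes if c.gene_id == gene_id]
    elif scope == "within-species":
        if species is None:
            raise ValueError("within-species scope needs species")
        sel = [c for c in cassettes if c.species == species]
    elif scope == "cross-species":
        sel = list(cassettes)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return sorted(sel, key=lambda c: (c.species, c.gene_id, c.index))


@dataclass(frozen=True)
class DuplicationBlock:
    """A contiguous run of highly similar cassettes within one gene."""

    gene_id: str
    members: tuple[int, ...]  # cassette indices, contiguous genomic order
    mean_identity: float

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a duplication block has >= 2 members")

    @property
    def size(self) -> int:
        return len(self.members)


def detect_blocks(
    matrix: pd.DataFrame, threshold: float = 80.0, gene_id: Optional[str] = None
) -> list[DuplicationBlock]:
    """Maximal runs of consecutive cassettes with adjacent identity >= threshold.

    The matrix must cover a single gene, labels in genomic order.
    Singleton runs are not reported.  Mean within-block identity averages
    all pairwise values inside the block (diagonal excluded).
    """
    labels = list(matrix.index)
    gids = {l.rsplit(".c", 1)[0] for l in labels}
    if len(gids) != 1:
        raise ValueError("detect_blocks expects cassettes from a single gene")
    gid = gene_id or gids.pop()
    idx = [int(l.rsplit(".c", 1)[1]) for l in labels]
    vals = matrix.to_numpy()
    blocks: list[DuplicationBlock] = []
    start = 0
    for k in range(1, len(labels) + 1):
        boundary = (
            k == len(labels)
            or vals[k - 1, k] < threshold
            or idx[k] != idx[k - 1] + 1  # non-adjacent in the genome
        )
        if boundary:
            if k - start >= 2:
                members = tuple(idx[start:k])
                sub = vals[start:k, start:k]
                iu = np.triu_indices(k - start, 1)
                blocks.append(DuplicationBlock(gid, members, float(sub[iu].mean())))
            start = k
    return blocks


def within_between_summary(
    cassettes: Sequence[CassetteSeq], scoring: AlignmentScoring = DEFAULT_SCORING
) -> pd.DataFrame:
    """Mean within-gene vs between-gene cassette identity, per species.

    Recent tandem cassette duplication inflates within-gene identity
    relative to between-gene identity (older gene duplications), so the
    difference is positive when cassette turnover outpaces gene turnover.
    Species with a single multi-cassette gene get empty between-gene
    fields.
    """
    rows = []
    for species in sorted({c.species for c in cassettes}):
        sub = [c for c in cassettes if c.species == species]
        within, between = [], []
        for a, b in combinations(sub, 2):
            pid = percent_identity(a.aa, b.aa, scoring)
            (within if a.gene_id == b.gene_id else between).append(pid)
        mw = float(np.mean(within)) if within else np.nan
        mb = float(np.mean(between)) if between else np.nan
        rows.append(
            {
                "species": species,
                "mean_within_gene_identity": mw,
                "mean_between_gene_identity": mb,
                "difference": mw - mb if within and between else np.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "species",
            "mean_within_gene_identity",
            "mean_between_gene_identity",
            "difference",
        ],
    )


def heatmap_export(
    matrix: pd.DataFrame,
    image_path: Optional[str] = None,
    tsv_path: Optional[str] = None,
    title: str = "",
) -> None:
    """Render the identity heatmap (colour scale fixed to [0, 100]) and/or
    write the matrix TSV, which is the source of truth."""
    if tsv_path is not None:
        write_table(matrix, tsv_path, index=True)
    if image_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        import seaborn as sns

        fig, ax = plt.subplots(
            figsize=(max(4, 0.25 * len(matrix)), max(3.5, 0.22 * len(matrix)))
        )
        sns.heatmap(
            matrix, vmin=0, vmax=100, cmap="viridis", square=True,
            cbar_kws={"label": "% identity"}, ax=ax,
        )
        if title:
            ax.set_title(title)
        fig.tight_layout()
        fig.savefig(image_path, dpi=120)
        plt.close(fig)
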