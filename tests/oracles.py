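"""Independent brute-force oracles used to validate the fast implementations.

These deliberately share no code with the package: the alignment oracle
enumerates every global alignment recursively, and the matching oracle
scans every position of every reference sequence.
"""

from __future__ import annotations

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def oracle_percent_identity(a, b, sub, gap_open=-10.0, gap_extend=-0.5):
    """Exhaustive-alignment percent identity.

    Enumerates every global alignment of a and b, scores it with the
    given substitution lookup and affine gap penalties (open for the
    first gap position, extend for each subsequent one), and returns the
    identity of the lexicographically optimal alignment: maximal score,
    then maximal identical columns, then minimal alignment length.
    ``sub`` maps a pair of residues to a score.
    """
    best = [None]

    def rec(i, j, prev, score, ident, cols):
        if i == len(a) and j == len(b):
            cand = (score, ident, -cols)
            if best[0] is None or cand > best[0]:
                best[0] = cand
            return
        if i < len(a) and j < len(b):
            rec(
                i + 1, j + 1, "M",
                score + sub[(a[i], b[j])],
                ident + (1 if a[i] == b[j] else 0),
                cols + 1,
            )
        if i < len(a):
            g = gap_extend if prev == "X" else gap_open
            rec(i + 1, j, "X", score + g, ident, cols + 1)
        if j < len(b):
            g = gap_extend if prev == "Y" else gap_open
            rec(i, j + 1, "Y", score + g, ident, cols + 1)

    rec(0, 0, "S", 0.0, 0, 0)
    score, ident, neg_cols = best[0]
    return 100.0 * ident / (-neg_cols)


def blosum62_lookup():
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")
    alpha = str(m.alphabet)
    return {
        (x, y): float(m[alpha.index(x), alpha.index(y)]) for x in alpha for y in alpha
    }


def brute_force_matches(fragments, regions):
    """Every occurrence of every fragment in the reference, by direct scan.

    Returns {fragment_id: sorted list of (region, position, strand)} for
    fragments with at least one perfect match; positions are on the
    forward strand of the region.
    """
    out = {}
    for fid, frag in fragments:
        frag = frag.upper()
        rc = revcomp(frag)
        loci = []
        for rid, seq in regions.items():
            seq = seq.upper()
            for pos in range(len(seq) - len(frag) + 1):
                window = seq[pos : pos + len(frag)]
                if window == frag:
                    loci.append((rid, pos, "+"))
                if window == rc:
                    loci.append((rid, pos, "-"))
        if loci:
            out[fid] = sorted(loci)
    return out


def pooled_t(a, b):
    """Textbook two-sample pooled-variance t statistic."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    return (ma - mb) / (sp2 * (1 / na + 1 / nb)) ** 0.5
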