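import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dscamkit.cassette_similarity import (
    AlignmentScoring,
    CassetteSeq,
    detect_blocks,
    heatmap_export,
    identity_matrix,
    percent_identity,
    translate_cassettes,
    within_between_summary,
)
from dscamkit.model_io import read_table
from dscamkit.synthetic_data import simulate_cassette_burst

from oracles import blosum62_lookup, oracle_percent_identity

BLOSUM = blosum62_lookup()


def test_identity_of_equal_and_near_equal_sequences():
    assert percent_identity("MKVLLA", "MKVLLA") == 100.0
    assert percent_identity("MKV", "MKI") == pytest.approx(200 / 3)


def test_empty_sequence_is_an_error():
    with pytest.raises(ValueError):
        percent_identity("", "MKV")


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    a=st.text(alphabet="ACGT", min_size=1, max_size=8),
    b=st.text(alphabet="ACGT", min_size=1, max_size=8),
)
def test_identity_matches_exhaustive_alignment_oracle(a, b):
    """The DP identity equals full enumeration of all affine-gap alignments."""
    expected = oracle_percent_identity(a, b, BLOSUM)
    assert percent_identity(a, b) == pytest.approx(expected, abs=1e-9)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    a=st.text(alphabet="ARNDCQEGH", min_size=1, max_size=30),
    b=st.text(alphabet="ARNDCQEGH", min_size=1, max_size=30),
)
def test_identity_is_symmetric_and_discriminates_equality(a, b):
    assert percent_identity(a, b) == pytest.approx(percent_identity(b, a))
    if a == b:
        assert percent_identity(a, b) == 100.0
    else:
        assert percent_identity(a, b) < 100.0


def test_long_random_pair_matches_dp_oracle(rng):
    """Spot-check a realistic-length pair against a slow pure-python Gotoh."""
    aas = "ACDEFGHIKLMNPQRSTVWY"
    a = "".join(rng.choice(list(aas), 40))
    b = "".join(rng.choice(list(aas), 40))
    # pure-python lexicographic Gotoh, independent of the jitted code path
    import itertools

    NEG = float("-inf")
    n, m = len(a), len(b)
    val = {(0, 0, 0): (0.0, 0, 0)}
    for i, j, s in itertools.product(range(n + 1), range(m + 1), range(3)):
        if (i, j) == (0, 0):
            continue
        cands = []
        if s == 0 and i and j:
            for ps in range(3):
                prev = val.get((i - 1, j - 1, ps))
                if prev:
                    cands.append(
                        (
                            prev[0] + BLOSUM[(a[i - 1], b[j - 1])],
                            prev[1] + (a[i - 1] == b[j - 1]),
                            prev[2] - 1,
                        )
                    )
        elif s == 1 and i:
            for ps in range(3):
                prev = val.get((i - 1, j, ps))
                if prev:
                    cands.append(
                        (prev[0] + (-0.5 if ps == 1 else -10.0), prev[1], prev[2] - 1)
                    )
        elif s == 2 and j:
            for ps in range(3):
                prev = val.get((i, j - 1, ps))
                if prev:
                    cands.append(
                        (prev[0] + (-0.5 if ps == 2 else -10.0), prev[1], prev[2] - 1)
                    )
        if cands:
            val[(i, j, s)] = max(cands)
    score, ident, neg_cols = max(val[(n, m, s)] for s in range(3) if (n, m, s) in val)
    assert percent_identity(a, b) == pytest.approx(100.0 * ident / -neg_cols)


def _mini_gene(seq_by_cassette, strand="+"):
    """One gene whose cassettes are single exons laid 100 nt apart on chr1."""
    from dscamkit.model_io import CassetteRepeat, GeneModel

    genome = ["A"] * 10_000
    array = []
    for i, s in enumerate(seq_by_cassette, 1):
        start = 100 * i
        genome[start : start + len(s)] = list(s)
        array.append(
            CassetteRepeat(
                index=i,
                interval=(start, start + len(s)),
                exons=((start, start + len(s)),),
                variable_exon=(start, start + len(s)),
                encoded_ig_count=1,
                intron_count=0,
            )
        )
    gene = GeneModel(
        gene_id="g1",
        species="spX",
        seqid="chr1",
        strand=strand,
        constant_exons=[(9000, 9300)],
        cassette_array=array,
    )
    return gene, {"chr1": "".join(genome)}


def test_translate_simple_plus_and_minus():
    gene, genomes = _mini_gene(["ATGGCC"])
    cass, excluded = translate_cassettes([gene], genomes)
    assert not excluded
    assert cass[0].aa == "MA"

    # on the minus strand the stored genomic slice is the reverse complement
    rc = "GGCCAT"  # revcomp("ATGGCC")
    gene_m, genomes_m = _mini_gene([rc], strand="-")
    cass_m, _ = translate_cassettes([gene_m], genomes_m)
    assert cass_m[0].aa == "MA"


def test_internal_stop_excluded_with_record():
    gene, genomes = _mini_gene(["TAACATGACTAGATAATCTGATAT"])  # stops in every frame
    cass, excluded = translate_cassettes([gene], genomes)
    assert excluded == ["g1.c1"]
    assert cass == []
    kept, excl2 = translate_cassettes([gene], genomes, keep_untranslatable=True)
    assert excl2 == ["g1.c1"] and kept[0].aa == "" and kept[0].nt


def _cassette(label, aa):
    gene, idx = label.rsplit(".c", 1)
    return CassetteSeq(label, gene, "spX", int(idx), aa, "")


def test_identity_matrix_properties():
    cass = [_cassette(f"g1.c{i}", "MKVLLAG") for i in range(1, 4)]
    m = identity_matrix(cass)
    assert (m.to_numpy() == 100.0).all()
    cass2 = [
        _cassette("g1.c1", "MKVLLAG"),
        _cassette("g1.c2", "MKILLAG"),
        _cassette("g1.c3", "WWRRCCH"),
    ]
    m2 = identity_matrix(cass2)
    assert np.allclose(m2.to_numpy(), m2.to_numpy().T)
    assert list(m2.index) == ["g1.c1", "g1.c2", "g1.c3"]


def _matrix_from_adjacent(identities):
    """Square matrix with the given adjacent-pair identities, 10 elsewhere."""
    n = len(identities) + 1
    vals = np.full((n, n), 10.0)
    np.fill_diagonal(vals, 100.0)
    for i, v in enumerate(identities):
        vals[i, i + 1] = vals[i + 1, i] = v
    labels = [f"g1.c{i+1}" for i in range(n)]
    return pd.DataFrame(vals, index=labels, columns=labels)


def brute_force_runs(adjacent, threshold):
    """Independent enumeration of maximal runs of above-threshold neighbours."""
    runs, cur = [], [1]
    for i, v in enumerate(adjacent, start=2):
        if v >= threshold:
            cur.append(i)
        else:
            if len(cur) >= 2:
                runs.append(tuple(cur))
            cur = [i]
    if len(cur) >= 2:
        runs.append(tuple(cur))
    return runs


@pytest.mark.parametrize(
    "adjacent",
    [
        [100.0, 100.0, 100.0, 100.0],
        [100.0, 50.0, 100.0, 50.0, 100.0],
        [50.0, 50.0],
        [90.0, 85.0, 10.0, 95.0],
    ],
)
def test_block_detection_matches_run_enumeration(adjacent):
    m = _matrix_from_adjacent(adjacent)
    blocks = detect_blocks(m, threshold=80.0)
    assert [b.members for b in blocks] == brute_force_runs(adjacent, 80.0)


def test_all_identical_cassettes_form_one_block():
    cass = [_cassette(f"g1.c{i}", "MKVLLAG") for i in range(1, 6)]
    blocks = detect_blocks(identity_matrix(cass), threshold=80.0)
    assert len(blocks) == 1
    assert blocks[0].members == (1, 2, 3, 4, 5)
    assert blocks[0].mean_identity == 100.0


def test_blocks_require_single_gene():
    m = identity_matrix([_cassette("g1.c1", "MKV"), _cassette("g2.c1", "MKV")])
    with pytest.raises(ValueError):
        detect_blocks(m)


def test_simulated_burst_recovered_as_block():
    family, burst = simulate_cassette_burst(seed=11, n_copies=5, substitution_rate=0.002)
    cass, _ = translate_cassettes(family.genes, family.genomes, keep_untranslatable=True)
    m = identity_matrix(cass, nucleotide=True)
    blocks = detect_blocks(m, threshold=80.0)
    assert len(blocks) == 1
    gid = burst[0].rsplit(".c", 1)[0]
    assert [f"{gid}.c{i}" for i in blocks[0].members] == burst
    # burst members are mutually more similar than they are to flanks
    labels = list(m.index)
    in_burst = [l in burst for l in labels]
    vals = m.to_numpy()
    within = [vals[i, j] for i in range(len(labels)) for j in range(i + 1, len(labels))
              if in_burst[i] and in_burst[j]]
    across = [vals[i, j] for i in range(len(labels)) for j in range(i + 1, len(labels))
              if in_burst[i] != in_burst[j]]
    assert np.mean(within) > np.mean(across)


def test_within_between_summary_behaviour():
    identical = [
        _cassette("g1.c1", "MKVLLAG"),
        _cassette("g1.c2", "MKVLLAG"),
        _cassette("g2.c1", "MKVLLAG"),
        _cassette("g2.c2", "MKVLLAG"),
    ]
    row = within_between_summary(identical).iloc[0]
    assert row["difference"] == 0.0

    single_gene = [_cassette("g1.c1", "MKV"), _cassette("g1.c2", "MKI")]
    row = within_between_summary(single_gene).iloc[0]
    assert np.isnan(row["mean_between_gene_identity"])

    recent = [
        _cassette("g1.c1", "MKVLLAG"),
        _cassette("g1.c2", "MKVLLAG"),
        _cassette("g2.c1", "WWRRCCH"),
        _cassette("g2.c2", "WWRRCCH"),
    ]
    row = within_between_summary(recent).iloc[0]
    assert row["mean_within_gene_identity"] > row["mean_between_gene_identity"]


def test_heatmap_export_tsv_is_source_of_truth(tmp_path):
    cass = [_cassette(f"g1.c{i}", "MKVLLAG") for i in range(1, 4)]
    m = identity_matrix(cass)
    heatmap_export(m, image_path=str(tmp_path / "h.png"), tsv_path=str(tmp_path / "h.tsv"))
    back = read_table(tmp_path / "h.tsv", index_col=0)
    assert np.array_equal(back.to_numpy(), m.to_numpy())
    assert list(back.index) == list(m.index)
    assert (tmp_path / "h.png").stat().st_size > 0


def test_nucleotide_scoring_option():
    s = AlignmentScoring(nucleotide=True)
    assert percent_identity("ACGTACGT", "ACGTACGT", s) == 100.0
    assert percent_identity("ACGTACGT", "ACGAACGT", s) == pytest.approx(87.5)
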