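import math

import numpy as np
import pandas as pd
import pytest

from dscamkit.classifier import classify_genes
from dscamkit.duplication_stats import (
    build_summary,
    genome_size_correlation,
    intron_loss_table,
    inverse_correlation,
    power_law_fit,
    subfamily_comparison,
)
from dscamkit.model_io import SpeciesRecord
from dscamkit.synthetic_data import make_budget_scenario

from conftest import make_gene
from oracles import pooled_t

SD = ["LEADER"] + ["IG"] * 3 + ["FN3"] * 3 + ["TM", "CYTO"]


def _summary(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "species", "gene_id", "subfamily", "cassette_count",
            "repeat_unit_size", "mean_intron_count", "constant_intron_count",
        ],
    )


def _hyperbola_summary(subfamily="sDscamAlpha"):
    rows = []
    for sp, (g, c) in enumerate([(1, 60), (2, 30), (3, 20), (6, 10)], 1):
        for i in range(g):
            rows.append(
                {"species": f"sp{sp}", "gene_id": f"sp{sp}.g{i}", "subfamily": subfamily,
                 "cassette_count": c, "repeat_unit_size": 400.0,
                 "mean_intron_count": 1.0, "constant_intron_count": 3}
            )
    return _summary(rows)


def test_inverse_correlation_on_exact_hyperbola():
    """Gene count x mean cassette count held at 60 isoforms: log-log r is -1."""
    summ = _hyperbola_summary()
    r, p = inverse_correlation(summ)["sDscamAlpha"]
    assert r < -0.85
    per_species = summ.groupby("species").agg(
        g=("gene_id", "size"), c=("cassette_count", "mean")
    )
    logr = np.corrcoef(np.log(per_species["g"]), np.log(per_species["c"]))[0, 1]
    assert logr == pytest.approx(-1.0, abs=1e-12)


def test_inverse_correlation_degenerate_and_invariances():
    rows = [
        {"species": f"sp{s}", "gene_id": f"sp{s}.g{i}", "subfamily": "sDscamAlpha",
         "cassette_count": 7, "repeat_unit_size": 400.0,
         "mean_intron_count": 1.0, "constant_intron_count": 3}
        for s in range(1, 4) for i in range(s)
    ]
    r, p = inverse_correlation(_summary(rows))["sDscamAlpha"]
    assert math.isnan(r)

    summ = _hyperbola_summary()
    shuffled = summ.sample(frac=1.0, random_state=0)
    rescaled = summ.assign(cassette_count=summ["cassette_count"] * 3)
    base = inverse_correlation(summ)["sDscamAlpha"][0]
    assert inverse_correlation(shuffled)["sDscamAlpha"][0] == pytest.approx(base)
    assert inverse_correlation(rescaled)["sDscamAlpha"][0] == pytest.approx(base)


def test_inverse_correlation_budget_scenario_recovery(rng):
    """A fixed isoform budget split randomly between genes and cassettes yields
    a strong negative correlation in nearly every draw."""
    hits = 0
    for seed in range(1, 26):
        summ = make_budget_scenario(6, 120, np.random.default_rng(seed))
        r, _ = inverse_correlation(summ)["sDscamAlpha"]
        hits += r <= -0.7
    assert hits >= 23


def test_power_law_fit_is_exact_on_noiseless_data():
    x = np.array([2, 4, 8, 16, 32], float)
    b, c, r2 = power_law_fit(x, 5.0 * x**-0.8)
    assert abs(b - (-0.8)) < 1e-9
    assert c == pytest.approx(5.0, rel=1e-9)
    assert r2 == pytest.approx(1.0, abs=1e-12)


def test_power_law_fit_rejects_bad_designs():
    with pytest.raises(ValueError):
        power_law_fit([3, 3, 3], [1, 2, 3])
    with pytest.raises(ValueError):
        power_law_fit([1, 2, -3], [1, 2, 3])
    with pytest.raises(ValueError):
        power_law_fit([1, 2], [1, 2])


def test_budget_scenario_sizes_give_negative_exponent(rng):
    summ = make_budget_scenario(6, 120, rng)
    b, _, _ = power_law_fit(summ["cassette_count"], summ["repeat_unit_size"])
    assert b < 0


def test_genome_size_correlation_proportional_and_missing():
    rows = [
        {"species": f"sp{s}", "gene_id": f"sp{s}.g1", "subfamily": "sDscamAlpha",
         "cassette_count": 5, "repeat_unit_size": 100.0 * s,
         "mean_intron_count": 1.0, "constant_intron_count": 3}
        for s in range(1, 5)
    ]
    records = {f"sp{s}": SpeciesRecord(f"sp{s}", 500.0 * s) for s in range(1, 5)}
    r, p, table = genome_size_correlation(_summary(rows), records)
    assert r == pytest.approx(1.0)
    assert "total_cassettes" in table.columns

    del records["sp4"]
    r2, _, table2 = genome_size_correlation(_summary(rows), records)
    assert len(table2) == 3 and r2 == pytest.approx(1.0)


def test_intron_loss_flags():
    genes = []
    for i in range(3):
        genes.append(make_gene(f"a{i}", tokens=SD, cassettes=4, ig_count=1))
    classify_genes(genes)
    # third gene lost its cassette introns
    for c in genes[2].cassette_array:
        object.__setattr__(c, "intron_count", 0)
    table = intron_loss_table(genes).set_index("gene_id")
    assert not table.loc["a0", "intron_loss"]
    assert not table.loc["a1", "intron_loss"]
    assert bool(table.loc["a2", "intron_loss"])
    assert (table["constant_region_introns"] == 1).all()

    uniform = [make_gene(f"u{i}", tokens=SD, cassettes=3, ig_count=1) for i in range(3)]
    classify_genes(uniform)
    assert not intron_loss_table(uniform)["intron_loss"].any()


def test_simulated_intron_loss_matches_event_log():
    from dscamkit.synthetic_data import SimulationConfig, simulate_family

    # loss probability kept low so losses stay a minority per subfamily,
    # the regime where the modal-count rule is valid
    fam = simulate_family(
        SimulationConfig(seed=22, n_species=4, intron_loss_probability=0.15,
                         substitution_rate=0.0)
    )
    genes = classify_genes(fam.genes)
    lost_truth = {
        f"{sp}.{gid}"
        for (kind, sp, gid) in [e[:3] for e in fam.events]
        if kind == "intron_loss"
    }
    table = intron_loss_table(genes)
    flagged = set(table[table["intron_loss"]]["gene_id"])
    # every truth loss present in the table must be flagged, and no extras
    in_table = lost_truth & set(table["gene_id"])
    assert flagged == in_table


def test_subfamily_comparison_identical_and_ratio():
    rows = []
    for sub, count in (("sDscamAlpha", 10), ("sDscamBeta", 10)):
        for i in range(2):
            rows.append({"species": "sp1", "gene_id": f"{sub}.g{i}", "subfamily": sub,
                         "cassette_count": count, "repeat_unit_size": 400.0,
                         "mean_intron_count": 1.0, "constant_intron_count": 3})
    table = subfamily_comparison(_summary(rows)).set_index("metric")
    assert table.loc["cassette_count", "t"] == 0.0
    assert table.loc["cassette_count", "p"] == 1.0

    rows2 = [dict(r, cassette_count=(20 if r["subfamily"] == "sDscamAlpha" else 10))
             for r in rows]
    table2 = subfamily_comparison(_summary(rows2)).set_index("metric")
    assert table2.loc["cassette_count", "alpha_mean"] / table2.loc[
        "cassette_count", "beta_mean"] == pytest.approx(2.0)


def test_subfamily_t_statistic_matches_textbook_formula():
    a_counts = [12, 15, 9, 14, 11]
    b_counts = [7, 8, 6, 10, 9]
    rows = []
    for sub, counts in (("sDscamAlpha", a_counts), ("sDscamBeta", b_counts)):
        for i, c in enumerate(counts):
            rows.append({"species": f"sp{i}", "gene_id": f"{sub}.g{i}", "subfamily": sub,
                         "cassette_count": c, "repeat_unit_size": 400.0,
                         "mean_intron_count": 1.0, "constant_intron_count": 3})
    table = subfamily_comparison(_summary(rows)).set_index("metric")
    assert table.loc["cassette_count", "t"] == pytest.approx(
        pooled_t(a_counts, b_counts)
    )


def test_build_summary_from_simulation(small_family):
    genes = classify_genes(small_family.genes)
    summ = build_summary(genes)
    assert (summ["cassette_count"] >= 1).all()
    assert (summ["repeat_unit_size"] > 0).all()
    truth_counts = {
        f"{sp}.{g.gene_id}": len(g.cassettes)
        for sp, sim_genes in small_family.state.items()
        for g in sim_genes
        if g.cassettes
    }
    got = dict(zip(summ["gene_id"], summ["cassette_count"]))
    assert got == truth_counts
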