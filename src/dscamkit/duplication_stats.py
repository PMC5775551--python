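"""Evolutionary trade-off statistics for the clustered Dscam families.

Across chelicerate species the isoform budget appears roughly conserved
but is spent differently: lineages with many sDscam gene duplicates carry
few 5' cassettes per gene and vice versa.  This module quantifies that
trade-off and its correlates:

* per-subfamily Pearson correlation between per-species gene-duplicate
  count and mean cassette count per gene (expected negative);
* power-law fit of repeat-unit size against cassette count per gene
  (OLS on log10–log10; more duplicates, smaller units);
* correlation of repeat-unit size with genome size;
* intron-loss flags per gene, by comparing the gene's modal per-cassette
  intron count against the subfamily-wide mode (constant-region introns
  tabulated separately — losses concentrate in the variable region);
* α-vs-β subfamily comparison (mean ± SD, two-tailed Student's t).

Significance is read at α = 0.05, two-tailed, throughout.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model_io import DscamClass, GeneModel, SpeciesRecord

logger = logging.getLogger("dscamkit")

SUBFAMILIES = (DscamClass.SDSCAM_ALPHA, DscamClass.SDSCAM_BETA)


def build_summary(genes: Iterable[GeneModel]) -> pd.DataFrame:
    """Per-gene duplication summary for the cassette-bearing subfamilies.

    repeat_unit_size is the mean genomic span of one cassette repeat
    (introns included) within the gene; intron counts are per-cassette
    means.
    """
    rows = []
    for g in genes:
        if g.dscam_class not in SUBFAMILIES or not g.cassette_array:
            continue
        sizes = [c.unit_size for c in g.cassette_array]
        introns = [c.intron_count for c in g.cassette_array]
        rows.append(
            {
                "species": g.species,
                "gene_id": g.gene_id,
                "subfamily": g.dscam_class.value,
                "cassette_count": len(g.cassette_array),
                "repeat_unit_size": float(np.mean(sizes)),
                "mean_intron_count": float(np.mean(introns)),
                "constant_intron_count": len(g.constant_exons) - 1,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "species", "gene_id", "subfamily", "cassette_count",
            "repeat_unit_size", "mean_intron_count", "constant_intron_count",
        ],
    )


def inverse_correlation(
    summary: pd.DataFrame, per_gene: bool = False
) -> dict[str, tuple[float, float]]:
    """Pearson r (and two-sided p) between gene count and cassette count.

    Default aggregation is per species: the number of gene duplicates of
    the subfamily in that species vs the species' mean cassette count per
    gene.  ``per_gene=True`` instead pairs each gene's cassette count
    with its species' gene count.  Zero variance in either variable gives
    (nan, nan).
    """
    out: dict[str, tuple[float, float]] = {}
    present = [c.value for c in SUBFAMILIES if (summary["subfamily"] == c.value).any()]
    if not present:
        raise ValueError("no cassette-bearing subfamily in summary")
    for sub in present:
        rows = summary[summary["subfamily"] == sub]
        if rows["species"].nunique() < 3:
            raise ValueError(f"{sub}: need >= 3 species for correlation")
        per_species = rows.groupby("species").agg(
            gene_count=("gene_id", "size"),
            mean_cassettes=("cassette_count", "mean"),
        )
        if per_gene:
            x = rows["species"].map(per_species["gene_count"]).to_numpy(float)
            y = rows["cassette_count"].to_numpy(float)
        else:
            x = per_species["gene_count"].to_numpy(float)
            y = per_species["mean_cassettes"].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out[sub] = (math.nan, math.nan)
            continue
        r, p = stats.pearsonr(x, y)
        out[sub] = (float(r), float(p))
    return out


def power_law_fit(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float]:
    """Fit y ≈ c·x^b by OLS of log10 y on log10 x; returns (b, c, R²)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("power_law_fit needs >= 3 paired points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires strictly positive values")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all x identical")
    res = stats.linregress(np.log10(x), np.log10(y))
    return float(res.slope), float(10.0 ** res.intercept), float(res.rvalue**2)


def genome_size_correlation(
    summary: pd.DataFrame,
    species_records: Mapping[str, SpeciesRecord] | Iterable[SpeciesRecord],
    subfamily: Optional[str] = None,
) -> tuple[float, float, pd.DataFrame]:
    """Pearson correlation of mean repeat-unit size with genome size (Mb).

    Returns (r, p, table); the table carries the per-species mean unit
    size, genome size, and total cassette count (the circle-size
    annotation used when plotting).  Species without a genome size are
    dropped with a warning; fewer than 3 remaining species is still
    computed but flagged in the log.
    """
    if not isinstance(species_records, Mapping):
        species_records = {r.species: r for r in species_records}
    rows = summary if subfamily is None else summary[summary["subfamily"] == subfamily]
    agg = rows.groupby("species").agg(
        mean_repeat_unit_size=("repeat_unit_size", "mean"),
        total_cassettes=("cassette_count", "sum"),
    )
    sizes = []
    keep = []
    for sp in agg.index:
        rec = species_records.get(sp)
        if rec is None:
            logger.warning("species %s has no genome size; dropped", sp)
            continue
        keep.append(sp)
        sizes.append(rec.genome_size_mb)
    table = agg.loc[keep].assign(genome_size_mb=sizes).reset_index()
    if len(table) < 2:
        raise ValueError("genome_size_correlation needs >= 2 species with sizes")
    if len(table) < 3:
        logger.warning("genome-size correlation on n=%d species: low power", len(table))
    r, p = stats.pearsonr(table["mean_repeat_unit_size"], table["genome_size_mb"])
    return float(r), float(p), table


def _mode(values: Sequence[int]) -> int:
    vals, counts = np.unique(np.asarray(values, int), return_counts=True)
    return int(vals[np.argmax(counts)])


def intron_loss_table(genes: Iterable[GeneModel]) -> pd.DataFrame:
    """Per-gene intron-loss flags from modal per-cassette intron counts.

    A gene is flagged when the modal intron count of its cassettes falls
    below the modal count across all cassettes of its subfamily (modes
    are robust to single mis-annotated cassettes).  Constant-region
    intron counts are reported alongside but never flag a loss.
    """
    genes = [g for g in genes if g.dscam_class in SUBFAMILIES and g.cassette_array]
    subfamily_counts: dict[str, list[int]] = {}
    for g in genes:
        subfamily_counts.setdefault(g.dscam_class.value, []).extend(
            c.intron_count for c in g.cassette_array
        )
    subfamily_mode = {k: _mode(v) for k, v in subfamily_counts.items()}
    rows = []
    for g in genes:
        gene_mode = _mode([c.intron_count for c in g.cassette_array])
        ref = subfamily_mode[g.dscam_class.value]
        rows.append(
            {
                "species": g.species,
                "gene_id": g.gene_id,
                "subfamily": g.dscam_class.value,
                "modal_cassette_introns": gene_mode,
                "subfamily_modal_introns": ref,
                "constant_region_introns": len(g.constant_exons) - 1,
                "intron_loss": gene_mode < ref,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "species", "gene_id", "subfamily", "modal_cassette_introns",
            "subfamily_modal_introns", "constant_region_introns", "intron_loss",
        ],
    )


def subfamily_comparison(summary: pd.DataFrame) -> pd.DataFrame:
    """α-vs-β comparison of cassette counts and per-species gene counts.

    Mean ± SD per subfamily plus a two-tailed Student's t-test (pooled
    variance).  With either subfamily absent the comparison is NA.
    """
    rows = []
    for metric, series in (
        ("cassette_count", lambda df: df["cassette_count"].to_numpy(float)),
        (
            "gene_count",
            lambda df: df.groupby("species")["gene_id"].size().to_numpy(float),
        ),
    ):
        a = series(summary[summary["subfamily"] == DscamClass.SDSCAM_ALPHA.value])
        b = series(summary[summary["subfamily"] == DscamClass.SDSCAM_BETA.value])
        row = {
            "metric": metric,
            "alpha_mean": float(np.mean(a)) if len(a) else math.nan,
            "alpha_sd": float(np.std(a, ddof=1)) if len(a) > 1 else math.nan,
            "beta_mean": float(np.mean(b)) if len(b) else math.nan,
            "beta_sd": float(np.std(b, ddof=1)) if len(b) > 1 else math.nan,
        }
        if len(a) >= 2 and len(b) >= 2:
            if np.ptp(np.concatenate([a, b])) == 0:
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(a, b, equal_var=True)
            row["t"] = float(t)
            row["p"] = float(p)
        else:
            row["t"] = math.nan
            row["p"] = math.nan
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["metric", "alpha_mean", "alpha_sd", "beta_mean", "beta_sd", "t", "p"],
    )
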