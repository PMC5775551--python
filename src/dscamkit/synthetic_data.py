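"""Forward simulator for clustered Dscam-like gene families.

Generates, per species, a genome contig carrying a small Dscam family
(canonical long genes, intermediate genes, and short genes with tandem 5'
variable cassette arrays), evolves it along independent branches from a
shared ancestor, and emits the exact inputs the analysis pipeline
consumes — genome FASTA, gene-model GFF3 in the package dialect, a
domain-call TSV, species metadata — plus RNA-seq reads at known isoform
abundances and a replayable event log recording the ground truth.

The generative model mirrors the statistical structure the analysis is
designed to detect:

* **adjacent cassette duplication** — a duplicated cassette is inserted
  immediately next to its template, so recent bursts form contiguous
  high-identity blocks;
* **gene duplication** — whole-gene copies appended to the contig;
* **substitution divergence** — independent per-site substitutions on
  each branch (uniform across the three alternative bases, a
  Jukes–Cantor-style neutral choice);
* **intron loss** — removal of all cassette-internal introns of one gene
  on one branch, shrinking its repeat units;
* **reads** — uniform start positions within isoforms drawn at configured
  abundances, with optional uniform substitution errors.

Every stochastic draw flows from a single ``numpy.random.Generator``
seeded in the config; the event log materialises every random choice, so
replaying it against the stored ancestor reproduces the final family
byte for byte.
"""

from __future__ import annotations

import copy
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model_io import (
    CassetteRepeat,
    DomainArchitecture,
    GeneModel,
    SpeciesRecord,
    write_domains,
    write_gene_models,
    write_table,
)

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CassetteUnit:
    """Exon/intron layout of one 5' cassette repeat (lengths in nt)."""

    exon_lengths: tuple[int, ...] = (180, 150)
    intron_lengths: tuple[int, ...] = (90,)
    encoded_ig_count: int = 1

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.exon_lengths + self.intron_lengths):
            raise ValueError("lengths must be > 0")
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError("need one intron between consecutive exons")
        if sum(self.exon_lengths) % 3:
            raise ValueError("cassette coding length must be divisible by 3")


#: sDscamβ cassettes carry two extra exons relative to α and encode two Ig domains
BETA_UNIT = CassetteUnit(
    exon_lengths=(180, 150, 150, 120), intron_lengths=(90, 90, 90), encoded_ig_count=2
)


@dataclass(frozen=True)
class AncestralGeneSpec:
    dscam_class: str  # LDscam | mDscam | sDscamAlpha | sDscamBeta | sDscamGamma
    n_cassettes: int = 0
    cassette_unit: Optional[CassetteUnit] = None
    constant_exon_lengths: tuple[int, ...] = (300, 300, 240, 180)
    constant_intron_lengths: tuple[int, ...] = (120, 120, 120)

    def __post_init__(self) -> None:
        has_array = self.dscam_class in ("sDscamAlpha", "sDscamBeta")
        if has_array and self.n_cassettes < 1:
            raise ValueError(f"{self.dscam_class} needs >= 1 cassette")
        if sum(self.constant_exon_lengths) % 3:
            raise ValueError("constant coding length must be divisible by 3")


DEFAULT_ANCESTRAL_GENES = (
    AncestralGeneSpec("LDscam", constant_exon_lengths=(600, 600, 600, 600),
                      constant_intron_lengths=(150, 150, 150)),
    AncestralGeneSpec("mDscam", constant_exon_lengths=(480, 480, 480),
                      constant_intron_lengths=(150, 150)),
    AncestralGeneSpec("mDscam", constant_exon_lengths=(480, 480, 480),
                      constant_intron_lengths=(150, 150)),
    AncestralGeneSpec("sDscamAlpha", n_cassettes=5, cassette_unit=CassetteUnit()),
    AncestralGeneSpec("sDscamBeta", n_cassettes=4, cassette_unit=BETA_UNIT),
    AncestralGeneSpec("sDscamGamma"),
)


#: a larger family emulating the census scale of a cassette-rich arachnid
#: genome: one canonical gene, four intermediate genes, and five short genes
#: (two α arrays, one β array, two γ).  Used by the expression-recovery and
#: expression-bias experiments, where group sizes matter.
CENSUS_ANCESTRAL_GENES = (
    AncestralGeneSpec("LDscam", constant_exon_lengths=(600, 600, 600, 600),
                      constant_intron_lengths=(150, 150, 150)),
) + tuple(
    AncestralGeneSpec("mDscam", constant_exon_lengths=(480, 480, 480),
                      constant_intron_lengths=(150, 150))
    for _ in range(4)
) + (
    AncestralGeneSpec("sDscamAlpha", n_cassettes=5, cassette_unit=CassetteUnit()),
    AncestralGeneSpec("sDscamAlpha", n_cassettes=5, cassette_unit=CassetteUnit()),
    AncestralGeneSpec("sDscamBeta", n_cassettes=4, cassette_unit=BETA_UNIT),
    AncestralGeneSpec("sDscamGamma"),
    AncestralGeneSpec("sDscamGamma"),
)


@dataclass(frozen=True)
class ReadConfig:
    read_length: int = 150
    depth: int = 2000
    error_rate: float = 0.0
    #: per-isoform relative abundances (normalised internally); None = uniform
    abundances: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        if self.read_length <= 0 or self.depth < 0:
            raise ValueError("read_length > 0 and depth >= 0 required")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate in [0, 1)")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated family.

    Rates are per species branch: duplication rates are Poisson means,
    ``substitution_rate`` is the per-site substitution probability, and
    ``intron_loss_probability`` applies per cassette-bearing gene.
    """

    seed: int = 1
    n_species: int = 6
    ancestral_genes: tuple[AncestralGeneSpec, ...] = DEFAULT_ANCESTRAL_GENES
    cassette_duplication_rate: float = 3.0
    gene_duplication_rate: float = 0.7
    substitution_rate: float = 0.02
    intron_loss_probability: float = 0.0
    #: genome sizes (Mb) per species; when given, intron and intergenic
    #: lengths scale proportionally to size / mean(size)
    genome_sizes_mb: Optional[tuple[float, ...]] = None
    intergenic_length: int = 300
    cassette_linker_length: int = 60
    read: ReadConfig = ReadConfig()

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species >= 1")
        for r in (
            self.cassette_duplication_rate,
            self.gene_duplication_rate,
            self.substitution_rate,
            self.intron_loss_probability,
        ):
            if r < 0:
                raise ValueError("rates must be >= 0")
        if self.genome_sizes_mb is not None and len(self.genome_sizes_mb) != self.n_species:
            raise ValueError("genome_sizes_mb must have one entry per species")

    def species_names(self) -> list[str]:
        return [f"sp{i + 1}" for i in range(self.n_species)]


# ---------------------------------------------------------------------------
# mutable simulation state
# ---------------------------------------------------------------------------

@dataclass
class SimCassette:
    exons: list[str]
    introns: list[str]
    encoded_ig_count: int


@dataclass
class SimGene:
    gene_id: str
    dscam_class: str
    constant_exons: list[str]
    constant_introns: list[str]
    cassettes: list[SimCassette] = field(default_factory=list)

    def element(self, key: tuple) -> str:
        kind = key[0]
        if kind == "constant_exon":
            return self.constant_exons[key[1]]
        if kind == "constant_intron":
            return self.constant_introns[key[1]]
        if kind == "cassette_exon":
            return self.cassettes[key[1]].exons[key[2]]
        if kind == "cassette_intron":
            return self.cassettes[key[1]].introns[key[2]]
        raise KeyError(key)

    def set_element(self, key: tuple, seq: str) -> None:
        kind = key[0]
        if kind == "constant_exon":
            self.constant_exons[key[1]] = seq
        elif kind == "constant_intron":
            self.constant_introns[key[1]] = seq
        elif kind == "cassette_exon":
            self.cassettes[key[1]].exons[key[2]] = seq
        elif kind == "cassette_intron":
            self.cassettes[key[1]].introns[key[2]] = seq
        else:
            raise KeyError(key)

    def element_keys(self) -> list[tuple]:
        keys: list[tuple] = []
        keys += [("constant_exon", i) for i in range(len(self.constant_exons))]
        keys += [("constant_intron", i) for i in range(len(self.constant_introns))]
        for ci, c in enumerate(self.cassettes):
            keys += [("cassette_exon", ci, ei) for ei in range(len(c.exons))]
            keys += [("cassette_intron", ci, ei) for ei in range(len(c.introns))]
        return keys


Event = tuple  # (type, species, ...) — see apply_events


# ---------------------------------------------------------------------------
# ancestor construction
# ---------------------------------------------------------------------------

def _random_coding(rng: np.random.Generator, length: int) -> str:
    """Random coding sequence of `length` nt (multiple of 3) with no stop codon."""
    idx = rng.integers(0, len(_CODONS), size=length // 3)
    return "".join(_CODONS[i] for i in idx)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _make_cassette(rng: np.random.Generator, unit: CassetteUnit) -> SimCassette:
    coding = _random_coding(rng, sum(unit.exon_lengths))
    exons, pos = [], 0
    for l in unit.exon_lengths:
        exons.append(coding[pos : pos + l])
        pos += l
    introns = [_random_seq(rng, l) for l in unit.intron_lengths]
    return SimCassette(exons, introns, unit.encoded_ig_count)


def build_ancestor(config: SimulationConfig, rng: np.random.Generator) -> list[SimGene]:
    genes = []
    counters: dict[str, int] = {}
    for spec in config.ancestral_genes:
        n = counters.get(spec.dscam_class, 0) + 1
        counters[spec.dscam_class] = n
        gid = f"{spec.dscam_class}{n}"
        coding = _random_coding(rng, sum(spec.constant_exon_lengths))
        const_exons, pos = [], 0
        for l in spec.constant_exon_lengths:
            const_exons.append(coding[pos : pos + l])
            pos += l
        const_introns = [_random_seq(rng, l) for l in spec.constant_intron_lengths]
        cassettes = [
            _make_cassette(rng, spec.cassette_unit)
            for _ in range(spec.n_cassettes)
        ]
        genes.append(SimGene(gid, spec.dscam_class, const_exons, const_introns, cassettes))
    return genes


# ---------------------------------------------------------------------------
# event drawing and replay
# ---------------------------------------------------------------------------

def draw_events(
    config: SimulationConfig, ancestor: list[SimGene], rng: np.random.Generator
) -> list[Event]:
    """Draw the full, materialised event list for every species branch.

    Event shapes:
      ("gene_dup", species, src_gene_id, new_gene_id)
      ("cassette_dup", species, gene_id, template_index0)   # copy inserted at template+1
      ("intron_loss", species, gene_id)
      ("substitution", species, gene_id, element_key, position, new_base)
    """
    events: list[Event] = []
    for species in config.species_names():
        # track structure on a scratch copy so later draws address valid targets
        state = copy.deepcopy(ancestor)
        by_id = {g.gene_id: g for g in state}

        n_gd = rng.poisson(config.gene_duplication_rate)
        for _ in range(n_gd):
            src = state[rng.integers(0, len(state))]
            new_id = f"{src.gene_id}_{species}d{sum(1 for g in state if g.gene_id.startswith(src.gene_id + '_'))+1}"
            events.append(("gene_dup", species, src.gene_id, new_id))
            dup = copy.deepcopy(src)
            dup.gene_id = new_id
            state.append(dup)
            by_id[new_id] = dup

        n_cd = rng.poisson(config.cassette_duplication_rate)
        arrayed = [g for g in state if g.cassettes]
        for _ in range(n_cd):
            if not arrayed:
                break
            g = arrayed[rng.integers(0, len(arrayed))]
            j = int(rng.integers(0, len(g.cassettes)))
            events.append(("cassette_dup", species, g.gene_id, j))
            g.cassettes.insert(j + 1, copy.deepcopy(g.cassettes[j]))

        for g in state:
            if g.cassettes and rng.random() < config.intron_loss_probability:
                events.append(("intron_loss", species, g.gene_id))
                for c in g.cassettes:
                    c.exons = ["".join(c.exons)]
                    c.introns = []

        events.extend(
            draw_substitutions(state, species, config.substitution_rate, rng)
        )
    return events


def draw_substitutions(
    state: Sequence[SimGene],
    species: str,
    rate: float,
    rng: np.random.Generator,
) -> list[Event]:
    """Materialise per-site substitution events on every element of ``state``.

    Mutates ``state`` in place (the scratch copy used while drawing) and
    returns the corresponding replayable events.
    """
    events: list[Event] = []
    if rate <= 0:
        return events
    for g in state:
        for key in g.element_keys():
            seq = g.element(key)
            n_mut = rng.binomial(len(seq), rate)
            if not n_mut:
                continue
            positions = rng.choice(len(seq), size=n_mut, replace=False)
            for pos in sorted(int(p) for p in positions):
                alternatives = [b for b in _BASES if b != seq[pos]]
                new = alternatives[rng.integers(0, 3)]
                events.append(("substitution", species, g.gene_id, key, pos, new))
                seq = seq[:pos] + new + seq[pos + 1 :]
            g.set_element(key, seq)
    return events


def apply_events(
    ancestor: Sequence[SimGene], events: Iterable[Event], species: str
) -> list[SimGene]:
    """Replay one species branch: apply its events to a copy of the ancestor."""
    state = copy.deepcopy(list(ancestor))
    by_id = {g.gene_id: g for g in state}
    for ev in events:
        if ev[1] != species:
            continue
        kind = ev[0]
        if kind == "gene_dup":
            _, _, src_id, new_id = ev
            dup = copy.deepcopy(by_id[src_id])
            dup.gene_id = new_id
            state.append(dup)
            by_id[new_id] = dup
        elif kind == "cassette_dup":
            _, _, gid, j = ev
            g = by_id[gid]
            g.cassettes.insert(j + 1, copy.deepcopy(g.cassettes[j]))
        elif kind == "intron_loss":
            g = by_id[ev[2]]
            for c in g.cassettes:
                c.exons = ["".join(c.exons)]
                c.introns = []
        elif kind == "substitution":
            _, _, gid, key, pos, new = ev
            g = by_id[gid]
            seq = g.element(key)
            g.set_element(key, seq[:pos] + new + seq[pos + 1 :])
        else:
            raise ValueError(f"unknown event type {kind!r}")
    return state


# ---------------------------------------------------------------------------
# emission: genomes, gene models, architectures
# ---------------------------------------------------------------------------

_ARCH_TEMPLATES = {
    # canonical: 10 Ig + 6 FNIII, Ig10 between FNIII4 and FNIII5
    "LDscam": ["LEADER"] + ["IG"] * 9 + ["FN3"] * 4 + ["IG"] + ["FN3"] * 2 + ["TM", "CYTO"],
    # lacks Ig10 and FNIII3–4
    "mDscam": ["LEADER"] + ["IG"] * 9 + ["FN3"] * 4 + ["TM", "CYTO"],
    # short constant region: three Ig + three FNIII + TM
    "sDscamAlpha": ["LEADER"] + ["IG"] * 3 + ["FN3"] * 3 + ["TM", "CYTO"],
    "sDscamBeta": ["LEADER"] + ["IG"] * 3 + ["FN3"] * 3 + ["TM", "CYTO"],
    "sDscamGamma": ["LEADER"] + ["IG"] * 3 + ["FN3"] * 3 + ["TM", "CYTO"],
}


def _architecture(gene_id: str, dscam_class: str) -> DomainArchitecture:
    tokens = _ARCH_TEMPLATES[dscam_class]
    widths = {"LEADER": 20, "IG": 100, "FN3": 95, "TM": 25, "CYTO": 60}
    domains, pos = [], 1
    for t in tokens:
        domains.append((t, pos, pos + widths[t]))
        pos += widths[t]
    return DomainArchitecture(gene_id, tuple(domains))


def _spacer(length: int) -> str:
    return ("ACGT" * (length // 4 + 1))[:length]


@dataclass
class SimulatedFamily:
    """Simulator output: genomes, gene models, truth channels."""

    config: SimulationConfig
    ancestor: list[SimGene]
    events: list[Event]
    genomes: dict[str, str]
    genes: list[GeneModel]
    species_records: list[SpeciesRecord]
    state: dict[str, list[SimGene]]  # final per-species gene states

    def write(self, outdir: str | os.PathLike) -> None:
        outdir = str(outdir)
        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "genomes.fasta"), "w") as fh:
            for seqid in sorted(self.genomes):
                fh.write(f">{seqid}\n")
                seq = self.genomes[seqid]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        write_gene_models(self.genes, os.path.join(outdir, "genes.gff3"))
        write_domains(
            [g.architecture for g in self.genes], os.path.join(outdir, "domains.tsv")
        )
        write_table(
            pd.DataFrame(
                [
                    {"species": r.species, "genome_size_mb": r.genome_size_mb}
                    for r in self.species_records
                ]
            ),
            os.path.join(outdir, "species.tsv"),
        )
        write_table(
            pd.DataFrame(
                [{"type": e[0], "species": e[1], "detail": repr(e[2:])} for e in self.events],
                columns=["type", "species", "detail"],
            ),
            os.path.join(outdir, "events.tsv"),
        )


def _emit_species(
    species: str,
    sim_genes: Sequence[SimGene],
    config: SimulationConfig,
    size_factor: float,
) -> tuple[str, list[GeneModel]]:
    """Lay out one species' genes on a contig; returns (sequence, models)."""
    seqid = f"chr_{species}"
    parts: list[str] = []
    pos = 0
    models: list[GeneModel] = []

    def emit(seq: str) -> tuple[int, int]:
        nonlocal pos
        parts.append(seq)
        span = (pos, pos + len(seq))
        pos += len(seq)
        return span

    intergenic = max(1, round(config.intergenic_length * size_factor))
    linker = max(1, round(config.cassette_linker_length * size_factor))
    for g in sim_genes:
        emit(_spacer(intergenic))
        cassettes: list[CassetteRepeat] = []
        for ci, c in enumerate(g.cassettes, 1):
            exon_spans = []
            start = pos
            for ei, exon in enumerate(c.exons):
                exon_spans.append(emit(exon))
                if ei < len(c.introns):
                    intron = c.introns[ei]
                    if size_factor != 1.0:
                        intron = intron + _spacer(
                            max(0, round(len(intron) * (size_factor - 1.0)))
                        )
                    emit(intron)
            cassettes.append(
                CassetteRepeat(
                    index=ci,
                    interval=(start, pos),
                    exons=tuple(exon_spans),
                    variable_exon=exon_spans[0],
                    encoded_ig_count=c.encoded_ig_count,
                    intron_count=len(c.introns),
                )
            )
            emit(_spacer(linker))
        constant_spans = []
        for ei, exon in enumerate(g.constant_exons):
            constant_spans.append(emit(exon))
            if ei < len(g.constant_introns):
                emit(g.constant_introns[ei])
        models.append(
            GeneModel(
                gene_id=f"{species}.{g.gene_id}",
                species=species,
                seqid=seqid,
                strand="+",
                constant_exons=constant_spans,
                cassette_array=cassettes,
                architecture=_architecture(f"{species}.{g.gene_id}", g.dscam_class),
            )
        )
    emit(_spacer(intergenic))
    return "".join(parts), models


def assemble_family(
    config: SimulationConfig, ancestor: list[SimGene], events: list[Event]
) -> SimulatedFamily:
    """Deterministically derive the emitted family from ancestor + event log."""
    sizes = config.genome_sizes_mb
    mean_size = float(np.mean(sizes)) if sizes else 1.0
    genomes: dict[str, str] = {}
    genes: list[GeneModel] = []
    records: list[SpeciesRecord] = []
    state: dict[str, list[SimGene]] = {}
    for i, species in enumerate(config.species_names()):
        final = apply_events(ancestor, events, species)
        state[species] = final
        factor = (sizes[i] / mean_size) if sizes else 1.0
        seq, models = _emit_species(species, final, config, factor)
        if not seq:
            raise ValueError("zero-length genome")
        genomes[f"chr_{species}"] = seq
        genes.extend(models)
        records.append(
            SpeciesRecord(
                species=species,
                genome_size_mb=sizes[i] if sizes else len(seq) / 1.0e6,
                gene_ids=tuple(m.gene_id for m in models),
            )
        )
    return SimulatedFamily(
        config=config,
        ancestor=ancestor,
        events=events,
        genomes=genomes,
        genes=genes,
        species_records=records,
        state=state,
    )


def simulate_family(config: SimulationConfig) -> SimulatedFamily:
    """Run the forward simulation; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    ancestor = build_ancestor(config, rng)
    events = draw_events(config, ancestor, rng)
    return assemble_family(config, ancestor, events)


def replay_family(family: SimulatedFamily) -> SimulatedFamily:
    """Re-derive the family from its stored ancestor + event log (truth check)."""
    return assemble_family(family.config, family.ancestor, family.events)


def simulate_cassette_burst(
    seed: int,
    n_copies: int = 6,
    n_flank: int = 2,
    substitution_rate: float = 0.005,
    cassette_unit: CassetteUnit = CassetteUnit(),
) -> tuple[SimulatedFamily, list[str]]:
    """Single-species α gene with one recent adjacent-duplication burst.

    The ancestor carries ``2 * n_flank + 1`` unrelated cassettes; the
    middle one is tandemly duplicated ``n_copies`` times (each copy
    inserted adjacent to its template), then substitution divergence is
    applied.  Returns the family and the labels of the burst members
    (template plus copies, contiguous in the genome), the truth for
    duplication-block and monophyly recovery tests.
    """
    config = SimulationConfig(
        seed=seed,
        n_species=1,
        ancestral_genes=(
            AncestralGeneSpec(
                "sDscamAlpha", n_cassettes=2 * n_flank + 1, cassette_unit=cassette_unit
            ),
        ),
        cassette_duplication_rate=0.0,
        gene_duplication_rate=0.0,
        substitution_rate=substitution_rate,
    )
    rng = np.random.default_rng(seed)
    ancestor = build_ancestor(config, rng)
    species = config.species_names()[0]
    gid = ancestor[0].gene_id
    template = n_flank  # 0-based middle cassette
    events: list[Event] = [
        ("cassette_dup", species, gid, template) for _ in range(n_copies)
    ]
    scratch = apply_events(ancestor, events, species)
    events.extend(draw_substitutions(scratch, species, substitution_rate, rng))
    family = assemble_family(config, ancestor, events)
    burst = [
        f"{species}.{gid}.c{i}"
        for i in range(template + 1, template + n_copies + 2)  # 1-based indices
    ]
    return family, burst


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def isoform_sequences(family: SimulatedFamily) -> dict[str, str]:
    """Per-isoform mRNA sequences: one isoform per cassette (its spliced
    exons followed by the spliced constant region), one for cassette-less
    genes."""
    from .model_io import spliced_sequence

    isoforms: dict[str, str] = {}
    for g in family.genes:
        const = spliced_sequence(family.genomes, g.seqid, g.constant_exons, g.strand)
        if g.cassette_array:
            for c in g.cassette_array:
                cass = spliced_sequence(family.genomes, g.seqid, list(c.exons), g.strand)
                isoforms[f"{g.gene_id}.c{c.index}"] = cass + const
        else:
            isoforms[g.gene_id] = const
    return isoforms


def simulate_reads(
    family: SimulatedFamily,
    read_config: Optional[ReadConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Sample reads from isoforms at configured abundances.

    Returns (reads, truth) where truth has one row per isoform with its
    normalised abundance and parent gene.  Reads start uniformly within
    the isoform; isoforms shorter than the read length are excluded (and
    absent from truth).  ``depth = 0`` gives an empty read list.
    """
    rc = read_config or family.config.read
    rng = rng or np.random.default_rng(family.config.seed + 10_000)
    isoforms = isoform_sequences(family)
    usable = {k: v for k, v in isoforms.items() if len(v) >= rc.read_length}
    if not usable:
        raise ValueError("no isoform long enough for the configured read length")
    ids = sorted(usable)
    if rc.abundances is not None:
        weights = np.array([rc.abundances.get(i, 0.0) for i in ids], float)
        if weights.sum() <= 0:
            raise ValueError("abundance vector sums to 0 over usable isoforms")
    else:
        weights = np.ones(len(ids))
    p = weights / weights.sum()
    reads: list[tuple[str, str]] = []
    if rc.depth > 0:
        choices = rng.choice(len(ids), size=rc.depth, p=p)
        for n, ci in enumerate(choices):
            iso = usable[ids[ci]]
            start = int(rng.integers(0, len(iso) - rc.read_length + 1))
            seq = iso[start : start + rc.read_length]
            if rc.error_rate > 0:
                n_err = rng.binomial(rc.read_length, rc.error_rate)
                if n_err:
                    pos = rng.choice(rc.read_length, size=n_err, replace=False)
                    chars = list(seq)
                    for pp in pos:
                        alts = [b for b in _BASES if b != chars[pp]]
                        chars[pp] = alts[rng.integers(0, 3)]
                    seq = "".join(chars)
            reads.append((f"read{n}", seq))
    truth = pd.DataFrame(
        {
            "isoform": ids,
            "gene_id": [i.rsplit(".c", 1)[0] if ".c" in i else i for i in ids],
            "abundance": p,
            "length_nt": [len(usable[i]) for i in ids],
        }
    )
    return reads, truth


def write_fastq(reads: Sequence[tuple[str, str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# budget scenario for the inverse-correlation recovery test
# ---------------------------------------------------------------------------

def make_budget_scenario(
    n_species: int,
    total_isoforms: int,
    rng: np.random.Generator,
    subfamily: str = "sDscamAlpha",
    noise_sd: float = 0.1,
    max_genes: int = 8,
    size_exponent: float = -0.5,
) -> pd.DataFrame:
    """Per-gene duplication summary under a fixed per-species isoform budget.

    Each species draws a gene-duplicate count g uniformly from 1..max_genes
    and spends the budget as ≈ total_isoforms / g cassettes per gene, with
    lognormal noise of spread ``noise_sd``.  Repeat-unit sizes shrink with
    cassette count following a power law of exponent ``size_exponent``
    (many small units vs few large ones).  The returned frame matches the
    columns of :func:`dscamkit.duplication_stats.build_summary`.
    """
    if total_isoforms < max_genes:
        raise ValueError("total_isoforms must be >= max_genes")
    rows = []
    for s in range(n_species):
        species = f"sp{s + 1}"
        g = int(rng.integers(1, max_genes + 1))
        for k in range(g):
            cassettes = max(1, round(total_isoforms / g * rng.lognormal(0.0, noise_sd)))
            unit = 800.0 * cassettes**size_exponent * rng.lognormal(0.0, noise_sd)
            rows.append(
                {
                    "species": species,
                    "gene_id": f"{species}.g{k + 1}",
                    "subfamily": subfamily,
                    "cassette_count": cassettes,
                    "repeat_unit_size": unit,
                    "mean_intron_count": 1.0,
                    "constant_intron_count": 3,
                }
            )
    return pd.DataFrame(rows)
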