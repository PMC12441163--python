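"""Synthetic data generation for the mapping pipeline.

This module emulates the experimental design behind a bulked-segregant
mapping study of a partially dominant fiber-color locus: an F2 population
from a brown x white cotton cross, CIELab color phenotypes with technical
replicates, contrasting phenotype bulks whose called variant sets reflect
pooled allele presence, a planted-effect RNA-seq count matrix, and locus
sequences carrying (or missing) an LTR retrotransposon.

All randomness flows through a single :class:`numpy.random.Generator`
seeded from :class:`CrossConfig`, so identical configurations reproduce
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .variants import VariantSet

__all__ = [
    "Chromosome",
    "GenomeModel",
    "CrossConfig",
    "Gamete",
    "F2Individual",
    "F2Population",
    "BROWN_PARENT_LAB",
    "WHITE_PARENT_LAB",
    "simulate_f2",
    "assign_phenotypes",
    "make_bulks",
    "draw_parental_sites",
    "simulate_bulk_variants",
    "simulate_counts",
    "simulate_marker_calls",
    "default_marker_panel",
    "simulate_locus_sequences",
]

#: Mature-fiber CIELab means of the brown parent (L*, a*, b*), from the
#: colorimeter characterisation of the rust-brown line (three technical
#: replicates averaged).
BROWN_PARENT_LAB: tuple[float, float, float] = (67.75, 11.58, 30.33)

#: Mature-fiber CIELab means of the white standard line.
WHITE_PARENT_LAB: tuple[float, float, float] = (96.49, 0.64, 10.25)


@dataclass(frozen=True)
class Chromosome:
    """One chromosome of the model genome.

    Parameters
    ----------
    name : str
        Contig name used in all coordinate-bearing output.
    length_bp : int
        Physical length in base pairs (> 0).
    length_cm : float
        Genetic map length in centiMorgans (>= 0). Recombination is
        modelled with no interference: crossover counts per gamete are
        Poisson with mean ``length_cm / 100`` (Haldane map function), and
        crossover positions are uniform on the physical length, i.e. a
        constant cM/bp ratio along the chromosome.
    """

    name: str
    length_bp: int
    length_cm: float

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"chromosome {self.name!r}: physical length must be > 0")
        if self.length_cm < 0:
            raise ValueError(f"chromosome {self.name!r}: genetic length must be >= 0")


@dataclass(frozen=True)
class GenomeModel:
    """Multi-chromosome genome with one biallelic causal locus.

    The default desk-scale genome (five 50-Mb chromosomes at 1 cM/Mb and
    one parental difference per kb) stands in for the 26-chromosome
    tetraploid cotton genome; everything is configurable upward.
    """

    chromosomes: tuple[Chromosome, ...]
    variant_density: float = 1.0e-3
    causal_locus: tuple[str, int] = ("A03", 22_500_000)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome needs at least one chromosome")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        if self.variant_density <= 0:
            raise ValueError("variant_density must be > 0")
        chrom, pos = self.causal_locus
        target = self.chromosome(chrom)
        if not 1 <= pos <= target.length_bp:
            raise ValueError("causal locus position outside its chromosome")

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"no chromosome named {name!r}")

    @property
    def contigs(self) -> dict[str, int]:
        return {c.name: c.length_bp for c in self.chromosomes}

    @classmethod
    def default(cls) -> "GenomeModel":
        chroms = tuple(
            Chromosome(f"A{i:02d}", 50_000_000, 50.0) for i in range(1, 6)
        )
        return cls(chromosomes=chroms)


@dataclass(frozen=True)
class CrossConfig:
    """Design parameters of the simulated cross and its assays.

    Defaults follow the study design this generator emulates: 508 F2
    individuals, 77-plant bulks, partially dominant color (heterozygote
    mean midway between the parents), and modest bulk-call noise.
    """

    n_f2: int = 508
    bulk_size: int = 77
    #: per-genotype CIELab means; key = copies of the mutant (brown) allele.
    dominance: Mapping[int, tuple[float, float, float]] = field(
        default_factory=lambda: {
            0: WHITE_PARENT_LAB,
            1: tuple((b + w) / 2 for b, w in zip(BROWN_PARENT_LAB, WHITE_PARENT_LAB)),
            2: BROWN_PARENT_LAB,
        }
    )
    noise_sd: float = 1.0
    genotyping_error: float = 0.02
    dropout: float = 0.05
    n_replicates: int = 3
    cream_band: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_f2 <= 0:
            raise ValueError("n_f2 must be > 0")
        if self.bulk_size < 0:
            raise ValueError("bulk_size must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for p, name in ((self.genotyping_error, "genotyping_error"), (self.dropout, "dropout")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if set(self.dominance) != {0, 1, 2}:
            raise ValueError("dominance must map genotypes 0, 1 and 2")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class Gamete:
    """A recombinant gamete on one chromosome.

    ``phase`` is the parental origin (1 = mutant/brown parent) of the
    leftmost segment; origin alternates at each breakpoint.
    """

    phase: int
    breakpoints: np.ndarray  # sorted float positions in (0, length_bp)

    def carries_mutant(self, positions: np.ndarray) -> np.ndarray:
        """Boolean: does this gamete carry the mutant-parent allele at ``positions``."""
        seg = np.searchsorted(self.breakpoints, np.asarray(positions, dtype=float))
        return (seg % 2) == (1 - self.phase)


@dataclass
class F2Individual:
    id: str
    gametes: dict[str, tuple[Gamete, Gamete]]
    causal_genotype: int
    color: np.ndarray | None = None  # (n_replicates, 3) of L*, a*, b*
    group: str | None = None

    def carrier_status(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        g1, g2 = self.gametes[chrom]
        return g1.carries_mutant(positions) | g2.carries_mutant(positions)


@dataclass
class F2Population:
    genome: GenomeModel
    config: CrossConfig
    individuals: list[F2Individual]

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)

    def by_id(self) -> dict[str, F2Individual]:
        return {ind.id: ind for ind in self.individuals}

    def genotype_counts(self) -> dict[int, int]:
        counts = {0: 0, 1: 0, 2: 0}
        for ind in self.individuals:
            counts[ind.causal_genotype] += 1
        return counts

    def group_ids(self, *groups: str) -> list[str]:
        return [ind.id for ind in self.individuals if ind.group in groups]

    def phenotype_frame(self) -> pd.DataFrame:
        """Long-format phenotype table: one row per technical replicate."""
        rows = []
        for ind in self.individuals:
            if ind.color is None:
                raise ValueError("phenotypes not assigned yet")
            for r, (L, a, b) in enumerate(ind.color, start=1):
                rows.append((ind.id, r, L, a, b, ind.group))
        return pd.DataFrame(rows, columns=["id", "replicate", "L", "a", "b", "group"])


def _draw_gamete(chrom: Chromosome, rng: np.random.Generator) -> Gamete:
    n_xo = rng.poisson(chrom.length_cm / 100.0) if chrom.length_cm > 0 else 0
    breaks = np.sort(rng.uniform(0.0, chrom.length_bp, size=n_xo))
    phase = int(rng.integers(2))
    return Gamete(phase=phase, breakpoints=breaks)


def simulate_f2(
    genome: GenomeModel, config: CrossConfig, rng: np.random.Generator | None = None
) -> F2Population:
    """Simulate an F2 population from a cross of two inbred parents.

    Both F1 parents are heterozygous at every parental-difference site, so
    each F2 individual is the union of two independent recombinant
    gametes. Crossovers per gamete and chromosome are Poisson with mean
    equal to the map length in Morgans (no interference); the genotype at
    any site, including the causal locus, derives from the breakpoints.
    """
    if rng is None:
        rng = config.rng()
    causal_chrom, causal_pos = genome.causal_locus
    individuals = []
    width = len(str(config.n_f2))
    for i in range(config.n_f2):
        gametes = {
            c.name: (_draw_gamete(c, rng), _draw_gamete(c, rng))
            for c in genome.chromosomes
        }
        g1, g2 = gametes[causal_chrom]
        pos = np.array([causal_pos])
        genotype = int(g1.carries_mutant(pos)[0]) + int(g2.carries_mutant(pos)[0])
        individuals.append(
            F2Individual(id=f"F2_{i + 1:0{width}d}", gametes=gametes, causal_genotype=genotype)
        )
    return F2Population(genome=genome, config=config, individuals=individuals)


def assign_phenotypes(
    population: F2Population,
    config: CrossConfig | None = None,
    rng: np.random.Generator | None = None,
) -> F2Population:
    """Draw replicated CIELab colors and classify each plant into a group.

    Colors are Gaussian around the genotype-class mean (incomplete
    dominance: the heterozygote mean is, by default, the arithmetic
    midpoint of the parental means). Three technical replicates are drawn
    per plant, averaged, and classified against the parental reference
    colors with a cream half-band (see :func:`fibermap.color.classify_colors`).
    """
    from .color import average_replicates, classify_colors

    if config is None:
        config = population.config
    if rng is None:
        rng = np.random.default_rng(config.rng().integers(2**31))
    means = {g: np.asarray(m, dtype=float) for g, m in config.dominance.items()}
    for ind in population.individuals:
        mu = means[ind.causal_genotype]
        ind.color = mu + rng.normal(0.0, config.noise_sd, size=(config.n_replicates, 3))
    pheno = population.phenotype_frame().drop(columns="group")
    averaged = average_replicates(pheno)
    labels = classify_colors(
        averaged,
        brown_ref=means[2],
        white_ref=means[0],
        cream_band=config.cream_band,
    )
    for ind in population.individuals:
        ind.group = labels[ind.id]
    return population


def make_bulks(
    population: F2Population,
    group_a: str,
    group_b: str,
    bulk_size: int,
    rng: np.random.Generator | None = None,
) -> tuple[list[str], list[str]]:
    """Sample two disjoint phenotype bulks of ``bulk_size`` plants each.

    Members are drawn without replacement within their named phenotype
    group (the study design gives no selection rule beyond group
    membership, so sampling is uniform at random within group).
    """
    if rng is None:
        rng = np.random.default_rng(population.config.rng().integers(2**31, size=2)[1])
    out = []
    for group in (group_a, group_b):
        ids = population.group_ids(*group.split("+"))
        if len(ids) < bulk_size:
            raise ValueError(
                f"group {group!r} has {len(ids)} individuals; cannot bulk {bulk_size}"
            )
        chosen = sorted(rng.choice(ids, size=bulk_size, replace=False)) if bulk_size else []
        out.append(list(chosen))
    bulk_a, bulk_b = out
    if set(bulk_a) & set(bulk_b):
        raise ValueError("bulks overlap; groups must be disjoint")
    return bulk_a, bulk_b


_BASES = np.array(list("ACGT"))


def draw_parental_sites(
    genome: GenomeModel,
    rng: np.random.Generator,
    snp_fraction: float = 0.9,
) -> pd.DataFrame:
    """Instantiate parental-difference sites along every chromosome.

    Site counts per chromosome are Poisson(``variant_density`` x length);
    positions are uniform, deduplicated, sorted. Each site gets random
    ref/alt alleles; a ``1 - snp_fraction`` share are 1-bp indels written
    as anchored allele strings (VCF style).
    """
    frames = []
    for c in genome.chromosomes:
        n = int(rng.poisson(genome.variant_density * c.length_bp))
        pos = np.unique(rng.integers(1, c.length_bp + 1, size=n))
        n = len(pos)
        ref_idx = rng.integers(4, size=n)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
        ref = _BASES[ref_idx].astype(object)
        alt = _BASES[alt_idx].astype(object)
        is_snp = rng.random(n) < snp_fraction
        extra = _BASES[rng.integers(4, size=n)]
        ins = rng.random(n) < 0.5
        for i in np.nonzero(~is_snp)[0]:
            if ins[i]:  # insertion relative to the reference
                alt[i] = ref[i] + extra[i]
            else:  # deletion: ref carries the extra base
                ref[i] = ref[i] + extra[i]
                alt[i] = ref[i][0]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": c.name,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "var_class": np.where(is_snp, "SNP", "indel"),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_bulk_variants(
    genome: GenomeModel,
    population: F2Population,
    bulks: Mapping[str, Sequence[str]],
    config: CrossConfig | None = None,
    sites: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, VariantSet]:
    """Emit the called variant set of each bulk.

    A parental-difference site is truly present in a bulk iff at least
    one member carries the mutant-parent allele there; true presence is
    then degraded by ``dropout`` (a present site is missed) and
    ``genotyping_error`` (the call is flipped). Both bulks are evaluated
    on the same instantiated site panel, mirroring joint variant calling
    against one reference. An empty bulk yields an empty set.
    """
    if config is None:
        config = population.config
    if rng is None:
        rng = np.random.default_rng(config.rng().integers(2**31, size=3)[2])
    if sites is None:
        sites = draw_parental_sites(genome, rng)
    by_id = population.by_id()
    out: dict[str, VariantSet] = {}
    for name, member_ids in bulks.items():
        if len(member_ids) == 0:
            empty = sites.iloc[0:0].copy()
            out[name] = VariantSet(empty, contigs=genome.contigs)
            continue
        present = np.zeros(len(sites), dtype=bool)
        for chrom, idx in sites.groupby("chrom", sort=False).indices.items():
            pos = sites["pos"].to_numpy()[idx].astype(float)
            chrom_present = np.zeros(len(idx), dtype=bool)
            for mid in member_ids:
                if chrom_present.all():
                    break
                chrom_present |= by_id[mid].carrier_status(chrom, pos)
            present[idx] = chrom_present
        called = present & (rng.random(len(sites)) >= config.dropout)
        called ^= rng.random(len(sites)) < config.genotyping_error
        out[name] = VariantSet(sites[called].reset_index(drop=True), contigs=genome.contigs)
    return out


def simulate_counts(
    n_genes: int,
    groups: Mapping[str, str],
    planted: Sequence[tuple[str, str, float]] = (),
    dispersion: float = 0.05,
    seed: int | np.random.Generator = 0,
    base_mean_log: float = np.log(50.0),
    base_mean_sd: float = 1.0,
    libsize_log: float = np.log(1.0e6),
    libsize_sd: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count matrix with planted fold changes.

    Parameters
    ----------
    n_genes : int
        Number of genes; ids are ``gene_0001`` ...
    groups : mapping of sample id -> group/line label
        At least two replicates per group are required.
    planted : sequence of (gene_id, group, fold_change)
        Multiplies the named group's expected expression for that gene.
        ``fold_change`` must be > 0.
    dispersion : float
        NB dispersion alpha (variance = mu + alpha mu^2); 0 gives Poisson.

    Returns ``(counts, design)``: a genes x samples integer DataFrame and
    a (sample, line) design table. Gene baseline expression is
    LogNormal(``base_mean_log``, ``base_mean_sd``) on a counts-per-million
    scale; library sizes are LogNormal(``libsize_log``, ``libsize_sd``).
    Planted genes take the median baseline (``exp(base_mean_log)``)
    rather than a random draw, so the planted contrast — not baseline
    sampling or library-composition distortion from an extreme
    baseline-times-fold product — is what downstream recovery measures.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    samples = list(groups)
    labels = pd.Series({s: groups[s] for s in samples})
    if labels.value_counts().min() < 2:
        raise ValueError("need >= 2 replicates per group")
    genes = [f"gene_{i + 1:04d}" for i in range(n_genes)]
    gene_index = {g: i for i, g in enumerate(genes)}
    base = rng.lognormal(base_mean_log, base_mean_sd, size=n_genes)
    fold = pd.DataFrame(1.0, index=genes, columns=sorted(set(groups.values())))
    for gene, group, fc in planted:
        if fc <= 0:
            raise ValueError("fold_change must be > 0")
        fold.loc[gene, group] = fc
        base[gene_index[gene]] = np.exp(base_mean_log)
    libsize = rng.lognormal(libsize_log, libsize_sd, size=len(samples))
    mu = np.empty((n_genes, len(samples)))
    for j, s in enumerate(samples):
        mu[:, j] = base * fold[groups[s]].to_numpy() * (libsize[j] / 1.0e6)
    if dispersion > 0:
        n_param = 1.0 / dispersion
        counts = rng.negative_binomial(n_param, n_param / (n_param + mu))
    else:
        counts = rng.poisson(mu)
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    counts_df.index.name = "gene"
    design = pd.DataFrame({"sample": samples, "line": [groups[s] for s in samples]})
    return counts_df, design


def default_marker_panel(genome: GenomeModel) -> pd.DataFrame:
    """An 11-marker dominant panel spanning the causal region.

    Offsets mimic a marker walk toward a candidate gene: wide flanks
    a megabase-plus out, and one marker a few kb from the locus.
    """
    chrom, pos = genome.causal_locus
    offsets = [
        -1_700_000, -1_000_000, -500_000, -200_000, -50_000,
        2_900, 50_000, 200_000, 500_000, 1_000_000, 1_670_000,
    ]
    length = genome.chromosome(chrom).length_bp
    rows = []
    for i, off in enumerate(offsets, start=1):
        p = pos + off
        if not 1 <= p <= length:
            raise ValueError("marker panel extends beyond the chromosome")
        rows.append((f"M{i:02d}", chrom, p))
    return pd.DataFrame(rows, columns=["name", "chrom", "pos"])


def simulate_marker_calls(
    population: F2Population, markers: pd.DataFrame
) -> pd.DataFrame:
    """Dominant mutant-specific marker calls (P/N) for every individual.

    A plant scores P at a marker iff it carries the mutant-parent
    haplotype there on at least one chromosome copy — exactly how a
    mutant-allele-specific PCR assay behaves (heterozygotes and mutant
    homozygotes are indistinguishable).
    """
    rows = []
    for ind in population.individuals:
        for _, m in markers.iterrows():
            carrier = bool(ind.carrier_status(m["chrom"], np.array([float(m["pos"])]))[0])
            rows.append((ind.id, m["name"], "P" if carrier else "N"))
    return pd.DataFrame(rows, columns=["individual", "marker", "call"])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(4, size=n)])


def simulate_locus_sequences(
    rng: np.random.Generator | int = 0,
    ltr_length: int = 2877,
    ltr3_insertion: int = 2,
    internal_length: int = 4687,
    flank: int = 2000,
    tsd: str = "CATGA",
) -> dict[str, str]:
    """Locus-region sequences around an LTR-retrotransposon insertion.

    Builds a Ty3/Gypsy-style element — a 5' LTR, an internal (polyprotein)
    region, and a 3' LTR that is the 5' LTR with a small insertion — to
    the structure reported for the Tf2-like element at the mapped locus
    (2877 + 4687 + 2879 bp by default). Returns a dict of sequences:

    - ``element``: the element alone;
    - ``insertion_region``: flanks + target-site duplication + element
      (the white-parent allele);
    - ``empty_region``: the same flanks with the target site present once
      and no duplication (the never-inserted brown-parent allele);
    - ``excised_tsd_region``: clean excision that left the TSD behind;
    - ``solo_ltr_region``: intra-element recombination left one LTR.

    The empty region is constructed so that no spurious 4–6 bp
    duplication straddles the insertion point.
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    ltr5 = _random_seq(rng, ltr_length)
    ins_at = ltr_length // 2
    ltr3 = ltr5[:ins_at] + _random_seq(rng, ltr3_insertion) + ltr5[ins_at:]
    internal = _random_seq(rng, internal_length)
    element = ltr5 + internal + ltr3
    left = _random_seq(rng, flank)
    right = _random_seq(rng, flank)
    # insertion point sits immediately after the (single) target site;
    # rebuild the right flank until no chance 4-6 bp duplication straddles it
    while any(
        (left + tsd)[-k:] == right[:k] for k in range(4, min(7, len(tsd) + 2))
    ):
        right = _random_seq(rng, flank)
    return {
        "element": element,
        "insertion_region": left + tsd + element + tsd + right,
        "empty_region": left + tsd + right,
        "excised_tsd_region": left + tsd + tsd + right,
        "solo_ltr_region": left + tsd + ltr3 + tsd + right,
    }
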