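"""Synthetic inputs with the statistical structure the analysis assumes.

The community generator plants what the downstream stages are built to
find: configuration blocks that shift community composition, guild
modules (syntroph + hydrogenotrophic-methanogen ASVs co-varying on the
latent log scale), compositional multinomial count noise at a realistic
sequencing depth, and physicochemical series tied linearly to the
process configuration.  Companion generators emit MAG records whose 16S
genes contain an ASV's V4 region at a controlled mismatch distance
(flanked by the 515F/806R primer sites), and matched metagenome /
metatranscriptome gene-count tables with a tunable MAG-level coupling.

Every generator takes an explicit seed; identical seeds give identical
outputs, byte for byte once written.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    AbundanceTable,
    ExpressionTable,
    Gene,
    MagRecord,
    ParameterSeries,
    TaxonomyTable,
    ValidationError,
)
from .linking import FWD_PRIMER, IUPAC, REV_PRIMER, reverse_complement

__all__ = [
    "GuildModule",
    "SimulationScenario",
    "GroundTruth",
    "default_scenario",
    "simulate_timeseries",
    "simulate_asv_sequences",
    "simulate_mag_fixtures",
    "simulate_expression",
]

LN2 = float(np.log(2.0))

# family names used for module members; non-members get neutral digester taxa
_GUILD_FAMILIES = {
    "hydrogenotrophic_methanogen": (
        ("Archaea", "Halobacterota", "Methanomicrobia", "Methanomicrobiales",
         "Methanoregulaceae"),
        ("Archaea", "Halobacterota", "Methanomicrobia", "Methanomicrobiales",
         "Methanospirillaceae"),
        ("Archaea", "Euryarchaeota", "Methanobacteria", "Methanobacteriales",
         "Methanobacteriaceae"),
        ("Archaea", "Halobacterota", "Methanomicrobia", "Methanomicrobiales",
         "Methanomicrobiaceae"),
    ),
    "acetoclastic_methanogen": (
        ("Archaea", "Halobacterota", "Methanosarcinia", "Methanotrichales",
         "Methanosaetaceae"),
    ),
    "syntroph": (
        ("Bacteria", "Desulfobacterota", "Syntrophia", "Syntrophales",
         "Syntrophaceae"),
        ("Bacteria", "Desulfobacterota", "Syntrophorhabdia",
         "Syntrophorhabdales", "Syntrophorhabdaceae"),
        ("Bacteria", "Firmicutes", "Clostridia", "Eubacteriales",
         "Syntrophomonadaceae"),
        ("Bacteria", "Synergistota", "Synergistia", "Synergistales",
         "Synergistaceae"),
    ),
}
_NEUTRAL_FAMILIES = (
    ("Bacteria", "Cloacimonadota", "Cloacimonadia", "Cloacimonadales",
     "Cloacimonadaceae"),
    ("Bacteria", "Bacteroidota", "Bacteroidia", "Bacteroidales", "Rikenellaceae"),
    ("Bacteria", "Chloroflexota", "Anaerolineae", "Anaerolineales",
     "Anaerolineaceae"),
    ("Bacteria", "Spirochaetota", "Spirochaetia", "Spirochaetales",
     "Spirochaetaceae"),
    ("Bacteria", "Bacteroidota", "Bacteroidia", "Bacteroidales",
     "Lentimicrobiaceae"),
    ("Bacteria", "Firmicutes", "Clostridia", "Oscillospirales", "Ruminococcaceae"),
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Burkholderiales",
     "Burkholderiaceae"),
    ("Bacteria", "Verrucomicrobiota", "Verrucomicrobiae", "Pedosphaerales",
     "Pedosphaeraceae"),
)


@dataclass
class GuildModule:
    """A planted block of co-varying ASVs.

    ``members`` index into the ASV axis; ``guilds`` gives one guild label
    per member; ``rho`` is the latent intra-module correlation;
    ``shifted_configuration`` (or None) names the configuration in which
    the whole module's log-mean rises by ``log2_fold_change`` log2 units.
    """

    members: tuple[int, ...]
    guilds: tuple[str, ...]
    rho: float = 0.9
    shifted_configuration: str | None = None
    log2_fold_change: float = 4.0

    def __post_init__(self):
        if len(self.members) != len(self.guilds):
            raise ValidationError("one guild label per module member required")
        if not 0.0 <= self.rho < 1.0:
            raise ValidationError("rho must lie in [0, 1)")


@dataclass
class SimulationScenario:
    """Desk-scale mirror of a two-year digester amplicon series.

    Defaults: 40 biweekly samples in four configuration blocks
    (15 / 10 / 9 / 6 samples for SOI / CEPT / SOII / SER, proportional to
    the study's sampling), 300 ASVs at depth 20,000 reads per sample, and
    five 3-member guild modules (one hydrogenotrophic methanogen + two
    syntrophs each) at latent correlation 0.9, four of them up-shifted by
    4 log2 units (16-fold, conditionally-rare-taxon dynamics) in one
    configuration apiece.
    """

    n_samples: int = 40
    n_asvs: int = 300
    configuration_blocks: tuple[tuple[str, int, int], ...] = (
        ("SOI", 0, 15), ("CEPT", 15, 25), ("SOII", 25, 34), ("SER", 34, 40),
    )
    guild_modules: tuple[GuildModule, ...] = ()
    baseline_log_mean_spread: float = 1.5
    baseline_log_sd: float = 0.6
    # module members model network-resident guild populations, which sit
    # around 0.1-1 % relative abundance; their baseline log-means are drawn
    # at this moderate level instead of from the heavy-tailed global spread
    module_log_mean: float = 1.0
    module_log_mean_sd: float = 0.5
    depth: int = 20_000
    n_parameters: int = 28
    n_coupled_parameters: int = 8
    start_date: _dt.date = _dt.date(2016, 10, 13)
    sampling_interval_days: int = 14
    seed: int = 0

    def __post_init__(self):
        edges = sorted((a, b) for _, a, b in self.configuration_blocks)
        covered = []
        for a, b in edges:
            covered.extend(range(a, b))
        if covered != list(range(self.n_samples)):
            raise ValidationError("configuration blocks must partition the samples")
        taken: set[int] = set()
        for mod in self.guild_modules:
            if taken & set(mod.members):
                raise ValidationError("module members must be disjoint")
            taken |= set(mod.members)

    def configuration_labels(self) -> np.ndarray:
        labels = np.empty(self.n_samples, dtype=object)
        for name, a, b in self.configuration_blocks:
            labels[a:b] = name
        return labels


def default_scenario(
    seed: int = 0, n_samples: int = 40, n_asvs: int = 300
) -> SimulationScenario:
    """The default five-module scenario (see :class:`SimulationScenario`).

    ``n_samples`` rescales the four configuration blocks proportionally;
    ``n_asvs`` must leave room for the 15 module members.
    """
    if n_asvs < 16:
        raise ValidationError("need at least 16 ASVs for the default modules")
    if n_samples < 8:
        raise ValidationError("need at least 8 samples for four blocks")
    configs = ("SOI", "CEPT", "SOII", "SER", None)
    modules = []
    for k in range(5):
        base = k * 3
        modules.append(
            GuildModule(
                members=(base, base + 1, base + 2),
                guilds=("hydrogenotrophic_methanogen", "syntroph", "syntroph"),
                rho=0.9,
                shifted_configuration=configs[k],
                log2_fold_change=4.0,
            )
        )
    # rescale the 15/10/9/6 block layout to the requested sample count
    fractions = (15, 10, 9, 6)
    edges = np.round(np.cumsum((0,) + fractions) / 40 * n_samples).astype(int)
    edges[-1] = n_samples
    blocks = tuple(
        (name, int(edges[i]), int(edges[i + 1]))
        for i, name in enumerate(("SOI", "CEPT", "SOII", "SER"))
    )
    return SimulationScenario(
        n_samples=n_samples, n_asvs=n_asvs, configuration_blocks=blocks,
        guild_modules=tuple(modules), seed=seed,
    )


@dataclass
class GroundTruth:
    """What the generator planted, keyed by ASV id."""

    planted_edges: list[tuple[str, str]] = field(default_factory=list)
    planted_indicators: list[tuple[str, str]] = field(default_factory=list)
    guild_labels: dict[str, str] = field(default_factory=dict)


def _asv_id(i: int) -> str:
    return f"ASV{i:04d}"


def _build_taxonomy(scenario: SimulationScenario, rng: np.random.Generator) -> TaxonomyTable:
    rows = {}
    module_guild = {}
    for mod in scenario.guild_modules:
        for idx, guild in zip(mod.members, mod.guilds):
            module_guild[idx] = guild
    counters: dict[str, int] = {}
    for i in range(scenario.n_asvs):
        guild = module_guild.get(i)
        if guild is not None:
            options = _GUILD_FAMILIES[guild]
            k = counters.get(guild, 0)
            lineage = options[k % len(options)]
            counters[guild] = k + 1
        else:
            lineage = _NEUTRAL_FAMILIES[int(rng.integers(len(_NEUTRAL_FAMILIES)))]
        rows[_asv_id(i)] = dict(zip(
            ("domain", "phylum", "class", "order", "family"), lineage
        ))
    return TaxonomyTable(pd.DataFrame.from_dict(rows, orient="index"))


def simulate_timeseries(scenario: SimulationScenario):
    """Generate (AbundanceTable, TaxonomyTable, ParameterSeries, GroundTruth).

    Latent per-sample log-abundances are multivariate normal with the
    block correlation structure of the guild modules; configuration
    effects enter as log-mean shifts; counts are a single multinomial
    draw per sample at the configured depth (column sums equal the depth
    exactly).  Physicochemical parameters are configuration means plus
    Gaussian noise, measured weekly across the sampled interval.
    """
    rng = np.random.default_rng(scenario.seed)
    n, p = scenario.n_samples, scenario.n_asvs
    if scenario.depth < p:
        warnings.warn(
            f"depth {scenario.depth} < {p} ASVs: expected nonzero count < 1 "
            "per ASV", stacklevel=2,
        )

    # correlation structure
    corr = np.eye(p)
    for mod in scenario.guild_modules:
        for a in mod.members:
            for b in mod.members:
                if a != b:
                    corr[a, b] = mod.rho
    sd = np.full(p, scenario.baseline_log_sd)
    cov = corr * np.outer(sd, sd)
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(p))

    mu = rng.normal(0.0, scenario.baseline_log_mean_spread, size=p)
    for mod in scenario.guild_modules:
        for idx in mod.members:
            mu[idx] = rng.normal(scenario.module_log_mean,
                                 scenario.module_log_mean_sd)
    labels = scenario.configuration_labels()
    shift = np.zeros((p, n))
    for mod in scenario.guild_modules:
        if mod.shifted_configuration is None:
            continue
        mask = labels == mod.shifted_configuration
        for idx in mod.members:
            shift[idx, mask] += mod.log2_fold_change * LN2

    eps = rng.standard_normal((p, n))
    latent = mu[:, None] + shift + chol @ eps
    rel = np.exp(latent)
    rel /= rel.sum(axis=0, keepdims=True)
    counts = np.column_stack(
        [rng.multinomial(scenario.depth, rel[:, j]) for j in range(n)]
    )

    sample_ids = [f"S{j:03d}" for j in range(n)]
    dates = [scenario.start_date + _dt.timedelta(days=scenario.sampling_interval_days * j)
             for j in range(n)]
    table = AbundanceTable(
        pd.DataFrame(counts, index=[_asv_id(i) for i in range(p)], columns=sample_ids),
        pd.Series(dates, index=sample_ids),
        pd.Series(labels, index=sample_ids),
    )
    taxonomy = _build_taxonomy(scenario, rng)

    # physicochemical series: weekly measurements, configuration means + noise
    meas_interval = max(scenario.sampling_interval_days // 2, 1)
    span = scenario.sampling_interval_days * (n - 1)
    meas_dates = [scenario.start_date + _dt.timedelta(days=d)
                  for d in range(0, span + 1, meas_interval)]
    config_names = [c for c, _, _ in scenario.configuration_blocks]

    def config_of(date: _dt.date) -> str:
        j = min((date - scenario.start_date).days // scenario.sampling_interval_days,
                n - 1)
        return labels[j]

    values = {}
    for q in range(scenario.n_parameters):
        name = f"param_{q + 1:02d}"
        if q < scenario.n_coupled_parameters:
            means = {c: rng.normal(0.0, 2.0) for c in config_names}
            noise_sd = 0.5
        else:
            means = {c: 0.0 for c in config_names}
            noise_sd = 1.0
        values[name] = [
            means[config_of(d)] + rng.normal(0.0, noise_sd) for d in meas_dates
        ]
    params = ParameterSeries(pd.DataFrame(values, index=meas_dates))

    truth = GroundTruth()
    for mod in scenario.guild_modules:
        ids = [_asv_id(i) for i in mod.members]
        if mod.rho > 0:
            truth.planted_edges.extend(
                (ids[a], ids[b])
                for a in range(len(ids)) for b in range(a + 1, len(ids))
            )
        if mod.shifted_configuration is not None:
            truth.planted_indicators.extend(
                (asv, mod.shifted_configuration) for asv in ids
            )
        truth.guild_labels.update(dict(zip(ids, mod.guilds)))
    return table, taxonomy, params, truth


# -- sequences and MAGs --------------------------------------------------


def _concretize(primer: str, rng: np.random.Generator) -> str:
    return "".join(c if len(IUPAC[c]) == 1 else IUPAC[c][int(rng.integers(len(IUPAC[c])))]
                   for c in primer)


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def simulate_asv_sequences(n_asvs: int, length: int = 253, seed: int = 0) -> dict[str, str]:
    """Random V4-length representative sequences, one per ASV id."""
    rng = np.random.default_rng(seed)
    return {_asv_id(i): _random_seq(length, rng) for i in range(n_asvs)}


def _mutate(seq: str, n_mismatches: int, rng: np.random.Generator) -> str:
    if n_mismatches > len(seq):
        raise ValidationError("more mismatches requested than positions")
    positions = rng.choice(len(seq), size=n_mismatches, replace=False)
    out = list(seq)
    for pos in positions:
        out[pos] = rng.choice([b for b in "ACGT" if b != out[pos]])
    return "".join(out)


def simulate_mag_fixtures(
    asv_sequences: dict[str, str],
    pairs: list[tuple[str, int]],
    taxonomy: TaxonomyTable | dict[str, list[str]] | None = None,
    seed: int = 0,
    completeness_range: tuple[float, float] = (91.0, 99.5),
    contamination_range: tuple[float, float] = (0.0, 4.5),
    flank_length: int = 150,
) -> list[MagRecord]:
    """One MAG per (asv_id, n_mismatches) pair.

    Each MAG's 16S is ``flank + 515F-site + mutated V4 + rc(806R-site) +
    flank``: the primer sites are concrete realizations of the degenerate
    primers and mutations land only inside the V4 region, so the primer
    sites can never be disrupted and ``extract_v4`` recovers a region at
    exactly ``n_mismatches`` Hamming distance from the ASV.  Gene content
    follows the MAG's guild (methanogenesis markers for hydrogenotrophic
    methanogens, etc.); quality metrics are drawn from the given ranges.
    """
    from .linking import assign_guilds

    rng = np.random.default_rng(seed)
    guilds = assign_guilds(taxonomy) if taxonomy is not None else {}
    mags = []
    for k, (asv_id, n_mm) in enumerate(pairs):
        v4 = _mutate(asv_sequences[asv_id].upper(), n_mm, rng)
        ssu = (
            _random_seq(flank_length, rng)
            + _concretize(FWD_PRIMER, rng)
            + v4
            + reverse_complement(_concretize(REV_PRIMER, rng))
            + _random_seq(flank_length, rng)
        )
        guild = guilds.get(asv_id, "other")
        genes = [Gene(f"MAG{k:03d}_g{i}", int(rng.integers(300, 3000)), ("housekeeping",))
                 for i in range(5)]
        if guild == "hydrogenotrophic_methanogen":
            for sym in MARKERS_HYDROGENOTROPHIC:
                genes.append(Gene(f"MAG{k:03d}_{sym}", int(rng.integers(600, 2400)),
                                  (sym,)))
        elif guild == "acetoclastic_methanogen":
            for sym in ("ack", "pta", "mcrA", "mcrB", "mcrG"):
                genes.append(Gene(f"MAG{k:03d}_{sym}", int(rng.integers(600, 2400)),
                                  (sym,)))
        elif guild == "syntroph":
            for sym in ("fdh", "fhs", "fol", "met", "gcvH", "gcvP", "gcvT"):
                genes.append(Gene(f"MAG{k:03d}_{sym}", int(rng.integers(600, 2400)),
                                  (sym,)))
        lineage = []
        if taxonomy is not None:
            if hasattr(taxonomy, "lineage"):
                lineage = taxonomy.lineage(asv_id)
            else:
                lineage = list(taxonomy.get(asv_id, []))
        mags.append(
            MagRecord(
                mag_id=f"MAG{k:03d}",
                taxonomy=lineage,
                completeness=float(rng.uniform(*completeness_range)),
                contamination=float(rng.uniform(*contamination_range)),
                rrna_counts={"5S": 1, "16S": 1, "23S": 1},
                ssu_sequences=[ssu],
                genes=genes,
            )
        )
    return mags


MARKERS_HYDROGENOTROPHIC = (
    "mcrA", "mcrB", "mcrC", "mcrD", "mcrG",
    "mtrA", "mtrB", "mtrC", "mtrD", "mtrE", "mtrF", "mtrH",
)


def simulate_expression(
    mags: list[MagRecord],
    n_samples: int,
    coupling: float,
    seed: int = 0,
    methanogen_mags: set[str] | None = None,
    methanogen_inflation: float = 3.0,
) -> tuple[ExpressionTable, ExpressionTable]:
    """Matched metagenome / metatranscriptome gene-count tables.

    Per MAG and sample, the metagenome latent log-abundance is standard
    normal; the metatranscriptome latent is
    ``coupling * mg + sqrt(1 - coupling^2) * noise`` so that ``coupling``
    is itself the latent MG-MT correlation (1 -> identical, 0 ->
    independent).  MAGs named in ``methanogen_mags`` are decoupled: their
    transcriptome latent is independent noise plus ``methanogen_inflation``
    log units, mimicking lineages that are rare in metagenomes but heavily
    transcribing.  Gene counts are expected counts (library size x
    length-weighted share), so TPM aggregation recovers the latent
    abundances without sampling noise.
    """
    if not 0.0 <= coupling <= 1.0:
        raise ValidationError("coupling must lie in [0, 1]")
    for mag in mags:
        if not mag.genes:
            raise ValidationError(f"MAG {mag.mag_id!r} has no genes")
    rng = np.random.default_rng(seed)
    methanogen_mags = methanogen_mags or set()
    samples = [f"T{j:02d}" for j in range(n_samples)]

    gene_rows, mg_counts, mt_counts = [], [], []
    mg_latent = {m.mag_id: rng.standard_normal(n_samples) for m in mags}
    lib_size = 1e6
    mag_mt = {}
    for mag in mags:
        g = mg_latent[mag.mag_id]
        if mag.mag_id in methanogen_mags:
            mt = rng.standard_normal(n_samples) + methanogen_inflation
        else:
            mt = coupling * g + np.sqrt(1.0 - coupling**2) * rng.standard_normal(n_samples)
        mag_mt[mag.mag_id] = mt

    for mag in mags:
        gene_effects = rng.normal(0.0, 0.25, size=len(mag.genes))
        for gene, eff in zip(mag.genes, gene_effects):
            gene_rows.append({"gene_id": gene.gene_id, "mag_id": mag.mag_id,
                              "length": gene.length})
            mg_counts.append(np.exp(mg_latent[mag.mag_id] + eff) * gene.length)
            mt_counts.append(np.exp(mag_mt[mag.mag_id] + eff) * gene.length)

    info = pd.DataFrame(gene_rows).set_index("gene_id")

    def _table(raw: list[np.ndarray]) -> ExpressionTable:
        m = np.vstack(raw)
        m = m / m.sum(axis=0, keepdims=True) * lib_size
        return ExpressionTable(info, pd.DataFrame(m, index=info.index, columns=samples))

    return _table(mg_counts), _table(mt_counts)
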