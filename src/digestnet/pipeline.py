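"""End-to-end orchestration: simulate or load inputs, then run the
stages in dependency order with explicit seeds and a provenance record.

Stage order: prep -> community -> network -> indicators -> link ->
expression -> subnets -> enrich.  Each stage writes its outputs under the
configured output directory and later stages read them back, so any
completed prefix of the pipeline can be resumed or re-run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .community import (
    bray_curtis,
    core_microbiome,
    dendrogram_newick,
    filter_low_abundance,
    hierarchical_cluster,
    pcoa,
    permanova,
    relative_abundance,
)
from .datatypes import ValidationError
from .indicators import indicator_test
from .linking import (
    aggregate_mag_expression,
    assign_guilds,
    mg_mt_correlation,
    pair_asv_mag,
)
from .metadata import bioenv_best_subset, interpolate_parameters
from .network import NetworkConfig, avg_clustering_coefficient, build_network
from .simulate import (
    SimulationScenario,
    default_scenario,
    simulate_asv_sequences,
    simulate_expression,
    simulate_mag_fixtures,
    simulate_timeseries,
)
from .subnetworks import extract_subnetworks, guild_enrichment

__all__ = ["PipelineConfig", "run_pipeline", "simulate_command", "STAGES"]

STAGES = ("prep", "community", "network", "indicators", "link", "expression",
          "subnets", "enrich")

_DEPENDS = {
    "prep": (),
    "community": ("prep",),
    "network": ("prep",),
    "indicators": ("prep",),
    "link": ("network",),
    "expression": ("link",),
    "subnets": ("link",),
    "enrich": ("subnets",),
}


class DependencyError(ValidationError):
    pass


@dataclass
class PipelineConfig:
    """One structured file drives the whole run; every stochastic stage
    carries its own seed."""

    output_dir: str = "digestnet_out"
    inputs: dict = field(default_factory=dict)  # abundance/metadata/taxonomy/...
    stages: tuple[str, ...] = STAGES
    filter_min_mean: float = 1.0
    prevalence_threshold: float = 0.25
    edge_method: str = "bicor_fdr"
    fdr_alpha: float = 0.05
    positive_edges_only: bool = True
    network_seed: int = 1
    permanova_n_perm: int = 999
    permanova_seed: int = 1
    bioenv_max_size: int = 2
    indicator_n_perm: int = 999
    indicator_seed: int = 1
    indicator_alpha: float = 0.05
    min_identity: float = 0.995
    enrichment_n_perm: int = 10_000
    enrichment_seed: int = 1
    enrichment_mode: str = "at_least"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


def _require(outdir: Path, stage: str, *files: str) -> None:
    missing = [f for f in files if not (outdir / f).exists()]
    if missing:
        raise DependencyError(
            f"stage {stage!r} needs outputs {missing} from an earlier stage; "
            "run its dependencies first"
        )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the run report (also written
    as ``run_report.json``)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config_hash": config.digest(),
        "config": config.to_dict(),
        "stages_run": [],
        "warnings": [],
        "results": {},
    }
    for stage in config.stages:
        if stage not in STAGES:
            raise ValidationError(f"unknown stage {stage!r}")
        for dep in _DEPENDS[stage]:
            if dep not in config.stages:
                _require(outdir, stage, *_STAGE_OUTPUTS[dep])
        _STAGE_FUNCS[stage](config, outdir, report)
        report["stages_run"].append(stage)
    from importlib.metadata import PackageNotFoundError, version

    try:
        report["version"] = version("digestnet")
    except PackageNotFoundError:
        report["version"] = "unknown"
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report


def _load_table(config: PipelineConfig, outdir: Path, filtered: bool = True):
    if filtered:
        return dio.read_abundance_table(
            outdir / "abundance_filtered.tsv", outdir / "metadata.tsv"
        )
    return dio.read_abundance_table(
        config.inputs["abundance"], config.inputs["metadata"]
    )


def _stage_prep(config: PipelineConfig, outdir: Path, report: dict) -> None:
    table = _load_table(config, outdir, filtered=False)
    table = filter_low_abundance(table, config.filter_min_mean)
    dio.write_abundance_table(
        table, outdir / "abundance_filtered.tsv", outdir / "metadata.tsv"
    )
    params = dio.read_parameter_series(config.inputs["parameters"])
    interp = interpolate_parameters(params, list(table.sample_dates))
    interp.to_frame().to_csv(outdir / "parameters_interpolated.tsv", sep="\t",
                             index=False)
    report["results"]["n_asvs_after_filter"] = len(table.asv_ids)
    for date, param in interp.suspect:
        report["warnings"].append(
            f"interpolated {param} at {date} strays beyond 1.5x measured range"
        )


def _stage_community(config: PipelineConfig, outdir: Path, report: dict) -> None:
    _require(outdir, "community", "abundance_filtered.tsv", "metadata.tsv")
    table = _load_table(config, outdir)
    rel = relative_abundance(table.counts)
    dist = bray_curtis(rel)
    pd.DataFrame(dist.matrix, index=dist.ids, columns=dist.ids).to_csv(
        outdir / "bray_curtis.tsv", sep="\t"
    )
    linkage = hierarchical_cluster(dist)
    (outdir / "dendrogram.nwk").write_text(dendrogram_newick(linkage, dist.ids))
    # paired physicochemical dendrogram (for side-by-side comparison with
    # the community one); parameters are range-standardized to [0, 1] so
    # Bray-Curtis stays defined on non-negative values
    interp_frame = pd.read_csv(outdir / "parameters_interpolated.tsv", sep="\t")
    wide_all = interp_frame.pivot(index="date", columns="parameter",
                                  values="value")
    wide_all = wide_all.loc[[d.isoformat() for d in table.sample_dates]]
    wide_all.index = table.sample_ids
    span = wide_all.max() - wide_all.min()
    ranged = ((wide_all - wide_all.min()) / span.replace(0, 1.0)).fillna(0.0)
    param_dist = bray_curtis(ranged.T)
    param_linkage = hierarchical_cluster(param_dist)
    (outdir / "dendrogram_parameters.nwk").write_text(
        dendrogram_newick(param_linkage, param_dist.ids)
    )
    ord_res = pcoa(dist)
    ord_res.coordinates.to_csv(outdir / "pcoa_coordinates.tsv", sep="\t")
    perm = permanova(dist, table.configuration, config.permanova_n_perm,
                     config.permanova_seed)
    core = core_microbiome(table)
    report["results"]["permanova"] = dataclasses.asdict(perm)
    report["results"]["core_size"] = len(core.members)
    report["results"]["core_read_fraction"] = core.read_fraction
    pd.Series(core.members, name="asv_id").to_csv(
        outdir / "core_microbiome.tsv", sep="\t", index=False
    )
    # environmental subset search on the interpolated parameters
    interp = pd.read_csv(outdir / "parameters_interpolated.tsv", sep="\t")
    wide = interp.pivot(index="date", columns="parameter", values="value")
    wide = wide.loc[[d.isoformat() for d in table.sample_dates]]
    wide.index = table.sample_ids
    constant = wide.columns[wide.std(ddof=1) == 0]
    bioenv = bioenv_best_subset(dist, wide.drop(columns=constant),
                                max_size=config.bioenv_max_size)
    bioenv.ranking.head(50).assign(
        subset=lambda df: df["subset"].map(lambda s: "+".join(s))
    ).to_csv(outdir / "bioenv_ranking.tsv", sep="\t", index=False)
    report["results"]["bioenv_best"] = {
        "subset": list(bioenv.best_subset), "rho": bioenv.rho,
        "rho_squared": bioenv.rho**2,
    }


def _stage_network(config: PipelineConfig, outdir: Path, report: dict) -> None:
    _require(outdir, "network", "abundance_filtered.tsv", "metadata.tsv")
    table = _load_table(config, outdir)
    cfg = NetworkConfig(
        prevalence_threshold=config.prevalence_threshold,
        edge_method=config.edge_method,
        fdr_alpha=config.fdr_alpha,
        positive_edges_only=config.positive_edges_only,
        seed=config.network_seed,
    )
    net = build_network(table, cfg)
    dio.write_network(net, outdir / "network_edges.tsv", "edge_tsv")
    dio.write_network(net, outdir / "network.graphml", "graphml")
    report["results"]["network_nodes"] = net.number_of_nodes()
    report["results"]["network_edges"] = net.number_of_edges()
    report["results"]["avg_clustering_coefficient"] = avg_clustering_coefficient(net)


def _stage_indicators(config: PipelineConfig, outdir: Path, report: dict) -> None:
    _require(outdir, "indicators", "abundance_filtered.tsv", "metadata.tsv")
    table = _load_table(config, outdir)
    results = indicator_test(
        table, n_perm=config.indicator_n_perm, seed=config.indicator_seed,
        alpha=config.indicator_alpha,
    )
    frame = pd.DataFrame([dataclasses.asdict(r) for r in results])
    frame.to_csv(outdir / "indicators.tsv", sep="\t", index=False)
    sig = frame[frame["q"] < config.indicator_alpha]
    report["results"]["n_indicators"] = int(len(sig))


def _annotated_network(outdir: Path, annotated: bool = True) -> nx.Graph:
    name = "network_annotated.graphml" if annotated else "network.graphml"
    net = dio.read_network(outdir / name, "graphml")
    # GraphML loses explicit None attributes; restore the schema defaults
    for _, data in net.nodes(data=True):
        for attr in ("guild", "indicator", "mag_id", "expression"):
            data.setdefault(attr, None)
    return net


def _stage_link(config: PipelineConfig, outdir: Path, report: dict) -> None:
    _require(outdir, "link", "network.graphml")
    net = _annotated_network(outdir, annotated=False)
    taxonomy = dio.read_taxonomy(config.inputs["taxonomy"])
    guilds = assign_guilds(taxonomy)
    for node in net.nodes:
        net.nodes[node]["guild"] = guilds.get(node, "other")
    if (outdir / "indicators.tsv").exists():
        ind = pd.read_csv(outdir / "indicators.tsv", sep="\t")
        sig = ind[ind["q"] < config.indicator_alpha]
        for row in sig.itertuples(index=False):
            if row.asv_id in net.nodes:
                net.nodes[row.asv_id]["indicator"] = row.group
    pairs = []
    if "asv_fasta" in config.inputs and "mag_dir" in config.inputs:
        asv_seqs = dio.read_fasta(config.inputs["asv_fasta"])
        mags = dio.read_mag_records(config.inputs["mag_dir"])
        asv_tax = {i: taxonomy.lineage(i) for i in taxonomy.ids}
        pairs = pair_asv_mag(asv_seqs, mags, config.min_identity, asv_tax)
        accepted = [p for p in pairs if p.accepted]
        for pair in accepted:
            if pair.asv_id in net.nodes:
                net.nodes[pair.asv_id]["mag_id"] = pair.mag_id
        pd.DataFrame([dataclasses.asdict(p) for p in pairs]).to_csv(
            outdir / "asv_mag_pairs.tsv", sep="\t", index=False
        )
        report["results"]["n_asv_mag_pairs_accepted"] = len(accepted)
    dio.write_network(net, outdir / "network_annotated.graphml", "graphml")


def _stage_expression(config: PipelineConfig, outdir: Path, report: dict) -> None:
    _require(outdir, "expression", "network_annotated.graphml")
    if "expression_mg" not in config.inputs:
        report["warnings"].append("no expression inputs; stage skipped")
        return
    net = _annotated_network(outdir)
    mags = dio.read_mag_records(config.inputs["mag_dir"])
    mg = dio.read_expression(config.inputs["expression_mg"])
    mt = dio.read_expression(config.inputs["expression_mt"])
    mg_mag = aggregate_mag_expression(mg, mags)
    mt_mag = aggregate_mag_expression(mt, mags)
    mt_mag.to_csv(outdir / "mag_expression_tpm.tsv", sep="\t")
    guild_by_mag = {}
    for node, data in net.nodes(data=True):
        if data.get("mag_id"):
            guild_by_mag[data["mag_id"]] = data.get("guild") or "other"
    methanogens = {m for m, g in guild_by_mag.items()
                   if g in ("hydrogenotrophic_methanogen", "acetoclastic_methanogen")}
    corr = mg_mt_correlation(mg_mag, mt_mag, exclude=methanogens)
    report["results"]["mg_mt_correlation"] = {
        "rho": corr.r, "t": corr.t, "df": corr.df, "p": corr.p,
        "excluded_methanogen_mags": len(methanogens),
    }
    mean_mt = mt_mag.mean(axis=1)
    for node, data in net.nodes(data=True):
        if data.get("mag_id") in mean_mt.index:
            data["expression"] = float(mean_mt[data["mag_id"]])
    dio.write_network(net, outdir / "network_annotated.graphml", "graphml")


def _stage_subnets(config: PipelineConfig, outdir: Path, report: dict) -> None:
    _require(outdir, "subnets", "network_annotated.graphml")
    net = _annotated_network(outdir)
    subs = extract_subnetworks(net)
    rows = [
        {"subnetwork": s.id, "size": s.size,
         "n_syntrophs": s.n_syntrophs, "n_methanogens": s.n_methanogens,
         "seeds": ",".join(sorted(map(str, s.seeds))),
         "members": ",".join(sorted(map(str, s.nodes)))}
        for s in subs
    ]
    pd.DataFrame(rows).to_csv(outdir / "subnetworks.tsv", sep="\t", index=False)
    report["results"]["n_subnetworks"] = len(subs)


def _stage_enrich(config: PipelineConfig, outdir: Path, report: dict) -> None:
    _require(outdir, "enrich", "subnetworks.tsv", "network_annotated.graphml")
    net = _annotated_network(outdir)
    subs = extract_subnetworks(net)
    rows = []
    for sub in subs:
        res = guild_enrichment(
            net, sub, n_perm=config.enrichment_n_perm,
            seed=config.enrichment_seed, mode=config.enrichment_mode,
        )
        rows.append(dataclasses.asdict(res))
    pd.DataFrame(rows).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    report["results"]["enrichment"] = rows


_STAGE_FUNCS = {
    "prep": _stage_prep,
    "community": _stage_community,
    "network": _stage_network,
    "indicators": _stage_indicators,
    "link": _stage_link,
    "expression": _stage_expression,
    "subnets": _stage_subnets,
    "enrich": _stage_enrich,
}

_STAGE_OUTPUTS = {
    "prep": ("abundance_filtered.tsv", "metadata.tsv",
             "parameters_interpolated.tsv"),
    "community": ("bray_curtis.tsv",),
    "network": ("network_edges.tsv", "network.graphml"),
    "indicators": ("indicators.tsv",),
    "link": ("network_annotated.graphml",),
    "expression": (),
    "subnets": ("subnetworks.tsv",),
    "enrich": ("enrichment.tsv",),
}


def simulate_command(
    directory,
    scenario: SimulationScenario | None = None,
    n_mags: int = 10,
    expression_samples: int = 6,
    expression_coupling: float = 0.6,
) -> dict:
    """Write a complete synthetic input bundle runnable by the pipeline.

    Emits abundance/metadata/taxonomy/parameter tables, ASV FASTA, MAG
    records (paired 0-1 mismatches to the first ``n_mags`` ASVs), matched
    expression tables, and the ground-truth record as JSON.  Returns the
    input-path mapping for :class:`PipelineConfig`.
    """
    scenario = scenario or default_scenario()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    table, taxonomy, params, truth = simulate_timeseries(scenario)
    dio.write_abundance_table(table, directory / "abundance.tsv",
                              directory / "metadata.tsv")
    dio.write_taxonomy(taxonomy, directory / "taxonomy.tsv")
    dio.write_parameter_series(params, directory / "parameters.tsv")
    seqs = simulate_asv_sequences(scenario.n_asvs, seed=scenario.seed + 1)
    dio.write_fasta(seqs, directory / "asv_sequences.fasta")
    rng = np.random.default_rng(scenario.seed + 2)
    module_asvs = sorted({a for mod in scenario.guild_modules
                          for a in (f"ASV{i:04d}" for i in mod.members)})
    others = [a for a in seqs if a not in module_asvs]
    chosen = module_asvs[:n_mags]
    if len(chosen) < n_mags:
        chosen += others[: n_mags - len(chosen)]
    pairs = [(a, int(rng.integers(0, 2))) for a in chosen]
    mags = simulate_mag_fixtures(seqs, pairs, taxonomy, seed=scenario.seed + 3)
    dio.write_mag_records(mags, directory / "mags")
    guilds = assign_guilds(taxonomy)
    methanogen_mags = {
        m.mag_id for m, (asv, _) in zip(mags, pairs)
        if guilds.get(asv, "other").endswith("methanogen")
    }
    mg, mt = simulate_expression(
        mags, expression_samples, expression_coupling,
        seed=scenario.seed + 4, methanogen_mags=methanogen_mags,
    )
    dio.write_expression(mg, directory / "expression_mg")
    dio.write_expression(mt, directory / "expression_mt")
    with open(directory / "ground_truth.json", "w") as fh:
        json.dump(
            {"planted_edges": truth.planted_edges,
             "planted_indicators": truth.planted_indicators,
             "guild_labels": truth.guild_labels},
            fh, indent=2,
        )
    return {
        "abundance": str(directory / "abundance.tsv"),
        "metadata": str(directory / "metadata.tsv"),
        "taxonomy": str(directory / "taxonomy.tsv"),
        "parameters": str(directory / "parameters.tsv"),
        "asv_fasta": str(directory / "asv_sequences.fasta"),
        "mag_dir": str(directory / "mags"),
        "expression_mg": str(directory / "expression_mg"),
        "expression_mt": str(directory / "expression_mt"),
    }
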