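"""End-to-end per-individual analysis: config in, report out.

The pipeline wires the stages together for a cohort of individuals:
variant/depth input -> genotype filters -> sex-scaffold classification ->
depth-matched heterozygosity (with the min-depth sweep) -> window and
scanning ROH callers -> length spectrum -> gene-set heterozygosity excess ->
exon-in-ROH permutation tests.  Every output is a TSV/BED/BEDGRAPH file
under the configured output directory, every stochastic step derives its
seed from the single config seed, and each filter logs input/output counts.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr
from . import heterozygosity as het_mod
from . import roh as roh_mod
from . import sexclass
from .simulate import (DepthModel, GeneSetSpec, ScaffoldDef,
                       SimulatedGenomeSpec, simulate_diploid_genome)
from .variant_io import (DepthTrack, FilterPolicy, build_callability,
                         filter_genotypes, mean_genome_depth, read_exon_bed,
                         read_scaffold_table, read_variants, write_exon_bed,
                         write_scaffold_table, write_vcf)

log = logging.getLogger("rohscape")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass(frozen=True)
class IndividualInput:
    name: str
    sex: str                     # "female" | "male"
    vcf: str
    depth: str


@dataclass
class RunConfig:
    """Declarative description of one cohort analysis.

    All tunables carry the defaults used throughout the package: variant
    quality >= 30, depth in [10, 2x mean], 40-kb scaffolds for calling and
    100-kb for ROH, 100-kb windows with a 0-heterozygote ROH rule, a
    50-site/1-het scanning window with 100-kb minimum runs, a 1-Mb
    long-ROH threshold and 1,000 permutations.
    """

    individuals: list[IndividualInput]
    scaffold_table: str
    exon_beds: dict = field(default_factory=dict)  # set -> path | {ind: path}
    filter_policy: FilterPolicy = field(default_factory=FilterPolicy)
    sex_policy: sexclass.SexClassPolicy = field(
        default_factory=sexclass.SexClassPolicy)
    window_size: int = 100_000
    max_het_per_window: int = 0
    snp_window: int = 50
    max_het_in_window: int = 1
    min_run_bp: int = 100_000
    long_threshold: int = 1_000_000
    n_permutations: int = 1000
    min_scaffold_len_calling: int = 40_000
    min_scaffold_len_roh: int = 100_000
    make_plots: bool = True
    seed: int = 0
    outdir: str = "rohscape_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = path.parent

        def rel(p):
            return str(base / p)

        individuals = [IndividualInput(d["name"], d["sex"], rel(d["vcf"]),
                                       rel(d["depth"]))
                       for d in raw["individuals"]]
        exon_beds = {}
        for gs, val in raw.get("gene_sets", {}).items():
            exon_beds[gs] = ({k: rel(v) for k, v in val.items()}
                             if isinstance(val, dict) else rel(val))
        kwargs = {}
        if "filter" in raw:
            kwargs["filter_policy"] = FilterPolicy(**raw["filter"])
        if "sex_policy" in raw:
            kwargs["sex_policy"] = sexclass.SexClassPolicy(**raw["sex_policy"])
        for key in ("window_size", "max_het_per_window", "snp_window",
                    "max_het_in_window", "min_run_bp", "long_threshold",
                    "n_permutations", "min_scaffold_len_calling",
                    "min_scaffold_len_roh", "seed", "make_plots"):
            if key in raw:
                kwargs[key] = raw[key]
        outdir = raw.get("outdir", "rohscape_out")
        return cls(individuals=individuals, scaffold_table=rel(raw["scaffold_table"]),
                   exon_beds=exon_beds, outdir=str(base / outdir), **kwargs)


def _child_seed(seed: int, *idx: int) -> int:
    ss = np.random.SeedSequence((seed,) + idx)
    return int(ss.generate_state(1)[0] % (2**31))


def _stage(name: str, individual: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(
                    f"stage {name!r} failed for {individual!r}: {exc}") from exc
            return False
    return _Ctx()


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Run the full analysis; returns (and writes) the per-individual report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scaffold_table = read_scaffold_table(config.scaffold_table)
    lengths = dict(zip(scaffold_table["scaffold"], scaffold_table["length"]))

    tracks: dict[str, DepthTrack] = {}
    summaries: dict[str, pd.DataFrame] = {}
    for ind in config.individuals:
        with _stage("depth_input", ind.name):
            tr = DepthTrack.from_bedgraph(ind.depth, lengths)
            tracks[ind.name] = tr
            s = tr.scaffold_mean_depth().reindex(lengths).fillna(0.0)
            summaries[ind.name] = pd.DataFrame(
                {"scaffold": list(lengths), "length": list(lengths.values()),
                 "mean_depth": s.to_numpy()})

    labels = _classify(config, scaffold_table, summaries)
    labels.to_csv(outdir / "scaffold_labels.tsv", sep="\t", index=False)
    auto_call, total_call = sexclass.autosomal_subset(
        labels, scaffold_table, config.min_scaffold_len_calling)
    auto_roh, total_roh = sexclass.autosomal_subset(
        labels, scaffold_table, config.min_scaffold_len_roh)
    log.info("autosomal scaffolds: %d (%.4g bp) for calling, %d (%.4g bp) for ROH",
             len(auto_call), total_call, len(auto_roh), total_roh)

    report_rows = []
    f_rows = []
    for i, ind in enumerate(config.individuals):
        row = {"individual": ind.name, "sex": ind.sex, "seed": config.seed}
        ind_dir = outdir / ind.name
        ind_dir.mkdir(exist_ok=True)

        with _stage("variants", ind.name):
            records = read_variants(ind.vcf)
            mean_depth = mean_genome_depth(tracks[ind.name])
            filtered = filter_genotypes(records, config.filter_policy,
                                        mean_depth)
            log.info("%s: %d records in, %d pass filters (mean depth %.1f)",
                     ind.name, len(records), len(filtered), mean_depth)
            callability = build_callability(tracks[ind.name],
                                            config.filter_policy, mean_depth,
                                            scaffold_table)
        row["mean_depth"] = mean_depth

        with _stage("heterozygosity", ind.name):
            call_auto = callability.restrict(auto_call["scaffold"])
            hets = het_mod.het_sites(filtered)
            hets_auto = hets[hets["scaffold"].isin(set(auto_call["scaffold"]))]
            rate = het_mod.genome_het_rate(hets_auto, call_auto)
            sweep = het_mod.depth_sweep(records, tracks[ind.name],
                                        config.filter_policy, mean_depth,
                                        auto_call)
            sweep.to_csv(ind_dir / "depth_sweep.tsv", sep="\t", index=False)
        row["n_het"] = rate.n_het_sites
        row["n_callable"] = rate.n_callable_sites
        row["het_rate_snps_per_mb"] = rate.rate_snps_per_mb

        with _stage("gene_set_het", ind.name):
            for gs_name in config.exon_beds:
                exons = _exons_for(config, gs_name, ind.name)
                exons = exons[exons["scaffold"].isin(set(auto_call["scaffold"]))]
                gs_rate, excess = het_mod.gene_set_het(
                    hets_auto, exons, call_auto,
                    reference_rate=rate.rate_snps_per_mb, name=gs_name)
                row[f"{gs_name}_rate"] = gs_rate.rate_snps_per_mb
                row[f"{gs_name}_excess"] = excess

        with _stage("roh", ind.name):
            call_roh = callability.restrict(auto_roh["scaffold"])
            hets_roh = hets[hets["scaffold"].isin(set(auto_roh["scaffold"]))]
            windows = het_mod.window_het_counts(hets_roh, auto_roh,
                                                config.window_size,
                                                callability=call_roh)
            labeling = roh_mod.window_roh(windows, config.max_het_per_window)
            runs = roh_mod.merge_runs(labeling)
            spec_w = roh_mod.length_spectrum(runs, total_roh,
                                             config.long_threshold)
            calls = filtered[filtered["scaffold"].isin(
                set(auto_roh["scaffold"]))]
            calls0 = pd.DataFrame({
                "scaffold": calls["scaffold"].to_numpy(),
                "pos": calls["pos"].to_numpy() - 1,
                "is_het": (calls["genotype_class"] == "het").to_numpy()})
            scan_runs = roh_mod.scan_roh(calls0, config.snp_window,
                                         config.max_het_in_window,
                                         config.min_run_bp)
            all_runs = pd.concat([runs, scan_runs], ignore_index=True)
            _write_runs_bed(all_runs, ind_dir / "roh_runs.bed")
            _write_window_rates(labeling, ind_dir / "window_het.bedgraph",
                                config.window_size)
        f_window = labeling.f_roh
        f_scan = float(scan_runs["length"].sum() / total_roh)
        row["f_roh_window"] = f_window
        row["f_roh_scan50"] = f_scan
        row["short_roh_fraction"] = spec_w.short_fraction
        row["long_roh_fraction"] = spec_w.long_fraction
        f_rows.append({"individual": ind.name, "window100k": f_window,
                       "scan50": f_scan})

        if config.exon_beds:
            with _stage("enrichment", ind.name):
                for j, gs_name in enumerate(sorted(config.exon_beds)):
                    exons = _exons_for(config, gs_name, ind.name)
                    assignment = enr.assign_exons(exons, labeling.windows)
                    res = enr.permute_labels_test(
                        assignment, labeling, n=config.n_permutations,
                        seed=_child_seed(config.seed, i, j))
                    row[f"{gs_name}_exon_roh_prop"] = res.observed_proportion
                    row[f"{gs_name}_expected_prop"] = res.expected_proportion
                    row[f"{gs_name}_p_deficiency"] = res.p_value
        else:
            log.warning("no exon annotations configured; enrichment skipped")

        if config.make_plots:
            with _stage("plots", ind.name):
                plot_het_track(labeling, ind_dir / "het_track.png",
                               title=ind.name)
        report_rows.append(row)

    report = pd.DataFrame(report_rows)
    report.to_csv(outdir / "report.tsv", sep="\t", index=False)
    f_est = pd.DataFrame(f_rows).set_index("individual")
    f_est.to_csv(outdir / "f_estimates.tsv", sep="\t")
    if len(f_est) >= 3:
        corr, means = roh_mod.compare_methods(f_est)
        corr.to_csv(outdir / "f_method_correlations.tsv", sep="\t")
        means.rename("mean_f").to_csv(outdir / "f_method_means.tsv", sep="\t")
    return report


def _classify(config, scaffold_table, summaries) -> pd.DataFrame:
    females = [i for i in config.individuals if i.sex == "female"]
    males = [i for i in config.individuals if i.sex == "male"]
    if len(females) == 1 and males:
        labels = sexclass.classify_scaffolds_multi(
            summaries[females[0].name],
            [summaries[m.name] for m in males], config.sex_policy)
        return labels
    log.warning("sex classification needs exactly one female and >=1 male; "
                "treating every scaffold as autosomal")
    out = scaffold_table.copy()
    out["ratio"] = np.nan
    out["label"] = "autosome"
    out["excluded"] = out["length"] <= config.sex_policy.min_scaffold_len
    return out


def _exons_for(config, gs_name, individual) -> pd.DataFrame:
    entry = config.exon_beds[gs_name]
    path = entry[individual] if isinstance(entry, dict) else entry
    return read_exon_bed(path, gene_set=gs_name)


def _write_runs_bed(runs: pd.DataFrame, path) -> None:
    out = runs[["scaffold", "start", "end", "method", "length"]]
    out.to_csv(path, sep="\t", header=False, index=False)


def _write_window_rates(labeling, path, window_size) -> None:
    w = labeling.windows
    rates = w["het_count"] * (1_000_000 / window_size)
    pd.DataFrame({"scaffold": w["scaffold"], "start": w["start"],
                  "end": w["end"], "rate": rates}
                 ).to_csv(path, sep="\t", header=False, index=False)


def plot_het_track(labeling, path, title: str = "",
                   min_scaffold_len: int = 2_000_000) -> None:
    """Per-scaffold window heterozygosity with ROH bars underneath."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    w = labeling.windows
    scafs = [s for s, g in w.groupby("scaffold")
             if g["end"].max() >= min_scaffold_len]
    if not scafs:
        scafs = list(dict.fromkeys(w["scaffold"]))[:1]
    fig, axes = plt.subplots(len(scafs), 1,
                             figsize=(10, 1.8 * len(scafs)), squeeze=False)
    window_size = int((w["end"] - w["start"]).iloc[0])
    for ax, scaf in zip(axes[:, 0], scafs):
        g = w[w["scaffold"] == scaf]
        mb = g["start"].to_numpy() / 1e6
        ax.plot(mb, g["het_count"] * (1e6 / window_size), lw=0.7,
                color="steelblue")
        roh = g[g["roh"]]
        ymin = -0.06 * max(1.0, g["het_count"].max() * (1e6 / window_size))
        ax.hlines([ymin] * len(roh), roh["start"] / 1e6, roh["end"] / 1e6,
                  color="black", lw=3)
        ax.set_ylabel(f"{scaf}\nSNPs/Mb", fontsize=7)
    axes[-1, 0].set_xlabel("position (Mb)")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


# ----------------------------------------------------------------------
# Demo cohort
# ----------------------------------------------------------------------

#: (name, theta SNPs/Mb, target F, sex) — six individuals spanning the
#: heterozygosity range 12-459 SNPs/Mb and inbreeding 0.11-0.70
DEMO_INDIVIDUALS = (
    ("ind1", 12.0, 0.70, "male"),
    ("ind2", 100.0, 0.45, "male"),
    ("ind3", 120.0, 0.50, "female"),
    ("ind4", 200.0, 0.40, "male"),
    ("ind5", 300.0, 0.30, "male"),
    ("ind6", 459.0, 0.11, "male"),
)

DEMO_SCAFFOLDS = (
    ScaffoldDef("sc1", 12_000_000), ScaffoldDef("sc2", 10_000_000),
    ScaffoldDef("sc3", 8_000_000), ScaffoldDef("sc4", 6_000_000),
    ScaffoldDef("sc5", 5_000_000), ScaffoldDef("sc6", 30_000),
    ScaffoldDef("scX", 6_000_000, "X"), ScaffoldDef("scY", 1_500_000, "Y"),
)

DEMO_GENE_SETS = (
    GeneSetSpec("mhc_like", n_genes=22, exons_per_gene=6, exon_len_bp=300,
                het_multiplier=12.0, n_clusters=1, roh_avoidance=True),
    GeneSetSpec("or_like", n_genes=48, exons_per_gene=4, exon_len_bp=150,
                het_multiplier=4.0, n_clusters=16, roh_avoidance=True),
)


def make_demo_dataset(outdir, seed: int = 0) -> Path:
    """Write a six-individual synthetic cohort and its run config.

    The cohort mirrors a strongly structured, partly inbred population: one
    near-monomorphic individual (12 SNPs/Mb, F=0.70), one diverse outbred
    one (459 SNPs/Mb, F=0.11), and a clustered MHC-like and OR-like gene
    family with heterozygosity excess and ROH avoidance.  Returns the path
    of the written YAML config; a truth table is written alongside.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lengths = {s.name: s.length for s in DEMO_SCAFFOLDS}
    write_scaffold_table(lengths, outdir / "scaffolds.tsv")
    cfg: dict = {"scaffold_table": "scaffolds.tsv", "seed": seed,
                 "outdir": "results", "individuals": [], "gene_sets": {}}
    gene_sets: dict[str, dict[str, str]] = {g.name: {} for g in DEMO_GENE_SETS}
    truth_rows = []
    for i, (name, theta, target_f, sex) in enumerate(DEMO_INDIVIDUALS):
        spec = SimulatedGenomeSpec(
            scaffolds=DEMO_SCAFFOLDS, theta=theta, target_f=target_f,
            gene_sets=DEMO_GENE_SETS, depth=DepthModel(30.0, resolution=1000),
            sex=sex, seed=_child_seed(seed, i))
        sim = simulate_diploid_genome(spec)
        write_vcf(sim.variants, lengths, outdir / f"{name}.vcf", sample=name)
        sim.depth_track.to_bedgraph(outdir / f"{name}.bedgraph")
        ind_dir = outdir / name
        ind_dir.mkdir(exist_ok=True)
        for gs in DEMO_GENE_SETS:
            sub = sim.exons[sim.exons["gene_set"] == gs.name]
            bed = f"{name}/exons_{gs.name}.bed"
            write_exon_bed(sub, outdir / bed)
            gene_sets[gs.name][name] = bed
        sim.truth.roh_intervals.to_csv(ind_dir / "truth_roh.tsv", sep="\t",
                                       index=False)
        truth_rows.append({"individual": name, "sex": sex, "theta": theta,
                           "target_f": target_f, "true_f": sim.truth.true_f})
        cfg["individuals"].append({"name": name, "sex": sex,
                                   "vcf": f"{name}.vcf",
                                   "depth": f"{name}.bedgraph"})
    cfg["gene_sets"] = gene_sets
    pd.DataFrame(truth_rows).to_csv(outdir / "truth_summary.tsv", sep="\t",
                                    index=False)
    cfg_path = outdir / "demo_config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return cfg_path
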