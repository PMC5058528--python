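"""Pipeline orchestration: simulate -> qc -> popgen -> ld -> scan -> seq ->
network -> ordination -> report.

Every stage reads its inputs from files written by earlier stages inside the
run directory, writes its outputs there, and records itself in
``checkpoint.json``; a failed run can resume from the last completed stage.
All stochastic stages draw their seeds deterministically from the single run
seed, so the same configuration and seed reproduce byte-identical report
tables.

Comparisons follow the inclusion rule used throughout: a location enters the
host-within-location comparisons only if at least five individuals were
sampled on each host there, and within-host among-location comparisons only
use locations with at least five individuals on that host.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import aflp_qc, dominant_popgen, ld_dominant, ordination, outlier_scan, seq_popgen
from .containers import (
    VALID_NUCLEOTIDES,
    MarkerMatrix,
    read_diploid_fasta,
    read_marker_tsv,
    write_haplotype_fasta,
    write_marker_tsv,
)
from .network_mj import annotate_root, build_mj_network, export_network
from .synthetic_data import SimConfig, simulate_dominant_markers, simulate_sequences, \
    write_fixture_set

STAGES = ("simulate", "qc", "popgen", "ld", "scan", "seqstats", "network",
          "ordinate", "report")


@dataclass
class RunConfig:
    """Run-level parameters; defaults reproduce the study's stated settings
    (5000 permutations, 30% trimmed mean, FDR 0.05) where they exist."""

    seed: int = 0
    outdir: str = "hostscan_out"
    sim: SimConfig | None = None
    markers_path: str | None = None
    sequences_path: str | None = None
    outgroup_path: str | None = None
    frame_offset: int = 0
    negative_control_sizes: tuple = ()
    ld_fdr_alpha: float = 0.05
    fdr_method: str = "bh"
    n_perm_fst: int = 5000
    n_perm_phist: int = 1000
    n_perm_adonis: int = 5000
    n_perm_envfit: int = 5000
    trim: float = 0.30
    envelope_loci: int = 50_000
    ld_pairs: str = "same_size_cross_primer"
    epsilon: int = 0
    nmds_restarts: int = 20
    phase_confidence: float = 0.9
    min_per_host: int = 5
    figures: bool = False

    def stage_seed(self, stage: str) -> int:
        return int(np.random.SeedSequence([self.seed, STAGES.index(stage)])
                   .generate_state(1)[0] % (2 ** 31))

    def to_json(self, path):
        d = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(d, indent=1, default=str))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        if d.get("sim") is not None:
            for key in ("hosts", "location_names", "host_snp_freqs",
                        "haplotype_pool_sizes", "size_range"):
                if d["sim"].get(key) is not None:
                    d["sim"][key] = tuple(d["sim"][key])
            d["sim"] = SimConfig(**d["sim"])
        if d.get("negative_control_sizes"):
            d["negative_control_sizes"] = tuple(d["negative_control_sizes"])
        return cls(**d)


class StageError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def validate_inputs(markers_path=None, sequences_path=None) -> list:
    """Schema diagnostics for input files; empty list means no problems."""
    problems = []
    matrix = aln = None
    if markers_path is not None:
        try:
            matrix = read_marker_tsv(markers_path)
        except Exception as exc:  # noqa: BLE001 - every schema error is reported
            problems.append(f"markers: {exc}")
    if sequences_path is not None:
        try:
            aln = read_diploid_fasta(sequences_path)
        except Exception as exc:  # noqa: BLE001
            problems.append(f"sequences: {exc}")
        else:
            for sid, seq in aln.sequences.items():
                bad = [(i + 1, ch) for i, ch in enumerate(seq)
                       if ch not in VALID_NUCLEOTIDES]
                for pos, ch in bad[:5]:
                    problems.append(
                        f"sequences: non-IUPAC character {ch!r} at position "
                        f"{pos} in {sid}")
    if matrix is not None and aln is not None:
        marker_ids = set(matrix.primary().calls.index)
        seq_ids = set(aln.sequences.index)
        only_seq = sorted(seq_ids - marker_ids)
        if only_seq and not marker_ids & seq_ids:
            problems.append(
                "cross-reference: no sample ids shared between the marker "
                f"matrix and the FASTA (e.g. {only_seq[:3]})")
    return problems


def _eligible_locations(metadata: pd.DataFrame, hosts, min_per_host: int) -> list:
    """Locations with at least ``min_per_host`` individuals on each host."""
    out = []
    for loc in sorted(metadata["location"].unique()):
        sub = metadata[metadata["location"] == loc]
        if all((sub["host"] == h).sum() >= min_per_host for h in hosts):
            out.append(loc)
    return out


def _workdir(config: RunConfig) -> Path:
    p = Path(config.outdir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _checkpoint(wd: Path) -> dict:
    cp = wd / "checkpoint.json"
    return json.loads(cp.read_text()) if cp.exists() else {"completed": []}


def _mark_done(wd: Path, stage: str):
    state = _checkpoint(wd)
    if stage not in state["completed"]:
        state["completed"].append(stage)
    (wd / "checkpoint.json").write_text(json.dumps(state, indent=1))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig) -> dict:
    wd = _workdir(config)
    if config.sim is None:
        if config.markers_path is None or config.sequences_path is None:
            raise ValueError("no simulation config and no input paths")
        return {"markers": config.markers_path, "sequences": config.sequences_path}
    matrix, truth_m = simulate_dominant_markers(config.sim)
    aln, truth_s = simulate_sequences(config.sim)
    truth_m.true_phases = truth_s.true_phases
    truth_m.haplotype_pools = truth_s.haplotype_pools
    truth_m.snp_positions = truth_s.snp_positions
    truth_m.diagnostic_position = truth_s.diagnostic_position
    truth_m.diag_freqs = truth_s.diag_freqs
    paths = write_fixture_set(matrix, aln, truth_m, wd / "fixtures")
    return {k: str(v) for k, v in paths.items()}


def _load_markers(config: RunConfig, wd: Path, filtered: bool = False) -> MarkerMatrix:
    if filtered:
        return read_marker_tsv(wd / "markers_filtered.tsv")
    if config.sim is not None:
        return read_marker_tsv(wd / "fixtures" / "markers.tsv")
    return read_marker_tsv(config.markers_path)


def _load_alignment(config: RunConfig, wd: Path):
    if config.sim is not None:
        path = wd / "fixtures" / "sequences.fasta"
        offset = config.sim.frame_offset
    else:
        path, offset = config.sequences_path, config.frame_offset
    return read_diploid_fasta(path, frame_offset=offset)


def stage_qc(config: RunConfig) -> dict:
    wd = _workdir(config)
    matrix = _load_markers(config, wd)
    filtered, report = aflp_qc.qc_report(matrix, config.negative_control_sizes,
                                         config.ld_fdr_alpha)
    write_marker_tsv(filtered, wd / "markers_filtered.tsv")
    aflp_qc.write_qc_log(filtered, wd / "qc_log.tsv")
    report.to_json(wd / "qc_report.json")
    return {"error_rate": report.error_rate,
            "n_loci_retained": filtered.n_loci,
            "size_freq_r": report.size_freq_r,
            "size_freq_p": report.size_freq_p}


def stage_popgen(config: RunConfig) -> dict:
    wd = _workdir(config)
    matrix = _load_markers(config, wd, filtered=True)
    meta = matrix.primary().metadata
    hosts = sorted(meta["host"].unique())
    seed = config.stage_seed("popgen")

    stats = dominant_popgen.locus_stats(matrix, "host")
    stats.to_csv(wd / "locus_stats.tsv", sep="\t")

    rows = []
    fst, _, p = dominant_popgen.fst_dominant(matrix, "host", config.n_perm_fst, seed)
    rows.append({"comparison": "host", "fst": fst, "p": p})
    eligible = _eligible_locations(meta, hosts, config.min_per_host)
    for loc in eligible:
        sub = _subset(matrix, meta["location"] == loc)
        fst, _, p = dominant_popgen.fst_dominant(sub, "host", config.n_perm_fst, seed)
        rows.append({"comparison": f"host_within_{loc}", "fst": fst, "p": p})
    for host in hosts:
        sub_meta = meta[meta["host"] == host]
        locs = [l for l in sorted(sub_meta["location"].unique())
                if (sub_meta["location"] == l).sum() >= config.min_per_host]
        if len(locs) >= 2:
            sub = _subset(matrix, (meta["host"] == host)
                          & meta["location"].isin(locs))
            fst, _, p = dominant_popgen.fst_dominant(sub, "location",
                                                     config.n_perm_fst, seed)
            rows.append({"comparison": f"locations_of_{host}", "fst": fst, "p": p})
    table = pd.DataFrame(rows)
    table.to_csv(wd / "fst_comparisons.tsv", sep="\t", index=False)
    return {"fst_host": float(table.iloc[0]["fst"]),
            "p_host": float(table.iloc[0]["p"]),
            "comparisons": table["comparison"].tolist()}


def _subset(matrix: MarkerMatrix, mask: pd.Series) -> MarkerMatrix:
    keep = matrix.primary()
    rows = keep.calls.index[mask.reindex(keep.calls.index).fillna(False)]
    return MarkerMatrix(keep.calls.loc[rows], keep.metadata.loc[rows],
                        keep.locus_info, list(keep.log))


def stage_ld(config: RunConfig) -> dict:
    wd = _workdir(config)
    matrix = _load_markers(config, wd, filtered=True)
    scan = ld_dominant.ld_scan(matrix, pairs=config.ld_pairs,
                               fdr_method=config.fdr_method)
    scan.to_csv(wd / "ld_scan.tsv", sep="\t", index=False)
    sig = scan[(scan["converged"]) & (scan["q"] <= config.ld_fdr_alpha)]
    return {"n_pairs": int(len(scan)), "n_significant": int(len(sig))}


def stage_scan(config: RunConfig) -> dict:
    wd = _workdir(config)
    matrix = _load_markers(config, wd, filtered=True)
    meta = matrix.primary().metadata
    hosts = sorted(meta["host"].unique())
    seed = config.stage_seed("scan")

    comparisons = {"combined": matrix}
    for loc in _eligible_locations(meta, hosts, config.min_per_host):
        comparisons[f"host_within_{loc}"] = _subset(matrix,
                                                    meta["location"] == loc)
    calls = []
    for idx, (name, sub) in enumerate(comparisons.items()):
        stats = dominant_popgen.locus_stats(sub, "host")
        tmean = dominant_popgen.trimmed_mean_fst(stats["fst"], config.trim)
        tmean = min(max(tmean, 0.005), 0.95)      # envelope needs (0, 1)
        sizes = sub.primary().metadata["host"].value_counts().reindex(hosts)
        env = outlier_scan.simulate_neutral_envelope(
            tmean, sizes.to_numpy(), n_sim_loci=config.envelope_loci,
            seed=seed + idx)
        env.to_tsv(wd / f"envelope_{name}.tsv")
        calls.append(outlier_scan.classify_outliers(stats, env, comparison=name))
    all_calls = pd.concat(calls, ignore_index=True)
    all_calls.to_csv(wd / "outlier_calls.tsv", sep="\t", index=False)
    counts = outlier_scan.nested_outlier_counts(all_calls)
    consensus = (sorted(outlier_scan.consensus_outliers(all_calls))
                 if all_calls["comparison"].nunique() >= 2 else [])
    (wd / "outlier_summary.json").write_text(json.dumps(
        {"counts": counts, "consensus": consensus}, indent=1))
    if config.figures:
        _plot_scan(wd, all_calls)
    return {"counts": counts, "n_consensus": len(consensus)}


def _plot_scan(wd: Path, calls: pd.DataFrame):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    sub = calls[calls["comparison"] == "combined"]
    env = pd.read_csv(wd / "envelope_combined.tsv", sep="\t")
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(sub["He"], sub["fst"], s=8,
               c=np.where(sub["level"] >= 95, "tab:red", "tab:gray"))
    mid = (env["he_lo"] + env["he_hi"]) / 2
    ax.plot(mid, env["q95"], "k--", label="95%")
    ax.plot(mid, env["q99"], "k-", label="99%")
    ax.set_xlabel("He")
    ax.set_ylabel("FST")
    ax.legend()
    fig.savefig(wd / "outlier_scan.svg")
    plt.close(fig)


def stage_seqstats(config: RunConfig) -> dict:
    wd = _workdir(config)
    aln = _load_alignment(config, wd)
    seed = config.stage_seed("seqstats")
    variants = seq_popgen.call_snps(aln)
    variants.to_csv(wd / "variants.tsv", sep="\t", index=False)
    haps = seq_popgen.em_phase(aln, seed=seed,
                               confidence_threshold=config.phase_confidence)
    write_haplotype_fasta(haps, wd / "haplotypes.fasta")
    summary = seq_popgen.haplotype_summary(haps, "host")
    summary.to_csv(wd / "seq_summary.tsv", sep="\t")

    hosts = sorted(aln.metadata["host"].unique())
    rows = []
    phi, p = seq_popgen.phi_st(haps, "host", config.n_perm_phist, seed)
    rows.append({"comparison": "host", "phi_st": phi, "p": p})
    phased_meta = aln.metadata.loc[list(haps.pairs)]
    for loc in _eligible_locations(phased_meta, hosts, config.min_per_host):
        sub_ids = phased_meta.index[phased_meta["location"] == loc]
        sub = _subset_haps(haps, sub_ids)
        phi, p = seq_popgen.phi_st(sub, "host", config.n_perm_phist, seed)
        rows.append({"comparison": f"host_within_{loc}", "phi_st": phi, "p": p})
    table = pd.DataFrame(rows)
    table.to_csv(wd / "phist_comparisons.tsv", sep="\t", index=False)

    majority = _majority_sequence(aln)
    effects = seq_popgen.annotate_codon_effect(variants, majority,
                                               aln.frame_offset)
    effects.to_csv(wd / "codon_effects.tsv", sep="\t", index=False)
    return {"n_snps": int(len(variants)),
            "n_phased": len(haps.pairs),
            "n_haplotypes": len(haps.haplotypes),
            "phi_st_host": float(table.iloc[0]["phi_st"]),
            "p_host": float(table.iloc[0]["p"])}


def _subset_haps(haps, ids):
    from .containers import HaplotypeSet
    pairs = {sid: haps.pairs[sid] for sid in ids if sid in haps.pairs}
    used = {h for pr in pairs.values() for h in pr}
    return HaplotypeSet({h: haps.haplotypes[h] for h in used}, pairs,
                        {sid: haps.confidence[sid] for sid in pairs},
                        haps.metadata.loc[list(ids)],
                        unphased=[s for s in haps.unphased if s in set(ids)])


def _majority_sequence(aln) -> str:
    cols = []
    seqs = list(aln.sequences)
    for i in range(aln.length):
        column = [s[i] for s in seqs if s[i] in "ACGT"]
        cols.append(pd.Series(column).mode().iloc[0] if column else "N")
    return "".join(cols)


def stage_network(config: RunConfig) -> dict:
    wd = _workdir(config)
    aln = _load_alignment(config, wd)
    haps = seq_popgen.em_phase(aln, seed=config.stage_seed("seqstats"),
                               confidence_threshold=config.phase_confidence)
    net = build_mj_network(haps, epsilon=config.epsilon)
    if config.outgroup_path:
        from Bio import SeqIO
        outgroups = [str(r.seq).upper()
                     for r in SeqIO.parse(str(config.outgroup_path), "fasta")]
        net = annotate_root(net, outgroups)
    export_network(net, wd / "network.graphml", "graphml")
    export_network(net, wd / "network.tsv", "tsv")
    n_medians = sum(1 for _, a in net.nodes(data=True) if a["is_median"])
    return {"n_nodes": net.number_of_nodes(), "n_edges": net.number_of_edges(),
            "n_medians": n_medians}


def stage_ordinate(config: RunConfig) -> dict:
    wd = _workdir(config)
    matrix = _load_markers(config, wd, filtered=True)
    meta = matrix.primary().metadata
    seed = config.stage_seed("ordinate")
    d = ordination.jaccard_matrix(matrix)
    ord_res = ordination.nmds(d, n_restarts=config.nmds_restarts, seed=seed)
    ord_res.scores.to_csv(wd / "nmds_scores.tsv", sep="\t")

    fits = {}
    for factor in ("host", "sex"):
        labels = meta[factor].replace("", np.nan).dropna()
        if labels.nunique() < 2:
            continue
        scores = ord_res.scores.loc[labels.index.intersection(ord_res.scores.index)]
        sub = dataclasses.replace(ord_res, scores=scores)
        r2, p = ordination.fit_factor(sub, labels, config.n_perm_envfit, seed)
        fits[factor] = {"r2": r2, "p": p}

    terms = ["location", "location:host"] if meta["location"].nunique() > 1 else ["host"]
    strata = "location" if meta["location"].nunique() > 1 else None
    part = ordination.adonis(d, meta, terms, n_perm=config.n_perm_adonis,
                             seed=seed, strata=strata)
    part.table.to_csv(wd / "adonis.tsv", sep="\t")
    (wd / "ordination.json").write_text(json.dumps(
        {"stress": ord_res.stress, "fits": fits}, indent=1))
    if config.figures:
        _plot_nmds(wd, ord_res, meta)
    return {"stress": ord_res.stress, "fits": fits,
            "adonis_terms": part.table.index.tolist()}


def _plot_nmds(wd: Path, ord_res, meta):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(5, 5))
    for host, block in ord_res.scores.groupby(meta.loc[ord_res.scores.index, "host"]):
        ax.scatter(block["NMDS1"], block["NMDS2"], s=12, label=host)
    ax.legend()
    ax.set_xlabel("NMDS1")
    ax.set_ylabel("NMDS2")
    fig.savefig(wd / "nmds.svg")
    plt.close(fig)


def stage_report(config: RunConfig) -> dict:
    wd = _workdir(config)
    report = {"seed": config.seed, "stages": {}}
    for name in ("qc_report.json", "outlier_summary.json", "ordination.json"):
        path = wd / name
        if path.exists():
            report["stages"][name.split(".")[0]] = json.loads(path.read_text())
    for name in ("fst_comparisons.tsv", "phist_comparisons.tsv", "seq_summary.tsv",
                 "adonis.tsv"):
        path = wd / name
        if path.exists():
            report["stages"][name.split(".")[0]] = pd.read_csv(
                path, sep="\t").to_dict(orient="records")
    (wd / "report.json").write_text(json.dumps(report, indent=1))
    return {"report": str(wd / "report.json")}


_STAGE_FUNCS = {
    "simulate": stage_simulate, "qc": stage_qc, "popgen": stage_popgen,
    "ld": stage_ld, "scan": stage_scan, "seqstats": stage_seqstats,
    "network": stage_network, "ordinate": stage_ordinate, "report": stage_report,
}


def run_pipeline(config: RunConfig, stages=STAGES, resume: bool = False) -> dict:
    """Execute the requested stages in dependency order.

    On failure a :class:`StageError` is raised after the checkpoint has been
    written, so a later call with ``resume=True`` skips completed stages.
    """
    wd = _workdir(config)
    config.to_json(wd / "run_config.json")
    done = set(_checkpoint(wd)["completed"]) if resume else set()
    results = {}
    for stage in STAGES:
        if stage not in stages or stage in done:
            continue
        try:
            results[stage] = _STAGE_FUNCS[stage](config)
        except Exception as exc:
            raise StageError(stage, exc) from exc
        _mark_done(wd, stage)
    return results
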