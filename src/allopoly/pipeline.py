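"""End-to-end pipeline: simulate -> assign -> date -> expression -> methylation.

Every stage persists its outputs under the run directory and the
consolidated report is written both as JSON and as human-readable text.
Stage inputs are always re-read from the persisted files, so any stage can
be reproduced from the intermediates alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import assignment as asg
from . import dating, expression, methylation
from . import io as apio
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger("allopoly")

REPORT_SECTIONS = ("provenance", "assignment", "dating", "expression", "methylation")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class PipelineConfig:
    out_dir: str = "allopoly_run"
    seed: int = 0
    simulate: bool = True
    input_dir: str | None = None
    sim_overrides: dict = field(default_factory=dict)
    # stage parameters
    min_depth: int = 5
    min_margin: float = 0.05
    clock_rate: float = 3.51e-9
    bin_width: float = 1.0
    rel_threshold: float = 0.25
    fold: float = 2.0
    extreme_fold: float = 32.0
    k_clusters: int = 8
    min_cov: int = 5
    error_rate: float = 0.01
    promoter_len: int = 2000
    downstream_len: int = 2000
    run_expression: bool = True
    run_methylation: bool = True

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _extract_gene_sequences(
    sequences: dict[str, str], genes: pd.DataFrame
) -> dict[str, str]:
    out = {}
    for g in genes.itertuples(index=False):
        if g.chrom not in sequences:
            continue
        seq = sequences[g.chrom][int(g.start) : int(g.end)]
        if g.strand == "-":
            seq = seq.translate(_COMPLEMENT)[::-1]
        out[g.gene_id] = seq
    return out


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: starting", name)
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return result

        return wrapped

    return deco


@_stage("assign")
def run_assignment_stage(data_dir: Path, out_dir: Path, config: PipelineConfig) -> dict:
    depth = apio.read_depth_tsv(data_dir / "depth.tsv")
    chrom_pairs = apio.read_tsv(data_dir / "chrom_pairs.tsv")
    identity = None
    ident_path = data_dir / "identity.tsv"
    if ident_path.exists():
        ident_frame = apio.read_tsv(ident_path)
        identity = asg.alignment_identity(
            {
                r.chrom: (r.matched, r.total)
                for r in ident_frame.itertuples(index=False)
            }
        )
    coverage = asg.effective_coverage(depth, min_depth=config.min_depth)
    pair_tuples = [
        (r.pair_id, r.chrom_1, r.chrom_2) for r in chrom_pairs.itertuples(index=False)
    ]
    assignments = asg.assign_subgenomes(
        pair_tuples, coverage, identity, min_margin=config.min_margin
    )
    names = asg.assign_chromosome_names(
        assignments,
        {r.pair_id: int(r.ref_num) for r in chrom_pairs.itertuples(index=False)},
    )
    frame = asg.assignment_frame(assignments, names)
    apio.write_tsv(out_dir / "assignment.tsv", frame)
    return {
        "n_pairs": len(assignments),
        "n_ambiguous": int(sum(a.ambiguous for a in assignments)),
        "chrom_subgenome": dict(zip(frame["chrom"], frame["subgenome"])),
        "chrom_names": names,
    }


@_stage("date")
def run_dating_stage(
    data_dir: Path,
    out_dir: Path,
    config: PipelineConfig,
    chrom_subgenome: dict[str, str],
) -> dict:
    sequences = apio.read_fasta(data_dir / "genome.fasta")
    diploid = apio.read_fasta(data_dir / "diploid.fasta")
    genes = apio.read_gff3_genes(data_dir / "genes.gff3")
    pairs = apio.read_homoeolog_tsv(data_dir / "homoeologs.tsv")
    gene_seqs = _extract_gene_sequences({**sequences, **diploid}, genes)

    ks_frame = dating.kaks_table(
        (r.pair_id, gene_seqs[r.gene_a], gene_seqs[r.gene_b])
        for r in pairs.itertuples(index=False)
    )
    apio.write_tsv(out_dir / "ks_pairs.tsv", ks_frame)
    clock = dating.ClockModel(config.clock_rate)
    modes = dating.ks_distribution_mode(ks_frame["ks"].dropna())
    mode_dates_mya = [dating.clock_date(m, clock) / 1e6 for m in modes]
    t_div = dating.clock_date(modes[0], clock)

    omega_vs_diploid = {}
    for which in ("gene_a", "gene_b"):
        sub = dating.kaks_table(
            (getattr(r, which), gene_seqs[getattr(r, which)], gene_seqs[r.diploid_ortholog])
            for r in pairs.itertuples(index=False)
        )
        omega_vs_diploid.update(dict(zip(sub["pair_id"], sub["omega"])))
    gene_to_chrom = {}
    for r in pairs.itertuples(index=False):
        gene_to_chrom[r.gene_a] = r.chrom_a
        gene_to_chrom[r.gene_b] = r.chrom_b
    kaks = dating.chromosome_kaks_summary(
        [(r.gene_a, r.gene_b) for r in pairs.itertuples(index=False)],
        omega_vs_diploid,
        gene_to_chrom,
        chrom_subgenome,
    )
    apio.write_tsv(out_dir / "kaks_per_chromosome.tsv", kaks.per_chromosome)

    result = {
        "ks_modes": modes,
        "mode_dates_mya": mode_dates_mya,
        "t_div_years": t_div,
        "mean_omega_a": kaks.mean_a,
        "mean_omega_b": kaks.mean_b,
        "omega_p_value": kaks.p_value,
        "omega_low_power": kaks.low_power,
        "n_omega_pairs": kaks.n_pairs,
        "n_omega_undefined": kaks.n_undefined,
    }

    te_path = data_dir / "te.tsv"
    if te_path.exists():
        te_table = apio.read_te_tsv(te_path)
        sizes = {"A": 0.0, "B": 0.0}
        for chrom, seq in sequences.items():
            sizes[chrom_subgenome[chrom]] += len(seq)
        profiles = dating.te_profile(
            te_table, chrom_subgenome, sizes, bin_width=config.bin_width
        )
        prof_frame = pd.DataFrame(
            {
                "bin_low": profiles["A"].bin_edges[:-1],
                "bin_high": profiles["A"].bin_edges[1:],
                "mass_a": profiles["A"].mass,
                "mass_b": profiles["B"].mass,
            }
        )
        apio.write_tsv(out_dir / "te_profile.tsv", prof_frame)
        interval = dating.detect_segregation_interval(
            profiles["A"], profiles["B"], rel_threshold=config.rel_threshold
        )
        if interval is not None:
            t_merge = dating.merger_time(t_div, interval)
            result.update(
                {
                    "segregation_interval": [interval.d_low, interval.d_high],
                    "t_merge_years": t_merge,
                    "t_merge_mya": t_merge / 1e6,
                }
            )
        else:
            result["segregation_interval"] = None
    return result


@_stage("expression")
def run_expression_stage(data_dir: Path, out_dir: Path, config: PipelineConfig) -> dict:
    fpkm = apio.read_fpkm_tsv(data_dir / "fpkm.tsv")
    pairs = apio.read_homoeolog_tsv(data_dir / "homoeologs.tsv")
    expressed, log_matrix = expression.filter_expressed(fpkm)
    pair_expressed = pairs[
        pairs["gene_a"].isin(expressed) | pairs["gene_b"].isin(expressed)
    ].reset_index(drop=True)
    mat_a = fpkm.loc[pair_expressed["gene_a"]]
    mat_b = fpkm.loc[pair_expressed["gene_b"]].set_axis(mat_a.index, axis=0)
    labels = expression.dominance_labels(mat_a, mat_b, fold=config.fold)
    labels.index = pair_expressed["pair_id"]
    apio.write_tsv(out_dir / "dominance_labels.tsv", labels, index=True)
    summary = expression.bias_summary(labels)
    extreme = expression.extreme_bias(mat_a, mat_b, fold=config.extreme_fold)
    clusters = expression.coexpression_clusters(log_matrix, k=config.k_clusters)
    apio.write_tsv(out_dir / "clusters.tsv", clusters.to_frame(), index=True)

    result = {
        "n_pairs": len(pairs),
        "n_expressed_pairs": len(pair_expressed),
        "bias_summary": summary.as_dict(),
        "n_extreme_a": int(len(extreme["exclusive_a"])),
        "n_extreme_b": int(len(extreme["exclusive_b"])),
        "n_extreme_union": int(len(extreme["union"])),
        "n_clusters": int(clusters[clusters > 0].nunique()),
    }

    dip_path = data_dir / "fpkm_diploid.tsv"
    if dip_path.exists():
        fpkm_dip = apio.read_fpkm_tsv(dip_path)
        fates = {}
        fate_rows = []
        for r in pair_expressed.itertuples(index=False):
            fate, p_a, p_b = expression.triplet_fate(
                fpkm_dip.loc[r.diploid_ortholog],
                fpkm.loc[r.gene_a],
                fpkm.loc[r.gene_b],
            )
            fates[fate] = fates.get(fate, 0) + 1
            fate_rows.append(
                {"pair_id": r.pair_id, "fate": fate, "p_a": p_a, "p_b": p_b}
            )
        fate_frame = pd.DataFrame(fate_rows)
        apio.write_tsv(out_dir / "triplet_fates.tsv", fate_frame)
        result["fate_counts"] = fates
        result["wilcoxon_min_p_note"] = (
            "n=12 paired tissues bounds the Wilcoxon p at ~5e-4; conservation "
            "calls are low-powered at this tissue count"
        )
        result["_fates_frame"] = fate_frame  # internal, stripped from report

    treat_path = data_dir / "treatment.tsv"
    if treat_path.exists():
        treatment = apio.read_fpkm_tsv(treat_path)["fpkm"]
        control = apio.read_fpkm_tsv(data_dir / "control.tsv")["fpkm"]
        per_pair, conventional, stress_summary = expression.stress_deg_summed(
            pairs, treatment, control, fold=config.fold
        )
        apio.write_tsv(out_dir / "stress_pairs.tsv", per_pair)
        result["stress"] = stress_summary
    return result


@_stage("methylation")
def run_methylation_stage(
    data_dir: Path,
    out_dir: Path,
    config: PipelineConfig,
    fates_frame: pd.DataFrame | None,
) -> dict:
    reports = []
    i = 1
    while (data_dir / f"cytosine_rep{i}.tsv").exists():
        reports.append(apio.read_cytosine_tsv(data_dir / f"cytosine_rep{i}.tsv"))
        i += 1
    if not reports:
        raise FileNotFoundError("no cytosine_rep*.tsv replicate tables found")
    genes = apio.read_gff3_genes(data_dir / "genes.gff3")
    pairs = apio.read_homoeolog_tsv(data_dir / "homoeologs.tsv")

    sites = methylation.conserved_sites(reports, min_cov=config.min_cov)
    called = methylation.call_mcg(sites, error_rate=config.error_rate)
    stats_ = methylation.genome_pcg(called)
    n_meth_all = int(called["methylated"].sum())
    regions = methylation.gene_region_extents(
        genes[genes["chrom"].isin(set(pairs["chrom_a"]) | set(pairs["chrom_b"]))],
        promoter_len=config.promoter_len,
        downstream_len=config.downstream_len,
    )
    summaries = methylation.gene_methylation_summaries(called, regions, stats_.pcg)
    summary_frame = pd.DataFrame(
        [
            {
                "gene_id": s.gene_id,
                "region": s.region,
                "ncg": s.ncg,
                "mcg": s.mcg,
                "level": s.level,
                "PCG": s.PCG,
                "body_methylated": s.body_methylated,
            }
            for s in summaries
        ]
    )
    apio.write_tsv(out_dir / "gene_methylation.tsv", summary_frame)

    map_path = data_dir / "site_map.tsv"
    dmcg_summary = None
    if map_path.exists():
        site_map = apio.read_tsv(map_path)
        res = methylation.dmcg_change_rate(site_map, called, called, pair_id="all")
        dmcg_summary = {
            "n_conserved_cg": res.n_conserved_cg,
            "n_dmcg": res.n_dmcg,
            "change_rate": res.change_rate,
        }

    promoter_bias = None
    if fates_frame is not None and len(fates_frame):
        nonfunc = fates_frame[fates_frame["fate"].str.startswith("nonfunctionalization")]
        pair_map = pairs.set_index("pair_id")
        dominant_genes, suppressed_genes = [], []
        for r in nonfunc.itertuples(index=False):
            row = pair_map.loc[r.pair_id]
            if r.fate.endswith("-A"):  # A copy silenced
                suppressed_genes.append(row["gene_a"])
                dominant_genes.append(row["gene_b"])
            else:
                suppressed_genes.append(row["gene_b"])
                dominant_genes.append(row["gene_a"])
        prom = summary_frame[summary_frame["region"] == "promoter"].set_index("gene_id")
        dom_levels = prom.loc[prom.index.intersection(dominant_genes), "level"]
        sup_levels = prom.loc[prom.index.intersection(suppressed_genes), "level"]
        if len(dom_levels) and len(sup_levels):
            p, diff, low_power = methylation.promoter_bias_test(dom_levels, sup_levels)
            profiles_dom, _ = methylation.metagene_profile(
                genes[genes["gene_id"].isin(dominant_genes)], called, regions
            )
            profiles_sup, _ = methylation.metagene_profile(
                genes[genes["gene_id"].isin(suppressed_genes)], called, regions
            )
            prof_frame = pd.DataFrame(
                {
                    f"{which}_{region}": prof[region]
                    for which, prof in (("dominant", profiles_dom), ("suppressed", profiles_sup))
                    for region in methylation.REGIONS
                }
            )
            apio.write_tsv(out_dir / "metagene_profiles.tsv", prof_frame)
            promoter_bias = {
                "p_value": p,
                "mean_difference": diff,
                "low_power": low_power,
                "n_dominant": int(len(dom_levels)),
                "n_suppressed": int(len(sup_levels)),
            }

    body = summary_frame[summary_frame["region"] == "body"]
    return {
        "n_replicates": len(reports),
        "n_conserved_sites": int(len(sites)),
        "n_methylated_sites": n_meth_all,
        "methylated_fraction_pct": 100.0 * n_meth_all / len(sites),
        "n_cg_sites": stats_.n_cg_sites,
        "n_mcg_sites": stats_.n_mcg_sites,
        "pcg_pct": 100.0 * stats_.pcg,
        "per_context": stats_.per_context,
        "n_body_methylated_genes": int(body["body_methylated"].eq(True).sum()),
        "dmcg": dmcg_summary,
        "promoter_bias": promoter_bias,
    }


@dataclass
class ReportBundle:
    sections: dict

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        missing = [s for s in REPORT_SECTIONS if s not in self.sections]
        if missing:
            raise ValueError(f"report is missing sections: {missing}")

    def to_json(self) -> str:
        return json.dumps(self.sections, indent=1, sort_keys=True, default=_json_default)

    @classmethod
    def from_json(cls, text: str) -> "ReportBundle":
        return cls(sections=json.loads(text))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_report(bundle: ReportBundle, out_dir: str | Path) -> tuple[Path, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.validate()
    json_path = out / "report.json"
    json_path.write_text(bundle.to_json())
    lines = ["allopoly pipeline report", "=" * 40]
    prov = bundle.sections["provenance"]
    lines.append(f"seed {prov['seed']}  config {prov['config_hash']}  v{prov['version']}")
    for section in REPORT_SECTIONS[1:]:
        content = bundle.sections[section]
        lines.append("")
        lines.append(f"[{section}]")
        if not isinstance(content, dict) or content.get("status") == "not run":
            lines.append("  not run")
            continue
        for key, value in content.items():
            if key.startswith("_"):
                continue
            lines.append(f"  {key}: {value}")
    text_path = out / "report.txt"
    text_path.write_text("\n".join(lines) + "\n")
    return json_path, text_path


def run_all(config: PipelineConfig) -> ReportBundle:
    """Run every enabled stage in dependency order and write the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.StreamHandler()
    if not logger.handlers:
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)

    if config.simulate:
        sim_config = SimulationConfig(seed=config.seed, **config.sim_overrides)
        logger.info("simulating dataset with seed %d", config.seed)
        dataset, truth = simulate_dataset(sim_config)
        data_dir = out / "sim"
        dataset.write(data_dir, truth)
        # the synthetic genome uses its own flank length as promoter extent
        config = dataclasses.replace(
            config,
            promoter_len=sim_config.flank_len,
            downstream_len=sim_config.flank_len,
        )
    elif config.input_dir:
        data_dir = Path(config.input_dir)
        if not data_dir.exists():
            raise FileNotFoundError(f"input directory does not exist: {data_dir}")
    else:
        raise ValueError("simulation disabled and no input_dir given: nothing to run")
    for required in ("depth.tsv", "genome.fasta", "homoeologs.tsv"):
        if not (data_dir / required).exists():
            raise FileNotFoundError(f"missing stage input: {data_dir / required}")

    sections: dict = {
        "provenance": {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "version": __version__,
            "data_dir": str(data_dir),
        }
    }
    assign_result = run_assignment_stage(data_dir, out, config)
    sections["assignment"] = {
        k: v for k, v in assign_result.items() if k != "chrom_subgenome"
    }
    sections["dating"] = run_dating_stage(
        data_dir, out, config, assign_result["chrom_subgenome"]
    )
    fates_frame = None
    if config.run_expression and (data_dir / "fpkm.tsv").exists():
        expr_result = run_expression_stage(data_dir, out, config)
        fates_frame = expr_result.pop("_fates_frame", None)
        sections["expression"] = expr_result
    else:
        sections["expression"] = {"status": "not run"}
    if config.run_methylation and (data_dir / "cytosine_rep1.tsv").exists():
        sections["methylation"] = run_methylation_stage(
            data_dir, out, config, fates_frame
        )
    else:
        sections["methylation"] = {"status": "not run"}

    bundle = ReportBundle(sections=sections)
    write_report(bundle, out)
    return bundle
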