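"""Seeded synthetic allotetraploid generator.

Produces a complete desk-scale dataset — two subgenomes plus a diploid
relative, gene models, a homoeolog table, diploid-alignment depth windows,
a TE table with an age-calibrated divergence "bubble", tissue FPKM matrices
with planted subgenome-B bias, stress treatment/control expression, and
replicate cytosine reports with planted promoter hypermethylation on
silenced copies — together with a machine-readable truth record.

Sequence evolution is a Jukes–Cantor site process with two site classes:
third positions of 4-fold degenerate codons (synonymous, evolving at the
planted synonymous distance, like all intergenic sequence) and first/second
codon positions (nonsynonymous, evolving at omega times that distance).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as apio

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "evolve_sequence",
    "simulate_dataset",
    "simulate_te_records",
    "simulate_expression_matrices",
    "simulate_methylation_tables",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {c: i for i, c in enumerate("ACGT")}
# 4-fold degenerate codon families without synonymous first-position changes
# (Ala, Gly, Pro, Thr, Val, Ser): third position is exactly one synonymous
# site, first/second positions are fully nonsynonymous.
_FOURFOLD_PREFIXES = np.array(
    [[2, 1], [2, 2], [1, 1], [0, 1], [2, 3], [3, 1]], dtype=np.uint8
)
_STOP_CODONS = np.array([48, 50, 56], dtype=np.int64)  # TAA, TAG, TGA

DOMINANCE_LABELS = ("A", "B", "neutral", "silenced-A", "silenced-B")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted evolutionary scenario.

    Times are in years; ``clock_rate`` is substitutions per synonymous site
    per year, so the expected pairwise homoeolog Ks is 2 * clock_rate *
    t_div. ``te_rate_per_mya`` converts TE insertion age to percent
    divergence.
    """

    t_div: float = 23e6
    t_merge: float = 12.4e6
    clock_rate: float = 3.51e-9
    n_chrom_pairs: int = 2
    genes_per_chrom: int = 40
    codons_per_gene: int = 120
    te_rate_per_mya: float = 13.0 / 23.0
    te_copies: int = 3000
    n_tissues: int = 12
    bias_fraction_a: float = 0.10
    bias_fraction_b: float = 0.30
    silenced_fraction: float = 0.10
    meth_promoter_delta: float = 0.40
    replicates: int = 3
    seed: int = 0
    # secondary knobs
    t_diploid_split: float = 6e6
    omega_a: float = 0.20
    omega_b: float = 0.18
    flank_len: int = 300
    intergenic_gap: int = 120
    depth_window: int = 500
    depth_mean_a: float = 2.0
    depth_mean_b: float = 8.0
    te_len_min: int = 200
    te_len_max: int = 2000
    te_diploid_mult_a: float = 0.15
    te_diploid_mult_b: float = 3.0
    expr_sigma: float = 0.15
    dominance_factor: float = 4.0
    stress_fraction: float = 0.20
    stress_fold: float = 3.0
    meth_coverage: float = 10.0
    meth_promoter_level: float = 0.30
    meth_body_level: float = 0.60
    meth_downstream_level: float = 0.35
    meth_background_level: float = 0.02
    # stage toggles
    with_depth: bool = True
    with_te: bool = True
    with_expression: bool = True
    with_methylation: bool = True

    def __post_init__(self):
        if self.t_merge > self.t_div:
            raise ValueError("t_merge must not exceed t_div")
        if self.clock_rate <= 0:
            raise ValueError("clock_rate must be positive")
        for name in (
            "bias_fraction_a",
            "bias_fraction_b",
            "silenced_fraction",
            "meth_promoter_delta",
            "stress_fraction",
        ):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must be within [0, 1]")
        if self.bias_fraction_a + self.bias_fraction_b + self.silenced_fraction > 1:
            raise ValueError("planted pair fractions exceed 1")
        for name in ("n_chrom_pairs", "genes_per_chrom", "codons_per_gene"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be at least 1")
        if self.replicates < 1:
            raise ValueError("replicates must be at least 1")
        if self.n_tissues < 1:
            raise ValueError("n_tissues must be at least 1")
        if self.te_rate_per_mya <= 0:
            raise ValueError("te_rate_per_mya must be positive")

    @property
    def planted_ks(self) -> float:
        return 2.0 * self.clock_rate * self.t_div


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator."""

    chrom_subgenome: dict[str, str]
    pairs: pd.DataFrame  # pair_id, gene_a, gene_b, diploid_ortholog, chrom_a, chrom_b
    pair_ks: dict[str, float]
    pair_dominance: dict[str, str]
    gene_methylation: dict[str, dict[str, float]]
    te_truth: dict | None = None
    stress_perturbed: dict[str, str] = field(default_factory=dict)  # pair -> copy
    cg_sites: pd.DataFrame | None = None  # chrom,pos,strand,context,level

    def to_json(self) -> str:
        payload = {
            "chrom_subgenome": self.chrom_subgenome,
            "pairs": self.pairs.to_dict(orient="records"),
            "pair_ks": self.pair_ks,
            "pair_dominance": self.pair_dominance,
            "gene_methylation": self.gene_methylation,
            "te_truth": self.te_truth,
            "stress_perturbed": self.stress_perturbed,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class SyntheticDataset:
    sequences: dict[str, str]
    diploid_sequences: dict[str, str]
    genes: pd.DataFrame
    homoeolog_table: pd.DataFrame
    chrom_pairs: pd.DataFrame
    depth: pd.DataFrame | None = None
    identity: pd.DataFrame | None = None
    te_table: pd.DataFrame | None = None
    fpkm: pd.DataFrame | None = None
    fpkm_diploid: pd.DataFrame | None = None
    treatment: pd.Series | None = None
    control: pd.Series | None = None
    cytosine_reports: list[pd.DataFrame] | None = None
    site_map: pd.DataFrame | None = None

    def write(self, out_dir: str | os.PathLike, truth: SyntheticTruth | None = None) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        apio.write_fasta(out / "genome.fasta", self.sequences)
        apio.write_fasta(out / "diploid.fasta", self.diploid_sequences)
        apio.write_gff3_genes(out / "genes.gff3", self.genes)
        apio.write_tsv(out / "homoeologs.tsv", self.homoeolog_table)
        apio.write_tsv(out / "chrom_pairs.tsv", self.chrom_pairs)
        if self.depth is not None:
            apio.write_tsv(out / "depth.tsv", self.depth)
        if self.identity is not None:
            apio.write_tsv(out / "identity.tsv", self.identity)
        if self.te_table is not None:
            apio.write_tsv(out / "te.tsv", self.te_table[apio.TE_COLUMNS])
        if self.fpkm is not None:
            apio.write_tsv(out / "fpkm.tsv", self.fpkm, index=True)
        if self.fpkm_diploid is not None:
            apio.write_tsv(out / "fpkm_diploid.tsv", self.fpkm_diploid, index=True)
        if self.treatment is not None:
            apio.write_tsv(out / "treatment.tsv", self.treatment.rename("fpkm").to_frame(), index=True)
            apio.write_tsv(out / "control.tsv", self.control.rename("fpkm").to_frame(), index=True)
        if self.cytosine_reports is not None:
            for i, rep in enumerate(self.cytosine_reports, start=1):
                apio.write_tsv(out / f"cytosine_rep{i}.tsv", rep)
        if self.site_map is not None:
            apio.write_tsv(out / "site_map.tsv", self.site_map)
        if truth is not None:
            (out / "truth.json").write_text(truth.to_json())


# ---------------------------------------------------------------------------
# sequence evolution


def _jc_change_prob(d: float) -> float:
    # probability a site differs from the ancestor after JC distance d
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))


def _mutate(arr: np.ndarray, mask: np.ndarray, d: float, rng: np.random.Generator) -> None:
    if d < 0:
        raise ValueError("distance must be non-negative")
    if d == 0:
        return
    p = _jc_change_prob(d)
    hit = mask & (rng.random(arr.size) < p)
    n = int(hit.sum())
    if n:
        arr[hit] = (arr[hit] + rng.integers(1, 4, size=n, dtype=np.uint8)) % 4


def _fix_stops(
    evolved: np.ndarray, ancestor: np.ndarray, gene_spans: list[tuple[int, int]]
) -> None:
    """Revert minimal positions of any evolved stop codon back to the
    ancestral base (stop codons that already exist in the ancestor are left
    untouched)."""
    for start, end in gene_spans:
        for revert_pos in (0, 1, 2):
            seg = evolved[start:end]
            codons = seg[0::3].astype(np.int64) * 16 + seg[1::3] * 4 + seg[2::3]
            anc_seg = ancestor[start:end]
            anc_codons = anc_seg[0::3].astype(np.int64) * 16 + anc_seg[1::3] * 4 + anc_seg[2::3]
            bad = np.isin(codons, _STOP_CODONS) & ~np.isin(anc_codons, _STOP_CODONS)
            if not bad.any():
                break
            idx = np.nonzero(bad)[0] * 3 + revert_pos + start
            evolved[idx] = ancestor[idx]


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[b] for b in seq.upper()], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"non-ACGT base in sequence: {exc}") from None


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode("ascii")


def evolve_sequence(
    ancestor_codons: str, d_syn: float, d_nonsyn: float, seed: int
) -> str:
    """Evolve a coding sequence under the two-class Jukes–Cantor process.

    Third codon positions form the synonymous class (distance ``d_syn``),
    first/second positions the nonsynonymous class (``d_nonsyn``). Length is
    preserved (no indels); substitutions that would create a stop codon are
    reverted.
    """
    if len(ancestor_codons) % 3 != 0:
        raise ValueError("ancestor length must be a multiple of 3")
    if d_syn < 0 or d_nonsyn < 0:
        raise ValueError("distances must be non-negative")
    arr = _encode(ancestor_codons)
    ancestor = arr.copy()
    syn_mask = np.zeros(arr.size, dtype=bool)
    syn_mask[2::3] = True
    rng = np.random.default_rng(seed)
    _mutate(arr, syn_mask, d_syn, rng)
    _mutate(arr, ~syn_mask, d_nonsyn, rng)
    _fix_stops(arr, ancestor, [(0, arr.size)])
    return _decode(arr)


def _random_gene(rng: np.random.Generator, n_codons: int) -> np.ndarray:
    prefix = _FOURFOLD_PREFIXES[rng.integers(0, len(_FOURFOLD_PREFIXES), n_codons)]
    third = rng.integers(0, 4, n_codons, dtype=np.uint8)
    return np.column_stack([prefix, third]).reshape(-1).astype(np.uint8)


# ---------------------------------------------------------------------------
# TE records


def simulate_te_records(
    config: SimulationConfig,
    seed: int | None = None,
    chrom_map: dict[str, list[tuple[str, int]]] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """TE tables for both subgenomes under the planted insertion history.

    Copies older than t_div or younger than t_merge are shared (identical
    rows in both subgenomes); copies inserted during the independent diploid
    window (t_merge, t_div) occur at subgenome-specific rates, which creates
    the divergence "bubble". Percent divergence = age(Mya) *
    te_rate_per_mya.

    Returns (table, truth) where the table carries a ``subgenome`` column in
    addition to the standard TE columns.
    """
    if config.t_merge >= config.t_div:
        raise ValueError("TE scenario requires t_merge < t_div")
    rng = rng if rng is not None else np.random.default_rng(seed)
    t_merge, t_div = config.t_merge / 1e6, config.t_div / 1e6
    anc_span = 0.7 * t_div
    durations = {"recent": t_merge, "diploid": t_div - t_merge, "ancient": anc_span}
    lam = config.te_copies / sum(durations.values())
    n_recent = int(round(lam * durations["recent"]))
    n_ancient = int(round(lam * durations["ancient"]))
    n_dip = {
        "A": int(rng.poisson(lam * durations["diploid"] * config.te_diploid_mult_a)),
        "B": int(rng.poisson(lam * durations["diploid"] * config.te_diploid_mult_b)),
    }
    if chrom_map is None:
        chrom_map = {"A": [("A_chr", 20_000_000)], "B": [("B_chr", 20_000_000)]}

    def _place(label: str, n: int) -> tuple[np.ndarray, np.ndarray]:
        chroms = chrom_map[label]
        weights = np.array([c[1] for c in chroms], dtype=float)
        idx = rng.choice(len(chroms), size=n, p=weights / weights.sum())
        starts = np.array(
            [rng.integers(0, max(1, chroms[i][1] - config.te_len_max)) for i in idx]
        )
        names = np.array([chroms[i][0] for i in idx])
        return names, starts

    shared = {
        "recent": {
            "ages": rng.uniform(0.0, t_merge, n_recent),
            "family": "TE_recent",
        },
        "ancient": {
            "ages": rng.uniform(t_div, t_div + anc_span, n_ancient),
            "family": "TE_ancient",
        },
    }
    for epoch in shared.values():
        epoch["lengths"] = rng.integers(config.te_len_min, config.te_len_max + 1,
                                        epoch["ages"].size)
    frames = []
    truth_ages: dict[str, dict[str, list[float]]] = {"A": {}, "B": {}}
    for label in ("A", "B"):
        parts = []
        for name, epoch in shared.items():
            chroms, starts = _place(label, epoch["ages"].size)
            parts.append(
                pd.DataFrame(
                    {
                        "subgenome": label,
                        "chrom": chroms,
                        "start": starts,
                        "end": starts + epoch["lengths"],
                        "family": epoch["family"],
                        "te_class": "DNA",
                        "perc_div": epoch["ages"] * config.te_rate_per_mya,
                    }
                )
            )
            truth_ages[label][name] = epoch["ages"].tolist()
        ages_dip = rng.uniform(t_merge, t_div, n_dip[label])
        lengths_dip = rng.integers(config.te_len_min, config.te_len_max + 1, n_dip[label])
        chroms, starts = _place(label, n_dip[label])
        parts.append(
            pd.DataFrame(
                {
                    "subgenome": label,
                    "chrom": chroms,
                    "start": starts,
                    "end": starts + lengths_dip,
                    "family": "TE_diploid",
                    "te_class": "DNA",
                    "perc_div": ages_dip * config.te_rate_per_mya,
                }
            )
        )
        truth_ages[label]["diploid"] = ages_dip.tolist()
        frames.append(pd.concat(parts, ignore_index=True))
    table = pd.concat(frames, ignore_index=True)
    truth = {
        "n_recent_shared": n_recent,
        "n_ancient_shared": n_ancient,
        "n_diploid_a": n_dip["A"],
        "n_diploid_b": n_dip["B"],
        "counts_per_subgenome": {
            "A": n_recent + n_ancient + n_dip["A"],
            "B": n_recent + n_ancient + n_dip["B"],
        },
        "ages_mya": truth_ages,
        "expected_interval": [
            t_merge * config.te_rate_per_mya,
            t_div * config.te_rate_per_mya,
        ],
    }
    return table, truth


# ---------------------------------------------------------------------------
# expression


def simulate_expression_matrices(
    truth: SyntheticTruth,
    config: SimulationConfig,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.Series]:
    """FPKM matrices for tetraploid genes and diploid orthologs, plus
    paired stress treatment/control vectors.

    Planted B-dominant pairs carry at least a ``dominance_factor`` expected
    fold in one or more tissues; silenced copies stay below FPKM 1 in all
    tissues. Noise is log-normal; stress perturbs one copy of a configured
    fraction of pairs.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    pairs = truth.pairs
    n = len(pairs)
    k = config.n_tissues
    tissues = [f"tissue{t:02d}" for t in range(1, k + 1)]
    labels = np.array([truth.pair_dominance[p] for p in pairs["pair_id"]])

    base = rng.lognormal(mean=2.5, sigma=1.0, size=(n, k))
    dom_tissue = rng.random((n, k)) < 0.5
    none_rows = ~dom_tissue.any(axis=1)
    dom_tissue[none_rows, rng.integers(0, k, int(none_rows.sum()))] = True
    factor_a = np.ones((n, k))
    factor_b = np.ones((n, k))
    is_a = labels == "A"
    is_b = labels == "B"
    planted = (is_a | is_b)[:, None] & dom_tissue
    base[planted] = np.maximum(base[planted], 5.0)
    factor_a[is_a[:, None] & dom_tissue] = config.dominance_factor
    factor_b[is_b[:, None] & dom_tissue] = config.dominance_factor

    noise = lambda: rng.lognormal(0.0, config.expr_sigma, size=(n, k))  # noqa: E731
    fpkm_a = base * factor_a * noise()
    fpkm_b = base * factor_b * noise()
    fpkm_d = base * noise()

    sil_a = labels == "silenced-A"
    sil_b = labels == "silenced-B"
    fpkm_a[sil_a] = rng.uniform(0.0, 0.8, size=(int(sil_a.sum()), k))
    fpkm_b[sil_b] = rng.uniform(0.0, 0.8, size=(int(sil_b.sum()), k))
    # make sure the surviving copy of a silenced pair is clearly expressed
    for mask, other in ((sil_a, fpkm_b), (sil_b, fpkm_a)):
        rows = np.nonzero(mask)[0]
        if rows.size:
            top = other[rows].argmax(axis=1)
            other[rows, top] = np.maximum(other[rows, top], 5.0)

    fpkm = pd.DataFrame(
        np.vstack([fpkm_a, fpkm_b]),
        index=pd.Index(list(pairs["gene_a"]) + list(pairs["gene_b"]), name="gene_id"),
        columns=tissues,
    )
    fpkm_diploid = pd.DataFrame(
        fpkm_d, index=pd.Index(pairs["diploid_ortholog"], name="gene_id"), columns=tissues
    )

    base_c = rng.lognormal(2.5, 1.0, size=n)
    noise1 = lambda: rng.lognormal(0.0, config.expr_sigma, size=n)  # noqa: E731
    control_a = base_c * noise1()
    control_b = base_c * noise1()
    treat_a = control_a * noise1()
    treat_b = control_b * noise1()
    perturbed = rng.random(n) < config.stress_fraction
    which = rng.integers(0, 2, n)
    treat_a[perturbed & (which == 0)] *= config.stress_fold
    treat_b[perturbed & (which == 1)] *= config.stress_fold
    truth.stress_perturbed = {
        str(pairs["pair_id"].iloc[i]): ("A" if which[i] == 0 else "B")
        for i in np.nonzero(perturbed)[0]
    }
    gene_index = pd.Index(list(pairs["gene_a"]) + list(pairs["gene_b"]), name="gene_id")
    treatment = pd.Series(np.concatenate([treat_a, treat_b]), index=gene_index, name="fpkm")
    control = pd.Series(np.concatenate([control_a, control_b]), index=gene_index, name="fpkm")
    return fpkm, fpkm_diploid, treatment, control


# ---------------------------------------------------------------------------
# methylation


def simulate_methylation_tables(
    truth: SyntheticTruth,
    config: SimulationConfig,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[pd.DataFrame]:
    """Replicate cytosine reports drawn binomially around the planted
    per-site levels in ``truth.cg_sites``.

    Coverage is Poisson(meth_coverage), so a small fraction of sites falls
    below the >=5-read conservation filter in at least one replicate.
    """
    if truth.cg_sites is None:
        raise ValueError("truth record carries no cytosine site catalogue")
    rng = rng if rng is not None else np.random.default_rng(seed)
    sites = truth.cg_sites
    levels = sites["level"].to_numpy(dtype=float)
    reports = []
    for _ in range(config.replicates):
        cov = rng.poisson(config.meth_coverage, size=len(sites))
        meth = rng.binomial(cov, levels)
        reports.append(
            pd.DataFrame(
                {
                    "chrom": sites["chrom"],
                    "pos": sites["pos"],
                    "strand": sites["strand"],
                    "context": sites["context"],
                    "count_methylated": meth,
                    "count_unmethylated": cov - meth,
                }
            )
        )
    return reports


# ---------------------------------------------------------------------------
# whole-dataset generation


def _classify_contexts(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Positions (0-based) of forward-strand cytosines and their context."""
    is_c = arr == 1
    nxt1 = np.roll(arr, -1)
    nxt2 = np.roll(arr, -2)
    is_c[-2:] = False  # avoid wrap-around context
    pos = np.nonzero(is_c)[0]
    context = np.where(
        nxt1[pos] == 2, "CG", np.where(nxt2[pos] == 2, "CHG", "CHH")
    )
    return pos, context


def simulate_dataset(config: SimulationConfig) -> tuple[SyntheticDataset, SyntheticTruth]:
    """Generate the full synthetic dataset and its truth record.

    The same (config, seed) always yields byte-identical outputs.
    """
    ss = np.random.SeedSequence(config.seed)
    rngs = {name: np.random.default_rng(s) for name, s in zip(
        ["seq", "assign", "depth", "te", "expr", "meth"], ss.spawn(6)
    )}
    r = config.clock_rate
    d_branch = r * config.t_div  # per-lineage synonymous distance
    d_dip = 2.0 * r * config.t_diploid_split

    glen = config.codons_per_gene * 3
    unit = config.flank_len + glen + config.flank_len + config.intergenic_gap
    chrom_len = config.genes_per_chrom * unit

    sequences: dict[str, str] = {}
    diploid_sequences: dict[str, str] = {}
    gene_rows = []
    pair_rows = []
    chrom_pair_rows = []
    chrom_subgenome: dict[str, str] = {}
    identity_rows = []
    depth_rows = []
    seq_arrays: dict[str, np.ndarray] = {}

    for i in range(1, config.n_chrom_pairs + 1):
        ancestor = rngs["seq"].integers(0, 4, chrom_len, dtype=np.uint8)
        gene_spans = []
        for j in range(config.genes_per_chrom):
            gstart = j * unit + config.flank_len
            ancestor[gstart : gstart + glen] = _random_gene(
                rngs["seq"], config.codons_per_gene
            )
            gene_spans.append((gstart, gstart + glen))
        nonsyn_mask = np.zeros(chrom_len, dtype=bool)
        for gstart, gend in gene_spans:
            nonsyn_mask[gstart:gend] = True
            nonsyn_mask[gstart + 2 : gend : 3] = False
        syn_mask = ~nonsyn_mask

        # which physical copy is subgenome A is random per pair
        first_is_a = bool(rngs["assign"].integers(0, 2))
        copies = {}
        for suffix, label in (("_1", "A" if first_is_a else "B"),
                              ("_2", "B" if first_is_a else "A")):
            omega = config.omega_a if label == "A" else config.omega_b
            arr = ancestor.copy()
            _mutate(arr, syn_mask, d_branch, rngs["seq"])
            _mutate(arr, nonsyn_mask, omega * d_branch, rngs["seq"])
            _fix_stops(arr, ancestor, gene_spans)
            copies[label] = (f"chr{i:02d}{suffix}", arr)
        dip_arr = copies["B"][1].copy()
        _mutate(dip_arr, syn_mask, d_dip, rngs["seq"])
        _mutate(dip_arr, nonsyn_mask, config.omega_b * d_dip, rngs["seq"])
        _fix_stops(dip_arr, copies["B"][1], gene_spans)
        dip_chrom = f"dchr{i:02d}"

        for label in ("A", "B"):
            chrom, arr = copies[label]
            chrom_subgenome[chrom] = label
            sequences[chrom] = _decode(arr)
            seq_arrays[chrom] = arr
            matched = int((dip_arr == arr).sum())
            identity_rows.append({"chrom": chrom, "matched": matched, "total": chrom_len})
        diploid_sequences[dip_chrom] = _decode(dip_arr)
        seq_arrays[dip_chrom] = dip_arr
        chrom_pair_rows.append(
            {
                "pair_id": f"p{i:02d}",
                "chrom_1": f"chr{i:02d}_1",
                "chrom_2": f"chr{i:02d}_2",
                "ref_num": i,
            }
        )

        for j, (gstart, gend) in enumerate(gene_spans, start=1):
            names = {}
            for label in ("A", "B"):
                chrom = copies[label][0]
                gid = f"{chrom}.g{j:03d}"
                names[label] = gid
                gene_rows.append(
                    {"chrom": chrom, "start": gstart, "end": gend, "strand": "+", "gene_id": gid}
                )
            dip_gid = f"{dip_chrom}.g{j:03d}"
            gene_rows.append(
                {"chrom": dip_chrom, "start": gstart, "end": gend, "strand": "+", "gene_id": dip_gid}
            )
            pair_rows.append(
                {
                    "pair_id": f"p{i:02d}.{j:03d}",
                    "gene_a": names["A"],
                    "gene_b": names["B"],
                    "diploid_ortholog": dip_gid,
                    "chrom_a": copies["A"][0],
                    "chrom_b": copies["B"][0],
                }
            )

        if config.with_depth:
            for suffix in ("_1", "_2"):
                chrom = f"chr{i:02d}{suffix}"
                mean = (
                    config.depth_mean_b
                    if chrom_subgenome[chrom] == "B"
                    else config.depth_mean_a
                )
                starts = np.arange(0, chrom_len, config.depth_window)
                ends = np.minimum(starts + config.depth_window, chrom_len)
                depths = rngs["depth"].poisson(mean, size=starts.size)
                depth_rows.append(
                    pd.DataFrame(
                        {"chrom": chrom, "start": starts, "end": ends, "depth": depths}
                    )
                )

    genes = pd.DataFrame(gene_rows, columns=apio.GENE_COLUMNS)
    pairs = pd.DataFrame(pair_rows, columns=apio.HOMOEOLOG_COLUMNS)
    chrom_pairs = pd.DataFrame(chrom_pair_rows)

    # planted dominance labels
    n_pairs = len(pairs)
    probs = [
        config.bias_fraction_a,
        config.bias_fraction_b,
        1.0
        - config.bias_fraction_a
        - config.bias_fraction_b
        - config.silenced_fraction,
        config.silenced_fraction / 2.0,
        config.silenced_fraction / 2.0,
    ]
    labels = rngs["expr"].choice(DOMINANCE_LABELS, size=n_pairs, p=probs)
    pair_dominance = dict(zip(pairs["pair_id"], labels))
    pair_ks = {p: config.planted_ks for p in pairs["pair_id"]}

    # planted per-gene region methylation levels
    gene_methylation: dict[str, dict[str, float]] = {}
    for row, label in zip(pairs.itertuples(index=False), labels):
        for gene, copy in ((row.gene_a, "A"), (row.gene_b, "B")):
            promoter = config.meth_promoter_level
            if label == f"silenced-{copy}":
                promoter = min(1.0, promoter + config.meth_promoter_delta)
            gene_methylation[gene] = {
                "promoter": promoter,
                "body": config.meth_body_level,
                "downstream": config.meth_downstream_level,
            }

    truth = SyntheticTruth(
        chrom_subgenome=chrom_subgenome,
        pairs=pairs,
        pair_ks=pair_ks,
        pair_dominance=pair_dominance,
        gene_methylation=gene_methylation,
    )

    dataset = SyntheticDataset(
        sequences=sequences,
        diploid_sequences=diploid_sequences,
        genes=genes,
        homoeolog_table=pairs,
        chrom_pairs=chrom_pairs,
        depth=pd.concat(depth_rows, ignore_index=True) if depth_rows else None,
        identity=pd.DataFrame(identity_rows) if identity_rows else None,
    )

    if config.with_te:
        chrom_map = {
            label: [
                (c, chrom_len) for c, lab in chrom_subgenome.items() if lab == label
            ]
            for label in ("A", "B")
        }
        te_table, te_truth = simulate_te_records(
            config, chrom_map=chrom_map, rng=rngs["te"]
        )
        dataset.te_table = te_table
        truth.te_truth = te_truth

    if config.with_expression:
        fpkm, fpkm_dip, treatment, control = simulate_expression_matrices(
            truth, config, rng=rngs["expr"]
        )
        dataset.fpkm = fpkm
        dataset.fpkm_diploid = fpkm_dip
        dataset.treatment = treatment
        dataset.control = control

    if config.with_methylation:
        site_frames = []
        gene_by_chrom = genes[genes["chrom"].isin(sequences)]
        region_levels: list[tuple[str, int, int, float]] = []
        for g in gene_by_chrom.itertuples(index=False):
            lv = gene_methylation[g.gene_id]
            region_levels.append((g.chrom, g.start - config.flank_len, g.start, lv["promoter"]))
            region_levels.append((g.chrom, g.start, g.end, lv["body"]))
            region_levels.append((g.chrom, g.end, g.end + config.flank_len, lv["downstream"]))
        for chrom in sequences:
            arr = seq_arrays[chrom]
            pos, context = _classify_contexts(arr)
            level = np.full(pos.size, config.meth_background_level)
            for rchrom, rs, re, lvl in region_levels:
                if rchrom != chrom:
                    continue
                mask = (pos >= rs) & (pos < re) & (context == "CG")
                level[mask] = lvl
            site_frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos + 1,
                        "strand": "+",
                        "context": context,
                        "level": level,
                    }
                )
            )
        truth.cg_sites = pd.concat(site_frames, ignore_index=True)
        dataset.cytosine_reports = simulate_methylation_tables(
            truth, config, rng=rngs["meth"]
        )
        # homoeologous CG-site correspondence (coordinates are alignable by
        # construction: no indels were introduced)
        map_rows = []
        for row in pairs.itertuples(index=False):
            a_arr = seq_arrays[row.chrom_a]
            b_arr = seq_arrays[row.chrom_b]
            gnum = int(row.pair_id.split(".")[1])
            gstart = (gnum - 1) * unit + config.flank_len
            span = slice(gstart - config.flank_len, gstart + glen + config.flank_len)
            a_seg = a_arr[span]
            b_seg = b_arr[span]
            cg_a = (a_seg[:-1] == 1) & (a_seg[1:] == 2)
            cg_b = (b_seg[:-1] == 1) & (b_seg[1:] == 2)
            offsets = np.nonzero(cg_a & cg_b)[0] + (gstart - config.flank_len)
            for off in offsets:
                map_rows.append(
                    {
                        "pair_id": row.pair_id,
                        "chrom_a": row.chrom_a,
                        "pos_a": int(off) + 1,
                        "chrom_b": row.chrom_b,
                        "pos_b": int(off) + 1,
                    }
                )
        dataset.site_map = pd.DataFrame(
            map_rows, columns=["pair_id", "chrom_a", "pos_a", "chrom_b", "pos_b"]
        )

    return dataset, truth
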