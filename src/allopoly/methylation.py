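"""WGBS methylation divergence statistics.

Sites come from Bismark-style cytosine reports (1-based positions). A site
is conserved when it reaches the coverage floor in every replicate; mCG
calls use a one-tailed binomial test against the bisulfite non-conversion
rate per replicate with an all-replicates consensus. The gene body test is
the exact upper-tail binomial sum against the genome-wide CG methylation
proportion pcg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenomeMethylationStats",
    "GeneMethylationSummary",
    "DmCGResult",
    "conserved_sites",
    "methylated_fraction",
    "site_level",
    "call_mcg",
    "genome_pcg",
    "body_methylation_P",
    "gene_region_extents",
    "gene_methylation_summaries",
    "dmcg_change_rate",
    "metagene_profile",
    "promoter_bias_test",
]

SITE_KEY = ["chrom", "pos", "strand", "context"]
DEFAULT_MIN_COV = 5
DEFAULT_ERROR_RATE = 0.01
DEFAULT_ALPHA = 0.05
REGIONS = ("promoter", "body", "downstream")


@dataclass(frozen=True)
class GenomeMethylationStats:
    n_cg_sites: int
    n_mcg_sites: int
    per_context: dict | None = None

    def __post_init__(self):
        if not 0 <= self.n_mcg_sites <= self.n_cg_sites:
            raise ValueError("methylated CG count must be within [0, total CG count]")

    @property
    def pcg(self) -> float:
        return self.n_mcg_sites / self.n_cg_sites


@dataclass(frozen=True)
class GeneMethylationSummary:
    gene_id: str
    region: str
    ncg: int
    mcg: int
    level: float  # pooled C / (C + T) over replicates
    PCG: float | None = None
    body_methylated: bool | None = None


@dataclass(frozen=True)
class DmCGResult:
    pair_id: str
    n_conserved_cg: int
    n_dmcg: int

    @property
    def change_rate(self) -> float:
        return self.n_dmcg / self.n_conserved_cg if self.n_conserved_cg else 0.0


def methylated_fraction(n_methylated: int, n_total: int) -> float:
    """Fraction of methylated cytosines among all conserved cytosines."""
    if n_total <= 0:
        raise ValueError("total cytosine count must be positive")
    if not 0 <= n_methylated <= n_total:
        raise ValueError("methylated count must be within [0, total]")
    return n_methylated / n_total


def conserved_sites(
    tables: Sequence[pd.DataFrame], min_cov: int = DEFAULT_MIN_COV
) -> pd.DataFrame:
    """Merge replicate cytosine reports and keep sites covered by at least
    ``min_cov`` reads in every replicate.

    Returns a frame keyed by (chrom, pos, strand, context) with columns
    ``C_<i>`` / ``T_<i>`` per replicate plus pooled ``level``.
    """
    if not tables:
        raise ValueError("need at least one replicate table")
    keys = [pd.MultiIndex.from_frame(t[SITE_KEY]) for t in tables]
    for i, key in enumerate(keys[1:], start=2):
        if not keys[0].equals(key):
            raise ValueError(
                f"replicate 1 and replicate {i} report different site coordinates"
            )
    merged = tables[0][SITE_KEY].copy()
    keep = np.ones(len(merged), dtype=bool)
    c_total = np.zeros(len(merged))
    t_total = np.zeros(len(merged))
    for i, table in enumerate(tables, start=1):
        c = table["count_methylated"].to_numpy(dtype=np.int64)
        t = table["count_unmethylated"].to_numpy(dtype=np.int64)
        merged[f"C_{i}"] = c
        merged[f"T_{i}"] = t
        keep &= (c + t) >= min_cov
        c_total += c
        t_total += t
    merged = merged[keep].reset_index(drop=True)
    cov = (c_total + t_total)[keep]
    merged["level"] = np.where(cov > 0, c_total[keep] / np.maximum(cov, 1), 0.0)
    merged.attrs["n_replicates"] = len(tables)
    return merged


def site_level(C: int, T: int) -> float:
    """Methylation level of one cytosine site: C / (C + T)."""
    if C < 0 or T < 0:
        raise ValueError("read counts must be non-negative")
    if C + T == 0:
        raise ValueError("site has zero coverage")
    return C / (C + T)


def call_mcg(
    sites: pd.DataFrame,
    error_rate: float = DEFAULT_ERROR_RATE,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Binomial methylation calls on conserved sites.

    Per replicate i, a site is methylated when the one-tailed binomial
    P(X >= C | n = C + T, p = error_rate) is below alpha; the consensus
    ``methylated`` flag requires every replicate to agree.
    """
    if not 0 < error_rate < 1:
        raise ValueError("error_rate must be in (0, 1)")
    n_rep = sites.attrs.get("n_replicates") or sum(
        1 for c in sites.columns if c.startswith("C_")
    )
    if n_rep == 0:
        raise ValueError("sites frame carries no replicate count columns")
    out = sites.copy()
    consensus = np.ones(len(sites), dtype=bool)
    for i in range(1, n_rep + 1):
        c = sites[f"C_{i}"].to_numpy(dtype=np.int64)
        t = sites[f"T_{i}"].to_numpy(dtype=np.int64)
        n = c + t
        if (n == 0).any():
            raise ValueError("non-conserved (zero-coverage) site in input")
        pvals = stats.binom.sf(c - 1, n, error_rate)
        flag = pvals < alpha
        out[f"methylated_{i}"] = flag
        consensus &= flag
    out["methylated"] = consensus
    out.attrs["n_replicates"] = n_rep
    return out


def genome_pcg(called_sites: pd.DataFrame) -> GenomeMethylationStats:
    """Genome-wide methylation statistics from consensus-called sites."""
    per_context = {}
    for context, group in called_sites.groupby("context"):
        per_context[context] = {
            "n_sites": int(len(group)),
            "n_methylated": int(group["methylated"].sum()),
        }
    cg = called_sites[called_sites["context"] == "CG"]
    if cg.empty:
        raise ValueError("no CG sites among conserved sites")
    return GenomeMethylationStats(
        n_cg_sites=int(len(cg)),
        n_mcg_sites=int(cg["methylated"].sum()),
        per_context=per_context,
    )


def body_methylation_P(ncg: int, mcg: int, pcg: float) -> float:
    """Exact upper-tail binomial sum:
    PCG = sum_{i=mcg}^{ncg} C(ncg, i) pcg^i (1-pcg)^(ncg-i)."""
    if not 0 <= mcg <= ncg:
        raise ValueError("require 0 <= mcg <= ncg")
    if not 0 < pcg < 1:
        raise ValueError("pcg must be in (0, 1)")
    return float(stats.binom.sf(mcg - 1, ncg, pcg))


def gene_region_extents(
    genes: pd.DataFrame,
    promoter_len: int = 2000,
    downstream_len: int = 2000,
) -> pd.DataFrame:
    """Strand-aware promoter/body/downstream extents (0-based half-open).

    The promoter is 5' of the TSS on the coding strand; downstream is past
    the TES.
    """
    rows = []
    for g in genes.itertuples(index=False):
        start, end = int(g.start), int(g.end)
        if g.strand == "+":
            regions = {
                "promoter": (max(0, start - promoter_len), start),
                "body": (start, end),
                "downstream": (end, end + downstream_len),
            }
        elif g.strand == "-":
            regions = {
                "promoter": (end, end + promoter_len),
                "body": (start, end),
                "downstream": (max(0, start - downstream_len), start),
            }
        else:
            raise ValueError(f"gene {g.gene_id} has unknown strand {g.strand!r}")
        for region, (rs, re) in regions.items():
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "chrom": g.chrom,
                    "region": region,
                    "start": rs,
                    "end": re,
                    "strand": g.strand,
                }
            )
    return pd.DataFrame(rows)


def _sites_in_region(
    sites: pd.DataFrame, chrom: str, start: int, end: int
) -> pd.DataFrame:
    pos0 = sites["pos"] - 1  # cytosine reports are 1-based
    return sites[(sites["chrom"] == chrom) & (pos0 >= start) & (pos0 < end)]


def gene_methylation_summaries(
    called_sites: pd.DataFrame,
    regions: pd.DataFrame,
    pcg: float,
    alpha: float = DEFAULT_ALPHA,
) -> list[GeneMethylationSummary]:
    """Per-gene, per-region CG methylation summaries; the Eq-style binomial
    tail probability and the body-methylated flag are computed on the body
    region."""
    cg = called_sites[called_sites["context"] == "CG"]
    out = []
    for row in regions.itertuples(index=False):
        sub = _sites_in_region(cg, row.chrom, int(row.start), int(row.end))
        ncg = int(len(sub))
        mcg = int(sub["methylated"].sum())
        level = float(sub["level"].mean()) if ncg else float("nan")
        if row.region == "body" and ncg > 0:
            P = body_methylation_P(ncg, mcg, pcg)
            flagged = P < alpha
        else:
            P, flagged = None, None
        out.append(
            GeneMethylationSummary(
                gene_id=row.gene_id,
                region=row.region,
                ncg=ncg,
                mcg=mcg,
                level=level,
                PCG=P,
                body_methylated=flagged,
            )
        )
    return out


def dmcg_change_rate(
    site_map: pd.DataFrame,
    called_a: pd.DataFrame,
    called_b: pd.DataFrame,
    pair_id: str = "pair",
) -> DmCGResult:
    """Differentially methylated CG rate over corresponding conserved sites.

    ``site_map`` holds the homoeologous site correspondence with columns
    chrom_a/pos_a/chrom_b/pos_b (1-based). A site counts as DmCG when it is
    methylated in every replicate of one copy and unmethylated in every
    replicate of the other.
    """
    if site_map.empty:
        raise ValueError("empty homoeologous site correspondence")
    n_rep_a = called_a.attrs.get("n_replicates", 1)
    n_rep_b = called_b.attrs.get("n_replicates", 1)

    def _flags(called: pd.DataFrame, n_rep: int, chrom_col, pos_col):
        idx = pd.MultiIndex.from_frame(called[["chrom", "pos"]])
        per_rep = called[[f"methylated_{i}" for i in range(1, n_rep + 1)]]
        all_meth = pd.Series(per_rep.all(axis=1).to_numpy(), index=idx)
        all_unmeth = pd.Series((~per_rep).all(axis=1).to_numpy(), index=idx)
        key = pd.MultiIndex.from_frame(site_map[[chrom_col, pos_col]].set_axis(["chrom", "pos"], axis=1))
        return (
            all_meth.reindex(key).to_numpy(),
            all_unmeth.reindex(key).to_numpy(),
        )

    meth_a, unmeth_a = _flags(called_a, n_rep_a, "chrom_a", "pos_a")
    meth_b, unmeth_b = _flags(called_b, n_rep_b, "chrom_b", "pos_b")
    present = (
        ~pd.isna(meth_a) & ~pd.isna(meth_b) & ~pd.isna(unmeth_a) & ~pd.isna(unmeth_b)
    )
    meth_a = meth_a[present].astype(bool)
    meth_b = meth_b[present].astype(bool)
    unmeth_a = unmeth_a[present].astype(bool)
    unmeth_b = unmeth_b[present].astype(bool)
    dmcg = (meth_a & unmeth_b) | (meth_b & unmeth_a)
    return DmCGResult(
        pair_id=pair_id, n_conserved_cg=int(present.sum()), n_dmcg=int(dmcg.sum())
    )


def metagene_profile(
    genes: pd.DataFrame,
    called_sites: pd.DataFrame,
    regions: pd.DataFrame,
    n_bins: int = 20,
) -> tuple[dict[str, np.ndarray], int]:
    """Binned mean CG methylation level per region across a gene set.

    Bins are ordered 5'->3' on the coding strand. Returns ({region: bin
    means}, n_genes_without_sites).
    """
    cg = called_sites[called_sites["context"] == "CG"]
    gene_ids = set(genes["gene_id"])
    sums = {r: np.zeros(n_bins) for r in REGIONS}
    counts = {r: np.zeros(n_bins) for r in REGIONS}
    genes_with_sites = set()
    for row in regions.itertuples(index=False):
        if row.gene_id not in gene_ids:
            continue
        sub = _sites_in_region(cg, row.chrom, int(row.start), int(row.end))
        if sub.empty:
            continue
        genes_with_sites.add(row.gene_id)
        length = int(row.end) - int(row.start)
        rel = (sub["pos"].to_numpy(dtype=float) - 1 - int(row.start)) / length
        if row.strand == "-":
            rel = 1.0 - rel - 1.0 / length  # mirror so bins run 5'->3'
        bins = np.clip((rel * n_bins).astype(int), 0, n_bins - 1)
        np.add.at(sums[row.region], bins, sub["level"].to_numpy(dtype=float))
        np.add.at(counts[row.region], bins, 1.0)
    profiles = {}
    for region in REGIONS:
        with np.errstate(invalid="ignore"):
            profiles[region] = np.where(
                counts[region] > 0, sums[region] / np.maximum(counts[region], 1), np.nan
            )
    n_missing = len(gene_ids - genes_with_sites)
    return profiles, n_missing


def promoter_bias_test(
    dominant_levels: Sequence[float],
    suppressed_levels: Sequence[float],
    test: str = "mannwhitney",
) -> tuple[float, float, bool]:
    """One-sided test that dominant-copy promoter methylation is lower.

    Returns (p_value, mean difference dominant - suppressed, low_power
    flag). ``test`` is 'mannwhitney' (default) or 'ttest'.
    """
    dom = np.asarray([x for x in dominant_levels if np.isfinite(x)], dtype=float)
    sup = np.asarray([x for x in suppressed_levels if np.isfinite(x)], dtype=float)
    if dom.size == 0 or sup.size == 0:
        raise ValueError("both gene sets must be non-empty")
    low_power = dom.size < 3 or sup.size < 3
    if low_power:
        warnings.warn("promoter bias test on fewer than 3 genes per set", stacklevel=2)
    if test == "mannwhitney":
        p = float(stats.mannwhitneyu(dom, sup, alternative="less").pvalue)
    elif test == "ttest":
        p = float(stats.ttest_ind(dom, sup, alternative="less", equal_var=False).pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return p, float(dom.mean() - sup.mean()), low_power
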