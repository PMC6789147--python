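"""Divergence estimation and event dating.

Implements Nei–Gojobori (1986) synonymous/nonsynonymous counting with
Jukes–Cantor multiple-hit correction, kernel-density peak finding on Ks
distributions, molecular-clock dating T = K / (2 r), per-chromosome Ka/Ks
asymmetry testing, transposable-element divergence landscapes and the
proportional merger-time estimate from the non-overlapping TE interval.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import stats

__all__ = [
    "CodonAlignment",
    "KsRecord",
    "ClockModel",
    "TEDivergenceProfile",
    "SegregationInterval",
    "count_sites_ng86",
    "jc_distance",
    "estimate_ka_ks",
    "kaks_table",
    "ks_distribution_mode",
    "clock_date",
    "chromosome_kaks_summary",
    "te_profile",
    "detect_segregation_interval",
    "merger_time",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


def _codon_str(index: int) -> str:
    return _BASES[index // 16] + _BASES[(index // 4) % 4] + _BASES[index % 4]


def _build_code() -> tuple[dict[int, str], frozenset[int]]:
    table = CodonTable.unambiguous_dna_by_id[1]
    translation: dict[int, str] = {}
    stops = set()
    for i in range(64):
        codon = _codon_str(i)
        if codon in table.stop_codons:
            stops.add(i)
            translation[i] = "*"
        else:
            translation[i] = table.forward_table[codon]
    return translation, frozenset(stops)


_TRANSLATE, _STOPS = _build_code()


def _neighbours(codon: int, pos: int) -> list[int]:
    base = (codon // (4 ** (2 - pos))) % 4
    out = []
    for alt in range(4):
        if alt != base:
            out.append(codon + (alt - base) * 4 ** (2 - pos))
    return out


def _build_site_table() -> np.ndarray:
    """Synonymous site count per codon (sum over the three positions of the
    fraction of the three possible changes that are synonymous; changes to
    stop codons count as nonsynonymous so that S + N = 3 per codon)."""
    syn = np.zeros(64)
    for c in range(64):
        if c in _STOPS:
            continue
        aa = _TRANSLATE[c]
        n_syn = 0
        for pos in range(3):
            for alt in _neighbours(c, pos):
                if alt not in _STOPS and _TRANSLATE[alt] == aa:
                    n_syn += 1
        syn[c] = n_syn / 3.0
    return syn


def _path_steps(c1: int, c2: int, order: Sequence[int]) -> tuple[float, float, bool]:
    """Walk from c1 to c2 changing positions in `order`; return (sd, nd, valid)
    where valid is False if the path passes through a stop codon."""
    sd = nd = 0.0
    cur = c1
    for pos in order:
        target_base = (c2 // (4 ** (2 - pos))) % 4
        cur_base = (cur // (4 ** (2 - pos))) % 4
        nxt = cur + (target_base - cur_base) * 4 ** (2 - pos)
        if _TRANSLATE[cur] == _TRANSLATE[nxt]:
            sd += 1
        else:
            nd += 1
        if nxt in _STOPS and nxt != c2:
            return sd, nd, False
        cur = nxt
    return sd, nd, True


def _build_pair_tables() -> tuple[np.ndarray, np.ndarray]:
    sd_tab = np.zeros((64, 64))
    nd_tab = np.zeros((64, 64))
    for c1 in range(64):
        if c1 in _STOPS:
            continue
        for c2 in range(64):
            if c2 in _STOPS or c2 == c1:
                continue
            positions = [p for p in range(3)
                         if (c1 // (4 ** (2 - p))) % 4 != (c2 // (4 ** (2 - p))) % 4]
            paths = []
            invalid = []
            for order in itertools.permutations(positions):
                sd, nd, ok = _path_steps(c1, c2, order)
                (paths if ok else invalid).append((sd, nd))
            if not paths:  # all orderings pass through a stop: fall back
                paths = invalid
            sd_tab[c1, c2] = float(np.mean([p[0] for p in paths]))
            nd_tab[c1, c2] = float(np.mean([p[1] for p in paths]))
    return sd_tab, nd_tab


_SYN_SITES = _build_site_table()
_PAIR_SD, _PAIR_ND = _build_pair_tables()


def encode_codons(sequence: str) -> np.ndarray:
    """Encode a nucleotide string into an int array of codon indices (0..63)."""
    seq = sequence.upper()
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    try:
        arr = np.array([_BASE_INDEX[b] for b in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-ACGT base in sequence: {exc}") from None
    return arr[0::3] * 16 + arr[1::3] * 4 + arr[2::3]


@dataclass(frozen=True)
class CodonAlignment:
    """A gapless pair of equal-length coding sequences."""

    gene_a: str
    gene_b: str
    codons_a: str
    codons_b: str

    def __post_init__(self):
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("aligned sequences differ in length")
        if len(self.codons_a) % 3 != 0:
            raise ValueError("alignment length is not a multiple of 3")


@dataclass(frozen=True)
class KsRecord:
    pair_id: str
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ks: float
    ka: float
    omega: float | None  # None when ks == 0 (undefined)


@dataclass(frozen=True)
class ClockModel:
    """Molecular clock: substitutions per synonymous site per year."""

    r: float = 3.51e-9

    def __post_init__(self):
        if self.r <= 0:
            raise ValueError("clock rate must be positive")


def _check_stops(codons: np.ndarray, label: str) -> None:
    stop_mask = np.isin(codons, list(_STOPS))
    if stop_mask.any():
        idx = int(np.nonzero(stop_mask)[0][0])
        raise ValueError(f"stop codon at codon index {idx} in {label}")


def count_sites_ng86(alignment: CodonAlignment) -> tuple[float, float, float, float]:
    """NG86 site and difference counts: returns (S, N, Sd, Nd).

    S and N are averaged over the two sequences; multi-hit codons average
    over all orderings of single-step mutational paths (paths through stop
    codons discarded when an alternative exists).
    """
    ca = encode_codons(alignment.codons_a)
    cb = encode_codons(alignment.codons_b)
    _check_stops(ca, alignment.gene_a)
    _check_stops(cb, alignment.gene_b)
    s_sites = 0.5 * (_SYN_SITES[ca].sum() + _SYN_SITES[cb].sum())
    n_sites = 3.0 * len(ca) - s_sites
    sd = _PAIR_SD[ca, cb].sum()
    nd = _PAIR_ND[ca, cb].sum()
    return float(s_sites), float(n_sites), float(sd), float(nd)


def jc_distance(p: float) -> float:
    """Jukes–Cantor corrected distance d = -(3/4) ln(1 - 4p/3)."""
    if p < 0:
        raise ValueError("proportion of differing sites must be non-negative")
    if p >= 0.75:
        raise ValueError(f"p = {p} is at or beyond JC saturation (p >= 0.75)")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def estimate_ka_ks(alignment: CodonAlignment, pair_id: str | None = None) -> KsRecord:
    """Ka/Ks for one pair: NG86 counts with Jukes–Cantor correction."""
    s_sites, n_sites, sd, nd = count_sites_ng86(alignment)
    if s_sites == 0:
        raise ValueError("no synonymous sites in alignment")
    if n_sites == 0:
        raise ValueError("no nonsynonymous sites in alignment")
    ks = jc_distance(sd / s_sites)
    ka = jc_distance(nd / n_sites)
    omega = ka / ks if ks > 0 else None
    return KsRecord(
        pair_id=pair_id or f"{alignment.gene_a}|{alignment.gene_b}",
        s_sites=s_sites,
        n_sites=n_sites,
        sd=sd,
        nd=nd,
        ks=float(ks),
        ka=float(ka),
        omega=None if omega is None else float(omega),
    )


def kaks_table(pairs: Iterable[tuple[str, str, str]]) -> pd.DataFrame:
    """Vectorised Ka/Ks over many (pair_id, seq_a, seq_b) tuples.

    Pairs that are synonymous-saturated (p >= 0.75) get NaN ks.
    """
    rows = []
    for pair_id, seq_a, seq_b in pairs:
        ca = encode_codons(seq_a)
        cb = encode_codons(seq_b)
        _check_stops(ca, pair_id)
        _check_stops(cb, pair_id)
        s_sites = 0.5 * (_SYN_SITES[ca].sum() + _SYN_SITES[cb].sum())
        n_sites = 3.0 * len(ca) - s_sites
        sd = _PAIR_SD[ca, cb].sum()
        nd = _PAIR_ND[ca, cb].sum()
        ps = sd / s_sites if s_sites > 0 else np.nan
        pn = nd / n_sites if n_sites > 0 else np.nan
        ks = jc_distance(ps) if 0 <= ps < 0.75 else np.nan
        ka = jc_distance(pn) if 0 <= pn < 0.75 else np.nan
        omega = ka / ks if np.isfinite(ks) and ks > 0 and np.isfinite(ka) else np.nan
        rows.append((pair_id, s_sites, n_sites, sd, nd, ks, ka, omega))
    return pd.DataFrame(
        rows, columns=["pair_id", "S", "N", "Sd", "Nd", "ks", "ka", "omega"]
    )


def _round_sig(x: float, sig: int = 3) -> float:
    if x == 0:
        return 0.0
    return float(np.format_float_positional(x, precision=sig, fractional=False))


def ks_distribution_mode(
    ks_values: Sequence[float],
    bandwidth: float | str | None = None,
    height_floor: float = 0.01,
    grid_points: int = 1024,
) -> list[float]:
    """Local maxima of a Gaussian-kernel density of Ks values.

    Modes are sorted by descending density height, reported to three
    significant figures; peaks below ``height_floor`` of the highest density
    are suppressed. Bandwidth defaults to Silverman's rule.
    """
    values = np.asarray([v for v in ks_values if np.isfinite(v)], dtype=float)
    if values.size == 0:
        raise ValueError("no finite Ks values supplied")
    if values.size < 10:
        raise ValueError("need at least 10 finite Ks values for a density mode")
    if np.ptp(values) == 0:
        return [_round_sig(float(values[0]))]
    kde = stats.gaussian_kde(values, bw_method=bandwidth or "silverman")
    h = kde.factor * values.std(ddof=1)
    grid = np.linspace(values.min() - 3 * h, values.max() + 3 * h, grid_points)
    density = kde(grid)
    interior = (density[1:-1] > density[:-2]) & (density[1:-1] >= density[2:])
    peaks = np.nonzero(interior)[0] + 1
    peaks = peaks[density[peaks] >= height_floor * density.max()]
    order = np.argsort(density[peaks])[::-1]
    return [_round_sig(float(grid[p])) for p in peaks[order]]


def clock_date(K: float, clock: ClockModel = ClockModel()) -> float:
    """Molecular clock divergence time in years: T = K / (2 r)."""
    if K < 0:
        raise ValueError("substitution distance must be non-negative")
    return K / (2.0 * clock.r)


@dataclass(frozen=True)
class ChromKaKsSummary:
    per_chromosome: pd.DataFrame  # chrom, subgenome, n, mean_omega
    mean_a: float
    mean_b: float
    p_value: float
    n_pairs: int
    n_undefined: int
    low_power: bool


def chromosome_kaks_summary(
    pairs: Sequence[tuple[str, str]],
    omega: Mapping[str, float],
    gene_to_chrom: Mapping[str, str],
    chrom_to_subgenome: Mapping[str, str],
) -> ChromKaKsSummary:
    """Per-chromosome mean omega plus a paired two-sided Wilcoxon signed-rank
    test over gene-level (omega_A, omega_B) pairs.

    ``pairs`` holds (gene_a, gene_b) with genes in subgenome A and B
    respectively (per ``chrom_to_subgenome``); omega maps gene id to its
    Ka/Ks against the diploid outgroup. Undefined (NaN) omegas are excluded
    and counted.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 homoeolog pairs")
    per_gene_rows = []
    oa, ob = [], []
    n_undef = 0
    for g1, g2 in pairs:
        w1, w2 = omega.get(g1, np.nan), omega.get(g2, np.nan)
        lab1 = chrom_to_subgenome[gene_to_chrom[g1]]
        lab2 = chrom_to_subgenome[gene_to_chrom[g2]]
        if {lab1, lab2} != {"A", "B"}:
            raise ValueError(f"pair ({g1}, {g2}) does not span subgenomes A and B")
        wa, wb = (w1, w2) if lab1 == "A" else (w2, w1)
        for g, w in ((g1, w1), (g2, w2)):
            if w is not None and np.isfinite(w):
                per_gene_rows.append((gene_to_chrom[g], chrom_to_subgenome[gene_to_chrom[g]], w))
        if (
            wa is not None and wb is not None
            and np.isfinite(wa) and np.isfinite(wb)
        ):
            oa.append(wa)
            ob.append(wb)
        else:
            n_undef += 1
    oa_arr, ob_arr = np.asarray(oa), np.asarray(ob)
    if oa_arr.size == 0:
        raise ValueError("no pairs with defined omega on both sides")
    for label, arr in (("A", oa_arr), ("B", ob_arr)):
        if arr.size == 0:
            raise ValueError(f"subgenome {label} has no defined omega values")
    per_gene = pd.DataFrame(per_gene_rows, columns=["chrom", "subgenome", "omega"])
    per_chrom = (
        per_gene.groupby(["chrom", "subgenome"], as_index=False)
        .agg(n=("omega", "size"), mean_omega=("omega", "mean"))
        .sort_values("chrom")
        .reset_index(drop=True)
    )
    diffs = oa_arr - ob_arr
    if np.all(diffs == 0):
        p_value = 1.0
    else:
        p_value = float(stats.wilcoxon(oa_arr, ob_arr, alternative="two-sided").pvalue)
    return ChromKaKsSummary(
        per_chromosome=per_chrom,
        mean_a=float(oa_arr.mean()),
        mean_b=float(ob_arr.mean()),
        p_value=p_value,
        n_pairs=int(oa_arr.size),
        n_undefined=n_undef,
        low_power=oa_arr.size < 10,
    )


@dataclass(frozen=True)
class TEDivergenceProfile:
    """Binned TE mass (percent of subgenome size) per percent-divergence bin."""

    subgenome: str
    bin_edges: np.ndarray  # length n_bins + 1, contiguous
    mass: np.ndarray  # percent of subgenome size per bin

    def __post_init__(self):
        if np.any(self.mass < 0):
            raise ValueError("bin mass must be non-negative")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def total_mass(self) -> float:
        return float(self.mass.sum())


@dataclass(frozen=True)
class SegregationInterval:
    """Percent-divergence bounds of the non-overlapping region."""

    d_low: float
    d_high: float

    def __post_init__(self):
        if not (0 <= self.d_low < self.d_high):
            raise ValueError("require 0 <= d_low < d_high")


def te_profile(
    te_table: pd.DataFrame,
    chrom_to_subgenome: Mapping[str, str],
    subgenome_sizes: Mapping[str, float],
    bin_width: float = 1.0,
    max_div: float | None = None,
) -> dict[str, TEDivergenceProfile]:
    """TE divergence landscape: per-bin TE base pairs as percent of
    subgenome size, for each subgenome."""
    unknown = sorted(set(te_table["chrom"]) - set(chrom_to_subgenome))
    if unknown:
        raise ValueError(f"TE records on unassigned chromosomes: {unknown}")
    labels = te_table["chrom"].map(chrom_to_subgenome)
    top = float(max_div) if max_div is not None else float(te_table["perc_div"].max()) if len(te_table) else bin_width
    n_bins = max(1, int(np.ceil(top / bin_width + 1e-9)))
    edges = np.arange(n_bins + 1, dtype=float) * bin_width
    profiles = {}
    for label, size in subgenome_sizes.items():
        if size <= 0:
            raise ValueError(f"subgenome {label} has non-positive size")
        sub = te_table[labels == label]
        lengths = (sub["end"] - sub["start"]).to_numpy(dtype=float)
        mass, _ = np.histogram(
            sub["perc_div"].to_numpy(dtype=float), bins=edges, weights=lengths
        )
        profiles[label] = TEDivergenceProfile(
            subgenome=label, bin_edges=edges, mass=mass / float(size) * 100.0
        )
    return profiles


def detect_segregation_interval(
    profile_a: TEDivergenceProfile,
    profile_b: TEDivergenceProfile,
    rel_threshold: float = 0.25,
) -> SegregationInterval | None:
    """Maximal contiguous run of bins whose relative mass difference exceeds
    the threshold; returns its divergence bounds or None if no bin differs."""
    if profile_a.bin_edges.shape != profile_b.bin_edges.shape or not np.allclose(
        profile_a.bin_edges, profile_b.bin_edges
    ):
        raise ValueError("profiles have mismatched bins")
    ma, mb = profile_a.mass, profile_b.mass
    peak = np.maximum(ma, mb)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(peak > 0, np.abs(ma - mb) / peak, 0.0)
    exceeds = rel > rel_threshold
    if not exceeds.any():
        return None
    best_start = best_len = cur_start = cur_len = 0
    for i, flag in enumerate(exceeds):
        if flag:
            if cur_len == 0:
                cur_start = i
            cur_len += 1
            if cur_len > best_len:
                best_start, best_len = cur_start, cur_len
        else:
            cur_len = 0
    edges = profile_a.bin_edges
    return SegregationInterval(
        d_low=float(edges[best_start]), d_high=float(edges[best_start + best_len])
    )


def merger_time(t_div: float, interval: SegregationInterval) -> float:
    """Genome merger time from the proportional TE-divergence rule
    T_merge = T_div * d_low / d_high."""
    if t_div <= 0:
        raise ValueError("t_div must be positive")
    if interval.d_high == 0:
        raise ValueError("interval upper edge must be positive")
    return t_div * interval.d_low / interval.d_high
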