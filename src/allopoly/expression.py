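"""Homoeolog expression bias, co-expression clustering, functional fates and
the summed-expression stress comparison.

All fold comparisons use a +1 pseudocount on FPKM so that ratios are defined
at zero; ``pseudocount=0`` switches to raw ratios with zero-denominator pairs
routed to the extreme class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "BiasSummary",
    "filter_expressed",
    "dominance_labels",
    "tissue_dominance",
    "bias_summary",
    "extreme_bias",
    "coexpression_clusters",
    "triplet_fate",
    "stress_deg_summed",
]

FATE_LABELS = (
    "conserved",
    "subfunctionalization-candidate",
    "neofunctionalization-candidate-A",
    "neofunctionalization-candidate-B",
    "nonfunctionalization-A",
    "nonfunctionalization-B",
)


@dataclass(frozen=True)
class BiasSummary:
    """Counts of homoeolog pairs with tissue-level expression bias.

    Identities: n_biased = n_higher_a + n_higher_b - n_swinging;
    exclusives are higher counts minus the swinging overlap.
    """

    n_higher_a: int
    n_higher_b: int
    n_swinging: int

    @property
    def n_biased(self) -> int:
        return self.n_higher_a + self.n_higher_b - self.n_swinging

    @property
    def n_exclusive_a(self) -> int:
        return self.n_higher_a - self.n_swinging

    @property
    def n_exclusive_b(self) -> int:
        return self.n_higher_b - self.n_swinging

    @property
    def dominance_direction(self) -> str:
        if self.n_exclusive_a == self.n_exclusive_b:
            return "balanced"
        return "A" if self.n_exclusive_a > self.n_exclusive_b else "B"

    def as_dict(self) -> dict:
        return {
            "n_biased": self.n_biased,
            "n_higher_a": self.n_higher_a,
            "n_higher_b": self.n_higher_b,
            "n_exclusive_a": self.n_exclusive_a,
            "n_exclusive_b": self.n_exclusive_b,
            "n_swinging": self.n_swinging,
            "dominance_direction": self.dominance_direction,
        }


def filter_expressed(
    matrix: pd.DataFrame, threshold: float = 1.0
) -> tuple[pd.Index, pd.DataFrame]:
    """Keep genes with FPKM strictly above threshold in at least one tissue;
    return the kept index and the log2(FPKM + 1)-transformed kept matrix."""
    if matrix.empty:
        raise ValueError("empty expression matrix")
    if (matrix < 0).any().any():
        raise ValueError("FPKM values must be non-negative")
    kept = matrix.index[(matrix > threshold).any(axis=1)]
    return kept, np.log2(matrix.loc[kept] + 1.0)


def dominance_labels(
    fpkm_a: pd.DataFrame,
    fpkm_b: pd.DataFrame,
    fold: float = 2.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-pair, per-tissue dominance labels over aligned A/B matrices.

    Label 'A' where (FPKM_A + c)/(FPKM_B + c) > fold, 'B' for the inverse,
    'neutral' otherwise. With ``pseudocount=0`` a zero denominator with a
    positive numerator counts as dominant.
    """
    if fold <= 1:
        raise ValueError("fold must be > 1")
    if fpkm_a.shape != fpkm_b.shape:
        raise ValueError("A and B matrices must be aligned")
    a = fpkm_a.to_numpy(dtype=float) + pseudocount
    b = fpkm_b.to_numpy(dtype=float) + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        a_dom = np.where(b > 0, a > fold * b, a > 0)
        b_dom = np.where(a > 0, b > fold * a, b > 0)
    labels = np.full(a.shape, "neutral", dtype=object)
    labels[a_dom] = "A"
    labels[b_dom] = "B"
    return pd.DataFrame(labels, index=fpkm_a.index, columns=fpkm_a.columns)


def tissue_dominance(
    fpkm_a: pd.Series, fpkm_b: pd.Series, fold: float = 2.0, pseudocount: float = 1.0
) -> pd.Series:
    """Dominance labels for a single homoeolog pair across tissues."""
    frame = dominance_labels(
        fpkm_a.to_frame().T, fpkm_b.to_frame().T, fold=fold, pseudocount=pseudocount
    )
    return frame.iloc[0]


def bias_summary(labels: pd.DataFrame) -> BiasSummary:
    """Summarise a per-pair x per-tissue label matrix.

    higher_a/b = pairs with at least one A/B-dominant tissue; swinging =
    pairs in both sets.
    """
    any_a = (labels == "A").any(axis=1)
    any_b = (labels == "B").any(axis=1)
    return BiasSummary(
        n_higher_a=int(any_a.sum()),
        n_higher_b=int(any_b.sum()),
        n_swinging=int((any_a & any_b).sum()),
    )


def extreme_bias(
    fpkm_a: pd.DataFrame,
    fpkm_b: pd.DataFrame,
    fold: float = 32.0,
    pseudocount: float = 1.0,
) -> dict[str, pd.Index]:
    """Pairs with expression difference above a high fold threshold.

    Returns exclusive-A, exclusive-B sets and their union (inclusion-
    exclusion over pairs that are extreme in both directions across
    tissues).
    """
    labels = dominance_labels(fpkm_a, fpkm_b, fold=fold, pseudocount=pseudocount)
    any_a = (labels == "A").any(axis=1)
    any_b = (labels == "B").any(axis=1)
    return {
        "exclusive_a": labels.index[any_a & ~any_b],
        "exclusive_b": labels.index[any_b & ~any_a],
        "union": labels.index[any_a | any_b],
    }


FLAT_CLUSTER = 0


def coexpression_clusters(log_matrix: pd.DataFrame, k: int = 8) -> pd.Series:
    """Agglomerative clustering with distance 1 - Pearson correlation and
    Ward linkage, cut at k clusters. Rows are z-scaled per gene first.

    Constant (zero-variance) rows cannot be correlated; they are assigned
    the designated flat cluster label 0 with a warning. Cluster labels are
    1..k.
    """
    if log_matrix.shape[1] < 2:
        raise ValueError("need at least 2 tissues to cluster")
    if log_matrix.shape[0] < k:
        raise ValueError(f"need at least k={k} genes to form k clusters")
    values = log_matrix.to_numpy(dtype=float)
    sd = values.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} constant expression rows assigned to flat cluster",
            stacklevel=2,
        )
    labels = np.full(len(values), FLAT_CLUSTER, dtype=int)
    usable = values[~flat]
    if len(usable) >= max(k, 2):
        scaled = (usable - usable.mean(axis=1, keepdims=True)) / usable.std(
            axis=1, keepdims=True
        )
        corr = np.corrcoef(scaled)
        dist = np.clip(1.0 - corr, 0.0, 2.0)
        np.fill_diagonal(dist, 0.0)
        linkage = hierarchy.linkage(squareform(dist, checks=False), method="ward")
        labels[~flat] = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    return pd.Series(labels, index=log_matrix.index, name="cluster")


def _wilcoxon_conserved_p(profile: np.ndarray, reference: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p for profile vs diploid reference."""
    diffs = profile - reference
    if np.all(diffs == 0):
        return 1.0
    return float(stats.wilcoxon(profile, reference, alternative="two-sided").pvalue)


def triplet_fate(
    diploid: pd.Series,
    copy_a: pd.Series,
    copy_b: pd.Series,
    alpha: float = 0.05,
    silent_threshold: float = 1.0,
) -> tuple[str, float, float]:
    """Classify a (diploid, A, B) expression triplet into a functional fate.

    Precedence: a copy silent everywhere while the other is expressed =>
    nonfunctionalization of the silent copy; then Wilcoxon conservation
    against the diploid orthologue decides conserved / neofunctionalization
    (on the diverged copy) / subfunctionalization.

    Returns (fate, p_a, p_b).
    """
    if not (diploid.index.equals(copy_a.index) and diploid.index.equals(copy_b.index)):
        raise ValueError("triplet profiles must share an identical tissue set")
    a = copy_a.to_numpy(dtype=float)
    b = copy_b.to_numpy(dtype=float)
    d = diploid.to_numpy(dtype=float)
    p_a = _wilcoxon_conserved_p(a, d)
    p_b = _wilcoxon_conserved_p(b, d)
    a_silent = bool(np.all(a < silent_threshold))
    b_silent = bool(np.all(b < silent_threshold))
    a_expressed = bool(np.any(a >= silent_threshold))
    b_expressed = bool(np.any(b >= silent_threshold))
    if a_silent and b_expressed:
        return "nonfunctionalization-A", p_a, p_b
    if b_silent and a_expressed:
        return "nonfunctionalization-B", p_a, p_b
    a_conserved = p_a > alpha
    b_conserved = p_b > alpha
    if a_conserved and b_conserved:
        return "conserved", p_a, p_b
    if a_conserved and not b_conserved:
        return "neofunctionalization-candidate-B", p_a, p_b
    if b_conserved and not a_conserved:
        return "neofunctionalization-candidate-A", p_a, p_b
    return "subfunctionalization-candidate", p_a, p_b


def stress_deg_summed(
    pairs: pd.DataFrame,
    treatment: pd.Series,
    control: pd.Series,
    fold: float = 2.0,
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Summed-expression stress comparison for homoeolog pairs.

    ``pairs`` needs columns gene_a / gene_b (plus optional pair_id);
    treatment and control map gene id -> FPKM. Returns (per-pair frame,
    per-gene conventional DEG flags, summary counts). Flags use a
    two-sided fold rule on pseudocounted ratios.
    """
    if fold <= 1:
        raise ValueError("fold must be > 1")
    genes = pd.Index(pairs["gene_a"]).append(pd.Index(pairs["gene_b"]))
    for name, series in (("treatment", treatment), ("control", control)):
        missing = genes.difference(series.index)
        if len(missing):
            raise ValueError(f"{name} matrix missing genes: {list(missing[:5])}")

    def _flag(num: np.ndarray, den: np.ndarray) -> np.ndarray:
        ratio = (num + pseudocount) / (den + pseudocount)
        return (ratio > fold) | (ratio < 1.0 / fold)

    conventional = pd.Series(
        _flag(treatment.loc[genes].to_numpy(float), control.loc[genes].to_numpy(float)),
        index=genes,
        name="deg",
    )
    t_sum = (
        treatment.loc[pairs["gene_a"]].to_numpy(float)
        + treatment.loc[pairs["gene_b"]].to_numpy(float)
    )
    c_sum = (
        control.loc[pairs["gene_a"]].to_numpy(float)
        + control.loc[pairs["gene_b"]].to_numpy(float)
    )
    ratio = (t_sum + pseudocount) / (c_sum + pseudocount)
    flagged = _flag(t_sum, c_sum)
    per_pair = pd.DataFrame(
        {
            "pair_id": pairs["pair_id"]
            if "pair_id" in pairs
            else [f"pair{i}" for i in range(len(pairs))],
            "treatment_sum": t_sum,
            "control_sum": c_sum,
            "summed_fold": ratio,
            "flagged": flagged,
        }
    )
    n_conv = int(conventional.sum())
    summary = {
        "n_conventional_deg": n_conv,
        "n_summed_deg": int(flagged.sum()),
        "summed_to_conventional_ratio": float(flagged.sum() / n_conv) if n_conv else np.nan,
    }
    return per_pair, conventional, summary
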