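"""Coverage-based subgenome assignment of homoeologous chromosome pairs.

Within each pair the chromosome with the higher effective coverage of the
diploid-relative alignment (ties broken by alignment identity) is labelled
B — the progenitor-B-like subgenome — and the other A. Chromosome names are
then emitted as subgenome letter + zero-padded reference chromosome number
(A01/B01 style).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "DepthWindow",
    "ChromPairAssignment",
    "effective_coverage",
    "alignment_identity",
    "assign_subgenomes",
    "assign_chromosome_names",
    "assignment_frame",
]

# "More than four mapped reads were considered effective" => depth >= 5.
DEFAULT_MIN_DEPTH = 5
DEFAULT_MIN_MARGIN = 0.05


@dataclass(frozen=True)
class DepthWindow:
    chrom: str
    start: int  # 0-based half-open
    end: int
    depth: float

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"window start must be < end ({self.chrom}:{self.start}-{self.end})")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")


@dataclass(frozen=True)
class ChromPairAssignment:
    pair_id: str
    chrom_1: str
    chrom_2: str
    coverage_1: float
    coverage_2: float
    identity_1: float | None
    identity_2: float | None
    label_1: str  # 'A' or 'B'
    label_2: str
    margin: float  # coverage_2 - coverage_1
    ambiguous: bool
    reference_homolog: str | None = None


def effective_coverage(
    windows: Sequence[DepthWindow] | pd.DataFrame,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> dict[str, float]:
    """Per-chromosome fraction of window bases at depth >= min_depth."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if isinstance(windows, pd.DataFrame):
        frame = windows
    else:
        frame = pd.DataFrame(
            [(w.chrom, w.start, w.end, w.depth) for w in windows],
            columns=["chrom", "start", "end", "depth"],
        )
    if frame.empty:
        raise ValueError("no depth windows supplied")
    if (frame["start"] >= frame["end"]).any():
        raise ValueError("window with start >= end")
    lengths = frame["end"] - frame["start"]
    effective = lengths.where(frame["depth"] >= min_depth, 0)
    total = lengths.groupby(frame["chrom"]).sum()
    if (total == 0).any():
        bad = total[total == 0].index.tolist()
        raise ValueError(f"chromosomes with zero total window length: {bad}")
    covered = effective.groupby(frame["chrom"]).sum()
    return (covered / total).to_dict()


def alignment_identity(block_stats: Mapping[str, tuple[float, float]]) -> dict[str, float]:
    """Per-chromosome identity = matched / total aligned bases."""
    out = {}
    for chrom, (matched, total) in block_stats.items():
        if total <= 0:
            raise ValueError(f"chromosome {chrom} has no aligned bases")
        if not 0 <= matched <= total:
            raise ValueError(f"chromosome {chrom}: matched must be within [0, total]")
        out[chrom] = matched / total
    return out


def assign_subgenomes(
    pairs: Sequence[tuple[str, str]] | Sequence[tuple[str, str, str]],
    coverage: Mapping[str, float],
    identity: Mapping[str, float] | None = None,
    min_margin: float = DEFAULT_MIN_MARGIN,
) -> list[ChromPairAssignment]:
    """Label each chromosome pair: higher coverage => B, lower => A.

    Ties on coverage are broken by identity; a residual exact tie is flagged
    ambiguous (labels then follow input order, chrom_1 -> A). Pairs whose
    absolute coverage margin is below ``min_margin`` are flagged ambiguous
    but still labelled.
    """
    out = []
    for i, pair in enumerate(pairs):
        if len(pair) == 3:
            pair_id, c1, c2 = pair
        else:
            c1, c2 = pair
            pair_id = f"pair{i + 1:02d}"
        for c in (c1, c2):
            if c not in coverage:
                raise ValueError(f"no coverage value for chromosome {c}")
        cov1, cov2 = float(coverage[c1]), float(coverage[c2])
        id1 = float(identity[c1]) if identity and c1 in identity else None
        id2 = float(identity[c2]) if identity and c2 in identity else None
        margin = cov2 - cov1
        ambiguous = abs(margin) < min_margin
        if cov2 > cov1:
            lab1, lab2 = "A", "B"
        elif cov1 > cov2:
            lab1, lab2 = "B", "A"
        elif id1 is not None and id2 is not None and id1 != id2:
            lab1, lab2 = ("B", "A") if id1 > id2 else ("A", "B")
        else:
            lab1, lab2 = "A", "B"  # exact tie: flagged, not silently trusted
            ambiguous = True
        out.append(
            ChromPairAssignment(
                pair_id=pair_id,
                chrom_1=c1,
                chrom_2=c2,
                coverage_1=cov1,
                coverage_2=cov2,
                identity_1=id1,
                identity_2=id2,
                label_1=lab1,
                label_2=lab2,
                margin=margin,
                ambiguous=ambiguous,
            )
        )
    return out


def assign_chromosome_names(
    assignments: Sequence[ChromPairAssignment],
    reference_homology: Mapping[str, int],
) -> dict[str, str]:
    """Map chromosome id -> subgenome letter + zero-padded reference number.

    ``reference_homology`` maps pair_id to the diploid reference chromosome
    number. Duplicate reference numbers are an error (names must be
    bijective over chromosomes).
    """
    seen: dict[int, str] = {}
    names: dict[str, str] = {}
    for a in assignments:
        if a.pair_id not in reference_homology:
            raise ValueError(f"no reference chromosome for pair {a.pair_id}")
        num = int(reference_homology[a.pair_id])
        if num in seen:
            raise ValueError(
                f"pairs {seen[num]} and {a.pair_id} both claim reference chromosome {num}"
            )
        seen[num] = a.pair_id
        names[a.chrom_1] = f"{a.label_1}{num:02d}"
        names[a.chrom_2] = f"{a.label_2}{num:02d}"
    return names


def assignment_frame(
    assignments: Sequence[ChromPairAssignment],
    names: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Long-format assignment table (one row per chromosome)."""
    rows = []
    for a in assignments:
        for chrom, cov, ident, label in (
            (a.chrom_1, a.coverage_1, a.identity_1, a.label_1),
            (a.chrom_2, a.coverage_2, a.identity_2, a.label_2),
        ):
            rows.append(
                {
                    "pair_id": a.pair_id,
                    "chrom": chrom,
                    "subgenome": label,
                    "coverage": cov,
                    "identity": ident,
                    "margin": a.margin,
                    "ambiguous": a.ambiguous,
                    "name": names.get(chrom) if names else None,
                }
            )
    return pd.DataFrame(rows)
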