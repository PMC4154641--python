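"""Genome-wide analysis of torsionally isolated gene pairs.

Selects pairs of neighbor genes that are (i) close enough to couple
torsionally — each gene's transcription unit within 5 kb of the partner's
promoter — and (ii) torsionally isolated — both promoters more than 3 kb
from any gene outside the pair — then classifies their orientation
(divergent / convergent / tandem), bins them by separation and computes
expression and co-expression statistics from a genes x experiments matrix.

Two genes of a pair count as co-expressed ("correlated") when they are
simultaneously expressed (both nonzero) in at least ``min_coexpressed``
experiments AND the Pearson correlation of their expression vectors over
all experiments exceeds ``r_threshold``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import gffutils
import numpy as np
import pandas as pd

__all__ = [
    "GeneAnnotation",
    "IsolatedPair",
    "AnnotationError",
    "read_annotations",
    "read_expression",
    "classify_orientation",
    "select_isolated_pairs",
    "pair_separation",
    "binned_statistics",
]

logger = logging.getLogger(__name__)


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene: 0-based half-open interval, strand, derived TSS."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise AnnotationError(
                f"gene {self.id!r}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.id!r}: strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tss_boundary(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class IsolatedPair:
    """An accepted neighbor-gene pair (gene_a left of gene_b)."""

    gene_a: GeneAnnotation
    gene_b: GeneAnnotation
    orientation: str
    separation: int            # intergenic gap, bp
    tss_distance: int          # TSS-to-TSS (boundary convention), bp
    correlated: Optional[bool] = None

    @property
    def upstream(self) -> GeneAnnotation:
        """Upstream member for tandem pairs (transcribed first)."""
        if self.orientation != "tandem":
            raise ValueError("upstream/downstream roles apply to tandem pairs only")
        return self.gene_a if self.gene_a.strand == "+" else self.gene_b

    @property
    def downstream(self) -> GeneAnnotation:
        if self.orientation != "tandem":
            raise ValueError("upstream/downstream roles apply to tandem pairs only")
        return self.gene_b if self.gene_a.strand == "+" else self.gene_a


def read_annotations(path, feature_type: str = "gene") -> list[GeneAnnotation]:
    """Parse a GFF3 or GTF file into gene records.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    Duplicate gene ids are rejected.
    """
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            merge_strategy="error",
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:
        raise AnnotationError(f"failed to parse {path}: {exc}") from exc
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    for feat in db.features_of_type(feature_type):
        gene_id = feat.attributes.get("gene_id", [feat.id])[0] or feat.id
        if gene_id in seen:
            raise AnnotationError(f"duplicate gene id {gene_id!r}")
        seen.add(gene_id)
        genes.append(
            GeneAnnotation(
                id=gene_id,
                chrom=feat.seqid,
                start=feat.start - 1,  # GFF is 1-based inclusive
                end=feat.end,
                strand=feat.strand,
            )
        )
    return genes


def read_expression(path) -> pd.DataFrame:
    """Read a genes x experiments TSV (first column: gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError("expression matrix contains negative entries")
    return df


def classify_orientation(a: GeneAnnotation, b: GeneAnnotation) -> str:
    """Orientation of two non-overlapping genes with ``a`` left of ``b``."""
    if a.chrom != b.chrom:
        raise ValueError("genes on different chromosomes")
    if a.start > b.start:
        raise ValueError("gene_a must be left of gene_b")
    if b.start < a.end:
        raise ValueError(f"genes {a.id!r} and {b.id!r} overlap")
    if a.strand == "-" and b.strand == "+":
        return "divergent"
    if a.strand == "+" and b.strand == "-":
        return "convergent"
    return "tandem"


def _point_interval_distance(point: int, start: int, end: int) -> int:
    """Nearest distance from a point to a half-open interval (0 if inside)."""
    if point < start:
        return start - point
    if point >= end:
        return point - end + 1
    return 0


def select_isolated_pairs(
    annotations,
    inclusion_radius: int = 5000,
    isolation_radius: int = 3000,
) -> list[IsolatedPair]:
    """Select torsionally isolated adjacent gene pairs.

    A candidate pair is two genes adjacent along the chromosome (after
    dropping genes that overlap another gene).  It is accepted when

    (i)  each gene's transcription unit comes within ``inclusion_radius``
         (nearest point) of the partner's TSS, and
    (ii) both TSSs lie more than ``isolation_radius`` from every other
         annotated transcription unit — all gene types count as
         perturbers, including non-coding genes.
    """
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in annotations:
        by_chrom.setdefault(g.chrom, []).append(g)

    pairs: list[IsolatedPair] = []
    n_overlapping = 0
    for chrom, genes in by_chrom.items():
        genes = sorted(genes, key=lambda g: (g.start, g.end))
        # drop genes overlapping any other gene (nested/overlapping)
        keep = []
        for i, g in enumerate(genes):
            overlaps = False
            for j in range(i - 1, -1, -1):
                if genes[j].end > g.start:
                    overlaps = True
                    break
                if g.start - genes[j].end > 10_000_000:
                    break
            if not overlaps:
                for j in range(i + 1, len(genes)):
                    if genes[j].start < g.end:
                        overlaps = True
                    break
            if overlaps:
                n_overlapping += 1
            else:
                keep.append(g)
        for a, b in zip(keep, keep[1:]):
            # criterion (i): mutual proximity of unit and partner promoter
            if _point_interval_distance(b.tss, a.start, a.end) >= inclusion_radius:
                continue
            if _point_interval_distance(a.tss, b.start, b.end) >= inclusion_radius:
                continue
            # criterion (ii): both promoters isolated from all other genes
            isolated = True
            for g in genes:
                if g.id in (a.id, b.id):
                    continue
                for tss in (a.tss, b.tss):
                    if _point_interval_distance(tss, g.start, g.end) <= isolation_radius:
                        isolated = False
                        break
                if not isolated:
                    break
            if not isolated:
                continue
            orientation = classify_orientation(a, b)
            pairs.append(
                IsolatedPair(
                    gene_a=a,
                    gene_b=b,
                    orientation=orientation,
                    separation=b.start - a.end,
                    tss_distance=abs(b.tss_boundary - a.tss_boundary),
                )
            )
    if n_overlapping:
        logger.info("dropped %d overlapping/nested genes before pairing", n_overlapping)
    return pairs


def pair_separation(pair: IsolatedPair, convention: str = "gap") -> int:
    """Pair separation in bp: intergenic gap (default) or TSS-to-TSS."""
    if convention == "gap":
        return pair.separation
    if convention == "tss":
        return pair.tss_distance
    raise ValueError("convention must be 'gap' or 'tss'")


def _is_correlated(
    xa: np.ndarray, xb: np.ndarray, min_coexpressed: int, r_threshold: float
) -> bool:
    joint = int(np.sum((xa > 0) & (xb > 0)))
    if joint < min_coexpressed:
        return False
    if np.std(xa) == 0 or np.std(xb) == 0:
        return False  # r undefined -> criterion fails
    r = float(np.corrcoef(xa, xb)[0, 1])
    return r > r_threshold


def binned_statistics(
    pairs,
    expr: pd.DataFrame,
    window: int = 200,
    min_coexpressed: int = 6,
    r_threshold: float = 0.5,
    separation: str = "gap",
    max_separation: Optional[int] = None,
) -> dict[str, pd.DataFrame]:
    """Per-orientation, per-200-bp-window pair and expression statistics.

    Returns a dict keyed by 'divergent', 'convergent', 'tandem_upstream'
    and 'tandem_downstream'.  For the symmetric orientations each window
    aggregates both pair members (2 * count genes); the tandem tables
    aggregate the named member only.  Columns:

    n_pairs, n_correlated, expressed_fraction (nonzero (gene, experiment)
    entries over all entries), total_expression (sum of per-gene mean
    levels) and mean_expression (total / number of genes), so that for the
    two-member tables total = 2 * count * mean exactly.
    """
    missing = sorted(
        {g.id for p in pairs for g in (p.gene_a, p.gene_b)} - set(expr.index)
    )
    if missing:
        warnings.warn(
            f"{len(missing)} pair genes missing from expression matrix, "
            f"excluded: {missing[:5]}{'...' if len(missing) > 5 else ''}"
        )
        missing_set = set(missing)
        pairs = [
            p
            for p in pairs
            if p.gene_a.id not in missing_set and p.gene_b.id not in missing_set
        ]

    n_exp = expr.shape[1]
    values = expr.values
    row = {g: i for i, g in enumerate(expr.index)}

    records: dict[str, list] = {
        "divergent": [],
        "convergent": [],
        "tandem_upstream": [],
        "tandem_downstream": [],
    }
    seps = []
    for p in pairs:
        sep = pair_separation(p, separation)
        if max_separation is not None and sep >= max_separation:
            continue
        seps.append(sep)
        xa = values[row[p.gene_a.id]]
        xb = values[row[p.gene_b.id]]
        p.correlated = _is_correlated(xa, xb, min_coexpressed, r_threshold)
        b = sep // window
        if p.orientation == "tandem":
            xu = values[row[p.upstream.id]]
            xd = values[row[p.downstream.id]]
            records["tandem_upstream"].append((b, p.correlated, xu))
            records["tandem_downstream"].append((b, p.correlated, xd))
        else:
            records[p.orientation].append((b, p.correlated, xa, xb))

    n_bins = (max(seps) // window + 1) if seps else 0
    out: dict[str, pd.DataFrame] = {}
    for key, recs in records.items():
        rows = []
        for b in range(n_bins):
            sel = [r for r in recs if r[0] == b]
            count = len(sel)
            n_corr = sum(1 for r in sel if r[1])
            gene_vectors = [v for r in sel for v in r[2:]]
            if gene_vectors:
                mat = np.vstack(gene_vectors)
                expressed = float(np.mean(mat > 0))
                per_gene_mean = mat.mean(axis=1)
                total = float(per_gene_mean.sum())
                mean = total / len(gene_vectors)
            else:
                expressed, total, mean = 0.0, 0.0, 0.0
            rows.append(
                {
                    "bin_left": b * window,
                    "bin_right": (b + 1) * window,
                    "n_pairs": count,
                    "n_correlated": n_corr,
                    "expressed_fraction": expressed,
                    "total_expression": total,
                    "mean_expression": mean,
                }
            )
        out[key] = pd.DataFrame(
            rows,
            columns=[
                "bin_left",
                "bin_right",
                "n_pairs",
                "n_correlated",
                "expressed_fraction",
                "total_expression",
                "mean_expression",
            ],
        )
    return out
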