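"""Synthetic annotations, expression matrices and promoter sequences.

Everything the other modules consume can be generated here without any
download: a sparse annotation with planted gene pairs of controlled
orientation, separation and isolation status (plus a truth table), an
expression matrix with log-normal basal levels, Bernoulli dropout,
model-driven coupling folds and designated correlated pairs, and random
promoter sequences with an AT-rich core for the melting calculator.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .genomics import GeneAnnotation

__all__ = [
    "SyntheticGenomeSpec",
    "SyntheticExpressionSpec",
    "make_genome",
    "make_uniform_genome",
    "make_expression",
    "make_promoters",
    "write_gff3",
    "write_fasta",
]

_SPOILER_TSS_DISTANCE = 1800  # bp from a planted spoiler gene to the pair TSS
_SPOILED_GAP_CAP = 1500  # keeps the truth table exactly enumerable


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Layout of a planted-pair synthetic genome.

    Pairs are placed in well-separated blocks (``spacer`` bp apart, far
    beyond the inclusion radius) so that a pair's isolation status is
    decided solely by deliberately planted spoiler genes.  Spoiled pairs
    get one background gene within 3 kb of one member's TSS, violating
    the isolation criterion; their gaps are capped at 1.5 kb so that the
    incidental spoiler-member pair provably also fails isolation, keeping
    the truth table exact.
    """

    n_divergent: int = 10
    n_convergent: int = 5
    n_tandem: int = 10
    n_spoiled_divergent: int = 0
    n_spoiled_convergent: int = 0
    n_spoiled_tandem: int = 0
    n_background_genes: int = 10
    separation_range: tuple[int, int] = (200, 2800)
    gene_length: int = 1000
    spacer: int = 15000
    chrom: str = "chrsim"
    seed: int = 0


@dataclass(frozen=True)
class SyntheticExpressionSpec:
    """Distributional parameters of the synthetic expression matrix.

    24 experiments emulate the 24-cell-line design; dropout controls the
    expressed (nonzero) fraction; ``coupling_amplitude`` scales the
    log-fold applied from the pair-coupling solutions (0 = off, 1 = the
    model's folds); designated correlated pairs share a latent factor of
    strength ``correlation_strength`` and a common dropout mask.
    """

    n_experiments: int = 24
    log_mean: float = 2.0
    log_sd: float = 1.0
    dropout: float = 0.5
    coupling_amplitude: float = 0.0
    correlated_fraction: float = 0.0
    correlated_fraction_by_orientation: Optional[dict] = None
    correlated_max_gap: Optional[int] = 1000
    correlation_strength: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout <= 1.0):
            raise ValueError("dropout must be in [0, 1]")
        if not (0.0 <= self.correlation_strength <= 1.0):
            raise ValueError("correlation_strength must be in [0, 1]")


def _place_pair(orientation, cursor, gap, length, chrom, idx):
    """Return (gene_a, gene_b) of one planted pair starting at ``cursor``."""
    sa = {"divergent": "-", "convergent": "+", "tandem": "+"}[orientation]
    sb = {"divergent": "+", "convergent": "-", "tandem": "+"}[orientation]
    a = GeneAnnotation(f"pair{idx:04d}_a", chrom, cursor, cursor + length, sa)
    b = GeneAnnotation(
        f"pair{idx:04d}_b", chrom, a.end + gap, a.end + gap + length, sb
    )
    return a, b


def make_genome(spec: SyntheticGenomeSpec):
    """Generate planted-pair annotations plus a truth table.

    Returns ``(annotations, truth)`` where ``truth`` is a DataFrame with
    one row per planted pair: pair id, member ids, orientation, gap and
    ``expected_isolated`` (False exactly for the spoiled pairs).
    Background genes beyond the spoilers are placed in their own isolated
    blocks and never interfere.
    """
    rng = np.random.default_rng(spec.seed)
    n_spoiled = (
        spec.n_spoiled_divergent + spec.n_spoiled_convergent + spec.n_spoiled_tandem
    )
    if n_spoiled and spec.gene_length > 1200:
        # the fixed spoiler offset must land within 3 kb of the far-edge TSS
        # of a divergent member; longer genes would break that guarantee
        raise ValueError("spoiled pairs require gene_length <= 1200")
    plan = (
        [("divergent", False)] * spec.n_divergent
        + [("divergent", True)] * spec.n_spoiled_divergent
        + [("convergent", False)] * spec.n_convergent
        + [("convergent", True)] * spec.n_spoiled_convergent
        + [("tandem", False)] * spec.n_tandem
        + [("tandem", True)] * spec.n_spoiled_tandem
    )
    rng.shuffle(plan)

    annotations: list[GeneAnnotation] = []
    truth_rows = []
    cursor = spec.spacer
    lo, hi = spec.separation_range
    n_spoilers = 0
    for idx, (orientation, spoiled) in enumerate(plan):
        gap_hi = min(hi, _SPOILED_GAP_CAP) if spoiled else hi
        gap = int(rng.integers(lo, max(gap_hi, lo + 1) + 1))
        if spoiled:
            # spoiler sits left of gene_a: reserve room for it first
            spoiler_gap = _SPOILER_TSS_DISTANCE
            spoiler = GeneAnnotation(
                f"spoiler{n_spoilers:04d}",
                spec.chrom,
                cursor,
                cursor + spec.gene_length,
                "+",
            )
            n_spoilers += 1
            a, b = _place_pair(
                orientation,
                spoiler.end + spoiler_gap,
                gap,
                spec.gene_length,
                spec.chrom,
                idx,
            )
            # the spoiler must fall within 3 kb of a TSS of the pair:
            # distance from gene_a's nearest TSS-side edge is spoiler_gap
            # (divergent/convergent/tandem all have an edge-adjacent TSS).
            annotations += [spoiler, a, b]
        else:
            a, b = _place_pair(orientation, cursor, gap, spec.gene_length, spec.chrom, idx)
            annotations += [a, b]
        truth_rows.append(
            {
                "pair_id": f"pair{idx:04d}",
                "gene_a": a.id,
                "gene_b": b.id,
                "orientation": orientation,
                "gap": gap,
                "expected_isolated": not spoiled,
            }
        )
        cursor = b.end + spec.spacer

    for k in range(spec.n_background_genes):
        g = GeneAnnotation(
            f"bg{k:04d}", spec.chrom, cursor, cursor + spec.gene_length, "+"
        )
        annotations.append(g)
        cursor = g.end + spec.spacer

    truth = pd.DataFrame(
        truth_rows,
        columns=["pair_id", "gene_a", "gene_b", "orientation", "gap", "expected_isolated"],
    )
    return annotations, truth


def make_uniform_genome(
    n_genes: int,
    chrom_length: int,
    gene_length: int = 1000,
    seed: int = 0,
    chrom: str = "chrrand",
) -> list[GeneAnnotation]:
    """Genes placed uniformly at random (non-overlapping), random strands."""
    rng = np.random.default_rng(seed)
    free = chrom_length - n_genes * gene_length
    if free < 0:
        raise ValueError("genes do not fit on the chromosome")
    # uniform non-overlapping placement: order statistics of the free space
    gaps = np.sort(rng.integers(0, free + 1, size=n_genes))
    starts = gaps + np.arange(n_genes) * gene_length
    strands = rng.choice(["+", "-"], size=n_genes)
    return [
        GeneAnnotation(f"r{i:04d}", chrom, int(s), int(s) + gene_length, str(st))
        for i, (s, st) in enumerate(zip(starts, strands))
    ]


def make_expression(
    annotations,
    truth: pd.DataFrame,
    espec: SyntheticExpressionSpec,
    coupling_model=None,
):
    """Generate a genes x experiments matrix with planted structure.

    Per experiment: log-normal basal draw per gene, Bernoulli dropout,
    then the members of each isolated pair are multiplied by the
    pair-coupling fold-changes of their orientation/separation (scaled by
    ``coupling_amplitude`` in log space).  A ``correlated_fraction`` of
    the isolated pairs share a latent factor (and a dropout mask).

    Returns ``(expr, truth)`` where ``truth`` gains ``planted_correlated``
    and per-member ``fold_a`` / ``fold_b`` columns.
    """
    rng = np.random.default_rng(espec.seed)
    gene_ids = [g.id for g in annotations]
    by_id = {g.id: g for g in annotations}
    n_genes, n_exp = len(gene_ids), espec.n_experiments

    log_basal = rng.normal(espec.log_mean, espec.log_sd, size=(n_genes, n_exp))
    keep = rng.random(size=(n_genes, n_exp)) >= espec.dropout

    truth = truth.copy()
    iso = truth["expected_isolated"].to_numpy()
    gaps = truth["gap"].to_numpy()
    orientations = truth["orientation"].to_numpy()
    fractions = espec.correlated_fraction_by_orientation or {
        o: espec.correlated_fraction for o in ("divergent", "convergent", "tandem")
    }
    close = gaps < espec.correlated_max_gap if espec.correlated_max_gap else np.ones_like(iso)
    planted_corr = np.zeros(len(truth), dtype=bool)
    for orientation, frac in fractions.items():
        eligible = np.flatnonzero(iso & close & (orientations == orientation))
        n_corr = int(round(frac * eligible.size))
        if n_corr:
            planted_corr[rng.choice(eligible, size=n_corr, replace=False)] = True
    truth["planted_correlated"] = planted_corr

    folds = np.ones((len(truth), 2))
    if espec.coupling_amplitude != 0.0 and coupling_model is not None:
        from .coupling import build_pair, solve

        cache: dict = {}
        for i, rowt in truth.iterrows():
            if not rowt["expected_isolated"]:
                continue
            key = (rowt["orientation"], int(rowt["gap"]))
            if key not in cache:
                system = build_pair(
                    rowt["orientation"],
                    int(rowt["gap"]),
                    lengths=(
                        by_id[rowt["gene_a"]].length,
                        by_id[rowt["gene_b"]].length,
                    ),
                    promoters=coupling_model.get("promoter"),
                    torsion=coupling_model.get("torsion"),
                    distance_convention="gap",
                )
                cache[key] = solve(system).fold_changes
            folds[i] = cache[key]
    truth["fold_a"] = folds[:, 0]
    truth["fold_b"] = folds[:, 1]

    row = {g: i for i, g in enumerate(gene_ids)}
    for i, rowt in truth.iterrows():
        ia, ib = row[rowt["gene_a"]], row[rowt["gene_b"]]
        if espec.coupling_amplitude != 0.0:
            log_basal[ia] += espec.coupling_amplitude * np.log(folds[i, 0])
            log_basal[ib] += espec.coupling_amplitude * np.log(folds[i, 1])
        if rowt["planted_correlated"]:
            z = rng.normal(size=n_exp)
            s = espec.correlation_strength
            for g in (ia, ib):
                eps = (log_basal[g] - log_basal[g].mean()) / max(log_basal[g].std(), 1e-12)
                log_basal[g] = (
                    log_basal[g].mean()
                    + espec.log_sd * (s * z + np.sqrt(1.0 - s * s) * eps)
                )
            keep[ib] = keep[ia]  # shared dropout mask

    expr = np.where(keep, np.exp(log_basal), 0.0)
    df = pd.DataFrame(expr, index=pd.Index(gene_ids, name="gene_id"))
    df.columns = [f"exp{j:02d}" for j in range(n_exp)]
    return df, truth


def make_promoters(
    n: int,
    length: int = 100,
    at_fraction: float = 1.0,
    seed: int = 0,
    core_length: int = 30,
    background_at: float = 0.5,
):
    """Random promoter sequences with an AT-rich central core.

    Returns a list of (id, sequence) tuples; promoters are
    thermodynamically unstable in the core, emulating real promoter
    regions.  ``length`` must be >= 60 so flanks exist on both sides.
    """
    if length < 60:
        raise ValueError("length must be >= 60")
    if core_length > length:
        raise ValueError("core_length must be <= length")
    rng = np.random.default_rng(seed)
    at = np.array(list("AT"))
    gc = np.array(list("GC"))
    lo = (length - core_length) // 2
    hi = lo + core_length
    out = []
    for i in range(n):
        is_at = rng.random(length) < background_at
        is_at[lo:hi] = rng.random(core_length) < at_fraction
        bases = np.where(
            is_at, at[rng.integers(0, 2, length)], gc[rng.integers(0, 2, length)]
        )
        out.append((f"promoter{i:03d}", "".join(bases)))
    return out


# ---------------------------------------------------------------------------
# writers (standard text formats consumed unchanged by the other modules)
# ---------------------------------------------------------------------------

def write_gff3(annotations, path, source: str = "torsioncouple") -> None:
    """Write annotations as GFF3 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(annotations, key=lambda g: (g.chrom, g.start)):
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.id}\n"
            )


def write_fasta(records, path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqio_write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in records],
        str(path),
        "fasta",
    )
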