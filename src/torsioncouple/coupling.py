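"""Self-consistent torsional coupling of neighboring genes.

Each transcribed gene perturbs the superhelical density at its neighbors'
promoters (:mod:`torsioncouple.torsion`), which modifies their
transcription rates (:mod:`torsioncouple.transcription`), which in turn
rescales the torsional output of those genes.  The steady state is the
fixed point of

    k_i = k0_i * rho_i( sigma0 + sum_{j != i} dsigma_{j->i}(k_j) ),

solved by damped synchronous iteration starting from the rates in absence
of local supercoiling (k_i = k0_i).  A gene's own torsional lobes do not
act back on its own promoter; only partner-generated perturbations enter.

Geometry convention: ``promoter_distance`` is TSS-to-TSS, measured between
half-open TSS boundary coordinates (gene start on '+', gene end on '-');
an intergenic-gap convention is available as a switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .torsion import TorsionParameters, TranscriptionUnit, perturbation_at
from .transcription import PromoterModel, fold_change

__all__ = [
    "GeneSystem",
    "SolverOptions",
    "CouplingResult",
    "PhaseDiagram",
    "GeometryError",
    "build_pair",
    "solve",
    "influence_curve",
    "phase_diagram",
]

ORIENTATIONS = ("divergent", "convergent", "tandem")


class GeometryError(ValueError):
    """Invalid gene geometry (overlap, promoter inside a partner unit...)."""


@dataclass
class GeneSystem:
    """Transcription units with attached promoter models and a torsion field."""

    units: list
    promoters: list
    torsion: TorsionParameters

    def __post_init__(self) -> None:
        if len(self.units) != len(self.promoters):
            raise ValueError("one promoter model per unit required")
        ivs = sorted(self.units, key=lambda u: u.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end:
                raise GeometryError(f"units {a.id!r} and {b.id!r} overlap")
        for u in self.units:
            for v in self.units:
                if u is not v and v.start <= u.tss < v.end:
                    raise GeometryError(
                        f"promoter of {u.id!r} lies inside unit {v.id!r}"
                    )


@dataclass(frozen=True)
class SolverOptions:
    """Damped fixed-point iteration controls.

    ``sigma_bounds`` clamps the promoter-local sigma iterate to the
    opening model's fitted validity range; outside that range the sigmoid
    extrapolation is physically meaningless and the self-reinforcing
    divergent configuration would otherwise admit no finite fixed point.
    """

    rel_tolerance: float = 1e-8
    max_iterations: int = 10_000
    damping: float = 0.5
    sigma_bounds: tuple[float, float] = (-0.15, 0.05)

    def __post_init__(self) -> None:
        if self.rel_tolerance <= 0:
            raise ValueError("rel_tolerance must be > 0")
        if not (0 < self.damping <= 1):
            raise ValueError("damping must be in (0, 1]")


@dataclass
class CouplingResult:
    rates: np.ndarray
    fold_changes: np.ndarray
    promoter_sigma: np.ndarray
    iterations: int
    converged: bool


def build_pair(
    orientation: str,
    promoter_distance: int,
    lengths: tuple[int, int] = (1000, 1000),
    promoters: Optional[Sequence[PromoterModel]] = None,
    torsion: TorsionParameters = TorsionParameters(),
    rates: tuple[float, float] = (1.0, 1.0),
    distance_convention: str = "tss",
    origin: int = 100_000,
) -> GeneSystem:
    """Place two genes on a linear axis in a named orientation.

    divergent:  <---A   d   B--->   (upstream lobes face each other)
    convergent: A--->   d   <---B   (downstream lobes face each other)
    tandem:     A--->   d   B--->   (same strand, A upstream)

    ``promoter_distance`` is TSS-to-TSS by default; with
    ``distance_convention='gap'`` it is the intergenic gap and is converted.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    la, lb = lengths
    d = int(promoter_distance)
    if distance_convention == "gap":
        if orientation == "convergent":
            d = d + la + lb
        elif orientation == "tandem":
            d = d + la
    elif distance_convention != "tss":
        raise ValueError("distance_convention must be 'tss' or 'gap'")

    if orientation == "divergent":
        a = TranscriptionUnit("gene_a", origin, origin + la, "-", rates[0])
        b = TranscriptionUnit("gene_b", origin + la + d, origin + la + d + lb, "+", rates[1])
    elif orientation == "convergent":
        if d < la + lb:
            raise GeometryError(
                f"convergent TSS-to-TSS distance {d} < sum of lengths {la + lb}"
            )
        a = TranscriptionUnit("gene_a", origin, origin + la, "+", rates[0])
        b = TranscriptionUnit("gene_b", origin + d - lb, origin + d, "-", rates[1])
    else:  # tandem
        if d < la:
            raise GeometryError(f"tandem TSS-to-TSS distance {d} < upstream length {la}")
        a = TranscriptionUnit("gene_a", origin, origin + la, "+", rates[0])
        b = TranscriptionUnit("gene_b", origin + d, origin + d + lb, "+", rates[1])

    if promoters is None:
        promoters = [PromoterModel(opening=_default_opening()), PromoterModel(opening=_default_opening())]
    elif isinstance(promoters, PromoterModel):
        promoters = [promoters, promoters]
    else:
        promoters = list(promoters)
    return GeneSystem(units=[a, b], promoters=promoters, torsion=torsion)


def _default_opening():
    # CMV-like synthetic default used by the illustrative simulations;
    # see docs/methods.md for the choice of values.
    from .opening import SigmoidOpening

    return SigmoidOpening(sigma_c=-0.042, width=0.01, amplitude=3.0, slope=2.0, offset=2.0)


def _coupling_matrix(system: GeneSystem) -> np.ndarray:
    """M[i, j] = dsigma at promoter i per unit rate of gene j (0 on diagonal)."""
    n = len(system.units)
    m = np.zeros((n, n))
    for i, ui in enumerate(system.units):
        # boundary TSS coordinate: keeps symmetric constructions exactly
        # symmetric (no 1-bp strand bias in promoter-edge distances)
        x = ui.tss_boundary
        for j, uj in enumerate(system.units):
            if i == j:
                continue  # self-influence excluded
            m[i, j] = perturbation_at(uj.with_rate(1.0), x, system.torsion)
    return m


def solve(system: GeneSystem, opts: SolverOptions = SolverOptions()) -> CouplingResult:
    """Damped synchronous fixed-point iteration of the coupled rates.

    Initialization is the transcription rate in absence of local
    supercoiling (fold-change 1 for every gene); convergence is declared
    when the maximal relative fixed-point residual drops below
    ``rel_tolerance``.
    """
    m = _coupling_matrix(system)
    sigma0 = system.torsion.sigma0
    k0 = np.array([u.rate for u in system.units], dtype=float)
    lo, hi = opts.sigma_bounds
    k = k0.copy()
    converged = False
    iterations = 0
    sigma_p = np.full_like(k, sigma0)
    for iterations in range(1, opts.max_iterations + 1):
        sigma_p = np.clip(sigma0 + m @ k, lo, hi)
        rho = np.array(
            [fold_change(s, sigma0, p) for s, p in zip(sigma_p, system.promoters)]
        )
        target = k0 * rho
        resid = np.max(np.abs(target - k) / np.maximum(np.abs(k), 1e-300))
        k = (1.0 - opts.damping) * k + opts.damping * target
        if resid < opts.rel_tolerance:
            converged = True
            break
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(k0 > 0, k / np.maximum(k0, 1e-300), 1.0)
    return CouplingResult(
        rates=k,
        fold_changes=fc,
        promoter_sigma=sigma_p,
        iterations=iterations,
        converged=converged,
    )


def influence_curve(
    active_unit: TranscriptionUnit,
    promoter: PromoterModel,
    positions,
    sigma0: float,
    torsion: TorsionParameters,
) -> np.ndarray:
    """One-way fold-change of a probe promoter vs genomic position.

    Only the single active gene's field acts; there is no feedback.
    Positions must lie outside the active unit.
    """
    positions = np.atleast_1d(np.asarray(positions, dtype=float))
    inside = (positions >= active_unit.start) & (positions < active_unit.end)
    if np.any(inside):
        raise ValueError("probe positions must lie outside the active unit")
    sigma = sigma0 + perturbation_at(active_unit, positions, torsion)
    return np.asarray(fold_change(sigma, sigma0, promoter))


@dataclass
class PhaseDiagram:
    """Fold-change matrices over (sigma0, promoter distance) grids.

    ``fold_change`` has shape (n_reported_genes, n_sigma0, n_d): one gene
    for the symmetric divergent/convergent constructions, two (upstream,
    downstream) for tandem.  ``converged`` has shape (n_sigma0, n_d).
    """

    orientation: str
    d_grid: np.ndarray
    sigma0_grid: np.ndarray
    fold_change: np.ndarray
    converged: np.ndarray

    def to_tsv(self, path, gene: int = 0) -> None:
        import pandas as pd

        df = pd.DataFrame(
            self.fold_change[gene],
            index=self.sigma0_grid,
            columns=self.d_grid.astype(int),
        )
        df.index.name = "sigma0"
        df.to_csv(path, sep="\t", float_format="%.8g")


def phase_diagram(
    orientation: str,
    d_grid,
    sigma0_grid,
    lengths: tuple[int, int] = (1000, 1000),
    promoters: Optional[Sequence[PromoterModel]] = None,
    torsion: TorsionParameters = TorsionParameters(),
    opts: SolverOptions = SolverOptions(),
    distance_convention: str = "tss",
) -> PhaseDiagram:
    """Solve the coupled pair on a (sigma0 x distance) grid."""
    d_grid = np.asarray(d_grid, dtype=float)
    sigma0_grid = np.asarray(sigma0_grid, dtype=float)
    if d_grid.size == 0 or sigma0_grid.size == 0:
        raise ValueError("grids must be non-empty")
    n_report = 2 if orientation == "tandem" else 1
    fc = np.empty((n_report, sigma0_grid.size, d_grid.size))
    ok = np.zeros((sigma0_grid.size, d_grid.size), dtype=bool)
    for si, s0 in enumerate(sigma0_grid):
        tors = TorsionParameters(
            sigma0=float(s0), decay_length=torsion.decay_length, alpha=torsion.alpha
        )
        for di, d in enumerate(d_grid):
            system = build_pair(
                orientation,
                int(d),
                lengths=lengths,
                promoters=promoters,
                torsion=tors,
                distance_convention=distance_convention,
            )
            res = solve(system, opts)
            ok[si, di] = res.converged
            if n_report == 1:
                fc[0, si, di] = res.fold_changes[0]
            else:
                fc[0, si, di] = res.fold_changes[0]  # upstream
                fc[1, si, di] = res.fold_changes[1]  # downstream
    return PhaseDiagram(
        orientation=orientation,
        d_grid=d_grid,
        sigma0_grid=sigma0_grid,
        fold_change=fc,
        converged=ok,
    )
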