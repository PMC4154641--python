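"""Supercoiling-dependent promoter opening free energy.

Equilibrium statistical mechanics of stress-induced duplex destabilization
(SIDD) in the single-bubble approximation, plus the monotone sigmoid fit
consumed by the transcription and coupling models.

Model
-----
A sequence of N bases under superhelical density ``sigma`` carries a
linking difference ``alpha_Lk = sigma * N / h`` (turns, ``h`` the helical
repeat).  States are the fully closed duplex and all single denatured runs
(start ``s``, length ``n``).  The energy of a run is

    E(s, n) = a_nuc + sum of per-base pairing energies over the run
              + G_tor(n; sigma)

where ``G_tor`` is obtained by minimising, over the uniform residual twist
``tau`` of the open region, the sum of the open-region torsional energy
``(C/2) n tau^2`` and the quadratic residual-superhelicity energy
``(K/2) a_r^2`` with ``a_r = alpha_Lk + n/h - n tau / (2 pi)`` (opening n
bases relaxes n/h turns of helicity).  The minimum is analytic:

    G_tor(n) = (K/2) * a^2 * C / (C + K n / (4 pi^2)),   a = alpha_Lk + n/h,

which also covers the closed state (n = 0).  Boltzmann statistics over all
states give the probability that a designated initiation window is fully
denatured, and the opening free energy is the log-odds

    dG_open(sigma) = -R T ln[ p_open / (1 - p_open) ].

The per-state energetics are knowledge-based defaults (overridable); the
downstream simulations only consume the fitted sigmoid, Eq. (dG below).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import expit, logsumexp

R_KCAL = 1.987204259e-3  # gas constant, kcal/mol/K

__all__ = [
    "SIDDParameters",
    "MeltingProfile",
    "SigmoidOpening",
    "sidd_profile",
    "base_opening_probabilities",
    "fit_sigmoid",
    "opening_energy",
    "SequenceError",
    "FitError",
]


class SequenceError(ValueError):
    """Sequence contains characters outside {A, C, G, T}."""


class FitError(RuntimeError):
    """The sigmoid fit did not converge."""


@dataclass(frozen=True)
class SIDDParameters:
    """Energetic and elastic parameters of the single-bubble SIDD model.

    Defaults are declared package defaults at 37 C, not literature claims:
    nucleation 10.8 kcal/mol per denatured run, pairing 0.26 (A/T) and
    1.30 (G/C) kcal/mol/bp, open-region torsional stiffness C = 2.5
    kcal/mol/rad^2/bp, helical repeat 10.4 bp/turn, and a residual
    superhelicity stiffness K = superhelical_stiffness_coefficient * R*T/N
    (kcal/mol per squared turn of residual linking difference).
    """

    nucleation_energy: float = 10.8
    pairing_energy_at: float = 0.26
    pairing_energy_gc: float = 1.30
    torsional_stiffness: float = 2.5
    superhelical_stiffness_coefficient: float = 2200.0
    helical_repeat: float = 10.4
    temperature: float = 310.15
    max_bubble_length: Optional[int] = None
    domain_size: Optional[int] = 5000
    dg_cap: float = 50.0

    @property
    def rt(self) -> float:
        return R_KCAL * self.temperature

    def domain(self, n_bases: int) -> int:
        """Size N of the superhelical domain carrying sigma.

        The analysed sequence window sits inside a closed topological
        domain of this size (default 5 kb, plasmid-like); tying N to the
        window length instead (``domain_size=None``) makes the torsional
        energetics depend on how much flank is included.
        """
        return self.domain_size or n_bases

    def stiffness(self, n_bases: int) -> float:
        """Quadratic residual-superhelicity coefficient K (kcal/mol/turn^2)."""
        return self.superhelical_stiffness_coefficient * self.rt / self.domain(n_bases)


@dataclass
class MeltingProfile:
    """Opening free energy and probability of an initiation site vs sigma."""

    sigma: np.ndarray
    dg_open: np.ndarray
    p_open: np.ndarray
    capped: np.ndarray  # True where p_open underflowed and dG was capped
    site: tuple[int, int] = (0, 0)

    def to_tsv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.sigma, self.dg_open, self.p_open]),
            fmt="%.10g",
            delimiter="\t",
            header="sigma\tdg_open\tp_open",
            comments="",
        )


@dataclass(frozen=True)
class SigmoidOpening:
    """Monotone sigmoid parameterization of dG_open(sigma).

        dG(sigma) = q + v*sigma + m * logistic((sigma - sigma_c) / w)

    ``sigma_c`` is the sequence-dependent destabilization threshold, ``w``
    the transition width, and ``m``, ``v``, ``q`` adjustable amplitude,
    slope and offset (kcal/mol; ``v`` per unit sigma).  ``sigma_range``
    records the fitted validity domain; evaluation itself never clamps
    (the coupling solver clamps its sigma iterates to this range instead).
    """

    sigma_c: float
    width: float
    amplitude: float
    slope: float = 0.0
    offset: float = 0.0
    sigma_range: tuple[float, float] = (-0.15, 0.05)
    residual: float = 0.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")

    def __call__(self, sigma):
        return opening_energy(sigma, self)

    def to_dict(self) -> dict:
        return {
            "sigma_c": self.sigma_c,
            "width": self.width,
            "amplitude": self.amplitude,
            "slope": self.slope,
            "offset": self.offset,
            "sigma_range": list(self.sigma_range),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SigmoidOpening":
        return cls(
            sigma_c=d["sigma_c"],
            width=d["width"],
            amplitude=d["amplitude"],
            slope=d.get("slope", 0.0),
            offset=d.get("offset", 0.0),
            sigma_range=tuple(d.get("sigma_range", (-0.15, 0.05))),
        )


def opening_energy(sigma, model: SigmoidOpening):
    """Evaluate the fitted opening free energy dG_open(sigma), kcal/mol."""
    sigma = np.asarray(sigma, dtype=float)
    x = (sigma - model.sigma_c) / model.width
    out = model.offset + model.slope * sigma + model.amplitude * expit(x)
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# single-bubble SIDD engine
# ---------------------------------------------------------------------------

def _pairing_energies(sequence: str, params: SIDDParameters) -> np.ndarray:
    seq = sequence.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise SequenceError(f"non-ACGT characters in sequence: {sorted(bad)}")
    energies = np.where(
        np.isin(np.frombuffer(seq.encode(), dtype="S1"), [b"A", b"T"]),
        params.pairing_energy_at,
        params.pairing_energy_gc,
    )
    return energies.astype(float)


def torsional_energy(n_open: int, sigma: float, n_bases: int, params: SIDDParameters) -> float:
    """Analytic minimum of open-region twist + residual superhelicity energy."""
    n_dom = params.domain(n_bases)
    alpha_lk = sigma * n_dom / params.helical_repeat
    a = alpha_lk + n_open / params.helical_repeat
    c = params.torsional_stiffness
    k = params.stiffness(n_bases)
    if n_open == 0:
        return 0.5 * k * a * a
    return 0.5 * k * a * a * c / (c + k * n_open / (4.0 * np.pi**2))


def sidd_profile(
    sequence: str,
    site: tuple[int, int],
    sigma_grid: Sequence[float],
    params: SIDDParameters = SIDDParameters(),
) -> MeltingProfile:
    """Opening free energy of ``site`` (0-based half-open) over a sigma grid.

    Enumerates the closed state and every single denatured run up to
    ``max_bubble_length``, Boltzmann-weights them at each sigma, and
    reports the log-odds that the full site is inside the run.
    """
    energies = _pairing_energies(sequence, params)
    n_bases = len(energies)
    s0, s1 = site
    if not (0 <= s0 < s1 <= n_bases):
        raise ValueError(f"site {site} outside sequence of length {n_bases}")
    site_len = s1 - s0
    max_n = params.max_bubble_length or n_bases
    max_n = min(max_n, n_bases)

    beta = 1.0 / params.rt
    cs = np.concatenate([[0.0], np.cumsum(energies)])

    # per run length n: log-sum over start positions of exp(-beta * seq part),
    # split into runs covering the site and runs not covering it (the closed
    # state belongs to the complement); keeping both sums exact avoids any
    # 1 - p cancellation at either end of the transition
    lse_all = np.full(max_n + 1, -np.inf)
    lse_cov = np.full(max_n + 1, -np.inf)
    lse_non = np.full(max_n + 1, -np.inf)
    lse_all[0] = 0.0  # closed state, sequence part zero
    lse_non[0] = 0.0
    for n in range(1, max_n + 1):
        run_sums = cs[n:] - cs[:-n]  # start s = 0 .. n_bases-n
        logw = -beta * (params.nucleation_energy + run_sums)
        lse_all[n] = logsumexp(logw)
        lo = max(0, s1 - n)
        hi = min(s0, n_bases - n)
        if n >= site_len and hi >= lo:
            lse_cov[n] = logsumexp(logw[lo : hi + 1])
            non = np.concatenate([logw[:lo], logw[hi + 1 :]])
            lse_non[n] = logsumexp(non) if non.size else -np.inf
        else:
            lse_non[n] = lse_all[n]

    sigma_grid = np.asarray(sigma_grid, dtype=float)
    dg = np.empty_like(sigma_grid)
    p = np.empty_like(sigma_grid)
    capped = np.zeros_like(sigma_grid, dtype=bool)
    ns = np.arange(max_n + 1)
    for i, sigma in enumerate(sigma_grid):
        tor = np.array(
            [torsional_energy(int(n), float(sigma), n_bases, params) for n in ns]
        )
        terms = -beta * tor
        log_z = logsumexp(lse_all + terms)
        log_num = logsumexp(lse_cov + terms)
        log_non = logsumexp(lse_non + terms)
        if not np.isfinite(log_num):
            p[i] = 0.0
            dg[i] = params.dg_cap
            capped[i] = True
            continue
        p[i] = np.exp(log_num - log_z)
        val = -params.rt * (log_num - log_non)  # exact log-odds
        if abs(val) > params.dg_cap:
            dg[i] = np.sign(val) * params.dg_cap
            capped[i] = True
        else:
            dg[i] = val
    return MeltingProfile(sigma=sigma_grid, dg_open=dg, p_open=p, capped=capped, site=site)


def base_opening_probabilities(
    sequence: str, sigma: float, params: SIDDParameters = SIDDParameters()
) -> np.ndarray:
    """Probability that each base is inside the denatured run, at one sigma."""
    energies = _pairing_energies(sequence, params)
    n_bases = len(energies)
    max_n = min(params.max_bubble_length or n_bases, n_bases)
    beta = 1.0 / params.rt
    cs = np.concatenate([[0.0], np.cumsum(energies)])

    log_weights = []  # (log w, s, n)
    log_weights.append((-beta * torsional_energy(0, sigma, n_bases, params), None, 0))
    for n in range(1, max_n + 1):
        run_sums = cs[n:] - cs[:-n]
        tor = torsional_energy(n, sigma, n_bases, params)
        lw = -beta * (params.nucleation_energy + run_sums + tor)
        for s, w in enumerate(lw):
            log_weights.append((w, s, n))
    all_lw = np.array([w for w, _, _ in log_weights])
    log_z = logsumexp(all_lw)
    p = np.zeros(n_bases)
    for w, s, n in log_weights:
        if n == 0:
            continue
        p[s : s + n] += np.exp(w - log_z)
    return p


# ---------------------------------------------------------------------------
# sigmoid fit
# ---------------------------------------------------------------------------

def _sigmoid_form(sigma, sigma_c, width, amplitude, slope, offset):
    return offset + slope * sigma + amplitude * expit((sigma - sigma_c) / width)


def fit_sigmoid(profile: MeltingProfile) -> SigmoidOpening:
    """Least-squares sigmoid fit of a melting profile.

    The profile should cover both plateaus of the crossover; capped grid
    points are excluded from the fit.
    """
    keep = ~profile.capped
    sigma = profile.sigma[keep]
    dg = profile.dg_open[keep]
    if sigma.size < 6:
        raise FitError("too few uncapped points to fit a 5-parameter sigmoid")

    order = np.argsort(sigma)
    sigma, dg = sigma[order], dg[order]
    # initial guesses: threshold at the steepest slope of the crossover
    grad = np.gradient(dg, sigma)
    i0 = int(np.argmax(grad))
    span = sigma[-1] - sigma[0]
    p0 = [
        sigma[i0],                    # sigma_c
        max(span / 20.0, 1e-4),       # width
        max(dg.max() - dg.min(), 1e-3),  # amplitude
        0.0,                          # slope
        dg.min(),                     # offset
    ]
    # slope and amplitude constrained >= 0 so the fitted curve is monotone
    # non-decreasing over the whole sigma axis, not only the sampled range
    bounds = (
        [sigma[0] - span, 1e-6, 0.0, 0.0, -np.inf],
        [sigma[-1] + span, span, np.inf, np.inf, np.inf],
    )
    try:
        popt, _ = curve_fit(_sigmoid_form, sigma, dg, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - diagnostics path
        raise FitError(f"sigmoid fit did not converge: {exc}") from exc
    residual = float(np.linalg.norm(_sigmoid_form(sigma, *popt) - dg))
    return SigmoidOpening(
        sigma_c=float(popt[0]),
        width=float(popt[1]),
        amplitude=float(popt[2]),
        slope=float(popt[3]),
        offset=float(popt[4]),
        sigma_range=(float(sigma[0]), float(sigma[-1])),
        residual=residual,
    )
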