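"""Transcription-generated superhelical-density fields.

An elongating RNA polymerase acts as a torsional motor ("twin supercoiled
domain"): it injects positive supercoiling ahead of the transcription unit
and negative supercoiling behind it.  Outside the gene the stress is
relaxed by topoisomerases with uniform per-base efficiency ``1/b``, which
yields a time-averaged perturbation decaying exponentially with distance
from the nearer edge of the unit,

    |dsigma(x)| = sigma_a * exp(-d / b),        sigma_a = alpha * k * l,

where ``k`` is the promoter strength (expression rate, arbitrary units),
``l`` the transcript length in bp, ``alpha`` an amplitude coefficient and
``b`` the propagation (decay) length in bp.  The sign is positive
downstream of the 3' end (ahead of the polymerase, in the direction of
transcription) and negative upstream of the TSS.

All coordinates are 0-based half-open; conversion from 1-based annotation
formats happens at the I/O boundary (:mod:`torsioncouple.genomics`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TranscriptionUnit",
    "TorsionParameters",
    "TorsionProfile",
    "perturbation_at",
    "field_at",
    "profile",
]


class ParameterError(ValueError):
    """Invalid physical parameter (negative rate, nonpositive decay length...)."""


@dataclass(frozen=True)
class TranscriptionUnit:
    """A gene's genomic interval, strand and expression rate.

    The unit is the source of the torsion field.  ``start``/``end`` are
    0-based half-open; ``rate`` is the promoter strength ``k`` in the
    arbitrary expression units for which ``alpha`` was calibrated.
    """

    id: str
    start: int
    end: int
    strand: str
    rate: float = 1.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ParameterError(
                f"unit {self.id!r}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ParameterError(f"unit {self.id!r}: strand must be '+' or '-'")
        if self.rate < 0:
            raise ParameterError(f"unit {self.id!r}: rate must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Transcription start site (base position, inside the unit)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tss_boundary(self) -> int:
        """TSS as a half-open boundary coordinate (used for distances)."""
        return self.start if self.strand == "+" else self.end

    def with_rate(self, rate: float) -> "TranscriptionUnit":
        return replace(self, rate=rate)


@dataclass(frozen=True)
class TorsionParameters:
    """Parameters of the torsion field.

    sigma0
        Basal superhelical density of the region/organism (dimensionless;
        ~0 for free eukaryotic DNA, about -0.06 on average in E. coli).
    decay_length
        Propagation distance ``b`` in bp, set by topoisomerase efficiency
        ``1/b``; in vivo measurements in both prokaryotes and eukaryotes
        consistently give ~1000 bp.
    alpha
        Amplitude coefficient per (rate * bp): a 1-kb gene at unit rate
        produces an edge amplitude ``sigma_a = alpha * k * l``.
    """

    sigma0: float = 0.0
    decay_length: float = 1000.0
    alpha: float = 3e-5

    def __post_init__(self) -> None:
        if self.decay_length <= 0:
            raise ParameterError("decay_length must be > 0")
        if self.alpha < 0:
            raise ParameterError("alpha must be >= 0")


@dataclass
class TorsionProfile:
    """Superhelical density sampled on a genomic grid."""

    positions: np.ndarray
    sigma: np.ndarray

    def to_tsv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.positions, self.sigma]),
            fmt=("%d", "%.10g"),
            delimiter="\t",
            header="position\tsigma",
            comments="",
        )


def perturbation_at(unit: TranscriptionUnit, x, params: TorsionParameters):
    """Superhelical-density increment of one transcribed unit at position(s) x.

    Outside the unit the increment decays exponentially from the nearer
    edge with decay length ``b``; the sign follows the twin-domain rule
    (+ ahead of the polymerase, - behind).  Inside the unit the value is a
    linear interpolation between -sigma_a at the TSS edge and +sigma_a at
    the 3' edge; this branch exists for plotting continuity only, the
    coupling model never evaluates a promoter inside a partner's unit.
    """
    x = np.asarray(x, dtype=float)
    sigma_a = params.alpha * unit.rate * unit.length
    b = params.decay_length

    left = x < unit.start
    right = x >= unit.end
    inside = ~(left | right)

    out = np.empty_like(x)
    # magnitude on either outside flank
    out[left] = sigma_a * np.exp(-(unit.start - x[left]) / b)
    out[right] = sigma_a * np.exp(-(x[right] - unit.end) / b)
    if unit.strand == "+":
        out[left] *= -1.0  # behind the polymerase
        frac = (x[inside] - unit.start) / unit.length
        out[inside] = sigma_a * (2.0 * frac - 1.0)
    else:
        out[right] *= -1.0
        frac = (x[inside] - unit.start) / unit.length
        out[inside] = sigma_a * (1.0 - 2.0 * frac)
    if out.ndim == 0:
        return float(out)
    return out


def field_at(units, x, params: TorsionParameters):
    """Total superhelical density sigma(x) = sigma0 + sum of unit perturbations.

    Superposition over sources is additive, so an N-gene chain reduces to
    the pair treatment for two genes.  With no units the field is flat at
    the basal level.
    """
    x = np.asarray(x, dtype=float)
    total = np.full_like(x, params.sigma0)
    for unit in units:
        total = total + perturbation_at(unit, x, params)
    if total.ndim == 0:
        return float(total)
    return total


def profile(units, interval, step, params: TorsionParameters) -> TorsionProfile:
    """Evaluate the field on a regular grid over ``interval = (lo, hi)``."""
    lo, hi = interval
    if hi <= lo:
        raise ValueError(f"empty interval ({lo}, {hi})")
    if step < 1:
        raise ValueError("step must be >= 1")
    positions = np.arange(lo, hi, step, dtype=float)
    return TorsionProfile(positions=positions, sigma=field_at(units, positions, params))
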