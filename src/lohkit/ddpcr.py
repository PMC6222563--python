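"""Droplet digital PCR concentration and copy-number estimation.

A ddPCR reaction partitions template into ~20,000 droplets; each droplet is
read as positive or negative for amplification. Templates land in droplets
as a Poisson process, so the copies-per-droplet concentration is recovered
from the fraction of positive droplets p by lambda = -ln(1 - p). Copy
number of a target locus per diploid genome is the target concentration
divided by a normalizer: the mean concentration of two reference amplicons
of known two-copy status, divided by 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DdpcrAssay",
    "CopyNumberCall",
    "DEFAULT_DROPLET_VOLUME_NL",
    "conc_from_droplets",
    "copy_number",
    "integer_call",
    "simulate_droplets",
]

# instrument-typical droplet volume; affects only volumetric units, not CN
DEFAULT_DROPLET_VOLUME_NL = 0.85

TARGET, REFERENCE, SINGLE_COPY_CONTROL = "target", "reference", "single-copy-control"


@dataclass
class DdpcrAssay:
    """One amplicon's droplet counts and derived concentration."""

    amplicon_id: str
    positives: int
    total: int
    role: str = TARGET
    V_d: float = DEFAULT_DROPLET_VOLUME_NL  # nL

    def __post_init__(self) -> None:
        if not (0 <= self.positives <= self.total):
            raise ValueError("require 0 <= positives <= total")
        if self.total < 1:
            raise ValueError("need at least one droplet")
        if self.role not in (TARGET, REFERENCE, SINGLE_COPY_CONTROL):
            raise ValueError(f"unknown role {self.role!r}")

    @property
    def lam(self) -> float:
        """Copies per droplet (Poisson-corrected)."""
        return conc_from_droplets(self.positives, self.total)

    def conc_per_nl(self) -> float:
        return self.lam / self.V_d


@dataclass
class CopyNumberCall:
    target_id: str
    CN: float
    normalizer: float  # mean reference lambda / 2
    integer: int | None  # nearest-integer call, None when outside the band

    def __post_init__(self) -> None:
        if self.CN < 0:
            raise ValueError("CN must be >= 0")


def conc_from_droplets(positives: int, total: int, V_d: float | None = None) -> float:
    """Poisson-corrected template concentration from droplet counts.

    lambda = -ln(1 - positives/total), in copies per droplet; dividing by
    the droplet volume ``V_d`` (nL) gives copies per nL. All droplets
    positive means the reaction is saturated and lambda is unbounded.
    """
    if not (0 <= positives <= total) or total < 1:
        raise ValueError("require 0 <= positives <= total, total >= 1")
    if positives == total:
        raise ValueError("saturated: all droplets positive, concentration unbounded")
    lam = -math.log1p(-positives / total)
    return lam / V_d if V_d is not None else lam


def copy_number(
    target_lambda: float,
    ref1_lambda: float,
    ref2_lambda: float,
    target_id: str = "target",
    integer_band: float = 0.3,
) -> CopyNumberCall:
    """Copy number per diploid genome via the two-reference normalizer.

    CN = target / (mean(ref1, ref2) / 2): the references are loci of known
    two-copy status flanking a stable region, so their average concentration
    corresponds to two copies. The call is scale-invariant in the template
    amount. An integer interpretation is attached when CN falls within
    ``integer_band`` of an integer.
    """
    if ref1_lambda <= 0 or ref2_lambda <= 0:
        raise ValueError("reference concentrations must be > 0")
    if target_lambda < 0:
        raise ValueError("target concentration must be >= 0")
    normalizer = (ref1_lambda + ref2_lambda) / 2.0 / 2.0
    cn = target_lambda / normalizer
    return CopyNumberCall(
        target_id=target_id,
        CN=cn,
        normalizer=normalizer,
        integer=integer_call(cn, band=integer_band),
    )


def integer_call(cn: float, band: float = 0.3) -> int | None:
    """Nearest-integer copy number, or None when outside the +/- band."""
    nearest = round(cn)
    return int(nearest) if abs(cn - nearest) <= band else None


def simulate_droplets(
    lam: float,
    total: int,
    seed: int | np.random.Generator | None = None,
) -> int:
    """Simulate the positive-droplet count at concentration ``lam``.

    Each droplet receives Poisson(lam) templates, so it is positive with
    probability 1 - exp(-lam); positives ~ Binomial(total, 1 - exp(-lam)).
    """
    if lam < 0 or total < 1:
        raise ValueError("require lam >= 0 and total >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return int(rng.binomial(total, -math.expm1(-lam)))
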