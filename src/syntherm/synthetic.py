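"""Synthetic batch-culture data with the stoichiometric structure the
analysis assumes.

Real enrichment time courses are not deposited, so this module generates
stand-ins: first-order substrate decay with stoichiometric product
accumulation plus additive Gaussian measurement noise, and the partial
hydrolysis of 2-bromoethanesulfonate (BrES) to isethionate + free bromide
that one autoclave cycle causes (mean fraction 0.16, sd 0.015, truncated to
[0, 1]).  First-order decay is the generator's modelling assumption - no
kinetic law is fitted anywhere in the package - and noise-free output is
exactly stoichiometric, so every balance operation can be tested against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

__all__ = [
    "TimeCourse",
    "SulfonateMixture",
    "simulate_batch_timecourse",
    "simulate_autoclaved_bres",
]


@dataclass
class TimeCourse:
    """Concentration series (mM) per species over strictly increasing days."""

    times: np.ndarray
    concentrations: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size == 0:
            raise ValueError("empty timepoints")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for sp, series in self.concentrations.items():
            series = np.asarray(series, dtype=float)
            if series.shape != self.times.shape:
                raise ValueError(f"series length mismatch for {sp!r}")
            self.concentrations[sp] = series

    def final(self) -> dict[str, float]:
        """Concentrations at the last timepoint."""
        return {sp: float(series[-1]) for sp, series in self.concentrations.items()}

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: columns time_d, species, mM."""
        records = [
            (t, sp, c)
            for sp, series in self.concentrations.items()
            for t, c in zip(self.times, series)
        ]
        return pd.DataFrame(records, columns=["time_d", "species", "mM"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class SulfonateMixture:
    """Composition (mM) of a BrES dose after autoclave hydrolysis.

    Invariants: BrES + isethionate equals the initial dose exactly, and free
    bromide equals isethionate (1:1 hydrolysis).
    """

    bres: float
    isethionate: float
    bromide: float
    cycles: int


def simulate_batch_timecourse(
    overall,
    substrate: str,
    s0_mM: float,
    rate_constant: float,
    timepoints: Sequence[float],
    noise_sd_mM: float = 0.1,
    seed: int | None = None,
    exclude: Sequence[str] = ("H2O", "H+"),
) -> TimeCourse:
    """Batch conversion of ``substrate`` through ``overall`` at first order.

    The substrate follows ``s0 * exp(-k t)``; each product accumulates
    stoichiometrically from the consumed substrate, and co-substrates are
    drawn down from the dose required for complete conversion.  Water and
    protons are not observable concentrations and are excluded by default.
    Independent Gaussian noise (sd ``noise_sd_mM``) is added per observation
    and clipped at zero; the same seed always yields the identical course.
    """
    if s0_mM < 0:
        raise ValueError("initial substrate concentration must be nonnegative")
    if rate_constant < 0:
        raise ValueError("rate constant must be nonnegative")
    if noise_sd_mM < 0:
        raise ValueError("noise sd must be nonnegative")
    t = np.asarray(timepoints, dtype=float)
    nu_s = overall.coefficient(substrate)
    if nu_s >= 0:
        raise ValueError(f"{substrate!r} is not a reactant of the overall reaction")

    s = s0_mM * np.exp(-rate_constant * t)
    consumed = s0_mM - s
    # identical float expression to predict_yields: amount/|nu_s| then * nu
    scale = consumed / float(-nu_s)
    conc: dict[str, np.ndarray] = {substrate: s}
    for sp, nu in overall.stoich.items():
        if sp == substrate or sp in exclude:
            continue
        if nu > 0:
            conc[sp] = float(nu) * scale
        else:
            conc[sp] = float(-nu) * (s / float(-nu_s))  # residual co-substrate
    if noise_sd_mM > 0:
        rng = np.random.default_rng(seed)
        for sp in conc:
            noisy = conc[sp] + rng.normal(0.0, noise_sd_mM, size=t.shape)
            conc[sp] = np.clip(noisy, 0.0, None)
    metadata = {
        "reaction": getattr(overall, "label", None),
        "substrate": substrate,
        "s0_mM": s0_mM,
        "rate_per_day": rate_constant,
        "noise_sd_mM": noise_sd_mM,
        "seed": seed,
    }
    return TimeCourse(t, conc, metadata)


def simulate_autoclaved_bres(
    initial_mM: float,
    cycles: int,
    fraction_mean: float = 0.16,
    fraction_sd: float = 0.015,
    seed: int | None = None,
) -> SulfonateMixture:
    """Hydrolysis of a BrES dose over repeated autoclave cycles.

    Each cycle converts a truncated-normal fraction (mean 0.16, sd 0.015,
    bounded to [0, 1]) of the *remaining* BrES to isethionate plus an equal
    amount of free bromide.  With ``fraction_sd=0`` the fraction is fixed at
    the mean.  Mass is conserved exactly: bres + isethionate == initial.
    """
    if initial_mM < 0:
        raise ValueError("initial BrES concentration must be nonnegative")
    if cycles < 0:
        raise ValueError("cycle count must be nonnegative")
    if not 0.0 <= fraction_mean <= 1.0:
        raise ValueError("hydrolysis fraction mean must lie in [0, 1]")
    if fraction_sd < 0:
        raise ValueError("hydrolysis fraction sd must be nonnegative")
    rng = np.random.default_rng(seed)
    remaining = Fraction(str(initial_mM))  # exact bookkeeping before any noise
    for _ in range(int(cycles)):
        if fraction_sd == 0:
            f = Fraction(str(fraction_mean))
        else:
            a = (0.0 - fraction_mean) / fraction_sd
            b = (1.0 - fraction_mean) / fraction_sd
            draw = float(truncnorm.rvs(a, b, loc=fraction_mean, scale=fraction_sd, random_state=rng))
            f = Fraction(draw)  # exact binary value of the drawn float
        remaining -= remaining * f
    bres = float(remaining)
    isethionate = initial_mM - bres  # exact complement in float arithmetic
    return SulfonateMixture(bres=bres, isethionate=isethionate, bromide=isethionate, cycles=int(cycles))
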