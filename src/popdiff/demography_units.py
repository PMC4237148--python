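"""Conversion of diffusion-scaled demographic parameters to natural units.

Diffusion-based demographic inference reports parameters scaled by an
unknown reference effective population size: theta = 4 Nref mu L for
the surveyed sequence length L, population sizes as nu = Ne / Nref,
times in units of 2 Nref generations, and symmetric migration as
M = 2 Nref m.  Given the mutation rate, surveyed length and generation
time, these convert to individuals and years.  The expected neutral
sequence divergence between two species separated T years ago is
2 mu T / g (per-generation substitutions accumulating on both
lineages).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class UnitConstants:
    """Rate and scale constants for the killer whale analysis.

    mu: substitutions / nucleotide / generation (odontocete nuclear rate)
    seq_length: surveyed sequence length in bp
    generation_time: years per generation
    divergence_time_years: species split versus the outgroup (years)
    genome_size: assembly size in bp (context only)
    """

    mu: float = 2.34e-8
    seq_length: float = 1.45e6
    generation_time: float = 25.7
    divergence_time_years: float = 10e6
    genome_size: float = 2.3e9

    def __post_init__(self) -> None:
        for name in ("mu", "seq_length", "generation_time", "divergence_time_years"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def reference_ne(theta: float, constants: UnitConstants = UnitConstants()) -> float:
    """Reference effective size Nref = theta / (4 mu L)."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    return theta / (4.0 * constants.mu * constants.seq_length)


def ne_to_theta(ne: float, constants: UnitConstants = UnitConstants()) -> float:
    """Inverse of :func:`reference_ne`."""
    if ne <= 0:
        raise ValueError("Ne must be positive")
    return ne * 4.0 * constants.mu * constants.seq_length


def scaled_time_to_years(
    t_scaled: float, ne_ref: float, constants: UnitConstants = UnitConstants()
) -> float:
    """Time in units of 2 Nref generations -> years."""
    if t_scaled < 0 or ne_ref <= 0:
        raise ValueError("t_scaled must be >= 0 and ne_ref > 0")
    return 2.0 * ne_ref * t_scaled * constants.generation_time


def migrants_per_generation(m_scaled: float, nu: float = 1.0) -> float:
    """Effective migrants per generation into a population of scaled size nu.

    Convention: with symmetric scaled migration M = 2 Nref m, the number
    of immigrant individuals per generation is M * nu / 2.
    """
    if m_scaled < 0 or nu <= 0:
        raise ValueError("m_scaled must be >= 0 and nu > 0")
    return m_scaled * nu / 2.0


def expected_divergence(constants: UnitConstants = UnitConstants()) -> float:
    """Expected pairwise sequence divergence (proportion): 2 mu T / g."""
    return 2.0 * constants.mu * (constants.divergence_time_years / constants.generation_time)


def convert_estimates(
    estimates: pd.DataFrame, constants: UnitConstants = UnitConstants()
) -> pd.DataFrame:
    """Convert a table of scaled estimates to natural units.

    ``estimates`` has columns ``parameter`` and ``value``; parameter
    names starting with ``theta`` set the reference size, ``nu`` are
    size ratios, ``T`` are scaled times and ``M`` scaled migration
    rates.  Rows are converted in order, so theta must precede the
    parameters that depend on it.
    """
    ne_ref = None
    rows = []
    for rec in estimates.itertuples():
        name, value = str(rec.parameter), float(rec.value)
        if name.startswith("theta"):
            ne_ref = reference_ne(value, constants)
            rows.append({"parameter": name, "value": value, "converted": ne_ref, "unit": "Nref (individuals)"})
        elif name.startswith("nu"):
            if ne_ref is None:
                raise ValueError("theta must precede nu parameters")
            rows.append({"parameter": name, "value": value, "converted": value * ne_ref, "unit": "Ne (individuals)"})
        elif name.startswith("T"):
            if ne_ref is None:
                raise ValueError("theta must precede time parameters")
            rows.append(
                {"parameter": name, "value": value, "converted": scaled_time_to_years(value, ne_ref, constants), "unit": "years"}
            )
        elif name.startswith("M"):
            rows.append(
                {"parameter": name, "value": value, "converted": migrants_per_generation(value), "unit": "migrants/generation (nu=1)"}
            )
        else:
            rows.append({"parameter": name, "value": value, "converted": value, "unit": "unconverted"})
    return pd.DataFrame(rows)
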