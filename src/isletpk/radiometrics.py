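"""Radioactivity bookkeeping.

Decay correction back to a reference time, decay-corrected radiochemical
yield, octanol/water partition coefficients from gamma counts, and the
percent-injected-dose-per-gram conversion used in biodistribution tables.

All activities are handled in arbitrary but consistent units; the canonical
absolute unit is Bq, with microcuries accepted at I/O boundaries
(1 uCi = 37 000 Bq).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Isotope",
    "CountMeasurement",
    "F18",
    "UCI_TO_BQ",
    "uci_to_bq",
    "bq_to_uci",
    "decay_correct",
    "decay_to",
    "dc_rcy",
    "log_partition",
    "logp_summary",
    "percent_id_per_gram",
]

#: Conversion factor: 1 microcurie in becquerel.
UCI_TO_BQ = 37_000.0


@dataclass(frozen=True)
class Isotope:
    """A radionuclide identified by name and physical half-life in minutes."""

    name: str
    half_life_min: float

    def __post_init__(self) -> None:
        if not (self.half_life_min > 0):
            raise ValueError(
                f"half_life_min must be positive, got {self.half_life_min!r}"
            )


#: Fluorine-18, physical half-life 109.8 min.
F18 = Isotope("F-18", 109.8)


@dataclass(frozen=True)
class CountMeasurement:
    """A single gamma-counter measurement.

    Parameters
    ----------
    counts:
        Registered counts (or Bq); must be nonnegative.
    elapsed_min:
        Minutes elapsed since the reference time point (e.g. injection or
        synthesis start); must be nonnegative.
    sample_mass_g:
        Wet mass of the counted sample in grams, when known.
    """

    counts: float
    elapsed_min: float = 0.0
    sample_mass_g: Optional[float] = None

    def __post_init__(self) -> None:
        if self.counts < 0:
            raise ValueError(f"counts must be nonnegative, got {self.counts!r}")
        if self.elapsed_min < 0:
            raise ValueError(
                f"elapsed_min must be nonnegative, got {self.elapsed_min!r}"
            )
        if self.sample_mass_g is not None and not (self.sample_mass_g > 0):
            raise ValueError(
                f"sample_mass_g must be positive when given, got {self.sample_mass_g!r}"
            )


def uci_to_bq(activity_uci: float) -> float:
    """Convert an activity from microcuries to becquerel."""
    return activity_uci * UCI_TO_BQ


def bq_to_uci(activity_bq: float) -> float:
    """Convert an activity from becquerel to microcuries."""
    return activity_bq / UCI_TO_BQ


def decay_correct(activity: float, elapsed_min: float, isotope: Isotope) -> float:
    """Correct a measured activity backward to the reference time.

    A sample measured ``elapsed_min`` minutes after the reference point has
    physically decayed by ``2**(-elapsed/half_life)``; the corrected value is
    ``activity * 2**(elapsed/half_life)``.

    Both ``activity`` and ``elapsed_min`` must be nonnegative: forward decay
    is expressed with :func:`decay_to`, never with a negative elapsed time.
    """
    if elapsed_min < 0:
        raise ValueError(f"elapsed_min must be nonnegative, got {elapsed_min!r}")
    if activity < 0:
        raise ValueError(f"activity must be nonnegative, got {activity!r}")
    return activity * 2.0 ** (elapsed_min / isotope.half_life_min)


def decay_to(activity: float, elapsed_min: float, isotope: Isotope) -> float:
    """Physically decay a reference-time activity forward by ``elapsed_min``."""
    if elapsed_min < 0:
        raise ValueError(f"elapsed_min must be nonnegative, got {elapsed_min!r}")
    if activity < 0:
        raise ValueError(f"activity must be nonnegative, got {activity!r}")
    return activity * 2.0 ** (-elapsed_min / isotope.half_life_min)


def dc_rcy(
    product_activity: float,
    start_activity: float,
    elapsed_min: float,
    isotope: Isotope,
) -> float:
    """Decay-corrected radiochemical yield in percent.

    The product activity is corrected back to the synthesis start and divided
    by the starting activity.
    """
    if not (start_activity > 0):
        raise ValueError(
            f"start_activity must be positive, got {start_activity!r}"
        )
    return 100.0 * decay_correct(product_activity, elapsed_min, isotope) / start_activity


def log_partition(counts_organic: float, counts_aqueous: float) -> float:
    """log10 partition coefficient from phase activities.

    ``log10(counts_organic / counts_aqueous)``; antisymmetric under swapping
    the two phases. Zero or negative counts leave the logarithm undefined and
    are rejected.
    """
    if not (counts_organic > 0):
        raise ValueError(
            f"counts_organic must be positive, got {counts_organic!r}"
        )
    if not (counts_aqueous > 0):
        raise ValueError(
            f"counts_aqueous must be positive, got {counts_aqueous!r}"
        )
    # as a difference of logs so that swapping phases negates exactly
    return math.log10(counts_organic) - math.log10(counts_aqueous)


def logp_summary(
    pairs: Sequence[tuple[float, float]],
) -> tuple[float, float]:
    """Mean and sample standard deviation of logP over replicate count pairs.

    Each pair is ``(counts_organic, counts_aqueous)``. At least two replicates
    are required for the standard deviation.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 replicate pairs for a summary")
    values = np.array([log_partition(o, a) for o, a in pairs])
    return float(values.mean()), float(values.std(ddof=1))


def percent_id_per_gram(
    sample: CountMeasurement,
    injected_counts: float,
    isotope: Optional[Isotope] = None,
) -> float:
    """Percent injected dose per gram of tissue.

    ``100 * counts / (injected_counts * sample_mass_g)``. When ``isotope`` is
    given the sample counts are first decay-corrected back to the injection
    time using ``sample.elapsed_min`` (whether published biodistribution
    values are decay-corrected is generally unstated; correction is therefore
    opt-in through this argument).
    """
    if sample.sample_mass_g is None:
        raise ValueError("sample_mass_g is required for %ID/g but is missing")
    if not (injected_counts > 0):
        raise ValueError(
            f"injected_counts must be positive, got {injected_counts!r}"
        )
    counts = sample.counts
    if isotope is not None:
        counts = decay_correct(counts, sample.elapsed_min, isotope)
    return 100.0 * counts / (injected_counts * sample.sample_mass_g)
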