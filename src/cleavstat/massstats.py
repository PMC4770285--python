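"""Fragment-mass distributions and the Kolmogorov deviation statistic.

The core predictor is ``K_stat``: for a protein and a cleavage rule, the
fragment masses ``m`` are normalized by their mean ``M`` and the empirical
exceedance distribution ``R_emp(m/M)`` is compared with the exponential null
``exp(-m/M)`` expected under random residue arrangement.  ``K_stat`` is the
maximum discrepancy between the two, taken either signed (empirical minus
theoretical, the spreadsheet convention) or in absolute value (the classical
Kolmogorov statistic).  One such value per cleavage rule gives the
16-dimensional feature vector consumed by the classifiers.

The empirical exceedance is evaluated at the observed points only,
``R_emp(x) = #{values > x} / N`` — deliberately matching the tabular
computation rather than the two-sided step evaluation of the textbook KS
test; the difference is O(1/N).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .digestion import (
    DEFAULT_MASS_TABLE,
    AminoAcidMassTable,
    CleavageRule,
    MassType,
    ProteinRecord,
    builtin_rules,
    digest,
)

logger = logging.getLogger("cleavstat")

KstatMode = Literal["signed", "absolute"]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MassSpectrum:
    """A multiset of fragment masses (Da), stored descending-sorted."""

    masses: np.ndarray
    source: str = "unknown"

    def __post_init__(self) -> None:
        arr = np.asarray(self.masses, dtype=float)
        if arr.size == 0:
            raise ValueError("empty mass spectrum")
        if np.any(arr <= 0):
            raise ValueError("masses must be strictly positive")
        object.__setattr__(self, "masses", np.sort(arr)[::-1])

    @property
    def N(self) -> int:
        return int(self.masses.size)

    @property
    def M(self) -> float:
        """Mean fragment mass (Da)."""
        return float(self.masses.mean())

    @classmethod
    def from_fragments(cls, fragments) -> "MassSpectrum":
        src = f"simulated({fragments.rule.short_notation}, missed<={fragments.max_missed})"
        return cls(fragments.masses(), source=src)


@dataclass(frozen=True)
class ExceedanceDistribution:
    """Empirical exceedance P(X > x) at the distinct observed values."""

    support: np.ndarray  # ascending distinct values
    R: np.ndarray        # non-increasing, in [0, 1], 0 at the largest value

    def __call__(self, x) -> np.ndarray:
        """Evaluate the empirical exceedance at arbitrary points."""
        idx = np.searchsorted(self.support, np.atleast_1d(x), side="right")
        return np.where(idx == 0, 1.0, self.R[np.maximum(idx - 1, 0)])


@dataclass(frozen=True)
class KStatResult:
    """Deviation of one protein/rule mass distribution from the exponential null."""

    value: float
    mode: KstatMode
    N: int
    rule: str = ""
    protein_id: str = ""


# ---------------------------------------------------------------------------
# Exceedance and K_stat
# ---------------------------------------------------------------------------

def exceedance(values) -> ExceedanceDistribution:
    """Empirical exceedance distribution R(x) = #{values > x} / N.

    Evaluated at each distinct observed value; ties collapse to one support
    point.  R is non-increasing and equals 0 at the largest observed value.
    """
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("empty value set")
    support, counts = np.unique(arr, return_counts=True)
    n = arr.size
    greater = n - np.cumsum(counts)
    return ExceedanceDistribution(support, greater / n)


def _kstat_value(x: np.ndarray, mode: KstatMode) -> float:
    """Max discrepancy between R_emp and exp(-x) at the observed points."""
    dist = exceedance(x)
    diff = dist.R - np.exp(-dist.support)
    if mode == "signed":
        return float(diff.max())
    if mode == "absolute":
        return float(np.abs(diff).max())
    raise ValueError(f"unknown mode {mode!r}")


def kstat(
    spectrum: MassSpectrum,
    mode: KstatMode = "signed",
    scale: float | None = None,
) -> KStatResult:
    """Kolmogorov deviation of the normalized mass distribution from exp(-x).

    Masses are divided by ``scale`` (default: the spectrum's own mean ``M``,
    so the normalized values average exactly 1).  ``signed`` mode returns
    ``max_i [R_emp(x_i) - exp(-x_i)]``; ``absolute`` mode the maximum
    absolute discrepancy.  Passing an external ``scale`` supports calibration
    against a fully specified (known-mean) exponential null, where the
    classical Kolmogorov critical values apply; with the mean estimated from
    the same sample the test is conservative.
    """
    x = spectrum.masses / (spectrum.M if scale is None else float(scale))
    return KStatResult(_kstat_value(x, mode), mode, spectrum.N)


def kolmogorov_pvalue(k_absolute: float, n: int) -> float:
    """Asymptotic Kolmogorov tail probability at lambda = sqrt(N) * K."""
    if k_absolute < 0:
        raise ValueError("K must be non-negative")
    if n < 1:
        raise ValueError("N must be >= 1")
    lam = math.sqrt(n) * k_absolute
    return float(np.clip(special.kolmogorov(lam), 0.0, 1.0))


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def kstat_features(
    records: Iterable[ProteinRecord],
    rules: Sequence[str] | dict[str, CleavageRule] | None = None,
    max_missed: int = 0,
    mode: KstatMode = "signed",
    mass_type: MassType = "average",
    table: AminoAcidMassTable = DEFAULT_MASS_TABLE,
    on_sparse: Literal["flag", "drop"] = "flag",
) -> pd.DataFrame:
    """Per-protein K_stat feature matrix (rows = proteins, columns = rules).

    A protein yielding fewer than two fragments for some rule has that cell
    set to NaN (``on_sparse="flag"``) or the whole row dropped
    (``on_sparse="drop"``).
    """
    registry = builtin_rules()
    if rules is None:
        rule_objs = registry
    elif isinstance(rules, dict):
        rule_objs = rules
    else:
        rule_objs = {r: registry[r] for r in rules}
    rows = {}
    for rec in records:
        row = {}
        for notation, rule in rule_objs.items():
            frags = digest(rec, rule, max_missed=max_missed,
                           mass_type=mass_type, table=table)
            if len(frags) < 2:
                row[notation] = np.nan
            else:
                row[notation] = kstat(MassSpectrum.from_fragments(frags), mode=mode).value
        rows[rec.id] = row
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(rule_objs))
    if on_sparse == "drop":
        n_before = len(df)
        df = df.dropna()
        if len(df) < n_before:
            logger.info("kstat_features: dropped %d sparse rows", n_before - len(df))
    return df


# ---------------------------------------------------------------------------
# Experimental mass lists and peak decomposability
# ---------------------------------------------------------------------------

def read_mass_list(path) -> MassSpectrum:
    """Parse a plain-text fragment-mass list (one mass per line).

    Takes the first whitespace-delimited numeric token of each line;
    non-numeric lines (headers, comments) are skipped with a log message.
    Tolerates the text export dialect of common peptide-mass services.
    """
    masses: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            tokens = line.split()
            if not tokens:
                continue
            try:
                masses.append(float(tokens[0]))
            except ValueError:
                logger.debug("read_mass_list: skipping line %d: %r", lineno, line.rstrip())
    if not masses:
        raise ValueError(f"no parseable masses in {path}")
    return MassSpectrum(np.array(masses), source=f"observed({path})")


def decomposable_mass(
    mass: float,
    table: AminoAcidMassTable = DEFAULT_MASS_TABLE,
    mass_type: MassType = "average",
    tolerance: float = 0.5,
) -> bool:
    """Whether a peak mass can correspond to a realistic oligopeptide.

    True iff ``mass - water`` lies within ``±tolerance`` of some non-empty
    non-negative integer combination of the 20 residue masses.  Decided by a
    reachability dynamic program on a mass grid of bin width
    ``<= tolerance / 2`` (floor 1e-4 Da), so grid rounding cannot eat the
    stated tolerance.
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    target = mass - table.water_mass(mass_type)
    residue_masses = sorted(set(table.residue_mass(mass_type).values()))
    if target < residue_masses[0] - tolerance:
        return False
    bin_w = max(tolerance / 2.0, 1e-4)
    n_bins = int(math.ceil((target + tolerance) / bin_w)) + 1
    reachable = np.zeros(n_bins, dtype=bool)
    reachable[0] = True  # the empty combination; excluded from the answer below
    steps = [int(round(m / bin_w)) for m in residue_masses]
    for step in steps:
        for b in range(step, n_bins):
            if reachable[b - step]:
                reachable[b] = True
    lo = max(int(math.floor((target - tolerance) / bin_w)), 1)
    hi = min(int(math.ceil((target + tolerance) / bin_w)), n_bins - 1)
    return bool(reachable[lo:hi + 1].any())
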