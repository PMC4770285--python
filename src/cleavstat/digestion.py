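"""Protein sequences, cleavage rules and in-silico proteolytic digestion.

The digestion engine simulates amino-acid-specific proteolytic cleavage of a
polypeptide chain.  A cleavage rule names the residues at which a protease or
chemical reagent cuts, the side of the residue on which the scissile bond
lies (N- or C-terminal), and contextual exceptions that suppress a cut when a
particular neighbour flanks the site (e.g. trypsin does not cut Lys-Pro or
Arg-Pro bonds).  Sixteen rules corresponding to commercially available
enzymes/reagents are built in, keyed by the residue-set shorthand used in
peptide-mass-fingerprinting practice ("KR" for trypsin, "AFILMV" for
thermolysin, ...).

Fragment masses are residue-mass sums plus one water; both average and
monoisotopic residue masses are supported.  Missed cleavages are modelled by
augmentation: a fragment with ``j`` missed cleavages is the concatenation of
``j + 1`` consecutive fully cleaved fragments and is reported alongside the
fully cleaved set, matching the behaviour of standard peptide-mass services.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, NamedTuple, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger("cleavstat")

# The 20 standard amino acids, alphabetical one-letter order.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET_SET = frozenset(ALPHABET)

MassType = Literal["monoisotopic", "average"]


class SequenceError(ValueError):
    """A sequence violates the 20-letter amino-acid alphabet."""


# ---------------------------------------------------------------------------
# Residue mass tables
# ---------------------------------------------------------------------------

#: Monoisotopic residue masses in Da (standard published values, as used by
#: the Expasy PeptideMass service).
MONOISOTOPIC_RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

#: Average residue masses in Da (same provenance).
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

WATER_MASS = {"monoisotopic": 18.010565, "average": 18.0153}


@dataclass(frozen=True)
class AminoAcidMassTable:
    """Residue masses (Da) for the 20 standard amino acids, plus water."""

    monoisotopic: dict[str, float]
    average: dict[str, float]
    water: dict[str, float]

    def residue_mass(self, mass_type: MassType) -> dict[str, float]:
        return getattr(self, mass_type)

    def water_mass(self, mass_type: MassType) -> float:
        return self.water[mass_type]

    def __post_init__(self) -> None:
        for tab in (self.monoisotopic, self.average):
            if set(tab) != ALPHABET_SET:
                raise ValueError("mass table must cover exactly the 20 standard residues")
            if any(m <= 0 for m in tab.values()):
                raise ValueError("residue masses must be strictly positive")
        for aa in ALPHABET:
            if self.monoisotopic[aa] > self.average[aa] + 0.1:
                raise ValueError(f"monoisotopic mass of {aa} exceeds average mass")


#: Default mass table used throughout the package.
DEFAULT_MASS_TABLE = AminoAcidMassTable(
    monoisotopic=MONOISOTOPIC_RESIDUE_MASS,
    average=AVERAGE_RESIDUE_MASS,
    water=WATER_MASS,
)


# ---------------------------------------------------------------------------
# Protein records and FASTA input
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    """An identified protein sequence over the 20-letter alphabet."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - ALPHABET_SET
        if bad:
            raise SequenceError(
                f"record {self.id!r}: illegal residue symbol(s) {sorted(bad)}"
            )
        if len(self.sequence) < 1:
            raise SequenceError(f"record {self.id!r}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


def load_fasta(path, policy: Literal["skip", "fail"] = "skip") -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    Sequences are upper-cased and trailing ``*`` stop symbols stripped.
    Records containing residues outside the 20-letter alphabet are skipped
    and logged (``policy="skip"``) or raise (``policy="fail"``).
    """
    records: list[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper().rstrip("*")
        try:
            records.append(ProteinRecord(id=entry.description or entry.id, sequence=seq))
        except SequenceError as exc:
            if policy == "fail":
                raise
            logger.warning("skipping record: %s", exc)
    if not records:
        warnings.warn(f"no valid protein records found in {path}", stacklevel=2)
    return records


def prepare_dataset(
    records: Iterable[ProteinRecord],
    min_length: int = 100,
    dedupe: bool = True,
) -> list[ProteinRecord]:
    """Apply the standard dataset-preparation filters.

    Removes proteins shorter than ``min_length`` residues (short chains show
    strong finite-size effects in interval and mass distributions) and, when
    ``dedupe`` is on, collapses exact sequence duplicates to the first record.
    """
    records = list(records)
    kept: list[ProteinRecord] = []
    seen: set[str] = set()
    n_short = n_dup = 0
    for rec in records:
        if rec.length < min_length:
            n_short += 1
            continue
        if dedupe:
            if rec.sequence in seen:
                n_dup += 1
                continue
            seen.add(rec.sequence)
        kept.append(rec)
    logger.info(
        "prepare_dataset: kept %d of %d (removed %d short, %d duplicate)",
        len(kept), len(records), n_short, n_dup,
    )
    return kept


# ---------------------------------------------------------------------------
# Cleavage rules
# ---------------------------------------------------------------------------

class SiteSpec(NamedTuple):
    residue: str
    side: Literal["N", "C"]  # side of the residue on which the bond is cut


class ExceptionSpec(NamedTuple):
    """Suppress the cut at a site residue when a stated neighbour flanks it."""

    applies_to: frozenset[str]      # subset of the rule's site residues
    neighbor_side: Literal["preceding", "following"]
    neighbor_residues: frozenset[str]


@dataclass(frozen=True)
class CleavageRule:
    """Residue/side/exception specification of a proteolytic cleavage."""

    short_notation: str
    display_name: str
    site_specs: tuple[SiteSpec, ...]
    exceptions: tuple[ExceptionSpec, ...] = ()

    def __post_init__(self) -> None:
        for spec in self.site_specs:
            if spec.residue not in ALPHABET_SET:
                raise ValueError(f"invalid site residue {spec.residue!r}")
        site_residues = {s.residue for s in self.site_specs}
        for exc in self.exceptions:
            if not exc.applies_to <= site_residues:
                raise ValueError("exception applies_to must be a subset of site residues")
            if not exc.neighbor_residues <= ALPHABET_SET:
                raise ValueError("invalid exception neighbour residue")

    @property
    def site_residues(self) -> frozenset[str]:
        return frozenset(s.residue for s in self.site_specs)


def _sites(residues: str, side: str) -> tuple[SiteSpec, ...]:
    return tuple(SiteSpec(r, side) for r in residues)  # type: ignore[arg-type]


def _exc(applies_to: str, neighbor_side: str, neighbors: str) -> ExceptionSpec:
    return ExceptionSpec(frozenset(applies_to), neighbor_side, frozenset(neighbors))  # type: ignore[arg-type]


def _builtin_registry() -> dict[str, CleavageRule]:
    rules = [
        CleavageRule(
            "AFILMV", "Thermolysin",
            _sites("AFILMV", "N"),
            (_exc("AFILMV", "preceding", "DE"),),
        ),
        CleavageRule("AFYWLIV", "Proteinase K", _sites("AFYWLIV", "C")),
        CleavageRule("D", "Microwave-assisted formic acid hydrolysis", _sites("D", "C")),
        CleavageRule(
            "DE", "Glu C (phosphate)",
            _sites("DE", "C"),
            (_exc("DE", "following", "P"), _exc("DE", "following", "E")),
        ),
        CleavageRule(
            "DEK", "Glu C (phosphate) + Lys C",
            _sites("DEK", "C"),
            (_exc("DE", "following", "P"), _exc("DE", "following", "E")),
        ),
        CleavageRule(
            "DK", "Asp N / Lys C",
            _sites("D", "N") + _sites("K", "C"),
        ),
        CleavageRule(
            "E", "Glu C (bicarbonate)",
            _sites("E", "C"),
            (_exc("E", "following", "P"), _exc("E", "following", "E")),
        ),
        CleavageRule("FL", "Pepsin (pH 1.3)", _sites("FL", "C")),
        CleavageRule(
            "FLMWY", "Chymotrypsin (F/L/M/W/Y)",
            _sites("FLMWY", "C"),
            (_exc("FLMWY", "following", "P"), _exc("Y", "preceding", "P")),
        ),
        CleavageRule("FLWYAEQ", "Pepsin (pH > 2)", _sites("FLWYAEQ", "C")),
        CleavageRule(
            "FYW", "Chymotrypsin (F/Y/W)",
            _sites("FYW", "C"),
            (_exc("FYW", "following", "P"), _exc("Y", "preceding", "P")),
        ),
        CleavageRule("K", "Lys C", _sites("K", "C")),
        CleavageRule(
            "KR", "Trypsin",
            _sites("KR", "C"),
            (_exc("KR", "following", "P"),),
        ),
        CleavageRule("KRFYW", "Trypsin/Chymotrypsin", _sites("KRFYW", "C")),
        CleavageRule("M", "CNBr", _sites("M", "C")),
        CleavageRule(
            "R", "Arg C",
            _sites("R", "C"),
            (_exc("R", "following", "P"),),
        ),
    ]
    return {r.short_notation: r for r in rules}


_REGISTRY = _builtin_registry()

#: Short notations of the 16 built-in cleavage rules, sorted.
RULE_NOTATIONS = tuple(sorted(_REGISTRY))


def builtin_rules() -> dict[str, CleavageRule]:
    """The 16 built-in cleavage rules, keyed by short notation."""
    return dict(_REGISTRY)


def get_rule(notation: str) -> CleavageRule:
    try:
        return _REGISTRY[notation]
    except KeyError:
        raise KeyError(
            f"unknown cleavage rule {notation!r}; known: {', '.join(RULE_NOTATIONS)}"
        ) from None


# ---------------------------------------------------------------------------
# Cleavage-site computation and digestion
# ---------------------------------------------------------------------------

def cleavage_sites(sequence: str, rule: CleavageRule) -> list[int]:
    """Cut positions of ``rule`` in ``sequence``.

    A cut at position ``i`` (1-based) lies between residues ``i`` and
    ``i + 1``.  A C-terminal site at residue ``i`` yields cut ``i``; an
    N-terminal site yields cut ``i - 1``.  Exceptions suppress their sites
    first; remaining cuts from all site residues are merged, and cuts at the
    sequence boundaries (0 or ``length``) are discarded.
    """
    bad = set(sequence) - ALPHABET_SET
    if bad:
        raise SequenceError(f"illegal residue symbol(s) {sorted(bad)}")
    n = len(sequence)
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    cuts: set[int] = set()
    for site in rule.site_specs:
        positions = np.nonzero(arr == ord(site.residue))[0] + 1  # 1-based
        if positions.size == 0:
            continue
        keep = np.ones(positions.size, dtype=bool)
        for exc in rule.exceptions:
            if site.residue not in exc.applies_to:
                continue
            if exc.neighbor_side == "preceding":
                nb_idx = positions - 2          # 0-based index of residue i-1
            else:
                nb_idx = positions              # 0-based index of residue i+1
            valid = (nb_idx >= 0) & (nb_idx < n)
            hit = np.zeros(positions.size, dtype=bool)
            nb = arr[nb_idx[valid]]
            hit[valid] = np.isin(nb, [ord(c) for c in exc.neighbor_residues])
            keep &= ~hit
        kept = positions[keep]
        cuts.update(int(p) if site.side == "C" else int(p) - 1 for p in kept)
    return sorted(c for c in cuts if 1 <= c <= n - 1)


class Fragment(NamedTuple):
    start: int      # 1-based inclusive
    end: int        # 1-based inclusive
    missed: int     # internal cleavage sites spanned
    mass: float     # Da


@dataclass
class FragmentSet:
    """Digestion result: base fragments plus missed-cleavage concatenations."""

    items: list[Fragment]
    rule: CleavageRule
    max_missed: int
    protein_id: str = ""
    mass_type: MassType = "average"

    def __iter__(self) -> Iterator[Fragment]:
        return iter(self.items)

    def __len__(self) -> int:
        return len(self.items)

    def masses(self) -> np.ndarray:
        return np.array([f.mass for f in self.items], dtype=float)

    def base_fragments(self) -> list[Fragment]:
        return [f for f in self.items if f.missed == 0]


def peptide_mass(
    residues: str,
    table: AminoAcidMassTable = DEFAULT_MASS_TABLE,
    mass_type: MassType = "average",
) -> float:
    """Mass of an oligopeptide: sum of residue masses plus one water (Da)."""
    if not residues:
        raise ValueError("empty peptide")
    masses = table.residue_mass(mass_type)
    try:
        total = sum(masses[aa] for aa in residues)
    except KeyError as exc:
        raise SequenceError(f"illegal residue symbol {exc.args[0]!r}") from None
    return total + table.water_mass(mass_type)


def digest(
    record: ProteinRecord,
    rule: CleavageRule,
    max_missed: int = 0,
    mass_type: MassType = "average",
    table: AminoAcidMassTable = DEFAULT_MASS_TABLE,
) -> FragmentSet:
    """In-silico digestion of ``record`` by ``rule``.

    The fully cleaved (missed = 0) fragments tile the sequence between
    consecutive cut positions; for ``max_missed = k`` every concatenation of
    up to ``k + 1`` consecutive base fragments is appended with its missed
    count.  Fragment masses use cumulative residue-mass sums, so the additive
    mass law (fragment mass = residue sum + water) holds to float precision.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    seq = record.sequence
    cuts = cleavage_sites(seq, rule)
    bounds = [0, *cuts, len(seq)]
    water = table.water_mass(mass_type)
    res_mass = table.residue_mass(mass_type)
    csum = np.concatenate(
        ([0.0], np.cumsum([res_mass[aa] for aa in seq]))
    )
    n_base = len(bounds) - 1
    items: list[Fragment] = []
    for j in range(0, min(max_missed, n_base - 1) + 1):
        for i in range(n_base - j):
            lo, hi = bounds[i], bounds[i + j + 1]
            items.append(Fragment(lo + 1, hi, j, float(csum[hi] - csum[lo] + water)))
    return FragmentSet(items, rule, max_missed, record.id, mass_type)
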