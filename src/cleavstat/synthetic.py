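"""Synthetic protein sequences with controlled statistical structure.

Two generators make the whole pipeline testable without external data:

* ``random_protein`` draws residues i.i.d. from a given composition — the
  null model, whose inter-residue intervals are geometric and whose
  normalized fragment-mass distributions are close to exponential.

* ``patchy_protein`` emulates the compositionally "patchy" arrangement seen
  in α-helical transmembrane proteins: a two-state Markov chain (kept with
  probability ``persistence`` per residue, otherwise redrawn uniformly)
  switches between a hydrophobic-enriched and a hydrophobic-depleted
  emission composition, producing interval and mass exceedance distributions
  broader than the exponential null.  The chain is symmetric, so the
  stationary state occupancy is 1/2 each and the marginal composition is the
  mean of the two state compositions independent of the persistence — which
  lets persistence be varied at fixed marginal composition.

The default state compositions enrich/deplete the thermolysin site set
(A, F, I, L, M, V) at 2.5x / 0.05x a uniform background, a contrast at which
the thermolysin-rule absolute K_stat separates patchy from composition-matched
i.i.d. groups nearly completely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .digestion import ALPHABET, ProteinRecord

#: Thermolysin cleavage-site residues (hydrophobic set driving the default patchiness).
HYDROPHOBIC_SET = "AFILMV"

_UNIFORM = np.full(20, 0.05)


def _composition_array(composition) -> np.ndarray:
    """Validate and convert a composition (dict or array in ALPHABET order)."""
    if isinstance(composition, dict):
        arr = np.array([composition.get(aa, 0.0) for aa in ALPHABET], dtype=float)
    else:
        arr = np.asarray(composition, dtype=float)
    if arr.shape != (20,):
        raise ValueError("composition must cover the 20 standard residues")
    if np.any(arr < 0):
        raise ValueError("composition frequencies must be non-negative")
    if abs(arr.sum() - 1.0) > 1e-9:
        raise ValueError(f"composition must sum to 1 (got {arr.sum():.12f})")
    return arr


def _scaled_composition(factor: float, subset: str = HYDROPHOBIC_SET) -> np.ndarray:
    """Uniform background with ``subset`` residues scaled by ``factor``."""
    arr = _UNIFORM.copy()
    idx = [ALPHABET.index(aa) for aa in subset]
    arr[idx] *= factor
    rest = [i for i in range(20) if i not in idx]
    arr[rest] *= (1.0 - arr[idx].sum()) / arr[rest].sum()
    return arr


#: Default "patch" emission compositions: thermolysin sites at 2.5x and 0.05x
#: a uniform background (hydrophobic-rich segments vs. depleted loops).
ENRICHED_COMPOSITION = _scaled_composition(2.5)
DEPLETED_COMPOSITION = _scaled_composition(0.05)
#: Marginal composition of the default patchy generator (state mean); used as
#: the matched-composition i.i.d. control group.
MIXTURE_COMPOSITION = (ENRICHED_COMPOSITION + DEPLETED_COMPOSITION) / 2.0


@dataclass(frozen=True)
class SyntheticGroupSpec:
    """Generation conditions for one labeled group of synthetic proteins."""

    n: int
    length_range: tuple[int, int] = (300, 600)
    compositions: tuple = (tuple(MIXTURE_COMPOSITION),)  # one (iid) or two (patchy) vectors
    persistence: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid length range")
        if not 0 <= self.persistence < 1:
            raise ValueError("persistence must lie in [0, 1)")
        if len(self.compositions) not in (1, 2):
            raise ValueError("one or two composition vectors required")
        for comp in self.compositions:
            _composition_array(np.asarray(comp))


def random_protein(length: int, composition=None, seed: int = 0,
                   record_id: str = "random") -> ProteinRecord:
    """I.i.d. residue sequence drawn from ``composition`` (default uniform)."""
    comp = _composition_array(_UNIFORM if composition is None else composition)
    rng = np.random.default_rng(seed)
    idx = rng.choice(20, size=length, p=comp)
    seq = "".join(ALPHABET[i] for i in idx)
    return ProteinRecord(id=record_id, sequence=seq)


def patchy_protein(length: int, state_compositions=None, persistence: float = 0.99,
                   seed: int = 0, record_id: str = "patchy") -> ProteinRecord:
    """Markov-modulated sequence with composition switching between two states.

    At each position the chain keeps its state with probability
    ``persistence`` and otherwise redraws it uniformly from the two states,
    so ``persistence = 0`` reduces exactly to i.i.d. draws from the state
    mixture; the current state's composition emits the residue.  Expected
    patch length is ``2 / (1 - persistence)``.  The initial state is drawn
    from the stationary (uniform) state distribution.
    """
    if state_compositions is None:
        state_compositions = (ENRICHED_COMPOSITION, DEPLETED_COMPOSITION)
    comps = [_composition_array(np.asarray(c)) for c in state_compositions]
    if len(comps) != 2:
        raise ValueError("exactly two state compositions required")
    if np.allclose(comps[0], comps[1]):
        warnings.warn("identical state compositions: degenerates to an i.i.d. "
                      "sequence", stacklevel=2)
    if not 0 <= persistence < 1:
        raise ValueError("persistence must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    # state path: keep with prob = persistence, else redraw uniformly
    redraw = rng.random(length) >= persistence
    redraw[0] = True
    proposals = rng.integers(0, 2, size=length)
    last_redraw = np.maximum.accumulate(np.where(redraw, np.arange(length), 0))
    state = proposals[last_redraw]
    u = rng.random(length)
    idx0 = np.searchsorted(np.cumsum(comps[0]), u, side="right")
    idx1 = np.searchsorted(np.cumsum(comps[1]), u, side="right")
    idx = np.minimum(np.where(state == 0, idx0, idx1), 19)
    seq = "".join(ALPHABET[i] for i in idx)
    return ProteinRecord(id=record_id, sequence=seq)


def generate_group(spec: SyntheticGroupSpec, label: str = "") -> list[ProteinRecord]:
    """Generate one group of proteins from its spec, deterministically."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    records = []
    for i in range(spec.n):
        length = int(rng.integers(lo, hi + 1))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        rec_id = f"{label or 'synth'}_{i:04d}"
        if len(spec.compositions) == 2:
            rec = patchy_protein(length, [np.asarray(c) for c in spec.compositions],
                                 spec.persistence, seed=sub_seed, record_id=rec_id)
        else:
            rec = random_protein(length, np.asarray(spec.compositions[0]),
                                 seed=sub_seed, record_id=rec_id)
        records.append(rec)
    return records


def make_benchmark(spec_group_a: SyntheticGroupSpec, spec_group_b: SyntheticGroupSpec,
                   labels: tuple[str, str] = ("A", "B")):
    """Labeled two-group benchmark: list of records plus an id -> label map."""
    recs_a = generate_group(spec_group_a, label=labels[0])
    recs_b = generate_group(spec_group_b, label=labels[1])
    records = recs_a + recs_b
    label_map = {r.id: labels[0] for r in recs_a}
    label_map.update({r.id: labels[1] for r in recs_b})
    return records, label_map


def patchy_spec(n: int, seed: int, length_range=(300, 600),
                persistence: float = 0.99) -> SyntheticGroupSpec:
    """Default patchy-group spec (thermolysin-site enriched/depleted states)."""
    return SyntheticGroupSpec(
        n=n, length_range=length_range,
        compositions=(tuple(ENRICHED_COMPOSITION), tuple(DEPLETED_COMPOSITION)),
        persistence=persistence, seed=seed,
    )


def random_spec(n: int, seed: int, length_range=(300, 600),
                composition=None) -> SyntheticGroupSpec:
    """I.i.d. control-group spec; defaults to the patchy marginal composition
    so that the two benchmark groups match in expected composition."""
    comp = MIXTURE_COMPOSITION if composition is None else _composition_array(composition)
    return SyntheticGroupSpec(n=n, length_range=length_range,
                              compositions=(tuple(comp),), seed=seed)
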