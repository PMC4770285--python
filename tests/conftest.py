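"""Shared fixtures and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from cleavstat import ProteinRecord, builtin_rules, random_protein


def brute_force_cleavage_sites(sequence: str, rule) -> list[int]:
    """Independent boundary-scanning oracle for cleavage positions.

    Checks every inter-residue boundary directly against the rule's site and
    exception text, without any of the engine's merging/vectorization logic.
    """
    n = len(sequence)
    cuts = []
    for b in range(1, n):  # boundary between residues b and b+1 (1-based)
        cut = False
        for site in rule.site_specs:
            if site.side == "C":
                pos = b            # site residue sits left of the boundary
            else:
                pos = b + 1        # N-terminal side: site residue right of it
            if sequence[pos - 1] != site.residue:
                continue
            suppressed = False
            for exc in rule.exceptions:
                if site.residue not in exc.applies_to:
                    continue
                if exc.neighbor_side == "preceding":
                    neighbor = sequence[pos - 2] if pos >= 2 else None
                else:
                    neighbor = sequence[pos] if pos < n else None
                if neighbor is not None and neighbor in exc.neighbor_residues:
                    suppressed = True
                    break
            if not suppressed:
                cut = True
                break
        if cut:
            cuts.append(b)
    return cuts


@pytest.fixture(scope="session")
def all_rules():
    return builtin_rules()


@pytest.fixture(scope="session")
def random_corpus() -> list[ProteinRecord]:
    """1000 i.i.d. random sequences of mixed lengths for engine-vs-oracle work."""
    rng = np.random.default_rng(2024)
    records = []
    for i in range(1000):
        length = int(rng.integers(30, 201))
        records.append(random_protein(length, seed=int(rng.integers(2**31 - 1)),
                                      record_id=f"rand_{i:04d}"))
    return records
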