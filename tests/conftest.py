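"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from phagetrna.trna_structure import pairing_count

_BASES = "ACGT"


def brute_force_arm(sequence: str, hint: str | None = None) -> int | None:
    """Independent exhaustive arm search (oracle).

    Scans every admissible loop placement directly, applying the same
    scoring and tie-break rules as the production finder but written as
    a flat loop with no shared code path beyond ``pairing_count``.
    Returns the winning loop start, or None if nothing passes the
    threshold.
    """
    sequence = sequence.upper()
    n = len(sequence)
    if hint is not None:
        starts = [p - 2 for p in range(n - 2) if sequence[p : p + 3] == hint]
        threshold = 3
    else:
        starts = list(range(n))
        threshold = 4
    best_key, best_start = None, None
    for loop_start in starts:
        if loop_start < 5 or loop_start + 12 > n:
            continue
        stem5 = sequence[loop_start - 5 : loop_start]
        stem3 = sequence[loop_start + 7 : loop_start + 12]
        pc = pairing_count(stem5, stem3)
        if pc < threshold:
            continue
        key = (-pc, abs(loop_start - 0.42 * n), loop_start)
        if best_key is None or key < best_key:
            best_key, best_start = key, loop_start
    return best_start


def complement_pair(base: str, rng: np.random.Generator) -> str:
    """A base that pairs with ``base`` (Watson–Crick or G:T wobble)."""
    partners = {"A": ["T"], "T": ["A", "G"], "G": ["C", "T"], "C": ["G"]}
    return str(rng.choice(partners[base]))


def random_planted_sequence(
    rng: np.random.Generator, anticodon: str
) -> str:
    """A random sequence with one fully paired planted anticodon arm."""
    stem5 = "".join(rng.choice(list(_BASES), size=5))
    stem3 = "".join(
        complement_pair(b, rng) for b in reversed(stem5)
    )
    flank1 = "".join(rng.choice(list(_BASES), size=2))
    flank2 = "".join(rng.choice(list(_BASES), size=2))
    loop = flank1 + anticodon + flank2
    prefix = "".join(
        rng.choice(list(_BASES), size=int(rng.integers(5, 35)))
    )
    suffix = "".join(
        rng.choice(list(_BASES), size=int(rng.integers(5, 35)))
    )
    return prefix + stem5 + loop + stem3 + suffix


def random_anticodon(rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_BASES), size=3))


@pytest.fixture(scope="session")
def small_scenario():
    """A trimmed scenario (5 phages) for fast unit tests."""
    import dataclasses

    from phagetrna.synthetic_data import default_scenario

    return dataclasses.replace(default_scenario(seed=42), n_phages=5)


@pytest.fixture(scope="session")
def small_pipeline(small_scenario):
    """Host genes, phage sets, truth and catalog for the small scenario."""
    from phagetrna.synthetic_data import (
        generate_host_trnas,
        generate_phage_collection,
        scenario_catalog,
    )

    host = generate_host_trnas(small_scenario)
    phage_sets, truth = generate_phage_collection(small_scenario, host)
    return {
        "scenario": small_scenario,
        "host": host,
        "phage_sets": phage_sets,
        "truth": truth,
        "catalog": scenario_catalog(small_scenario),
    }
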