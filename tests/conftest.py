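"""Shared fixtures: small synthetic study configurations, a demo pipeline
run, and the naive brute-force mapping oracle used to validate the k-mer
mapper."""

from __future__ import annotations

import numpy as np
import pytest

from evsmallrna.pipeline import demo_config, run_all
from evsmallrna.synthetic import SimConfig


def brute_force_map(read: str, targets: dict[str, str]) -> set[tuple[str, str]]:
    """O(reads x targets x length) double-loop containment scan implementing
    the acceptance predicate: the independent oracle for the k-mer mapper.

    Returns the set of (target_id, mode) pairs the predicate accepts.
    """
    hits = set()
    for tid, tseq in targets.items():
        lr, lt = len(read), len(tseq)
        if lr <= lt:
            if read in tseq and 2 * lr >= lt:          # coverage >= 1/2, inclusive
                hits.add((tid, "read_in_target"))
        else:
            if tseq in read and 2 * lr <= 3 * lt:      # ratio <= 3/2, inclusive
                hits.add((tid, "target_in_read"))
    return hits


def random_targets(rng: np.random.Generator, n: int, min_len: int = 10,
                   max_len: int = 40) -> dict[str, str]:
    out = {}
    for i in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        out[f"t{i:03d}"] = "".join("ACGT"[j] for j in rng.integers(0, 4, length))
    return out


@pytest.fixture(scope="session")
def equal_composition() -> dict:
    """Class compositions identical across conditions, so every unplanted
    feature has an exactly zero true log2 fold change."""
    comp = {"miRNA": 0.7, "snoRNA": 0.2, "piRNA": 0.1}
    return {"cell": dict(comp), "ev": dict(comp)}


@pytest.fixture(scope="session")
def small_config(equal_composition) -> SimConfig:
    """A fast generator configuration for unit-level checks."""
    return SimConfig(
        seed=11,
        classes=(("miRNA", 60, 18, 25), ("snoRNA", 30, 60, 100), ("piRNA", 30, 26, 32)),
        class_composition=equal_composition,
        n_features_enriched=8, n_features_depleted=4,
        library_size=20_000, duplicate_rate=0.1,
    )


@pytest.fixture(scope="session")
def demo_dir(tmp_path_factory):
    """One full demo pipeline run shared by the orchestration tests."""
    outdir = tmp_path_factory.mktemp("demo")
    run_all(demo_config(seed=1), outdir)
    return outdir
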