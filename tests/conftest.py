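"""Shared fixtures and independent oracles for the test suite."""

from functools import lru_cache

import numpy as np
import pytest

from culturoscope.seq import AlignScoring, IUPAC_MASK
from culturoscope.simulate import generate_reference_db


def pytest_configure(config):
    # hypothesis: derandomised, small budgets, CI-safe
    try:
        from hypothesis import settings, HealthCheck

        settings.register_profile(
            "suite", deadline=None, derandomize=True, max_examples=30,
            suppress_health_check=[HealthCheck.too_slow],
        )
        settings.load_profile("suite")
    except ImportError:
        pass


@pytest.fixture(scope="session")
def refdb_small():
    """Eight mock type strains, mutually <90% identical in the window."""
    return generate_reference_db(8, seed=11)


@pytest.fixture(scope="session")
def noise_free_run(tmp_path_factory):
    """A small noise-free end-to-end pipeline run, shared across tests."""
    from culturoscope.pipeline import RunConfig, run_pipeline

    outdir = tmp_path_factory.mktemp("noise_free_run")
    cfg = RunConfig(seed=3, scenario="demo", scenario_overrides={
        "error_model": {"substitution_rate": 0.0, "homopolymer_indel_rate": 0.0,
                        "bad_segment_prob": 0.0},
        "reads_per_sample": 250, "reads_per_colony": 20,
    })
    result = run_pipeline(cfg, outdir)
    return result


# ---------------------------------------------------------------------------
# Independent brute-force alignment oracle (recursive, free end gaps,
# affine run costs) — deliberately written as plain recursion over the
# remaining suffixes, not as the matrix recurrence the implementation uses.
# ---------------------------------------------------------------------------


def _compat(x: str, y: str) -> bool:
    mx = 0 if x == "N" else IUPAC_MASK[x]
    my = 0 if y == "N" else IUPAC_MASK[y]
    return bool(mx & my)


def oracle_align_score(a: str, b: str, sc: AlignScoring = AlignScoring()) -> float:
    n, m = len(a), len(b)

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, state: str) -> float:
        if i == n or j == m:
            return 0.0  # the rest is a free terminal gap
        s = sc.match if _compat(a[i], b[j]) else sc.mismatch
        options = [s + rec(i + 1, j + 1, "M")]
        options.append((sc.gap_extend if state == "X" else sc.gap_open)
                       + rec(i + 1, j, "X"))
        options.append((sc.gap_extend if state == "Y" else sc.gap_open)
                       + rec(i, j + 1, "Y"))
        return max(options)

    best = rec(0, 0, "start")
    for i0 in range(1, n + 1):       # free leading gap consuming a
        best = max(best, rec(i0, 0, "start"))
    for j0 in range(1, m + 1):       # free leading gap consuming b
        best = max(best, rec(0, j0, "start"))
    return best


def score_of_alignment(ra: str, rb: str, sc: AlignScoring = AlignScoring()) -> float:
    """Score an explicit alignment, terminal gap runs free, affine internal."""
    ncol = len(ra)
    lead = max(len(ra) - len(ra.lstrip("-")), len(rb) - len(rb.lstrip("-")))
    trail = max(len(ra) - len(ra.rstrip("-")), len(rb) - len(rb.rstrip("-")))
    score = 0.0
    in_gap = None
    for k in range(lead, ncol - trail):
        x, y = ra[k], rb[k]
        if x == "-" or y == "-":
            gap_row = "a" if x == "-" else "b"
            score += sc.gap_extend if in_gap == gap_row else sc.gap_open
            in_gap = gap_row
        else:
            score += sc.match if _compat(x, y) else sc.mismatch
            in_gap = None
    return score


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
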