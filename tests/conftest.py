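"""Shared fixtures: small synthetic maps, simulated lots, decoding oracle."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from nipscnv.cnv_hmm import HMMParams, batch_stats, normalize_totals
from nipscnv.gc_correct import identity_correction
from nipscnv.genome_windows import WindowMap, build_windows, uniform_track
from nipscnv import simulate as sim


@pytest.fixture
def uniform_10mb_map() -> WindowMap:
    """One 10 Mb chromosome, fully mappable, 1 Mb windows."""
    track = uniform_track([("chr1", 10_000_000)], bin_size=10_000, gc=0.41)
    return build_windows(track, 1_000_000)


@pytest.fixture
def coarse_genome_map() -> WindowMap:
    """Default macro genome at 10 Mb windows (fast whole-pipeline runs)."""
    return sim.default_genome_windows(10_000_000)


def simulate_lot(
    windows: WindowMap,
    n_samples: int,
    seed: int,
    depth: float = 10e6,
    events=(),
    gc_bias=None,
    male_fraction: float = 0.5,
):
    cfg = sim.SimConfig(
        windows=windows,
        n_samples=n_samples,
        depth_mean=depth,
        depth_sd=0.0,
        ff_model=sim.POST_ENRICHMENT,
        events=list(events),
        gc_bias=gc_bias,
        male_fraction=male_fraction,
        seed=seed,
    )
    samples, truth = sim.simulate_cohort(cfg)
    return samples, truth


def euploid_stats(windows: WindowMap, n_samples: int, seed: int, depth: float = 10e6):
    """Identity-corrected, normalized lot plus its batch statistics."""
    samples, _ = simulate_lot(windows, n_samples, seed, depth=depth, male_fraction=0.0)
    corrected = normalize_totals([identity_correction(s, windows) for s in samples])
    return corrected, batch_stats(corrected, windows)


def path_logprob(path, symbols, params: HMMParams) -> float:
    with np.errstate(divide="ignore"):
        logE = np.log(params.emission)
        logT = np.log(params.transition)
        logI = np.log(params.initial)
    score = logI[path[0]] + logE[path[0], symbols[0]]
    for t in range(1, len(symbols)):
        score += logT[path[t - 1], path[t]] + logE[path[t], symbols[t]]
    return float(score)


def viterbi_bruteforce(symbols, params: HMMParams, tol: float = 1e-9):
    """Exhaustive path enumeration oracle for the Viterbi decoder.

    Scores every state path in log space; returns the optimal score and
    every path within ``tol`` of it (floating-point score ties — including
    genuinely tied optima — cannot be ordered portably, so the decoder is
    required to produce *a* maximum-probability path, and the unique one
    when the optimum is separated by more than ``tol``).
    """
    sym = list(symbols)
    n_states = params.emission.shape[0]
    scored = [
        (path_logprob(path, sym, params), path)
        for path in itertools.product(range(n_states), repeat=len(sym))
    ]
    best = max(s for s, _ in scored)
    if not np.isfinite(best):
        raise ValueError("impossible emission")
    return best, [np.array(p) for s, p in scored if s >= best - tol]
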