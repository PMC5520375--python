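"""Synthetic-data generators with ground-truth tables.

Three generators emit fixtures with the statistical structure each pipeline
stage assumes, alongside truth tables for parameter-recovery tests:

* :func:`simulate_proteomes` — protein families at controlled percent
  identity (with paralog copies) buried among compositionally matched decoy
  sequences, the substrate of the reciprocal best-hit screen;
* :func:`simulate_clock_systems` — boolean factor-presence matrices with
  independent Bernoulli columns except for planted pairs at a specified odds
  ratio, the null/alternative structure of the co-occurrence test;
* :func:`simulate_expression` — expression matrices in which a stated
  fraction of genes carries a fixed-period sinusoid (given phase and
  amplitude) on top of a linear-trend background with Gaussian noise,
  sampled at the cadence of the diurnal microarray studies (default every
  4 h over 48 h).

All generators are deterministic for a given seed: identical configuration
plus seed yields byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Callable, Sequence

import numpy as np
import pandas as pd

from clockmine.datatypes import STANDARD_AA, ProteinSeq, TaxonGroup
from clockmine.homology import load_matrix

#: Sampling grid of the reference diurnal time-series design: every 4 h
#: across two full 24-h cycles.
DEFAULT_TIMEPOINTS = tuple(float(t) for t in range(0, 48, 4))

Dist = "float | tuple | Callable[[np.random.Generator, int], np.ndarray]"


def _draw(dist, rng: np.random.Generator, n: int) -> np.ndarray:
    """Draw n values from a scalar, ('uniform', lo, hi) / ('normal', mu, sd)
    spec, or a callable(rng, n)."""
    if callable(dist):
        return np.asarray(dist(rng, n), dtype=float)
    if isinstance(dist, (int, float)):
        return np.full(n, float(dist))
    kind, *params = dist
    if kind == "uniform":
        lo, hi = params
        return rng.uniform(lo, hi, size=n)
    if kind == "normal":
        mu, sd = params
        return rng.normal(mu, sd, size=n)
    raise ValueError(f"unknown distribution spec {dist!r}")


# ---------------------------------------------------------------------------
# Proteome simulation


@dataclass
class ProteomeSim:
    """Output bundle of :func:`simulate_proteomes`."""

    queries: list[ProteinSeq]
    proteomes: dict[str, list[ProteinSeq]]
    metadata: dict[str, tuple[str, TaxonGroup]]  # organism -> (genus, group)
    truth: pd.DataFrame  # columns: organism, subject_id, query_id


def _random_sequence(rng: np.random.Generator, length: int, alphabet: str = STANDARD_AA) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def _positive_exchange_table() -> dict[str, tuple[list[str], np.ndarray]]:
    """Per residue: BLOSUM62-positive exchange partners and weights."""
    matrix = load_matrix("BLOSUM62")
    table: dict[str, tuple[list[str], np.ndarray]] = {}
    for a in STANDARD_AA:
        partners = [b for b in STANDARD_AA if b != a and matrix[a, b] > 0]
        if partners:
            weights = np.array([matrix[a, b] for b in partners], dtype=float)
            table[a] = (partners, weights / weights.sum())
        else:
            others = [b for b in STANDARD_AA if b != a]
            table[a] = (others, np.full(len(others), 1.0 / len(others)))
    return table


def mutate_to_identity(
    sequence: str, identity: float, rng: np.random.Generator
) -> str:
    """Derive a homolog at a target percent identity by seeded substitution.

    ``round((1 - identity/100) * L)`` distinct positions are replaced, each
    by a residue drawn proportionally to its BLOSUM62-positive exchange
    scores, so realized identity equals the target to rounding precision.
    """
    table = _positive_exchange_table()
    length = len(sequence)
    n_sub = int(round((1.0 - identity / 100.0) * length))
    positions = rng.choice(length, size=n_sub, replace=False)
    chars = list(sequence)
    for pos in positions:
        partners, weights = table[chars[pos]]
        chars[pos] = str(rng.choice(partners, p=weights))
    return "".join(chars)


def simulate_proteomes(
    n_taxa: int,
    families: Sequence[tuple[str, float, int]],
    n_decoys: int,
    seed: int,
    query_length: int = 200,
    taxon_group: TaxonGroup = TaxonGroup.CYANOBACTERIA,
) -> ProteomeSim:
    """Simulate per-taxon proteomes containing planted homolog families.

    ``families`` lists ``(query_id, identity_percent, copies)``: each taxon
    receives ``copies`` homologs of each query, mutated to the target
    identity, plus ``n_decoys`` decoy sequences of shuffled composition.
    Identity must lie in [20, 100].
    """
    for query_id, identity, _ in families:
        if not 20.0 <= identity <= 100.0:
            raise ValueError(f"identity for {query_id!r} must lie in [20, 100]")
    rng = np.random.default_rng(seed)
    queries = [
        ProteinSeq(
            id=query_id,
            sequence=_random_sequence(rng, query_length),
            organism="query organism",
            taxon_group=taxon_group,
        )
        for query_id, _, _ in families
    ]
    pooled = "".join(q.sequence for q in queries)
    pool = np.array(list(pooled))
    proteomes: dict[str, list[ProteinSeq]] = {}
    metadata: dict[str, tuple[str, TaxonGroup]] = {}
    truth_rows = []
    for taxon_idx in range(n_taxa):
        organism = f"Simulotaxon strain T{taxon_idx + 1:03d}"
        genus = "Simulotaxon"
        metadata[organism] = (genus, taxon_group)
        prots: list[ProteinSeq] = []
        for (query_id, identity, copies), query in zip(families, queries):
            for copy_idx in range(copies):
                subject_id = f"T{taxon_idx + 1:03d}_{query_id}_c{copy_idx + 1}"
                seq = (
                    query.sequence
                    if identity >= 100.0
                    else mutate_to_identity(query.sequence, identity, rng)
                )
                prots.append(
                    ProteinSeq(
                        id=subject_id,
                        sequence=seq,
                        organism=organism,
                        genus=genus,
                        taxon_group=taxon_group,
                    )
                )
                truth_rows.append(
                    {"organism": organism, "subject_id": subject_id, "query_id": query_id}
                )
        for decoy_idx in range(n_decoys):
            seq = "".join(rng.choice(pool, size=query_length))
            prots.append(
                ProteinSeq(
                    id=f"T{taxon_idx + 1:03d}_decoy{decoy_idx + 1}",
                    sequence=seq,
                    organism=organism,
                    genus=genus,
                    taxon_group=taxon_group,
                )
            )
        proteomes[organism] = prots
    truth = pd.DataFrame(truth_rows, columns=["organism", "subject_id", "query_id"])
    return ProteomeSim(queries=queries, proteomes=proteomes, metadata=metadata, truth=truth)


# ---------------------------------------------------------------------------
# Presence-matrix simulation


def cell_probabilities(p_i: float, p_j: float, odds_ratio: float) -> tuple[float, float, float, float]:
    """2x2 cell probabilities with the given marginals and odds ratio.

    Returns ``(p11, p10, p01, p00)``. The joint-presence probability solves
    the quadratic implied by ``p11*p00 / (p10*p01) = OR``; infeasible
    (marginal, OR) combinations raise a config error.
    """
    if not (0.0 < p_i < 1.0 and 0.0 < p_j < 1.0):
        raise ValueError("marginals must lie strictly in (0, 1)")
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    if odds_ratio == 1.0:
        p11 = p_i * p_j
    else:
        a = odds_ratio - 1.0
        s = p_i + p_j
        disc = (1.0 + a * s) ** 2 - 4.0 * a * odds_ratio * p_i * p_j
        if disc < 0:
            raise ValueError("infeasible (marginal, odds ratio) combination")
        p11 = ((1.0 + a * s) - np.sqrt(disc)) / (2.0 * a)
    p10 = p_i - p11
    p01 = p_j - p11
    p00 = 1.0 - p_i - p_j + p11
    cells = (p11, p10, p01, p00)
    if min(cells) < -1e-12:
        raise ValueError("infeasible (marginal, odds ratio) combination")
    return tuple(max(c, 0.0) for c in cells)


@dataclass
class SystemsSim:
    """Output bundle of :func:`simulate_clock_systems`."""

    presence: pd.DataFrame  # boolean systems x factors
    truth: pd.DataFrame  # columns: factor_i, factor_j, odds_ratio


def simulate_clock_systems(
    n_systems: int,
    base_prevalence: dict[str, float],
    enriched_pairs: Sequence[tuple[str, str, float]] = (),
    seed: int = 0,
) -> SystemsSim:
    """Simulate a presence matrix with planted enriched factor pairs.

    Columns are independent Bernoulli draws at the given prevalences, except
    that each ``(i, j, odds_ratio)`` pair is drawn jointly from the 2x2
    distribution with those marginals and odds ratio. A factor may belong to
    at most one enriched pair. Prevalence 1.0 produces an all-ones column
    (0.0 all zeros); such constant columns cannot be enriched.
    """
    rng = np.random.default_rng(seed)
    factors = list(base_prevalence)
    enriched_factors: set[str] = set()
    for fi, fj, _ in enriched_pairs:
        for f in (fi, fj):
            if f not in base_prevalence:
                raise ValueError(f"enriched factor {f!r} has no prevalence")
            if f in enriched_factors:
                raise ValueError(f"factor {f!r} appears in more than one enriched pair")
            enriched_factors.add(f)
    data = pd.DataFrame(False, index=range(n_systems), columns=factors)
    for fi, fj, odds_ratio in enriched_pairs:
        p11, p10, p01, p00 = cell_probabilities(
            base_prevalence[fi], base_prevalence[fj], odds_ratio
        )
        draws = rng.choice(4, size=n_systems, p=[p11, p10, p01, p00])
        data[fi] = np.isin(draws, [0, 1])
        data[fj] = np.isin(draws, [0, 2])
    for f in factors:
        if f in enriched_factors:
            continue
        p = base_prevalence[f]
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"prevalence for {f!r} outside [0, 1]")
        data[f] = rng.random(n_systems) < p
    truth = pd.DataFrame(
        [{"factor_i": fi, "factor_j": fj, "odds_ratio": orat} for fi, fj, orat in enriched_pairs],
        columns=["factor_i", "factor_j", "odds_ratio"],
    )
    data.index = [f"system_{i + 1}" for i in range(n_systems)]
    return SystemsSim(presence=data, truth=truth)


# ---------------------------------------------------------------------------
# Expression simulation


@dataclass
class ExpressionSim:
    """Output bundle of :func:`simulate_expression`."""

    matrix: pd.DataFrame  # genes x timepoints, log-ratio units
    truth: pd.DataFrame  # gene_id, oscillating, phase, amplitude, slope, intercept


def simulate_expression(
    n_genes: int,
    frac_oscillating: float = 0.2,
    period: float = 24.0,
    phase_dist=("uniform", 0.0, 24.0),
    amp_dist=1.0,
    noise_sd: float = 0.5,
    trend_slope_dist=("normal", 0.0, 0.01),
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS,
    seed: int = 0,
) -> ExpressionSim:
    """Simulate an expression matrix with a planted oscillating fraction.

    Oscillators follow ``b0 + b1*t + A*cos(2*pi*(t - phi)/period)`` plus
    Gaussian noise; the remaining genes carry only the linear trend plus
    noise. Values are in log-ratio (l2m-like) units, so downstream analysis
    should skip the transform. The truth table records each gene's flag,
    phase, amplitude, slope and intercept.
    """
    if not 0.0 <= frac_oscillating <= 1.0:
        raise ValueError("frac_oscillating must lie in [0, 1]")
    t = np.asarray(list(timepoints), dtype=float)
    if t.size < 6:
        raise ValueError("at least 6 timepoints required")
    rng = np.random.default_rng(seed)
    n_osc = int(round(frac_oscillating * n_genes))
    oscillating = np.zeros(n_genes, dtype=bool)
    oscillating[:n_osc] = True
    phases = np.where(oscillating, _draw(phase_dist, rng, n_genes) % period, np.nan)
    amps = np.where(oscillating, np.abs(_draw(amp_dist, rng, n_genes)), 0.0)
    slopes = _draw(trend_slope_dist, rng, n_genes)
    intercepts = np.zeros(n_genes)
    w = 2.0 * np.pi / period
    rows = np.empty((n_genes, t.size))
    for g in range(n_genes):
        signal = intercepts[g] + slopes[g] * t
        if oscillating[g]:
            signal = signal + amps[g] * np.cos(w * (t - phases[g]))
        noise = rng.normal(0.0, noise_sd, size=t.size) if noise_sd > 0 else 0.0
        rows[g] = signal + noise
    gene_ids = [f"gene_{i + 1:05d}" for i in range(n_genes)]
    matrix = pd.DataFrame(rows, index=gene_ids, columns=[f"{x:g}" for x in t])
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "oscillating": oscillating,
            "phase": phases,
            "amplitude": amps,
            "slope": slopes,
            "intercept": intercepts,
        }
    ).set_index("gene_id")
    return ExpressionSim(matrix=matrix, truth=truth)
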