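"""Synthetic data generation and the random-weight null experiment.

The null experiment asks whether differential-degree findings could arise
from the master network's topology alone: weights are redrawn i.i.d. uniform
over the observed range, the whole degree pipeline is re-run, and SSP counts
are tallied over many trials.  The synthetic generator produces master
networks and weight matrices at the study's scale (79 nodes / 155 edges, 24
samples in 4 groups of 6) with optional planted between-group effects and
known ground truth, so every pipeline stage can be tested without external
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .design import ComparisonDesign, comparison_label, four_group_design
from .network import degree_matrix
from .stats import detect_ssp

__all__ = [
    "generate_random_weight_matrix",
    "run_random_null",
    "NullSummary",
    "generate_master_graph",
    "SyntheticScenario",
    "generate_group_weights",
    "simulate_dataset",
    "SimulatedDataset",
    "evaluate_recovery",
]


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def generate_random_weight_matrix(
    n_proteins: int,
    n_samples: int,
    weight_range: tuple[float, float],
    rng: np.random.Generator | int | None = None,
    protein_ids: Sequence[str] | None = None,
    sample_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Draw an i.i.d. uniform weight matrix over ``[low, high]``.

    ``low`` must be positive: these stand in for normalized spectral counts,
    which are strictly positive after the shared-protein filter.
    """
    low, high = map(float, weight_range)
    if low <= 0:
        raise ValueError(f"weight range minimum must be > 0, got {low}")
    if low >= high:
        raise ValueError(f"invalid weight range [{low}, {high}]")
    rng = _as_rng(rng)
    values = rng.uniform(low, high, size=(n_proteins, n_samples))
    index = pd.Index(
        protein_ids if protein_ids is not None else [f"P{i + 1}" for i in range(n_proteins)],
        name="protein",
    )
    columns = (
        list(sample_ids)
        if sample_ids is not None
        else [f"S{j + 1}" for j in range(n_samples)]
    )
    return pd.DataFrame(values, index=index, columns=columns)


@dataclass(frozen=True)
class NullSummary:
    """Outcome of the random-weight null: per-trial SSP counts and p summaries.

    ``trials`` has one row per (trial, comparison) with the SSP count and the
    minimum / median adjusted p-value; ``n_trials_with_ssp`` counts trials in
    which any comparison produced at least one SSP."""

    trials: pd.DataFrame
    n_trials: int
    n_trials_with_ssp: int
    alpha: float
    weight_range: tuple[float, float]
    seed: int | None


def run_random_null(
    master: nx.Graph,
    design: ComparisonDesign,
    n_trials: int = 100,
    weight_range: tuple[float, float] | None = None,
    observed: pd.DataFrame | None = None,
    alpha: float = 0.1,
    seed: int | None = None,
    equal_var: bool = False,
) -> NullSummary:
    """Re-run the SSP pipeline on randomly weighted networks.

    Each trial draws a fresh uniform weight matrix over ``weight_range``
    (taken from the min/max of ``observed`` when not given), computes the
    degree matrix on the same master network, and runs SSP detection with the
    same design.  Any SSP found here would be attributable to topology plus
    chance, not to the experimental weighting.
    """
    if weight_range is None:
        if observed is None:
            raise ValueError("provide weight_range or an observed weight matrix")
        values = observed.to_numpy(dtype=float)
        weight_range = (float(values.min()), float(values.max()))
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = _as_rng(seed)
    nodes = list(master.nodes)
    samples = design.sample_ids
    rows = []
    trials_with_ssp = 0
    for trial in range(n_trials):
        weights = generate_random_weight_matrix(
            len(nodes), len(samples), weight_range, rng,
            protein_ids=nodes, sample_ids=samples,
        )
        degrees = degree_matrix(master, weights)
        table = detect_ssp(degrees, design, alpha=alpha, equal_var=equal_var)
        any_ssp = False
        for (treated, control) in design.comparisons:
            label = comparison_label(treated, control)
            sub = table.loc[table["comparison"] == label]
            n_ssp = int(sub["is_ssp"].sum())
            any_ssp = any_ssp or n_ssp > 0
            rows.append(
                {
                    "trial": trial,
                    "comparison": label,
                    "n_ssp": n_ssp,
                    "min_p_adjusted": float(sub["p_adjusted"].min()),
                    "median_p_adjusted": float(sub["p_adjusted"].median()),
                }
            )
        trials_with_ssp += int(any_ssp)
    return NullSummary(
        trials=pd.DataFrame(rows),
        n_trials=n_trials,
        n_trials_with_ssp=trials_with_ssp,
        alpha=alpha,
        weight_range=weight_range,
        seed=seed,
    )


def generate_master_graph(
    n_nodes: int = 79,
    n_edges: int = 155,
    seed: np.random.Generator | int | None = None,
    model: str = "uniform",
) -> nx.Graph:
    """Generate a connected simple graph with exact node and edge counts.

    A uniformly random spanning tree (random attachment order) guarantees
    connectivity; the remaining ``n_edges - (n_nodes - 1)`` edges are sampled
    uniformly from the non-edges.  Defaults match the study's master network
    scale (79 proteins, 155 interactions).
    """
    if model != "uniform":
        raise ValueError(f"unknown model {model!r}")
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    max_edges = n_nodes * (n_nodes - 1) // 2
    if not n_nodes - 1 <= n_edges <= max_edges:
        raise ValueError(
            f"edge count {n_edges} infeasible for a connected simple graph "
            f"on {n_nodes} nodes (need {n_nodes - 1}..{max_edges})"
        )
    rng = _as_rng(seed)
    width = len(str(n_nodes))
    names = [f"P{str(i + 1).zfill(width)}" for i in range(n_nodes)]
    order = rng.permutation(n_nodes)
    g = nx.Graph()
    g.add_nodes_from(names)
    for pos in range(1, n_nodes):
        parent = order[rng.integers(0, pos)]
        g.add_edge(names[order[pos]], names[parent])
    while g.number_of_edges() < n_edges:
        i, j = rng.integers(0, n_nodes, size=2)
        if i != j and not g.has_edge(names[i], names[j]):
            g.add_edge(names[i], names[j])
    return g


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth labels of a planted-effect simulation.

    ``targets`` are the proteins the effect was aimed at (every one of their
    neighbours was shifted, so their degree shift is maximal).  ``shifted``
    are the proteins whose treated-group weights were actually multiplied.
    ``expected_ssps`` are all master nodes adjacent to at least one shifted
    protein — every node whose degree distribution genuinely differs between
    groups, targets included.  A detection outside ``expected_ssps`` is a true
    statistical false positive; a detection inside it but outside ``targets``
    is a real second-order effect of the perturbation, not an error.
    """

    targets: frozenset
    shifted: frozenset
    expected_ssps: frozenset


@dataclass(frozen=True)
class SyntheticScenario:
    """A stated world for end-to-end tests: study-scale network and design,
    log-normal baseline weights, and an optional planted effect.

    The planted effect multiplies the *treated-group* weights of the
    neighbours of each target protein by ``effect_size``; because a master
    node's degree is the sum of its neighbours' weights, this makes the
    *target* degree-differential, mirroring how neighbourhood abundance — not
    a protein's own level — drives its network prominence.  ``truth`` is
    therefore the target set.

    Defaults: the study's scale (79 nodes, 155 edges, 4 groups of 6 samples);
    baseline weights log-normal with median ``exp(-6) ≈ 2.5e-3`` and
    log-sd 1.5, spanning roughly 1e-4..1e-1 like molecular-weight-normalized
    spectral counts; multiplicative per-cell noise with log-sd 0.3 (~30%
    coefficient of variation, typical of spectral-count replicates).
    """

    n_nodes: int = 79
    n_edges: int = 155
    design: ComparisonDesign = field(default_factory=four_group_design)
    targets: tuple[str, ...] = ()
    effect_size: float = 1.0
    baseline_log_mean: float = -6.0
    baseline_log_sd: float = 1.5
    noise_log_sd: float = 0.3
    seed: int | None = None


def generate_group_weights(
    master: nx.Graph,
    design: ComparisonDesign,
    targets: Iterable[Hashable] = (),
    effect_size: float = 1.0,
    baseline_log_mean: float = -6.0,
    baseline_log_sd: float = 1.5,
    noise_log_sd: float = 0.3,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Simulate a weight matrix over a master network with a planted effect.

    Each protein gets a log-normal baseline shared across samples, perturbed
    per cell by multiplicative log-normal noise.  For every comparison's
    treated group, the weights of the *neighbours* of each target are
    multiplied by ``effect_size`` — the target itself is untouched, yet its
    degree shifts by the full factor, because degree sums neighbour weights.
    Returns ``(weights, truth)``; with ``effect_size == 1`` no signal is
    planted and all truth sets are empty.
    """
    if effect_size <= 0:
        raise ValueError("effect size must be > 0")
    targets = set(targets)
    outside = targets - set(master.nodes)
    if outside:
        raise ValueError(f"targets not in master network: {sorted(map(str, outside))}")
    rng = _as_rng(rng)
    nodes = list(master.nodes)
    samples = design.sample_ids
    baseline = np.exp(rng.normal(baseline_log_mean, baseline_log_sd, size=len(nodes)))
    noise = np.exp(rng.normal(0.0, noise_log_sd, size=(len(nodes), len(samples))))
    weights = pd.DataFrame(
        baseline[:, None] * noise,
        index=pd.Index(nodes, name="protein"),
        columns=samples,
    )
    shifted = sorted(
        {u for t in targets for u in master.neighbors(t)}, key=str
    )
    if effect_size != 1.0 and shifted:
        treated_samples = sorted(
            {s for treated, _ in design.comparisons for s in design.samples_of(treated)}
        )
        weights.loc[shifted, treated_samples] *= effect_size
    if effect_size == 1.0 or not shifted:
        truth = PlantedTruth(frozenset(), frozenset(), frozenset())
    else:
        shifted_set = frozenset(shifted)
        expected = frozenset(
            v for v in nodes if any(u in shifted_set for u in master.neighbors(v))
        )
        truth = PlantedTruth(frozenset(targets), shifted_set, expected)
    return weights, truth


@dataclass(frozen=True)
class SimulatedDataset:
    master: nx.Graph
    weights: pd.DataFrame
    design: ComparisonDesign
    truth: PlantedTruth
    scenario: SyntheticScenario


def simulate_dataset(scenario: SyntheticScenario) -> SimulatedDataset:
    """Realise a scenario: master graph, weight matrix, design and truth.

    If the scenario names no targets but has ``effect_size != 1``, one target
    is drawn uniformly at random from the master nodes.
    """
    rng = _as_rng(scenario.seed)
    master = generate_master_graph(scenario.n_nodes, scenario.n_edges, seed=rng)
    targets: tuple[str, ...] = scenario.targets
    if not targets and scenario.effect_size != 1.0:
        nodes = list(master.nodes)
        targets = (nodes[int(rng.integers(0, len(nodes)))],)
    weights, truth = generate_group_weights(
        master,
        scenario.design,
        targets=targets,
        effect_size=scenario.effect_size,
        baseline_log_mean=scenario.baseline_log_mean,
        baseline_log_sd=scenario.baseline_log_sd,
        noise_log_sd=scenario.noise_log_sd,
        rng=rng,
    )
    return SimulatedDataset(
        master=master, weights=weights, design=scenario.design,
        truth=truth, scenario=scenario,
    )


def evaluate_recovery(
    ssp_table: pd.DataFrame,
    truth: PlantedTruth | Iterable[Hashable],
    comparison: str | None = None,
) -> dict:
    """Score SSP detection against planted ground truth.

    ``truth`` may be a plain iterable of target proteins — then the
    true-positive rate is computed on it and every other detection counts as
    a false positive — or a :class:`PlantedTruth`, in which case the TPR is
    still on the targets but false positives are detections outside
    ``expected_ssps`` (proteins with no shifted neighbour, i.e. no real
    effect).  With ``comparison`` given only that comparison's rows are
    scored; otherwise a protein flagged in any comparison counts as detected.
    """
    if isinstance(truth, PlantedTruth):
        targets = set(truth.targets)
        no_effect_beyond = set(truth.expected_ssps) | targets
    else:
        targets = set(truth)
        no_effect_beyond = set(targets)
    table = ssp_table
    if comparison is not None:
        table = table.loc[table["comparison"] == comparison]
    detected = set(table.loc[table["is_ssp"], "protein"])
    tpr = len(detected & targets) / len(targets) if targets else float("nan")
    return {
        "tpr": tpr,
        "n_false_positives": len(detected - no_effect_beyond),
        "n_secondary": len((detected - targets) & no_effect_beyond),
        "detected": frozenset(detected),
    }
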