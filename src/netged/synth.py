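"""Synthetic data generators with planted shared structure.

Real disease association data cannot be shipped with the package, so every
analysis stage is exercised on synthetic inputs that reproduce the
statistical structure the methods presume:

* :class:`MechanismModel` emulates pairs of association tables whose
  entities (diseases) draw their annotations from latent "mechanisms".
  The overlap parameter ``rho`` controls the probability that an entity
  uses the *same* mechanism in both data types; at ``rho = 0`` the two
  tables are independent given the entity identities, while at
  ``rho = 1`` (and zero noise) two entities share annotations in the
  second table exactly when they do in the first.
* :class:`ComorbidityModel` emulates patient diagnosis records with
  planted comorbid disease pairs at a stated relative risk while keeping
  the marginal prevalences intact.
* :func:`simulate_random_network` draws uniform simple graphs with i.i.d.
  weights for oracle and property tests.

All generators are bit-reproducible from their (model, seed) arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io_formats import AssociationTable, DiagnosisRecords

__all__ = [
    "MechanismModel",
    "ComorbidityModel",
    "simulate_association_pair",
    "simulate_patient_records",
    "simulate_random_network",
]


@dataclass(frozen=True)
class MechanismModel:
    """Latent-mechanism model for a pair of association tables.

    Each of ``n_entities`` entities picks ``mechanisms_per_entity`` latent
    mechanisms per data type (out of ``n_mechanisms``); its annotations in
    a data type are the full annotation pools of its mechanisms for that
    type (pools of size ``pool_size``, disjoint across mechanisms and data
    types) plus ``noise_rate`` uniformly random annotations from that data
    type's annotation universe.  With probability ``rho`` a mechanism slot
    in data type 2 copies the corresponding slot of data type 1; otherwise
    it is drawn independently.
    """

    n_entities: int = 100
    n_mechanisms: int = 10
    mechanisms_per_entity: int = 1
    pool_size: int = 8
    rho: float = 0.5
    noise_rate: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mechanisms < 1:
            raise ValueError("n_mechanisms must be >= 1")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if self.mechanisms_per_entity < 1 or self.mechanisms_per_entity > self.n_mechanisms:
            raise ValueError("mechanisms_per_entity must be in [1, n_mechanisms]")
        if self.n_entities < 1 or self.pool_size < 1 or self.noise_rate < 0:
            raise ValueError("invalid model sizes")


def _pool(data_type: int, mechanism: int, size: int) -> list[str]:
    return [f"t{data_type}_m{mechanism:03d}_a{k:03d}" for k in range(size)]


def simulate_association_pair(model: MechanismModel) -> tuple[AssociationTable, AssociationTable]:
    """Draw two association tables over one entity set from the model."""
    rng = np.random.default_rng(model.seed)
    K, mpe = model.n_mechanisms, model.mechanisms_per_entity
    pools = {
        (t, k): _pool(t, k, model.pool_size) for t in (1, 2) for k in range(K)
    }
    universe = {t: [a for k in range(K) for a in pools[(t, k)]] for t in (1, 2)}
    entries1: dict[str, set[str]] = {}
    entries2: dict[str, set[str]] = {}
    for e in range(model.n_entities):
        name = f"ent{e:04d}"
        mech1 = rng.choice(K, size=mpe, replace=False)
        copy = rng.random(mpe) < model.rho
        mech2 = np.where(copy, mech1, rng.integers(0, K, size=mpe))
        anns1 = {a for k in mech1 for a in pools[(1, int(k))]}
        anns2 = {a for k in mech2 for a in pools[(2, int(k))]}
        if model.noise_rate:
            anns1.update(rng.choice(universe[1], size=model.noise_rate, replace=False))
            anns2.update(rng.choice(universe[2], size=model.noise_rate, replace=False))
        entries1[name] = anns1
        entries2[name] = anns2
    t1 = AssociationTable("synthetic-disease", "type1-annotation", entries1)
    t2 = AssociationTable("synthetic-disease", "type2-annotation", entries2)
    return t1, t2


@dataclass(frozen=True)
class ComorbidityModel:
    """Patient-record model with planted comorbid pairs.

    ``prevalences`` maps disease codes to marginal prevalences in (0, 1);
    ``planted`` lists (disease_i, disease_j, RR) triples where RR >= 1 is
    the relative co-occurrence lift, P(both) = RR * p_i * p_j.  A planted
    pair is sampled jointly from the 2x2 distribution with that joint
    probability, which leaves the marginals unchanged; all other diseases
    are independent Bernoulli draws.  A disease may occur in at most one
    planted pair.
    """

    n_patients: int = 10_000
    prevalences: dict[str, float] = field(default_factory=dict)
    planted: tuple[tuple[str, str, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for d, p in self.prevalences.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"prevalence of {d!r} must lie in (0, 1)")
        seen: set[str] = set()
        for i, j, rr in self.planted:
            if rr < 1.0:
                raise ValueError("relative risk must be >= 1")
            if i == j or i in seen or j in seen:
                raise ValueError("each disease may occur in at most one planted pair")
            seen.update((i, j))
            pi, pj = self.prevalences[i], self.prevalences[j]
            if rr * pi * pj > min(pi, pj):
                raise ValueError(
                    f"infeasible planting for ({i}, {j}): RR * p_i * p_j exceeds min(p_i, p_j)"
                )
            if pi + pj - rr * pi * pj > 1.0:
                raise ValueError(f"infeasible planting for ({i}, {j}): negative cell probability")


def default_disease_codes(n: int) -> list[str]:
    """Syntactically valid three-character ICD-10-style codes A00, A01, ..."""
    if n > 26 * 100:
        raise ValueError("too many diseases for the default code scheme")
    return [f"{chr(ord('A') + k // 100)}{k % 100:02d}" for k in range(n)]


def simulate_patient_records(model: ComorbidityModel) -> DiagnosisRecords:
    """Draw diagnosis records with the planted comorbidity structure."""
    rng = np.random.default_rng(model.seed)
    N = model.n_patients
    planted_members = {d for i, j, _ in model.planted for d in (i, j)}
    diseases = sorted(model.prevalences)
    cols: dict[str, np.ndarray] = {}
    for d in diseases:
        if d not in planted_members:
            cols[d] = rng.random(N) < model.prevalences[d]
    for i, j, rr in model.planted:
        pi, pj = model.prevalences[i], model.prevalences[j]
        p11 = rr * pi * pj
        probs = np.array([1 - pi - pj + p11, pj - p11, pi - p11, p11])
        draw = rng.choice(4, size=N, p=probs)
        cols[i] = draw >= 2
        cols[j] = (draw == 1) | (draw == 3)
    patients = {
        f"pat{row:06d}": {d for d in diseases if cols[d][row]} for row in range(N)
    }
    return DiagnosisRecords(patients)


def simulate_random_network(
    n_nodes: int,
    n_edges: int,
    weight_distribution: str = "uniform",
    seed: int = 0,
) -> nx.Graph:
    """Uniform simple graph on ``n_nodes`` with i.i.d. edge weights.

    ``weight_distribution`` is "uniform" (weights in (0, 1]) or "unit"
    (all weights 1).
    """
    max_edges = n_nodes * (n_nodes - 1) // 2
    if not 0 <= n_edges <= max_edges:
        raise ValueError(f"n_edges must lie in [0, {max_edges}]")
    rng = np.random.default_rng(seed)
    nodes = [f"n{k:04d}" for k in range(n_nodes)]
    g = nx.Graph(vocabulary="synthetic")
    g.add_nodes_from(nodes)
    chosen = rng.choice(max_edges, size=n_edges, replace=False)
    # map a flat index to the (i, j) pair with i < j
    pairs = np.array(np.triu_indices(n_nodes, k=1)).T
    for flat in chosen:
        i, j = pairs[flat]
        if weight_distribution == "uniform":
            w = float(1.0 - rng.random())  # in (0, 1]
        elif weight_distribution == "unit":
            w = 1.0
        else:
            raise ValueError(f"unknown weight distribution {weight_distribution!r}")
        g.add_edge(nodes[i], nodes[j], weight=w)
    return g
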