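"""Synthetic fixtures with the statistical structure the pipeline assumes.

Two generators:

* GGM embeddings — the embedding vector of each code, conditional on the
  others, is Gaussian with mean sum_c B_wc V_c and variance sigma^2, i.e.
  the joint columns are i.i.d. draws from a zero-mean Gaussian whose
  precision is (I - B)/sigma^2.  The planted support of the sparse
  symmetric B is the ground truth against which screening and regression
  recovery are measured.

* Patient event streams — codes are partitioned into latent conditions;
  each patient activates a random subset of conditions, and an active
  condition emits its codes clustered within a short window, on top of a
  low background rate.  Codes of the same condition therefore co-occur
  within the counting window at elevated rates, the structure the
  co-occurrence/SPPMI/SVD stage is designed to expose.

Neither generator attempts realistic EHR marginals (visit structure, code
frequency skew, billing semantics); they emulate only the dependency
structure the method consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .embed import EmbeddingSet
from .evaluate import RelationPair, RelationPairSet
from .io import EventTable, Vocabulary

__all__ = [
    "GGMSpec",
    "SyntheticTruth",
    "make_regular_spec",
    "make_chain_spec",
    "simulate_ggm_embeddings",
    "simulate_multisite_embeddings",
    "simulate_patient_events",
    "make_relation_pairs",
]


@dataclass
class GGMSpec:
    """Sparse symmetric conditional-dependency coefficients of the model.

    The implied precision is (I - B)/sigma^2; it must be positive definite,
    which holds whenever the spectral radius of B is below 1 (guaranteed by
    keeping row sums of |B| below 1).
    """

    B: np.ndarray
    sigma2: float = 1.0
    M: int = 1

    def __post_init__(self):
        self.B = np.asarray(self.B, dtype=float)
        p = self.B.shape[0]
        if self.B.shape != (p, p) or not np.allclose(self.B, self.B.T):
            raise ValueError("B must be square and symmetric")
        if np.any(np.diag(self.B) != 0):
            raise ValueError("B must have a zero diagonal")

    @property
    def p(self) -> int:
        return self.B.shape[0]

    def precision(self) -> np.ndarray:
        return (np.eye(self.p) - self.B) / self.sigma2

    def covariance(self) -> np.ndarray:
        omega = self.precision()
        vals = np.linalg.eigvalsh(omega)
        if vals.min() <= 0:
            raise ValueError(
                "implied precision is not positive definite; use a smaller edge magnitude"
            )
        return np.linalg.inv(omega)

    def support(self) -> np.ndarray:
        return self.B != 0

    def neighbors(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.B[i] != 0)

    def edges(self) -> list[tuple[int, int]]:
        iu, ju = np.nonzero(np.triu(self.B, k=1))
        return list(zip(iu.tolist(), ju.tolist()))


@dataclass
class SyntheticTruth:
    """Ground truth bundled with a synthetic fixture."""

    ggm: GGMSpec | None
    vocab: Vocabulary
    group_assignments: dict[str, int] | None = None
    known_pairs: RelationPairSet | None = None
    seeds: dict[str, int] = field(default_factory=dict)

    def neighbor_codes(self, code: str) -> tuple[str, ...]:
        i = self.vocab.index(code)
        return tuple(self.vocab.codes[j] for j in self.ggm.neighbors(i))


def _default_vocab(p: int, prefix: str = "PheCode") -> Vocabulary:
    return Vocabulary(tuple(f"{prefix}:{i:03d}" for i in range(p)))


def make_regular_spec(
    p: int,
    n_neighbors: int = 5,
    edge_magnitude: float = 0.15,
    sigma2: float = 1.0,
    seed: int = 0,
) -> GGMSpec:
    """Random regular support graph with constant positive edge weights.

    Every node has exactly ``n_neighbors`` planted neighbors; positive-
    definiteness requires n_neighbors * edge_magnitude < 1.
    """
    if (p * n_neighbors) % 2:
        raise ValueError("p * n_neighbors must be even for a regular support graph")
    if n_neighbors * edge_magnitude >= 1.0:
        raise ValueError(
            "n_neighbors * edge_magnitude must be < 1 for a positive definite precision; "
            "use a smaller edge magnitude"
        )
    g = nx.random_regular_graph(n_neighbors, p, seed=seed)
    B = np.zeros((p, p))
    for i, j in g.edges:
        B[i, j] = B[j, i] = edge_magnitude
    return GGMSpec(B, sigma2=sigma2)


def make_chain_spec(p: int = 3, edge: float = 0.3, sigma2: float = 1.0) -> GGMSpec:
    """Chain graph 0-1-2-...-(p-1): adjacent nodes conditionally dependent."""
    B = np.zeros((p, p))
    for i in range(p - 1):
        B[i, i + 1] = B[i + 1, i] = edge
    return GGMSpec(B, sigma2=sigma2)


def _sample_embeddings(spec: GGMSpec, vocab: Vocabulary, d: int, seed: int) -> EmbeddingSet:
    cov = spec.covariance()
    L = np.linalg.cholesky(cov)
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((spec.p, d))
    return EmbeddingSet(vocab, L @ Z)


def simulate_ggm_embeddings(
    p: int = 100,
    d: int = 1000,
    n_neighbors: int = 5,
    edge_magnitude: float = 0.15,
    sigma2: float = 1.0,
    seed: int = 0,
    spec: GGMSpec | None = None,
    code_prefix: str = "PheCode",
) -> tuple[EmbeddingSet, SyntheticTruth]:
    """Draw a p x d embedding matrix whose columns are i.i.d. GGM samples.

    The covariance Cholesky factor is computed once from the spec; the d
    draws are vectorized.  Same seed, same spec -> bit-identical output.
    """
    if spec is None:
        spec = make_regular_spec(p, n_neighbors, edge_magnitude, sigma2, seed=seed)
    vocab = _default_vocab(spec.p, code_prefix)
    emb = _sample_embeddings(spec, vocab, d, seed)
    truth = SyntheticTruth(
        spec, vocab, known_pairs=make_relation_pairs_from_spec(spec, vocab), seeds={"embeddings": seed}
    )
    return emb, truth


def simulate_multisite_embeddings(
    p: int = 60,
    d: int = 800,
    n_neighbors: int = 4,
    strong: float = 0.2,
    weak: float = 0.04,
    sigma2: float = 1.0,
    seed: int = 0,
    n_sites: int = 2,
    site_vocab_fraction: float = 1.0,
) -> tuple[list[EmbeddingSet], list[EmbeddingSet], SyntheticTruth]:
    """Two-plus-site fixture: shared support, heterogeneous edge magnitudes.

    Every planted edge is present at all sites, but is strong at one
    randomly chosen site and weak at the others — the regime in which
    pooling sites through the group penalty pays off, since no single site
    sees all edges clearly.  ``site_vocab_fraction < 1`` additionally drops
    a random fraction of codes from each site's vocabulary to exercise
    site-specific code availability.  Returns (train sets, validation sets,
    truth); validation sets are independent draws from the same per-site
    model.
    """
    rng = np.random.default_rng(seed)
    support = make_regular_spec(p, n_neighbors, min(strong, 0.9 / n_neighbors), seed=seed)
    edges = support.edges()
    specs = []
    strong_site = rng.integers(0, n_sites, size=len(edges))
    for m in range(n_sites):
        B = np.zeros((p, p))
        for e, (i, j) in enumerate(edges):
            mag = strong if strong_site[e] == m else weak
            B[i, j] = B[j, i] = mag
        specs.append(GGMSpec(B, sigma2=sigma2, M=n_sites))
    shared = GGMSpec(sum(s.B for s in specs) / n_sites, sigma2=sigma2, M=n_sites)
    vocab = _default_vocab(p)

    train, valid = [], []
    for m, s in enumerate(specs):
        site_vocab = vocab
        site_spec = s
        if site_vocab_fraction < 1.0:
            keep = np.sort(
                rng.choice(p, size=max(2, int(round(site_vocab_fraction * p))), replace=False)
            )
            site_vocab = Vocabulary(tuple(vocab.codes[i] for i in keep))
            site_spec = GGMSpec(s.B[np.ix_(keep, keep)], sigma2=sigma2, M=n_sites)
        t_seed = int(rng.integers(0, 2**31))
        v_seed = int(rng.integers(0, 2**31))
        train.append(_sample_embeddings(site_spec, site_vocab, d, t_seed))
        valid.append(_sample_embeddings(site_spec, site_vocab, d, v_seed))
    truth = SyntheticTruth(
        shared, vocab, known_pairs=make_relation_pairs_from_spec(shared, vocab), seeds={"base": seed}
    )
    return train, valid, truth


def simulate_patient_events(
    n_patients: int = 2000,
    groups: dict[str, int] | list[list[str]] | None = None,
    n_codes: int = 20,
    n_groups: int = 4,
    rate_within: float = 2.0,
    rate_background: float = 0.3,
    p_active: float = 0.4,
    horizon_days: int = 360,
    window: int = 30,
    seed: int = 0,
) -> tuple[EventTable, SyntheticTruth]:
    """Patient event streams in which same-condition codes cluster in time.

    Each patient activates each latent condition independently with
    probability ``p_active``; an active condition picks an onset day and
    each of its codes emits Poisson(``rate_within``) events uniformly
    within ``window`` days of onset.  Every code also emits
    Poisson(``rate_background``) background events uniformly over the
    horizon.  Same-day repeats collapse on ingestion.
    """
    if rate_within <= 0 or rate_background < 0:
        raise ValueError("rates must be positive (background may be zero)")
    if groups is None:
        per = n_codes // n_groups
        codes = [f"PheCode:{i:03d}" for i in range(n_codes)]
        groups = {c: i // per if i // per < n_groups else n_groups - 1 for i, c in enumerate(codes)}
    elif isinstance(groups, list):
        groups = {c: g for g, members in enumerate(groups) for c in members}
    codes = sorted(groups)
    group_ids = sorted(set(groups.values()))
    if not group_ids:
        raise ValueError("groups must be non-empty")
    members = {g: [c for c in codes if groups[c] == g] for g in group_ids}

    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str, int]] = []
    for pi in range(n_patients):
        pid = f"P{pi:05d}"
        for g in group_ids:
            if rng.random() >= p_active:
                continue
            onset = int(rng.integers(0, max(1, horizon_days - window)))
            for c in members[g]:
                k = rng.poisson(rate_within)
                for day in rng.integers(onset, onset + window + 1, size=k):
                    rows.append((pid, c, int(day)))
        for c in codes:
            k = rng.poisson(rate_background)
            for day in rng.integers(0, horizon_days, size=k):
                rows.append((pid, c, int(day)))
    table = EventTable.from_records(rows)
    vocab = Vocabulary(tuple(codes))
    pairs = [
        RelationPair(a, b, "similar", source="synthetic-group")
        for g in group_ids
        for ai, a in enumerate(members[g])
        for b in members[g][ai + 1 :]
    ]
    truth = SyntheticTruth(
        None,
        vocab,
        group_assignments=dict(groups),
        known_pairs=RelationPairSet(pairs),
        seeds={"events": seed},
    )
    return table, truth


def make_relation_pairs_from_spec(spec: GGMSpec, vocab: Vocabulary) -> RelationPairSet:
    """Planted conditional-dependency edges as 'related' pairs."""
    return RelationPairSet(
        RelationPair(vocab.codes[i], vocab.codes[j], "related", source="synthetic-edge")
        for i, j in spec.edges()
    )


def make_relation_pairs(truth: SyntheticTruth) -> RelationPairSet:
    """Read the truth out as a typed relation-pair set.

    Planted graph edges become 'related' pairs; same-latent-condition codes
    become 'similar' pairs.  Pair types derive from code namespaces.
    """
    pairs: list[RelationPair] = []
    if truth.ggm is not None:
        pairs.extend(make_relation_pairs_from_spec(truth.ggm, truth.vocab))
    if truth.group_assignments:
        by_group: dict[int, list[str]] = {}
        for c, g in truth.group_assignments.items():
            by_group.setdefault(g, []).append(c)
        for g, members in by_group.items():
            members = sorted(members)
            for ai, a in enumerate(members):
                for b in members[ai + 1 :]:
                    pairs.append(RelationPair(a, b, "similar", source="synthetic-group"))
    return RelationPairSet(pairs)
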