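"""Node-wise knowledge-network construction and serialization.

Running the sparse embedding regression with every code in a subset as the
target yields, per target, a selected neighborhood; aggregating the
neighborhoods gives a weighted graph of conditionally dependent codes.  The
model assumes a symmetric support, but node-wise fits can disagree, so
edges are symmetrized by union by default (an edge is kept if selected in
either direction — the "OR" neighborhood-selection convention), with the
"AND" rule available.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .embed import EmbeddingSet
from .io import code_type
from .regression import (
    IntegrativeEmbeddingRegression,
    ScreenSet,
    null_cosine_thresholds,
    screen,
)

__all__ = ["KnowledgeNetwork", "build_network", "export_network", "load_network"]

EDGE_COLUMNS = ["code_w", "code_c", "weight_wc", "weight_cw", "sites_wc", "sites_cw"]


@dataclass
class KnowledgeNetwork:
    """Weighted undirected graph over codes with per-direction provenance.

    Each edge row records the group-coefficient norm and the selecting
    sites for both regression directions (w as target selecting c, and c
    as target selecting w); a zero weight with empty sites means that
    direction did not select the edge.
    """

    nodes: tuple[str, ...]
    edges: pd.DataFrame
    rule: str = "union"
    failures: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if list(self.edges.columns) != EDGE_COLUMNS:
            self.edges = self.edges.reindex(columns=EDGE_COLUMNS)
        if ((self.edges["code_w"] == self.edges["code_c"])).any():
            raise ValueError("self-edges are not allowed")
        self.edges = self.edges.reset_index(drop=True)

    def __eq__(self, other) -> bool:
        if not isinstance(other, KnowledgeNetwork):
            return NotImplemented
        a = self.edges.sort_values(["code_w", "code_c"]).reset_index(drop=True)
        b = other.edges.sort_values(["code_w", "code_c"]).reset_index(drop=True)
        return self.nodes == other.nodes and self.rule == other.rule and a.equals(b)

    def edge_set(self) -> set[frozenset]:
        return {frozenset((w, c)) for w, c in zip(self.edges["code_w"], self.edges["code_c"])}

    def neighbors(self, code: str) -> tuple[str, ...]:
        out = set()
        for w, c in zip(self.edges["code_w"], self.edges["code_c"]):
            if w == code:
                out.add(c)
            elif c == code:
                out.add(w)
        return tuple(sorted(out))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(rule=self.rule)
        for n in self.nodes:
            g.add_node(n, code_type=code_type(n))
        for row in self.edges.itertuples(index=False):
            g.add_edge(
                row.code_w,
                row.code_c,
                weight=max(row.weight_wc, row.weight_cw),
                weight_wc=row.weight_wc,
                weight_cw=row.weight_cw,
                sites_wc=row.sites_wc,
                sites_cw=row.sites_cw,
            )
        return g

    def plot(self, ax=None, **draw_kw):
        """Spring-layout rendering colored by code type (needs matplotlib)."""
        import matplotlib.pyplot as plt

        g = self.to_networkx()
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 7))
        pos = nx.spring_layout(g, seed=0)
        palette = {"PheCode": "tab:blue", "RXNORM": "tab:orange", "CCS": "tab:green", "LAB": "tab:red"}
        colors = [palette.get(code_type(n), "tab:gray") for n in g.nodes]
        nx.draw_networkx(g, pos=pos, ax=ax, node_color=colors, font_size=7, **draw_kw)
        ax.set_axis_off()
        return ax


def _target_seed(base_seed: int, target: str) -> int:
    h = hashlib.blake2b(target.encode(), key=int(base_seed).to_bytes(8, "little"), digest_size=4)
    return int.from_bytes(h.digest(), "little") % (2**31)


def build_network(
    train_embs: Sequence[EmbeddingSet],
    valid_embs: Sequence[EmbeddingSet] | None = None,
    nodes: Sequence[str] | None = None,
    alpha: float | None = 0.05,
    n_null: int = 1000,
    seed: int = 0,
    lam1_grid=None,
    lam2_grid=None,
    fixed_lams: tuple[float, float] | None = None,
    rule: str = "union",
    site_names: Sequence[str] | None = None,
) -> KnowledgeNetwork:
    """Run the tuned integrative regression with every node as target.

    ``nodes`` defaults to the union of the site vocabularies; a target is
    fitted with the sites that carry it.  Penalties are tuned per target
    against ``valid_embs`` unless ``fixed_lams`` pins them.  Per-node
    failures are recorded in the returned network's failure manifest
    rather than aborting the build.  The result is independent of the
    iteration order of the targets (per-target randomness is keyed by the
    target code, not its position).
    """
    if rule not in ("union", "and"):
        raise ValueError("rule must be 'union' or 'and'")
    if fixed_lams is None and valid_embs is None:
        raise ValueError("validation embeddings required unless fixed_lams is given")
    site_names = list(site_names) if site_names else [f"site{m+1}" for m in range(len(train_embs))]
    if nodes is None:
        seen: list[str] = []
        have = set()
        for e in train_embs:
            for c in e.vocab.codes:
                if c not in have:
                    have.add(c)
                    seen.append(c)
        nodes = seen
    nodes = list(nodes)

    # screening thresholds computed once per site (global per pair type)
    thresholds_by_site: list[dict[str, dict[str, float]]] = []
    if alpha is not None:
        for e in train_embs:
            per_type: dict[str, dict[str, float]] = {}
            for tt in sorted(set(code_type(c) for c in nodes)):
                per_type[tt] = null_cosine_thresholds(e, tt, alpha=alpha, n_null=n_null, seed=seed)
            thresholds_by_site.append(per_type)

    directed: dict[tuple[str, str], tuple[float, list[str]]] = {}
    failures: dict[str, str] = {}
    for target in sorted(nodes):
        sites_with = [m for m, e in enumerate(train_embs) if target in e.vocab]
        if not sites_with:
            failures[target] = "absent from every site"
            continue
        try:
            tseed = _target_seed(seed, target)
            screens = []
            for m in sites_with:
                if alpha is None:
                    s = screen(train_embs[m], target, alpha=None, site=site_names[m])
                else:
                    s = screen(
                        train_embs[m],
                        target,
                        alpha=alpha,
                        n_null=n_null,
                        seed=tseed,
                        thresholds=thresholds_by_site[m][code_type(target)],
                        site=site_names[m],
                    )
                screens.append(s)
            model = IntegrativeEmbeddingRegression(
                [train_embs[m] for m in sites_with],
                target,
                screen_sets=screens,
                site_names=[site_names[m] for m in sites_with],
            )
            if fixed_lams is not None:
                res = model.fit(*fixed_lams)
            else:
                if valid_embs is None:
                    raise ValueError("validation embeddings required unless fixed_lams is given")
                res = model.fit_tuned(
                    [valid_embs[m] for m in sites_with], lam1_grid=lam1_grid, lam2_grid=lam2_grid
                )
            df = res.params
            for c in res.support:
                row = df.loc[c]
                w = float(np.linalg.norm(row.to_numpy()))
                sel_sites = [s for s in row.index if row[s] != 0.0]
                directed[(target, c)] = (w, sel_sites)
        except Exception as exc:  # per-node failure: log and continue
            failures[target] = str(exc)

    rows = []
    seen_pairs: set[frozenset] = set()
    for (w, c), (weight, sites_sel) in sorted(directed.items()):
        key = frozenset((w, c))
        if key in seen_pairs:
            continue
        seen_pairs.add(key)
        rev = directed.get((c, w))
        if rule == "and" and rev is None:
            continue
        rows.append(
            {
                "code_w": w,
                "code_c": c,
                "weight_wc": weight,
                "weight_cw": rev[0] if rev else 0.0,
                "sites_wc": ",".join(sites_sel),
                "sites_cw": ",".join(rev[1]) if rev else "",
            }
        )
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    if failures:
        warnings.warn(f"{len(failures)} node(s) failed during network construction")
    return KnowledgeNetwork(tuple(sorted(nodes)), edges, rule=rule, failures=failures)


def export_network(net: KnowledgeNetwork, directory, name: str = "network") -> tuple[Path, Path]:
    """Write the edge-list TSV and a JSON node-link document; round-trips."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tsv = directory / f"{name}.tsv"
    net.edges.to_csv(tsv, sep="\t", index=False, float_format="%.17g")
    doc = {
        "rule": net.rule,
        "nodes": [{"id": n, "code_type": code_type(n)} for n in net.nodes],
        "failures": net.failures,
        "links": net.edges.to_dict(orient="records"),
    }
    js = directory / f"{name}.json"
    js.write_text(json.dumps(doc, indent=1))
    return tsv, js


def load_network(path) -> KnowledgeNetwork:
    doc = json.loads(Path(path).read_text())
    edges = pd.DataFrame(doc["links"], columns=EDGE_COLUMNS)
    if len(edges):
        edges = edges.astype({"weight_wc": float, "weight_cw": float})
        edges["sites_wc"] = edges["sites_wc"].fillna("")
        edges["sites_cw"] = edges["sites_cw"].fillna("")
    return KnowledgeNetwork(
        tuple(n["id"] for n in doc["nodes"]), edges, rule=doc["rule"], failures=doc.get("failures", {})
    )
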