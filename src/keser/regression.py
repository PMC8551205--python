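"""Sparse embedding regression: cosine screening, single-site adaptive
elastic net, and integrative multi-site group-penalized regression.

The statistical model: embedding vectors follow a Gaussian graphical model
in which the vector of a target code w, conditional on all other code
vectors, is Gaussian with mean sum_c B_wc V_c and isotropic noise.  The
support of B encodes conditional dependency between codes, so selecting the
nonzero B_wc amounts to finding the codes clinically related to w.

Single site (adaptive elastic net, solved by cyclic coordinate descent on
the cosine Gram form):

    min_B || V_w/||V_w|| - sum_c B_wc V_c/||V_c|| ||^2
          + lam1 sum_c |B_wc| / |cos(V_w, V_c)| + lam2 sum_c B_wc^2

Multi-site (ridge + group lasso across sites, block coordinate descent):

    min_B sum_m || V_w(m)/||.|| - sum_c B_wc(m) V_c(m)/||.|| ||^2
        + sum_c lam1 * ||B_.c||_2 / ( max_m |cos_m(w,c)| * sqrt(#sites with c) )
        + lam2 sum_{c,m} B_wc(m)^2

with B_wc(m) fixed at zero for codes outside site m's screened candidate
set.  Both objectives are implemented exactly as stated — no 1/2 or 1/n
factors — so penalty grids are on the model's own scale.

Candidates are pre-screened per relation type: a code enters the candidate
set only if its cosine with the target reaches the upper-alpha quantile
(rho) of cosines among random pairs of the same type.

Tuning cannot use cross-validation over embedding coordinates (the d
columns are not independent replicates), so penalties are chosen by
minimizing a basis-free validation loss 1 - 2 b'r_v + b'G_v b computed from
a second embedding set trained on held-out patients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .embed import EmbeddingSet
from .evaluate import n_available_pairs, sample_null_pairs
from .io import code_type

__all__ = [
    "ScreenSet",
    "screen",
    "null_cosine_thresholds",
    "EmbeddingRegression",
    "EmbeddingRegressionResults",
    "IntegrativeEmbeddingRegression",
    "IntegrativeResults",
    "fit_single_site",
    "tune_single_site",
    "fit_integrative",
    "default_lambda2_grid",
]

# ---------------------------------------------------------------------------
# screening


@dataclass
class ScreenSet:
    """Candidate codes passing the per-type cosine screen for one target."""

    target: str
    candidates: tuple[str, ...]
    cosines: dict[str, float]
    rho: dict[str, float]
    alpha: float | None
    seed: int | None = None
    site: str | None = None

    def __post_init__(self):
        if self.target in self.candidates:
            raise ValueError("target cannot be its own candidate")


def null_cosine_thresholds(
    emb: EmbeddingSet,
    target_type: str,
    alpha: float = 0.05,
    n_null: int = 1000,
    seed: int = 0,
) -> dict[str, float]:
    """Upper-alpha cosine quantiles among random pairs, per relation type.

    One threshold per pair type involving ``target_type``, computed globally
    over the vocabulary (not per target).  alpha=0 uses the maximum null
    cosine.
    """
    from .evaluate import pair_scores

    thresholds: dict[str, float] = {}
    other_types = sorted(set(emb.vocab.types))
    for ot in other_types:
        ptype = "-".join(sorted((target_type, ot)))
        if ptype in thresholds:
            continue
        avail = n_available_pairs(emb.vocab, ptype)
        if avail == 0:
            continue
        nulls = sample_null_pairs(emb.vocab, ptype, min(n_null, avail), seed=seed)
        scores = pair_scores(emb, nulls)
        if alpha == 0:
            thresholds[ptype] = float(scores.max())
        else:
            thresholds[ptype] = float(np.quantile(scores, 1.0 - alpha, method="higher"))
    return thresholds


def screen(
    emb: EmbeddingSet,
    target: str,
    alpha: float | None = 0.05,
    n_null: int = 1000,
    seed: int = 0,
    candidate_types: Sequence[str] | None = None,
    thresholds: dict[str, float] | None = None,
    site: str | None = None,
) -> ScreenSet:
    """Marginal cosine screening of regression candidates for one target.

    Keeps codes whose cosine with the target reaches rho, the upper-alpha
    quantile of cosines among random pairs of the same relation type
    (thresholds may be precomputed once per vocabulary and passed in).
    ``alpha=None`` disables screening and admits every other code — the
    right choice for vocabularies too small to estimate null quantiles.
    """
    if target not in emb.vocab:
        raise ValueError(f"target {target!r} not in vocabulary")
    U = emb.rows_normalized()
    ti = emb.vocab.index(target)
    cos_all = U @ U[ti]
    ttype = code_type(target)

    cands, cosines = [], {}
    if alpha is None:
        for j, c in enumerate(emb.vocab.codes):
            if c == target:
                continue
            if candidate_types is not None and code_type(c) not in candidate_types:
                continue
            cands.append(c)
            cosines[c] = float(cos_all[j])
        return ScreenSet(target, tuple(cands), cosines, {}, None, seed, site)

    if thresholds is None:
        thresholds = null_cosine_thresholds(emb, ttype, alpha=alpha, n_null=n_null, seed=seed)
    for j, c in enumerate(emb.vocab.codes):
        if c == target:
            continue
        ctype = code_type(c)
        if candidate_types is not None and ctype not in candidate_types:
            continue
        ptype = "-".join(sorted((ttype, ctype)))
        if ptype not in thresholds:
            continue
        if cos_all[j] >= thresholds[ptype]:
            cands.append(c)
            cosines[c] = float(cos_all[j])
    if not cands:
        warnings.warn(f"screen for {target!r} selected no candidates")
    return ScreenSet(target, tuple(cands), cosines, dict(thresholds), alpha, seed, site)


# ---------------------------------------------------------------------------
# solvers

#: relative validation-loss tolerance of the tuning tie-break: among grid
#: points within this fraction of the minimal validation loss, the sparsest
#: fit (then the smaller lam2) wins.  A one-standard-error-style rule for a
#: deterministic loss: a spurious noise-level coefficient moves the loss by
#: O(1/d), well inside the tolerance, while a genuine signal moves it by
#: its squared coefficient, well outside.
TUNING_LOSS_TOL = 0.01


def _soft(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


def _cd_elastic_net(
    r: np.ndarray,
    G: np.ndarray,
    w: np.ndarray,
    lam1: float,
    lam2: float,
    b0: np.ndarray | None = None,
    max_iter: int = 2000,
    tol: float = 1e-10,
) -> tuple[np.ndarray, int, bool]:
    """Cyclic coordinate descent for the single-site objective in Gram form.

    Minimizes 1 - 2 b'r + b'Gb + lam1 sum w_j|b_j| + lam2 sum b_j^2 with
    G_jj = 1.  Each coordinate update is the exact scalar minimizer
    (soft-threshold over an elastic-net denominator), so the objective is
    non-increasing every sweep.
    """
    p = r.size
    b = np.zeros(p) if b0 is None else b0.astype(float).copy()
    Gb = G @ b
    thr = lam1 * w / 2.0
    denom = np.diag(G) + lam2
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        max_step = 0.0
        for j in range(p):
            z = r[j] - (Gb[j] - G[j, j] * b[j])
            new = _soft(z, thr[j]) / denom[j]
            step = new - b[j]
            if step != 0.0:
                Gb += G[:, j] * step
                b[j] = new
                max_step = max(max_step, abs(step))
        if max_step < tol:
            converged = True
            break
    return b, it, converged


def _bcd_group(
    r_sites: list[np.ndarray],
    G_sites: list[np.ndarray],
    member_idx: list[np.ndarray],
    group_w: np.ndarray,
    lam1: float,
    lam2: float,
    b0: list[np.ndarray] | None = None,
    max_iter: int = 2000,
    tol: float = 1e-10,
) -> tuple[list[np.ndarray], int, bool]:
    """Block coordinate descent over cross-site coefficient groups.

    ``member_idx[m]`` maps each of site m's candidate positions to a group
    id; group g collects coefficient B_wc(m) for code c across the sites
    where c was screened in.  Each block update is the exact group
    soft-threshold for the stated objective (site losses have unit diagonal
    Gram entries).
    """
    M = len(r_sites)
    n_groups = group_w.size
    b = [np.zeros(r.size) for r in r_sites] if b0 is None else [x.astype(float).copy() for x in b0]
    Gb = [G_sites[m] @ b[m] for m in range(M)]
    # positions of each group in each site's coefficient vector
    pos: list[list[tuple[int, int]]] = [[] for _ in range(n_groups)]
    for m in range(M):
        for j, g in enumerate(member_idx[m]):
            pos[g].append((m, j))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        max_step = 0.0
        for g in range(n_groups):
            members = pos[g]
            z = np.array(
                [r_sites[m][j] - (Gb[m][j] - G_sites[m][j, j] * b[m][j]) for m, j in members]
            )
            znorm = float(np.linalg.norm(z))
            t = lam1 * group_w[g] / 2.0
            if znorm <= t:
                beta = np.zeros(len(members))
            else:
                beta = z * (1.0 - t / znorm) / (1.0 + lam2)
            for (m, j), new in zip(members, beta):
                step = new - b[m][j]
                if step != 0.0:
                    Gb[m] += G_sites[m][:, j] * step
                    b[m][j] = new
                    max_step = max(max_step, abs(step))
        if max_step < tol:
            converged = True
            break
    return b, it, converged


# ---------------------------------------------------------------------------
# single-site model


def _gram_quantities(emb: EmbeddingSet, target: str, candidates: Sequence[str]):
    U = emb.rows_normalized()
    ti = emb.vocab.index(target)
    ci = np.array([emb.vocab.index(c) for c in candidates], dtype=int)
    X = U[ci]
    r = X @ U[ti]
    G = X @ X.T
    np.fill_diagonal(G, 1.0)
    return r, G


def _adaptive_weights(cosines: np.ndarray, rho: dict[str, float]) -> np.ndarray:
    """1/|cos| penalty weights with a safety cap at 1/rho_min.

    Screening normally keeps |cos| away from zero; the cap only guards the
    unscreened (alpha=None) path against division blow-up.
    """
    floor = min((abs(v) for v in rho.values() if v != 0), default=1e-8)
    floor = max(min(floor, 1.0), 1e-8)
    capped = np.maximum(np.abs(cosines), floor)
    small = np.abs(cosines) < floor
    if small.any():
        warnings.warn(f"{int(small.sum())} candidate(s) hit the 1/|cos| weight cap")
    return 1.0 / capped


class EmbeddingRegression:
    """Single-site sparse embedding regression for one target code.

    Built from an :class:`EmbeddingSet` plus either a :class:`ScreenSet`
    (the usual route) or an explicit candidate list.  ``fit`` solves the
    adaptive elastic net at given penalties; ``fit_tuned`` grid-searches
    the penalties against validation embeddings.
    """

    def __init__(
        self,
        embeddings: EmbeddingSet,
        target: str,
        screen_set: ScreenSet | None = None,
        candidates: Sequence[str] | None = None,
    ):
        if target not in embeddings.vocab:
            raise ValueError(f"target {target!r} not in vocabulary")
        if screen_set is None and candidates is None:
            screen_set = screen(embeddings, target, alpha=None)
        if screen_set is not None:
            if screen_set.target != target:
                raise ValueError("screen set targets a different code")
            candidates = screen_set.candidates
            rho = screen_set.rho
        else:
            candidates = tuple(candidates)
            rho = {}
        if len(candidates) == 0:
            raise ValueError("candidate set is empty")
        self.embeddings = embeddings
        self.target = target
        self.screen_set = screen_set
        self.candidates = tuple(candidates)
        self.r, self.G = _gram_quantities(embeddings, target, self.candidates)
        self.weights = _adaptive_weights(self.r, rho)

    @classmethod
    def from_screen(cls, embeddings: EmbeddingSet, screen_set: ScreenSet) -> "EmbeddingRegression":
        return cls(embeddings, screen_set.target, screen_set=screen_set)

    @property
    def lambda1_max(self) -> float:
        """Smallest lam1 at which the all-zero solution is stationary."""
        return float(np.max(2.0 * np.abs(self.r) / self.weights))

    def default_lambda1_grid(self, n: int = 20, decades: float = 3.0) -> np.ndarray:
        top = max(self.lambda1_max, 1e-12)
        return np.geomspace(top, top * 10.0**-decades, n)

    def objective(self, b: np.ndarray, lam1: float, lam2: float) -> float:
        b = np.asarray(b, dtype=float)
        return float(
            1.0
            - 2.0 * b @ self.r
            + b @ self.G @ b
            + lam1 * np.sum(self.weights * np.abs(b))
            + lam2 * np.sum(b**2)
        )

    def fit(
        self,
        lam1: float,
        lam2: float,
        start: np.ndarray | None = None,
        max_iter: int = 2000,
        tol: float = 1e-10,
    ) -> "EmbeddingRegressionResults":
        if lam1 < 0 or lam2 < 0:
            raise ValueError("penalties must be non-negative")
        b, n_iter, converged = _cd_elastic_net(
            self.r, self.G, self.weights, lam1, lam2, b0=start, max_iter=max_iter, tol=tol
        )
        if not converged:
            warnings.warn(f"coordinate descent did not converge in {max_iter} sweeps")
        return EmbeddingRegressionResults(self, b, lam1, lam2, n_iter, converged)

    def validation_quantities(self, valid_emb: EmbeddingSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(shared-candidate mask, r_v, G_v) from validation embeddings."""
        shared = np.array([c in valid_emb.vocab for c in self.candidates])
        if self.target not in valid_emb.vocab:
            raise ValueError("target absent from validation embeddings")
        cand_v = [c for c, ok in zip(self.candidates, shared) if ok]
        if not cand_v:
            raise ValueError("no candidates shared with validation embeddings")
        r_v, G_v = _gram_quantities(valid_emb, self.target, cand_v)
        return shared, r_v, G_v

    def fit_tuned(
        self,
        valid_emb: EmbeddingSet,
        lam1_grid: Sequence[float] | None = None,
        lam2_grid: Sequence[float] | None = None,
        loss_tol: float = TUNING_LOSS_TOL,
        **fit_kw,
    ) -> "EmbeddingRegressionResults":
        """Grid search minimizing the basis-free validation loss.

        The loss 1 - 2 b'r_v + b'G_v b uses only cosine quantities from the
        validation embeddings, so the two factorizations need not share a
        basis.  Among grid points within ``loss_tol`` (relative) of the
        minimal loss, the sparsest fit wins, then the smaller lam2.  Fits
        on candidates shared between the two vocabularies.
        """
        shared, r_v, G_v = self.validation_quantities(valid_emb)
        if not shared.all():
            model = EmbeddingRegression(
                self.embeddings,
                self.target,
                candidates=[c for c, ok in zip(self.candidates, shared) if ok],
            )
            if self.screen_set is not None:
                model.weights = _adaptive_weights(model.r, self.screen_set.rho)
            return model.fit_tuned(valid_emb, lam1_grid, lam2_grid, loss_tol, **fit_kw)
        if lam1_grid is None:
            lam1_grid = self.default_lambda1_grid()
        if lam2_grid is None:
            lam2_grid = default_lambda2_grid()
        best = None
        for lam2 in sorted(lam2_grid):
            start = None
            for lam1 in sorted(lam1_grid, reverse=True):
                res = self.fit(lam1, lam2, start=start, **fit_kw)
                start = res.params_array
                loss = float(1.0 - 2.0 * start @ r_v + start @ G_v @ start)
                key = (loss, res.n_selected, lam2)
                if best is None or _tuning_better(key, best[0], rtol=loss_tol):
                    best = (key, res)
        res = best[1]
        res.validation_loss = best[0][0]
        return res


def _tuning_better(key, ref, rtol: float = TUNING_LOSS_TOL) -> bool:
    loss, nsel, lam2 = key
    rloss, rnsel, rlam2 = ref
    scale = max(abs(loss), abs(rloss), 1.0)
    if loss < rloss - rtol * scale:
        return True
    if loss > rloss + rtol * scale:
        return False
    return (nsel, lam2) < (rnsel, rlam2)


def default_lambda2_grid(n: int = 5) -> np.ndarray:
    return np.geomspace(1e-4, 1.0, n)


class EmbeddingRegressionResults:
    """Fitted coefficients and diagnostics of a single-site regression."""

    def __init__(self, model: EmbeddingRegression, b: np.ndarray, lam1, lam2, n_iter, converged):
        self.model = model
        self.params_array = np.asarray(b, dtype=float)
        self.lam1 = float(lam1)
        self.lam2 = float(lam2)
        self.n_iter = int(n_iter)
        self.converged = bool(converged)
        self.objective = model.objective(self.params_array, self.lam1, self.lam2)
        self.validation_loss: float | None = None

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.params_array, index=list(self.model.candidates), name=self.model.target)

    @property
    def selected(self) -> tuple[str, ...]:
        return tuple(c for c, v in zip(self.model.candidates, self.params_array) if v != 0.0)

    @property
    def n_selected(self) -> int:
        return int(np.count_nonzero(self.params_array))

    def kkt_residual(self) -> float:
        """Maximum violation of the stationarity conditions at the solution."""
        m = self.model
        b = self.params_array
        grad = -2.0 * m.r + 2.0 * m.G @ b + 2.0 * self.lam2 * b
        pen = self.lam1 * m.weights
        active = b != 0
        res = 0.0
        if active.any():
            res = max(res, float(np.max(np.abs(grad[active] + pen[active] * np.sign(b[active])))))
        if (~active).any():
            res = max(res, float(np.max(np.maximum(np.abs(grad[~active]) - pen[~active], 0.0))))
        return res

    def summary(self) -> str:
        lines = [
            "Sparse embedding regression (single site)",
            "=" * 45,
            f"target:       {self.model.target}",
            f"candidates:   {len(self.model.candidates)}  (selected: {self.n_selected})",
            f"lam1, lam2:   {self.lam1:.6g}, {self.lam2:.6g}",
            f"objective:    {self.objective:.6g}",
            f"converged:    {self.converged} ({self.n_iter} sweeps)",
        ]
        if self.validation_loss is not None:
            lines.append(f"valid. loss:  {self.validation_loss:.6g}")
        sel = self.params[self.params != 0].sort_values(key=np.abs, ascending=False)
        if len(sel):
            lines.append("-" * 45)
            lines.append(f"{'code':<30}{'coef':>12}")
            for code, coef in sel.items():
                lines.append(f"{code:<30}{coef:>12.5f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "target": self.model.target,
            "lam1": self.lam1,
            "lam2": self.lam2,
            "objective": self.objective,
            "converged": self.converged,
            "coefficients": {c: float(v) for c, v in self.params.items() if v != 0.0},
            "rho": self.model.screen_set.rho if self.model.screen_set else {},
            "seed": self.model.screen_set.seed if self.model.screen_set else None,
        }


# ---------------------------------------------------------------------------
# integrative model


class IntegrativeEmbeddingRegression:
    """Multi-site embedding regression with a cross-site group penalty.

    Coefficient groups collect a candidate code's coefficients across the
    sites where it passed screening; the group-lasso penalty selects a code
    when its pooled evidence is strong, borrowing signal across sites while
    the per-site coefficients absorb heterogeneity in magnitude.
    """

    def __init__(
        self,
        embeddings: Sequence[EmbeddingSet],
        target: str,
        screen_sets: Sequence[ScreenSet] | None = None,
        site_names: Sequence[str] | None = None,
    ):
        if len(embeddings) < 1:
            raise ValueError("need at least one site")
        self.embeddings = list(embeddings)
        self.M = len(embeddings)
        self.target = target
        self.site_names = list(site_names) if site_names else [f"site{m+1}" for m in range(self.M)]
        if screen_sets is None:
            screen_sets = [screen(e, target, alpha=None) for e in embeddings]
        if len(screen_sets) != self.M:
            raise ValueError("one screen set per site required")
        for e in embeddings:
            if target not in e.vocab:
                raise ValueError(f"target {target!r} absent at a site")
        self.screen_sets = list(screen_sets)

        union: list[str] = []
        seen = set()
        for s in screen_sets:
            for c in s.candidates:
                if c not in seen:
                    seen.add(c)
                    union.append(c)
        if not union:
            raise ValueError("no candidates at any site")
        self.union_candidates = tuple(union)
        gidx = {c: g for g, c in enumerate(union)}

        self.site_candidates = [tuple(s.candidates) for s in screen_sets]
        self.member_idx = [
            np.array([gidx[c] for c in cands], dtype=int) for cands in self.site_candidates
        ]
        self.r_sites, self.G_sites = [], []
        for e, cands in zip(embeddings, self.site_candidates):
            r, G = _gram_quantities(e, target, cands)
            self.r_sites.append(r)
            self.G_sites.append(G)

        # group weight 1 / (max_m |cos_m(w,c)| * sqrt(#sites with c))
        n_groups = len(union)
        maxcos = np.zeros(n_groups)
        counts = np.zeros(n_groups)
        for m in range(self.M):
            for j, g in enumerate(self.member_idx[m]):
                maxcos[g] = max(maxcos[g], abs(self.r_sites[m][j]))
                counts[g] += 1
        rho_all: dict[str, float] = {}
        for s in screen_sets:
            rho_all.update(s.rho)
        floor = min((abs(v) for v in rho_all.values() if v != 0), default=1e-8)
        floor = max(min(floor, 1.0), 1e-8)
        self.group_weights = 1.0 / (np.maximum(maxcos, floor) * np.sqrt(counts))
        self.group_counts = counts

    @property
    def lambda1_max(self) -> float:
        """Group-KKT threshold zeroing every cross-site group at b = 0."""
        n_groups = len(self.union_candidates)
        sq = np.zeros(n_groups)
        for m in range(self.M):
            np.add.at(sq, self.member_idx[m], self.r_sites[m] ** 2)
        return float(np.max(2.0 * np.sqrt(sq) / self.group_weights))

    def default_lambda1_grid(self, n: int = 20, decades: float = 3.0) -> np.ndarray:
        top = max(self.lambda1_max, 1e-12)
        return np.geomspace(top, top * 10.0**-decades, n)

    def objective(self, b_sites: Sequence[np.ndarray], lam1: float, lam2: float) -> float:
        total = 0.0
        n_groups = len(self.union_candidates)
        gsq = np.zeros(n_groups)
        for m in range(self.M):
            b = np.asarray(b_sites[m], dtype=float)
            total += 1.0 - 2.0 * b @ self.r_sites[m] + b @ self.G_sites[m] @ b
            total += lam2 * float(np.sum(b**2))
            np.add.at(gsq, self.member_idx[m], b**2)
        total += lam1 * float(np.sum(self.group_weights * np.sqrt(gsq)))
        return total

    def fit(
        self,
        lam1: float,
        lam2: float,
        start: Sequence[np.ndarray] | None = None,
        max_iter: int = 2000,
        tol: float = 1e-10,
    ) -> "IntegrativeResults":
        if lam1 < 0 or lam2 < 0:
            raise ValueError("penalties must be non-negative")
        b, n_iter, converged = _bcd_group(
            self.r_sites,
            self.G_sites,
            self.member_idx,
            self.group_weights,
            lam1,
            lam2,
            b0=list(start) if start is not None else None,
            max_iter=max_iter,
            tol=tol,
        )
        if not converged:
            warnings.warn(f"block coordinate descent did not converge in {max_iter} sweeps")
        return IntegrativeResults(self, b, lam1, lam2, n_iter, converged)

    def fit_tuned(
        self,
        valid_embs: Sequence[EmbeddingSet],
        lam1_grid: Sequence[float] | None = None,
        lam2_grid: Sequence[float] | None = None,
        loss_tol: float = TUNING_LOSS_TOL,
        **fit_kw,
    ) -> "IntegrativeResults":
        """Grid search on the summed per-site basis-free validation loss.

        Same tolerance-based sparsity tie-break as the single-site tuner.
        """
        if len(valid_embs) != self.M:
            raise ValueError("one validation embedding set per site required")
        vq = []
        for m, ve in enumerate(valid_embs):
            cands = self.site_candidates[m]
            shared = np.array([c in ve.vocab for c in cands])
            if self.target not in ve.vocab or not shared.any():
                raise ValueError(f"validation embeddings unusable at site {self.site_names[m]}")
            cand_v = [c for c, ok in zip(cands, shared) if ok]
            r_v, G_v = _gram_quantities(ve, self.target, cand_v)
            vq.append((shared, r_v, G_v))
        if lam1_grid is None:
            lam1_grid = self.default_lambda1_grid()
        if lam2_grid is None:
            lam2_grid = default_lambda2_grid()
        best = None
        for lam2 in sorted(lam2_grid):
            start = None
            for lam1 in sorted(lam1_grid, reverse=True):
                res = self.fit(lam1, lam2, start=start, **fit_kw)
                start = res.params_sites
                loss = 0.0
                for m, (shared, r_v, G_v) in enumerate(vq):
                    bm = res.params_sites[m][shared]
                    loss += float(1.0 - 2.0 * bm @ r_v + bm @ G_v @ bm)
                key = (loss, len(res.support), lam2)
                if best is None or _tuning_better(key, best[0], rtol=loss_tol):
                    best = (key, res)
        res = best[1]
        res.validation_loss = best[0][0]
        return res


class IntegrativeResults:
    """Per-site coefficients and the cross-site selected support."""

    def __init__(self, model: IntegrativeEmbeddingRegression, b_sites, lam1, lam2, n_iter, converged):
        self.model = model
        self.params_sites = [np.asarray(b, dtype=float) for b in b_sites]
        self.lam1 = float(lam1)
        self.lam2 = float(lam2)
        self.n_iter = int(n_iter)
        self.converged = bool(converged)
        self.objective = model.objective(self.params_sites, self.lam1, self.lam2)
        self.validation_loss: float | None = None

    @property
    def params(self) -> pd.DataFrame:
        """Coefficients indexed by union candidates, one column per site.

        Codes outside a site's screened set hold a structural zero.
        """
        df = pd.DataFrame(
            0.0, index=list(self.model.union_candidates), columns=self.model.site_names
        )
        for m, name in enumerate(self.model.site_names):
            for j, c in enumerate(self.model.site_candidates[m]):
                df.loc[c, name] = self.params_sites[m][j]
        return df

    @property
    def support(self) -> tuple[str, ...]:
        """Codes whose cross-site coefficient group has nonzero norm."""
        df = self.params
        mask = df.abs().sum(axis=1) != 0.0
        return tuple(df.index[mask])

    def site_selected(self, site: str) -> tuple[str, ...]:
        df = self.params
        return tuple(df.index[df[site] != 0.0])

    def kkt_residual(self) -> float:
        """Maximum group-stationarity violation at the solution."""
        m = self.model
        n_groups = len(m.union_candidates)
        grads = [[] for _ in range(n_groups)]
        betas = [[] for _ in range(n_groups)]
        for s in range(m.M):
            b = self.params_sites[s]
            g = -2.0 * m.r_sites[s] + 2.0 * m.G_sites[s] @ b + 2.0 * self.lam2 * b
            for j, gid in enumerate(m.member_idx[s]):
                grads[gid].append(g[j])
                betas[gid].append(b[j])
        res = 0.0
        for gid in range(n_groups):
            gv = np.array(grads[gid])
            bv = np.array(betas[gid])
            t = self.lam1 * m.group_weights[gid]
            nb = np.linalg.norm(bv)
            if nb > 0:
                res = max(res, float(np.max(np.abs(gv + t * bv / nb))))
            else:
                res = max(res, max(float(np.linalg.norm(gv)) - t, 0.0))
        return res

    def summary(self) -> str:
        lines = [
            "Integrative sparse embedding regression",
            "=" * 45,
            f"target:       {self.model.target}",
            f"sites:        {', '.join(self.model.site_names)}",
            f"candidates:   {len(self.model.union_candidates)} (union)"
            f"  selected: {len(self.support)}",
            f"lam1, lam2:   {self.lam1:.6g}, {self.lam2:.6g}",
            f"objective:    {self.objective:.6g}",
            f"converged:    {self.converged} ({self.n_iter} sweeps)",
        ]
        df = self.params.loc[list(self.support)]
        if len(df):
            order = df.abs().sum(axis=1).sort_values(ascending=False).index
            lines.append("-" * 45)
            lines.append(f"{'code':<26}" + "".join(f"{s:>12}" for s in self.model.site_names))
            for code in order:
                lines.append(
                    f"{code:<26}" + "".join(f"{df.loc[code, s]:>12.5f}" for s in self.model.site_names)
                )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        df = self.params
        return {
            "target": self.model.target,
            "sites": self.model.site_names,
            "lam1": self.lam1,
            "lam2": self.lam2,
            "objective": self.objective,
            "converged": self.converged,
            "support": list(self.support),
            "coefficients": {
                c: {s: float(df.loc[c, s]) for s in self.model.site_names if df.loc[c, s] != 0.0}
                for c in self.support
            },
        }


# ---------------------------------------------------------------------------
# functional wrappers (spec-level operations)


def fit_single_site(
    emb: EmbeddingSet, screen_set: ScreenSet, lam1: float, lam2: float, **kw
) -> EmbeddingRegressionResults:
    return EmbeddingRegression.from_screen(emb, screen_set).fit(lam1, lam2, **kw)


def tune_single_site(
    train_emb: EmbeddingSet,
    valid_emb: EmbeddingSet,
    target: str,
    screen_set: ScreenSet | None = None,
    lam1_grid=None,
    lam2_grid=None,
    **kw,
) -> EmbeddingRegressionResults:
    model = EmbeddingRegression(train_emb, target, screen_set=screen_set)
    return model.fit_tuned(valid_emb, lam1_grid, lam2_grid, **kw)


def fit_integrative(
    embs: Sequence[EmbeddingSet],
    screens: Sequence[ScreenSet],
    lam1: float,
    lam2: float,
    **kw,
) -> IntegrativeResults:
    target = screens[0].target
    return IntegrativeEmbeddingRegression(embs, target, screen_sets=screens).fit(lam1, lam2, **kw)
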