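"""Pocket structural alignment and the PS-score.

Two pockets (a *template* of length ``L_T`` and a *query* of length ``L_Q``)
are aligned by a three-phase search:

1. seed generation (gapless shifts, fragment matches, coarse secondary
   structure, local contact patterns),
2. iterative dynamic programming from the best seeds, yielding the optimal
   *sequential* (sequence-order preserving) alignment,
3. iterative linear-sum-assignment refinement, yielding the best
   *non-sequential* alignment, which is kept if it scores higher.

The score of an alignment under a rigid superposition is

    PS = (1/L_Q) * sum_i  [1 / (1 + d_i^2/d0^2)] * (p_i + c*r_i) / (1 + c)

where ``d_i`` is the Ca-Ca distance of aligned pair *i*, ``d0`` a
length-dependent distance scale, ``p_i`` the Ca->Cb directional similarity
(1 when both residues are Gly, 0.77 when exactly one is), and ``r_i`` a 0/1
chemical-group indicator over eight amino-acid groups.  The reported PS-score
is the maximum over the superpositions explored; identical pockets score
exactly 1.0.  Significance is assessed against a Gumbel null model calibrated
on random pocket pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy.spatial.distance import cdist
from scipy.stats import gumbel_r

from .errors import AlignmentError, CalibrationError, SuperpositionError
from .structure_io import Pocket, Residue

# Amino-acid chemical groups I-VIII: LVIMC / AG / ST / P / FYW / EDNQ / KR / H
CHEM_GROUPS: dict[str, int] = {}
for _g, _members in enumerate(["LVIMC", "AG", "ST", "P", "FYW", "EDNQ", "KR", "H"]):
    for _a in _members:
        CHEM_GROUPS[_a] = _g

ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII"]


def chem_group(aa: str) -> str | None:
    """Roman-numeral chemical group of a one-letter amino acid, None if nonstandard."""
    g = CHEM_GROUPS.get(aa.upper())
    return None if g is None else ROMAN[g]


@dataclass(frozen=True)
class PSParams:
    """Tunable constants of the PS-score and its alignment search.

    The d0 constants and the length-scaling exponent are the package's own
    calibrated defaults (see docs/methods.md and `fit_d0_constants` /
    `fit_length_scaling` in the pipeline module).
    """

    d0_a: float = 0.70
    d0_b: float = -0.20
    d0_min: float = 0.50
    length_scale_alpha: float = -0.2  # exponent of (L_Q / length_ref) applied to d0
    length_ref: int = 50
    chem_weight: float = 0.10  # weight c of the chemical-group term
    one_gly_p: float = 0.77  # directional term when exactly one residue is Gly
    gap_open_frac: float = 0.60  # DP gap opening = -frac * mean(pair score); extension 0
    max_dp_iter: int = 30
    max_lsap_iter: int = 30
    n_top_seeds: int = 3
    frag_k: int = 6
    pair_floor_frac: float = 0.10  # drop non-sequential pairs below frac*max contribution
    max_gapless_seeds: int = 60


DEFAULT_PARAMS = PSParams()


def d0_for_length(L_Q: int, params: PSParams = DEFAULT_PARAMS) -> float:
    """Length-dependent distance scale d0 (A) for a query of length L_Q."""
    base = params.d0_a * max(L_Q - 5, 1) ** (1.0 / 3.0) + params.d0_b
    base *= (L_Q / params.length_ref) ** params.length_scale_alpha
    return max(base, params.d0_min)


@dataclass
class PocketAlignment:
    """Residue correspondence + rigid superposition + PS-score of a pocket pair."""

    pairs: list[tuple[int, int]]  # (template index, query index)
    rotation: np.ndarray  # 3x3, applied to the query
    translation: np.ndarray  # 3-vector, A
    ps_score: float
    rmsd: float
    n_aligned: int
    sequential: bool
    p_value: float | None = None
    template_id: str = ""
    query_id: str = ""


# ---------------------------------------------------------------------------
# Rigid superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of B onto A: A_i ~ R @ B_i + t.

    Returns (rotation, translation, rmsd); the rotation is proper (det = +1).
    Raises SuperpositionError for fewer than 3 points or collinear point sets.
    """
    A = np.asarray(coords_a, float)
    B = np.asarray(coords_b, float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise SuperpositionError("coordinate sets must both be (n, 3)")
    n = A.shape[0]
    if n < 3:
        raise SuperpositionError("need at least 3 points")
    ca_, cb_ = A.mean(axis=0), B.mean(axis=0)
    Ac, Bc = A - ca_, B - cb_
    sa = np.linalg.svd(Ac, compute_uv=False)
    sb = np.linalg.svd(Bc, compute_uv=False)
    if sa[1] < 1e-8 * max(sa[0], 1.0) or sb[1] < 1e-8 * max(sb[0], 1.0):
        raise SuperpositionError("degenerate (collinear) point set")
    H = Bc.T @ Ac
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = ca_ - R @ cb_
    diff = Ac - Bc @ R.T
    rmsd = float(np.sqrt((diff * diff).sum() / n))
    return R, t, rmsd


# ---------------------------------------------------------------------------
# Dynamic programming (global, affine gaps with free extension) -- numba
# ---------------------------------------------------------------------------

@njit(cache=False)
def _nw_pairs(w, gap_open):  # pragma: no cover - exercised via wrappers
    n, m = w.shape
    NEG = -1e30
    H = np.full((n + 1, m + 1), NEG)
    E = np.full((n + 1, m + 1), NEG)  # ends with query j in a gap
    F = np.full((n + 1, m + 1), NEG)  # ends with template i in a gap
    ph = np.zeros((n + 1, m + 1), np.int8)
    pe = np.zeros((n + 1, m + 1), np.int8)
    pf = np.zeros((n + 1, m + 1), np.int8)
    H[0, 0] = 0.0
    for j in range(1, m + 1):
        E[0, j] = gap_open
        pe[0, j] = 0 if j == 1 else 1
    for i in range(1, n + 1):
        F[i, 0] = gap_open
        pf[i, 0] = 0 if i == 1 else 1
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = H[i - 1, j - 1]
            b = 0
            if E[i - 1, j - 1] > best:
                best = E[i - 1, j - 1]
                b = 1
            if F[i - 1, j - 1] > best:
                best = F[i - 1, j - 1]
                b = 2
            H[i, j] = best + w[i - 1, j - 1]
            ph[i, j] = b
            eo = H[i, j - 1] + gap_open
            ee = E[i, j - 1]
            if eo >= ee:
                E[i, j] = eo
                pe[i, j] = 0
            else:
                E[i, j] = ee
                pe[i, j] = 1
            fo = H[i - 1, j] + gap_open
            fe = F[i - 1, j]
            if fo >= fe:
                F[i, j] = fo
                pf[i, j] = 0
            else:
                F[i, j] = fe
                pf[i, j] = 1
    # traceback
    i, j = n, m
    state = 0
    best = H[n, m]
    if E[n, m] > best:
        best = E[n, m]
        state = 1
    if F[n, m] > best:
        best = F[n, m]
        state = 2
    cap = min(n, m)
    ti = np.empty(cap, np.int64)
    qi = np.empty(cap, np.int64)
    k = 0
    while i > 0 or j > 0:
        if state == 0:
            ti[k] = i - 1
            qi[k] = j - 1
            k += 1
            state = ph[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            state = 0 if pe[i, j] == 0 else 1
            j -= 1
        else:
            state = 0 if pf[i, j] == 0 else 2
            i -= 1
    return ti[:k][::-1].copy(), qi[:k][::-1].copy()


# ---------------------------------------------------------------------------
# Linear sum assignment: shortest augmenting path (Jonker-Volgenant style)
# ---------------------------------------------------------------------------

@njit(cache=False)
def _lsap_core(cost):  # pragma: no cover - exercised via solve_lsap
    n, m = cost.shape  # requires n <= m
    INF = 1e30
    u = np.zeros(n + 1)
    v = np.zeros(m + 1)
    p = np.zeros(m + 1, np.int64)  # p[j] = row matched to column j (1-based, 0 free)
    way = np.zeros(m + 1, np.int64)
    for i in range(1, n + 1):
        p[0] = i
        j0 = 0
        minv = np.full(m + 1, INF)
        used = np.zeros(m + 1, np.bool_)
        while True:
            used[j0] = True
            i0 = p[j0]
            delta = INF
            j1 = 0
            for j in range(1, m + 1):
                if not used[j]:
                    cur = cost[i0 - 1, j - 1] - u[i0] - v[j]
                    if cur < minv[j]:
                        minv[j] = cur
                        way[j] = j0
                    if minv[j] < delta:
                        delta = minv[j]
                        j1 = j
            for j in range(m + 1):
                if used[j]:
                    u[p[j]] += delta
                    v[j] -= delta
                else:
                    minv[j] -= delta
            j0 = j1
            if p[j0] == 0:
                break
        while j0 != 0:
            j1 = way[j0]
            p[j0] = p[j1]
            j0 = j1
    row_to_col = np.full(n, -1, np.int64)
    for j in range(1, m + 1):
        if p[j] != 0:
            row_to_col[p[j] - 1] = j - 1
    return row_to_col


def solve_lsap(cost: np.ndarray) -> np.ndarray:
    """Minimum-cost assignment of rows to columns via shortest augmenting paths.

    Works on rectangular matrices; every row of the smaller side is assigned.
    Returns ``row_to_col`` (length = number of rows; -1 never occurs for
    feasible inputs).  O(N^3).
    """
    cost = np.ascontiguousarray(np.asarray(cost, float))
    n, m = cost.shape
    if n <= m:
        return _lsap_core(cost)
    col_to_row = _lsap_core(np.ascontiguousarray(cost.T))
    row_to_col = np.full(n, -1, np.int64)
    for j, i in enumerate(col_to_row):
        row_to_col[i] = j
    return row_to_col


# ---------------------------------------------------------------------------
# Scoring context
# ---------------------------------------------------------------------------

class _PairContext:
    """Precomputed arrays for scoring one (template, query) pocket pair."""

    def __init__(self, template: Pocket, query: Pocket, params: PSParams):
        self.params = params
        self.Lt = template.L
        self.Lq = query.L
        self.tca = template.ca
        self.qca = query.ca
        self.d0 = d0_for_length(self.Lq, params)
        self.d02 = self.d0 * self.d0

        def units(p: Pocket) -> tuple[np.ndarray, np.ndarray]:
            cb = p.cb_or_nan()
            v = cb - p.ca
            norm = np.linalg.norm(v, axis=1)
            has = np.isfinite(norm) & (norm > 1e-9)
            u = np.zeros_like(v)
            u[has] = v[has] / norm[has, None]
            return u, has

        self.tu, self.t_has = units(template)
        self.qu, self.q_has = units(query)
        # p-term masks: residues without a Cb (Gly or unresolvable) follow the
        # Gly convention: both -> 1.0, exactly one -> 0.77
        self.both_gly = np.outer(~self.t_has, ~self.q_has)
        self.one_gly = np.logical_xor.outer(~self.t_has, ~self.q_has)
        tg = np.array([CHEM_GROUPS.get(r.aa, -1) for r in template.residues])
        qg = np.array([CHEM_GROUPS.get(r.aa, -2) for r in query.residues])
        self.r = (tg[:, None] == qg[None, :]).astype(float)

    def transform_query(self, R: np.ndarray, t: np.ndarray) -> np.ndarray:
        return self.qca @ R.T + t

    def score_matrix(self, R: np.ndarray, t: np.ndarray) -> np.ndarray:
        """Per-pair PS contributions (before 1/L_Q) for all residue pairs."""
        q = self.transform_query(R, t)
        d2 = cdist(self.tca, q, "sqeuclidean")
        kernel = 1.0 / (1.0 + d2 / self.d02)
        cosm = np.clip(self.tu @ (self.qu @ R.T).T, -1.0, 1.0)
        p = 0.5 * (1.0 + cosm)
        p = np.where(self.both_gly, 1.0, np.where(self.one_gly, self.params.one_gly_p, p))
        c = self.params.chem_weight
        return kernel * (p + c * self.r) / (1.0 + c)

    def pair_scores(self, ti: np.ndarray, qi: np.ndarray, R, t) -> np.ndarray:
        q = self.transform_query(R, t)
        d2 = ((self.tca[ti] - q[qi]) ** 2).sum(axis=1)
        kernel = 1.0 / (1.0 + d2 / self.d02)
        cos = np.clip((self.tu[ti] * (self.qu[qi] @ R.T)).sum(axis=1), -1.0, 1.0)
        p = 0.5 * (1.0 + cos)
        p = np.where(
            self.both_gly[ti, qi], 1.0,
            np.where(self.one_gly[ti, qi], self.params.one_gly_p, p),
        )
        c = self.params.chem_weight
        return kernel * (p + c * self.r[ti, qi]) / (1.0 + c)

    def evaluate(self, ti: np.ndarray, qi: np.ndarray):
        """Best (ps, R, t) for fixed pairs: iterative subset re-superposition.

        Implements the max-over-superpositions heuristic: superpose on all
        pairs, then repeatedly on the close subset, keeping the best score.
        """
        ti = np.asarray(ti, np.int64)
        qi = np.asarray(qi, np.int64)
        if len(ti) < 3:
            return None
        try:
            R, t, _ = kabsch_superpose(self.tca[ti], self.qca[qi])
        except SuperpositionError:
            return None
        best = None
        cut = max(2.0 * self.d0, 4.5)
        prev_subset: frozenset | None = None
        for _ in range(6):
            scores = self.pair_scores(ti, qi, R, t)
            ps = float(scores.sum() / self.Lq)
            if best is None or ps > best[0]:
                best = (ps, R, t)
            q = self.transform_query(R, t)
            d = np.linalg.norm(self.tca[ti] - q[qi], axis=1)
            keep = d < cut
            if keep.sum() < 3:
                break
            subset = frozenset(np.nonzero(keep)[0].tolist())
            if subset == prev_subset:
                break
            prev_subset = subset
            try:
                R, t, _ = kabsch_superpose(self.tca[ti[keep]], self.qca[qi[keep]])
            except SuperpositionError:
                break
        return best


# ---------------------------------------------------------------------------
# Public scoring operations
# ---------------------------------------------------------------------------

def vector_term(
    res_t: Residue,
    res_q: Residue,
    superposition: tuple[np.ndarray, np.ndarray] | None = None,
    params: PSParams = DEFAULT_PARAMS,
) -> float:
    """Directional similarity p of two Ca->Cb vectors, with the Gly conventions."""
    t_missing = res_t.cb is None
    q_missing = res_q.cb is None
    if t_missing and q_missing:
        return 1.0
    if t_missing or q_missing:
        return params.one_gly_p
    vt = res_t.cb - res_t.ca
    vq = res_q.cb - res_q.ca
    if superposition is not None:
        R, _ = superposition
        vq = R @ vq
    cos = float(
        np.clip(vt @ vq / (np.linalg.norm(vt) * np.linalg.norm(vq)), -1.0, 1.0)
    )
    return 0.5 * (1.0 + cos)


def ps_score(
    pairs: list[tuple[int, int]],
    template: Pocket,
    query: Pocket,
    superposition: tuple[np.ndarray, np.ndarray],
    params: PSParams = DEFAULT_PARAMS,
) -> float:
    """PS-score of a fixed alignment under a fixed superposition (no search)."""
    if not len(pairs):
        return 0.0
    ctx = _PairContext(template, query, params)
    ti = np.array([p[0] for p in pairs], np.int64)
    qi = np.array([p[1] for p in pairs], np.int64)
    R, t = superposition
    return float(ctx.pair_scores(ti, qi, np.asarray(R, float), np.asarray(t, float)).sum() / query.L)


# ---------------------------------------------------------------------------
# Seeds
# ---------------------------------------------------------------------------

def _ss_states(ca: np.ndarray) -> np.ndarray:
    """Coarse 3-state secondary structure (0=helix, 1=strand, 2=coil) from Ca."""
    L = len(ca)
    states = np.full(L, 2, np.int8)
    for i in range(L - 3):
        d = np.linalg.norm(ca[i + 3] - ca[i])
        if 4.3 <= d <= 6.2:
            states[i] = 0
        elif 9.0 <= d <= 11.5:
            states[i] = 1
    return states


def _contact_profile(ca: np.ndarray, cutoff: float = 8.0) -> np.ndarray:
    d = cdist(ca, ca)
    mask = d < cutoff
    np.fill_diagonal(mask, False)
    return mask.sum(axis=1).astype(float)


def seed_alignments(
    template: Pocket, query: Pocket, params: PSParams = DEFAULT_PARAMS
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Candidate seed alignments (each a pair of index arrays), best-effort >= 1."""
    Lt, Lq = template.L, query.L
    if min(Lt, Lq) < 3:
        raise AlignmentError("pockets must have at least 3 residues")
    seeds: list[tuple[np.ndarray, np.ndarray]] = []
    seen: set = set()

    def add(ti: np.ndarray, qi: np.ndarray) -> None:
        if len(ti) < 3:
            return
        key = (tuple(ti.tolist()), tuple(qi.tolist()))
        if key not in seen:
            seen.add(key)
            seeds.append((ti, qi))

    def diagonal(offset: int) -> tuple[np.ndarray, np.ndarray]:
        lo = max(0, -offset)
        hi = min(Lt, Lq - offset)
        ti = np.arange(lo, hi, dtype=np.int64)
        return ti, ti + offset

    # gapless shifts, enumerated outward from zero shift
    offsets = sorted(range(-(Lt - 3), Lq - 2), key=abs)
    for off in offsets[: params.max_gapless_seeds]:
        add(*diagonal(off))

    # fragment (k-mer) matches by internal-distance similarity
    k = params.frag_k
    if Lt >= k and Lq >= k:
        dt = cdist(template.ca, template.ca)
        dq = cdist(query.ca, query.ca)
        step = max(1, k // 2)
        for a in range(0, Lt - k + 1, step):
            block_t = dt[a : a + k, a : a + k]
            for b in range(0, Lq - k + 1, step):
                diff = np.abs(block_t - dq[b : b + k, b : b + k]).mean()
                if diff < 0.8:
                    add(*diagonal(b - a))

    # coarse secondary-structure alignment
    st, sq = _ss_states(template.ca), _ss_states(query.ca)
    w = (st[:, None] == sq[None, :]).astype(float)
    ti, qi = _nw_pairs(np.ascontiguousarray(w), -0.5)
    add(ti, qi)

    # local Ca contact-pattern alignment
    pt, pq = _contact_profile(template.ca), _contact_profile(query.ca)
    w = 1.0 / (1.0 + np.abs(pt[:, None] - pq[None, :]))
    ti, qi = _nw_pairs(np.ascontiguousarray(w), -0.5)
    add(ti, qi)

    if not seeds:  # degenerate fall-back: shortest gapless overlap
        add(*diagonal(0))
    return seeds


# ---------------------------------------------------------------------------
# Phase 2: iterative dynamic programming
# ---------------------------------------------------------------------------

def _rank_seeds(ctx: _PairContext, seeds, n_top: int):
    scored = []
    for ti, qi in seeds:
        try:
            R, t, _ = kabsch_superpose(ctx.tca[ti], ctx.qca[qi])
        except SuperpositionError:
            continue
        ps = float(ctx.pair_scores(ti, qi, R, t).sum() / ctx.Lq)
        scored.append((ps, ti, qi, R, t))
    scored.sort(key=lambda s: -s[0])
    return scored[:n_top]


def _is_sequential(ti: np.ndarray, qi: np.ndarray) -> bool:
    return bool(np.all(np.diff(ti) > 0) and np.all(np.diff(qi) > 0))


def iterative_dp_align(
    template: Pocket,
    query: Pocket,
    seeds: list[tuple[np.ndarray, np.ndarray]] | None = None,
    params: PSParams = DEFAULT_PARAMS,
) -> PocketAlignment:
    """Best sequential alignment: iterated (superpose -> score -> NW) from seeds."""
    ctx = _PairContext(template, query, params)
    if seeds is None:
        seeds = seed_alignments(template, query, params)
    best = None  # (ps, ti, qi, R, t)
    for _, ti, qi, R, t in _rank_seeds(ctx, seeds, params.n_top_seeds):
        ev = ctx.evaluate(ti, qi)
        if ev is None:
            continue
        ps, R, t = ev
        if best is None or ps > best[0]:
            best = (ps, ti, qi, R, t)
        history = {(tuple(ti.tolist()), tuple(qi.tolist()))}
        for _ in range(params.max_dp_iter):
            w = ctx.score_matrix(R, t)
            gap_open = -params.gap_open_frac * float(w.mean())
            ti2, qi2 = _nw_pairs(np.ascontiguousarray(w), gap_open)
            ev = ctx.evaluate(ti2, qi2)
            if ev is None:
                break
            ps2, R, t = ev
            if ps2 > best[0]:
                best = (ps2, ti2, qi2, R, t)
            key = (tuple(ti2.tolist()), tuple(qi2.tolist()))
            if key in history:
                break
            history.add(key)
    if best is None:
        raise AlignmentError("no viable seed alignment")
    ps, ti, qi, R, t = best
    _, _, rmsd = kabsch_superpose(ctx.tca[ti], ctx.qca[qi])
    return PocketAlignment(
        pairs=list(zip(ti.tolist(), qi.tolist())),
        rotation=R,
        translation=t,
        ps_score=ps,
        rmsd=rmsd,
        n_aligned=len(ti),
        sequential=True,
        template_id=template.pocket_id,
        query_id=query.pocket_id,
    )


# ---------------------------------------------------------------------------
# Phase 3: non-sequential alignment via LSAP
# ---------------------------------------------------------------------------

def _principal_axis_starts(ctx: _PairContext) -> list[tuple[np.ndarray, np.ndarray]]:
    """Permutation-invariant starting superpositions from principal axes."""
    def axes(x: np.ndarray) -> np.ndarray:
        xc = x - x.mean(axis=0)
        _, _, vt = np.linalg.svd(xc, full_matrices=False)
        a = vt.T  # columns = principal axes
        a[:, 2] = np.cross(a[:, 0], a[:, 1])
        return a

    at = axes(ctx.tca)
    ct = ctx.tca.mean(axis=0)
    cq = ctx.qca.mean(axis=0)
    starts = []
    base = axes(ctx.qca)
    for s0, s1 in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        aq = base.copy()
        aq[:, 0] *= s0
        aq[:, 1] *= s1
        aq[:, 2] = np.cross(aq[:, 0], aq[:, 1])
        R = at @ aq.T
        starts.append((R, ct - R @ cq))
    return starts


def lsap_align(
    template: Pocket,
    query: Pocket,
    superposition: tuple[np.ndarray, np.ndarray] | None = None,
    params: PSParams = DEFAULT_PARAMS,
) -> PocketAlignment:
    """Best non-sequential alignment by iterated assignment + re-superposition.

    ``superposition`` seeds the search; principal-axis starts are always
    explored as well, which makes the result robust to residue-order
    permutation of either pocket.
    """
    ctx = _PairContext(template, query, params)
    starts = _principal_axis_starts(ctx)
    if superposition is not None:
        starts = [superposition] + starts
    best = None  # (ps, ti, qi, R, t)
    for R0, t0 in starts:
        R, t = np.asarray(R0, float), np.asarray(t0, float)
        prev = None
        for _ in range(params.max_lsap_iter):
            w = ctx.score_matrix(R, t)
            if ctx.Lt <= ctx.Lq:
                cols = solve_lsap(-w)
                ti = np.arange(ctx.Lt, dtype=np.int64)
                qi = cols
            else:
                rows = solve_lsap(-w.T)
                qi = np.arange(ctx.Lq, dtype=np.int64)
                ti = rows
            contrib = w[ti, qi]
            keep = contrib >= params.pair_floor_frac * max(contrib.max(), 1e-12)
            ti, qi = ti[keep], qi[keep]
            if len(ti) < 3:
                break
            order = np.argsort(ti)
            ti, qi = ti[order], qi[order]
            ev = ctx.evaluate(ti, qi)
            if ev is None:
                break
            ps, R, t = ev
            if best is None or ps > best[0]:
                best = (ps, ti, qi, R, t)
            key = (tuple(ti.tolist()), tuple(qi.tolist()))
            if key == prev:
                break
            prev = key
    if best is None:
        raise AlignmentError("non-sequential search failed")
    ps, ti, qi, R, t = best
    _, _, rmsd = kabsch_superpose(ctx.tca[ti], ctx.qca[qi])
    return PocketAlignment(
        pairs=list(zip(ti.tolist(), qi.tolist())),
        rotation=R,
        translation=t,
        ps_score=ps,
        rmsd=rmsd,
        n_aligned=len(ti),
        sequential=_is_sequential(ti, qi),
        template_id=template.pocket_id,
        query_id=query.pocket_id,
    )


# ---------------------------------------------------------------------------
# Full three-phase alignment
# ---------------------------------------------------------------------------

def align_pockets(
    template: Pocket,
    query: Pocket,
    model: "GumbelModel | None" = None,
    params: PSParams = DEFAULT_PARAMS,
) -> PocketAlignment:
    """Three-phase alignment; returns the better of sequential and non-sequential.

    Ties prefer the sequential result, then larger N_a, then lower RMSD.
    """
    if template.L < 3 or query.L < 3:
        raise AlignmentError("pockets must have at least 3 residues")
    seeds = seed_alignments(template, query, params)
    seq = iterative_dp_align(template, query, seeds, params)
    nonseq = lsap_align(template, query, (seq.rotation, seq.translation), params)
    if nonseq.ps_score > seq.ps_score + 1e-9:
        result = nonseq
    elif seq.ps_score > nonseq.ps_score + 1e-9:
        result = seq
    else:
        result = max(seq, nonseq, key=lambda a: (a.sequential, a.n_aligned, -a.rmsd))
    if model is not None:
        result.p_value = p_value(result.ps_score, query.L, model)
    return result


# ---------------------------------------------------------------------------
# Gumbel significance model
# ---------------------------------------------------------------------------

@dataclass
class GumbelModel:
    """Per-length-bin Gumbel (type I extreme value) null model of the PS-score."""

    bin_edges: np.ndarray  # length k+1
    mu: np.ndarray  # location per bin
    beta: np.ndarray  # scale per bin (> 0)
    n_samples: np.ndarray

    def bin_index(self, L: int) -> int:
        idx = int(np.searchsorted(self.bin_edges, L, side="right")) - 1
        return int(np.clip(idx, 0, len(self.mu) - 1))  # nearest-bin fallback

    def p_value(self, score: float, L: int) -> float:
        b = self.bin_index(L)
        p = float(gumbel_r.sf(score, loc=self.mu[b], scale=self.beta[b]))
        return max(p, np.finfo(float).tiny)

    def threshold(self, L: int, alpha: float = 0.05) -> float:
        """Smallest score whose P-value is below alpha, from the closed form."""
        b = self.bin_index(L)
        return float(self.mu[b] + self.beta[b] * (-np.log(-np.log1p(-alpha))))


def calibrate_gumbel(
    random_pairs: list[tuple[float, int]],
    bins: np.ndarray | list[float],
    min_per_bin: int = 200,
) -> GumbelModel:
    """Fit a per-bin Gumbel null model to (ps_score, query length) samples.

    Underfilled bins are widened symmetrically (with a warning) until they
    hold at least ``min_per_bin`` samples.
    """
    edges = np.asarray(bins, float)
    if edges.ndim != 1 or len(edges) < 2:
        raise CalibrationError("need at least one bin (two edges)")
    scores = np.array([s for s, _ in random_pairs], float)
    lengths = np.array([l for _, l in random_pairs], float)
    k = len(edges) - 1
    mu = np.empty(k)
    beta = np.empty(k)
    n_samples = np.zeros(k, int)
    assign = np.clip(np.searchsorted(edges, lengths, side="right") - 1, 0, k - 1)
    for b in range(k):
        width = 0
        while True:
            lo, hi = max(0, b - width), min(k - 1, b + width)
            sel = (assign >= lo) & (assign <= hi)
            if sel.sum() >= min_per_bin or (lo == 0 and hi == k - 1):
                break
            width += 1
        if width > 0:
            warnings.warn(
                f"length bin {b} underfilled; widened to bins [{lo}, {hi}]"
            )
        sample = scores[sel]
        if len(sample) < 10:
            raise CalibrationError(f"too few null scores for bin {b} ({len(sample)})")
        loc, scale = gumbel_r.fit(sample)
        mu[b], beta[b] = loc, max(scale, 1e-9)
        n_samples[b] = int(sel.sum())
    return GumbelModel(edges, mu, beta, n_samples)


def p_value(score: float, L_Q: int, model: GumbelModel | None) -> float:
    """Gumbel survival probability of a PS-score for a query of length L_Q."""
    if model is None:
        raise CalibrationError(
            "no Gumbel model: calibrate one with calibrate_gumbel on null scores"
        )
    return model.p_value(score, L_Q)
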