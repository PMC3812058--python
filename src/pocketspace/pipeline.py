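"""End-to-end orchestration: all-against-all comparison, null-model
calibration, template search, promiscuity scan, and ligand-vs-pocket
similarity tables.

All stochastic steps take an explicit seed and are fully reproducible.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import pocket_align, synthetic_data
from .errors import DomainError, PocketspaceError
from .ligand_chem import Fingerprint, tanimoto
from .pocket_align import (
    DEFAULT_PARAMS,
    GumbelModel,
    PSParams,
    align_pockets,
    calibrate_gumbel,
)
from .structure_io import Pocket, sequence_identity

RESULT_COLUMNS = [
    "template_id", "query_id", "ps_score", "p_value", "rmsd", "n_aligned", "seq_flag",
]

# Named threshold presets used throughout the survey analyses.
PS_THRESHOLDS = (0.36, 0.40, 0.45, 0.50, 0.60)
P_THRESHOLDS = (0.05, 0.01, 1e-3, 1e-4, 1e-5)
TC_THRESHOLDS = (0.3, 0.4, 0.7, 0.8, 0.99)


@dataclass
class RunConfig:
    """File-serializable run parameters for the CLI pipeline."""

    seed: int = 1
    ps_min_grid: tuple[float, ...] = PS_THRESHOLDS
    p_max: float = 0.01
    tc_bins: tuple[float, ...] = TC_THRESHOLDS
    identity_cutoff: float = 0.30
    output_dir: str = "results"
    radii_path: str | None = None

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("ps_min_grid", "tc_bins"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# All-against-all comparison
# ---------------------------------------------------------------------------

def all_vs_all(
    pockets: list[Pocket],
    params: PSParams = DEFAULT_PARAMS,
    model: GumbelModel | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Both-direction pairwise alignments (n*(n-1) rows, no self rows)."""
    if len(pockets) < 2:
        raise DomainError("all_vs_all needs at least two pockets")
    rows = []
    total = len(pockets) * (len(pockets) - 1)
    done = 0
    for tmpl in pockets:
        for qry in pockets:
            if tmpl.pocket_id == qry.pocket_id:
                continue
            try:
                aln = align_pockets(tmpl, qry, model=model, params=params)
            except PocketspaceError as exc:
                warnings.warn(f"skipping {tmpl.pocket_id} vs {qry.pocket_id}: {exc}")
                continue
            rows.append(
                {
                    "template_id": tmpl.pocket_id,
                    "query_id": qry.pocket_id,
                    "ps_score": aln.ps_score,
                    "p_value": aln.p_value if aln.p_value is not None else np.nan,
                    "rmsd": aln.rmsd,
                    "n_aligned": aln.n_aligned,
                    "seq_flag": aln.sequential,
                }
            )
            done += 1
            if progress and done % 100 == 0:
                print(f"  aligned {done}/{total} directed pairs")
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


# ---------------------------------------------------------------------------
# Null-model calibration
# ---------------------------------------------------------------------------

def null_scores(
    n_pairs: int,
    lengths: tuple[int, int] = (45, 55),
    seed: int = 1,
    params: PSParams = DEFAULT_PARAMS,
    pool_size: int | None = None,
) -> list[tuple[float, int]]:
    """PS-scores of aligned pairs of unrelated synthetic pockets.

    A pool of independent pockets with lengths uniform on ``lengths`` is
    generated, then ``n_pairs`` distinct unordered pairs are aligned.
    Returns (ps_score, query length) samples.
    """
    rng = np.random.default_rng(seed)
    if pool_size is None:
        # enough pockets that pairs are essentially disjoint but cheap to build
        pool_size = max(int(np.ceil((1 + np.sqrt(1 + 8 * n_pairs)) / 2)), 16)
    lo, hi = lengths
    pockets = []
    for k in range(pool_size):
        L = int(rng.integers(lo, hi + 1))
        sub = int(rng.integers(0, 2**31 - 1))
        pockets.append(synthetic_data.make_pocket(L=L, seed=sub))
    n_possible = pool_size * (pool_size - 1) // 2
    if n_pairs > n_possible:
        raise DomainError("pool too small for the requested number of pairs")
    pair_idx = rng.choice(n_possible, size=n_pairs, replace=False)
    pairs = []
    # enumerate unordered pairs lexicographically
    lookup = [(i, j) for i in range(pool_size) for j in range(i + 1, pool_size)]
    out = []
    for k in np.sort(pair_idx):
        i, j = lookup[k]
        aln = align_pockets(pockets[i], pockets[j], params=params)
        out.append((aln.ps_score, pockets[j].L))
    return out


def calibrate_null_model(
    n_pairs: int = 2000,
    lengths: tuple[int, int] = (45, 55),
    seed: int = 1,
    params: PSParams = DEFAULT_PARAMS,
    bin_edges: tuple[float, ...] | None = None,
) -> tuple[GumbelModel, list[tuple[float, int]]]:
    """Convenience: simulate a null ensemble and fit the Gumbel model on it."""
    samples = null_scores(n_pairs, lengths, seed, params)
    if bin_edges is None:
        bin_edges = (lengths[0] - 0.5, lengths[1] + 0.5)
    model = calibrate_gumbel(samples, np.asarray(bin_edges, float))
    return model, samples


def significance_threshold(model: GumbelModel, L: int, alpha: float = 0.05) -> float:
    """Smallest PS-score with P < alpha for pockets of length L."""
    return model.threshold(L, alpha)


# ---------------------------------------------------------------------------
# Score-constant recalibration (run once; defaults are frozen in PSParams)
# ---------------------------------------------------------------------------

def random_alignment_distances(
    L: int, n_pairs: int = 50, seed: int = 1
) -> np.ndarray:
    """Ca distances of random gapless correspondences after Kabsch superposition."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_pairs):
        a = synthetic_data.make_pocket(L=L, seed=int(rng.integers(0, 2**31 - 1)))
        b = synthetic_data.make_pocket(L=L, seed=int(rng.integers(0, 2**31 - 1)))
        R, t, _ = pocket_align.kabsch_superpose(a.ca, b.ca)
        d = np.linalg.norm(a.ca - (b.ca @ R.T + t), axis=1)
        out.append(d)
    return np.concatenate(out)


def fit_d0_constants(
    lengths: tuple[int, ...] = (20, 30, 40, 50, 65, 80),
    n_pairs: int = 40,
    seed: int = 1,
    quantile: float = 0.25,
) -> tuple[float, float]:
    """Fit d0(L) = a*(L-5)^(1/3) + b to a fixed quantile of the distance
    distribution of random pocket alignments (the distance scale at which a
    random aligned pair still contributes appreciably)."""
    targets = []
    for L in lengths:
        d = random_alignment_distances(L, n_pairs, seed)
        targets.append(np.quantile(d, quantile))
    x = np.array([(L - 5) ** (1.0 / 3.0) for L in lengths])
    y = np.array(targets)
    a, b = np.polyfit(x, y, 1)
    return float(a), float(b)


def null_mean_by_length(
    lengths: tuple[int, ...] = (20, 40, 80),
    n_pairs: int = 40,
    seed: int = 1,
    params: PSParams = DEFAULT_PARAMS,
) -> dict[int, float]:
    """Mean null PS-score per pocket length (equal-length random pairs)."""
    out = {}
    for L in lengths:
        samples = null_scores(n_pairs, (L, L), seed=seed + L, params=params)
        out[L] = float(np.mean([s for s, _ in samples]))
    return out


def fit_length_scaling(
    lengths: tuple[int, ...] = (20, 40, 80),
    n_pairs: int = 30,
    seed: int = 1,
    alphas: tuple[float, ...] = (-0.3, -0.2, -0.1, 0.0, 0.1, 0.2, 0.3),
    params: PSParams = DEFAULT_PARAMS,
) -> float:
    """Choose the d0 length-scaling exponent that makes the mean null PS-score
    flattest across pocket lengths (relative spread of bin means)."""
    best_alpha, best_spread = 0.0, np.inf
    for alpha in alphas:
        p = dataclasses.replace(params, length_scale_alpha=alpha)
        means = np.array(list(null_mean_by_length(lengths, n_pairs, seed, p).values()))
        spread = (means.max() - means.min()) / means.mean()
        if spread < best_spread:
            best_alpha, best_spread = alpha, spread
    return best_alpha


# ---------------------------------------------------------------------------
# Survey analyses
# ---------------------------------------------------------------------------

@dataclass
class TemplateEntry:
    pocket: Pocket
    sequence: str
    fingerprint: Fingerprint


def find_best_template(
    target: Pocket,
    target_sequence: str,
    target_fingerprint: Fingerprint,
    library: list[TemplateEntry],
    model: GumbelModel,
    max_identity: float = 0.30,
    tc_min: float = 0.4,
    params: PSParams = DEFAULT_PARAMS,
):
    """Best-P-value template with sequence identity < max_identity and ligand
    Tc > tc_min; returns (entry, alignment) or None."""
    best = None
    for entry in library:
        if sequence_identity(target_sequence, entry.sequence) >= max_identity:
            continue
        if tanimoto(target_fingerprint, entry.fingerprint) <= tc_min:
            continue
        aln = align_pockets(entry.pocket, target, model=model, params=params)
        key = (aln.p_value, -aln.ps_score)
        if best is None or key < best[0]:
            best = (key, entry, aln)
    if best is None:
        return None
    return best[1], best[2]


def template_search_curve(
    targets: list[tuple[Pocket, str, Fingerprint]],
    library: list[TemplateEntry],
    model: GumbelModel,
    tc_min: float = 0.4,
    p_grid: tuple[float, ...] = P_THRESHOLDS,
    max_identity: float = 0.30,
    params: PSParams = DEFAULT_PARAMS,
) -> pd.DataFrame:
    """Cumulative fraction of targets matched at P below each grid value."""
    best_p = []
    for pocket, seq, fp in targets:
        hit = find_best_template(pocket, seq, fp, library, model,
                                 max_identity=max_identity, tc_min=tc_min,
                                 params=params)
        best_p.append(np.inf if hit is None else hit[1].p_value)
    best_p = np.array(best_p)
    rows = [
        {"p_threshold": p, "fraction_matched": float((best_p < p).mean())}
        for p in sorted(p_grid, reverse=True)
    ]
    return pd.DataFrame(rows)


def promiscuity_scan(
    pockets: list[Pocket],
    results: pd.DataFrame,
    tc_lookup: dict[tuple[str, str], float],
    identity_lookup: dict[tuple[str, str], float] | None = None,
    ps_min: float = 0.60,
    identity: float = 1.0,
    tc_max: float = 0.30,
    length_ratio: tuple[float, float] = (0.7, 1.43),
) -> pd.DataFrame:
    """Promiscuous pocket pairs: same protein (identity = 1), comparable size,
    highly similar pockets (PS > ps_min) bound to dissimilar ligands (Tc < tc_max).

    ``tc_lookup`` maps unordered pocket-id pairs to ligand Tc;
    ``identity_lookup`` likewise for sequence identity (computed from pocket
    sequences when absent).
    """
    by_id = {p.pocket_id: p for p in pockets}
    rows = []
    seen = set()
    for row in results.itertuples(index=False):
        key = tuple(sorted((row.template_id, row.query_id)))
        if key in seen or row.template_id == row.query_id:
            continue
        seen.add(key)
        pa, pb = by_id.get(key[0]), by_id.get(key[1])
        if pa is None or pb is None:
            continue
        ratio = pa.L / pb.L
        if not (length_ratio[0] <= ratio <= length_ratio[1]):
            continue
        both = results[
            ((results["template_id"] == key[0]) & (results["query_id"] == key[1]))
            | ((results["template_id"] == key[1]) & (results["query_id"] == key[0]))
        ]
        ps = float(both["ps_score"].max())
        if ps <= ps_min:
            continue
        if identity_lookup is not None:
            ident = identity_lookup.get(key, identity_lookup.get((key[1], key[0]), 0.0))
        else:
            ident = sequence_identity(pa.sequence or pa.aa, pb.sequence or pb.aa)
        if ident < identity:
            continue
        tc = tc_lookup.get(key, tc_lookup.get((key[1], key[0])))
        if tc is None or tc >= tc_max:
            continue
        rows.append(
            {"pocket_a": key[0], "pocket_b": key[1], "ps_score": ps,
             "identity": ident, "tc": tc}
        )
    return pd.DataFrame(rows, columns=["pocket_a", "pocket_b", "ps_score", "identity", "tc"])


def tc_vs_pocket_similarity(
    results: pd.DataFrame,
    tc_lookup: dict[tuple[str, str], float],
    p_bins: tuple[float, ...] = (0.05, 0.01, 1e-3, 1e-4, 1e-5),
    tc_significant: float = 0.4,
) -> pd.DataFrame:
    """Ligand-similarity distribution per pocket-similarity (P-value) bin.

    Bins are [p_{k+1}, p_k) half-open intervals over descending thresholds,
    with a final open bin below the smallest threshold.  Empty bins are
    omitted (missing, not zero).
    """
    missing = [
        (t, q) for t, q in zip(results["template_id"], results["query_id"])
        if tuple(sorted((t, q))) not in tc_lookup
        and (t, q) not in tc_lookup and (q, t) not in tc_lookup
    ]
    if missing:
        raise DomainError(f"no ligand Tc for pocket pairs: {sorted(set(missing))[:5]} ...")
    thresholds = sorted(p_bins, reverse=True)  # e.g. 0.05, 0.01, ...
    edges = [np.inf] + thresholds
    rows = []
    pvals = results["p_value"].to_numpy()
    tcs = np.array(
        [
            tc_lookup.get(tuple(sorted((t, q))),
                          tc_lookup.get((t, q), tc_lookup.get((q, t))))
            for t, q in zip(results["template_id"], results["query_id"])
        ]
    )
    for k, p_hi in enumerate(thresholds):
        p_lo = thresholds[k + 1] if k + 1 < len(thresholds) else 0.0
        sel = (pvals < p_hi) & (pvals >= p_lo)
        if k == 0:
            sel = (pvals < p_hi) & (pvals >= p_lo)
        if not sel.any():
            continue
        sub = tcs[sel]
        rows.append(
            {
                "p_upper": p_hi,
                "p_lower": p_lo,
                "n_pairs": int(sel.sum()),
                "median_tc": float(np.median(sub)),
                "frac_tc_significant": float((sub > tc_significant).mean()),
            }
        )
    return pd.DataFrame(
        rows, columns=["p_upper", "p_lower", "n_pairs", "median_tc", "frac_tc_significant"]
    )
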