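"""Synthetic inputs with known ground truth for every pipeline stage.

The generators stand in for the PDB-derived survey data: compact
self-avoiding Ca traces with ideal-geometry Cb atoms play the role of
pocket-lining residues; helix-wrapped protein/ligand complexes produce exact,
margin-guaranteed contact tables; fingerprint pairs hit a requested Tanimoto
coefficient; and random or clustered directed graphs come with planted
structure and (for small n) the exact minimum dominating set.

Everything is deterministic given (spec, seed).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, PocketspaceError
from .ligand_chem import Fingerprint
from .structure_io import (
    AtomRecord,
    Chain,
    ContactRecord,
    HetGroup,
    Pocket,
    ProteinResidue,
    Residue,
    Structure,
)

_AA_BY_GROUP = ["LVIMC", "AG", "ST", "P", "FYW", "EDNQ", "KR", "H"]
_ALL_AA = "".join(_AA_BY_GROUP)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study conditions."""

    seed: int = 1
    L: int = 40  # pocket length (residues)
    noise_sigma: float = 0.0  # A, coordinate perturbation
    mutate_frac: float = 0.0
    n_ligand_atoms: int = 12
    target_tc: float = 0.5
    n_nodes: int = 12  # graph parameters
    edge_density: float = 0.3
    n_clusters: int = 3

    def __post_init__(self) -> None:
        if self.L < 11:
            raise DomainError("pocket length must be >= 11")
        if not 0.0 <= self.mutate_frac <= 1.0:
            raise DomainError("mutate_frac must lie in [0, 1]")
        if not 0.0 <= self.target_tc <= 1.0:
            raise DomainError("target_tc must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Pockets
# ---------------------------------------------------------------------------

def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _pseudo_cb(ca: np.ndarray, i: int) -> np.ndarray:
    """Cb at ~1.53 A from Ca, ideal-geometry direction from the local trace."""
    L = len(ca)
    if L < 3:
        return ca[i] + np.array([1.53, 0.0, 0.0])
    j = min(max(i, 1), L - 2)
    d1 = ca[j] - ca[j - 1]
    d2 = ca[j] - ca[j + 1]
    d1 /= np.linalg.norm(d1)
    d2 /= np.linalg.norm(d2)
    bis = d1 + d2
    perp = np.cross(d1, d2)
    if np.linalg.norm(bis) < 1e-6 or np.linalg.norm(perp) < 1e-6:
        ref = np.array([0.0, 0.0, 1.0]) if abs(d1[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        bis = np.cross(d1, ref)
        perp = np.cross(d1, bis)
    bis /= np.linalg.norm(bis)
    perp /= np.linalg.norm(perp)
    direction = 0.82 * bis + 0.57 * perp  # ~tetrahedral tilt out of the chain plane
    direction /= np.linalg.norm(direction)
    return ca[i] + 1.53 * direction


def _sample_chain(rng: np.random.Generator, L: int, confine_radius: float,
                  min_sep: float = 4.0, step_tries: int = 200) -> np.ndarray:
    """Self-avoiding random Ca trace with 3.8 +/- 0.2 A steps inside a sphere."""
    for _ in range(60):
        pts = [rng.uniform(-0.3, 0.3, size=3) * confine_radius]
        ok = True
        for _i in range(1, L):
            placed = False
            for _try in range(step_tries):
                step = float(np.clip(rng.normal(3.8, 0.2), 3.2, 4.4))
                cand = pts[-1] + step * _random_unit(rng)
                if np.linalg.norm(cand) > confine_radius:
                    continue
                if len(pts) > 1:
                    d = np.linalg.norm(np.array(pts[:-1]) - cand, axis=1)
                    if d.min() < min_sep:
                        continue
                pts.append(cand)
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return np.array(pts)
    raise PocketspaceError("self-avoiding chain generation failed; relax parameters")


def _sample_aa(rng: np.random.Generator, L: int) -> list[str]:
    # uniform over the 8 chemical groups, then uniform within the group
    groups = rng.integers(0, 8, size=L)
    return [
        _AA_BY_GROUP[g][rng.integers(0, len(_AA_BY_GROUP[g]))] for g in groups
    ]


def make_pocket(spec: SyntheticSpec | None = None, *, L: int | None = None,
                seed: int | None = None, entry_id: str | None = None,
                het_code: str = "LIG", year: int | None = None,
                resolution: float | None = None) -> Pocket:
    """A synthetic pocket: compact self-avoiding Ca trace + ideal Cb + random AAs."""
    if spec is None:
        spec = SyntheticSpec(seed=1 if seed is None else seed, L=40 if L is None else L)
    rng = np.random.default_rng(spec.seed)
    confine = 3.2 * spec.L ** (1.0 / 3.0)
    ca = _sample_chain(rng, spec.L, confine)
    aas = _sample_aa(rng, spec.L)
    residues = []
    for i, (pos, aa) in enumerate(zip(ca, aas)):
        cb = None if aa == "G" else _pseudo_cb(ca, i)
        residues.append(Residue(aa, "A", i + 1, pos, cb))
    return Pocket(
        residues=residues,
        entry_id=entry_id or f"S{spec.seed % 10000:04d}",
        het_code=het_code,
        year=year,
        resolution=resolution,
        primary_chain="A",
        sequence="".join(aas),
    )


def perturb_pocket(pocket: Pocket, sigma: float, seed: int = 1,
                   mutate_frac: float = 0.0) -> Pocket:
    """Copy with i.i.d. Gaussian displacement of all atoms (sigma=0: identical)."""
    rng = np.random.default_rng(seed)
    residues = []
    for r in pocket.residues:
        ca = r.ca + (rng.normal(0.0, sigma, size=3) if sigma > 0 else 0.0)
        cb = None
        if r.cb is not None:
            cb = r.cb + (rng.normal(0.0, sigma, size=3) if sigma > 0 else 0.0)
        residues.append(Residue(r.aa, r.chain_id, r.seq_index, ca, cb, r.icode))
    if mutate_frac > 0:
        n_mut = int(round(mutate_frac * len(residues)))
        idx = rng.choice(len(residues), size=n_mut, replace=False)
        for i in idx:
            r = residues[i]
            new_aa = _ALL_AA[rng.integers(0, len(_ALL_AA))]
            residues[i] = Residue(new_aa, r.chain_id, r.seq_index, r.ca, r.cb, r.icode)
    from dataclasses import replace

    return replace(pocket, residues=residues)


# ---------------------------------------------------------------------------
# Complexes with exact contact ground truth
# ---------------------------------------------------------------------------

_CC_THRESHOLD = 1.70 + 1.70 + 2.8  # carbon-carbon contact cutoff, 6.20 A


def make_complex(
    n_contact_residues: int = 12,
    n_tail_residues: int = 8,
    n_ligand_atoms: int = 12,
    seed: int = 1,
    entry_id: str = "SYN1",
    het_code: str = "LIG",
    year: int | None = 2010,
    resolution: float | None = 2.0,
    split_chain_at: int | None = None,
    displace_ligand: float = 0.0,
) -> tuple[Structure, list[tuple[str, int, str]]]:
    """A protein/ligand complex built so that exactly ``n_contact_residues``
    residues satisfy the vdW + 2.8 A contact rule, all with >= 0.5 A margin,
    and every other residue clears the cutoff by >= 1 A.

    The protein is a helix wound around an axial ligand; the tail spirals
    outward.  Returns the structure and the ground-truth list of contacting
    residue keys.  ``displace_ligand`` shifts the ligand away (A) to create
    contact-free complexes.
    """
    if n_contact_residues < 1:
        raise DomainError("need at least one contact residue")
    if n_ligand_atoms < 2:
        raise DomainError("need at least two ligand atoms")
    rng = np.random.default_rng(seed)

    helix_r = 5.5
    dtheta = math.radians(30.0)
    dz = math.sqrt(max(3.8**2 - (2.0 * helix_r * math.sin(dtheta / 2.0)) ** 2, 0.1))
    phase = rng.uniform(0, 2 * math.pi)

    ca = np.zeros((n_contact_residues + n_tail_residues, 3))
    for i in range(n_contact_residues):
        th = phase + i * dtheta
        ca[i] = (helix_r * math.cos(th), helix_r * math.sin(th), i * dz)
    # tail: jump to radius >= 7.4 in one 3.8 A step, then spiral outward
    r_prev = helix_r
    z_prev = (n_contact_residues - 1) * dz
    th_prev = phase + (n_contact_residues - 1) * dtheta
    for j in range(n_tail_residues):
        i = n_contact_residues + j
        r_new = r_prev + (1.9 if j == 0 else 1.5)
        chord2 = 3.8**2 - (r_new - r_prev) ** 2
        dth = 2.0 * math.asin(math.sqrt(max(chord2, 0.5)) / (r_prev + r_new))
        th_new = th_prev + dth
        ca[i] = (r_new * math.cos(th_new), r_new * math.sin(th_new), z_prev)
        r_prev, th_prev = r_new, th_new

    # ligand: axial chain of carbons spanning the helix z-range
    z_lo, z_hi = -0.5, (n_contact_residues - 1) * dz + 0.5
    lig_z = np.linspace(z_lo, z_hi, n_ligand_atoms)
    lig = np.column_stack([np.zeros(n_ligand_atoms), np.zeros(n_ligand_atoms), lig_z])
    if displace_ligand:
        lig[:, 0] += displace_ligand

    aas = _sample_aa(rng, len(ca))
    # random rigid placement of the whole complex
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    shift = rng.uniform(-20, 20, size=3)
    ca = ca @ R.T + shift
    lig = lig @ R.T + shift

    residues: list[ProteinResidue] = []
    split = len(ca) + 1 if split_chain_at is None else split_chain_at
    for i in range(len(ca)):
        chain_id = "A" if i < split else "B"
        cb = _pseudo_cb(ca, i)
        atoms = [AtomRecord("CA", "C", ca[i])]
        if aas[i] != "G":
            atoms.append(AtomRecord("CB", "C", cb))
        residues.append(ProteinResidue(aas[i], chain_id, i + 1, "", atoms))
    chains = []
    for cid in ("A", "B"):
        rs = [r for r in residues if r.chain_id == cid]
        if rs:
            chains.append(Chain(cid, rs))
    het = HetGroup(
        het_code, 1, "L", 1,
        [AtomRecord(f"C{k+1}", "C", lig[k]) for k in range(n_ligand_atoms)],
    )
    structure = Structure(entry_id, year, resolution, chains, [het])

    # exact ground truth from the same distance rule the extractor applies
    expected: list[tuple[str, int, str]] = []
    for res in residues:
        dmin = min(
            float(np.linalg.norm(a.pos - lp))
            for a in res.atoms
            for lp in lig
        )
        if dmin < _CC_THRESHOLD:
            expected.append(res.key)
    if not displace_ligand and len(expected) != n_contact_residues:
        raise PocketspaceError(
            f"construction violated contact ground truth "
            f"({len(expected)} != {n_contact_residues})"
        )
    return structure, expected


def structure_to_pdb(structure: Structure) -> str:
    """Serialize a (synthetic) structure to minimal PDB text."""
    lines = []
    if structure.deposition_year:
        lines.append(
            f"HEADER    SYNTHETIC POCKET                        01-JAN-"
            f"{structure.deposition_year % 100:02d}   {structure.entry_id:<4s}"
        )
    if structure.resolution:
        lines.append(
            f"REMARK   2 RESOLUTION.    {structure.resolution:4.2f} ANGSTROMS."
        )
    serial = 1
    from .structure_io import _STANDARD_AA3

    aa3 = {v: k for k, v in _STANDARD_AA3.items()}
    for ch in structure.chains:
        for res in ch.residues:
            rn = aa3.get(res.aa, "ALA")
            for a in res.atoms:
                x, y, z = a.pos
                lines.append(
                    f"ATOM  {serial:5d} {a.name:^4s}{rn:>4s} {ch.chain_id}{res.seq_index:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {a.element:>2s}"
                )
                serial += 1
    for het in structure.het_groups:
        for a in het.atoms:
            x, y, z = a.pos
            lines.append(
                f"HETATM{serial:5d} {a.name:^4s}{het.het_code:>4s} {het.chain_id}{het.seq_index:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {a.element:>2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Fingerprint pairs of controlled Tanimoto
# ---------------------------------------------------------------------------

def make_fingerprint_pair(
    target_tc: float, seed: int = 1, union_size: int = 100, width: int = 1024
) -> tuple[Fingerprint, Fingerprint]:
    """Two fingerprints whose Tanimoto coefficient is within 0.02 of target_tc."""
    if not 0.0 <= target_tc <= 1.0:
        raise DomainError("target_tc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    union = rng.choice(width, size=union_size, replace=False)
    n_shared = int(round(target_tc * union_size))
    shared = set(union[:n_shared].tolist())
    rest = union[n_shared:]
    half = len(rest) // 2
    a_only = set(rest[:half].tolist())
    b_only = set(rest[half:].tolist())
    if target_tc == 1.0:
        a_only = b_only = set()
        shared = set(union.tolist())
    fa = Fingerprint(bits=frozenset(shared | a_only), het_code="SYA", width=width)
    fb = Fingerprint(bits=frozenset(shared | b_only), het_code="SYB", width=width)
    return fa, fb


# ---------------------------------------------------------------------------
# Graphs with planted ground truth
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGraph:
    edges: list[tuple[str, str]]  # directed
    nodes: list[str]
    planted_clusters: list[list[str]] | None = None
    exact_min_dominating: int | None = None


def _exact_min_dominating(nodes: list[str], edges: set[tuple[str, str]]) -> int:
    """Exhaustive minimum dominating set under bidirectional matching (n <= 12)."""
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    # bitmask of nodes each node dominates (itself + bidirectional partners)
    dom = [1 << i for i in range(n)]
    for a, b in edges:
        if (b, a) in edges:
            dom[idx[a]] |= 1 << idx[b]
            dom[idx[b]] |= 1 << idx[a]
    full = (1 << n) - 1
    for k in range(1, n + 1):
        for combo in itertools.combinations(range(n), k):
            mask = 0
            for i in combo:
                mask |= dom[i]
            if mask == full:
                return k
    return n


def make_graph(
    n: int,
    model: str = "random",
    edge_density: float = 0.3,
    n_clusters: int = 3,
    seed: int = 1,
) -> SyntheticGraph:
    """Directed graph with known structure.

    ``clustered``: ``n_clusters`` bidirectional cliques, no inter-cluster
    edges (planted SCC count = cluster count).  ``random``: each ordered pair
    carries an edge with probability ``edge_density``.  For n <= 12 the exact
    minimum dominating set size is computed by exhaustive search.
    """
    rng = np.random.default_rng(seed)
    nodes = [f"n{i:03d}" for i in range(n)]
    edges: set[tuple[str, str]] = set()
    planted = None
    if model == "clustered":
        sizes = np.full(n_clusters, n // n_clusters)
        sizes[: n % n_clusters] += 1
        planted = []
        start = 0
        for s in sizes:
            block = nodes[start : start + s]
            planted.append(block)
            for a in block:
                for b in block:
                    if a != b:
                        edges.add((a, b))
            start += s
    elif model == "random":
        for a in nodes:
            for b in nodes:
                if a != b and rng.random() < edge_density:
                    edges.add((a, b))
    else:
        raise DomainError(f"unknown graph model {model!r}")
    exact = _exact_min_dominating(nodes, edges) if n <= 12 else None
    return SyntheticGraph(sorted(edges), nodes, planted, exact)
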