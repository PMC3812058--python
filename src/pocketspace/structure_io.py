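"""Structure parsing, protein-ligand contact detection, pocket extraction and curation.

A *pocket* is the set of protein residues with at least one heavy atom closer
to a ligand heavy atom than the sum of the two van der Waals radii plus 2.8 A
(the diameter of a water probe).  Pockets are extracted from holo complexes,
then curated: ligands must have 10-199 heavy atoms, one instance per
(entry, HET code) is kept (most contacts), primary chains are clustered at
90% sequence identity with one best-resolution representative per
(cluster, HET code), and pockets with 10 or fewer residues are dropped.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import (
    ConfigurationError,
    DomainError,
    EmptyPocketError,
    EmptyStructureError,
    ParseError,
)

# Bondi-style van der Waals radii (A).  The set is editable: pass your own
# mapping to find_contacts / extract_pocket, or load one from YAML via the CLI.
DEFAULT_VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
    "B": 1.92,
}
DEFAULT_FALLBACK_RADIUS = 1.70
PROBE_DIAMETER = 2.8  # diameter of a probing water molecule, A

# Solvent/buffer/ion HET codes never treated as ligands.
DEFAULT_EXCLUDED_HET: frozenset[str] = frozenset(
    """HOH DOD WAT NA K LI CS RB CL BR IOD F MG CA ZN MN FE FE2 CU CU1 CO NI CD HG
    SO4 PO4 NO3 CO3 ACT FMT GOL EDO PEG PGE PG4 MPD DMS BME TRS EPE MES IMD
    """.split()
)

_STANDARD_AA3 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
_NUCLEOTIDES = {"A", "C", "G", "U", "T", "DA", "DC", "DG", "DT", "DU", "I", "DI"}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class AtomRecord:
    name: str
    element: str
    pos: np.ndarray  # (3,) A

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)


@dataclass
class ProteinResidue:
    """A full protein residue as read from a structure file."""

    aa: str  # one-letter code, 'X' if non-standard
    chain_id: str
    seq_index: int
    icode: str
    atoms: list[AtomRecord]

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_index, self.icode)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Chain:
    chain_id: str
    residues: list[ProteinResidue]

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)


@dataclass
class HetGroup:
    het_code: str
    instance: int  # 1-based instance counter within the entry
    chain_id: str
    seq_index: int
    atoms: list[AtomRecord]  # heavy atoms only


@dataclass
class Structure:
    entry_id: str
    deposition_year: int | None
    resolution: float | None
    chains: list[Chain]
    het_groups: list[HetGroup]

    def chain(self, chain_id: str) -> Chain | None:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        return None


@dataclass
class Residue:
    """A pocket-lining residue reduced to what scoring needs (Ca/Cb + identity)."""

    aa: str
    chain_id: str
    seq_index: int
    ca: np.ndarray  # (3,)
    cb: np.ndarray | None = None  # None for Gly or when unresolvable
    icode: str = ""

    def __post_init__(self) -> None:
        self.ca = np.asarray(self.ca, dtype=float)
        if self.cb is not None:
            self.cb = np.asarray(self.cb, dtype=float)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_index, self.icode)


@dataclass
class ContactRecord:
    residue_key: tuple[str, int, str]
    protein_atom: AtomRecord
    ligand_atom: AtomRecord
    distance: float
    contact_type: str | None = None  # filled by interface_contacts
    csa: float | None = None  # contact surface area, A^2


@dataclass
class Pocket:
    """Ordered pocket-lining residues tied to a source structure and ligand."""

    residues: list[Residue]
    entry_id: str = "SYNT"
    het_code: str = "LIG"
    instance: int = 1
    year: int | None = None
    resolution: float | None = None
    primary_chain: str | None = None
    n_contacts: int = 0
    sequence: str | None = None  # primary-chain sequence, for identity clustering

    @property
    def L(self) -> int:
        return len(self.residues)

    @property
    def pocket_id(self) -> str:
        return f"{self.entry_id}:{self.het_code}:{self.instance}"

    @property
    def ca(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues], dtype=float)

    @property
    def aa(self) -> str:
        return "".join(r.aa for r in self.residues)

    def cb_or_nan(self) -> np.ndarray:
        out = np.full((self.L, 3), np.nan)
        for i, r in enumerate(self.residues):
            if r.cb is not None:
                out[i] = r.cb
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Pocket":
        """Return a rigid-body transformed copy (x -> R x + t)."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        res = [
            replace(
                r,
                ca=R @ r.ca + t,
                cb=None if r.cb is None else R @ r.cb + t,
            )
            for r in self.residues
        ]
        return replace(self, residues=res)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _resolve_altlocs(atoms: list) -> list:
    """Keep one atom per name: highest occupancy, ties by first occurrence."""
    best: dict[str, object] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in best:
            best[a.name] = a
            order.append(a.name)
        elif a.occ > best[a.name].occ:
            best[a.name] = a
    return [best[n] for n in order]


def parse_structure(
    path: str,
    format: str = "pdb",
    excluded_het: frozenset[str] = DEFAULT_EXCLUDED_HET,
) -> Structure:
    """Parse a PDB file into a :class:`Structure`.

    Waters and HET codes on ``excluded_het`` (buffers, common ions) are
    dropped; hydrogens are ignored everywhere; alternate locations are
    resolved to the highest-occupancy conformer.
    """
    import gemmi

    if format != "pdb":
        raise ParseError(f"unsupported format {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError, OSError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc

    info = dict(st.info)
    year = None
    date = info.get("_pdbx_database_status.recvd_initial_deposition_date", "")
    if len(date) >= 4 and date[:4].isdigit():
        year = int(date[:4])
    resolution = float(st.resolution) if st.resolution and st.resolution > 0 else None
    entry_id = info.get("_entry.id", "").strip() or "XXXX"

    chains: dict[str, Chain] = {}
    het_groups: list[HetGroup] = []
    het_counter: dict[str, int] = {}
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no model")
    model = st[0]
    for ch in model:
        for res in ch:
            atoms = [
                AtomRecord(a.name, a.element.name.upper(), np.array(a.pos.tolist()))
                for a in _resolve_altlocs(list(res))
                if a.element.name.upper() not in ("H", "D")
            ]
            if not atoms:
                continue
            if res.het_flag == "A" and res.name in _STANDARD_AA3 or (
                res.het_flag == "A" and gemmi.find_tabulated_residue(res.name) is not None
                and gemmi.find_tabulated_residue(res.name).is_amino_acid()
            ):
                aa = _STANDARD_AA3.get(res.name, "X")
                chains.setdefault(ch.name, Chain(ch.name, [])).residues.append(
                    ProteinResidue(aa, ch.name, res.seqid.num, res.seqid.icode.strip(), atoms)
                )
            else:
                if res.is_water() or res.name.strip() in excluded_het:
                    continue
                if res.name.strip() in _STANDARD_AA3 or res.name.strip() in _NUCLEOTIDES:
                    continue  # polymer unit modelled as HETATM
                het_counter[res.name] = het_counter.get(res.name, 0) + 1
                het_groups.append(
                    HetGroup(res.name.strip(), het_counter[res.name], ch.name,
                             res.seqid.num, atoms)
                )
    chain_list = [c for c in chains.values() if c.residues]
    if not chain_list:
        raise EmptyStructureError(f"{path}: no protein chain found")
    return Structure(entry_id, year, resolution, chain_list, het_groups)


# ---------------------------------------------------------------------------
# Contacts and pocket extraction
# ---------------------------------------------------------------------------

def _radius(element: str, radii: dict[str, float], fallback: float | None) -> float:
    r = radii.get(element.upper())
    if r is None:
        if fallback is None:
            raise ConfigurationError(
                f"no van der Waals radius for element {element!r} and no fallback set"
            )
        return fallback
    return r


def find_contacts(
    structure: Structure,
    ligand: HetGroup,
    radii: dict[str, float] | None = None,
    probe: float = PROBE_DIAMETER,
    fallback_radius: float | None = DEFAULT_FALLBACK_RADIUS,
) -> list[ContactRecord]:
    """All protein-heavy-atom / ligand-heavy-atom pairs closer than vdW sum + probe."""
    radii = DEFAULT_VDW_RADII if radii is None else radii
    prot_atoms: list[tuple[ProteinResidue, AtomRecord]] = []
    for ch in structure.chains:
        for res in ch.residues:
            for a in res.atoms:
                prot_atoms.append((res, a))
    if not prot_atoms:
        return []
    coords = np.array([a.pos for _, a in prot_atoms])
    prot_r = np.array([_radius(a.element, radii, fallback_radius) for _, a in prot_atoms])
    max_r = prot_r.max() if len(prot_r) else 0.0
    tree = cKDTree(coords)
    contacts: list[ContactRecord] = []
    for la in ligand.atoms:
        lr = _radius(la.element, radii, fallback_radius)
        idx = tree.query_ball_point(la.pos, r=lr + max_r + probe)
        for i in sorted(idx):
            res, pa = prot_atoms[i]
            d = float(np.linalg.norm(pa.pos - la.pos))
            if d < prot_r[i] + lr + probe:
                contacts.append(ContactRecord(res.key, pa, la, d))
    contacts.sort(key=lambda c: (c.residue_key, c.protein_atom.name, c.ligand_atom.name))
    return contacts


_CB_A, _CB_B, _CB_C = -0.58273431, 0.56802827, -0.54067466


def _reconstruct_cb(res: ProteinResidue) -> np.ndarray | None:
    """Ideal-geometry Cb from backbone N/CA/C (used when CB is unresolved)."""
    n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
    if n is None or ca is None or c is None:
        return None
    b = ca.pos - n.pos
    cdir = c.pos - ca.pos
    a = np.cross(b, cdir)
    return _CB_A * a + _CB_B * b + _CB_C * cdir + ca.pos


def extract_pocket(
    structure: Structure,
    ligand: HetGroup,
    radii: dict[str, float] | None = None,
    probe: float = PROBE_DIAMETER,
    contacts: list[ContactRecord] | None = None,
) -> Pocket:
    """Residues with >=1 ligand contact, in chain/sequence order, from any chain."""
    if contacts is None:
        contacts = find_contacts(structure, ligand, radii=radii, probe=probe)
    if not contacts:
        raise EmptyPocketError(
            f"{structure.entry_id}:{ligand.het_code}:{ligand.instance} has no contacts"
        )
    per_res_counts: dict[tuple[str, int, str], int] = {}
    for c in contacts:
        per_res_counts[c.residue_key] = per_res_counts.get(c.residue_key, 0) + 1
    chain_counts: dict[str, int] = {}
    for key, n in per_res_counts.items():
        chain_counts[key[0]] = chain_counts.get(key[0], 0) + n
    primary_chain = max(sorted(chain_counts), key=lambda c: chain_counts[c])

    residues: list[Residue] = []
    for ch in structure.chains:
        for res in ch.residues:
            if res.key not in per_res_counts:
                continue
            ca = res.atom("CA")
            if ca is None:
                warnings.warn(f"residue {res.key} lacks CA, skipped from pocket")
                continue
            cb_atom = res.atom("CB")
            if cb_atom is not None:
                cb = cb_atom.pos
            elif res.aa == "G":
                cb = None
            else:
                cb = _reconstruct_cb(res)
            residues.append(Residue(res.aa, res.chain_id, res.seq_index, ca.pos, cb, res.icode))
    pchain = structure.chain(primary_chain)
    return Pocket(
        residues=residues,
        entry_id=structure.entry_id,
        het_code=ligand.het_code,
        instance=ligand.instance,
        year=structure.deposition_year,
        resolution=structure.resolution,
        primary_chain=primary_chain,
        n_contacts=len(contacts),
        sequence=pchain.sequence if pchain else None,
    )


# ---------------------------------------------------------------------------
# Sequence identity and curation
# ---------------------------------------------------------------------------

def sequence_identity(seq_a: str, seq_b: str) -> float:
    """Identity fraction of an optimal global alignment over the shorter length."""
    if not seq_a or not seq_b:
        raise DomainError("sequence_identity requires non-empty sequences")
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(seq_a, seq_b)[0]
    ident = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        ident += sum(1 for x, y in zip(seq_a[a0:a1], seq_b[b0:b1]) if x == y)
    return ident / min(len(seq_a), len(seq_b))


def _looks_polymeric(het: HetGroup) -> bool:
    """Heuristic: peptide- or nucleotide-like linkage atoms mark polymer HET groups."""
    names = {a.name for a in het.atoms}
    if {"N", "CA", "C", "O"} <= names:
        return True
    if "P" in names and ({"O3'", "O5'"} & names or {"O3*", "O5*"} & names):
        return True
    return False


def cluster_sequences(sequences: list[str], threshold: float = 0.9) -> list[int]:
    """Greedy incremental clustering (longest first); returns a cluster id per input."""
    order = sorted(range(len(sequences)), key=lambda i: -len(sequences[i]))
    reps: list[tuple[int, str]] = []  # (cluster id, representative sequence)
    labels = [0] * len(sequences)
    for i in order:
        seq = sequences[i]
        assigned = None
        for cid, rep in reps:
            if sequence_identity(seq, rep) >= threshold:
                assigned = cid
                break
        if assigned is None:
            assigned = len(reps)
            reps.append((assigned, seq))
        labels[i] = assigned
    return labels


def curate_dataset(
    structures: list[Structure],
    radii: dict[str, float] | None = None,
    min_ligand_atoms: int = 10,
    max_ligand_atoms: int = 200,
    min_pocket_residues: int = 11,
    identity_threshold: float = 0.9,
) -> list[Pocket]:
    """Apply the survey's curation filters and return the non-redundant pocket set.

    Filters, in order: ligand heavy-atom count in ``[min, max)``; polymeric HET
    groups removed; one instance per (entry, HET code) by max contacts; primary
    chains clustered at ``identity_threshold``; one representative per
    (cluster, HET code) by best resolution then most contacts; pockets with
    fewer than ``min_pocket_residues`` residues dropped.
    """
    candidates: list[Pocket] = []
    for st in structures:
        per_code: dict[str, list[tuple[list[ContactRecord], HetGroup]]] = {}
        for het in st.het_groups:
            if not (min_ligand_atoms <= len(het.atoms) < max_ligand_atoms):
                continue
            if _looks_polymeric(het):
                continue
            contacts = find_contacts(st, het, radii=radii)
            if not contacts:
                continue
            per_code.setdefault(het.het_code, []).append((contacts, het))
        for code, group in per_code.items():
            # one instance per (entry, het code): most contacts, first on ties
            contacts, het = max(group, key=lambda ch: len(ch[0]))
            candidates.append(extract_pocket(st, het, radii=radii, contacts=contacts))

    if not candidates:
        return []
    seqs = [p.sequence or p.aa for p in candidates]
    labels = cluster_sequences(seqs, identity_threshold)

    best: dict[tuple[int, str], Pocket] = {}
    for p, cid in zip(candidates, labels):
        key = (cid, p.het_code)
        cur = best.get(key)
        if cur is None or _representative_rank(p) < _representative_rank(cur):
            best[key] = p
    kept = [p for p in best.values() if p.L >= min_pocket_residues]
    kept.sort(key=lambda p: p.pocket_id)
    return kept


def _representative_rank(p: Pocket) -> tuple:
    res = p.resolution if p.resolution is not None else math.inf
    return (res, -p.n_contacts, p.pocket_id)


# ---------------------------------------------------------------------------
# Pocket JSON / TSV I/O
# ---------------------------------------------------------------------------

def pocket_to_dict(p: Pocket) -> dict:
    return {
        "pocket_id": p.pocket_id,
        "entry_id": p.entry_id,
        "het_code": p.het_code,
        "instance": p.instance,
        "year": p.year,
        "resolution": p.resolution,
        "primary_chain": p.primary_chain,
        "n_contacts": p.n_contacts,
        "sequence": p.sequence,
        "residues": [
            {
                "aa": r.aa,
                "chain_id": r.chain_id,
                "seq_index": r.seq_index,
                "icode": r.icode,
                "ca": [round(float(x), 4) for x in r.ca],
                "cb": None if r.cb is None else [round(float(x), 4) for x in r.cb],
            }
            for r in p.residues
        ],
    }


def pocket_from_dict(d: dict) -> Pocket:
    residues = [
        Residue(
            rr["aa"], rr["chain_id"], rr["seq_index"],
            np.array(rr["ca"], float),
            None if rr["cb"] is None else np.array(rr["cb"], float),
            rr.get("icode", ""),
        )
        for rr in d["residues"]
    ]
    return Pocket(
        residues=residues,
        entry_id=d["entry_id"],
        het_code=d["het_code"],
        instance=d["instance"],
        year=d.get("year"),
        resolution=d.get("resolution"),
        primary_chain=d.get("primary_chain"),
        n_contacts=d.get("n_contacts", 0),
        sequence=d.get("sequence"),
    )


def write_pockets_json(pockets: list[Pocket], path: str) -> None:
    with open(path, "w") as fh:
        json.dump([pocket_to_dict(p) for p in pockets], fh, indent=1)


def read_pockets_json(path: str) -> list[Pocket]:
    with open(path) as fh:
        return [pocket_from_dict(d) for d in json.load(fh)]


def pocket_index(pockets: list[Pocket]) -> pd.DataFrame:
    """TSV-ready index: one row per pocket."""
    return pd.DataFrame(
        {
            "pocket_id": [p.pocket_id for p in pockets],
            "entry_id": [p.entry_id for p in pockets],
            "het_code": [p.het_code for p in pockets],
            "L": [p.L for p in pockets],
            "year": [p.year for p in pockets],
            "resolution": [p.resolution for p in pockets],
        }
    )
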