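"""PDB reading, preprocessing and QC for protein-protein complexes.

A complex arrives as a PDB file plus two partner chain-ID sets. Before any
descriptor can be computed the structure is quality-controlled and
normalized:

1. search the backbone of every chain for gaps (residue-numbering breaks,
   over-long peptide C-N distances, or residues missing backbone heavy
   atoms);
2. record whether hydrogens are present (placement itself belongs to the
   external optimization engine);
3. keep whitelisted single-atom ions (Mg, Ca, Na, Cl, Fe, K, Zn) only when
   they sit within 2.0 A (strict) of a protein atom — these are structural
   and participate in the interface energetics;
4. eliminate every other heteroatom: waters, nonstructural ions, small
   ligands, cofactors, and glycan residues.

Chains are then renamed A, B, C, ... in order of first appearance, and a
report records everything that was found or removed. Resolution worse than
2.5 A is flagged (warn-only at prediction time; training-set curation
filters on it).

File parsing and writing are delegated to gemmi; this module owns the
preprocessing rules.
"""

from __future__ import annotations

import dataclasses
import string
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .errors import ChainSpecError, EmptyStructureError, GapRejectionError, PDBParseError

__all__ = [
    "Atom",
    "StructureModel",
    "ComplexSpec",
    "GapRecord",
    "IonRecord",
    "PreprocessReport",
    "read_pdb",
    "write_pdb",
    "detect_backbone_gaps",
    "classify_heteroatoms",
    "rename_chains",
    "preprocess",
    "ION_WHITELIST",
    "RESOLUTION_MAX",
]

#: Single-atom ion species retained when close enough to the protein.
ION_WHITELIST = frozenset({"MG", "CA", "NA", "CL", "FE", "K", "ZN"})

#: Strict Euclidean cutoff (A) for an ion to count as structural.
ION_CUTOFF = 2.0

#: C(i)-N(i+1) distance (A) beyond which consecutive residues are a gap.
#: The peptide bond is ~1.33 A; the margin absorbs refinement noise.
GAP_DISTANCE_MAX = 2.5

#: Training-set resolution ceiling (A); warn-only at prediction time.
RESOLUTION_MAX = 2.5

_WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})
_SUGAR_NAMES = frozenset(
    {"NAG", "NDG", "BMA", "MAN", "GAL", "GLC", "FUC", "SIA", "XYS", "GLA", "BGC", "A2G"}
)


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    coords: tuple[float, float, float]
    occupancy: float
    altloc: str
    chain_id: str
    res_seq: int
    icode: str
    res_name: str
    record: str  # "ATOM" or "HETATM"

    @property
    def is_protein(self) -> bool:
        return self.record == "ATOM"

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


@dataclass
class StructureModel:
    """Ordered atomic model of one (first) PDB model."""

    atoms: list[Atom]
    chain_order: list[str]
    resolution: float | None = None
    id: str = ""

    def chains(self) -> dict[str, list[Atom]]:
        out: dict[str, list[Atom]] = {c: [] for c in self.chain_order}
        for a in self.atoms:
            out[a.chain_id].append(a)
        return out

    def protein_coords(self, include_hydrogens: bool = True) -> np.ndarray:
        pts = [
            a.coords
            for a in self.atoms
            if a.is_protein and (include_hydrogens or not a.is_hydrogen)
        ]
        return np.asarray(pts, dtype=float).reshape(-1, 3)

    @property
    def has_hydrogens(self) -> bool:
        return any(a.is_hydrogen for a in self.atoms)


@dataclass(frozen=True)
class ComplexSpec:
    """The two binding partners, each a set of chain IDs."""

    partner1: frozenset[str]
    partner2: frozenset[str]

    def __post_init__(self) -> None:
        p1, p2 = frozenset(self.partner1), frozenset(self.partner2)
        object.__setattr__(self, "partner1", p1)
        object.__setattr__(self, "partner2", p2)
        if not p1 or not p2:
            raise ChainSpecError("both partners need at least one chain ID")
        if p1 & p2:
            raise ChainSpecError(f"partners share chains: {sorted(p1 & p2)}")

    def validate_against(self, model: StructureModel) -> None:
        known = set(model.chain_order)
        missing = (self.partner1 | self.partner2) - known
        if missing:
            raise ChainSpecError(
                f"chains {sorted(missing)} not in structure (has {model.chain_order})"
            )


@dataclass(frozen=True)
class GapRecord:
    chain: str
    res_before: int
    res_after: int
    reason: str  # "numbering" | "distance" | "missing heavy atoms"


@dataclass(frozen=True)
class IonRecord:
    name: str
    chain: str
    res_seq: int
    min_distance: float


@dataclass
class PreprocessReport:
    gaps: list[GapRecord] = field(default_factory=list)
    structural_ions: list[IonRecord] = field(default_factory=list)
    removed_het: dict[str, int] = field(default_factory=dict)
    chain_rename_map: dict[str, str] = field(default_factory=dict)
    hydrogens_present: bool = False
    resolution_pass: bool = True


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed)


def read_pdb(path: str | Path) -> StructureModel:
    """Parse a PDB file into a StructureModel.

    Keeps the first MODEL only (crystal structures are single-model) and
    resolves alternate locations to the highest-occupancy conformer, first
    in file on ties. Elements missing from the file are inferred from the
    atom name.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models in file")

    model = st[0]
    atoms: list[Atom] = []
    chain_order: list[str] = []
    serial = 0
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            # altloc: keep highest occupancy per atom name, ties -> first
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for at in res:
                if at.name not in best:
                    best[at.name] = at
                    order.append(at.name)
                elif at.occ > best[at.name].occ:
                    best[at.name] = at
            for name in order:
                at = best[name]
                elem = at.element.name
                if not elem or elem == "X":
                    elem = _infer_element(at.name, res.name)
                serial += 1
                atoms.append(
                    Atom(
                        serial=serial,
                        name=at.name,
                        element=elem.upper(),
                        coords=(at.pos.x, at.pos.y, at.pos.z),
                        occupancy=float(at.occ),
                        altloc=at.altloc if at.altloc != "\x00" else "",
                        chain_id=chain.name,
                        res_seq=res.seqid.num,
                        icode=res.seqid.icode.strip(),
                        res_name=res.name,
                        record="HETATM" if het else "ATOM",
                    )
                )
        if chain.name not in chain_order and any(a.chain_id == chain.name for a in atoms):
            chain_order.append(chain.name)

    if not any(a.is_protein for a in atoms):
        raise EmptyStructureError(f"{path}: no ATOM (protein) records")

    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    return StructureModel(
        atoms=atoms, chain_order=chain_order, resolution=resolution, id=st.name or path.stem
    )


def _infer_element(atom_name: str, res_name: str) -> str:
    name = atom_name.strip()
    if res_name.strip().upper() in ION_WHITELIST and len(name) <= 2:
        return name.upper()
    stripped = name.lstrip("0123456789")
    if stripped and stripped[0] in "Hh" and name[0].isdigit():
        return "H"
    return stripped[:1].upper() if stripped else "X"


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model as a PDB file (round-trips atom order and coords)."""
    st = gemmi.Structure()
    st.name = model.id or "model"
    if model.resolution is not None:
        st.resolution = model.resolution
    gm = gemmi.Model("1")
    for chain_id, chain_atoms in model.chains().items():
        ch = gemmi.Chain(chain_id)
        res = None
        res_key = None
        for a in chain_atoms:
            key = (a.res_seq, a.icode, a.res_name)
            if key != res_key:
                new_res = gemmi.Residue()
                new_res.name = a.res_name
                new_res.seqid = gemmi.SeqId(a.res_seq, a.icode or " ")
                new_res.het_flag = "H" if a.record == "HETATM" else "A"
                # add_residue copies; keep the reference it returns
                res = ch.add_residue(new_res)
                res_key = key
            at = gemmi.Atom()
            at.name = a.name
            at.element = gemmi.Element(a.element.capitalize())
            at.pos = gemmi.Position(*a.coords)
            at.occ = a.occupancy
            at.altloc = a.altloc or "\x00"
            res.add_atom(at)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Preprocessing rules

_BACKBONE = ("N", "CA", "C")


def _protein_residues(model: StructureModel) -> dict[str, list[list[Atom]]]:
    """Ordered protein residues per chain, each as its atom list."""
    out: dict[str, list[list[Atom]]] = {c: [] for c in model.chain_order}
    for chain_id, chain_atoms in model.chains().items():
        key = None
        for a in chain_atoms:
            if not a.is_protein:
                continue
            k = (a.res_seq, a.icode)
            if k != key:
                out[chain_id].append([])
                key = k
            out[chain_id][-1].append(a)
    return out


def detect_backbone_gaps(model: StructureModel) -> list[GapRecord]:
    """Find chain discontinuities.

    A gap is flagged between consecutive protein residues of a chain when
    the residue numbering jumps by more than one (insertion-coded residues
    sharing a number are contiguous), or when the C(i)-N(i+1) distance
    exceeds ``GAP_DISTANCE_MAX``. A residue missing any backbone heavy atom
    (N, CA, C) is itself flagged.
    """
    gaps: list[GapRecord] = []
    for chain_id in model.chain_order:
        residues = _protein_residues(model)[chain_id]
        for i, res in enumerate(residues):
            names = {a.name for a in res}
            if not set(_BACKBONE) <= names:
                seq = res[0].res_seq
                gaps.append(GapRecord(chain_id, seq, seq, "missing heavy atoms"))
        for prev, cur in zip(residues, residues[1:]):
            seq_prev, seq_cur = prev[0].res_seq, cur[0].res_seq
            if seq_cur - seq_prev > 1:
                gaps.append(GapRecord(chain_id, seq_prev, seq_cur, "numbering"))
                continue
            c = next((a for a in prev if a.name == "C"), None)
            n = next((a for a in cur if a.name == "N"), None)
            if c is None or n is None:
                continue  # already flagged as missing heavy atoms
            d = float(np.linalg.norm(np.subtract(c.coords, n.coords)))
            if d > GAP_DISTANCE_MAX:
                gaps.append(GapRecord(chain_id, seq_prev, seq_cur, "distance"))
    return gaps


def classify_heteroatoms(
    model: StructureModel,
    cutoff: float = ION_CUTOFF,
    include_hydrogens: bool = True,
) -> tuple[list[IonRecord], list[Atom]]:
    """Partition HETATMs into structural ions and removable atoms.

    A whitelisted single-atom ion residue is structural iff its distance to
    the nearest protein atom is strictly below ``cutoff``. Everything else
    (waters, ligands, cofactors, glycans, non-whitelisted or too-distant
    ions) is removable. The classification is total: every HETATM lands in
    exactly one of the two groups.
    """
    het_residues: dict[tuple, list[Atom]] = {}
    for a in model.atoms:
        if a.record == "HETATM":
            het_residues.setdefault((a.chain_id, a.res_seq, a.icode, a.res_name), []).append(a)

    coords = model.protein_coords(include_hydrogens=include_hydrogens)
    tree = cKDTree(coords) if coords.size else None

    structural: list[IonRecord] = []
    structural_keys: set[tuple] = set()
    removable: list[Atom] = []
    for key, res_atoms in het_residues.items():
        chain_id, res_seq, _icode, res_name = key
        code = res_name.strip().upper()
        is_ion = len(res_atoms) == 1 and (
            code in ION_WHITELIST or res_atoms[0].element.upper() in ION_WHITELIST
        )
        if is_ion and tree is not None:
            d, _ = tree.query(np.asarray(res_atoms[0].coords))
            if d < cutoff:
                structural.append(IonRecord(code, chain_id, res_seq, float(d)))
                structural_keys.add(key)
                continue
        removable.extend(res_atoms)
    structural.sort(key=lambda r: (r.chain, r.res_seq))
    return structural, removable


def _het_category(atom: Atom) -> str:
    code = atom.res_name.strip().upper()
    if code in _WATER_NAMES:
        return "waters"
    if code in _SUGAR_NAMES:
        return "sugars"
    if code in ION_WHITELIST or (atom.element.upper() in ION_WHITELIST and len(code) <= 2):
        return "nonstructural_ions"
    return "ligands"


def rename_chains(
    model: StructureModel, spec: ComplexSpec
) -> tuple[StructureModel, dict[str, str], ComplexSpec]:
    """Relabel chains A, B, C, ... in order of first appearance.

    The partner spec is remapped consistently and the old->new map is
    returned for traceability (identity when no rename is needed).
    """
    spec.validate_against(model)
    if len(model.chain_order) > len(string.ascii_uppercase):
        raise ChainSpecError(
            f"{len(model.chain_order)} chains exceed single-letter chain ID space"
        )
    mapping = {old: string.ascii_uppercase[i] for i, old in enumerate(model.chain_order)}
    if all(old == new for old, new in mapping.items()):
        return model, mapping, spec
    new_atoms = [dataclasses.replace(a, chain_id=mapping[a.chain_id]) for a in model.atoms]
    new_model = StructureModel(
        atoms=new_atoms,
        chain_order=[mapping[c] for c in model.chain_order],
        resolution=model.resolution,
        id=model.id,
    )
    new_spec = ComplexSpec(
        partner1=frozenset(mapping[c] for c in spec.partner1),
        partner2=frozenset(mapping[c] for c in spec.partner2),
    )
    return new_model, mapping, new_spec


def preprocess(
    model: StructureModel,
    spec: ComplexSpec,
    strict: bool = False,
    ion_cutoff: float = ION_CUTOFF,
) -> tuple[StructureModel, ComplexSpec, PreprocessReport]:
    """Run the full preprocessing pipeline.

    Gap search, heteroatom classification and removal, chain renaming, and
    QC bookkeeping. In strict mode any backbone gap aborts with a
    structured rejection listing the gaps.
    """
    spec.validate_against(model)
    report = PreprocessReport()
    report.gaps = detect_backbone_gaps(model)
    if strict and report.gaps:
        raise GapRejectionError(report.gaps)

    structural, removable = classify_heteroatoms(model, cutoff=ion_cutoff)
    report.structural_ions = structural
    counts: dict[str, int] = {"waters": 0, "ligands": 0, "nonstructural_ions": 0, "sugars": 0}
    removed_keys = {(a.chain_id, a.res_seq, a.icode, a.res_name, a.name) for a in removable}
    seen_residues: set[tuple] = set()
    for a in removable:
        rk = (a.chain_id, a.res_seq, a.icode, a.res_name)
        if rk not in seen_residues:
            counts[_het_category(a)] += 1
            seen_residues.add(rk)
    report.removed_het = counts

    kept = [
        a
        for a in model.atoms
        if (a.chain_id, a.res_seq, a.icode, a.res_name, a.name) not in removed_keys
    ]
    chain_order = [c for c in model.chain_order if any(a.chain_id == c for a in kept)]
    cleaned = StructureModel(
        atoms=kept, chain_order=chain_order, resolution=model.resolution, id=model.id
    )
    report.hydrogens_present = cleaned.has_hydrogens
    report.resolution_pass = model.resolution is None or model.resolution <= RESOLUTION_MAX

    cleaned, mapping, spec = rename_chains(cleaned, spec)
    report.chain_rename_map = mapping
    return cleaned, spec, report
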