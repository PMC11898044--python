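"""Synthetic structures and descriptor tables with planted ground truth.

Every preprocessing and learning stage is testable without downloading
real structures:

- :func:`make_pdb` builds idealized polyalanine complexes with ions,
  waters, ligands, sugars and backbone gaps planted at exactly specified
  positions, and returns a manifest of the planted facts so tests can
  assert counts without tolerances;
- :func:`make_table` builds labeled descriptor tables from a linear (or
  additive-nonlinear) generative model with Gaussian features and a
  label distribution shifted into the physically typical binding
  free-energy range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .descriptors import LABEL_COLUMN, FeatureSchema, LabeledTable, default_schema
from .structure import ION_WHITELIST, Atom, StructureModel, write_pdb

__all__ = [
    "SyntheticStructureSpec",
    "SyntheticTableSpec",
    "build_structure",
    "make_pdb",
    "make_table",
]

# Planar idealized residue template (relative to residue origin, A).
# Consecutive residue origins are 3.8 A apart along x, which places the
# peptide C(i)-N(i+1) distance at exactly 1.33 A.
_RESIDUE_TEMPLATE = (
    ("N", "N", (0.000, 0.000, 0.000)),
    ("CA", "C", (1.200, 0.800, 0.000)),
    ("C", "C", (2.470, 0.000, 0.000)),
    ("O", "O", (2.800, -1.100, 0.000)),
    ("CB", "C", (1.200, 1.600, 1.200)),
)
_RESIDUE_SPACING = 3.8
_CHAIN_SPACING = 10.0


@dataclass(frozen=True)
class SyntheticStructureSpec:
    """Recipe for a planted-fact polyalanine complex."""

    chains: tuple[tuple[str, int], ...] = (("A", 10), ("B", 10))
    ions: tuple[tuple[str, float], ...] = ()  # (element code, min distance to protein, A)
    n_waters: int = 0
    n_ligand_residues: int = 0
    n_sugar_residues: int = 0
    gap_at: tuple[str, int, str] | None = None  # (chain, after residue number, mode)
    seed: int = 0

    def __post_init__(self) -> None:
        for _, n in self.chains:
            if n < 2:
                raise ValueError("each chain needs at least 2 residues")
        for _, d in self.ions:
            if d < 0:
                raise ValueError("ion distances must be >= 0")
        if self.gap_at is not None and self.gap_at[2] not in ("numbering", "distance"):
            raise ValueError("gap mode must be 'numbering' or 'distance'")


def build_structure(spec: SyntheticStructureSpec) -> tuple[StructureModel, dict]:
    """Construct the StructureModel and the manifest of planted facts.

    Geometry is deterministic given the spec: ideal template coordinates,
    ions placed at *exactly* the requested minimum distance below a CA
    atom, waters/ligands/sugars placed well away from every ion anchor.
    A numbering-mode gap skips one residue number after ``gap_at``; a
    distance-mode gap translates all later residues so the planted
    C-N distance is exactly 4.0 A.
    """
    atoms: list[Atom] = []
    serial = 0
    ca_anchors: list[tuple[float, float]] = []  # (x, y) of CA atoms of chain 1
    manifest: dict = {
        "expected_gaps": [],
        "expected_structural_ions": [],
        "expected_nonstructural_ions": [],
        "expected_removed": {"waters": spec.n_waters, "ligands": spec.n_ligand_residues,
                             "nonstructural_ions": 0, "sugars": spec.n_sugar_residues},
        "chains": {cid: n for cid, n in spec.chains},
    }

    for chain_index, (chain_id, n_res) in enumerate(spec.chains):
        y0 = _CHAIN_SPACING * chain_index
        seq = 0
        x_shift = 0.0
        for i in range(n_res):
            seq += 1
            if spec.gap_at is not None and spec.gap_at[0] == chain_id and i > 0:
                gap_chain, after, mode = spec.gap_at
                if seq - 1 == after:
                    if mode == "numbering":
                        manifest["expected_gaps"].append((chain_id, seq - 1, seq + 1, "numbering"))
                        seq += 1
                    else:
                        x_shift += 4.0 - 1.33  # stretches planted C-N to 4.0 A
                        manifest["expected_gaps"].append((chain_id, seq - 1, seq, "distance"))
            x0 = _RESIDUE_SPACING * i + x_shift
            for name, element, (dx, dy, dz) in _RESIDUE_TEMPLATE:
                serial += 1
                atoms.append(
                    Atom(serial=serial, name=name, element=element,
                         coords=(x0 + dx, y0 + dy, dz), occupancy=1.0, altloc="",
                         chain_id=chain_id, res_seq=seq, icode="", res_name="ALA",
                         record="ATOM")
                )
                if chain_index == 0 and name == "CA":
                    ca_anchors.append((x0 + 1.200, y0 + 0.800))

    chain_order = [cid for cid, _ in spec.chains]
    het_chain = "X" if "X" not in chain_order else "Z"
    het_seq = 0

    def add_het(res_name: str, atom_specs: list[tuple[str, str, tuple[float, float, float]]]):
        nonlocal serial, het_seq
        het_seq += 1
        for name, element, xyz in atom_specs:
            serial += 1
            atoms.append(
                Atom(serial=serial, name=name, element=element, coords=xyz,
                     occupancy=1.0, altloc="", chain_id=het_chain, res_seq=het_seq,
                     icode="", res_name=res_name, record="HETATM")
            )

    # Ions hang directly below CA anchors of chain 1; the anchor CA is
    # then the unique nearest protein atom, at exactly the spec distance.
    anchor_iter = iter(ca_anchors)
    for element, dist in spec.ions:
        ax, ay = next(anchor_iter)
        code = element.strip().upper()
        add_het(code, [(code, code, (ax, ay, -dist))])
        if code in ION_WHITELIST and dist < 2.0:
            manifest["expected_structural_ions"].append((code, dist))
        else:
            manifest["expected_nonstructural_ions"].append((code, dist))
            manifest["expected_removed"]["nonstructural_ions"] += 1

    # remaining heteroatoms live far below the complex, away from ions
    z_far = -8.0
    for w in range(spec.n_waters):
        add_het("HOH", [("O", "O", (4.0 * w, -6.0, z_far))])
    for l in range(spec.n_ligand_residues):
        x0 = 4.0 * l
        add_het("LIG", [("C1", "C", (x0, -12.0, z_far)),
                        ("C2", "C", (x0 + 1.5, -12.0, z_far)),
                        ("O1", "O", (x0, -13.2, z_far))])
    for s in range(spec.n_sugar_residues):
        x0 = 4.0 * s
        add_het("NAG", [("C1", "C", (x0, -18.0, z_far)),
                        ("O5", "O", (x0 + 1.4, -18.0, z_far)),
                        ("N2", "N", (x0, -19.4, z_far))])

    if het_seq:
        chain_order = chain_order + [het_chain]
    model = StructureModel(
        atoms=atoms, chain_order=chain_order, resolution=1.8, id=f"synthetic-{spec.seed}"
    )
    manifest["n_atoms"] = len(atoms)
    manifest["n_protein_atoms"] = sum(1 for a in atoms if a.record == "ATOM")
    return model, manifest


def make_pdb(spec: SyntheticStructureSpec, path: str | Path) -> dict:
    """Write the synthetic complex as a PDB file; return the manifest."""
    model, manifest = build_structure(spec)
    write_pdb(model, path)
    return manifest


@dataclass(frozen=True)
class SyntheticTableSpec:
    """Recipe for a labeled synthetic descriptor table.

    Labels follow ``y = dg_mean + w . x_active (+ nonlinearity) + noise``
    with standard-normal features. When ``weights`` is None, active-feature
    weights are drawn once (seeded) and rescaled so that sd(y) is close to
    ``dg_sd`` — with the defaults, labels mimic a Gaussian binding
    free-energy distribution centered at -10 kcal/mol with 2.5 kcal/mol
    spread (roughly the micromolar-to-picomolar affinity window).
    """

    n: int = 300
    schema: FeatureSchema | None = None
    n_active: int = 6
    weights: tuple[float, ...] | None = None
    noise_sd: float = 1.0
    nonlinearity: str = "none"  # none | quadratic | interaction
    dg_mean: float = -10.0
    dg_sd: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.nonlinearity not in ("none", "quadratic", "interaction"):
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")
        if self.n < 2:
            raise ValueError("need at least 2 rows")


def make_table(spec: SyntheticTableSpec) -> tuple[LabeledTable, dict]:
    """Generate the table and its ground truth (weights, noise sd, ids)."""
    schema = spec.schema or default_schema()
    m = len(schema)
    n_active = min(spec.n_active, m)
    rng = np.random.default_rng(spec.seed)
    X = rng.standard_normal((spec.n, m))
    active = np.arange(n_active)

    if spec.weights is not None:
        w = np.asarray(spec.weights, dtype=float)
        if w.shape != (n_active,):
            raise ValueError(f"weights must have length n_active={n_active}")
    elif n_active == 0:
        w = np.zeros(0)
    else:
        w = rng.standard_normal(n_active)
        signal_var = max(spec.dg_sd**2 - spec.noise_sd**2, 0.25)
        w *= np.sqrt(signal_var) / np.linalg.norm(w)

    signal = X[:, active] @ w
    if spec.nonlinearity == "quadratic" and n_active:
        signal = signal + 0.5 * (X[:, active] ** 2 - 1.0) @ w
    elif spec.nonlinearity == "interaction" and n_active >= 2:
        signal = signal + 0.5 * abs(w).mean() * X[:, active[0]] * X[:, active[1]]

    y = spec.dg_mean + signal + rng.normal(0.0, spec.noise_sd, size=spec.n)
    ids = [f"cpx{i:04d}" for i in range(spec.n)]
    frame = pd.DataFrame(X, columns=list(schema.names), index=ids)
    frame[LABEL_COLUMN] = y
    table = LabeledTable(schema=schema, frame=frame)
    truth = {
        "weights": w,
        "active_features": [schema.names[i] for i in active],
        "noise_sd": spec.noise_sd,
        "dg_mean": spec.dg_mean,
        "seed": spec.seed,
    }
    return table, truth
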