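"""Interface-descriptor schema, provider contract, and table I/O.

Each complex is summarized by an ordered vector of numeric interface
descriptors (contact molecular surface, interface-analyzer metrics,
per-term interface energies). The production descriptors come from an
external macromolecular-modelling engine; this package treats descriptor
computation as a *provider contract*:

- :class:`EngineDescriptorProvider` adapts such an engine and fails with an
  explicit capability error when none is installed — never a silent
  fallback;
- :class:`SyntheticDescriptorProvider` derives a deterministic vector from
  a content hash of the structure, so every downstream stage is testable
  without the engine.

The default 52-name schema shipped with the package is a synthetic
stand-in that follows the field's naming conventions; it is data, not
code, and can be replaced verbatim by a production list.

Labeled descriptor tables (features + experimental binding free energy
``dg_exp`` in kcal/mol) are read and written as UTF-8 TSV.
"""

from __future__ import annotations

import hashlib
import shutil
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CapabilityError, SchemaError
from .structure import ComplexSpec, StructureModel

__all__ = [
    "FeatureSchema",
    "DescriptorVector",
    "LabeledTable",
    "default_schema",
    "validate_vector",
    "read_table",
    "write_table",
    "DescriptorProvider",
    "SyntheticDescriptorProvider",
    "EngineDescriptorProvider",
]

LABEL_COLUMN = "dg_exp"


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered, named feature list with unit tags."""

    names: tuple[str, ...]
    units: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.units):
            raise SchemaError("names and units must have equal length")
        if len(set(self.names)) != len(self.names):
            raise SchemaError("feature names must be unique")
        if not self.names:
            raise SchemaError("schema must have at least one feature")

    def __len__(self) -> int:
        return len(self.names)

    @classmethod
    def from_file(cls, path: str | Path) -> "FeatureSchema":
        names, units = [], []
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            names.append(parts[0])
            units.append(parts[1] if len(parts) > 1 else "dimensionless")
        return cls(names=tuple(names), units=tuple(units))

    def to_file(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for n, u in zip(self.names, self.units):
                fh.write(f"{n}\t{u}\n")


def default_schema() -> FeatureSchema:
    """The packaged 52-feature schema (synthetic stand-in list)."""
    ref = resources.files("slbind.data") / "schema_52_synthetic.tsv"
    with resources.as_file(ref) as path:
        return FeatureSchema.from_file(path)


@dataclass(frozen=True)
class DescriptorVector:
    """One complex's descriptor values, ordered per schema."""

    schema: FeatureSchema
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        violations = validate_vector(self.schema, dict(zip(self.schema.names, v)))
        if violations:
            raise SchemaError("; ".join(violations))

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.schema.names))


def validate_vector(schema: FeatureSchema, values: dict[str, float]) -> list[str]:
    """Check a name->value mapping against the schema; return violations."""
    violations = []
    for name in schema.names:
        if name not in values:
            violations.append(f"missing feature {name!r}")
        elif not np.isfinite(values[name]):
            violations.append(f"non-finite value for {name!r}: {values[name]!r}")
    extra = set(values) - set(schema.names)
    if extra:
        violations.append(f"unknown features: {sorted(extra)}")
    return violations


@dataclass
class LabeledTable:
    """Descriptor matrix plus experimental labels, indexed by complex id."""

    schema: FeatureSchema
    frame: pd.DataFrame  # columns = schema.names + [dg_exp], index = ids

    def __post_init__(self) -> None:
        expected = list(self.schema.names) + [LABEL_COLUMN]
        if list(self.frame.columns) != expected:
            raise SchemaError(
                f"table columns do not match schema (+'{LABEL_COLUMN}'): "
                f"got {list(self.frame.columns)[:5]}..."
            )
        if self.frame.index.has_duplicates:
            dupes = self.frame.index[self.frame.index.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate complex ids: {dupes}")
        if not np.isfinite(self.frame.to_numpy(dtype=float)).all():
            raise SchemaError("table contains non-finite values")

    @property
    def X(self) -> pd.DataFrame:
        return self.frame[list(self.schema.names)]

    @property
    def y(self) -> pd.Series:
        return self.frame[LABEL_COLUMN]

    def __len__(self) -> int:
        return len(self.frame)


def read_table(path: str | Path, schema: FeatureSchema | None = None) -> LabeledTable:
    """Read a labeled TSV descriptor table.

    When no schema is given, it is reconstructed from the header (all
    columns before ``dg_exp``, unit tags unknown).
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if LABEL_COLUMN not in frame.columns:
        raise SchemaError(f"table lacks the '{LABEL_COLUMN}' label column")
    if schema is None:
        names = tuple(c for c in frame.columns if c != LABEL_COLUMN)
        schema = FeatureSchema(names=names, units=("unknown",) * len(names))
    return LabeledTable(schema=schema, frame=frame)


def write_table(table: LabeledTable, path: str | Path) -> None:
    """Write a labeled table as TSV, lossless to full float precision."""
    table.frame.to_csv(path, sep="\t", index_label="id", float_format="%.17g")


# ---------------------------------------------------------------------------
# Providers


class DescriptorProvider:
    """Contract: map a preprocessed complex to a DescriptorVector."""

    schema: FeatureSchema

    def compute(self, model: StructureModel, spec: ComplexSpec) -> DescriptorVector:
        raise NotImplementedError


class SyntheticDescriptorProvider(DescriptorProvider):
    """Deterministic descriptors from a content hash of the structure.

    The vector is standard normal noise seeded by a SHA-256 digest of the
    complex id, the chain/residue composition, the partner definition and
    the schema names — identical inputs always give identical vectors, and
    any structural change changes the vector. Values carry no physical
    meaning; the provider exists so the pipeline is exercisable end to end
    without the external engine.
    """

    def __init__(self, schema: FeatureSchema | None = None, seed: int = 0) -> None:
        self.schema = schema or default_schema()
        self.seed = seed

    def compute(self, model: StructureModel, spec: ComplexSpec) -> DescriptorVector:
        h = hashlib.sha256()
        h.update(str(self.seed).encode())
        h.update(model.id.encode())
        for name in self.schema.names:
            h.update(name.encode())
        for chain_id, atoms in sorted(model.chains().items()):
            h.update(chain_id.encode())
            h.update(str(len(atoms)).encode())
            for a in atoms:
                h.update(f"{a.res_name}{a.res_seq}{a.name}".encode())
                h.update(np.round(np.asarray(a.coords), 3).tobytes())
        h.update(",".join(sorted(spec.partner1)).encode())
        h.update(",".join(sorted(spec.partner2)).encode())
        derived = int.from_bytes(h.digest()[:4], "little")
        rng = np.random.default_rng(derived)
        return DescriptorVector(schema=self.schema, values=rng.standard_normal(len(self.schema)))


class EngineDescriptorProvider(DescriptorProvider):
    """Adapter for an external descriptor engine.

    The engine performs geometry optimization (constrained then all-atom
    minimization with His/Asn/Gln flip sampling during hydrogen placement)
    and computes the interface metrics, activating metal setup when
    structural ions are present. The adapter only shells out to it; when
    the executable is absent, :meth:`compute` raises a capability error —
    descriptor values are never fabricated.
    """

    def __init__(self, schema: FeatureSchema | None = None, executable: str = "") -> None:
        self.schema = schema or default_schema()
        self.executable = executable

    def available(self) -> bool:
        return bool(self.executable) and shutil.which(self.executable) is not None

    def compute(self, model: StructureModel, spec: ComplexSpec) -> DescriptorVector:
        if not self.available():
            raise CapabilityError(
                "descriptor engine unavailable"
                + (f" (executable {self.executable!r} not found)" if self.executable else "")
                + "; install the engine or use the synthetic provider for testing"
            )
        raise CapabilityError(
            f"engine adapter protocol not configured for {self.executable!r}"
        )  # pragma: no cover - requires an installed engine
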